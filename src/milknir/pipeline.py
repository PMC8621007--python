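"""End-to-end orchestration: simulate/load -> split -> grid training ->
wavelength selection -> validation -> cross-spectrometer comparison.

One :class:`PipelineConfig` drives the whole analysis for every requested
(spectrometer window x milk component) combination and writes all artifacts
(split assignment, ranked grid, selection report, evaluation summary,
serialized models, manifest) under one output directory.  Identical config +
seed reproduces byte-identical CSV output; timestamps live only in the log.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import (COMPONENTS, STANDARD_WINDOWS, CompositionTable,
                      SpectralDataset, read_dataset)
from .errors import ConfigError
from .evaluation import EvalResult, compare_spectrometers, evaluate_predictions
from .model_selection import (SelectionConfig, evaluate_grid, grid_frame,
                              make_cv_folds, select_chain)
from .plsr import fit_plsr, predict
from .preprocessing import enumerate_chains, fast_chains
from .split import duplex_split
from .synthetic import SyntheticConfig, simulate_dataset
from .variable_selection import (VariableSelectionConfig, choose_selection,
                                 fipls, full_spectrum, jackknife_select,
                                 ripls, selection_frame, vip_select)

log = logging.getLogger("milknir")

_SELECTORS = {
    "VIP": vip_select,
    "JK": jackknife_select,
    "RiPLS": ripls,
    "FiPLS": fipls,
}


@dataclass
class PipelineConfig:
    """Everything needed for one full analysis run."""

    components: tuple[str, ...] = ("fat", "protein", "lactose")
    windows: tuple[str, ...] = ("NIRONE_2.5_T",)
    grid: str = "fast"                     # full | fast
    alpha: float = 0.05
    max_latent: int = 20
    k_folds: int = 10
    vip_threshold: float = 1.0
    n_intervals: int = 20
    selection_methods: tuple[str, ...] = ("VIP", "JK", "RiPLS", "FiPLS")
    out_dir: str = "milknir_out"
    seed: int = 0
    # synthetic mode (default); set spectra_path/composition_path to load CSVs
    synthetic: SyntheticConfig | None = None
    spectra_path: str | None = None
    composition_path: str | None = None

    def __post_init__(self) -> None:
        if not self.components:
            raise ConfigError("at least one milk component must be requested")
        unknown = set(self.components) - set(COMPONENTS)
        if unknown:
            raise ConfigError(f"unknown components: {sorted(unknown)}")
        if self.grid not in ("full", "fast"):
            raise ConfigError(f"grid must be 'full' or 'fast', got {self.grid!r}")
        bad = [m for m in self.selection_methods if m not in _SELECTORS]
        if bad:
            raise ConfigError(f"unknown selection methods: {bad}")
        if self.spectra_path is None and self.synthetic is None:
            self.synthetic = SyntheticConfig(seed=self.seed)
        if self.spectra_path is not None and self.composition_path is None:
            raise ConfigError("composition_path required when spectra_path is set")
        for w in self.windows:
            if self.spectra_path is None and w not in STANDARD_WINDOWS:
                raise ConfigError(f"unknown window {w!r}; known: {sorted(STANDARD_WINDOWS)}")

    def selection_config(self) -> VariableSelectionConfig:
        return VariableSelectionConfig(
            alpha=self.alpha, max_latent=self.max_latent, k_folds=self.k_folds,
            vip_threshold=self.vip_threshold, n_intervals=self.n_intervals,
        )

    def config_hash(self) -> str:
        blob = json.dumps(_config_dict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    return d


def _acquire_datasets(cfg: PipelineConfig) -> dict[str, tuple[SpectralDataset, CompositionTable]]:
    """One dataset per window; synthetic windows share compositions and cows."""
    datasets = {}
    if cfg.spectra_path is not None:
        ds, comp = read_dataset(cfg.spectra_path, cfg.composition_path)
        label = cfg.windows[0] if cfg.windows else (ds.instrument_label or "input")
        datasets[label] = (ds, comp)
        return datasets
    base = cfg.synthetic
    for name in cfg.windows:
        window = STANDARD_WINDOWS[name]
        emit = "reflectance" if window.geometry == "reflectance" else base.emit_mode
        wcfg = replace(base, window=window, emit_mode=emit)
        ds, comp, _ = simulate_dataset(wcfg)   # same seed -> same compositions
        datasets[name] = (ds, comp)
    return datasets


@dataclass
class TrainedCombination:
    """All artifacts of one (window, component) model build."""

    window: str
    component: str
    grid: pd.DataFrame
    chain_label: str
    selection: pd.DataFrame
    chosen_method: str
    model_json: dict
    eval_result: EvalResult
    scatter: pd.DataFrame = field(repr=False)


def train_one(window: str, ds_cal: SpectralDataset, y_cal: np.ndarray,
              ds_val: SpectralDataset, y_val: np.ndarray, component: str,
              cfg: PipelineConfig) -> TrainedCombination:
    """Grid search, chain selection, wavelength selection and validation for
    one (window, component) combination."""
    sel_cfg = cfg.selection_config()
    folds = make_cv_folds(ds_cal.cow_ids, k=cfg.k_folds, seed=cfg.seed)
    wl = ds_cal.wavelengths_nm
    chains = enumerate_chains() if cfg.grid == "full" else fast_chains()

    rows = evaluate_grid(
        chains, ds_cal.intensities, y_cal, folds, sel_cfg, wavelengths=wl,
        on_chain=lambda lbl, a, r: log.info(
            "%s/%s chain %s: A=%d RMSECV=%.4g", window, component, lbl, a, r),
    )
    chosen = select_chain(rows, sel_cfg)
    log.info("%s/%s selected chain %s (A=%d, RMSECV=%.4g)",
             window, component, chosen.label, chosen.n_latent, chosen.rmsecv)

    candidates = [full_spectrum(chosen.chain, ds_cal.intensities, y_cal, folds,
                                sel_cfg, wavelengths=wl)]
    for name in cfg.selection_methods:
        candidates.append(_SELECTORS[name](
            chosen.chain, ds_cal.intensities, y_cal, folds, sel_cfg,
            wavelengths=wl, n_latent=chosen.n_latent,
        ))
    picked = choose_selection(candidates, sel_cfg)
    log.info("%s/%s selected wavelengths via %s (%d WL, A=%d, RMSECV=%.4g)",
             window, component, picked.method, picked.n_retained,
             picked.n_latent, picked.rmsecv)

    # final fit on the whole calibration set, applied once to validation
    fitted = chosen.chain.fit(ds_cal.intensities, y_cal, wavelengths=wl)
    X_cal_p = fitted.X_cal_processed[:, picked.mask]
    model = fit_plsr(X_cal_p, y_cal, picked.n_latent,
                     wavelength_mask=picked.mask, chain_label=chosen.label)
    X_val_p = fitted.transform(ds_val.intensities)[:, picked.mask]
    y_val_pred = predict(model, X_val_p)

    result = evaluate_predictions(
        component, window, y_val, y_val_pred,
        rmsecv=picked.rmsecv, r2cv=float(picked.cv.r2cv[picked.n_latent - 1]),
    )
    a_cv = picked.n_latent
    scatter = pd.DataFrame({
        "sample_id": np.concatenate([ds_cal.sample_ids, ds_val.sample_ids]),
        "set": ["cal"] * len(y_cal) + ["val"] * len(y_val),
        "reference": np.concatenate([y_cal, y_val]),
        "prediction": np.concatenate(
            [picked.cv.predictions[:, a_cv - 1], y_val_pred]),
    })
    return TrainedCombination(
        window=window, component=component,
        grid=grid_frame(rows), chain_label=chosen.label,
        selection=selection_frame(candidates, wl), chosen_method=picked.method,
        model_json=model.to_dict(), eval_result=result, scatter=scatter,
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis and write all artifacts under ``out_dir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    datasets = _acquire_datasets(cfg)

    # the duplex split depends only on the compositions, shared across windows
    first_ds, first_comp = next(iter(datasets.values()))
    split = duplex_split(first_comp, first_ds.cow_ids)
    split.assignment_frame().to_csv(out / "split.csv", index=False)
    split.stats.to_csv(out / "split_stats.csv", index=False, float_format="%.6g")
    log.info("duplex split: %d calibration cows, %d validation cows",
             len(split.calibration_cows), len(split.validation_cows))

    results: list[TrainedCombination] = []
    for window, (ds, comp) in datasets.items():
        cal_mask = np.isin(ds.sample_ids, split.calibration_sample_ids)
        ds_cal = SpectralDataset(ds.wavelengths_nm, ds.intensities[cal_mask],
                                 ds.mode, ds.sample_ids[cal_mask],
                                 ds.cow_ids[cal_mask], ds.instrument_label)
        ds_val = SpectralDataset(ds.wavelengths_nm, ds.intensities[~cal_mask],
                                 ds.mode, ds.sample_ids[~cal_mask],
                                 ds.cow_ids[~cal_mask], ds.instrument_label)
        for component in cfg.components:
            y_cal = comp.subset(ds_cal.sample_ids).component(component)
            y_val = comp.subset(ds_val.sample_ids).component(component)
            try:
                res = train_one(window, ds_cal, y_cal, ds_val, y_val, component, cfg)
            except Exception:
                log.exception("stage train failed for %s/%s", window, component)
                raise
            tag = f"{window}_{component}"
            res.grid.to_csv(out / f"grid_{tag}.csv", index=False, float_format="%.8g")
            res.selection.to_csv(out / f"selection_{tag}.csv", index=False,
                                 float_format="%.8g")
            res.scatter.to_csv(out / f"scatter_{tag}.csv", index=False,
                               float_format="%.8g")
            (out / f"model_{tag}.json").write_text(json.dumps(res.model_json))
            results.append(res)

    summary = pd.DataFrame([r.eval_result.summary() for r in results])
    summary.insert(2, "chain", [r.chain_label for r in results])
    summary.insert(3, "selection", [r.chosen_method for r in results])
    summary.to_csv(out / "evaluation.csv", index=False, float_format="%.6g")

    # cross-spectrometer comparison per component (complete validation matrix)
    comparisons = {}
    if len(datasets) > 1:
        for component in cfg.components:
            cols = {}
            for r in results:
                if r.component == component:
                    cols[r.window] = (r.eval_result.y_val - r.eval_result.y_val_pred) ** 2
            frame = pd.DataFrame(cols)
            comp_res = compare_spectrometers(frame, alpha=cfg.alpha)
            comp_res.anova.to_csv(out / f"anova_{component}.csv", float_format="%.8g")
            comp_res.tukey.to_csv(out / f"tukey_{component}.csv", index=False,
                                  float_format="%.8g")
            comparisons[component] = comp_res.letters

    manifest = {
        "package": "milknir",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_models": len(results),
        "windows": list(datasets),
        "components": list(cfg.components),
        "letters": comparisons,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def load_pipeline_config(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    syn = raw.pop("synthetic", None)
    for key in ("components", "windows", "selection_methods"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    cfg = PipelineConfig(**raw)
    if syn is not None:
        cfg.synthetic = SyntheticConfig(**syn, seed=cfg.seed) \
            if "seed" not in syn else SyntheticConfig(**syn)
    return cfg
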