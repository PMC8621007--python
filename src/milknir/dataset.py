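"""Data model and I/O for NIR spectra and milk composition references.

A :class:`SpectralDataset` holds a samples-by-wavelengths intensity matrix
together with sample and cow identifiers; a :class:`CompositionTable` holds the
per-sample fat/protein/lactose reference values (% w/w) produced by the
laboratory analysis.  The two are linked by ``sample_id``.

Instrument-side corrections live here as well: white/dark standard
referencing, replicate-scan averaging, and restriction of a wide wavelength
grid to one spectrometer's physical window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError

MODES = ("raw", "transmittance", "reflectance", "absorbance")

COMPONENTS = ("fat", "protein", "lactose")


@dataclass(frozen=True)
class InstrumentWindow:
    """Physical wavelength window of one spectrometer.

    Parameters
    ----------
    name : str
        Human-readable instrument label, e.g. ``"NIRONE 2.5 T"``.
    lo_nm, hi_nm : float
        Closed-interval wavelength bounds in nm.
    geometry : str
        ``"transmittance"`` or ``"reflectance"``.
    """

    name: str
    lo_nm: float
    hi_nm: float
    geometry: str = "transmittance"

    def __post_init__(self) -> None:
        if not self.lo_nm < self.hi_nm:
            raise SchemaError(f"window {self.name!r}: lo_nm must be < hi_nm")
        if self.geometry not in ("transmittance", "reflectance"):
            raise SchemaError(f"window {self.name!r}: bad geometry {self.geometry!r}")


#: The four spectrometer windows emulated by the synthetic generator, plus the
#: benchtop benchmark: three MEMS Fabry-Perot modules in transmittance, one in
#: reflectance, and a diode-array instrument covering 960-1690 nm.
STANDARD_WINDOWS: dict[str, InstrumentWindow] = {
    "NIRONE_1.4_T": InstrumentWindow("NIRONE_1.4_T", 1100.0, 1400.0, "transmittance"),
    "NIRONE_2.0_T": InstrumentWindow("NIRONE_2.0_T", 1550.0, 1950.0, "transmittance"),
    "NIRONE_2.5_T": InstrumentWindow("NIRONE_2.5_T", 2000.0, 2450.0, "transmittance"),
    "NIRONE_2.0_R": InstrumentWindow("NIRONE_2.0_R", 1550.0, 1950.0, "reflectance"),
    "TEC5_T": InstrumentWindow("TEC5_T", 960.0, 1690.0, "transmittance"),
}


@dataclass
class SpectralDataset:
    """Spectra of a set of milk samples on a common wavelength grid."""

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    mode: str
    sample_ids: np.ndarray
    cow_ids: np.ndarray
    instrument_label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.sample_ids = np.asarray(self.sample_ids)
        self.cow_ids = np.asarray(self.cow_ids)
        if self.mode not in MODES:
            raise SchemaError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        w = self.wavelengths_nm
        if w.ndim != 1 or w.size == 0:
            raise SchemaError("wavelengths_nm must be a non-empty 1-D sequence")
        if np.any(np.diff(w) <= 0):
            raise SchemaError("wavelengths_nm must be strictly increasing")
        n, p = self.intensities.shape
        if p != w.size:
            raise SchemaError(
                f"intensities has {p} columns but {w.size} wavelengths given"
            )
        if len(self.sample_ids) != n or len(self.cow_ids) != n:
            raise SchemaError("sample_ids/cow_ids length must match intensity rows")
        if len(set(map(str, self.sample_ids))) != n:
            raise SchemaError("sample_ids must be unique")
        if self.mode != "raw" and not np.all(np.isfinite(self.intensities)):
            raise SchemaError(f"mode={self.mode}: all intensities must be finite")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.intensities.shape[1]


@dataclass
class CompositionTable:
    """Per-sample reference milk composition in % w/w."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = ["sample_id", "fat_pct", "protein_pct", "lactose_pct"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise SchemaError(f"composition table missing columns: {missing}")
        tab = self.table.reset_index(drop=True)
        if tab["sample_id"].astype(str).duplicated().any():
            dup = tab.loc[tab["sample_id"].astype(str).duplicated(), "sample_id"]
            raise SchemaError(f"duplicate sample_id in composition table: {list(dup)[:5]}")
        vals = tab[["fat_pct", "protein_pct", "lactose_pct"]].to_numpy(float)
        if not np.all(np.isfinite(vals)):
            raise SchemaError("composition values must be finite")
        if np.any(vals <= 0) or np.any(vals >= 100):
            raise SchemaError("composition values must lie strictly in (0, 100) % w/w")
        self.table = tab

    @property
    def sample_ids(self) -> np.ndarray:
        return self.table["sample_id"].to_numpy()

    def values(self) -> np.ndarray:
        """Return the (n_samples, 3) matrix of fat/protein/lactose values."""
        return self.table[["fat_pct", "protein_pct", "lactose_pct"]].to_numpy(float)

    def component(self, name: str) -> np.ndarray:
        if name not in COMPONENTS:
            raise SchemaError(f"unknown component {name!r}; expected one of {COMPONENTS}")
        return self.table[f"{name}_pct"].to_numpy(float)

    def subset(self, sample_ids) -> "CompositionTable":
        idx = self.table.set_index(self.table["sample_id"].astype(str))
        rows = idx.loc[[str(s) for s in sample_ids]]
        return CompositionTable(rows.reset_index(drop=True))


# ---------------------------------------------------------------------------
# CSV I/O
#
# spectra CSV:      sample_id,cow_id,mode,<nm1>,<nm2>,...   (one row per sample)
# composition CSV:  sample_id,fat_pct,protein_pct,lactose_pct
# ---------------------------------------------------------------------------

_META_COLS = ("sample_id", "cow_id", "mode")


def write_dataset(ds: SpectralDataset, comp: CompositionTable | None,
                  spectra_path, composition_path=None) -> None:
    """Write a dataset (and optionally its composition table) to CSV."""
    cols = {c: None for c in _META_COLS}
    cols["sample_id"] = ds.sample_ids
    cols["cow_id"] = ds.cow_ids
    cols["mode"] = [ds.mode] * ds.n_samples
    frame = pd.DataFrame(cols)
    for j, w in enumerate(ds.wavelengths_nm):
        frame[format(w, ".10g")] = ds.intensities[:, j]
    frame.to_csv(spectra_path, index=False, float_format="%.17g")
    if comp is not None:
        if composition_path is None:
            raise SchemaError("composition_path required when writing a composition table")
        comp.table.to_csv(composition_path, index=False, float_format="%.17g")


def read_spectra(spectra_path, instrument_label: str = "") -> SpectralDataset:
    frame = pd.read_csv(spectra_path)
    for c in _META_COLS:
        if c not in frame.columns:
            raise SchemaError(f"spectra CSV missing column {c!r}")
    wl_cols = [c for c in frame.columns if c not in _META_COLS]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise SchemaError(f"non-numeric wavelength header in spectra CSV: {exc}") from exc
    modes = frame["mode"].unique()
    if len(modes) != 1:
        raise SchemaError(f"spectra CSV mixes acquisition modes: {list(modes)}")
    return SpectralDataset(
        wavelengths_nm=wavelengths,
        intensities=frame[wl_cols].to_numpy(float),
        mode=str(modes[0]),
        sample_ids=frame["sample_id"].to_numpy(),
        cow_ids=frame["cow_id"].to_numpy(),
        instrument_label=instrument_label,
    )


def read_dataset(spectra_path, composition_path, strict: bool = True,
                 instrument_label: str = "") -> tuple[SpectralDataset, CompositionTable]:
    """Read and align a spectra CSV with its composition CSV.

    With ``strict=True`` any sample present in only one of the two files raises
    a :class:`SchemaError`; with ``strict=False`` unmatched samples are dropped
    from both sides.
    """
    ds = read_spectra(spectra_path, instrument_label=instrument_label)
    comp = CompositionTable(pd.read_csv(composition_path))
    ds_ids = [str(s) for s in ds.sample_ids]
    comp_ids = [str(s) for s in comp.sample_ids]
    common = [s for s in ds_ids if s in set(comp_ids)]
    if strict and (len(common) != len(ds_ids) or len(common) != len(comp_ids)):
        only_spec = sorted(set(ds_ids) - set(comp_ids))
        only_comp = sorted(set(comp_ids) - set(ds_ids))
        raise SchemaError(
            f"sample_id mismatch between files: {len(only_spec)} only in spectra "
            f"(e.g. {only_spec[:3]}), {len(only_comp)} only in composition "
            f"(e.g. {only_comp[:3]})"
        )
    if len(common) == 0:
        raise SchemaError("no sample_id shared between spectra and composition files")
    keep = np.array([s in set(comp_ids) for s in ds_ids])
    ds = SpectralDataset(
        wavelengths_nm=ds.wavelengths_nm,
        intensities=ds.intensities[keep],
        mode=ds.mode,
        sample_ids=ds.sample_ids[keep],
        cow_ids=ds.cow_ids[keep],
        instrument_label=ds.instrument_label,
    )
    comp = comp.subset(ds.sample_ids)  # align row order to the spectra
    return ds, comp


# ---------------------------------------------------------------------------
# Instrument-side corrections
# ---------------------------------------------------------------------------

def standard_correct(sample_raw: np.ndarray, white_raw: np.ndarray,
                     dark_raw: np.ndarray) -> np.ndarray:
    """Reference raw detector counts against white and dark standards.

    Returns ``(S - D) / (W - D)`` elementwise, i.e. the transmittance (or
    reflectance, depending on geometry) relative to the white standard.
    """
    sample = np.atleast_2d(np.asarray(sample_raw, dtype=float))
    white = np.asarray(white_raw, dtype=float).ravel()
    dark = np.asarray(dark_raw, dtype=float).ravel()
    if sample.shape[1] != white.size or white.size != dark.size:
        raise SchemaError("sample, white and dark must share one wavelength grid")
    denom = white - dark
    bad = np.flatnonzero(denom == 0)
    if bad.size:
        raise DomainError(
            f"white and dark standards coincide at wavelength index(es) {bad[:5].tolist()}"
        )
    out = (sample - dark) / denom
    return out if np.asarray(sample_raw).ndim > 1 else out[0]


def average_scans(scans: np.ndarray) -> np.ndarray:
    """Average k replicate scans of one sample into a single spectrum."""
    scans = np.atleast_2d(np.asarray(scans, dtype=float))
    if scans.shape[0] == 0:
        raise DomainError("cannot average an empty set of scans")
    return scans.mean(axis=0)


def restrict_wavelengths(ds: SpectralDataset, window: InstrumentWindow) -> SpectralDataset:
    """Keep only wavelengths inside the closed interval [lo_nm, hi_nm]."""
    keep = (ds.wavelengths_nm >= window.lo_nm) & (ds.wavelengths_nm <= window.hi_nm)
    if not keep.any():
        raise DomainError(
            f"window {window.name!r} [{window.lo_nm}, {window.hi_nm}] nm does not "
            f"overlap the grid [{ds.wavelengths_nm[0]}, {ds.wavelengths_nm[-1]}] nm"
        )
    return replace(
        ds,
        wavelengths_nm=ds.wavelengths_nm[keep],
        intensities=ds.intensities[:, keep],
    )
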