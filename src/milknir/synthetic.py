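"""Synthetic raw-milk NIR dataset generator.

Emulates the statistical structure the calibration pipeline assumes: milk
compositions with realistic herd-level moments and within-cow clustering,
Beer-Lambert absorption from Gaussian component bands over an instrument
window, per-sample multiplicative/additive scatter distortion (fat-globule
light scattering), and additive detector noise.

The band library is a set of fictional-but-plausible generator parameters
placed near known NIR overtone/combination regions (fat C-H around 1210, 1725
and 2310 nm; water O-H near 1450 and 1940 nm; protein and lactose combination
bands in the 2000-2300 nm range).  It is configuration, not a claim about any
particular instrument, and every value can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import COMPONENTS, CompositionTable, InstrumentWindow, SpectralDataset
from .errors import ConfigError

__all__ = [
    "Band",
    "CompositionMoments",
    "SyntheticConfig",
    "GroundTruth",
    "sample_compositions",
    "generate_spectra",
    "simulate_dataset",
    "DEFAULT_MOMENTS",
    "DEFAULT_BANDS",
    "DEFAULT_WATER_BANDS",
]


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band: A(lambda) = amplitude * exp(-((l-c)/w)^2/2).

    ``amplitude`` is an absorptivity-like coefficient in absorbance units per
    (% w/w of component) per mm of optical path.
    """

    center_nm: float
    width_nm: float
    amplitude: float

    def absorptivity(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        z = (np.asarray(wavelengths_nm, float) - self.center_nm) / self.width_nm
        return self.amplitude * np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class CompositionMoments:
    """Target herd-level moments for one milk component (% w/w)."""

    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min < self.mean < self.max):
            raise ConfigError(f"need min < mean < max, got {self}")
        if self.sd < 0:
            raise ConfigError("sd must be >= 0")


# Herd-level composition moments of the farm campaign that this generator
# emulates: 299 samples from 71 cows, fat the most variable component,
# lactose the least.
DEFAULT_MOMENTS: dict[str, CompositionMoments] = {
    "fat": CompositionMoments(mean=4.715, sd=1.107, min=1.71, max=7.7),
    "protein": CompositionMoments(mean=3.899, sd=0.415, min=2.99, max=5.07),
    "lactose": CompositionMoments(mean=4.62, sd=0.154, min=4.09, max=5.1),
}

DEFAULT_BANDS: dict[str, tuple[Band, ...]] = {
    # fat: C-H second overtone near 1210, first overtone doublet near
    # 1725/1765, combination bands near 2310/2350 nm
    "fat": (
        Band(1210.0, 35.0, 0.030),
        Band(1725.0, 30.0, 0.045),
        Band(1765.0, 30.0, 0.035),
        Band(2310.0, 25.0, 0.050),
        Band(2350.0, 25.0, 0.040),
    ),
    # protein: N-H/amide combination bands
    "protein": (
        Band(1500.0, 45.0, 0.008),
        Band(1690.0, 40.0, 0.008),
        Band(2055.0, 40.0, 0.016),
        Band(2180.0, 40.0, 0.018),
    ),
    # lactose: O-H/C-H combination bands of the dissolved sugar
    "lactose": (
        Band(1590.0, 45.0, 0.006),
        Band(2100.0, 35.0, 0.014),
        Band(2270.0, 35.0, 0.016),
    ),
}

# Water dominates raw milk (~87-89 % w/w); its absorptivity per % is kept small
# enough that the simulated transmittance stays measurable through a 1.5 mm
# cuvette, which is what a short-pathlength transmission cell achieves.
DEFAULT_WATER_BANDS: tuple[Band, ...] = (
    Band(1190.0, 70.0, 0.0012),
    Band(1450.0, 55.0, 0.0050),
    Band(1790.0, 70.0, 0.0012),
    Band(1940.0, 65.0, 0.0080),
    Band(2450.0, 120.0, 0.0030),
)


@dataclass
class SyntheticConfig:
    """Full parameterization of one synthetic acquisition campaign.

    Defaults emulate the farm study conditions: 71 cows with a few samples
    each, compositions matching the herd moments above, a 1.5 mm cuvette,
    mild per-sample scatter distortion and low detector noise.
    """

    n_cows: int = 71
    samples_per_cow: int | tuple[int, int] = (3, 5)  # inclusive uniform range
    window: InstrumentWindow = field(
        default_factory=lambda: InstrumentWindow("NIRONE_2.5_T", 2000.0, 2450.0)
    )
    grid_step_nm: float = 5.0
    composition_moments: dict[str, CompositionMoments] = field(
        default_factory=lambda: dict(DEFAULT_MOMENTS)
    )
    cow_effect_sd: dict[str, float] | None = None  # default: half the total SD
    pathlength_mm: float = 1.5
    band_library: dict[str, tuple[Band, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    water_bands: tuple[Band, ...] = DEFAULT_WATER_BANDS
    scatter_slope_sd: float = 0.15
    scatter_offset_sd: float = 0.05
    noise_sd: float = 0.002  # absorbance units
    emit_mode: str = "transmittance"  # or "absorbance"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cows < 1:
            raise ConfigError("n_cows must be >= 1")
        if self.grid_step_nm <= 0 or self.pathlength_mm <= 0:
            raise ConfigError("grid_step_nm and pathlength_mm must be > 0")
        for v in (self.scatter_slope_sd, self.scatter_offset_sd, self.noise_sd):
            if v < 0:
                raise ConfigError("all noise/scatter SDs must be >= 0")
        if self.cow_effect_sd is None:
            self.cow_effect_sd = {
                c: 0.5 * m.sd for c, m in self.composition_moments.items()
            }
        for c, m in self.composition_moments.items():
            if self.cow_effect_sd.get(c, 0.0) > m.sd:
                raise ConfigError(
                    f"{c}: cow_effect_sd ({self.cow_effect_sd[c]}) exceeds total SD ({m.sd})"
                )
        if self.emit_mode not in ("transmittance", "reflectance", "absorbance"):
            raise ConfigError(f"bad emit_mode {self.emit_mode!r}")
        for comp, bands in self.band_library.items():
            for b in bands:
                if not np.isfinite([b.center_nm, b.width_nm, b.amplitude]).all():
                    raise ConfigError(f"non-finite band parameter for {comp!r}: {b}")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        n = int(np.floor((self.window.hi_nm - self.window.lo_nm) / self.grid_step_nm))
        return self.window.lo_nm + self.grid_step_nm * np.arange(n + 1)


@dataclass
class GroundTruth:
    """Bookkeeping of the latent quantities behind one synthetic dataset."""

    samples: pd.DataFrame      # sample_id, cow_id, true comps, scatter slope/offset
    cow_effects: pd.DataFrame  # cow_id, per-component cow-level deviation


def _samples_per_cow(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(cfg.samples_per_cow, int):
        if cfg.samples_per_cow < 1:
            raise ConfigError("samples_per_cow must be >= 1")
        return np.full(cfg.n_cows, cfg.samples_per_cow, dtype=int)
    lo, hi = cfg.samples_per_cow
    if lo < 1 or hi < lo:
        raise ConfigError(f"bad samples_per_cow range {cfg.samples_per_cow}")
    return rng.integers(lo, hi + 1, size=cfg.n_cows)


def sample_compositions(cfg: SyntheticConfig) -> tuple[CompositionTable, GroundTruth]:
    """Draw per-sample compositions with within-cow clustering.

    Each cow receives a normal cow-level deviation (SD = ``cow_effect_sd``);
    samples are then drawn from a truncated normal around the cow mean with
    residual SD chosen so the total SD matches the target moments.  Truncation
    enforces the component's min/max bounds exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    counts = _samples_per_cow(cfg, rng)
    cow_ids = np.array([f"cow{c:03d}" for c in range(cfg.n_cows)])

    cow_eff = {}
    for comp in COMPONENTS:
        sd_cow = cfg.cow_effect_sd[comp]
        cow_eff[comp] = rng.normal(0.0, sd_cow, size=cfg.n_cows) if sd_cow > 0 else np.zeros(cfg.n_cows)

    cow_index = np.repeat(np.arange(cfg.n_cows), counts)
    n_total = cow_index.size
    samples = pd.DataFrame({
        "sample_id": [f"s{k:04d}" for k in range(n_total)],
        "cow_id": cow_ids[cow_index],
    })
    for comp in COMPONENTS:
        m = cfg.composition_moments[comp]
        sd_res = float(np.sqrt(max(m.sd**2 - cfg.cow_effect_sd[comp] ** 2, 0.0)))
        mu = m.mean + cow_eff[comp][cow_index]
        if sd_res == 0.0:
            samples[f"{comp}_pct"] = np.clip(mu, m.min, m.max)
        else:
            a, b = (m.min - mu) / sd_res, (m.max - mu) / sd_res
            samples[f"{comp}_pct"] = stats.truncnorm.rvs(
                a, b, loc=mu, scale=sd_res, random_state=rng
            )
    comp_table = CompositionTable(
        samples[["sample_id", "fat_pct", "protein_pct", "lactose_pct"]].copy()
    )
    truth = GroundTruth(
        samples=samples.copy(),
        cow_effects=pd.DataFrame(
            {"cow_id": cow_ids, **{f"{c}_effect": cow_eff[c] for c in COMPONENTS}}
        ),
    )
    return comp_table, truth


def generate_spectra(cfg: SyntheticConfig, comps: CompositionTable,
                     truth: GroundTruth) -> SpectralDataset:
    """Turn compositions into spectra via Beer-Lambert mixing.

    Absorbance ``A = L * (sum_i c_i eps_i(l) + c_w eps_w(l))`` with the water
    concentration ``c_w = 100 - sum_i c_i`` (% w/w); then a per-sample affine
    scatter distortion ``A' = (1 + slope) * A + offset`` and i.i.d. Gaussian
    detector noise; finally emitted as absorbance or as transmittance
    ``T = 10**(-A')`` per ``cfg.emit_mode``.
    """
    # independent stream so compositions and spectra can be re-generated
    # separately under the same config seed
    rng = np.random.default_rng((cfg.seed, 1))
    wl = cfg.wavelengths_nm
    n = len(comps.sample_ids)

    eps = np.zeros((len(COMPONENTS), wl.size))
    for i, comp in enumerate(COMPONENTS):
        for band in cfg.band_library.get(comp, ()):
            eps[i] += band.absorptivity(wl)
    eps_w = np.zeros(wl.size)
    for band in cfg.water_bands:
        eps_w += band.absorptivity(wl)

    conc = comps.values()                      # (n, 3)
    c_water = 100.0 - conc.sum(axis=1)         # (n,)
    absorb = cfg.pathlength_mm * (conc @ eps + np.outer(c_water, eps_w))

    slope = rng.normal(0.0, cfg.scatter_slope_sd, size=n) if cfg.scatter_slope_sd > 0 else np.zeros(n)
    offset = rng.normal(0.0, cfg.scatter_offset_sd, size=n) if cfg.scatter_offset_sd > 0 else np.zeros(n)
    absorb = (1.0 + slope)[:, None] * absorb + offset[:, None]
    if cfg.noise_sd > 0:
        absorb = absorb + rng.normal(0.0, cfg.noise_sd, size=absorb.shape)

    truth.samples = truth.samples.assign(scatter_slope=slope, scatter_offset=offset)

    if cfg.emit_mode == "absorbance":
        intensities, mode = absorb, "absorbance"
    else:
        intensities, mode = np.power(10.0, -absorb), cfg.emit_mode

    return SpectralDataset(
        wavelengths_nm=wl,
        intensities=intensities,
        mode=mode,
        sample_ids=np.asarray(comps.sample_ids),
        cow_ids=truth.samples["cow_id"].to_numpy(),
        instrument_label=cfg.window.name,
    )


def simulate_dataset(cfg: SyntheticConfig) -> tuple[SpectralDataset, CompositionTable, GroundTruth]:
    """Convenience wrapper: compositions then spectra, both from ``cfg.seed``."""
    comps, truth = sample_compositions(cfg)
    ds = generate_spectra(cfg, comps, truth)
    return ds, comps, truth


def with_window(cfg: SyntheticConfig, window: InstrumentWindow) -> SyntheticConfig:
    """Same campaign on another spectrometer window (shared compositions)."""
    return replace(cfg, window=window)
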