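"""Synthetic soil VNIR spectra with a known SOM dependence.

The generator emulates the qualitative structure of lab-measured paddy-soil
reflectance so that every pipeline stage is testable without field data:

* SOM drawn from a truncated normal, default mean 28.54 g/kg, sd 7.80,
  range 11.85-58.22 (the descriptive statistics of the study population this
  generator stands in for);
* a smooth baseline continuum rising through the visible and plateauing in
  the NIR;
* multiplicative Gaussian absorption features near 1400/1900/2200 nm with
  per-sample random depths (water/clay nuisance, independent of SOM);
* monotone darkening ``exp(-beta(lambda) * SOM_eff)`` with ``beta`` largest
  over 400-900 nm, so reflectance falls with SOM at every band and the
  SOM-reflectance correlation peaks in the visible;
* a 550-650 nm arch whose amplitude shrinks with SOM, so the deviation of
  arch (DOA) correlates negatively with SOM;
* ``SOM_eff = SOM + N(0, som_noise_sd)``: compositional variability that
  darkens spectra exactly like organic matter and is therefore inseparable
  from it, bounding the achievable R² at 1 - som_noise_sd²/Var(SOM).  The
  default is calibrated so the *validation-set* R² of a well-specified model
  is about 0.85: Kennard-Stone validation subsets have a smaller SOM spread
  (sd near 5.9 g/kg) than the population, and 5.9 * sqrt(0.15) gives 2.3;
* independent per-band Gaussian measurement noise of sd ``noise_sd``.

All spectra are emitted on the native 350-2500 nm, 1 nm grid (2151 bands,
``transform_tag='RAW'``) and clipped to (0.001, 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .exceptions import ParameterError
from .indices import PAIR_KINDS, SpectralIndexDef, pair_index_values
from .spectra import SoilSampleTable, SpectrumSet

GRID_NM = np.arange(350, 2501)


@dataclass(frozen=True)
class AbsorptionFeature:
    """One Gaussian absorption valley: center (nm), width sigma (nm), and the
    uniform range its per-sample fractional depth is drawn from."""

    center_nm: float
    width_nm: float
    depth_range: tuple = (0.05, 0.20)


@dataclass(frozen=True)
class PlantedPair:
    """A two-band index planted into the data with a target |r| to SOM."""

    kind: str
    band_i_nm: int
    band_j_nm: int
    target_abs_r: float = 0.98
    contrast_sd: float = 0.08  # per-sample amplitude sd of the planted contrast
    contrast_width_nm: float = 2.5


@dataclass
class SyntheticConfig:
    n_samples: int = 178
    som_mean: float = 28.54
    som_sd: float = 7.80
    som_min: float = 11.85
    som_max: float = 58.22
    features: tuple = (
        AbsorptionFeature(1400.0, 30.0, (0.10, 0.25)),
        AbsorptionFeature(1900.0, 45.0, (0.15, 0.35)),
        AbsorptionFeature(2200.0, 22.0, (0.05, 0.15)),
    )
    beta_base: float = 0.0040  # per g/kg, NIR floor of the darkening profile
    beta_vis_gain: float = 0.0060  # extra visible-range darkening
    beta_vis_center_nm: float = 650.0
    beta_vis_width_nm: float = 300.0
    arch_gain: float = 0.040  # reflectance amplitude of the 550-650 nm arch
    arch_width_nm: float = 35.0
    som_noise_sd: float = 2.3  # g/kg; SOM-mimicking compositional nuisance
    noise_sd: float = 0.001  # reflectance units, per band
    planted_pair: Optional[PlantedPair] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ParameterError("n_samples must be positive")
        if not self.som_min < self.som_mean < self.som_max:
            raise ParameterError("need som_min < som_mean < som_max")
        if self.som_sd <= 0:
            raise ParameterError("som_sd must be positive")
        if self.noise_sd < 0 or self.som_noise_sd < 0:
            raise ParameterError("noise levels must be non-negative")
        for f in self.features:
            if not 350 <= f.center_nm <= 2500:
                raise ParameterError(f"feature center {f.center_nm} nm outside 350-2500")


def _beta_profile(cfg: SyntheticConfig, wl: np.ndarray) -> np.ndarray:
    vis = np.exp(-(((wl - cfg.beta_vis_center_nm) / cfg.beta_vis_width_nm) ** 2))
    return cfg.beta_base + cfg.beta_vis_gain * vis


def _baseline(wl: np.ndarray) -> np.ndarray:
    # monotone rise through the visible, plateau in the NIR
    return 0.18 + 0.42 / (1.0 + np.exp(-(wl - 700.0) / 300.0))


def _draw_som(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    # moment-match the parent normal so the *truncated* distribution has the
    # configured mean and sd (plain truncation would shrink the sd ~10%)
    loc, scale = cfg.som_mean, cfg.som_sd
    for _ in range(40):
        a = (cfg.som_min - loc) / scale
        b = (cfg.som_max - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        loc += cfg.som_mean - float(m)
        scale *= cfg.som_sd / math.sqrt(float(v))
        if abs(m - cfg.som_mean) < 1e-9 and abs(math.sqrt(float(v)) - cfg.som_sd) < 1e-9:
            break
    a = (cfg.som_min - loc) / scale
    b = (cfg.som_max - loc) / scale
    dist = stats.truncnorm(a, b, loc=loc, scale=scale)
    return dist.rvs(size=cfg.n_samples, random_state=rng)


def _build_spectra(
    cfg: SyntheticConfig,
    som: np.ndarray,
    rng: np.random.Generator,
    contrast: Optional[np.ndarray] = None,
) -> np.ndarray:
    wl = GRID_NM.astype(float)
    n = cfg.n_samples
    som_eff = som + rng.normal(0.0, cfg.som_noise_sd, size=n)

    vals = np.tile(_baseline(wl), (n, 1))
    for f in cfg.features:
        depth = rng.uniform(*f.depth_range, size=n)
        shape = np.exp(-0.5 * ((wl - f.center_nm) / f.width_nm) ** 2)
        vals *= 1.0 - depth[:, None] * shape[None, :]
    vals *= np.exp(-np.outer(som_eff, _beta_profile(cfg, wl)))

    # visible arch, flattening as SOM rises (drives the negative DOA-SOM r)
    arch_shape = np.exp(-0.5 * ((wl - 600.0) / cfg.arch_width_nm) ** 2)
    amp = cfg.arch_gain * np.clip(1.0 - som_eff / (cfg.som_max + 2.0), 0.0, None)
    vals += amp[:, None] * arch_shape[None, :]

    if contrast is not None:
        vals *= contrast
    if cfg.noise_sd > 0:
        vals += rng.normal(0.0, cfg.noise_sd, size=vals.shape)
    return np.clip(vals, 0.001, 1.0)


def generate_soil_spectra(cfg: SyntheticConfig) -> tuple[SpectrumSet, SoilSampleTable]:
    """Generate a RAW SpectrumSet over 350-2500 nm plus its SOM table."""
    rng = np.random.default_rng(cfg.seed)
    som = _draw_som(cfg, rng)
    vals = _build_spectra(cfg, som, rng)
    ids = [f"S{k:04d}" for k in range(cfg.n_samples)]
    return SpectrumSet(ids, GRID_NM.copy(), vals, "RAW"), SoilSampleTable(ids, som)


def generate_planted_index_data(
    cfg: SyntheticConfig,
) -> tuple[SpectrumSet, SoilSampleTable, SpectralIndexDef]:
    """Spectra with a recoverable planted two-band index.

    A narrow antisymmetric contrast (reflectance up at band i, down at band
    j, independent per-sample amplitude) is multiplied into the spectra, and
    SOM is rebuilt as a linear function of the realized standardized index
    value plus calibrated Gaussian noise, so the SOM-index correlation equals
    the requested target in population (and within ±0.05 in samples of a few
    hundred).  ``target_abs_r = 0`` plants nothing detectable: SOM is then
    independent noise.
    """
    pp = cfg.planted_pair
    if pp is None:
        raise ParameterError("config has no planted_pair")
    if pp.kind not in PAIR_KINDS:
        raise ParameterError(f"planted kind must be one of {PAIR_KINDS}")
    if not 0.0 <= pp.target_abs_r <= 1.0:
        raise ParameterError(
            f"target |r|={pp.target_abs_r} unreachable; achievable range is [0, 1]"
        )
    for b in (pp.band_i_nm, pp.band_j_nm):
        if b not in GRID_NM:
            raise ParameterError(f"planted band {b} nm not on the 350-2500 grid")

    rng = np.random.default_rng(cfg.seed)
    som0 = _draw_som(cfg, rng)
    wl = GRID_NM.astype(float)
    u = rng.normal(0.0, pp.contrast_sd, size=cfg.n_samples)
    gi = np.exp(-0.5 * ((wl - pp.band_i_nm) / pp.contrast_width_nm) ** 2)
    gj = np.exp(-0.5 * ((wl - pp.band_j_nm) / pp.contrast_width_nm) ** 2)
    contrast = 1.0 + u[:, None] * (gi - gj)[None, :]
    vals = _build_spectra(cfg, som0, rng, contrast=contrast)

    ids = [f"S{k:04d}" for k in range(cfg.n_samples)]
    spectra = SpectrumSet(ids, GRID_NM.copy(), vals, "RAW")

    z = pair_index_values(spectra, pp.band_i_nm, pp.band_j_nm, pp.kind)
    if not np.all(np.isfinite(z)) or np.std(z) == 0:
        raise ParameterError("planted index is degenerate on the generated spectra")
    z_std = (z - z.mean()) / np.std(z)
    eps = rng.standard_normal(cfg.n_samples)
    eps = (eps - eps.mean()) / np.std(eps)
    r = pp.target_abs_r
    som = cfg.som_mean + cfg.som_sd * (r * z_std + math.sqrt(1.0 - r * r) * eps)
    som = np.maximum(som, 0.5)  # SOM must stay positive; clip is negligible here

    achieved = float(np.corrcoef(som, z)[0, 1]) if np.std(som) > 0 else 0.0
    defn = SpectralIndexDef(pp.kind, "RAW", pp.band_i_nm, pp.band_j_nm, achieved)
    return spectra, SoilSampleTable(ids, som), defn


def generate_planted_bands_data(
    n_samples: int = 120,
    n_bands: int = 200,
    informative_bands: Optional[np.ndarray] = None,
    signal_scale: float = 1.0,
    band_noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Benchmark matrix for band selectors: a few informative bands carrying a
    linear SOM signal, the rest pure noise.

    Returns (X, y, informative_band_indices).  Informative band k equals
    ``signal_scale * standardized(y) + N(0, band_noise_sd)``; noise bands are
    standard normal.  ``band_noise_sd=0`` yields noiseless informative bands.
    """
    rng = np.random.default_rng(seed)
    if informative_bands is None:
        informative_bands = np.linspace(10, n_bands - 10, 10).round().astype(int)
    informative_bands = np.asarray(informative_bands, dtype=int)
    y = rng.normal(28.54, 7.80, size=n_samples)
    y = np.maximum(y, 1.0)
    ys = (y - y.mean()) / np.std(y)
    x = rng.standard_normal((n_samples, n_bands))
    for k, b in enumerate(informative_bands):
        sgn = 1.0 if k % 2 == 0 else -1.0
        noise = rng.normal(0.0, band_noise_sd, size=n_samples) if band_noise_sd > 0 else 0.0
        x[:, b] = sgn * signal_scale * ys + noise
    return x, y, informative_bands
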