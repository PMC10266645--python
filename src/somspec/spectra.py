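"""Spectral containers and the four spectral representations.

Diffuse reflectance spectra live on a uniform integer wavelength grid
(nominally 350-2500 nm at 1 nm).  Four representations are used for soil
organic matter (SOM) modeling:

``R``
    reflectance after Savitzky-Golay smoothing,
``LR``
    inverse-log reflectance, log10(1/R),
``CR``
    continuum-removed reflectance, R divided by its upper convex hull,
``FDR``
    first-order derivative reflectance (per nm).

All transforms preserve sample order and count; smoothing trims half a
window at each grid end so that a 2151-band raw spectrum over 350-2500 nm
becomes a 2141-band smoothed spectrum over 355-2495 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import DomainError, ParameterError

VALID_TAGS = ("RAW", "R", "LR", "CR", "FDR")

#: tolerance for "reflectance must lie in [0, 1]" checks
_UNIT_TOL = 1e-9


@dataclass
class SpectrumSet:
    """Per-sample spectra on a shared uniform wavelength grid.

    Parameters
    ----------
    sample_ids : list of str
        Ordered sample identifiers, unique.
    wavelengths_nm : ndarray of int
        Strictly increasing, uniform integer step (1 nm for native data;
        coarser strides are allowed for sub-sampled working copies).
    values : ndarray, shape (n_samples, n_bands)
        One spectrum per row.  Range depends on ``transform_tag``:
        [0, 1] for RAW/R, (0, 1] for CR, unbounded for LR/FDR.
    transform_tag : {"RAW", "R", "LR", "CR", "FDR"}
    """

    sample_ids: list
    wavelengths_nm: np.ndarray
    values: np.ndarray
    transform_tag: str = "RAW"

    def __post_init__(self):
        self.wavelengths_nm = np.asarray(self.wavelengths_nm)
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = list(self.sample_ids)
        if self.transform_tag not in VALID_TAGS:
            raise ParameterError(f"unknown transform_tag {self.transform_tag!r}")
        wl = self.wavelengths_nm
        if wl.ndim != 1 or wl.size < 1:
            raise ParameterError("wavelengths_nm must be a 1-D array")
        if not np.issubdtype(wl.dtype, np.integer):
            if not np.allclose(wl, np.round(wl)):
                raise ParameterError("wavelengths must be integers (nm)")
            self.wavelengths_nm = wl = np.round(wl).astype(int)
        if wl.size > 1:
            steps = np.diff(wl)
            if steps[0] <= 0 or not np.all(steps == steps[0]):
                raise ParameterError(
                    "wavelength grid must be strictly increasing with a constant step"
                )
        if self.values.ndim != 2:
            raise ParameterError("values must be 2-D (samples x bands)")
        if self.values.shape != (len(self.sample_ids), wl.size):
            raise ParameterError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {wl.size} bands"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ParameterError("sample ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("values contain non-finite entries")
        if self.transform_tag in ("RAW", "R"):
            if self.values.min() < -_UNIT_TOL or self.values.max() > 1 + _UNIT_TOL:
                raise ParameterError(
                    f"{self.transform_tag} reflectance must lie in [0, 1]; "
                    f"range is [{self.values.min():.4g}, {self.values.max():.4g}]"
                )
        elif self.transform_tag == "CR":
            if self.values.min() <= 0 or self.values.max() > 1 + _UNIT_TOL:
                raise ParameterError("CR values must lie in (0, 1]")

    # -- conveniences -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_bands(self) -> int:
        return self.wavelengths_nm.size

    @property
    def step_nm(self) -> int:
        if self.n_bands < 2:
            return 1
        return int(self.wavelengths_nm[1] - self.wavelengths_nm[0])

    def band_index(self, wavelength_nm: int) -> int:
        """Index of a wavelength on the grid; ParameterError if absent."""
        idx = np.searchsorted(self.wavelengths_nm, wavelength_nm)
        if idx >= self.n_bands or self.wavelengths_nm[idx] != wavelength_nm:
            raise ParameterError(f"wavelength {wavelength_nm} nm not on the grid")
        return int(idx)

    def select_bands(self, mask_or_step) -> "SpectrumSet":
        """Sub-sample bands: integer stride or boolean/index mask."""
        if np.isscalar(mask_or_step):
            sel = slice(None, None, int(mask_or_step))
        else:
            sel = np.asarray(mask_or_step)
        return SpectrumSet(
            self.sample_ids,
            self.wavelengths_nm[sel],
            self.values[:, sel],
            self.transform_tag,
        )

    def crop(self, lo_nm: int, hi_nm: int) -> "SpectrumSet":
        keep = (self.wavelengths_nm >= lo_nm) & (self.wavelengths_nm <= hi_nm)
        return self.select_bands(keep)

    def copy(self) -> "SpectrumSet":
        return replace(self, values=self.values.copy())


@dataclass
class SoilSampleTable:
    """Sample ids paired with SOM concentration (g/kg, finite, > 0)."""

    sample_ids: list
    som_g_per_kg: np.ndarray

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.som_g_per_kg = np.asarray(self.som_g_per_kg, dtype=float)
        if self.som_g_per_kg.ndim != 1 or self.som_g_per_kg.size != len(self.sample_ids):
            raise ParameterError("SOM vector must align 1:1 with sample ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ParameterError("sample ids must be unique")
        if not np.all(np.isfinite(self.som_g_per_kg)) or np.any(self.som_g_per_kg <= 0):
            raise ParameterError("SOM values must be finite and > 0 g/kg")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def check_aligned(s: SpectrumSet, som: SoilSampleTable) -> None:
    if s.sample_ids != som.sample_ids:
        raise ParameterError("SpectrumSet and SoilSampleTable sample ids differ")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def savitzky_golay_smooth(
    s: SpectrumSet, window_bands: int = 11, poly_order: int = 2
) -> SpectrumSet:
    """Savitzky-Golay smoothing; edge bands are trimmed, not padded.

    Each output value is the center value of the degree-``poly_order``
    least-squares polynomial fitted to the ``window_bands``-wide window.
    The output grid loses (window_bands - 1) / 2 bands at each end, so the
    native 2151-band 350-2500 nm grid becomes 2141 bands over 355-2495 nm.
    """
    if window_bands % 2 == 0 or window_bands <= poly_order:
        raise ParameterError(
            f"window_bands must be odd and > poly_order (got {window_bands}, {poly_order})"
        )
    if s.n_bands < window_bands:
        raise ParameterError(
            f"spectrum has {s.n_bands} bands, fewer than window_bands={window_bands}"
        )
    half = (window_bands - 1) // 2
    smoothed = savgol_filter(s.values, window_bands, poly_order, axis=1)
    # interior values of savgol_filter are the exact windowed LS fits;
    # only the padded edges differ between modes, and those are dropped here
    sl = slice(half, s.n_bands - half)
    vals = np.clip(smoothed[:, sl], 0.0, 1.0)
    return SpectrumSet(s.sample_ids, s.wavelengths_nm[sl], vals, "R")


def _require_tag(s: SpectrumSet, op: str) -> None:
    if s.transform_tag != "R":
        raise ParameterError(
            f"{op} expects smoothed reflectance (transform_tag='R'); "
            f"got {s.transform_tag!r} — apply savitzky_golay_smooth first"
        )


def transform_lr(s: SpectrumSet) -> SpectrumSet:
    """Inverse-log reflectance: log10(1 / R)."""
    _require_tag(s, "transform_lr")
    bad = s.values <= 0
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DomainError(
            f"non-positive reflectance at sample {s.sample_ids[i]!r}, "
            f"band {s.wavelengths_nm[j]} nm; LR is undefined"
        )
    return SpectrumSet(s.sample_ids, s.wavelengths_nm, -np.log10(s.values), "LR")


def upper_convex_hull(wavelengths: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Continuum line: upper convex hull of (wavelength, value) points,
    anchored at the first and last band, evaluated at every wavelength.

    Andrew's monotone-chain scan over points already sorted by wavelength.
    """
    x = np.asarray(wavelengths, dtype=float)
    y = np.asarray(values, dtype=float)
    hull = [0]
    for k in range(1, x.size):
        while len(hull) >= 2:
            i, j = hull[-2], hull[-1]
            # pop j if it lies below (or on) the chord i -> k
            if (x[j] - x[i]) * (y[k] - y[i]) >= (y[j] - y[i]) * (x[k] - x[i]):
                hull.pop()
            else:
                break
        hull.append(k)
    return np.interp(x, x[hull], y[hull])


def transform_cr(s: SpectrumSet) -> SpectrumSet:
    """Continuum removal: per-sample division by the upper convex hull."""
    _require_tag(s, "transform_cr")
    if s.n_bands < 2:
        raise ParameterError("continuum removal needs at least 2 bands")
    if s.values.min() <= 0:
        raise DomainError("continuum removal requires strictly positive reflectance")
    out = np.empty_like(s.values)
    for row in range(s.n_samples):
        hull = upper_convex_hull(s.wavelengths_nm, s.values[row])
        out[row] = s.values[row] / hull
    out = np.minimum(out, 1.0)
    out[:, 0] = 1.0
    out[:, -1] = 1.0
    return SpectrumSet(s.sample_ids, s.wavelengths_nm, out, "CR")


def transform_fdr(s: SpectrumSet) -> SpectrumSet:
    """First-order derivative reflectance per nm.

    Central differences at interior bands, one-sided differences at the two
    boundary bands, so the band count is preserved and all four
    representations share one grid.
    """
    _require_tag(s, "transform_fdr")
    if s.n_bands < 3:
        raise ParameterError("derivative needs at least 3 bands")
    deriv = np.gradient(s.values, s.wavelengths_nm.astype(float), axis=1)
    return SpectrumSet(s.sample_ids, s.wavelengths_nm, deriv, "FDR")


def all_transforms(raw: SpectrumSet, window_bands: int = 11, poly_order: int = 2) -> dict:
    """Smooth a RAW set and derive the four representations from smoothed R."""
    r = savitzky_golay_smooth(raw, window_bands, poly_order)
    return {
        "R": r,
        "LR": transform_lr(r),
        "CR": transform_cr(r),
        "FDR": transform_fdr(r),
    }
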