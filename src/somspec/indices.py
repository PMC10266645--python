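"""Two-band spectral indexes and their SOM correlation maps.

Index definitions (reflectance ``R_i`` at wavelength ``i``):

    DOA = R(600) - (R(550) + R(650)) / 2      (deviation of arch, R spectra)
    DI  = R_i - R_j                            (difference index)
    RI  = R_i / R_j                            (ratio index)
    NDI = (R_i - R_j) / (R_i + R_j)            (normalized difference index)

For every ordered band pair the Pearson correlation between the index and
SOM is assembled into a contour-map-like matrix; the highest-|r| cells define
the optimal indexes.  The SI feature table stacks DOA with the top-k DI/RI/NDI
indexes of each of the four spectral representations (1 + 12 k columns:
13 for k=1, 37 for k=3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, ParameterError
from .spectra import SoilSampleTable, SpectrumSet, check_aligned

PAIR_KINDS = ("DI", "RI", "NDI")
#: denominators with absolute value below this are treated as invalid
DENOM_EPS = 1e-12
#: variance below this (on standardized data) marks a degenerate index vector
_VAR_EPS = 1e-24


@dataclass(frozen=True)
class SpectralIndexDef:
    """Identity of one selected index, e.g. ``DI_FDR(1408, 1396)``."""

    kind: str  # DOA, DI, RI, NDI
    transform_tag: str
    band_i_nm: Optional[int]
    band_j_nm: Optional[int]
    r_with_som: float

    def __post_init__(self):
        if self.kind not in ("DOA",) + PAIR_KINDS:
            raise ParameterError(f"unknown index kind {self.kind!r}")
        if self.kind != "DOA" and self.band_i_nm == self.band_j_nm:
            raise ParameterError("pair index needs two distinct bands")

    @property
    def name(self) -> str:
        if self.kind == "DOA":
            return "DOA"
        return f"{self.kind}_{self.transform_tag}({self.band_i_nm},{self.band_j_nm})"


@dataclass
class IndexCorrelationMap:
    """All-ordered-pairs Pearson-r surface for one (transform, index kind).

    ``r_matrix[a, b]`` is r(index(bands[a], bands[b]), SOM); ``valid`` masks
    cells whose index vector is defined and non-degenerate.
    """

    kind: str
    transform_tag: str
    bands: np.ndarray
    r_matrix: np.ndarray
    valid: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r_matrix, index=self.bands, columns=self.bands)


def deviation_of_arch(s: SpectrumSet) -> np.ndarray:
    """DOA = R(600) - (R(550) + R(650)) / 2, per sample (on R spectra).

    High-SOM soils have a flat visible arch, so DOA shrinks as SOM rises.
    """
    i550 = s.band_index(550)
    i600 = s.band_index(600)
    i650 = s.band_index(650)
    v = s.values
    return v[:, i600] - (v[:, i550] + v[:, i650]) / 2.0


def pair_index_values(s: SpectrumSet, i_nm: int, j_nm: int, kind: str) -> np.ndarray:
    """Per-sample DI/RI/NDI values for one band pair; NaN marks invalid samples
    (ratio/normalized-difference denominator within ``DENOM_EPS`` of zero)."""
    if kind not in PAIR_KINDS:
        raise ParameterError(f"kind must be one of {PAIR_KINDS}, got {kind!r}")
    if kind in ("RI", "NDI") and i_nm == j_nm:
        raise ParameterError(f"{kind} requires two distinct bands")
    ri = s.values[:, s.band_index(i_nm)]
    rj = s.values[:, s.band_index(j_nm)]
    if kind == "DI":
        return ri - rj
    den = rj if kind == "RI" else ri + rj
    num = ri if kind == "RI" else ri - rj
    out = np.full(ri.shape, np.nan)
    ok = np.abs(den) >= DENOM_EPS
    out[ok] = num[ok] / den[ok]
    return out


def _pearson_columns(m: np.ndarray, yc: np.ndarray, sy: float) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each column of ``m`` with a centered target ``yc``.

    Returns (r, valid); columns with ~zero variance are invalid.  ``yc`` sums
    to zero, so the covariance reduces to a single matrix-vector product.
    """
    n = m.shape[0]
    mean = m.mean(axis=0)
    var = np.einsum("ij,ij->j", m, m) / n - mean * mean
    np.maximum(var, 0.0, out=var)
    cov = (yc @ m) / n
    valid = var > _VAR_EPS
    r = np.full(m.shape[1], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        r[valid] = cov[valid] / (np.sqrt(var[valid]) * sy)
    np.clip(r, -1.0, 1.0, out=r)
    return r, valid


def index_correlation_map(
    s: SpectrumSet, som: SoilSampleTable, kind: str, band_step: int = 1
) -> IndexCorrelationMap:
    """Pearson r between SOM and every ordered band-pair index.

    ``band_step`` computes the map on a strided wavelength subset (useful for
    tests and quick looks; the native map is 2141 x 2141).
    """
    if kind not in PAIR_KINDS:
        raise ParameterError(f"kind must be one of {PAIR_KINDS}, got {kind!r}")
    check_aligned(s, som)
    if s.n_samples < 3:
        raise ParameterError("need at least 3 samples for a correlation map")
    y = som.som_g_per_kg
    yc = y - y.mean()
    sy = float(np.sqrt((yc * yc).mean()))
    if sy <= np.sqrt(_VAR_EPS):
        raise DegenerateInputError("SOM has zero variance")

    ss = s.select_bands(band_step) if band_step != 1 else s
    x = ss.values
    n, p = x.shape
    if kind == "DI":
        # closed form from band moments: cov(y, R_a - R_b) = c_a - c_b and
        # var(R_a - R_b) = V_a + V_b - 2 S_ab, so one Gram matrix gives the map
        xc = x - x.mean(axis=0)
        c = (yc @ xc) / n
        cov_bands = (xc.T @ xc) / n
        v = np.diag(cov_bands).copy()
        var_pair = v[:, None] + v[None, :] - 2.0 * cov_bands
        np.maximum(var_pair, 0.0, out=var_pair)
        valid = var_pair > _VAR_EPS
        r = np.full((p, p), np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            r[valid] = (c[:, None] - c[None, :])[valid] / (np.sqrt(var_pair[valid]) * sy)
        np.clip(r, -1.0, 1.0, out=r)
        return IndexCorrelationMap(kind, ss.transform_tag, ss.wavelengths_nm.copy(), r, valid)

    r = np.full((p, p), np.nan)
    valid = np.zeros((p, p), dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        for b in range(p):  # column b: index(i = every band, j = bands[b])
            col = x[:, [b]]
            if kind == "RI":
                if np.any(np.abs(col) < DENOM_EPS):
                    continue  # denominator band invalid for every i
                m = x / col
                bad = None
            else:  # NDI
                den = x + col
                bad = np.abs(den) < DENOM_EPS
                m = (x - col) / np.where(bad, 1.0, den)
            rb, vb = _pearson_columns(m, yc, sy)
            if bad is not None:
                vb &= ~bad.any(axis=0)
            vb[b] = False  # RI/NDI undefined on the diagonal
            r[:, b] = rb
            valid[:, b] = vb
    r[~valid] = np.nan
    return IndexCorrelationMap(kind, ss.transform_tag, ss.wavelengths_nm.copy(), r, valid)


def select_top_indexes(cmap: IndexCorrelationMap, k: int) -> list[SpectralIndexDef]:
    """Top-k index definitions of a map, ranked by |r| descending.

    DI and NDI are antisymmetric, so mirrored ordered pairs carry identical
    |r|; they are collapsed to the ``i < j`` orientation before ranking.  RI
    orderings are genuinely different indexes and both remain candidates.
    Ties in |r| break to the lexicographically smaller (band_i, band_j).
    """
    if k < 1:
        raise ParameterError("k must be a positive integer")
    bands = cmap.bands
    ii, jj = np.nonzero(cmap.valid)
    if cmap.kind in ("DI", "NDI"):
        keep = ii < jj
        ii, jj = ii[keep], jj[keep]
    if ii.size < k:
        raise ParameterError(
            f"k={k} exceeds the {ii.size} valid candidate cells of the {cmap.kind} map"
        )
    r = cmap.r_matrix[ii, jj].astype(float)
    order = np.lexsort((bands[jj], bands[ii], -np.abs(r)))
    top = order[:k]
    return [
        SpectralIndexDef(cmap.kind, cmap.transform_tag, int(bands[a]), int(bands[b]), float(rv))
        for a, b, rv in zip(ii[top], jj[top], r[top])
    ]


def compute_index_column(
    defn: SpectralIndexDef, spectra_by_tag: dict[str, SpectrumSet]
) -> np.ndarray:
    """Recompute one feature column from its stored definition."""
    if defn.kind == "DOA":
        return deviation_of_arch(spectra_by_tag["R"])
    s = spectra_by_tag[defn.transform_tag]
    return pair_index_values(s, defn.band_i_nm, defn.band_j_nm, defn.kind)


def assemble_si_features(
    spectra_by_tag: dict[str, SpectrumSet],
    som: SoilSampleTable,
    k: int = 1,
    band_step: int = 1,
) -> tuple[pd.DataFrame, list[SpectralIndexDef]]:
    """SI feature table: DOA plus top-k DI/RI/NDI per transform.

    Column count is 1 + 12 k (13 for the SI set, 37 for the SI3 set).
    Returns the samples-x-features DataFrame and the column definitions.
    """
    for tag in ("R", "LR", "CR", "FDR"):
        if tag not in spectra_by_tag:
            raise ParameterError(f"missing transform {tag!r}")
        check_aligned(spectra_by_tag[tag], som)
    defs: list[SpectralIndexDef] = [
        SpectralIndexDef(
            "DOA",
            "R",
            None,
            None,
            float(np.corrcoef(deviation_of_arch(spectra_by_tag["R"]), som.som_g_per_kg)[0, 1]),
        )
    ]
    for tag in ("R", "LR", "CR", "FDR"):
        for kind in PAIR_KINDS:
            cmap = index_correlation_map(spectra_by_tag[tag], som, kind, band_step=band_step)
            defs.extend(select_top_indexes(cmap, k))
    cols = {d.name: compute_index_column(d, spectra_by_tag) for d in defs}
    frame = pd.DataFrame(cols, index=som.sample_ids)
    return frame, defs


def index_defs_to_frame(defs: list[SpectralIndexDef]) -> pd.DataFrame:
    """Ranked-index table (kind, transform, band_i, band_j, r) for export."""
    return pd.DataFrame(
        [
            {
                "kind": d.kind,
                "transform": d.transform_tag,
                "band_i_nm": d.band_i_nm,
                "band_j_nm": d.band_j_nm,
                "r_with_som": d.r_with_som,
            }
            for d in defs
        ]
    )
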