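"""Reading and writing the wide spectra-table dialect.

Layout: header ``sample_id, som_g_per_kg, 350, 351, ..., 2500``; one row per
sample.  CSV by default, TSV when the filename ends in ``.tsv``.  Reflectance
is stored as a fraction in [0, 1]; percent-scale files (any spectral value
> 1.5) are rejected with a message rather than silently rescaled.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .exceptions import FormatError
from .spectra import SoilSampleTable, SpectrumSet

ID_COL = "sample_id"
SOM_COL = "som_g_per_kg"


def _sep_for(path) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def read_spectra_table(path) -> tuple[SpectrumSet, SoilSampleTable]:
    """Read a wide spectra table; returns an aligned (SpectrumSet, SoilSampleTable).

    Wavelength columns are sorted ascending regardless of file order; the
    returned SpectrumSet carries ``transform_tag='RAW'``.
    """
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    cols = list(df.columns)
    if len(cols) < 3 or cols[0] != ID_COL:
        raise FormatError(f"first column must be {ID_COL!r}, got {cols[:1]}")
    if cols[1] != SOM_COL:
        raise FormatError(f"second column must be {SOM_COL!r}, got {cols[1]!r}")

    wl_cols = cols[2:]
    wavelengths = []
    for c in wl_cols:
        try:
            w = int(str(c).strip())
        except ValueError:
            raise FormatError(f"non-integer wavelength column header {c!r}") from None
        wavelengths.append(w)
    wavelengths = np.asarray(wavelengths)

    ids = df[ID_COL].astype(str).tolist()
    dup = df[ID_COL][df[ID_COL].duplicated()]
    if len(dup):
        raise FormatError(f"duplicated sample id {dup.iloc[0]!r}")

    for c in [SOM_COL] + wl_cols:
        col = pd.to_numeric(df[c], errors="coerce")
        if col.isna().any():
            row = int(col.isna().idxmax())
            raise FormatError(
                f"non-numeric or missing value in column {c!r}, row {row} "
                f"(sample {ids[row]!r})"
            )

    som = df[SOM_COL].to_numpy(dtype=float)
    values = df[wl_cols].to_numpy(dtype=float)
    order = np.argsort(wavelengths)
    wavelengths, values = wavelengths[order], values[:, order]
    if values.max() > 1.5:
        raise FormatError(
            "spectral values exceed 1.5 — file appears to be on a percent "
            "scale; convert reflectance to a fraction in [0, 1] first"
        )
    return (
        SpectrumSet(ids, wavelengths, values, "RAW"),
        SoilSampleTable(ids, som),
    )


def write_spectra_table(path, s: SpectrumSet, som: SoilSampleTable) -> None:
    """Write the same dialect ``read_spectra_table`` reads (round-trip exact)."""
    if s.sample_ids != som.sample_ids:
        raise FormatError("SpectrumSet and SoilSampleTable ids differ")
    df = pd.DataFrame(s.values, columns=[str(w) for w in s.wavelengths_nm])
    df.insert(0, SOM_COL, som.som_g_per_kg)
    df.insert(0, ID_COL, s.sample_ids)
    # default float formatting writes the shortest exact repr -> lossless round trip
    df.to_csv(path, sep=_sep_for(path), index=False)
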