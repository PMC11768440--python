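"""Reading and writing the site x metal concentration table.

The on-disk format is a UTF-8 CSV with a ``site_id`` string column followed
by one numeric column per metal, concentrations in mg/kg.
"""

from __future__ import annotations

import pandas as pd

from .risk import ReferenceDoseTable

__all__ = ["read_concentration_csv", "write_concentration_csv"]


def write_concentration_csv(concentrations: pd.DataFrame, path) -> None:
    """Write a site x metal table to CSV (``site_id`` column + metal columns).

    Values round-trip losslessly at 12 significant digits.
    """
    if concentrations.shape[0] == 0:
        raise ValueError("concentration table has no sites")
    if concentrations.shape[1] == 0:
        raise ValueError("concentration table has no metal columns")
    out = concentrations.copy()
    out.insert(0, "site_id", concentrations.index.astype(str))
    out.to_csv(path, index=False, float_format="%.12g")


def read_concentration_csv(path, rfd: ReferenceDoseTable | None = None) -> pd.DataFrame:
    """Read and validate a concentration CSV.

    Every cell must be present and non-negative.  When ``rfd`` is given,
    metal columns are matched case-insensitively against its entries and an
    unknown metal is an error listing the known ones.
    """
    df = pd.read_csv(path, dtype={"site_id": str})
    if "site_id" not in df.columns:
        raise ValueError(f"{path}: missing required 'site_id' column")
    df = df.set_index("site_id")
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no metal columns found")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna().to_numpy().argmax()]
            raise ValueError(f"{path}: missing or non-numeric value at site {row!r}, metal {col!r}")
        if (vals < 0).any():
            row = df.index[(vals < 0).to_numpy().argmax()]
            raise ValueError(f"{path}: negative concentration at site {row!r}, metal {col!r}")
        df[col] = vals.astype(float)
    if rfd is not None:
        folded = {m.lower(): m for m in rfd.metals()}
        renames = {}
        for col in df.columns:
            if col.lower() not in folded:
                known = ", ".join(sorted(rfd.metals()))
                raise ValueError(f"{path}: metal {col!r} has no reference dose; known metals: {known}")
            renames[col] = folded[col.lower()]
        df = df.rename(columns=renames)
    return df
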