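"""Dose-resolved cellular thermal shift assay (CETSA) quantification.

Immunoblot band intensities of the target protein at a single denaturing
temperature, across a drug dilution series, are normalised to a loading
control and Z-transformed within each (drug, context) group so that panels
from different blots and cell backgrounds are comparable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["quantify_ratio", "zscore_series", "min_stabilizing_dose"]

GROUP_COLS = ("drug", "context")


def quantify_ratio(series: pd.DataFrame) -> pd.DataFrame:
    """Add the loading-normalised band ratio (target / loading).

    Expects columns ``drug``, ``context``, ``dose_nm``, ``target``,
    ``loading``; intensities must be positive.
    """
    required = {"drug", "context", "dose_nm", "target", "loading"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"CETSA table is missing columns: {sorted(missing)}")
    if (series["loading"] <= 0).any() or (series["target"] <= 0).any():
        raise ValueError("band intensities must be positive")
    if (series["dose_nm"] < 0).any():
        raise ValueError("doses must be non-negative")
    out = series.copy()
    out["ratio"] = out["target"] / out["loading"]
    return out


def zscore_series(
    ratios: pd.DataFrame, by: tuple[str, ...] = GROUP_COLS, ddof: int = 0
) -> pd.DataFrame:
    """Z-transform the ratio within each (drug, context) group.

    Population SD (``ddof=0``) by default, so a 3-point series maps to
    +-1.2247; set ``ddof=1`` for the sample-SD convention. Groups with
    fewer than 2 doses or zero variance are rejected by name.
    """
    if "ratio" not in ratios.columns:
        ratios = quantify_ratio(ratios)
    out = ratios.copy()
    z = np.empty(len(out))
    for key, idx in out.groupby(list(by)).groups.items():
        vals = out.loc[idx, "ratio"].to_numpy(dtype=float)
        if vals.size < 2:
            raise ValueError(f"group {key} has a single dose: Z-score undefined")
        sd = vals.std(ddof=ddof)
        if sd == 0:
            raise ValueError(f"group {key} has zero ratio variance (flat series)")
        z[out.index.get_indexer(idx)] = (vals - vals.mean()) / sd
    out["z"] = z
    return out


def min_stabilizing_dose(
    series: pd.DataFrame, threshold: float = 0.5
) -> float | None:
    """Lowest dose whose Z-score reaches ``threshold``, or None.

    Summarises a dose series as the minimal concentration with clear
    stabilisation. Expects a single (drug, context) group with a ``z``
    column (run :func:`zscore_series` first).
    """
    if "z" not in series.columns:
        raise ValueError("series lacks a 'z' column; run zscore_series first")
    s = series.sort_values("dose_nm")
    qualifying = s.loc[s["z"] >= threshold, "dose_nm"]
    if qualifying.empty:
        return None
    return float(qualifying.iloc[0])
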