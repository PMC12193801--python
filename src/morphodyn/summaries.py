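"""Collapse per-cell time series into 31 morphodynamic quantifiers.

For each of the nine time-series features (area, perimeter, solidity,
convexity, circularity, aspect ratio, angularity, maximum protrusion
length, protrusiveness) three statistics are kept: the mean, the sample
standard deviation normalized by the mean, and the least-squares slope
against time. Four further quantifiers — fixed area, mean mobile area,
mobile/fixed ratio and the slope of the cumulative DAC sum — complete
the 31-dimensional summary vector.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import TIMESERIES_FEATURES, CellTimeSeries
from .io_config import get_logger

__all__ = ["QUANTIFIER_COLUMNS", "summarize_cell", "build_population"]

logger = get_logger(__name__)

#: canonical, fixed order of the 31 quantifier columns
QUANTIFIER_COLUMNS: tuple[str, ...] = tuple(
    f"{feat}_{stat}" for feat in TIMESERIES_FEATURES for stat in ("mean", "var", "trend")
) + ("fixed_area", "mobile_area", "ratio_mobile_fixed", "dac_cumsum_slope")

assert len(QUANTIFIER_COLUMNS) == 31

#: per-row metadata carried alongside the quantifiers
METADATA_COLUMNS: tuple[str, ...] = ("cell_id", "condition", "experiment")


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    """Ordinary least-squares slope of y against t."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    tc = t - t.mean()
    denom = (tc**2).sum()
    if denom == 0:
        return 0.0
    return float((tc * (y - y.mean())).sum() / denom)


def _normalized_sd(y: np.ndarray, raw_sd: bool = False) -> float:
    sd = float(np.std(y, ddof=1))
    if raw_sd:
        return sd
    mean = float(np.mean(y))
    if mean == 0.0:
        if sd == 0.0:
            return 0.0
        return float("nan")
    return sd / abs(mean)


def summarize_cell(ts: CellTimeSeries, raw_sd: bool = False) -> dict[str, float]:
    """The 31 morphodynamic quantifiers of one cell.

    Requires a complete (unflagged) time series of at least 3 frames.
    ``raw_sd`` disables the division of the standard deviation by the
    mean. Trend units are per second. A zero fixed area leaves the
    mobile/fixed ratio undefined and raises.
    """
    if ts.flags:
        raise ValueError(f"cell {ts.cell_id} is flagged: {ts.flags}")
    if len(ts.times_s) < 3:
        raise ValueError("summaries need at least 3 frames")

    out: dict[str, float] = {}
    t = np.asarray(ts.times_s, dtype=float)
    for feat in TIMESERIES_FEATURES:
        y = ts.features[feat].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError(f"cell {ts.cell_id}: NaN in feature '{feat}'")
        out[f"{feat}_mean"] = float(np.mean(y))
        out[f"{feat}_var"] = _normalized_sd(y, raw_sd=raw_sd)
        out[f"{feat}_trend"] = _ols_slope(t, y)

    fixed = ts.fixed_mobile.fixed_area
    if fixed <= 0:
        raise ValueError(f"cell {ts.cell_id}: fixed area is 0, ratio undefined")
    mobile_mean = float(np.mean(ts.fixed_mobile.mobile_area))
    out["fixed_area"] = fixed
    out["mobile_area"] = mobile_mean
    out["ratio_mobile_fixed"] = mobile_mean / fixed

    dac_t = t[: len(ts.dac)]
    out["dac_cumsum_slope"] = _ols_slope(dac_t, np.cumsum(ts.dac))

    assert set(out) == set(QUANTIFIER_COLUMNS)
    return {col: out[col] for col in QUANTIFIER_COLUMNS}


def build_population(
    summaries: list[dict[str, float]],
    cell_ids: list | None = None,
    condition: str | list | None = None,
    experiment: str | list | None = None,
) -> pd.DataFrame:
    """Stack summary vectors into a cells × quantifiers matrix.

    Metadata columns (cell_id, condition, experiment) come first, then
    the 31 quantifiers in their canonical order. Duplicate cell ids are
    rejected.
    """
    n = len(summaries)
    if cell_ids is None:
        cell_ids = list(range(n))
    if len(cell_ids) != n:
        raise ValueError("cell_ids length mismatch")
    if len(set(cell_ids)) != n:
        raise ValueError("duplicated cell ids")

    def _broadcast(value, default):
        if value is None:
            return [default] * n
        if isinstance(value, (str, int)):
            return [value] * n
        value = list(value)
        if len(value) != n:
            raise ValueError("label length mismatch")
        return value

    conditions = _broadcast(condition, "unlabeled")
    experiments = _broadcast(experiment, "exp0")

    rows = []
    for cid, cond, exp, summary in zip(cell_ids, conditions, experiments, summaries):
        if set(summary) != set(QUANTIFIER_COLUMNS):
            raise ValueError("summary vector does not match the 31-quantifier schema")
        row = {"cell_id": cid, "condition": cond, "experiment": exp}
        row.update({col: summary[col] for col in QUANTIFIER_COLUMNS})
        rows.append(row)
    columns = list(METADATA_COLUMNS) + list(QUANTIFIER_COLUMNS)
    return pd.DataFrame(rows, columns=columns)
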