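"""Colony-size phenotype QC, summary statistics, and extreme-pool selection.

Replicate filtering follows the screening convention used for the hybrid
progeny: within each strain x condition set of four technical replicates,
values further than 1.25 x IQR beyond the first or third quartile are
excluded, and the median of the kept replicates is the strain's fitness.
Quartiles use linear interpolation (numpy default, type-7); the convention
is configurable via the ``quartile_method`` argument.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REP_COLUMNS = ["rep1", "rep2", "rep3", "rep4"]


def _quartiles(values: np.ndarray, method: str = "linear") -> tuple[float, float]:
    q1, q3 = np.percentile(values, [25, 75], method=method)
    return float(q1), float(q3)


def filter_replicates(
    values, k: float = 1.25, quartile_method: str = "linear"
) -> np.ndarray:
    """Drop replicates outside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles are computed over the original values; order is preserved.
    Requires at least two finite values (quartiles are undefined otherwise).
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValueError(f"need >= 2 finite replicate values, got {arr.size}")
    if (arr < 0).any():
        raise ValueError("replicate sizes must be non-negative")
    q1, q3 = _quartiles(arr, quartile_method)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return arr[(arr >= lo) & (arr <= hi)]


def summarize(
    table: pd.DataFrame,
    control: str = "YPD",
    k: float = 1.25,
    quartile_method: str = "linear",
) -> pd.DataFrame:
    """Per strain x condition: replicate filtering, median, normalized size.

    Input columns: strain, condition, rep1..rep4 (NaN = missing replicate).
    Output columns: strain, condition, n_kept, median, normalized where
    ``normalized`` is median(condition) / median(control) per strain, absent
    (NaN) when the strain lacks the control condition or the control median
    is zero.  Strains whose replicate set cannot be filtered (fewer than two
    finite values) are flagged with n_kept=0 and a NaN median.
    """
    rows = []
    for row in table.itertuples():
        reps = np.array([getattr(row, c) for c in REP_COLUMNS], dtype=float)
        try:
            kept = filter_replicates(reps, k=k, quartile_method=quartile_method)
        except ValueError:
            logger.warning(
                "strain %s condition %s: unfilterable replicates %s",
                row.strain, row.condition, reps,
            )
            rows.append((row.strain, row.condition, 0, np.nan))
            continue
        rows.append((row.strain, row.condition, kept.size, float(np.median(kept))))
    out = pd.DataFrame(rows, columns=["strain", "condition", "n_kept", "median"])
    ctrl = (
        out.loc[out["condition"] == control, ["strain", "median"]]
        .rename(columns={"median": "_ctrl"})
    )
    out = out.merge(ctrl, on="strain", how="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        out["normalized"] = np.where(
            out["_ctrl"] > 0, out["median"] / out["_ctrl"], np.nan
        )
    missing_ctrl = out.loc[out["_ctrl"].isna(), "strain"].unique()
    if missing_ctrl.size and (out["condition"] != control).any():
        logger.warning(
            "%d strains lack the control condition %r; normalized size absent",
            missing_ctrl.size, control,
        )
    return out.drop(columns="_ctrl")


def dispersion_qcd(values, quartile_method: str = "linear") -> float:
    """Quartile coefficient of dispersion (Q3 - Q1)/(Q3 + Q1)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("empty input")
    q1, q3 = _quartiles(arr, quartile_method)
    if q3 + q1 == 0:
        logger.warning("QCD undefined: Q1 + Q3 == 0")
        return float("nan")
    return (q3 - q1) / (q3 + q1)


def viability(values, threshold: float = 0.0) -> float:
    """Fraction of strains with median size above ``threshold``."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("empty input")
    return float(np.mean(arr > threshold))


@dataclass(frozen=True)
class PoolAssignment:
    condition: str
    high_pool: tuple[str, ...]
    low_pool: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.high_pool) & set(self.low_pool):
            raise ValueError("pools overlap")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.condition, "high", s) for s in self.high_pool]
            + [(self.condition, "low", s) for s in self.low_pool],
            columns=["condition", "pool", "strain"],
        )


def select_pools(
    pheno: pd.DataFrame, condition: str, n: int = 20, by: str = "median"
) -> PoolAssignment:
    """Two-tailed selection: the n largest and n smallest medians.

    Ties at pool boundaries are broken by lexicographic strain id so the
    assignment is deterministic under input-row permutation.  Strains with
    no usable median in the condition are ineligible.
    """
    sub = pheno.loc[
        (pheno["condition"] == condition) & pheno[by].notna(),
        ["strain", by],
    ]
    if len(sub) < 2 * n:
        raise ValueError(
            f"condition {condition!r}: need >= {2 * n} strains with a usable "
            f"{by}, found {len(sub)}"
        )
    asc = sub.sort_values([by, "strain"], ascending=[True, True], kind="mergesort")
    low = tuple(asc["strain"].head(n))
    high = tuple(asc["strain"].tail(n)[::-1])
    return PoolAssignment(condition=condition, high_pool=high, low_pool=low)
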