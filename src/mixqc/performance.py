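"""Deviation-from-predicted metrics and the reliable dynamic range.

For every detected miRNA the deviation D is the observed minus the
predicted log2 ratio.  The median of D over all miRNAs indicates bias and
its inter-quartile range indicates precision.  The *reliable range* is
the interval of average log2 signal within which at least a ``coverage``
fraction (default 95%) of the deviation distribution stays inside a
tolerance (default +-log2(1.5) ~ 0.585, half a fold change).  The
deviation distribution along the dynamic range is modeled empirically:
records are sorted by signal and central-coverage quantile intervals are
computed over sliding windows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .mixture_model import RatioTable
from .selectivity import SelectivityClassification

__all__ = [
    "DEFAULT_TOLERANCE_LOG2",
    "DeviationTable",
    "BiasPrecision",
    "ReliableRange",
    "deviation_table",
    "bias_precision",
    "reliable_range",
]

#: Half a fold change on the log2 scale, the default deviation tolerance.
DEFAULT_TOLERANCE_LOG2 = math.log2(1.5)

#: DataFrame indexed by miRNA id with columns ``D`` (observed M - predicted
#: M), ``A_avg`` (mean of observed and predicted A) and ``class``.
DeviationTable = pd.DataFrame


def deviation_table(
    predicted: RatioTable,
    observed: RatioTable,
    classification: Optional[SelectivityClassification] = None,
) -> DeviationTable:
    """Join predicted and observed MA records into per-miRNA deviations.

    miRNAs present in only one input are excluded; their count is kept in
    ``.attrs["n_excluded"]``.
    """
    common = predicted.index.intersection(observed.index)
    n_excluded = (len(predicted) - len(common)) + (len(observed) - len(common))
    if len(common) == 0:
        warnings.warn("predicted and observed records share no miRNAs", stacklevel=2)
    out = pd.DataFrame(
        {
            "D": observed.loc[common, "M"] - predicted.loc[common, "M"],
            "A_avg": (observed.loc[common, "A"] + predicted.loc[common, "A"]) / 2.0,
        },
        index=common,
    )
    if classification is not None:
        out["class"] = classification.class_of.reindex(common)
    out.attrs["n_excluded"] = int(n_excluded)
    return out


@dataclass
class BiasPrecision:
    """Median deviation (bias) and IQR of deviation (precision)."""

    median: float
    iqr: float
    per_class: Optional[pd.DataFrame] = None  # columns: median, iqr, n


def _iqr(x: np.ndarray) -> float:
    q1, q3 = np.percentile(x, [25.0, 75.0])
    return float(q3 - q1)


def bias_precision(records: DeviationTable, by_class: bool = False) -> BiasPrecision:
    """Summarize the deviation distribution, overall and optionally per class.

    Quantiles use the linear-interpolation rule.
    """
    if len(records) == 0:
        raise ValueError("no deviation records")
    d = records["D"].to_numpy(float)
    result = BiasPrecision(median=float(np.median(d)), iqr=_iqr(d))
    if by_class:
        if "class" not in records.columns:
            raise ValueError("records carry no class labels")
        rows = {}
        for label, grp in records.groupby("class", sort=True):
            g = grp["D"].to_numpy(float)
            rows[label] = {"median": float(np.median(g)), "iqr": _iqr(g), "n": len(g)}
        result.per_class = pd.DataFrame(rows).T
    return result


@dataclass
class ReliableRange:
    """The reliable region of the dynamic range (log2 signal units).

    ``defined`` is False (and the limits None) when no window satisfies
    the tolerance — the "not determined" case.
    """

    lower_limit: Optional[float]
    upper_limit: Optional[float]
    tolerance: float
    coverage: float
    window_size: int
    defined: bool
    reason: Optional[str] = None

    @property
    def range_span(self) -> Optional[float]:
        if not self.defined:
            return None
        return self.upper_limit - self.lower_limit

    def contains(self, a_values: pd.Series) -> pd.Series:
        if not self.defined:
            raise ValueError("reliable range is not determined")
        return (a_values >= self.lower_limit) & (a_values <= self.upper_limit)


def _window_quantile_intervals(
    d_sorted: np.ndarray, window_size: int, coverage: float
) -> tuple[np.ndarray, np.ndarray]:
    """Central-coverage empirical interval of D over each sliding window."""
    lo_q = (1.0 - coverage) / 2.0
    windows = np.lib.stride_tricks.sliding_window_view(d_sorted, window_size)
    lo = np.quantile(windows, lo_q, axis=1, method="linear")
    hi = np.quantile(windows, 1.0 - lo_q, axis=1, method="linear")
    return lo, hi


def reliable_range(
    records: DeviationTable,
    tolerance: float = DEFAULT_TOLERANCE_LOG2,
    coverage: float = 0.95,
    window_size: Optional[int] = None,
    assess_upper: bool = False,
) -> ReliableRange:
    """Locate the signal interval where deviations stay within tolerance.

    Records are sorted by ``A_avg``; over sliding windows of
    ``window_size`` consecutive records (default max(50, 5% of records))
    the empirical central ``coverage`` interval of D is computed.  A
    window *complies* when that interval lies within [-tolerance,
    +tolerance].

    Without upper-limit assessment (sequencing platforms) the lower limit
    is the center A of the first window from which every higher-signal
    window complies, and the upper limit is the maximum ``A_avg`` (the
    maximum detectable value).  With ``assess_upper`` (hybridization
    platforms, which can saturate) both limits bound the longest
    contiguous run of compliant windows (ties broken toward higher
    signal).  If no window complies the range is flagged not determined.
    """
    n = len(records)
    if window_size is None:
        window_size = max(50, int(np.ceil(0.05 * n)))
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    if n < 2 * window_size:
        return ReliableRange(
            None, None, tolerance, coverage, window_size, False,
            reason=f"insufficient records ({n} < {2 * window_size})",
        )
    order = records["A_avg"].to_numpy(float).argsort(kind="stable")
    a = records["A_avg"].to_numpy(float)[order]
    d = records["D"].to_numpy(float)[order]
    lo, hi = _window_quantile_intervals(d, window_size, coverage)
    compliant = (lo >= -tolerance) & (hi <= tolerance)
    centers = a[np.arange(len(compliant)) + window_size // 2]

    if not compliant.any():
        return ReliableRange(
            None, None, tolerance, coverage, window_size, False,
            reason="no window meets the deviation tolerance",
        )

    if assess_upper:
        # longest contiguous compliant run; prefer the higher-signal run on ties
        best_start = best_len = -1
        i = 0
        while i < len(compliant):
            if compliant[i]:
                j = i
                while j < len(compliant) and compliant[j]:
                    j += 1
                if (j - i) >= best_len:
                    best_start, best_len = i, j - i
                i = j
            else:
                i += 1
        lower = float(centers[best_start])
        upper = float(centers[best_start + best_len - 1])
    else:
        # earliest window from which all higher-signal windows comply
        suffix_ok = np.flip(np.logical_and.accumulate(np.flip(compliant)))
        if not suffix_ok.any():
            return ReliableRange(
                None, None, tolerance, coverage, window_size, False,
                reason="no suffix of windows meets the deviation tolerance",
            )
        first = int(np.argmax(suffix_ok))
        lower = float(centers[first])
        upper = float(a.max())
    return ReliableRange(lower, upper, tolerance, coverage, window_size, True)
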