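"""FRAP normalization, mobile fractions, group summaries and Welch tests.

Normalized recovery is (F_t - F_bleach) / (F_pre - F_bleach), with F_pre the
mean of the pre-bleach frames (optionally the single frame preceding the
bleach) and F_bleach the intensity of the first post-bleach frame. The mobile
fraction is the same normalization applied to F_end, the average of the final
three timepoints: M = (F_end - F_bleach) / (F_pre - F_bleach).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .datatypes import FrapResult, FrapTrace

__all__ = [
    "normalize_trace",
    "mobile_fraction",
    "analyze_trace",
    "group_summary",
    "fold_change",
    "welch_t_test",
]


def _reference_levels(trace: FrapTrace, pre_mode: str) -> tuple[float, float]:
    if pre_mode == "mean":
        f_pre = float(trace.intensities[:trace.n_pre].mean())
    elif pre_mode == "last":
        f_pre = float(trace.intensities[trace.n_pre - 1])
    else:
        raise ValueError(f"unknown pre_mode {pre_mode!r}")
    f_bleach = float(trace.intensities[trace.bleach_index])
    if f_pre == f_bleach:
        raise ZeroDivisionError(
            f"trace {trace.name or '<unnamed>'}: F_pre equals F_bleach; "
            "normalization undefined")
    return f_pre, f_bleach


def normalize_trace(trace: FrapTrace, pre_mode: str = "mean") -> np.ndarray:
    """Per-frame normalized intensity (F_t - F_bleach) / (F_pre - F_bleach)."""
    f_pre, f_bleach = _reference_levels(trace, pre_mode)
    return (trace.intensities - f_bleach) / (f_pre - f_bleach)


def mobile_fraction(trace: FrapTrace, pre_mode: str = "mean") -> float:
    """M = (F_end - F_bleach) / (F_pre - F_bleach), F_end = mean of the
    final three timepoints."""
    n_post = len(trace.intensities) - trace.bleach_index
    if n_post < 3:
        raise ValueError(f"need >= 3 post-bleach frames, got {n_post}")
    f_pre, f_bleach = _reference_levels(trace, pre_mode)
    f_end = float(trace.intensities[-3:].mean())
    return (f_end - f_bleach) / (f_pre - f_bleach)


def analyze_trace(trace: FrapTrace, pre_mode: str = "mean") -> FrapResult:
    """Normalized curve plus mobile fraction; out-of-range fractions flagged."""
    f_pre, f_bleach = _reference_levels(trace, pre_mode)
    norm = (trace.intensities - f_bleach) / (f_pre - f_bleach)
    m = mobile_fraction(trace, pre_mode)
    return FrapResult(normalized=norm, mobile_fraction=m, f_pre=f_pre,
                      f_bleach=f_bleach,
                      f_end=float(trace.intensities[-3:].mean()),
                      flagged=not (-0.1 <= m <= 1.1))


def group_summary(values) -> dict:
    """Mean, s.d. (ddof 1), s.e. and n of a sample of mobile fractions."""
    v = np.asarray(list(values), dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    sd = float(v.std(ddof=1))
    return {"mean": float(v.mean()), "sd": sd,
            "se": sd / np.sqrt(len(v)), "n": len(v)}


def fold_change(numerator_mean: float, denominator_mean: float) -> tuple[float, float]:
    """Ratio of group means, reported half-up to one decimal.

    Returns (rounded, exact); e.g. mean mobile fractions 50.7% over 13.6%
    report as a 3.7-fold increase.
    """
    if denominator_mean <= 0:
        raise ZeroDivisionError("denominator mean must be positive")
    exact = numerator_mean / denominator_mean
    rounded = float(np.floor(exact * 10.0 + 0.5) / 10.0)
    return rounded, exact


def welch_t_test(a, b, tails: int = 2) -> dict:
    """Unpaired t test with Welch's correction (unequal variances).

    Returns t, the Welch-Satterthwaite degrees of freedom, and the one- or
    two-tailed p (one-tailed: alternative mean(a) > mean(b)).
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return {"t": 0.0, "df": float(len(a) + len(b) - 2), "p": 1.0}
        raise ValueError("both samples degenerate with unequal means")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    alt = "two-sided" if tails == 2 else "greater"
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alt)
    return {"t": float(res.statistic), "df": float(res.df),
            "p": float(res.pvalue)}
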