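"""Statistical primitives: Student's t, one-way ANOVA, Duncan's MRT.

Thin, explicit wrappers around scipy for the two standard tests, plus
an implementation of Duncan's multiple range test whose critical points
are computed from the studentized range distribution at Duncan's
protection level 1−(1−α)^(p−1) — no tabulated values.
"""

from __future__ import annotations

import string
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import StatisticsError

GroupedSamples = Dict[str, Sequence[float]]


def _as_array(sample: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(sample, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise StatisticsError(f"sample {name!r} needs ≥2 observations")
    return arr


def student_t(
    a: Sequence[float], b: Sequence[float], variant: str = "pooled"
) -> Tuple[float, float, float]:
    """Two-sample two-sided t-test.

    Returns (t, df, p). ``variant`` is ``pooled`` (classic Student,
    default) or ``welch``. Two samples with zero variance and equal
    means give t = 0, p = 1 by convention.
    """
    x, y = _as_array(a, "a"), _as_array(b, "b")
    if variant not in ("pooled", "welch"):
        raise StatisticsError(f"unknown t-test variant {variant!r}")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        df = len(x) + len(y) - 2 if variant == "pooled" else float(len(x) + len(y) - 2)
        return 0.0, float(df), 1.0
    res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def one_way_anova(groups: GroupedSamples) -> Tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA. Returns (F, df_between, df_within, p).

    All observations identical yields F = 0, p = 1 (scipy returns NaN
    for zero total variance).
    """
    if len(groups) < 2:
        raise StatisticsError("ANOVA needs ≥2 groups")
    arrays = [_as_array(v, k) for k, v in groups.items()]
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    df1, df2 = k - 1, n_total - k
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, df1, df2, 1.0
    f_stat, p = sps.f_oneway(*arrays)
    if not np.isfinite(f_stat):  # zero within-group variance, unequal means
        return float("inf"), df1, df2, 0.0
    return float(f_stat), df1, df2, float(p)


def _mean_square_error(arrays: List[np.ndarray]) -> Tuple[float, int]:
    df = sum(len(a) - 1 for a in arrays)
    sse = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    return (sse / df if df > 0 else 0.0), df


def duncan_mrt(groups: GroupedSamples, alpha: float = 0.05) -> Dict[str, str]:
    """Duncan's multiple range test letter display.

    Groups are ranked by mean; the range spanning p ordered means is
    declared homogeneous when it does not exceed the least significant
    range R_p = q(1−α_p; p, df_e)·sqrt(MSE/n_h), with Duncan's
    protection level α_p = 1−(1−α)^(p−1) and n_h the harmonic mean
    group size. Ranges inside a homogeneous range are not subdivided
    (step-down rule). Groups sharing a letter are not significantly
    different.
    """
    if not 0 < alpha < 1:
        raise StatisticsError("alpha must be in (0, 1)")
    names = list(groups)
    if len(names) == 1:
        return {names[0]: "a"}
    arrays = {k: _as_array(v, k) for k, v in groups.items()}
    mse, dfe = _mean_square_error(list(arrays.values()))
    n_h = len(arrays) / sum(1.0 / len(a) for a in arrays.values())
    ranked = sorted(names, key=lambda k: -arrays[k].mean())
    means = np.array([arrays[k].mean() for k in ranked])
    k = len(ranked)

    if mse == 0.0:
        # Degenerate data: any difference in means is significant.
        segments = []
        i = 0
        while i < k:
            j = i
            while j + 1 < k and means[j + 1] == means[i]:
                j += 1
            segments.append((i, j))
            i = j + 1
    else:
        lsr = {
            p: float(sps.studentized_range.ppf(1 - (1 - (1 - alpha) ** (p - 1)), p, dfe))
            * np.sqrt(mse / n_h)
            for p in range(2, k + 1)
        }

        segments: List[Tuple[int, int]] = []

        def step_down(lo: int, hi: int) -> None:
            if lo >= hi:
                segments.append((lo, hi))
                return
            span = hi - lo + 1
            if means[lo] - means[hi] <= lsr[span]:
                segments.append((lo, hi))
                return
            step_down(lo, hi - 1)
            step_down(lo + 1, hi)

        step_down(0, k - 1)
        # Drop segments contained in another homogeneous segment.
        segments = sorted(set(segments))
        segments = [
            s
            for s in segments
            if not any(t != s and t[0] <= s[0] and s[1] <= t[1] for t in segments)
        ]
        segments.sort()

    letters = {name: "" for name in names}
    alphabet = string.ascii_lowercase
    for idx, (lo, hi) in enumerate(segments):
        letter = alphabet[idx % len(alphabet)] * (idx // len(alphabet) + 1)
        for pos in range(lo, hi + 1):
            letters[ranked[pos]] += letter
    return letters
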