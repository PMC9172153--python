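"""Shared statistical primitives.

Three primitives drive all downstream stages:

* Welch's unequal-variance t-test (two-sided), used for every per-feature
  genotype comparison.  No multiplicity correction is applied downstream:
  with tiny group sizes the Welch test is conservative, and each feature is
  reported with its raw p-value.
* Spearman rank correlation with a t-approximation critical value, used to
  flag motif associations.
* The signed normalized contrast x = (m - w) / (m + w) of genotype mean
  rates, the volcano x-axis.  It saturates at +/-1 exactly when one genotype
  mean is zero, which is what puts all-or-nothing events on the plot edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

#: Published preset for the motif-association |rho| threshold at n = 571
#: events; the default is computed from the t-approximation instead.
PRESET_RHO_THRESHOLD = 0.0655


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def _as_array(xs: Sequence[float], name: str) -> np.ndarray:
    a = np.asarray(xs, dtype=float)
    if a.ndim != 1 or a.size < 2:
        raise ValueError(f"{name}: need a 1-d group with >= 2 values")
    return a


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Two-sided Welch t-test of mean(group_a) - mean(group_b).

    Degenerate zero-variance groups are handled explicitly: equal means give
    t = 0, p = 1; unequal means give p = 0 with the ``degenerate`` flag set,
    so all-or-nothing events stay in the output and remain auditable.
    """
    a = _as_array(group_a, "group_a")
    b = _as_array(group_b, "group_b")
    return welch_t_from_summary(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )


def welch_t_from_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
) -> WelchResult:
    """Welch test from summary statistics (sample SDs, ddof = 1)."""
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    va, vb = sd_a ** 2, sd_b ** 2
    if va == 0.0 and vb == 0.0:
        if mean_a == mean_b:
            return WelchResult(0.0, float(n_a + n_b - 2), 1.0)
        return WelchResult(
            math.copysign(math.inf, mean_a - mean_b),
            float(n_a + n_b - 2), 0.0, degenerate=True,
        )
    se2 = va / n_a + vb / n_b
    t = (mean_a - mean_b) / math.sqrt(se2)
    df = se2 ** 2 / (
        (va / n_a) ** 2 / (n_a - 1) + (vb / n_b) ** 2 / (n_b - 1)
    )
    p = float(2.0 * sps.t.sf(abs(t), df))
    return WelchResult(float(t), float(df), p)


def spearman_rho(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Spearman correlation: Pearson correlation of average-fractional ranks.

    Returns NaN when either vector is constant (undefined correlation).
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d vectors")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.dot(rx, ry) / math.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))


def spearman_critical(n: int, alpha: float = 0.05, tails: str = "one") -> float:
    """Critical |rho| at significance alpha via the t-approximation.

    rho* = t* / sqrt(n - 2 + t*^2) with t* the upper-tail t quantile on
    n - 2 degrees of freedom (alpha split in half for two-tailed use).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    q = alpha if tails == "one" else alpha / 2.0
    tstar = float(sps.t.isf(q, n - 2))
    return tstar / math.sqrt(n - 2 + tstar ** 2)


def normalized_contrast(
    mut_rates: Sequence[float], wt_rates: Sequence[float]
) -> float:
    """Signed contrast x = (m - w) / (m + w) of genotype mean rates.

    x lies in [-1, +1]; x = +1 exactly when the WT mean is 0 and the mutant
    mean positive.  NaN when both means are 0 (no evidence either way);
    callers drop such events.
    """
    m = float(np.mean(np.asarray(mut_rates, dtype=float)))
    w = float(np.mean(np.asarray(wt_rates, dtype=float)))
    if m < 0 or w < 0:
        raise ValueError("rates must be non-negative")
    if m == 0.0 and w == 0.0:
        return float("nan")
    return (m - w) / (m + w)
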