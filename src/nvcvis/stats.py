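"""Statistical layer: paired t-test, chi-square, Levene's test.

The paired t-test is additionally exposed in a summary-driven form so the
before/after quality comparison can be reproduced from printed means and
standard deviations without raw per-case data.  Test statistics are
computed from the textbook formulas; only reference distributions come from
scipy.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedTResult",
    "paired_t",
    "summary_t",
    "chi_square_2x2",
    "levene",
]


@dataclass
class PairedTResult:
    n: int
    mean_diff: float
    sd_diff: float
    se: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    p_two_tailed: float


def _t_from_summary(mean_diff: float, sd_diff: float, n: int) -> PairedTResult:
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    if sd_diff <= 0:
        raise ValueError("degenerate: zero-variance differences")
    df = n - 1
    se = sd_diff / np.sqrt(n)
    t = mean_diff / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    tcrit = float(sps.t.ppf(0.975, df))
    return PairedTResult(
        n=n,
        mean_diff=float(mean_diff),
        sd_diff=float(sd_diff),
        se=float(se),
        ci_low=float(mean_diff - tcrit * se),
        ci_high=float(mean_diff + tcrit * se),
        t=float(t),
        df=df,
        p_two_tailed=p,
    )


def paired_t(before, after) -> PairedTResult:
    """Two-tailed paired t-test on differences ``before - after``.

    The sign convention matches before/after quality comparisons where an
    improvement after the intervention yields a negative mean difference.
    """
    b = np.asarray(before, float)
    a = np.asarray(after, float)
    if b.shape != a.shape or b.ndim != 1:
        raise ValueError("before/after must be 1-D sequences of equal length")
    if len(b) < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = b - a
    sd = float(d.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate: zero-variance differences")
    return _t_from_summary(float(d.mean()), sd, len(d))


def summary_t(mean_diff: float, sd_diff: float, n: int) -> PairedTResult:
    """Paired t-test driven by printed summary statistics."""
    return _t_from_summary(mean_diff, sd_diff, int(n))


def chi_square_2x2(
    table, correction: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 contingency table (df = 1).

    Continuity correction is off by default; enable with ``correction=True``.
    """
    obs = np.asarray(table, float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("degenerate margin (zero row or column)")
    expected = np.outer(row, col) / total
    dev = np.abs(obs - expected)
    if correction:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev**2 / expected).sum())
    p = float(sps.chi2.sf(stat, 1))
    return stat, 1, p


def levene(*groups) -> tuple[float, float]:
    """Classic Levene test (absolute deviations from the group means).

    ``W`` follows an F(k-1, N-k) reference distribution under equal
    variances.
    """
    gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 2:
        raise ValueError("Levene test needs at least 2 groups")
    if any(len(g) < 2 for g in gs):
        raise ValueError("every group needs at least 2 observations")
    k = len(gs)
    ns = np.array([len(g) for g in gs])
    N = int(ns.sum())
    z = [np.abs(g - g.mean()) for g in gs]
    zbars = np.array([zi.mean() for zi in z])
    zbar = float(np.concatenate(z).mean())
    num = float((ns * (zbars - zbar) ** 2).sum())
    den = float(sum(((zi - zb) ** 2).sum() for zi, zb in zip(z, zbars)))
    if den == 0:
        if num == 0:
            return 0.0, 1.0
        raise ValueError("degenerate: zero within-group deviation variance")
    W = (N - k) / (k - 1) * num / den
    p = float(sps.f.sf(W, k - 1, N - k))
    return float(W), p
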