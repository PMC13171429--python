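"""Bootstrap equality-of-means test and box-plot summaries.

The focal-gene omega set is compared with the core-gene background by the
standard shift bootstrap for equality of means: both groups are recentred on
the pooled mean (imposing the null), resampled with replacement at their own
sizes, and the two-sided p-value is the add-one fraction of replicate mean
differences at least as extreme as the observed one,
``p = (1 + #{|T*| >= |T_obs|}) / (B + 1)`` — never exactly zero, floor
``1/(B+1)``. Percentiles use linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BootstrapResult:
    t_obs: float
    B: int
    p_value: float
    seed: int
    n_a: int
    n_b: int


@dataclass(frozen=True)
class BoxSummary:
    q25: float
    median: float
    q75: float
    whisker_lo: float
    whisker_hi: float
    n: int


def boot_mean_eq_test(group_a, group_b, B: int = 1000, seed: int = 0) -> BootstrapResult:
    """Two-sided shift-bootstrap test for equality of group means."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    if B < 1:
        raise ValueError("B must be >= 1")
    t_obs = float(a.mean() - b.mean())
    pooled = float(np.concatenate([a, b]).mean())
    a0 = a - a.mean() + pooled
    b0 = b - b.mean() + pooled
    rng = np.random.default_rng(seed)
    ra = rng.choice(a0, size=(B, a.size), replace=True).mean(axis=1)
    rb = rng.choice(b0, size=(B, b.size), replace=True).mean(axis=1)
    t_star = ra - rb
    p = (1.0 + int(np.count_nonzero(np.abs(t_star) >= abs(t_obs)))) / (B + 1.0)
    return BootstrapResult(
        t_obs=t_obs, B=B, p_value=p, seed=seed, n_a=a.size, n_b=b.size
    )


def box_summary(values) -> BoxSummary:
    """Quartiles (linear interpolation) and Tukey 1.5*IQR whiskers."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values")
    q25, med, q75 = np.percentile(v, [25, 50, 75], method="linear")
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return BoxSummary(
        q25=float(q25),
        median=float(med),
        q75=float(q75),
        whisker_lo=float(inside.min()),
        whisker_hi=float(inside.max()),
        n=v.size,
    )
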