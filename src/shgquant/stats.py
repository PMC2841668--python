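"""Group comparisons: t-tests from summary statistics and depth-wise profile tests.

The bulk-optics comparisons are two-sided two-sample t-tests computed from
printed group summaries (mean, SD, n).  The pooled-variance Student form is
the default; a Welch companion is provided for robustness checks.  Profile
groups (per-subject F/B curves) are compared depth by depth at a fixed
interval, with no multiple-testing correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .montecarlo import DepthProfile
from .optics import GroupSummary

__all__ = [
    "pooled_ttest_from_summary",
    "welch_ttest_from_summary",
    "depthwise_profile_test",
]


def _ttest(a: GroupSummary, b: GroupSummary, equal_var: bool):
    pooled_num = (a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2
    if pooled_num == 0 and a.sd == 0 and b.sd == 0:
        # degenerate: no within-group variance
        if a.mean == b.mean:
            return 0.0, float(a.n + b.n - 2), 1.0, True
        return np.inf, float(a.n + b.n - 2), 0.0, True
    t, p = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=equal_var
    )
    if equal_var:
        df = float(a.n + b.n - 2)
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(t), df, float(p), False


def pooled_ttest_from_summary(
    a: GroupSummary, b: GroupSummary
) -> tuple[float, int, float]:
    """Two-sided pooled-variance Student t-test from group summaries.

    Returns ``(t, df, p)`` with ``df = n_a + n_b - 2``.  A degenerate
    zero-variance comparison with unequal means reports p = 0.
    """
    t, df, p, _ = _ttest(a, b, equal_var=True)
    return t, int(df), p


def welch_ttest_from_summary(
    a: GroupSummary, b: GroupSummary
) -> tuple[float, float, float]:
    """Two-sided Welch t-test (Satterthwaite df) from group summaries."""
    return _ttest(a, b, equal_var=False)[:3]


def depthwise_profile_test(
    group_a: list[DepthProfile],
    group_b: list[DepthProfile],
    interval: float = 10.0,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Two-sample t-tests between profile groups at fixed depth intervals.

    Profiles are linearly resampled onto a common grid spanning the overlap
    of all profiles at spacing ``interval`` (um).  Returns a DataFrame with
    columns ``depth_um, t, p, n_a, n_b, flagged``; depths where either group
    has fewer than 2 defined subjects are flagged and carry no p-value.
    The ``attrs`` carry ``all_significant`` — True when every unflagged
    depth has p below ``alpha``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 profiles per group")
    lo = max(p.depths.min() for p in group_a + group_b)
    hi = min(p.depths.max() for p in group_a + group_b)
    grid = np.arange(lo, hi + 1e-9, interval)

    def resample(profiles: list[DepthProfile]) -> np.ndarray:
        out = np.empty((len(profiles), grid.size))
        for i, p in enumerate(profiles):
            ok = ~p.undefined
            out[i] = np.interp(grid, p.depths[ok], p.values[ok])
        return out

    va, vb = resample(group_a), resample(group_b)
    rows = []
    for j, z in enumerate(grid):
        xa, xb = va[:, j], vb[:, j]
        xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
        if xa.size < 2 or xb.size < 2:
            rows.append((z, np.nan, np.nan, xa.size, xb.size, True))
            continue
        if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
            # degenerate: no within-group variance at this depth
            t, p = (0.0, 1.0) if xa.mean() == xb.mean() else (np.inf, 0.0)
        else:
            t, p = sps.ttest_ind(xa, xb, equal_var=True)
        rows.append((z, float(t), float(p), xa.size, xb.size, False))
    df = pd.DataFrame(rows, columns=["depth_um", "t", "p", "n_a", "n_b", "flagged"])
    valid = df.loc[~df.flagged, "p"]
    df.attrs["all_significant"] = bool(valid.size and (valid < alpha).all())
    return df
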