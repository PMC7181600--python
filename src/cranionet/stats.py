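"""Group-comparison statistics for network parameters and morphospace.

Implements the comparative battery used on the specimen table: two-sided
Mann–Whitney U reported as a normal-approximation z (tie-corrected, no
continuity correction), two-sample Kolmogorov–Smirnov D, OLS of each
descriptor against relative skull size, an ANCOVA slope-equality F-test,
and a permutational MANOVA (PERMANOVA) on the morphospace distances with
Bonferroni-corrected pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .netio import SpecimenMeta, Stage


@dataclass
class TestResult:
    statistic: float
    p: float
    kind: str  # "mwu_z" | "ks_d" | "permanova_F"
    n1: int
    n2: int
    sign: int = 0          # sign of the z statistic (mwu only)
    U: float | None = None  # raw Mann–Whitney U (mwu only)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    R2: float
    p_slope: float
    n: int


@dataclass
class AncovaResult:
    F: float
    p: float
    df1: int
    df2: int


# ---------------------------------------------------------------------
# Rank tests


def mann_whitney(x, y, continuity: bool = False) -> TestResult:
    """Two-sided Mann–Whitney U reported on the z scale.

    z = (U - n1 n2 / 2) / sigma_U with the tie-corrected variance; no
    continuity correction by default. The reported statistic is |z|, with
    the sign available separately.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0  # number of (x > y) pairs counting ties as 1/2
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:  # all observations identical
        return TestResult(0.0, 1.0, "mwu_z", n1, n2, sign=0, U=float(u1))
    diff = u1 - mu
    if continuity:
        diff = np.sign(diff) * max(abs(diff) - 0.5, 0.0)
    z = diff / np.sqrt(var)
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return TestResult(float(abs(z)), float(min(p, 1.0)), "mwu_z", n1, n2,
                      sign=int(np.sign(z)), U=float(u1))


def ks_test(x, y) -> TestResult:
    """Two-sample Kolmogorov–Smirnov: D = sup |ECDF_x - ECDF_y|, asymptotic p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = scipy.stats.ks_2samp(x, y, method="asymp")
    return TestResult(float(res.statistic), float(res.pvalue), "ks_d",
                      len(x), len(y))


# ---------------------------------------------------------------------
# Regression


def ols(x, y) -> RegressionResult:
    """Simple least-squares regression with a two-sided t-test on the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant; slope undefined")
    res = scipy.stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        R2=float(res.rvalue ** 2),
        p_slope=float(res.pvalue),
        n=len(x),
    )


def ancova_slopes(x1, y1, x2, y2) -> AncovaResult:
    """F-test for equality of regression slopes between two groups.

    Compares the full model (separate slopes, i.e. a group × covariate
    interaction) against the reduced common-slope model:
    F = (SSE_reduced - SSE_full) / (SSE_full / (n1 + n2 - 4)), df = (1, n-4).
    """
    x1, y1 = np.asarray(x1, float), np.asarray(y1, float)
    x2, y2 = np.asarray(x2, float), np.asarray(y2, float)
    if len(x1) < 3 or len(x2) < 3:
        raise ValueError("each group needs n >= 3")
    n = len(x1) + len(x2)
    df2 = n - 4
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom")
    g = np.concatenate([np.zeros(len(x1)), np.ones(len(x2))])
    x = np.concatenate([x1, x2])
    y = np.concatenate([y1, y2])
    full = np.column_stack([np.ones(n), g, x, g * x])
    reduced = full[:, :3]
    sse_full = _sse(full, y)
    sse_red = _sse(reduced, y)
    f = max(sse_red - sse_full, 0.0) / (sse_full / df2)
    p = float(scipy.stats.f.sf(f, 1, df2))
    return AncovaResult(F=float(f), p=p, df1=1, df2=df2)


def _sse(design: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid)


# ---------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    overall: TestResult
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Anderson's pseudo-F from squared distances and integer group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.nonzero(codes == g)[0]
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df1 = n_groups - 1
    df2 = n - n_groups
    return (ss_among / df1) / (ss_within / df2)


def permanova(
    dist: pd.DataFrame | np.ndarray,
    groups,
    n_permutations: int = 10000,
    seed: int | np.random.Generator | None = None,
    pairwise: bool = True,
) -> PermanovaResult:
    """One-way PERMANOVA with optional Bonferroni-corrected pairwise tests.

    The permutation p-value is (#{F_perm >= F_obs} + 1) / (n_permutations + 1);
    pairwise p-values are multiplied by the number of comparisons and capped
    at 1. Groups of size 1 are skipped in the pairwise table with a warning.
    """
    d = np.asarray(dist, dtype=float)
    groups = np.asarray(groups)
    if d.shape[0] != len(groups):
        raise ValueError("distance matrix and group labels disagree in length")
    uniq, codes = np.unique(groups, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    d2 = d ** 2

    def run(idx: np.ndarray, labels: np.ndarray) -> TestResult:
        u, c = np.unique(labels, return_inverse=True)
        sub2 = d2[np.ix_(idx, idx)]
        f_obs = _pseudo_f(sub2, c, len(u))
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(c)
            if _pseudo_f(sub2, perm, len(u)) >= f_obs - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
        sizes = [int((c == g).sum()) for g in range(len(u))]
        return TestResult(float(f_obs), float(p), "permanova_F",
                          sizes[0], sizes[-1])

    overall = run(np.arange(len(groups)), groups)
    rows = []
    if pairwise:
        import warnings as _w

        pairs = [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1:]]
        n_cmp = len(pairs)
        for a, b in pairs:
            idx = np.nonzero((groups == a) | (groups == b))[0]
            if (groups == a).sum() < 2 or (groups == b).sum() < 2:
                _w.warn(f"pairwise PERMANOVA {a} vs {b} skipped (group of size 1)",
                        stacklevel=2)
                continue
            res = run(idx, groups[idx])
            rows.append({
                "group_a": a, "group_b": b, "F": res.statistic,
                "p_raw": res.p, "p_bonferroni": min(res.p * n_cmp, 1.0),
            })
    return PermanovaResult(overall=overall, pairwise=pd.DataFrame(rows))


# ---------------------------------------------------------------------
# Relative skull size helper


def relative_sizes(metas: dict[str, SpecimenMeta]) -> pd.Series:
    """Relative skull size (%) from skull-box volumes.

    Juveniles: percentage of the conspecific adult's skull-box volume.
    Adults: percentage of the largest sampled adult skull-box volume.
    """
    adults = {m.taxon: m for m in metas.values()
              if m.stage is Stage.ADULT and m.box_volume}
    if not adults:
        raise ValueError("no adult specimens with skull-box volumes")
    vmax = max(m.box_volume for m in adults.values())
    out = {}
    for sid, m in metas.items():
        if m.box_volume is None or m.stage is None:
            continue
        if m.stage is Stage.ADULT:
            out[sid] = 100.0 * m.box_volume / vmax
        else:
            adult = adults.get(m.taxon)
            if adult is None:
                continue
            out[sid] = 100.0 * m.box_volume / adult.box_volume
    return pd.Series(out, name="relative_size")
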