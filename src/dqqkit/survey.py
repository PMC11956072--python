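"""Design-aware descriptive statistics and comparison tests.

Respondents from a multistage cluster survey are correlated within primary
sampling units, so a classical Pearson chi-square overstates evidence.
:func:`cluster_adjusted_chi2` applies the Rao-Scott design-effect correction
to the Pearson statistic computed on (optionally weighted) estimated cell
proportions: the covariance of the cell-proportion estimator is obtained by
Taylor linearization with with-replacement PSU totals, generalized design
effects are the eigenvalues of ``inv(V_srs) @ V_design`` on the interaction
contrast space, and the p-value is taken from an F reference distribution
(second-order Satterthwaite correction by default, first-order optionally or
as a fallback).

Medians are compared with the plain (not cluster-adjusted) Mann-Whitney U
rank-sum test: a tie-corrected two-sided normal approximation without
continuity correction, replaced by exact enumeration of all rank
arrangements for small samples (both sizes <= 8).

Alpha is 0.05 two-sided throughout the reporting layer.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

EXACT_MW_MAX_N = 8

CORRECTION_NONE = "none"
CORRECTION_RS1 = "rao_scott_first_order"
CORRECTION_RS2 = "rao_scott_second_order"


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a between-group comparison test."""

    test: str  # "cluster_adjusted_chi2" | "mann_whitney"
    statistic: float
    df: Union[tuple[float, float], int, None]
    p_value: float
    n: int
    correction: str = CORRECTION_NONE
    design_df: Optional[int] = None  # (R-1)(C-1) of the contingency table
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")

    def format(self) -> str:
        """Serialize as ``test, statistic (4 dp), df, p (3 dp floored), n, correction``."""
        if isinstance(self.df, tuple):
            df_str = f"({self.df[0]:.2f}, {self.df[1]:.2f})"
        else:
            df_str = str(self.df)
        return (
            f"{self.test}, statistic={self.statistic:.4f}, df={df_str}, "
            f"{format_p(self.p_value)}, n={self.n}, correction={self.correction}"
        )


def format_p(p: float) -> str:
    """Display convention: three decimals, floored at 'p < 0.001'."""
    if p < 0.001:
        return "p < 0.001"
    return f"p = {p:.3f}"


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive summary of one group: a proportion or a median with IQR."""

    group_label: str
    n: int
    proportion_pct: Optional[float] = None
    frequency: Optional[int] = None
    median: Optional[float] = None
    q1: Optional[float] = None
    q3: Optional[float] = None

    def __post_init__(self) -> None:
        if self.frequency is not None and self.frequency > self.n:
            raise ValueError("frequency cannot exceed n")
        if self.median is not None and not (self.q1 <= self.median <= self.q3):
            raise ValueError("require q1 <= median <= q3")


def proportion_summary(
    flags: Sequence[bool],
    weights: Optional[Sequence[float]] = None,
    group_label: str = "",
) -> GroupSummary:
    """Weighted proportion (percent) with the unweighted frequency.

    Frequencies are always raw respondent counts; only the percentage is
    weighted.
    """
    f = np.asarray(flags, dtype=bool)
    if f.size == 0:
        raise ValueError("cannot summarize an empty group")
    if weights is None:
        w = np.ones(f.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != f.shape or np.any(w <= 0):
            raise ValueError("weights must be positive and match flags in length")
    pct = 100.0 * float(np.sum(w * f) / np.sum(w))
    return GroupSummary(
        group_label=group_label, n=int(f.size), proportion_pct=pct, frequency=int(f.sum())
    )


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """Median and quartiles by linear interpolation between order statistics.

    Uses the inclusive linear-interpolation percentile rule (numpy default),
    fixed for determinism across implementations.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot take the median of an empty sample")
    med, q1, q3 = np.percentile(v, [50, 25, 75])
    return float(med), float(q1), float(q3)


# ---------------------------------------------------------------------------
# Cluster-adjusted Pearson chi-square (Rao-Scott)
# ---------------------------------------------------------------------------


def _interaction_jacobian(P: np.ndarray) -> np.ndarray:
    """Jacobian of h_rc = p_rc - p_r+ * p_+c (r < R-1, c < C-1) w.r.t. the
    RC cell probabilities, evaluated at P."""
    R, C = P.shape
    pr = P.sum(axis=1)
    pc = P.sum(axis=0)
    d = (R - 1) * (C - 1)
    H = np.zeros((d, R * C))
    row = 0
    for r in range(R - 1):
        for c in range(C - 1):
            # dh/dp_ab = [a=r][b=c] - [a=r] p_+c - [b=c] p_r+
            Hrc = np.zeros((R, C))
            Hrc[r, c] += 1.0
            Hrc[r, :] -= pc[c]
            Hrc[:, c] -= pr[r]
            H[row] = Hrc.ravel()
            row += 1
    return H


def cluster_adjusted_chi2(
    outcome: Sequence,
    group: Sequence,
    cluster_id: Sequence,
    weights: Optional[Sequence[float]] = None,
    correction: str = "second_order",
) -> ComparisonResult:
    """Rao-Scott cluster-adjusted Pearson chi-square test of independence.

    Parameters
    ----------
    outcome, group
        Categorical per-respondent vectors (>= 2 levels each after dropping
        empty levels).
    cluster_id
        Primary sampling unit of each respondent; at least 2 distinct
        clusters are required for variance estimation.
    weights
        Optional positive survey weights (default: unweighted).
    correction
        ``"second_order"`` (Satterthwaite, default) or ``"first_order"``.

    Returns
    -------
    ComparisonResult
        ``statistic`` is the uncorrected Pearson X2 on estimated
        proportions (the quantity conventionally printed alongside the
        design-adjusted p-value); ``df`` is the (numerator, denominator)
        pair of the F reference; ``design_df`` is (R-1)(C-1).

    Notes
    -----
    With one respondent per cluster and unit weights the design covariance
    equals ``n/(n-1)`` times the multinomial covariance, so the adjusted
    statistic is the classical Pearson X2 scaled by ``(n-1)/n`` referred to
    an F distribution — asymptotically the classical test.
    """
    if correction not in ("first_order", "second_order"):
        raise ValueError("correction must be 'first_order' or 'second_order'")
    y = pd.Series(list(outcome)).reset_index(drop=True)
    g = pd.Series(list(group)).reset_index(drop=True)
    cl = pd.Series(list(cluster_id)).reset_index(drop=True)
    if not (len(y) == len(g) == len(cl)):
        raise ValueError("outcome, group and cluster_id must have equal length")
    if y.isna().any() or g.isna().any() or cl.isna().any():
        raise ValueError("missing values are not allowed")
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (len(y),) or np.any(w <= 0):
        raise ValueError("weights must be positive and match length")

    warns: list[str] = []
    # drop zero-margin levels
    for s, name in ((y, "outcome"), (g, "group")):
        counts = s.value_counts()
        empty = [lev for lev in counts.index if counts[lev] == 0]
        if empty:
            warns.append(f"dropped empty {name} levels: {empty}")
    out_levels = sorted(y.unique(), key=str)
    grp_levels = sorted(g.unique(), key=str)
    C = len(out_levels)
    R = len(grp_levels)
    if R < 2 or C < 2:
        raise ValueError(
            "need at least 2 group levels and 2 outcome levels with observations"
        )
    clusters = pd.unique(cl)
    K = len(clusters)
    if K < 2:
        raise ValueError("variance is inestimable with fewer than 2 clusters")

    n = len(y)
    gi = g.map({lev: i for i, lev in enumerate(grp_levels)}).to_numpy()
    oi = y.map({lev: i for i, lev in enumerate(out_levels)}).to_numpy()
    ci = cl.map({lev: i for i, lev in enumerate(clusters)}).to_numpy()
    cell = gi * C + oi
    RC = R * C

    W = w.sum()
    phat = np.bincount(cell, weights=w, minlength=RC) / W
    P = phat.reshape(R, C)
    pr = P.sum(axis=1)
    pc = P.sum(axis=0)
    E = np.outer(pr, pc)
    X2 = float(n * ((P - E) ** 2 / E).sum())

    # linearized design covariance of phat: cluster totals of w_i (y_i - phat) / W
    T = np.zeros((K, RC))
    np.add.at(T, (ci, cell), w)
    wk = np.bincount(ci, weights=w, minlength=K)
    Z = (T - np.outer(wk, phat)) / W
    V = (K / (K - 1)) * (Z.T @ Z)

    V0 = (np.diag(phat) - np.outer(phat, phat)) / n

    d = (R - 1) * (C - 1)
    H = _interaction_jacobian(P)
    Vh = H @ V @ H.T
    V0h = H @ V0 @ H.T

    used = CORRECTION_RS2 if correction == "second_order" else CORRECTION_RS1
    try:
        Delta = np.linalg.solve(V0h, Vh)
        eig = np.linalg.eigvals(Delta).real
        if np.any(eig <= 0):
            raise np.linalg.LinAlgError("non-positive generalized design effects")
        delta_bar = float(eig.mean())
        a2 = max(0.0, float((eig**2).mean()) / delta_bar**2 - 1.0)
    except np.linalg.LinAlgError:
        # rank-deficient design-effect matrix: first-order (mean) correction
        delta_bar = float(np.trace(np.linalg.pinv(V0h) @ Vh)) / d
        a2 = 0.0
        used = CORRECTION_RS1
        warns.append("design-effect matrix rank-deficient; fell back to first-order correction")
    if used == CORRECTION_RS1:
        a2 = 0.0
    if delta_bar <= 0:
        raise ValueError("estimated design effect is non-positive")

    nu = K - 1  # design degrees of freedom (clusters minus one, no strata)
    df1 = d / (1.0 + a2)
    df2 = df1 * nu
    F = X2 / (d * delta_bar)
    p = float(stats.f.sf(F, df1, df2))

    return ComparisonResult(
        test="cluster_adjusted_chi2",
        statistic=X2,
        df=(df1, df2),
        p_value=min(1.0, max(0.0, p)),
        n=n,
        correction=used,
        design_df=d,
        warnings=tuple(warns),
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def _exact_mw_p(pooled_ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided exact p by enumerating all assignments of the pooled ranks."""
    n = pooled_ranks.size
    n2 = n - n1
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu)
    offset = n1 * (n1 + 1) / 2.0
    hits = 0
    for idx in combinations(range(n), n1):
        u = pooled_ranks[list(idx)].sum() - offset
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
    return hits / comb(n, n1)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> ComparisonResult:
    """Two-sided Mann-Whitney U rank-sum test.

    Tie-corrected normal approximation without continuity correction;
    replaced by exact enumeration over all C(n1+n2, n1) rank arrangements
    when both sample sizes are <= 8.  The test is not cluster-adjusted.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = xa.size, ya.size
    pooled = np.concatenate([xa, ya])
    ranks = stats.rankdata(pooled)
    u_stat = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    warns: list[str] = []

    if np.ptp(pooled) == 0:
        warns.append("all values identical across both samples; p set to 1")
        return ComparisonResult(
            test="mann_whitney",
            statistic=u_stat,
            df=None,
            p_value=1.0,
            n=n1 + n2,
            warnings=tuple(warns),
        )

    if max(n1, n2) <= EXACT_MW_MAX_N:
        p = _exact_mw_p(ranks, n1, u_stat)
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            xa, ya, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        p = float(res.pvalue)
        method = "asymptotic"
    warns.append(f"method={method}")
    return ComparisonResult(
        test="mann_whitney",
        statistic=u_stat,
        df=None,
        p_value=min(1.0, max(0.0, p)),
        n=n1 + n2,
        warnings=tuple(warns),
    )


# ---------------------------------------------------------------------------
# Intra-cluster correlation (generator validation)
# ---------------------------------------------------------------------------


def intra_cluster_correlation(values: Sequence[float], cluster_id: Sequence) -> float:
    """ANOVA estimator of the intra-cluster correlation of an outcome.

    ``rho = (MSB - MSW) / (MSB + (m0 - 1) MSW)`` with ``m0`` the
    size-adjusted mean cluster size.  Suitable for binary outcomes; returns
    0.0 when the outcome has no variance.
    """
    v = np.asarray(values, dtype=float)
    cl = pd.Series(list(cluster_id))
    if v.size != len(cl):
        raise ValueError("values and cluster_id must have equal length")
    groups = pd.Series(v).groupby(cl.values)
    K = groups.ngroups
    if K < 2:
        raise ValueError("at least 2 clusters are required")
    N = v.size
    sizes = groups.size().to_numpy(dtype=float)
    means = groups.mean().to_numpy()
    grand = v.mean()
    ssb = float(np.sum(sizes * (means - grand) ** 2))
    within_mean = groups.transform("mean").to_numpy()
    ssw = float(np.sum((v - within_mean) ** 2))
    msb = ssb / (K - 1)
    msw = ssw / (N - K) if N > K else 0.0
    m0 = (N - float(np.sum(sizes**2)) / N) / (K - 1)
    denom = msb + (m0 - 1.0) * msw
    if denom <= 0:
        return 0.0
    return float((msb - msw) / denom)
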