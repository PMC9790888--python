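"""Nonparametric evaluation layer: scores, rank tests and equivalence testing.

The campaign's primary score is post-thaw total motility; from the late
generations onward the relative total motility — the per-sample ratio of a
candidate extender's motility to the split-sample control's motility — is
used instead, because the shared bull effect cancels in the ratio.

Hypothesis testing is rank-based throughout: Kruskal–Wallis as the omnibus
location test, Dunn's z-tests for post-hoc pairwise comparisons (with Holm
adjustment available), Fligner–Killeen for variance homogeneity, and the
Mann–Whitney test for *equivalence* in Wellek's formulation.  The latter
reverses the usual burden of proof: the null hypothesis is non-equivalence,
and rejection (REJ = 1) establishes that P(X > Y) lies provably inside the
margin band around 1/2.

With W+ the tie-corrected U-statistic estimate of P(X > Y) and sigma-hat its
asymptotic standard error, the decision rule is

    REJ = 1  iff  |W+ − 1/2 − (eps2 − eps1)/2| / sigma_hat < CRIT,

where CRIT is the square root of the alpha-quantile of the noncentral
chi-square distribution with 1 degree of freedom and noncentrality
((eps1 + eps2)/2)² / sigma_hat².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import DataError

__all__ = [
    "EquivalenceConfig",
    "EquivalenceResult",
    "RankTestResult",
    "relative_total_motility",
    "percent_improvement",
    "w_plus",
    "mann_whitney_equivalence",
    "equivalence_decision",
    "kruskal_wallis",
    "dunn_posthoc",
    "fligner_killeen",
    "build_score_table",
    "generation_summary",
]


# --------------------------------------------------------------------------
# Scores
# --------------------------------------------------------------------------


def relative_total_motility(treatment: float, control: float) -> float:
    """Ratio of a treatment sample's motility to its split-sample control's.

    Dimensionless; raises :class:`DataError` for a non-positive control (the
    ratio is undefined and the record should be excluded upstream).
    """
    if control <= 0:
        raise DataError(f"control motility must be positive, got {control}")
    return treatment / control


def percent_improvement(treatment_mean: float, control_mean: float) -> float:
    """100 · (treatment/control − 1): percent gain of treatment over control."""
    if control_mean <= 0:
        raise DataError("control mean must be positive")
    return 100.0 * (treatment_mean / control_mean - 1.0)


def build_score_table(records: pd.DataFrame, metric: str = "total") -> pd.DataFrame:
    """Aggregate straw-level records into per-(formulation, bull) scores.

    Replicates are averaged within each (generation, formulation, bull) cell;
    ``relative_total_motility`` is the ratio of those cell means.  The active
    metric is exposed as the ``score`` column.
    """
    if metric not in ("total", "relative"):
        raise DataError(f"unknown metric {metric!r}")
    if len(records) == 0:
        raise DataError("no motility records to score")
    grouped = (
        records.groupby(["generation", "formulation_id", "bull_id"], sort=True)
        .agg(
            total_motility=("total_motility", "mean"),
            control_motility=("control_motility", "mean"),
        )
        .reset_index()
    )
    if (grouped["control_motility"] <= 0).any() and metric == "relative":
        raise DataError("relative metric undefined: non-positive control motility")
    with np.errstate(divide="ignore"):
        grouped["relative_total_motility"] = (
            grouped["total_motility"] / grouped["control_motility"]
        )
    grouped["metric_in_use"] = metric
    grouped["score"] = (
        grouped["total_motility"] if metric == "total"
        else grouped["relative_total_motility"]
    )
    return grouped


def generation_summary(
    records: pd.DataFrame, metric: str = "total"
) -> pd.DataFrame:
    """Per-generation median ± SD of the active metric (trajectory table)."""
    table = build_score_table(records, metric=metric)

    def _sd(x: pd.Series) -> float:
        return 0.0 if len(x) < 2 else float(np.std(x, ddof=1))

    out = (
        table.groupby("generation")["score"]
        .agg(median="median", sd=_sd, n="count")
        .reset_index()
    )
    out["metric"] = metric
    return out


# --------------------------------------------------------------------------
# Rank-based tests
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    df: int
    p_value: float
    test_tag: str
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.statistic < 0 or not (0 <= self.p_value <= 1):
            raise DataError("invalid rank-test result")


def _check_groups(groups: Sequence[np.ndarray], min_groups: int = 2) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < min_groups:
        raise DataError(f"need at least {min_groups} groups")
    if any(len(a) == 0 for a in arrays):
        raise DataError("all groups must be non-empty")
    return arrays


def kruskal_wallis(groups: Sequence[np.ndarray]) -> RankTestResult:
    """Kruskal–Wallis omnibus rank test with tie correction (chi-square scale)."""
    arrays = _check_groups(groups)
    if all(np.array_equal(arrays[0], a) for a in arrays[1:]):
        # identical groups: H = 0 exactly; scipy raises when all values tie
        return RankTestResult(0.0, len(arrays) - 1, 1.0, "kruskal_wallis")
    stat, p = sps.kruskal(*arrays)
    return RankTestResult(float(stat), len(arrays) - 1, float(p), "kruskal_wallis")


def fligner_killeen(x: np.ndarray, y: np.ndarray) -> RankTestResult:
    """Fligner–Killeen variance-homogeneity test for two samples (df = 1)."""
    arrays = _check_groups([x, y])
    if any(len(a) < 2 for a in arrays):
        raise DataError("Fligner-Killeen needs at least 2 values per sample")
    if all(np.ptp(a) == 0 for a in arrays):
        raise DataError("Fligner-Killeen undefined for constant samples")
    stat, p = sps.fligner(*arrays)
    return RankTestResult(float(stat), 1, float(p), "fligner_killeen")


def dunn_posthoc(
    groups: Sequence[np.ndarray],
    labels: Sequence[str] | None = None,
    adjust: str = "holm",
) -> list[RankTestResult]:
    """Dunn's post-hoc pairwise z-tests on the pooled ranks, tie-corrected.

    For groups i, j the statistic is z = (R̄_i − R̄_j) / σ_ij with

        σ_ij² = [N(N+1)/12 − Σ(t³ − t)/(12(N−1))] · (1/n_i + 1/n_j),

    reported on the chi-square scale (z², df = 1).  Both unadjusted and
    Holm-adjusted p-values are computed; ``p_value`` carries the adjusted one
    when ``adjust='holm'`` and each result's ``groups`` names the pair.
    """
    arrays = _check_groups(groups)
    labels = list(labels) if labels is not None else [
        f"group{i}" for i in range(len(arrays))
    ]
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    # tie correction over pooled ranks
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks, sizes = [], []
    start = 0
    for a in arrays:
        mean_ranks.append(float(np.mean(ranks[start : start + len(a)])))
        sizes.append(len(a))
        start += len(a)
    pairs, z_values = [], []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            sigma = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / sigma
            pairs.append((labels[i], labels[j]))
            z_values.append(z)
    raw_p = [2.0 * sps.norm.sf(abs(z)) for z in z_values]
    if adjust == "holm":
        adj_p = multipletests(raw_p, method="holm")[1]
    elif adjust in (None, "none"):
        adj_p = raw_p
    else:
        raise DataError(f"unknown adjustment {adjust!r}")
    return [
        RankTestResult(
            statistic=float(z**2),
            df=1,
            p_value=float(min(p, 1.0)),
            test_tag="dunn_pair",
            groups=pair,
        )
        for z, p, pair in zip(z_values, adj_p, pairs)
    ]


# --------------------------------------------------------------------------
# Mann–Whitney test for equivalence (Wellek)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EquivalenceConfig:
    """Significance level and equivalence margins on the P(X>Y) − 1/2 scale."""

    alpha: float = 0.05
    eps1: float = 0.15
    eps2: float = 0.15

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise DataError("alpha must be in (0, 1)")
        if not (0 < self.eps1 < 0.5 and 0 < self.eps2 < 0.5):
            raise DataError("margins must be in (0, 0.5)")


@dataclass(frozen=True)
class EquivalenceResult:
    W_plus: float
    sigma_hat: float
    CRIT: float
    REJ: int
    m: int
    n: int
    config: EquivalenceConfig = field(default_factory=EquivalenceConfig)

    def __post_init__(self) -> None:
        if not (0 <= self.W_plus <= 1) or self.sigma_hat < 0:
            raise DataError("invalid equivalence result")


def _h_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pairwise kernel h(x_i, y_j) = 1{x>y} + ½·1{x=y} (ties weighted half)."""
    diff = x[:, None] - y[None, :]
    return (diff > 0).astype(float) + 0.5 * (diff == 0)


def w_plus(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-corrected U-statistic estimate of P(X > Y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DataError("samples must be non-empty")
    return float(_h_matrix(x, y).mean())


def equivalence_decision(
    w: float,
    sigma_hat: float,
    crit: float,
    eps1: float = 0.15,
    eps2: float = 0.15,
) -> int:
    """Apply the decision rule to summary statistics (W+, σ̂, CRIT).

    Useful for auditing reported test summaries without the raw samples.
    With symmetric margins the centring term vanishes and the rule reduces to
    ``|W+ − 1/2| / σ̂ < CRIT``.
    """
    if sigma_hat <= 0:
        raise DataError("sigma_hat must be positive")
    center = 0.5 + (eps2 - eps1) / 2.0
    return int(abs(w - center) / sigma_hat < crit)


def mann_whitney_equivalence(
    x: Sequence[float],
    y: Sequence[float],
    cfg: EquivalenceConfig | None = None,
) -> EquivalenceResult:
    """Wellek's two-sample Mann–Whitney test for equivalence.

    Estimates W+ = P(X > Y) with tie weight ½ and its asymptotic standard
    error from the U-statistic covariance components

        π̂_xxy = P(X > Y, X' > Y),   π̂_xyy = P(X > Y, X > Y'),

    then rejects non-equivalence (REJ = 1) when the standardized distance of
    W+ from the margin-band centre falls below the noncentral-chi-square
    critical bound.  Raises :class:`DataError` for degenerate samples with
    zero estimated variance.
    """
    cfg = cfg or EquivalenceConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = len(x), len(y)
    if m < 2 or n < 2:
        raise DataError("equivalence test needs at least 2 values per sample")
    h = _h_matrix(x, y)
    w = float(h.mean())
    row = h.sum(axis=1)  # per x_i over y
    col = h.sum(axis=0)  # per y_j over x
    sq = h**2
    # π̂_xyy: same x against two distinct y's; π̂_xxy: two distinct x's, same y
    pi_xyy = float(np.sum(row**2 - sq.sum(axis=1)) / (m * n * (n - 1)))
    pi_xxy = float(np.sum(col**2 - sq.sum(axis=0)) / (n * m * (m - 1)))
    var = (w * (1 - w) + (n - 1) * (pi_xyy - w**2) + (m - 1) * (pi_xxy - w**2)) / (
        m * n
    )
    if var <= 0:
        raise DataError("degenerate samples: estimated variance of W+ is zero")
    sigma = float(np.sqrt(var))
    eps_bar = (cfg.eps1 + cfg.eps2) / 2.0
    nc = (eps_bar / sigma) ** 2
    crit = float(np.sqrt(sps.ncx2.ppf(cfg.alpha, df=1, nc=nc)))
    rej = equivalence_decision(w, sigma, crit, cfg.eps1, cfg.eps2)
    return EquivalenceResult(
        W_plus=w, sigma_hat=sigma, CRIT=crit, REJ=rej, m=m, n=n, config=cfg
    )


def format_equivalence(result: EquivalenceResult) -> str:
    """Reporting-order one-liner: m, n, ε1, ε2, W+, σ̂, CRIT, REJ."""
    c = result.config
    return (
        f"m = {result.m}, n = {result.n}, eps1 = {c.eps1}, eps2 = {c.eps2}, "
        f"W+ = {result.W_plus:.2f}, sigma_hat = {result.sigma_hat:.2f}, "
        f"CRIT = {result.CRIT:.2f}, REJ = {result.REJ}"
    )
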