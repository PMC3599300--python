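"""Reproducibility and linearity evaluation of quantification metrics.

Two study designs are supported.  *Replicate reproducibility*: score the
same metric on pairs of replicate runs, correlate the shared proteins by
Spearman rank correlation, then ask with paired Wilcoxon signed-rank
tests (Bonferroni-corrected across the metric pairs) which metric is
more reproducible, and with a rank-sum test whether technical replicates
beat biological ones.  *Dilution linearity*: regress each spiked
protein's count on its known amount across a dilution series and compare
metrics on the per-protein correlation, R^2 and mean percent error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import QuantTable

__all__ = [
    "ReplicatePairResult",
    "MetricComparisonResult",
    "RankSumResult",
    "DilutionRun",
    "DilutionSeries",
    "RegressionResult",
    "LinearityResult",
    "replicate_correlation",
    "paired_metric_comparison",
    "tech_vs_bio_comparison",
    "linearity_analysis",
    "linearity_metric_comparison",
]


@dataclass(frozen=True)
class ReplicatePairResult:
    """Spearman correlation between two replicate runs of one metric."""

    label: str
    metric_name: str
    n_shared: int
    spearman_rho: float


@dataclass
class MetricComparisonResult:
    """All pairwise paired tests between metrics on one statistic.

    ``pvalues`` maps each unordered metric pair (as a sorted tuple) to a
    two-sided Wilcoxon signed-rank p-value; ``threshold`` is the
    Bonferroni-corrected significance level alpha / (number of pairs);
    ``edges`` lists (winner, loser) for pairs where the winner dominates
    and the p-value beats the threshold.
    """

    pvalues: dict
    edges: list
    threshold: float
    alpha: float = 0.05

    @property
    def n_comparisons(self) -> int:
        return len(self.pvalues)


@dataclass(frozen=True)
class RankSumResult:
    """Two-group rank-sum comparison (e.g. technical vs biological rho)."""

    mean_a: float
    mean_b: float
    pvalue: float
    n_a: int
    n_b: int


def replicate_correlation(
    a: QuantTable, b: QuantTable, label: str = ""
) -> ReplicatePairResult:
    """Spearman rho over proteins scored in both runs.

    Proteins identified in only one of the two runs are ignored; tied
    scores receive average ranks.  Requires at least two shared proteins.
    """
    if a.metric_name != b.metric_name or a.level != b.level:
        raise ValueError(
            f"tables disagree: {a.metric_name}/{a.level} vs {b.metric_name}/{b.level}"
        )
    shared = sorted(set(a.scores) & set(b.scores))
    if len(shared) < 2:
        raise ValueError(f"only {len(shared)} shared protein(s); need >= 2 for rho")
    rho = stats.spearmanr([a.scores[p] for p in shared], [b.scores[p] for p in shared]).statistic
    return ReplicatePairResult(label, a.metric_name, len(shared), float(rho))


def _signed_rank(diffs: np.ndarray) -> tuple:
    """Two-sided signed-rank p-value and the net rank direction.

    Zero differences are dropped; the exact null distribution is used up
    to 25 non-zero differences, the normal approximation beyond.  The
    returned direction is W+ - W- (positive when the first sample
    dominates); (1.0, 0.0) when every difference is zero.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0, 0.0
    method = "exact" if d.size <= 25 else "approx"
    p = float(
        stats.wilcoxon(
            d, zero_method="wilcox", alternative="two-sided", method=method
        ).pvalue
    )
    ranks = stats.rankdata(np.abs(d))
    direction = float(np.sum(np.sign(d) * ranks))
    return p, direction


def _compare_metrics(
    values_by_metric: Mapping, alpha: float, higher_is_better: bool = True
) -> MetricComparisonResult:
    metrics = sorted(values_by_metric)
    if len(metrics) < 2:
        raise ValueError("need at least two metrics to compare")
    sizes = {m: len(values_by_metric[m]) for m in metrics}
    if len(set(sizes.values())) != 1:
        raise ValueError(f"metrics evaluated on different numbers of pairs: {sizes}")
    pairs = list(combinations(metrics, 2))
    threshold = alpha / len(pairs)
    pvalues: dict = {}
    edges: list = []
    for a, b in pairs:
        d = np.asarray(values_by_metric[a], float) - np.asarray(values_by_metric[b], float)
        p, direction = _signed_rank(d)
        pvalues[(a, b)] = p
        if p < threshold and direction != 0.0:
            a_dominates = direction > 0
            winner, loser = (a, b) if a_dominates == higher_is_better else (b, a)
            edges.append((winner, loser))
    return MetricComparisonResult(pvalues, edges, threshold, alpha)


def paired_metric_comparison(
    correlations: Mapping, alpha: float = 0.05
) -> MetricComparisonResult:
    """Which metric is more reproducible, across all metric pairs.

    ``correlations`` maps metric name to its Spearman rho values over the
    same ordered list of replicate pairs.  Each unordered metric pair is
    tested with a two-sided Wilcoxon signed-rank test on the paired rho
    differences; an edge winner -> loser is emitted when the winner's
    correlations dominate at the Bonferroni-corrected level alpha/(number
    of pairs).
    """
    return _compare_metrics(correlations, alpha, higher_is_better=True)


def tech_vs_bio_comparison(tech_rhos: Sequence, bio_rhos: Sequence) -> RankSumResult:
    """Compare technical vs biological replicate correlations.

    Two-sided Mann-Whitney rank-sum test: exact null distribution when
    both groups have at most 20 values and no ties, otherwise the
    tie-corrected normal approximation.
    """
    tech = np.asarray(tech_rhos, float)
    bio = np.asarray(bio_rhos, float)
    if tech.size == 0 or bio.size == 0:
        raise ValueError("both replicate groups must be non-empty")
    pooled = np.concatenate([tech, bio])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (max(tech.size, bio.size) <= 20 and no_ties) else "asymptotic"
    p = float(
        stats.mannwhitneyu(tech, bio, alternative="two-sided", method=method).pvalue
    )
    return RankSumResult(float(tech.mean()), float(bio.mean()), p, tech.size, bio.size)


@dataclass
class DilutionRun:
    """One standard of a dilution curve: its table and known spike amounts."""

    label: str
    table: QuantTable
    amounts: dict  # spiked protein id -> fmol in this standard


@dataclass
class DilutionSeries:
    """An ordered dilution curve (at least three standards)."""

    runs: list

    def __post_init__(self):
        if len(self.runs) < 3:
            raise ValueError("a dilution series needs at least 3 runs")
        for run in self.runs:
            for prot, amount in run.amounts.items():
                if amount <= 0:
                    raise ValueError(
                        f"non-positive amount {amount} for {prot!r} in run {run.label!r}"
                    )

    @property
    def spiked_proteins(self) -> set:
        out: set = set()
        for run in self.runs:
            out |= set(run.amounts)
        return out


@dataclass(frozen=True)
class RegressionResult:
    """Per-protein linear fit of count against known amount."""

    protein_id: str
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    mpe: float  # mean percent error, %
    n_points: int


@dataclass
class LinearityResult:
    results: list
    skipped: dict = field(default_factory=dict)  # protein -> reason


def linearity_analysis(series: DilutionSeries, min_positive: int = 3) -> LinearityResult:
    """Ordinary least-squares fit per spiked protein over the curve.

    For each spiked protein with a positive count in at least
    ``min_positive`` runs, counts (response) are regressed on known
    amounts (predictor) over the runs where the protein is scored; runs
    with a zero or absent count are excluded from the fit.  The mean
    percent error is 100/m * sum |fitted - observed| / observed over the
    m fitted points.  Proteins failing the filter (or with constant
    amounts, where the fit is undefined) are reported in ``skipped``.
    """
    results: list = []
    skipped: dict = {}
    for prot in sorted(series.spiked_proteins):
        points = [
            (run.amounts[prot], run.table.scores[prot])
            for run in series.runs
            if prot in run.amounts
            and run.table.scores.get(prot, 0.0) > 0.0
        ]
        if len(points) < min_positive:
            skipped[prot] = (
                f"positive count in only {len(points)} run(s); need >= {min_positive}"
            )
            continue
        x = np.array([p[0] for p in points], float)
        y = np.array([p[1] for p in points], float)
        if np.unique(x).size == 1:
            skipped[prot] = "constant amounts across runs; regression undefined"
            continue
        if np.unique(y).size == 1:
            # flat response: OLS gives slope 0 and a perfect-fit intercept,
            # but no association — report r = 0 rather than scipy's nan
            results.append(
                RegressionResult(prot, 0.0, float(y[0]), 0.0, 0.0, 0.0, len(points))
            )
            continue
        fit = stats.linregress(x, y)
        fitted = fit.slope * x + fit.intercept
        with np.errstate(divide="ignore"):
            mpe = float(100.0 * np.mean(np.abs(fitted - y) / y))
        results.append(
            RegressionResult(
                protein_id=prot,
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                pearson_r=float(fit.rvalue),
                r_squared=float(fit.rvalue) ** 2,
                mpe=mpe,
                n_points=len(points),
            )
        )
    return LinearityResult(results, skipped)


_LINEARITY_STATS = ("pearson_r", "r_squared", "mpe")


def linearity_metric_comparison(
    results_by_metric: Mapping, alpha: float = 0.05
) -> dict:
    """Pairwise metric comparison on linearity, one test per statistic.

    ``results_by_metric`` maps metric name to its list of
    :class:`RegressionResult` over the same protein set.  For each of
    pearson_r, r_squared and mpe, every metric pair gets a two-sided
    signed-rank p-value over per-protein paired values; edges point from
    the better metric (higher r/R^2, lower MPE) at the Bonferroni level.
    """
    by_metric = {
        m: {r.protein_id: r for r in results} for m, results in results_by_metric.items()
    }
    protein_sets = {m: frozenset(d) for m, d in by_metric.items()}
    if len(set(protein_sets.values())) != 1:
        raise ValueError(f"metrics fitted on different protein sets: { {m: sorted(s) for m, s in protein_sets.items()} }")
    proteins = sorted(next(iter(protein_sets.values())))
    out: dict = {}
    for stat in _LINEARITY_STATS:
        values = {
            m: [getattr(by_metric[m][p], stat) for p in proteins] for m in by_metric
        }
        out[stat] = _compare_metrics(values, alpha, higher_is_better=(stat != "mpe"))
    return out
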