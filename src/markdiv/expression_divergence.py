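"""Expression-pattern divergence of paralog pairs, stratified by mark class.

Divergence of expression between two paralogs is summarized by the Pearson
correlation of their profiles across samples.  Class-level results are
reported as medians with pairwise two-sided Kolmogorov-Smirnov comparisons,
against a null distribution built from randomly combined gene pairs
(10,000 draws by default).  To control for expression level as a
confounder, pairs are additionally stratified into quintiles of joint
expression level (the two profiles summed over all samples), and the
relation between level and correlation is assessed by ordinary least
squares on Fisher-style transformed correlations ``ln((1+r)/(1-r))``
(without the conventional 1/2 factor, matching how such regressions are
reported for paralog expression data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "ExpressionMatrix",
    "PairCorrelation",
    "NullDistribution",
    "KSResult",
    "PairLevel",
    "pair_correlation",
    "pair_correlations",
    "apply_measurability_mask",
    "random_pair_null",
    "ks_two_sided",
    "class_distribution_summary",
    "joint_levels_and_quintiles",
    "fisher_transform",
    "level_correlation_regression",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples table of normalized intensities.

    Thin wrapper over a :class:`pandas.DataFrame` (genes as index, samples
    as columns) enforcing uniqueness and finiteness.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if df.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if not np.isfinite(df.to_numpy(dtype=float)).all():
            raise ValueError("non-finite values in expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def profile(self, gene_id: str) -> np.ndarray:
        return self.data.loc[gene_id].to_numpy(dtype=float)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.data.index


@dataclass(frozen=True)
class PairCorrelation:
    pair_id: str
    r: float                 # NaN when undefined
    n_samples: int
    defined: bool


@dataclass(frozen=True)
class NullDistribution:
    """Seeded random-pair null for a pairwise statistic."""

    statistic: str
    values: np.ndarray
    n_draws: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.values) != self.n_draws:
            raise ValueError("null length does not match n_draws")

    @property
    def median(self) -> float:
        return float(np.median(self.values))


@dataclass(frozen=True)
class KSResult:
    d: float
    p_value: float


@dataclass(frozen=True)
class PairLevel:
    pair_id: str
    joint_level: float
    quintile: int


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; NaN for zero-variance profiles."""
    if x.std() == 0.0 or y.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def pair_correlation(pair, matrix: ExpressionMatrix) -> PairCorrelation:
    """Pearson correlation of the two paralogs' profiles across samples."""
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 samples for a correlation")
    x = matrix.profile(pair.gene_a)
    y = matrix.profile(pair.gene_b)
    r = _pearson(x, y)
    return PairCorrelation(pair_id=pair.pair_id, r=r,
                           n_samples=matrix.n_samples,
                           defined=not math.isnan(r))


def pair_correlations(pairs: Iterable, matrix: ExpressionMatrix
                      ) -> tuple[list[PairCorrelation], list[str]]:
    """Correlations for many pairs; pairs with missing genes are skipped.

    Returns (correlations, skipped pair ids); the skip mirrors probe
    coverage loss on real arrays.
    """
    out: list[PairCorrelation] = []
    skipped: list[str] = []
    for pair in pairs:
        if pair.gene_a not in matrix or pair.gene_b not in matrix:
            skipped.append(pair.pair_id)
            continue
        out.append(pair_correlation(pair, matrix))
    return out, skipped


def apply_measurability_mask(pairs: Sequence, measurable_genes: set[str]
                             ) -> tuple[list, dict[str, int]]:
    """Keep pairs whose both genes are measurable; report retention per class.

    The mask stands in for unique-probe coverage of an array platform.
    Retention percentages are rounded to integers, per class.
    """
    if not measurable_genes:
        raise ValueError("empty measurability mask")
    kept = [p for p in pairs
            if p.gene_a in measurable_genes and p.gene_b in measurable_genes]
    retention: dict[str, int] = {}
    classes = {p.mark_class for p in pairs if p.mark_class is not None}
    for cls in sorted(classes):
        n_in = sum(1 for p in pairs if p.mark_class == cls)
        n_kept = sum(1 for p in kept if p.mark_class == cls)
        retention[cls] = round(100.0 * n_kept / n_in) if n_in else 0
    return kept, retention


def random_pair_null(matrix: ExpressionMatrix, n_draws: int = 10_000,
                     seed: int = 0) -> NullDistribution:
    """Null distribution of Pearson r over randomly combined gene pairs.

    Each draw picks two distinct genes uniformly; the same pair may recur
    across draws.  Zero-variance draws are re-drawn.  Fully seeded.
    """
    values_matrix = matrix.data.to_numpy(dtype=float)
    n_genes = values_matrix.shape[0]
    if n_genes < 2:
        raise ValueError("need at least 2 genes for a random-pair null")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    # standardize once; r is then a mean product of z-scores
    sd = values_matrix.std(axis=1)
    ok = sd > 0
    centered = values_matrix - values_matrix.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = centered / sd[:, None]
    candidates = np.flatnonzero(ok)
    if len(candidates) < 2:
        raise ValueError("fewer than 2 genes with variance")
    i = rng.choice(candidates, size=n_draws)
    j = rng.choice(candidates, size=n_draws)
    clash = i == j
    while clash.any():
        j[clash] = rng.choice(candidates, size=int(clash.sum()))
        clash = i == j
    vals = (z[i] * z[j]).mean(axis=1)
    return NullDistribution(statistic="pearson_r", values=vals,
                            n_draws=n_draws, seed=seed)


def ks_two_sided(sample_a: Sequence[float], sample_b: Sequence[float]) -> KSResult:
    """Two-sided two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample in KS test")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    d = float(res.statistic)
    # asymptotic Kolmogorov survival function; always in (0, 1], unlike
    # scipy's small-sample asymp p which can underflow to exactly 0 at D=1
    en = math.sqrt(a.size * b.size / (a.size + b.size))
    p = float(special.kolmogorov(en * d))
    return KSResult(d=d, p_value=min(max(p, 5e-324), 1.0))


def class_distribution_summary(correlations_by_class: Mapping[str, Sequence[float]]
                               ) -> dict:
    """Per-class n and median plus all pairwise KS comparisons.

    Input values should already exclude undefined correlations.  Medians use
    the midpoint-of-central-values convention for even n.
    """
    summary: dict = {"classes": {}, "ks": {}}
    for cls, values in correlations_by_class.items():
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise ValueError(f"no values for class {cls!r}")
        summary["classes"][cls] = {"n": int(arr.size),
                                   "median": float(np.median(arr))}
    names = list(correlations_by_class)
    for idx, ca in enumerate(names):
        for cb in names[idx + 1:]:
            ks = ks_two_sided(correlations_by_class[ca], correlations_by_class[cb])
            summary["ks"][f"{ca}_vs_{cb}"] = {"D": ks.d, "p_value": ks.p_value}
    return summary


def joint_levels_and_quintiles(pairs: Sequence, matrix: ExpressionMatrix,
                               n_bins: int = 5) -> list[PairLevel]:
    """Joint expression level per pair and its level quantile bin (1..n_bins).

    The joint level is the sum over samples of both genes' intensities.
    Bins are equal-size (+-1) by rank, ties broken by stable input order.
    """
    levels = []
    for pair in pairs:
        lvl = float(matrix.profile(pair.gene_a).sum() + matrix.profile(pair.gene_b).sum())
        levels.append((pair.pair_id, lvl))
    n = len(levels)
    order = sorted(range(n), key=lambda k: (levels[k][1], k))
    quintile = [0] * n
    for rank, k in enumerate(order):
        quintile[k] = 1 + (rank * n_bins) // n
    return [PairLevel(pair_id=pid, joint_level=lvl, quintile=q)
            for (pid, lvl), q in zip(levels, quintile)]


def fisher_transform(r: float) -> float:
    """``ln((1+r)/(1-r))`` — the transform as used for these regressions.

    Twice the conventional atanh; |r| = 1 maps to +-inf (callers flag and
    exclude such values from regression).
    """
    if r >= 1.0:
        return float("inf")
    if r <= -1.0:
        return float("-inf")
    return math.log((1.0 + r) / (1.0 - r))


def level_correlation_regression(levels: Sequence[float],
                                 transformed_r: Sequence[float]):
    """OLS of transformed correlation on joint expression level.

    Non-finite points are dropped; returns :func:`scipy.stats.linregress`
    result (slope, intercept, rvalue, pvalue, stderr).
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(transformed_r, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 finite points for regression")
    if x.std() == 0:
        raise ValueError("degenerate regressor: zero variance in levels")
    return stats.linregress(x, y)
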