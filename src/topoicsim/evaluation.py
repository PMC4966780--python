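"""Benchmark statistics for gene-set similarity measures.

IntraSet similarity is the mean of all n^2 pairwise gene similarities
within a set (self-pairs included); InterSet similarity is the grand mean
over the n x m cross pairs of two sets.  Discriminating power

    DP(S_k) = (p - 1) IntraSet(S_k) / sum_{i != k} InterSet(S_k, S_i)

rewards measures that score within-set pairs above between-set pairs, and
IDP(S_k) = IntraSet(S_k) x DP(S_k) combines the two.

The module also provides the empirical distance correlation (an energy
statistic that is zero iff the samples are independent), a deterministic
grouped correlation between expression- and annotation-similarity pairs
(quantile or grid grouping standing in for a self-organising map), and an
annotation-length-bias audit over random same-size term groups.
"""

from __future__ import annotations

import io
import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .go_dag_io import OntologyGraph
from .info_content import ICTable
from .similarity import TermSimilarityCache, aggregate_matrix, similarity_matrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------
# Gene-set statistics
# ---------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Ordered label -> gene-list map (each set non-empty)."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("collection must contain at least one gene set")
        for label, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {label!r} is empty")

    @property
    def p(self) -> int:
        return len(self.sets)

    @property
    def labels(self) -> list[str]:
        return list(self.sets)

    @property
    def all_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for genes in self.sets.values():
            for g in genes:
                seen.setdefault(g)
        return list(seen)

    @classmethod
    def from_tsv(cls, stream) -> "GeneSetCollection":
        """Two-column (set_label, gene_id) TSV, '#' comments allowed."""
        if isinstance(stream, str) and "\n" in stream:
            stream = io.StringIO(stream)
        close = isinstance(stream, str)
        fh = open(stream) if close else stream
        try:
            sets: dict[str, list[str]] = {}
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                label, gene = line.rstrip("\n").split("\t")[:2]
                sets.setdefault(label, []).append(gene)
        finally:
            if close:
                fh.close()
        return cls(sets=sets)


@dataclass
class EvalReport:
    """Per-set IntraSet/DP/IDP values and the p x p InterSet matrix."""

    intraset: pd.Series
    interset: pd.DataFrame
    dp: pd.Series
    idp: pd.Series


def intraset_sim(matrix: np.ndarray) -> float:
    """Mean of all n^2 entries of a within-set similarity matrix
    (self-pairs included in the denominator)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("empty gene set")
    return float(matrix.mean())


def interset_sim(cross: np.ndarray) -> float:
    """Grand mean of an n x m between-set similarity matrix."""
    cross = np.asarray(cross, dtype=float)
    if cross.size == 0:
        raise ValueError("empty gene set")
    return float(cross.mean())


def discriminating_power(intraset: pd.Series, interset: pd.DataFrame) -> pd.Series:
    """DP(S_k) = (p-1) IntraSet(S_k) / sum over other sets of InterSet."""
    p = len(intraset)
    if p < 2:
        raise ValueError("discriminating power needs at least two sets")
    dp = {}
    for k in intraset.index:
        denom = float(interset.loc[k].drop(k).sum())
        if denom == 0.0:
            warnings.warn(f"zero InterSet denominator for set {k!r}")
            dp[k] = math.inf
        else:
            dp[k] = (p - 1) * intraset[k] / denom
    return pd.Series(dp)


def idp(intraset: pd.Series, dp: pd.Series) -> pd.Series:
    """IDP(S_k) = IntraSet(S_k) x DP(S_k)."""
    return intraset * dp


def evaluate_collection(
    sim: pd.DataFrame, collection: GeneSetCollection
) -> EvalReport:
    """Full IntraSet/InterSet/DP/IDP report from a gene-level similarity
    matrix covering every gene of the collection."""
    labels = collection.labels
    inter = pd.DataFrame(0.0, index=labels, columns=labels)
    for a, b in itertools.combinations_with_replacement(labels, 2):
        block = sim.loc[collection.sets[a], collection.sets[b]].to_numpy()
        value = intraset_sim(block) if a == b else interset_sim(block)
        inter.loc[a, b] = inter.loc[b, a] = value
    intra = pd.Series(np.diag(inter), index=labels)
    if collection.p >= 2:
        dp_values = discriminating_power(intra, inter)
        idp_values = idp(intra, dp_values)
    else:
        dp_values = pd.Series(np.nan, index=labels)
        idp_values = pd.Series(np.nan, index=labels)
    return EvalReport(intraset=intra, interset=inter, dp=dp_values, idp=idp_values)


# ---------------------------------------------------------------------
# Distance correlation
# ---------------------------------------------------------------------

def distance_correlation(X, Y) -> tuple[float, float]:
    """Empirical distance covariance and correlation of two samples.

    ``X`` and ``Y`` are (n,) or (n, d) arrays of paired observations.
    Returns (dcov^2, dcor) where dcov^2 = S1 + S2 - 2 S3 over the pairwise
    Euclidean distance matrices and dcor normalises by the marginal
    statistics; dcor is 0 when either marginal dcov^2 vanishes.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    if Y.shape[0] == 1:
        Y = Y.T
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("X and Y must have equal sample sizes")
    if n < 2:
        raise ValueError("need at least two observations")

    a = cdist(X, X)
    b = cdist(Y, Y)

    def dcov2(a: np.ndarray, b: np.ndarray) -> float:
        s1 = float((a * b).mean())
        s2 = float(a.mean()) * float(b.mean())
        s3 = float((a.mean(axis=1) * b.mean(axis=1)).mean())
        # tiny negatives are floating error near independence
        return max(s1 + s2 - 2.0 * s3, 0.0)

    v_xy = dcov2(a, b)
    v_xx = dcov2(a, a)
    v_yy = dcov2(b, b)
    if v_xx == 0.0 or v_yy == 0.0:
        return v_xy, 0.0
    return v_xy, float(math.sqrt(math.sqrt(v_xy) / math.sqrt(math.sqrt(v_xx * v_yy))))


# ---------------------------------------------------------------------
# Grouped expression-vs-annotation correlation
# ---------------------------------------------------------------------

@dataclass
class PairedSample:
    """Paired (expression similarity r, annotation similarity s) values
    for a collection of gene pairs."""

    r: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.r.shape != self.s.shape or self.r.ndim != 1:
            raise ValueError("r and s must be equal-length 1-D arrays")
        if not (np.isfinite(self.r).all() and np.isfinite(self.s).all()):
            raise ValueError("paired sample must be finite")

    def __len__(self) -> int:
        return len(self.r)


def _pair_correlation(r: np.ndarray, s: np.ndarray, corr: str) -> float:
    if corr == "pearson":
        return float(stats.pearsonr(r, s).statistic)
    if corr == "spearman":
        return float(stats.spearmanr(r, s).statistic)
    if corr == "dcor":
        return distance_correlation(r, s)[1]
    raise ValueError(f"unknown correlation {corr!r}")


def grouped_correlation(
    sample: PairedSample,
    grouping: str = "quantile",
    n_groups: int = 6,
    corr: str = "pearson",
    min_group_corr: float = 0.5,
    group_fn: Callable[[PairedSample], np.ndarray] | None = None,
) -> float:
    """Mean within-group correlation over groups correlating >= threshold.

    Pairs are partitioned deterministically — ``quantile`` bins on r, or a
    fixed 2-D ``grid`` on (r, s) with ~sqrt(n_groups) bins per axis — and
    the within-group correlations of qualifying groups (correlation >=
    ``min_group_corr``) are averaged.  A custom ``group_fn`` returning
    integer labels can stand in for any clustering (e.g. a trained SOM).
    Returns NaN when no group qualifies.
    """
    if len(sample) < n_groups:
        raise ValueError("sample smaller than the number of groups")
    if group_fn is not None:
        labels = np.asarray(group_fn(sample))
    elif grouping == "quantile":
        edges = np.quantile(sample.r, np.linspace(0, 1, n_groups + 1)[1:-1])
        labels = np.searchsorted(edges, sample.r, side="right")
    elif grouping == "grid":
        per_axis = max(int(round(math.sqrt(n_groups))), 1)

        def axis_bins(v: np.ndarray) -> np.ndarray:
            lo, hi = v.min(), v.max()
            if hi == lo:
                return np.zeros(len(v), dtype=int)
            return np.minimum(
                ((v - lo) / (hi - lo) * per_axis).astype(int), per_axis - 1
            )

        labels = axis_bins(sample.r) * per_axis + axis_bins(sample.s)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    kept: list[float] = []
    for g in np.unique(labels):
        mask = labels == g
        r, s = sample.r[mask], sample.s[mask]
        if mask.sum() < 2 or np.ptp(r) == 0 or np.ptp(s) == 0:
            logger.warning("skipping degenerate group %s (n=%d)", g, mask.sum())
            continue
        c = _pair_correlation(r, s, corr)
        if c >= min_group_corr:
            kept.append(c)
    return float(np.mean(kept)) if kept else math.nan


# ---------------------------------------------------------------------
# Spearman with exact small-sample p-value
# ---------------------------------------------------------------------

def spearman_with_pvalue(x, y) -> tuple[float, float]:
    """Spearman rank correlation with an exact permutation p-value for
    n <= 10 (two-sided) and the t-approximation otherwise.

    Constant inputs use the ties convention r = 0 (p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = float(stats.pearsonr(rx, ry).statistic)
    if n <= 10:
        observed = abs(r)
        sx = rx - rx.mean()
        sy = ry - ry.mean()
        denom = math.sqrt(float(sx @ sx) * float(sy @ sy))
        count = total = 0
        chunk: list[tuple[int, ...]] = []
        for perm in itertools.permutations(range(n)):
            chunk.append(perm)
            if len(chunk) == 100_000:
                count, total = _perm_tally(sx, sy, denom, observed, chunk, count, total)
                chunk = []
        if chunk:
            count, total = _perm_tally(sx, sy, denom, observed, chunk, count, total)
        return r, count / total
    return r, float(stats.spearmanr(x, y).pvalue)


def _perm_tally(sx, sy, denom, observed, chunk, count, total):
    stat = np.abs(sx[np.asarray(chunk)] @ sy) / denom
    return count + int((stat >= observed - 1e-12).sum()), total + len(chunk)


# ---------------------------------------------------------------------
# Annotation-length bias audit
# ---------------------------------------------------------------------

@dataclass
class BiasAuditResult:
    """Mean score per group size plus the size-vs-score rank correlation."""

    sizes: list[int]
    mean_scores: list[float]
    spearman_r: float
    p_value: float
    per_pair_scores: dict[int, np.ndarray] = field(default_factory=dict)


def make_topoicsim_group_measure(
    graph: OntologyGraph, ic: ICTable, aggregator: str = "rcmax"
) -> Callable[[Sequence[str], Sequence[str]], float]:
    """Term-group similarity callable (rcmax over the TopoICSim term
    matrix) with a shared term-pair cache, for the bias audit."""
    cache = TermSimilarityCache(graph, ic)

    def measure(terms1: Sequence[str], terms2: Sequence[str]) -> float:
        s = similarity_matrix(graph, ic, list(terms1), list(terms2), cache)
        return aggregate_matrix(s, aggregator)

    return measure


def length_bias_audit(
    graph: OntologyGraph,
    measure: Callable[[Sequence[str], Sequence[str]], float],
    sizes: Sequence[int] = tuple(range(1, 11)),
    n_pairs: int = 100,
    seed: int = 0,
) -> BiasAuditResult:
    """Score random same-size term-group pairs and correlate size vs score.

    For each group size k, ``n_pairs`` pairs of k-term groups are drawn
    uniformly (without replacement within a group) from the graph's terms
    and scored with ``measure``; the Spearman correlation between group
    size and mean score summarises any annotation-length bias.
    """
    terms = graph.terms
    if len(terms) < max(sizes):
        raise ValueError("graph has fewer terms than the largest group size")
    rng = np.random.default_rng(seed)
    means: list[float] = []
    per_pair: dict[int, np.ndarray] = {}
    for k in sizes:
        scores = np.empty(n_pairs)
        for i in range(n_pairs):
            group1 = list(rng.choice(terms, size=k, replace=False))
            group2 = list(rng.choice(terms, size=k, replace=False))
            scores[i] = measure(group1, group2)
        per_pair[k] = scores
        means.append(float(scores.mean()))
    r, p = spearman_with_pvalue(np.asarray(sizes, dtype=float), np.asarray(means))
    return BiasAuditResult(
        sizes=list(sizes), mean_scores=means, spearman_r=r, p_value=p,
        per_pair_scores=per_pair,
    )
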