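"""Gene-set level summarization: over-representation analysis, significance
and size filters, relative-risk similarity between gene sets, k-means
clustering with gap-statistic model selection, and cross-analysis membership
matrices."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .core_data import DataValidationError, GeneSet, GeneSetCollection

__all__ = [
    "ora_fisher",
    "filter_gene_sets",
    "RRMatrix",
    "rr_matrix",
    "ClusterAssignment",
    "cluster_rr",
    "cross_analysis_membership",
]


def ora_fisher(query: Iterable[str], gs: GeneSet, universe: Iterable[str]) -> float:
    """Right-tailed Fisher exact test of query/gene-set overlap.

    Equals the hypergeometric upper tail at the observed overlap over the
    2x2 table (in-query x in-set) on the universe.
    """
    query = set(query)
    universe = set(universe)
    if not query or not universe:
        raise DataValidationError("query and universe must be nonempty")
    if not query <= universe:
        raise DataValidationError("query must be a subset of the universe")
    genes = gs.genes & universe
    overlap = len(query & genes)
    n_universe = len(universe)
    # P(X >= overlap), X ~ Hypergeom(N, |set|, |query|)
    return float(stats.hypergeom.sf(overlap - 1, n_universe, len(genes), len(query)))


def filter_gene_sets(
    collection: GeneSetCollection, alpha: float = 0.05, min_genes: int = 3
) -> GeneSetCollection:
    """Keep sets with p_value strictly below ``alpha`` and >= ``min_genes`` genes."""
    kept = []
    for s in collection:
        if s.p_value is None:
            raise DataValidationError(f"gene set {s.set_id!r} carries no p-value; run ORA first")
        if s.p_value < alpha and len(s.genes) >= min_genes:
            kept.append(s)
    if not kept:
        raise DataValidationError(
            f"no gene set passes p < {alpha} with >= {min_genes} genes; relax the thresholds")
    return GeneSetCollection(kept)


@dataclass(frozen=True)
class RRMatrix:
    """Symmetric pairwise relative-risk similarity between gene sets.

    ``RR(A, B) = |A & B| * N / (|A| * |B|)`` over a universe of size N:
    observed co-membership relative to expectation under independence.  The
    diagonal equals ``N / |A|``; disjoint pairs score 0.
    """

    set_ids: tuple[str, ...]
    values: np.ndarray
    universe_size: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.set_ids), columns=list(self.set_ids))


def rr_matrix(
    collection: GeneSetCollection,
    universe: Iterable[str] | None = None,
    epidemiological: bool = False,
) -> RRMatrix:
    """Pairwise relative risk of gene co-membership for all set pairs.

    The default is the symmetric co-occurrence ratio (see :class:`RRMatrix`).
    ``epidemiological=True`` switches to the classical 2x2 risk ratio
    ``[a/(a+b)] / [c/(c+d)]`` with a 0.5 continuity correction on zero
    cells; that variant is asymmetric in general and is returned as the
    average of the two orientations to keep the matrix symmetric.
    """
    if len(collection) < 2:
        raise DataValidationError("need >= 2 gene sets")
    universe = set(universe) if universe is not None else collection.all_genes()
    n = len(universe)
    for s in collection:
        outside = s.genes - universe
        if outside:
            raise DataValidationError(
                f"gene set {s.set_id!r} has gene {sorted(outside)[0]!r} outside the universe")
    m = len(collection)
    sets = [s.genes for s in collection]
    sizes = np.array([len(g) for g in sets], dtype=float)
    values = np.zeros((m, m))
    for i in range(m):
        for j in range(i, m):
            a = len(sets[i] & sets[j])
            if epidemiological:
                values[i, j] = values[j, i] = _epi_rr(a, sizes[i], sizes[j], n)
            else:
                values[i, j] = values[j, i] = a * n / (sizes[i] * sizes[j])
    return RRMatrix(tuple(collection.set_ids), values, n)


def _epi_rr(a: int, size_i: float, size_j: float, n: int) -> float:
    """Symmetrized epidemiological risk ratio with 0.5 continuity correction."""
    def one_way(a, b, c, d):
        if a == 0 or c == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a / (a + b)) / (c / (c + d))

    b = size_i - a
    c = size_j - a
    d = n - size_i - size_j + a
    return 0.5 * (one_way(a, b, c, d) + one_way(a, c, b, d))


@dataclass(frozen=True)
class ClusterAssignment:
    set_ids: tuple[str, ...]
    cluster_labels: np.ndarray  # integers 1..k
    k: int
    gap_curve: pd.DataFrame  # columns: k, gap, se

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"set_id": list(self.set_ids), "cluster": self.cluster_labels})


def _within_dispersion(x: np.ndarray, k: int, seed) -> tuple[float, np.ndarray]:
    if k == 1:
        centroid = x.mean(axis=0)
        return float(((x - centroid) ** 2).sum()), np.zeros(len(x), dtype=int)
    km = KMeans(n_clusters=k, n_init=25, random_state=seed).fit(x)
    return float(km.inertia_), km.labels_


def cluster_rr(
    rr: RRMatrix,
    k: int | None = None,
    k_max: int = 10,
    n_ref: int = 20,
    seed: int | None = 0,
) -> ClusterAssignment:
    """k-means on the rows of the RR matrix, with gap-statistic selection.

    When ``k`` is not given it is chosen as the smallest candidate with
    ``Gap(k) >= Gap(k+1) - SE(k+1)``, where the reference distribution draws
    ``n_ref`` datasets uniformly over the observed per-column ranges.
    """
    x = rr.values
    m = x.shape[0]
    if k is not None and not (1 <= k <= m):
        raise ValueError(f"k={k} outside [1, {m}]")
    if k_max >= m:
        warnings.warn(f"k_max={k_max} >= number of sets {m}; clamping to {m - 1}")
        k_max = max(m - 1, 1)

    rng = np.random.default_rng(seed)
    km_seed = int(rng.integers(2**31 - 1))

    gap_rows = []
    labels_by_k = {}
    if k is None:
        lo, hi = x.min(axis=0), x.max(axis=0)
        refs = [lo + (hi - lo) * rng.random(x.shape) for _ in range(n_ref)]
        for kk in range(1, k_max + 1):
            w, labels = _within_dispersion(x, kk, km_seed)
            labels_by_k[kk] = labels
            log_w_refs = np.array([
                np.log(max(_within_dispersion(r, kk, km_seed)[0], 1e-300)) for r in refs])
            gap = float(log_w_refs.mean() - np.log(max(w, 1e-300)))
            se = float(log_w_refs.std(ddof=0) * np.sqrt(1.0 + 1.0 / n_ref))
            gap_rows.append((kk, gap, se))
        k = k_max
        for i in range(len(gap_rows) - 1):
            if gap_rows[i][1] >= gap_rows[i + 1][1] - gap_rows[i + 1][2]:
                k = gap_rows[i][0]
                break
        labels = labels_by_k[k]
    else:
        _, labels = _within_dispersion(x, k, km_seed)

    # canonical labels: clusters numbered 1..k by first appearance
    canon = {}
    final = np.empty(m, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in canon:
            canon[lab] = len(canon) + 1
        final[i] = canon[lab]
    gap_curve = pd.DataFrame(gap_rows, columns=["k", "gap", "se"])
    return ClusterAssignment(rr.set_ids, final, int(k), gap_curve)


def cross_analysis_membership(collections) -> pd.DataFrame:
    """Presence matrix: which gene sets were identified by which analysis.

    ``collections`` is a mapping from analysis label to collection, or an
    iterable of ``(label, collection)`` pairs.  Rows are the union of set ids
    across analyses (first-appearance order); columns are analysis labels;
    entries are boolean.
    """
    pairs = list(collections.items()) if isinstance(collections, Mapping) else list(collections)
    labels = [label for label, _ in pairs]
    if len(labels) < 2:
        raise DataValidationError("need >= 2 labeled collections")
    if len(set(labels)) != len(labels):
        raise DataValidationError("duplicate analysis labels")
    collections = dict(pairs)
    order: list[str] = []
    seen = set()
    for label in labels:
        for s in collections[label]:
            if s.set_id not in seen:
                seen.add(s.set_id)
                order.append(s.set_id)
    data = {
        label: [sid in set(collections[label].set_ids) for sid in order]
        for label in labels
    }
    return pd.DataFrame(data, index=order)
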