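"""Seeded generators for every statistical structure the framework assumes:
blocks sharing low-rank joint structure, paired differential features with
cross-omic noise correlation, survival outcomes linked to features, and
gene-set collections with planted cluster structure.

All generators are pure functions of their parameters and seed, and emit the
exact data types the rest of the package consumes, alongside a ground-truth
record sufficient to score any estimator.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core_data import (
    DataValidationError,
    FeatureMapping,
    GeneSet,
    GeneSetCollection,
    OmicsDataset,
    SampleMetadata,
)

__all__ = [
    "simulate_joint_blocks",
    "simulate_paired_differential",
    "simulate_survival_omics",
    "simulate_gene_set_collection",
    "JointBlocksTruth",
    "PairedDifferentialTruth",
    "SurvivalTruth",
    "GeneSetTruth",
]


def _write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Joint/individual low-rank blocks
# ---------------------------------------------------------------------------


@dataclass
class JointBlocksTruth:
    joint_rank: int
    individual_ranks: list[int]
    joint_sample_basis: np.ndarray          # n x r, orthonormal
    individual_sample_bases: list[np.ndarray]
    joint_parts: list[np.ndarray]
    individual_parts: list[np.ndarray]
    snr: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        _write_json({
            "scenario": "joint_blocks",
            "joint_rank": self.joint_rank,
            "individual_ranks": self.individual_ranks,
            "snr": self.snr,
            "seed": self.seed,
            "joint_sample_basis": self.joint_sample_basis.tolist(),
        }, path)


def simulate_joint_blocks(
    n_samples: int,
    features_per_block: Sequence[int],
    joint_rank: int,
    individual_ranks: Sequence[int],
    snr: float = 10.0,
    seed: int = 0,
) -> tuple[list[OmicsDataset], JointBlocksTruth]:
    """Blocks X_i = joint low-rank + block-specific low-rank + Gaussian noise.

    The joint part shares one orthonormal sample-space basis across blocks;
    individual sample subspaces are orthogonal to it (and to the constant
    vector, so signal rows are exactly mean-centered).  Noise is scaled so
    that per block ``||signal||_F^2 / ||noise||_F^2 = snr``.
    """
    if len(features_per_block) != len(individual_ranks):
        raise ValueError("features_per_block and individual_ranks must have equal length")
    total_dims = 1 + joint_rank + int(sum(individual_ranks))
    if total_dims > n_samples:
        raise DataValidationError(
            f"infeasible ranks: 1 + joint + sum(individual) = {total_dims} > n_samples={n_samples}")
    for p, r_i in zip(features_per_block, individual_ranks):
        if joint_rank + r_i > p:
            raise DataValidationError(f"block with {p} features cannot host rank {joint_rank + r_i}")

    rng = np.random.default_rng(seed)
    basis = np.hstack([np.ones((n_samples, 1)), rng.standard_normal((n_samples, total_dims - 1))])
    q, _ = np.linalg.qr(basis)
    v_joint = q[:, 1:1 + joint_rank]
    offset = 1 + joint_rank
    w_bases = []
    for r_i in individual_ranks:
        w_bases.append(q[:, offset:offset + r_i])
        offset += r_i

    # joint components made deliberately stronger than individual ones so
    # that rank selection has a detectable gap at moderate SNR
    sv_joint = np.linspace(1.0, 0.7, joint_rank) if joint_rank else np.zeros(0)
    blocks: list[OmicsDataset] = []
    joint_parts, individual_parts = [], []
    for i, (p, r_i) in enumerate(zip(features_per_block, individual_ranks)):
        l_i, _ = np.linalg.qr(rng.standard_normal((p, max(joint_rank, 1))))
        m_i, _ = np.linalg.qr(rng.standard_normal((p, max(r_i, 1))))
        sv_ind = np.linspace(0.5, 0.3, r_i) if r_i else np.zeros(0)
        j_i = (l_i[:, :joint_rank] * sv_joint) @ v_joint.T if joint_rank else np.zeros((p, n_samples))
        a_i = (m_i[:, :r_i] * sv_ind) @ w_bases[i].T if r_i else np.zeros((p, n_samples))
        signal = j_i + a_i
        if np.isinf(snr):
            noise = np.zeros((p, n_samples))
        else:
            sd = np.sqrt((signal**2).sum() / (snr * p * n_samples))
            noise = sd * rng.standard_normal((p, n_samples))
        x = signal + noise
        x = x - x.mean(axis=1, keepdims=True)
        blocks.append(OmicsDataset(
            name=f"block_{i+1}",
            feature_ids=tuple(f"b{i+1}_f{j+1}" for j in range(p)),
            sample_ids=tuple(f"s{j+1}" for j in range(n_samples)),
            values=x,
        ))
        joint_parts.append(j_i)
        individual_parts.append(a_i)

    truth = JointBlocksTruth(joint_rank, list(individual_ranks), v_joint, w_bases,
                             joint_parts, individual_parts, snr, seed)
    return blocks, truth


# ---------------------------------------------------------------------------
# Paired differential features across two blocks
# ---------------------------------------------------------------------------


@dataclass
class PairedDifferentialTruth:
    true_pair_indices: np.ndarray
    true_genes: list[str]
    effect_per_block: float
    cross_corr: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        _write_json({
            "scenario": "paired_differential",
            "true_pair_indices": self.true_pair_indices.tolist(),
            "true_genes": self.true_genes,
            "effect_per_block": self.effect_per_block,
            "cross_corr": self.cross_corr,
            "seed": self.seed,
        }, path)


def simulate_paired_differential(
    n_per_group: int,
    n_features: int,
    n_true_pairs: int,
    effect_per_block: float,
    cross_corr: float = 0.0,
    seed: int = 0,
) -> tuple[OmicsDataset, OmicsDataset, FeatureMapping, SampleMetadata, PairedDifferentialTruth]:
    """Two-group design where true pairs carry a mean shift in *both* blocks.

    Feature-wise Gaussian noise is correlated across blocks at ``cross_corr``
    for every mapped pair; pair i of block a is linked to pair i of block b
    through gene ``G_i``.
    """
    if n_true_pairs > n_features:
        raise ValueError("n_true_pairs cannot exceed n_features")
    if not (0.0 <= cross_corr < 1.0):
        raise ValueError("cross_corr must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    z1 = rng.standard_normal((n_features, n))
    z2 = rng.standard_normal((n_features, n))
    xa = z1
    xb = cross_corr * z1 + np.sqrt(1.0 - cross_corr**2) * z2

    true_idx = np.sort(rng.choice(n_features, size=n_true_pairs, replace=False))
    group2 = np.arange(n_per_group, n)
    xa = xa.copy()
    xb = xb.copy()
    xa[np.ix_(true_idx, group2)] += effect_per_block
    xb[np.ix_(true_idx, group2)] += effect_per_block

    samples = tuple(f"s{j+1}" for j in range(n))
    genes = [f"G{i+1}" for i in range(n_features)]
    feats_a = tuple(f"a{i+1}" for i in range(n_features))
    feats_b = tuple(f"b{i+1}" for i in range(n_features))
    block_a = OmicsDataset("omic_a", feats_a, samples, xa)
    block_b = OmicsDataset("omic_b", feats_b, samples, xb)
    mapping = FeatureMapping(
        tuple((genes[i], feats_a[i], feats_b[i]) for i in range(n_features)), retain_all=True)
    frame = pd.DataFrame({
        "group": ["g1"] * n_per_group + ["g2"] * n_per_group,
        "age": np.round(rng.normal(58.0, 10.0, size=n), 1),
    }, index=list(samples))
    meta = SampleMetadata(frame, categorical=["group"], numeric=["age"])
    truth = PairedDifferentialTruth(true_idx, [genes[i] for i in true_idx],
                                    effect_per_block, cross_corr, seed)
    return block_a, block_b, mapping, meta, truth


# ---------------------------------------------------------------------------
# Survival outcomes linked to features
# ---------------------------------------------------------------------------


@dataclass
class SurvivalTruth:
    true_feature_indices: np.ndarray
    beta: float
    censoring_fraction: float
    realized_censoring: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        _write_json({
            "scenario": "survival",
            "true_feature_indices": self.true_feature_indices.tolist(),
            "beta": self.beta,
            "censoring_fraction": self.censoring_fraction,
            "realized_censoring": self.realized_censoring,
            "seed": self.seed,
        }, path)


def simulate_survival_omics(
    n_samples: int,
    n_features: int,
    n_true: int = 1,
    beta: float = 1.0,
    censoring_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[OmicsDataset, SampleMetadata, SurvivalTruth]:
    """Exponential event times with hazard proportional to
    ``exp(beta * sum(true features) + 0.02 * age)`` and uniform censoring
    calibrated to the requested fraction.  Age is drawn N(58, 10)."""
    if censoring_fraction >= 0.95:
        raise ValueError("censoring_fraction >= 0.95 leaves too few events")
    if n_true > n_features:
        raise ValueError("n_true cannot exceed n_features")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_features, n_samples))
    age = rng.normal(58.0, 10.0, size=n_samples)
    true_idx = np.sort(rng.choice(n_features, size=n_true, replace=False))
    lp = beta * x[true_idx].sum(axis=0) + 0.02 * age
    hazard = np.exp(lp - lp.mean())  # centered for numeric stability only
    t_event = rng.exponential(1.0, size=n_samples) / hazard

    if censoring_fraction <= 0:
        time, event = t_event, np.ones(n_samples, dtype=int)
    else:
        u = np.maximum(rng.random(n_samples), 1e-12)

        def censored_frac(c_max: float) -> float:
            return float((c_max * u < t_event).mean()) - censoring_fraction

        hi = float(t_event.max() / u.min()) + 1.0
        c_max = brentq(censored_frac, 1e-12, hi, xtol=1e-10)
        cens = c_max * u
        event = (t_event <= cens).astype(int)
        time = np.minimum(t_event, cens)
    time = np.maximum(time, 1e-12)

    samples = tuple(f"s{j+1}" for j in range(n_samples))
    block = OmicsDataset(
        "omic_surv",
        tuple(f"f{i+1}" for i in range(n_features)),
        samples,
        x,
    )
    frame = pd.DataFrame({
        "age": age,
        "survival_time": time,
        "survival_event": event,
    }, index=list(samples))
    meta = SampleMetadata(frame, numeric=["age"],
                          time_to_event={"survival": ("survival_time", "survival_event")})
    truth = SurvivalTruth(true_idx, beta, censoring_fraction,
                          float(1.0 - event.mean()), seed)
    return block, meta, truth


# ---------------------------------------------------------------------------
# Gene-set collections with planted clusters
# ---------------------------------------------------------------------------


@dataclass
class GeneSetTruth:
    cluster_labels: np.ndarray
    n_clusters: int
    within_overlap: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        _write_json({
            "scenario": "gene_sets",
            "cluster_labels": self.cluster_labels.tolist(),
            "n_clusters": self.n_clusters,
            "within_overlap": self.within_overlap,
            "seed": self.seed,
        }, path)


def simulate_gene_set_collection(
    n_sets: int,
    universe_size: int,
    n_clusters: int,
    within_overlap: float = 0.7,
    seed: int = 0,
    set_size: int = 20,
    pool_size: int = 30,
) -> tuple[GeneSetCollection, GeneSetTruth]:
    """Gene sets whose clusters share a disjoint core gene pool.

    A fraction ``within_overlap`` of each set is drawn from its cluster's
    pool; the remainder is drawn uniformly from the rest of the universe.
    All sets carry simulated p-values < 0.05 and sizes >= 3 so they pass the
    default significance/size filters.
    """
    if not (0.0 <= within_overlap <= 1.0):
        raise ValueError("within_overlap must lie in [0, 1]")
    if n_clusters * pool_size > universe_size:
        raise DataValidationError(
            f"{n_clusters} pools of {pool_size} genes exceed universe of {universe_size}")
    if set_size < 3:
        raise ValueError("set_size must be >= 3 to pass the size filter")
    rng = np.random.default_rng(seed)
    universe = [f"g{i+1:05d}" for i in range(universe_size)]
    pools = [universe[c * pool_size:(c + 1) * pool_size] for c in range(n_clusters)]
    outside = universe[n_clusters * pool_size:]

    labels = np.array([i * n_clusters // n_sets for i in range(n_sets)])
    sets = []
    for j in range(n_sets):
        c = int(labels[j])
        n_core = int(round(within_overlap * set_size))
        core = list(rng.choice(pools[c], size=min(n_core, pool_size), replace=False))
        pool_others = outside if outside else [g for g in universe if g not in set(pools[c])]
        n_rest = set_size - len(core)
        rest = list(rng.choice(pool_others, size=n_rest, replace=False)) if n_rest > 0 else []
        p = float(rng.uniform(0.001, 0.049))
        sets.append(GeneSet(f"S{j+1:03d}", frozenset(core + rest),
                            description=f"planted cluster {c+1}", p_value=p))
    return GeneSetCollection(sets), GeneSetTruth(labels, n_clusters, within_overlap, seed)
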