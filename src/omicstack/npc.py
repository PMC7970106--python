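"""Non-parametric combination (NPC) of statistical evidence across omics.

Each block is analysed separately under a *joint* permutation scheme that
preserves cross-omic sample coupling; per-feature permutation p-values are
combined across mapped features with Fisher, Liptak or Tippett combining
functions, and the combined statistic is referred to its own permutation
distribution to obtain a global p-value.  A closed-form parametric
combination (independence assumed) is provided as a fast alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from ._multitest import adjust
from ._survival import cox_wald_z
from .core_data import (
    DataValidationError,
    FeatureMapping,
    OmicsDataset,
    SampleMetadata,
    TimeToEvent,
)

__all__ = [
    "Design",
    "LinearModelEngine",
    "CoxEngine",
    "linear_model_t",
    "cox_z",
    "joint_permutations",
    "PermutationPlan",
    "permutation_pvalues",
    "combine_pvalues",
    "omics_npc",
    "NPCResult",
    "parametric_combination",
    "parametric_feature_pvalues",
    "count_novel_features",
    "NovelCounts",
]

COMBINING_METHODS = ("fisher", "liptak", "tippett")


@dataclass(frozen=True)
class Design:
    """Outcome variable plus optional covariates, resolved against metadata."""

    outcome: str
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if self.outcome in self.covariates:
            raise DataValidationError(f"outcome {self.outcome!r} repeated among covariates")

    def resolve(self, meta: SampleMetadata):
        """Return (outcome columns or TimeToEvent, covariate matrix)."""
        kind = meta.kind_of(self.outcome)
        if kind == "time_to_event":
            y = meta.get(self.outcome)
        elif kind == "numeric":
            y = meta.get(self.outcome)[:, None].astype(float)
        else:
            labels = meta.get(self.outcome)
            levels = sorted(pd.unique(labels))
            if len(levels) < 2:
                raise DataValidationError(f"categorical outcome {self.outcome!r} has < 2 levels")
            # dummy code, dropping the first (reference) level
            y = np.column_stack([(labels == lev).astype(float) for lev in levels[1:]])
        z_cols = []
        for c in self.covariates:
            ck = meta.kind_of(c)
            if ck == "numeric":
                z_cols.append(meta.get(c)[:, None].astype(float))
            elif ck == "categorical":
                labels = meta.get(c)
                levels = sorted(pd.unique(labels))
                z_cols.append(np.column_stack([(labels == lev).astype(float) for lev in levels[1:]]))
            else:
                raise DataValidationError(f"covariate {c!r} must be categorical or numeric")
        z = np.hstack(z_cols) if z_cols else np.zeros((len(meta.sample_ids), 0))
        return y, z


def _take_outcome(y, idx):
    return y.take(idx) if isinstance(y, TimeToEvent) else y[idx]


# ---------------------------------------------------------------------------
# Statistic engines
# ---------------------------------------------------------------------------


def _ols_stats(values: np.ndarray, ycols: np.ndarray, z: np.ndarray, moderated: bool):
    """Vectorized least squares of every feature on [1 | outcome | covariates].

    Returns ``(stats, df, kind)`` where ``stats`` is a t statistic of the
    single outcome column, or the F statistic of the outcome block when the
    outcome is dummy-coded into several columns.
    """
    n = values.shape[1]
    ones = np.ones((n, 1))
    d = np.hstack([ones, ycols, z])
    q = d.shape[1]
    if n <= q + 1:
        raise DataValidationError(f"n_samples={n} too small for {q} design columns")
    if np.linalg.matrix_rank(d) < q:
        raise DataValidationError(
            f"singular design matrix ({q} columns incl. intercept, outcome, covariates); "
            "remove collinear variables")
    y = values.T  # n x features
    g = np.linalg.inv(d.T @ d)
    b = g @ (d.T @ y)
    resid = y - d @ b
    df = n - q
    s2 = (resid**2).sum(axis=0) / df

    k = ycols.shape[1]
    if k == 1:
        if moderated:
            s2_use = _squeeze_var(s2, df)
        else:
            s2_use = s2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = b[1] / np.sqrt(s2_use * g[1, 1])
        return np.where(np.isfinite(t), t, 0.0), df, "t"
    # multi-level outcome: F test of the outcome block vs the reduced model
    d0 = np.hstack([ones, z])
    b0 = np.linalg.lstsq(d0, y, rcond=None)[0]
    rss0 = ((y - d0 @ b0) ** 2).sum(axis=0)
    rss1 = (resid**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss1) / k) / (rss1 / df)
    return np.where(np.isfinite(f), f, 0.0), df, "f"


def _squeeze_var(s2: np.ndarray, df: int) -> np.ndarray:
    """Empirical-Bayes shrinkage of residual variances.

    Prior variance is the 10%-trimmed mean of the observed variances; the
    prior degrees of freedom are moment-matched so that the excess variance
    of log s^2 over its chi-square expectation equals trigamma(d0/2).
    """
    s2 = np.maximum(s2, 1e-300)
    s0 = float(stats.trim_mean(s2, 0.1))
    logs = np.log(s2)
    excess = float(np.var(logs, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if excess <= 0 or len(s2) < 3:
        return np.full_like(s2, s0)  # d0 -> infinity: full shrinkage
    from scipy.optimize import brentq

    d0 = 2.0 * brentq(lambda a: special.polygamma(1, a) - excess, 1e-8, 1e8)
    return (d0 * s0 + df * s2) / (d0 + df)


class LinearModelEngine:
    """Per-feature t (or F for multi-level outcomes) from least squares,
    optionally with empirical-Bayes variance moderation."""

    kind = "linear_model_t"

    def __init__(self, moderated: bool = False) -> None:
        self.moderated = moderated

    def __call__(self, values: np.ndarray, y, z: np.ndarray) -> np.ndarray:
        if isinstance(y, TimeToEvent):
            raise DataValidationError("linear model engine cannot use a time-to-event outcome")
        return _ols_stats(values, y, z, self.moderated)[0]


class CoxEngine:
    """Per-feature Wald z from a Cox model of the time-to-event outcome."""

    kind = "cox_z"

    def __call__(self, values: np.ndarray, y, z: np.ndarray) -> np.ndarray:
        if not isinstance(y, TimeToEvent):
            raise DataValidationError("Cox engine requires a time-to-event outcome")
        n_events = int(y.event.sum())
        if n_events == 0:
            raise DataValidationError("Cox engine: no events in outcome")
        if n_events < 5:
            warnings.warn(f"only {n_events} events; Cox statistics will be unstable")
        out = np.empty(values.shape[0])
        n_failed = 0
        for i in range(values.shape[0]):
            zi = cox_wald_z(values[i], y.time, y.event, z if z.size else None)
            if not np.isfinite(zi):
                n_failed += 1
                zi = np.nan
            out[i] = zi
        if n_failed:
            warnings.warn(f"Cox model failed to converge for {n_failed} feature(s); "
                          "their statistics are NaN (treated as p = 1)")
        return out


def linear_model_t(d: OmicsDataset, meta: SampleMetadata, design: Design,
                   moderated: bool = False) -> np.ndarray:
    """Observed per-feature linear-model statistic for a block."""
    meta = meta.subset(d.sample_ids)
    y, z = design.resolve(meta)
    return LinearModelEngine(moderated)(d.values, y, z)


def cox_z(d: OmicsDataset, meta: SampleMetadata, design: Design) -> np.ndarray:
    """Observed per-feature Cox Wald z for a block."""
    meta = meta.subset(d.sample_ids)
    y, z = design.resolve(meta)
    return CoxEngine()(d.values, y, z)


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PermutationPlan:
    """B permutations of outcome assignments for each dataset.

    ``index_arrays[d][b, j]`` gives the sample position whose outcome is
    assigned to position ``j`` of dataset ``d`` in permutation ``b``.  Shared
    samples are permuted identically across datasets; dataset-exclusive
    samples (``all_samples`` mode) are permuted among themselves.
    """

    mode: str
    B: int
    seed: int | None
    sample_ids: tuple[tuple[str, ...], ...]
    index_arrays: tuple[np.ndarray, ...]


def joint_permutations(
    sample_ids_per_dataset: Sequence[Sequence[str]],
    mode: str = "overlap",
    B: int = 1000,
    seed: int | None = None,
) -> PermutationPlan:
    """Build the coupled permutation plan for two or more datasets."""
    if mode not in ("overlap", "all_samples"):
        raise ValueError(f"unknown mode {mode!r}")
    if B < 20:
        raise ValueError("B < 20 permutations cannot resolve any p-value")
    if B < 100:
        warnings.warn(f"B={B} gives coarse p-value granularity (minimum p = {1/(B+1):.3g})")

    id_lists = [tuple(str(s) for s in ids) for ids in sample_ids_per_dataset]
    sets = [set(ids) for ids in id_lists]
    shared = [s for s in id_lists[0] if all(s in st for st in sets[1:])]
    if mode == "overlap":
        if any(st != sets[0] for st in sets[1:]):
            raise DataValidationError("overlap mode requires identical sample sets across datasets")
    if len(shared) < 2:
        raise DataValidationError("fewer than two shared samples across datasets")

    rng = np.random.default_rng(seed)
    positions = [{s: i for i, s in enumerate(ids)} for ids in id_lists]
    shared_pos = [[pos[s] for s in shared] for pos in positions]
    excl_pos = [[i for i, s in enumerate(ids) if s not in set(shared)] for ids in id_lists]

    arrays = [np.tile(np.arange(len(ids)), (B, 1)) for ids in id_lists]
    n_shared = len(shared)
    for b in range(B):
        sigma = rng.permutation(n_shared)
        for d in range(len(id_lists)):
            sp = shared_pos[d]
            for t in range(n_shared):
                arrays[d][b, sp[t]] = sp[sigma[t]]
        if mode == "all_samples":
            for d in range(len(id_lists)):
                ep = np.asarray(excl_pos[d], dtype=int)
                if len(ep) > 1:
                    arrays[d][b, ep] = ep[rng.permutation(len(ep))]
    return PermutationPlan(mode, B, seed, tuple(id_lists), tuple(a for a in arrays))


@dataclass(frozen=True)
class PermutationPValues:
    """Observed and pseudo permutation p-values for one block."""

    p_observed: np.ndarray   # features
    pseudo: np.ndarray       # B x features
    t_observed: np.ndarray
    t_permuted: np.ndarray


def _rank_pvalues(t_obs: np.ndarray, t_perm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leave-observed-in two-sided permutation p-values.

    Every row of the (B+1)-row statistic matrix (observed first) is ranked
    within the full distribution: p = #{|T_j| >= |T_i|} / (B + 1), counting
    itself.  This makes observed and permuted combined statistics
    exchangeable under the null.  NaN statistics sink to p = 1.
    """
    all_t = np.abs(np.vstack([t_obs[None, :], t_perm]))
    all_t = np.where(np.isnan(all_t), -np.inf, all_t)
    n = all_t.shape[0]
    srt = np.sort(all_t, axis=0)
    p = np.empty_like(all_t)
    for j in range(all_t.shape[1]):
        p[:, j] = (n - np.searchsorted(srt[:, j], all_t[:, j], side="left")) / n
    return p[0], p[1:]


def permutation_pvalues(
    engine: Callable,
    d: OmicsDataset,
    meta: SampleMetadata,
    design: Design,
    plan_indices: np.ndarray,
) -> PermutationPValues:
    """Per-feature permutation p-values under the given plan.

    The outcome (and covariates, jointly — preserving their dependence) is
    permuted according to each row of ``plan_indices``.
    """
    meta = meta.subset(d.sample_ids)
    y, z = design.resolve(meta)
    t_obs = engine(d.values, y, z)
    nan_frac = float(np.isnan(t_obs).mean())
    if nan_frac > 0.10:
        raise RuntimeError(
            f"{d.name}: statistic engine failed on {nan_frac:.0%} of features (> 10%)")
    B = plan_indices.shape[0]
    t_perm = np.empty((B, d.n_features))
    for b in range(B):
        idx = plan_indices[b]
        t_perm[b] = engine(d.values, _take_outcome(y, idx), z[idx])
    p_obs, pseudo = _rank_pvalues(np.asarray(t_obs, float), t_perm)
    return PermutationPValues(p_obs, pseudo, np.asarray(t_obs, float), t_perm)


# ---------------------------------------------------------------------------
# Combining functions
# ---------------------------------------------------------------------------


def combine_pvalues(pvals: Sequence[float], method: str) -> float:
    """Combine partial p-values into one statistic (larger = more evidence).

    fisher: -2 sum(ln p); liptak: sum(probit(1 - p)); tippett: max(1 - p).
    """
    p = np.asarray([v for v in pvals if v == v], dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "fisher":
        return float(-2.0 * np.log(p).sum())
    if method == "liptak":
        return float(special.ndtri(1.0 - p).sum())
    if method == "tippett":
        return float((1.0 - p).max())
    raise ValueError(f"unknown combining method {method!r}")


def _combine_rows(p3: np.ndarray, method: str) -> np.ndarray:
    """Vectorized combination over a (rows, tuples, k) array with NaN = absent."""
    with np.errstate(divide="ignore", invalid="ignore"):
        if method == "fisher":
            return -2.0 * np.nansum(np.log(p3), axis=2)
        if method == "liptak":
            return np.nansum(special.ndtri(1.0 - p3), axis=2)
        if method == "tippett":
            return np.nanmax(1.0 - p3, axis=2)
    raise ValueError(f"unknown combining method {method!r}")


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


@dataclass
class NPCResult:
    """Per-tuple NPC output plus per-feature single-omic permutation p-values."""

    genes: list[str]
    features_a: list[str | None]
    features_b: list[str | None]
    p_a: np.ndarray
    p_b: np.ndarray
    combined: dict[str, dict[str, np.ndarray]]  # method -> {statistic, p_global, p_adjusted}
    feature_pvalues: dict[str, pd.Series]
    block_names: tuple[str, str]
    B: int
    seed: int | None
    mode: str
    adjust_method: str

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "gene": self.genes,
            "feature_a": [a or "" for a in self.features_a],
            "feature_b": [b or "" for b in self.features_b],
            "p_a": self.p_a,
            "p_b": self.p_b,
        })
        for m, d in self.combined.items():
            df[f"stat_{m}"] = d["statistic"]
            df[f"p_{m}"] = d["p_global"]
            df[f"p_adj_{m}"] = d["p_adjusted"]
        return df


def _restrict_mapping(mapping: FeatureMapping, feats_a: set[str], feats_b: set[str]):
    tuples = []
    dropped = 0
    for g, a, b in mapping.tuples:
        a2 = a if (a is None or a in feats_a) else None
        b2 = b if (b is None or b in feats_b) else None
        if (a2 != a) or (b2 != b):
            dropped += 1
        if a2 is None and b2 is None:
            continue
        tuples.append((g, a2, b2))
    if dropped:
        warnings.warn(f"dropped unknown features from {dropped} mapping tuple(s)")
    tuples = list(dict.fromkeys(tuples))
    if not tuples:
        raise DataValidationError("no mapping tuples reference features present in the blocks")
    return tuples


def omics_npc(
    datasets: Sequence[OmicsDataset],
    meta: SampleMetadata,
    mapping: FeatureMapping,
    design: Design | Sequence[Design],
    engines: Sequence[Callable] | None = None,
    methods: Sequence[str] = COMBINING_METHODS,
    B: int = 1000,
    seed: int | None = 0,
    mode: str = "overlap",
    adjust_method: str = "bh",
) -> NPCResult:
    """Full NPC pipeline over two mapped blocks.

    Joint permutations -> per-block permutation p-values -> per-tuple
    combination of observed and pseudo p-values -> global permutation
    p-values -> multiplicity adjustment across tuples per method.
    """
    if len(datasets) != 2:
        raise DataValidationError("omics_npc integrates exactly two blocks")
    da, db = datasets
    designs = [design, design] if isinstance(design, Design) else list(design)
    if engines is None:
        engines = []
        for d_i, des in zip(datasets, designs):
            kind = meta.kind_of(des.outcome)
            engines.append(CoxEngine() if kind == "time_to_event" else LinearModelEngine())
    for m in methods:
        if m not in COMBINING_METHODS:
            raise ValueError(f"unknown combining method {m!r}")

    tuples = _restrict_mapping(mapping, set(da.feature_ids), set(db.feature_ids))

    plan = joint_permutations([da.sample_ids, db.sample_ids], mode=mode, B=B, seed=seed)
    pp_a = permutation_pvalues(engines[0], da, meta, designs[0], plan.index_arrays[0])
    pp_b = permutation_pvalues(engines[1], db, meta, designs[1], plan.index_arrays[1])

    full_a = np.vstack([pp_a.p_observed[None, :], pp_a.pseudo])
    full_b = np.vstack([pp_b.p_observed[None, :], pp_b.pseudo])
    pos_a = {f: i for i, f in enumerate(da.feature_ids)}
    pos_b = {f: i for i, f in enumerate(db.feature_ids)}
    ia = np.array([pos_a[a] if a is not None else 0 for _, a, _ in tuples])
    ib = np.array([pos_b[b] if b is not None else 0 for _, _, b in tuples])
    has_a = np.array([a is not None for _, a, _ in tuples])
    has_b = np.array([b is not None for _, _, b in tuples])
    pa = np.where(has_a[None, :], full_a[:, ia], np.nan)
    pb = np.where(has_b[None, :], full_b[:, ib], np.nan)
    p3 = np.stack([pa, pb], axis=-1)

    combined: dict[str, dict[str, np.ndarray]] = {}
    for m in methods:
        tmat = _combine_rows(p3, m)
        t0 = tmat[0]
        p_global = (1.0 + (tmat[1:] >= t0[None, :]).sum(axis=0)) / (B + 1.0)
        combined[m] = {
            "statistic": t0,
            "p_global": p_global,
            "p_adjusted": adjust(p_global, adjust_method),
        }

    return NPCResult(
        genes=[g for g, _, _ in tuples],
        features_a=[a for _, a, _ in tuples],
        features_b=[b for _, _, b in tuples],
        p_a=pa[0],
        p_b=pb[0],
        combined=combined,
        feature_pvalues={
            da.name: pd.Series(pp_a.p_observed, index=list(da.feature_ids)),
            db.name: pd.Series(pp_b.p_observed, index=list(db.feature_ids)),
        },
        block_names=(da.name, db.name),
        B=B,
        seed=seed,
        mode=mode,
        adjust_method=adjust_method,
    )


# ---------------------------------------------------------------------------
# Parametric alternative
# ---------------------------------------------------------------------------


def parametric_combination(p_lists: Sequence[Sequence[float]], method: str) -> np.ndarray:
    """Closed-form global p-values assuming independent partial p-values.

    fisher: chi-square(2k) upper tail of -2 sum(ln p); liptak: N(0, k) upper
    tail of sum(probit(1 - p)); tippett: 1 - (1 - p_min)^k.
    """
    out = np.empty(len(p_lists))
    for i, ps in enumerate(p_lists):
        p = np.asarray([v for v in ps if v == v], dtype=float)
        if p.size == 0:
            raise ValueError("need at least one p-value per tuple")
        if np.any(p <= 0) or np.any(p > 1):
            raise ValueError("p-values must lie in (0, 1]")
        k = p.size
        t = combine_pvalues(p, method)
        if method == "fisher":
            out[i] = stats.chi2.sf(t, df=2 * k)
        elif method == "liptak":
            out[i] = stats.norm.sf(t, scale=np.sqrt(k))
        elif method == "tippett":
            out[i] = 1.0 - (1.0 - p.min()) ** k
        else:
            raise ValueError(f"unknown combining method {method!r}")
    return out


def parametric_feature_pvalues(
    d: OmicsDataset, meta: SampleMetadata, design: Design, moderated: bool = False
) -> np.ndarray:
    """Per-feature two-sided parametric p-values matching the engine choice."""
    meta = meta.subset(d.sample_ids)
    y, z = design.resolve(meta)
    if isinstance(y, TimeToEvent):
        zstat = CoxEngine()(d.values, y, z)
        p = 2.0 * stats.norm.sf(np.abs(zstat))
        return np.where(np.isnan(zstat), 1.0, p)
    statv, df, kind = _ols_stats(d.values, y, z, moderated)
    if kind == "t":
        return 2.0 * stats.t.sf(np.abs(statv), df)
    return stats.f.sf(statv, y.shape[1], df)


# ---------------------------------------------------------------------------
# Novel-feature accounting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NovelCounts:
    significant_single: int
    significant_pairs: int
    novel: int
    novel_features: frozenset[str]


def count_novel_features(
    npc: NPCResult,
    single_omic_p: Mapping[str, Mapping[str, float] | pd.Series],
    alpha: float = 0.05,
    method: str = "fisher",
) -> dict[str, NovelCounts]:
    """Features implicated by NPC but missed by single-omic analysis.

    ``single_omic_p`` maps block name to per-feature p-values already on the
    scale to be thresholded (adjusted or raw — the caller chooses).  A block's
    *novel* count is the number of its features appearing in a tuple with NPC
    adjusted p < alpha that are not single-omic significant.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    adj = npc.combined[method]["p_adjusted"]
    sig = adj < alpha
    implicated = {name: set() for name in npc.block_names}
    for i in np.flatnonzero(sig):
        if npc.features_a[i] is not None:
            implicated[npc.block_names[0]].add(npc.features_a[i])
        if npc.features_b[i] is not None:
            implicated[npc.block_names[1]].add(npc.features_b[i])
    out = {}
    for name in npc.block_names:
        pmap = single_omic_p[name]
        series = pmap if isinstance(pmap, pd.Series) else pd.Series(dict(pmap))
        single_sig = set(series.index[series < alpha])
        novel = implicated[name] - single_sig
        out[name] = NovelCounts(
            significant_single=len(single_sig),
            significant_pairs=int(sig.sum()),
            novel=len(novel),
            novel_features=frozenset(novel),
        )
    return out
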