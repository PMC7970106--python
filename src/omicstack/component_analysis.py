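"""Per-omic and joint component analysis.

Step 1 of the workflow is per-block PCA plus association of component scores
with sample metadata; step 2 decomposes two or more aligned blocks into
joint (shared across blocks), individual (block-specific) and residual
structure, with the joint/individual ranks chosen either by a permutation
test or by a PCA + canonical-correlation cross-check.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._multitest import adjust
from ._survival import cox_score_test
from .core_data import DataValidationError, OmicsDataset, SampleMetadata

__all__ = [
    "ComponentModel",
    "JIVEModel",
    "pca",
    "jive_decompose",
    "select_model_jive",
    "select_model_pca_gca",
    "associate_components",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComponentModel:
    """Truncated PCA of one block.

    ``scores`` (samples x k) times ``loadings.T`` (k x features) reproduces
    the best rank-k approximation of the transposed data matrix; loadings
    columns are orthonormal and explained-variance fractions are
    non-increasing and sum to at most 1.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_fraction: np.ndarray
    feature_ids: tuple[str, ...] = ()
    sample_ids: tuple[str, ...] = ()

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    """Deterministic sign convention: largest-|loading| entry positive."""
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1


def pca(d: OmicsDataset, n_components: int) -> ComponentModel:
    """Truncated SVD of a (centered) features x samples block.

    Warns if feature rows are not mean-centered.  The sign of each component
    is fixed so repeated runs are identical.
    """
    if n_components < 1 or n_components > min(d.shape):
        raise ValueError(f"n_components={n_components} outside [1, {min(d.shape)}]")
    row_means = d.values.mean(axis=1)
    if np.max(np.abs(row_means)) > 1e-8:
        warnings.warn(f"{d.name}: features are not mean-centered (max |mean| = "
                      f"{np.max(np.abs(row_means)):.3g}); PCA assumes centered input")
    u, s, vt = np.linalg.svd(d.values, full_matrices=False)
    k = n_components
    loadings = u[:, :k].copy()
    scores = (vt[:k].T * s[:k]).copy()
    _fix_signs(loadings, scores)
    total = float((d.values**2).sum())
    frac = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return ComponentModel(scores, loadings, frac, d.feature_ids, d.sample_ids)


# ---------------------------------------------------------------------------
# JIVE decomposition
# ---------------------------------------------------------------------------


def _svd_trunc(m: np.ndarray, r: int) -> tuple[np.ndarray, np.ndarray]:
    """Rank-r truncation of ``m``; returns (approximation, right basis V n x r)."""
    if r == 0:
        return np.zeros_like(m), np.zeros((m.shape[1], 0))
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    r = min(r, len(s))
    return (u[:, :r] * s[:r]) @ vt[:r], vt[:r].T


@dataclass
class JIVEModel:
    """Joint + individual + residual decomposition of aligned blocks.

    For every block ``X_i = joint[i] + individual[i] + residual[i]`` exactly;
    the stacked joint rows live in a rank-``joint_rank`` sample subspace
    orthogonal to every individual part.
    """

    block_names: list[str]
    feature_ids: list[tuple[str, ...]]
    sample_ids: tuple[str, ...]
    joint_rank: int
    individual_ranks: list[int]
    joint: list[np.ndarray]
    individual: list[np.ndarray]
    residual: list[np.ndarray]
    joint_scores: np.ndarray
    objective_trace: list[float]
    converged: bool
    n_iter: int

    def orthogonality_gap(self) -> float:
        """max |J_stacked @ A_stacked.T| — 0 at exact joint/individual orthogonality."""
        j = np.vstack(self.joint)
        a = np.vstack(self.individual)
        if j.size == 0 or a.size == 0:
            return 0.0
        return float(np.max(np.abs(j @ a.T)))

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, fids, j, a, r in zip(self.block_names, self.feature_ids,
                                       self.joint, self.individual, self.residual):
            for tag, mat in (("joint", j), ("individual", a), ("residual", r)):
                pd.DataFrame(mat, index=list(fids), columns=list(self.sample_ids)).to_csv(
                    path / f"{name}.{tag}.tsv", sep="\t", index_label="feature_id")
        pd.DataFrame(self.joint_scores, index=list(self.sample_ids),
                     columns=[f"joint_{i+1}" for i in range(self.joint_scores.shape[1])]
                     ).to_csv(path / "joint_scores.tsv", sep="\t", index_label="sample_id")
        manifest = {
            "block_names": self.block_names,
            "joint_rank": self.joint_rank,
            "individual_ranks": self.individual_ranks,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "objective_trace": self.objective_trace,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _check_aligned(blocks: Sequence[OmicsDataset]) -> None:
    if len(blocks) < 2:
        raise DataValidationError("need >= 2 blocks")
    first = blocks[0].sample_ids
    for b in blocks[1:]:
        if b.sample_ids != first:
            raise DataValidationError(
                f"blocks {blocks[0].name!r} and {b.name!r} are not sample-aligned; "
                "run align_common_samples first")


def jive_decompose(
    blocks: Sequence[OmicsDataset],
    joint_rank: int,
    individual_ranks: Sequence[int],
    tol: float = 1e-8,
    max_iter: int = 500,
) -> JIVEModel:
    """Alternating joint/individual estimation.

    Joint structure is the rank-r SVD of the stacked ``X - A``; each block's
    individual part is the rank-r_i SVD of ``X_i - J_i`` projected onto the
    orthocomplement of the joint sample subspace.  Iteration stops when the
    relative change of total residual sum of squares falls below ``tol``.
    """
    _check_aligned(blocks)
    if len(individual_ranks) != len(blocks):
        raise ValueError("one individual rank per block required")
    n = blocks[0].n_samples
    if joint_rank + max(individual_ranks) > n:
        raise ValueError(f"joint_rank + max individual rank exceeds n_samples={n}")

    xs = [b.values for b in blocks]
    sizes = [x.shape[0] for x in xs]
    x_stack = np.vstack(xs)
    total_ss = float((x_stack**2).sum())
    a_stack = np.zeros_like(x_stack)
    bounds = np.cumsum([0] + sizes)

    trace: list[float] = []
    converged = False
    j_stack = np.zeros_like(x_stack)
    v_joint = np.zeros((n, 0))
    it = 0
    for it in range(1, max_iter + 1):
        j_stack, v_joint = _svd_trunc(x_stack - a_stack, joint_rank)
        proj = np.eye(n) - v_joint @ v_joint.T
        for i, r_i in enumerate(individual_ranks):
            lo, hi = bounds[i], bounds[i + 1]
            z = (x_stack[lo:hi] - j_stack[lo:hi]) @ proj
            a_stack[lo:hi], _ = _svd_trunc(z, r_i)
        obj = float(((x_stack - j_stack - a_stack) ** 2).sum())
        trace.append(obj)
        if len(trace) >= 2:
            # relative to the current objective, floored so that exactly
            # decomposable inputs terminate once the residual hits machine zero
            if abs(trace[-2] - obj) <= tol * max(obj, total_ss * 1e-12):
                converged = True
                break
        if max(individual_ranks) == 0 or joint_rank == 0:
            converged = True  # single half-step problem, solved exactly
            break
    if not converged:
        warnings.warn(f"JIVE did not converge in {max_iter} iterations")

    # joint scores: right singular structure of the stacked joint part
    if joint_rank > 0:
        _, s, vt = np.linalg.svd(j_stack, full_matrices=False)
        scores = vt[:joint_rank].T * s[:joint_rank]
        load_proxy = vt[:joint_rank].T  # sign fixed on sample-space basis
        _fix_signs(load_proxy, scores)
    else:
        scores = np.zeros((n, 0))
    residual = x_stack - j_stack - a_stack
    return JIVEModel(
        block_names=[b.name for b in blocks],
        feature_ids=[b.feature_ids for b in blocks],
        sample_ids=blocks[0].sample_ids,
        joint_rank=joint_rank,
        individual_ranks=list(individual_ranks),
        joint=[j_stack[bounds[i]:bounds[i + 1]] for i in range(len(blocks))],
        individual=[a_stack[bounds[i]:bounds[i + 1]] for i in range(len(blocks))],
        residual=[residual[bounds[i]:bounds[i + 1]] for i in range(len(blocks))],
        joint_scores=scores,
        objective_trace=trace,
        converged=converged,
        n_iter=it,
    )


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------


def _svals(m: np.ndarray) -> np.ndarray:
    return np.linalg.svd(m, compute_uv=False)


def select_model_jive(
    blocks: Sequence[OmicsDataset],
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int | None = None,
    max_rank: int | None = None,
) -> tuple[int, list[int]]:
    """Sequential permutation test for the joint and individual ranks.

    Joint: candidate components are tested one at a time.  The leading
    singular value of the (deflated) stacked matrix is compared with the
    (1 - alpha) quantile of leading singular values under column-wise
    within-block permutations of the same deflated matrix — permutations
    destroy cross-block correlation while preserving each block's own
    structure, so only genuinely shared components survive.  Accepted
    components are deflated before the next test.  Individual ranks are
    chosen analogously on the joint-removed residual of each block, with
    entry-wise row permutations as the null.
    """
    _check_aligned(blocks)
    if n_perm < 20:
        raise ValueError("n_perm < 20 makes the null quantile unstable")
    rng = np.random.default_rng(seed)
    xs = [b.values for b in blocks]
    n = xs[0].shape[1]
    x_stack = np.vstack(xs)
    cap = min(n, x_stack.shape[0]) - 1 if max_rank is None else max_rank
    bounds = np.cumsum([0] + [x.shape[0] for x in xs])

    def deflate(m: np.ndarray) -> np.ndarray:
        approx, _ = _svd_trunc(m, 1)
        return m - approx

    r = 0
    resid = x_stack.copy()
    while r < cap:
        s_obs = _svals(resid)[0]
        null = np.empty(n_perm)
        for p in range(n_perm):
            perm = np.vstack([resid[bounds[i]:bounds[i + 1]][:, rng.permutation(n)]
                              for i in range(len(xs))])
            null[p] = _svals(perm)[0]
        if s_obs <= np.quantile(null, 1.0 - alpha):
            break
        r += 1
        resid = deflate(resid)

    j_stack, _ = _svd_trunc(x_stack, r)
    individual: list[int] = []
    for i, x in enumerate(xs):
        z = x - j_stack[bounds[i]:bounds[i + 1]]
        cap_i = min(z.shape) - 1
        obs_i = _svals(z)
        # entry-wise row permutations of the full residual: signal energy is
        # spread into the null bulk, so every q_k is conservative
        null_i = np.empty((n_perm, len(obs_i)))
        for p in range(n_perm):
            idx = rng.random(z.shape).argsort(axis=1)
            null_i[p] = _svals(np.take_along_axis(z, idx, axis=1))
        q_i = np.quantile(null_i, 1.0 - alpha, axis=0)
        r_i = 0
        while r_i < cap_i and obs_i[r_i] > q_i[r_i]:
            r_i += 1
        individual.append(r_i)
    return r, individual


def select_model_pca_gca(
    blocks: Sequence[OmicsDataset],
    var_threshold: float = 0.9,
    corr_threshold: float = 0.9,
) -> tuple[int, list[int]]:
    """PCA-GCA model selection for two blocks.

    Per block, retain the smallest number of components reaching
    ``var_threshold`` cumulative explained variance; the joint rank is the
    number of canonical-correlation pairs between the two score sets with
    correlation >= ``corr_threshold``; distinctive ranks are the remainders.
    """
    _check_aligned(blocks)
    if len(blocks) != 2:
        raise DataValidationError("PCA-GCA selection is defined for exactly two blocks")
    for t in (var_threshold, corr_threshold):
        if not (0.0 < t <= 1.0):
            raise ValueError(f"threshold {t} outside (0, 1]")

    score_sets = []
    counts = []
    for b in blocks:
        full = pca(b, min(b.shape))
        cum = np.cumsum(full.explained_variance_fraction)
        # smallest k with cumulative explained variance >= threshold
        hits = cum >= var_threshold - 1e-12
        k = int(np.argmax(hits) + 1) if hits.any() else len(cum)
        counts.append(k)
        score_sets.append(full.scores[:, :k])

    qa, _ = np.linalg.qr(score_sets[0])
    qb, _ = np.linalg.qr(score_sets[1])
    cc = np.linalg.svd(qa.T @ qb, compute_uv=False)
    cc = np.clip(cc, 0.0, 1.0)
    shared = int((cc >= corr_threshold).sum())
    distinct = [max(c - shared, 0) for c in counts]
    return shared, distinct


# ---------------------------------------------------------------------------
# Component-metadata association
# ---------------------------------------------------------------------------


def associate_components(
    scores: np.ndarray,
    meta: SampleMetadata,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Test every (component, metadata variable) pair.

    Kruskal-Wallis for categorical variables, Spearman correlation for
    numeric ones, and the Cox partial-likelihood score test for
    time-to-event outcomes.  Rows that cannot be tested (e.g. a single-level
    categorical) carry ``p = NaN`` and are excluded from the correction
    count.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if scores.shape[0] != len(meta.sample_ids):
        raise DataValidationError("scores and metadata sample counts differ")

    rows = []
    for c in range(scores.shape[1]):
        x = scores[:, c]
        for var, kind in meta.variables:
            stat, p = np.nan, np.nan
            if kind == "categorical":
                labels = meta.get(var)
                ok = np.array([lab is not None and lab == lab for lab in labels])
                groups = [x[ok][labels[ok] == lev] for lev in pd.unique(labels[ok])]
                groups = [g for g in groups if len(g) > 0]
                if len(groups) < 2:
                    warnings.warn(f"variable {var!r} has < 2 non-empty levels; emitting NaN")
                else:
                    stat, p = stats.kruskal(*groups)
                test = "kruskal_wallis"
            elif kind == "numeric":
                y = meta.get(var)
                ok = np.isfinite(y)
                if ok.sum() >= 3 and np.std(x[ok]) > 0 and np.std(y[ok]) > 0:
                    stat, p = stats.spearmanr(x[ok], y[ok])
                else:
                    warnings.warn(f"variable {var!r}: not enough variation for Spearman")
                test = "spearman"
            else:  # time_to_event
                tte = meta.get(var)
                if tte.event.sum() == 0:
                    warnings.warn(f"variable {var!r} has no events; emitting NaN")
                else:
                    stat, p = cox_score_test(x, tte.time, tte.event)
                test = "cox"
            rows.append((c + 1, var, test, stat, p))

    table = pd.DataFrame(rows, columns=["component", "variable", "test", "statistic", "p_value"])
    table["p_adjusted"] = adjust(table["p_value"].to_numpy(), correction)
    return table
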