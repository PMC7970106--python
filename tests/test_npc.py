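import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omicstack import (
    CoxEngine,
    Design,
    FeatureMapping,
    LinearModelEngine,
    OmicsDataset,
    SampleMetadata,
    combine_pvalues,
    count_novel_features,
    cox_z,
    joint_permutations,
    linear_model_t,
    omics_npc,
    parametric_combination,
    simulate_paired_differential,
    simulate_survival_omics,
)
from omicstack.core_data import DataValidationError
from omicstack.npc import NPCResult, _rank_pvalues
from omicstack._multitest import bh_adjust

from conftest import make_dataset


# ---------------------------------------------------------------------------
# linear model engine
# ---------------------------------------------------------------------------


def _meta_two_groups(n_per_group, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    frame = pd.DataFrame({"group": ["g1"] * n_per_group + ["g2"] * n_per_group,
                          "age": rng.normal(58, 10, n)},
                         index=[f"s{j+1}" for j in range(n)])
    return SampleMetadata(frame, categorical=["group"], numeric=["age"])


def test_perfect_association_maximal_t(rng):
    meta = _meta_two_groups(10)
    y = np.array([0.0] * 10 + [1.0] * 10)
    x = np.vstack([y, rng.standard_normal((20, 20))])
    d = OmicsDataset("x", tuple(f"f{i}" for i in range(21)), tuple(meta.sample_ids), x)
    t = linear_model_t(d, meta, Design("group"))
    assert np.argmax(np.abs(t)) == 0


def test_orthogonal_feature_zero_t():
    meta = _meta_two_groups(3)
    # feature orthogonal to the (centered) dummy outcome and the intercept
    x = np.array([[1.0, -2.0, 1.0, 1.0, -2.0, 1.0]])
    d = OmicsDataset("x", ("f1",), tuple(meta.sample_ids), x)
    t = linear_model_t(d, meta, Design("group"))
    assert abs(t[0]) < 1e-10


def test_ols_oracle_with_covariate():
    rng = np.random.default_rng(42)
    meta = _meta_two_groups(15, seed=3)
    n = 30
    x = rng.standard_normal((500, n))
    d = OmicsDataset("x", tuple(f"f{i}" for i in range(500)), tuple(meta.sample_ids), x)
    design = Design("group", ("age",))
    t = linear_model_t(d, meta, design)

    # independent per-feature OLS oracle
    y = (np.array(meta.get("group")) == "g2").astype(float)
    age = meta.get("age")
    dm = np.column_stack([np.ones(n), y, age])
    gram_inv = np.linalg.inv(dm.T @ dm)
    for i in rng.choice(500, 25, replace=False):
        beta, res, *_ = np.linalg.lstsq(dm, x[i], rcond=None)
        resid = x[i] - dm @ beta
        s2 = (resid**2).sum() / (n - 3)
        t_oracle = beta[1] / np.sqrt(s2 * gram_inv[1, 1])
        assert t[i] == pytest.approx(t_oracle, abs=1e-10)


def test_moderated_t_finite_and_shrunk():
    rng = np.random.default_rng(0)
    meta = _meta_two_groups(10, seed=1)
    x = rng.standard_normal((300, 20))
    d = OmicsDataset("x", tuple(f"f{i}" for i in range(300)), tuple(meta.sample_ids), x)
    t_plain = linear_model_t(d, meta, Design("group"))
    t_mod = linear_model_t(d, meta, Design("group"), moderated=True)
    assert np.all(np.isfinite(t_mod))
    # moderation pulls extreme statistics toward the bulk
    assert np.abs(t_mod).max() <= np.abs(t_plain).max() + 1e-9


def test_singular_design_error():
    meta = _meta_two_groups(5)
    frame = meta.frame.copy()
    frame["age2"] = frame["age"]  # exact collinearity
    meta2 = SampleMetadata(frame, categorical=["group"], numeric=["age", "age2"])
    d = make_dataset(np.random.default_rng(0), 5, 10, name="x")
    with pytest.raises(DataValidationError, match="singular|collinear"):
        linear_model_t(d, meta2, Design("group", ("age", "age2")))


# ---------------------------------------------------------------------------
# Cox engine
# ---------------------------------------------------------------------------


def test_cox_null_distribution():
    block, meta, _ = simulate_survival_omics(100, 200, n_true=1, beta=0.0,
                                             censoring_fraction=0.3, seed=2)
    z = cox_z(block, meta, Design("survival", ("age",)))
    z = z[np.isfinite(z)]
    assert stats.kstest(z, "norm").pvalue > 0.01


def test_cox_beta_recovery():
    block, meta, truth = simulate_survival_omics(200, 5, n_true=1, beta=1.0,
                                                 censoring_fraction=0.3, seed=1)
    from omicstack._survival import cox_fit
    i = truth.true_feature_indices[0]
    design = np.column_stack([block.values[i], meta.get("age")])
    tte = meta.get("survival")
    beta, cov, converged = cox_fit(design, tte.time, tte.event)
    assert converged
    assert beta[0] == pytest.approx(1.0, abs=0.2)


def test_cox_no_events_error():
    rng = np.random.default_rng(0)
    frame = pd.DataFrame({"t": rng.uniform(1, 5, 10), "e": [0] * 10},
                         index=[f"s{i+1}" for i in range(10)])
    meta = SampleMetadata(frame, time_to_event={"surv": ("t", "e")})
    d = make_dataset(rng, 3, 10)
    with pytest.raises(DataValidationError, match="event"):
        cox_z(d, meta, Design("surv"))


# ---------------------------------------------------------------------------
# permutation plans
# ---------------------------------------------------------------------------


def test_overlap_coupling():
    ids = [tuple(f"s{i}" for i in range(8))] * 2
    plan = joint_permutations(ids, mode="overlap", B=50, seed=3)
    np.testing.assert_array_equal(plan.index_arrays[0], plan.index_arrays[1])


def test_all_samples_partition():
    ids_a = ("s1", "s2", "s3", "s4", "a1", "a2")
    ids_b = ("s2", "s1", "s4", "s3", "b1", "b2", "b3")
    plan = joint_permutations([ids_a, ids_b], mode="all_samples", B=40, seed=5)
    shared = ["s1", "s2", "s3", "s4"]
    pos_a = {s: i for i, s in enumerate(ids_a)}
    pos_b = {s: i for i, s in enumerate(ids_b)}
    inv_a = {i: s for s, i in pos_a.items()}
    inv_b = {i: s for s, i in pos_b.items()}
    for b in range(40):
        # restriction to shared samples is the same label permutation in both
        map_a = {s: inv_a[plan.index_arrays[0][b, pos_a[s]]] for s in shared}
        map_b = {s: inv_b[plan.index_arrays[1][b, pos_b[s]]] for s in shared}
        assert map_a == map_b
        # exclusive samples stay within their own dataset's exclusive pool
        for s in ("a1", "a2"):
            assert inv_a[plan.index_arrays[0][b, pos_a[s]]] in ("a1", "a2")
        for s in ("b1", "b2", "b3"):
            assert inv_b[plan.index_arrays[1][b, pos_b[s]]] in ("b1", "b2", "b3")


def test_plan_determinism():
    ids = [tuple(f"s{i}" for i in range(10))] * 2
    p1 = joint_permutations(ids, B=30, seed=9)
    p2 = joint_permutations(ids, B=30, seed=9)
    for a, b in zip(p1.index_arrays, p2.index_arrays):
        np.testing.assert_array_equal(a, b)


def test_plan_b_validation():
    ids = [tuple(f"s{i}" for i in range(6))] * 2
    with pytest.raises(ValueError):
        joint_permutations(ids, B=10)
    with pytest.warns(UserWarning, match="granularity"):
        joint_permutations(ids, B=50)


def test_overlap_requires_identical_sets():
    with pytest.raises(DataValidationError):
        joint_permutations([("s1", "s2", "s3"), ("s1", "s2", "s4")], mode="overlap", B=30)


# ---------------------------------------------------------------------------
# permutation p-values (counting formula)
# ---------------------------------------------------------------------------


def test_counting_formula_b99():
    rng = np.random.default_rng(0)
    t_perm = rng.uniform(0, 1, (99, 1))
    t_obs = np.array([np.sort(t_perm[:, 0])[-5] + 1e-9])  # exactly 4 permuted >= observed
    p_obs, pseudo = _rank_pvalues(t_obs, t_perm)
    assert p_obs[0] == pytest.approx(5 / 100)


def test_observed_largest_lower_bound():
    rng = np.random.default_rng(1)
    t_perm = rng.uniform(0, 1, (99, 3))
    t_obs = np.array([2.0, 3.0, 4.0])
    p_obs, pseudo = _rank_pvalues(t_obs, t_perm)
    np.testing.assert_allclose(p_obs, 1 / 100)
    assert np.all(pseudo >= 1 / 100) and np.all(pseudo <= 1.0)


# ---------------------------------------------------------------------------
# combining functions
# ---------------------------------------------------------------------------


def test_fisher_no_evidence():
    assert combine_pvalues((1.0, 1.0), "fisher") == pytest.approx(0.0)


def test_liptak_symmetry():
    assert combine_pvalues((0.25, 0.75), "liptak") == pytest.approx(0.0, abs=1e-12)


def test_fisher_derived_value():
    assert combine_pvalues((0.05, 0.05), "fisher") == pytest.approx(-4 * np.log(0.05), abs=1e-12)
    assert combine_pvalues((0.05, 0.05), "fisher") == pytest.approx(11.983, abs=1e-3)


def test_tippett_max():
    assert combine_pvalues((0.2, 0.7), "tippett") == pytest.approx(0.8)


def test_combine_validation():
    with pytest.raises(ValueError):
        combine_pvalues((0.0, 0.5), "fisher")
    with pytest.raises(ValueError):
        combine_pvalues((0.5,), "nope")


# ---------------------------------------------------------------------------
# omics_npc end to end
# ---------------------------------------------------------------------------


def test_arity_one_tuples_equal_feature_p():
    mapping = FeatureMapping((("G1", "a1", None), ("G2", None, "b5"), ("G3", "a3", "b3")))
    a, b, _, meta, _ = simulate_paired_differential(15, 20, 5, 0.5, seed=3)
    res = omics_npc([a, b], meta, mapping, Design("group"), B=100, seed=4)
    for m in ("fisher", "liptak", "tippett"):
        pg = res.combined[m]["p_global"]
        assert pg[0] == res.feature_pvalues["omic_a"]["a1"]
        assert pg[1] == res.feature_pvalues["omic_b"]["b5"]


def test_p_bounds_and_adjustment():
    a, b, mapping, meta, _ = simulate_paired_differential(10, 30, 5, 1.0, seed=6)
    res = omics_npc([a, b], meta, mapping, Design("group"), B=100, seed=7)
    lo = 1.0 / 101.0
    for m in ("fisher", "liptak", "tippett"):
        pg = res.combined[m]["p_global"]
        adj = res.combined[m]["p_adjusted"]
        assert np.all(pg >= lo - 1e-15) and np.all(pg <= 1.0)
        assert np.all(adj >= pg - 1e-15)
    for s in res.feature_pvalues.values():
        assert np.all(s >= lo - 1e-15) and np.all(s <= 1.0)


def test_npc_determinism():
    a, b, mapping, meta, _ = simulate_paired_differential(10, 25, 5, 0.5, seed=1)
    r1 = omics_npc([a, b], meta, mapping, Design("group"), B=100, seed=11)
    r2 = omics_npc([a, b], meta, mapping, Design("group"), B=100, seed=11)
    pd.testing.assert_frame_equal(r1.to_frame(), r2.to_frame())


def test_tippett_bracket_sanity():
    # tippett global p answers "is the best of the two partial p-values this
    # small by chance"; by a union bound it sits between the minimum partial
    # p and twice that minimum (up to permutation granularity)
    a, b, mapping, meta, _ = simulate_paired_differential(15, 40, 10, 0.8, seed=2)
    res = omics_npc([a, b], meta, mapping, Design("group"), B=200, seed=3)
    tip = res.combined["tippett"]["p_global"]
    slack = 2.0 / 201.0
    single_min = np.fmin(res.p_a, res.p_b)
    both = ~np.isnan(res.p_a) & ~np.isnan(res.p_b)
    assert np.all(tip[both] >= single_min[both] - slack)
    assert np.all(tip[both] <= 2.0 * single_min[both] + slack)


def test_unknown_features_dropped():
    mapping = FeatureMapping((("G1", "a1", "b1"), ("GX", "zz", "b2"), ("GY", "zz", "qq")))
    a, b, _, meta, _ = simulate_paired_differential(10, 5, 0, 0.0, seed=5)
    with pytest.warns(UserWarning, match="dropped"):
        res = omics_npc([a, b], meta, mapping, Design("group"), B=50, seed=2)
    assert ("GX", None, "b2") in list(zip(res.genes, res.features_a, res.features_b))
    assert len(res.genes) == 2


def test_all_unknown_features_error():
    mapping = FeatureMapping((("GX", "zz", "qq"),))
    a, b, _, meta, _ = simulate_paired_differential(10, 5, 0, 0.0, seed=5)
    with pytest.raises(DataValidationError):
        with pytest.warns(UserWarning):
            omics_npc([a, b], meta, mapping, Design("group"), B=50, seed=2)


# ---------------------------------------------------------------------------
# parametric combination
# ---------------------------------------------------------------------------


def test_parametric_fisher_closed_form():
    p = parametric_combination([(0.5, 0.5)], "fisher")[0]
    t = -2 * (np.log(0.5) + np.log(0.5))
    assert t == pytest.approx(2.7726, abs=1e-4)
    # chi-square(4) survival has elementary form exp(-t/2) * (1 + t/2)
    assert p == pytest.approx(np.exp(-t / 2) * (1 + t / 2), abs=1e-12)
    assert p == pytest.approx(0.5966, abs=1e-3)


def test_parametric_fisher_matches_chi2_everywhere():
    rng = np.random.default_rng(4)
    ps = rng.uniform(0.001, 1.0, (50, 2))
    got = parametric_combination(list(map(tuple, ps)), "fisher")
    t = -2 * np.log(ps).sum(axis=1)
    expected = np.exp(-t / 2) * (1 + t / 2)
    np.testing.assert_allclose(got, expected, atol=1e-12)


def test_parametric_tippett_no_evidence():
    assert parametric_combination([(1.0, 1.0)], "tippett")[0] == pytest.approx(1.0)


def test_parametric_liptak_null_median():
    # p = (0.5, 0.5) -> T = 0 -> upper tail of N(0, 2) at 0 is 0.5
    assert parametric_combination([(0.5, 0.5)], "liptak")[0] == pytest.approx(0.5, abs=1e-12)


def test_parametric_arity_one_identity():
    for m in ("fisher", "liptak", "tippett"):
        assert parametric_combination([(0.2,)], m)[0] == pytest.approx(0.2, abs=1e-10)


# ---------------------------------------------------------------------------
# novel-feature accounting
# ---------------------------------------------------------------------------


def _toy_result(adj_fisher):
    n = len(adj_fisher)
    return NPCResult(
        genes=[f"G{i+1}" for i in range(n)],
        features_a=[f"a{i+1}" for i in range(n)],
        features_b=[f"b{i+1}" for i in range(n)],
        p_a=np.full(n, 0.5),
        p_b=np.full(n, 0.5),
        combined={"fisher": {"statistic": np.zeros(n),
                             "p_global": np.asarray(adj_fisher),
                             "p_adjusted": np.asarray(adj_fisher)}},
        feature_pvalues={},
        block_names=("omic_a", "omic_b"),
        B=100, seed=0, mode="overlap", adjust_method="bh",
    )


def test_novel_counts_fixture():
    res = _toy_result([0.01, 0.5])
    counts = count_novel_features(res, {"omic_a": {"a2": 0.01, "a1": 0.9},
                                        "omic_b": {"b1": 0.9, "b2": 0.9}}, alpha=0.05)
    assert counts["omic_a"].novel == 1 and "a1" in counts["omic_a"].novel_features
    assert counts["omic_b"].novel == 1 and "b1" in counts["omic_b"].novel_features
    assert counts["omic_a"].significant_single == 1
    assert counts["omic_a"].significant_pairs == 1


def test_novel_zero_when_no_significant_tuples():
    res = _toy_result([0.5, 0.9])
    counts = count_novel_features(res, {"omic_a": {}, "omic_b": {}}, alpha=0.05)
    assert all(c.novel == 0 for c in counts.values())


def test_novel_zero_when_single_covers():
    res = _toy_result([0.01])
    counts = count_novel_features(res, {"omic_a": {"a1": 0.001}, "omic_b": {"b1": 0.001}},
                                  alpha=0.05)
    assert all(c.novel == 0 for c in counts.values())
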