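"""Matrix processing and moderated differential testing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import septimark as sm


def _matrix(arr, state="raw", prefix="s"):
    arr = np.asarray(arr, dtype=float)
    return sm.AbundanceMatrix(
        pd.DataFrame(arr, index=[f"f{i}" for i in range(arr.shape[0])],
                     columns=[f"{prefix}{j}" for j in range(arr.shape[1])]),
        state=state)


# -- missingness filter ------------------------------------------------------

def test_missingness_filter_is_inclusive_at_the_boundary():
    arr = np.full((3, 8), 10.0)
    arr[0, 2:] = np.nan   # 2/8 = 25% observed -> kept
    arr[1, 1:] = np.nan   # 1/8 observed -> dropped
    m = sm.missingness_filter(_matrix(arr), 0.25)
    assert m.features == ["f0", "f2"]


def test_missingness_filter_identity_on_complete_matrix():
    m = _matrix(np.arange(12.0).reshape(3, 4) + 1)
    assert sm.missingness_filter(m).values.equals(m.values)
    with pytest.raises(sm.ConfigError):
        sm.missingness_filter(m, 0.0)


# -- quantile normalization --------------------------------------------------

def test_quantile_normalize_hand_example():
    m = _matrix([[1.0, 2.0], [3.0, 8.0]])
    out = sm.quantile_normalize(m)
    expected = np.array([[1.5, 1.5], [5.5, 5.5]])
    assert np.allclose(out.values.to_numpy(), expected)
    assert out.state == "normalized"


def test_quantile_normalize_identical_columns_unchanged():
    col = np.array([2.0, 7.0, 4.0])
    m = _matrix(np.column_stack([col, col, col]))
    out = sm.quantile_normalize(m)
    assert np.allclose(out.values.to_numpy(), np.column_stack([col, col, col]))


def test_quantile_normalize_equalizes_and_is_idempotent():
    rng = np.random.default_rng(0)
    m = _matrix(rng.lognormal(3, 1, size=(50, 6)))
    once = sm.quantile_normalize(m)
    cols = np.sort(once.values.to_numpy(), axis=0)
    for j in range(1, 6):
        assert np.allclose(cols[:, 0], cols[:, j], atol=1e-12)
    twice = sm.quantile_normalize(once.with_values(once.values, "raw"))
    assert np.allclose(once.values.to_numpy(), twice.values.to_numpy(), atol=1e-12)


def test_quantile_normalize_with_missing_values_keeps_mask():
    arr = np.array([[1.0, 2.0, 2.5], [3.0, np.nan, 6.0], [9.0, 8.0, 7.0]])
    out = sm.quantile_normalize(_matrix(arr))
    assert np.isnan(out.values.iloc[1, 1])
    assert out.values.notna().sum().sum() == 8
    # rank order within each sample is preserved
    orig_order = np.argsort(arr[:, 0])
    new_order = np.argsort(out.values.to_numpy()[:, 0])
    assert (orig_order == new_order).all()


def test_quantile_normalize_all_missing_sample_is_an_error():
    arr = np.array([[1.0, np.nan], [2.0, np.nan]])
    with pytest.raises(sm.ValidationError, match="s1"):
        sm.quantile_normalize(_matrix(arr))


# -- log2 + imputation -------------------------------------------------------

def test_log2_min_impute_uses_global_minimum():
    arr = np.array([[4.0, 8.0], [np.nan, 16.0]])
    out = sm.log2_min_impute(sm.AbundanceMatrix(
        _matrix(arr).values, state="normalized"))
    assert out.state == "imputed"
    # global min of log2 values is 2; the missing cell gets it, not the
    # per-feature minimum (which would be 4)
    assert out.values.iloc[1, 0] == 2.0
    assert out.values.iloc[0, 1] == 3.0


def test_log2_min_impute_pure_transform_without_missing():
    arr = np.array([[4.0, 8.0], [2.0, 16.0]])
    out = sm.log2_min_impute(sm.AbundanceMatrix(_matrix(arr).values, "normalized"))
    assert np.allclose(out.values.to_numpy(), np.log2(arr))


def test_log2_min_impute_rejects_nonpositive_values():
    arr = np.array([[4.0, -1.0]])
    with pytest.raises(sm.ValidationError, match="non-positive"):
        sm.log2_min_impute(sm.AbundanceMatrix(_matrix(arr).values, "normalized"))


def test_pipeline_state_ordering_is_enforced():
    raw = _matrix(np.full((12, 4), 8.0))
    with pytest.raises(sm.ValidationError):
        sm.moderated_de(raw, ["s0", "s1"], ["s2", "s3"])
    with pytest.raises(sm.ValidationError):
        sm.log2_min_impute(raw)  # must be normalized first
    with pytest.raises(sm.ValidationError):
        sm.quantile_normalize(sm.AbundanceMatrix(raw.values, "normalized"))


# -- fold-change screen ------------------------------------------------------

def test_fold_change_screen_arithmetic_and_threshold():
    arr = np.array([
        [11.1, 11.1, 10.0, 10.0],   # log2 diff 1.1 -> fold 2.14, called up
        [10.0, 10.0, 10.0, 10.0],   # no difference
        [10.0, 10.0, 11.5, 11.5],   # fold 1/2.83, called down
    ])
    proc = _matrix(arr, "imputed")
    de = sm.fold_change_screen(proc, ["s0", "s1"], ["s2", "s3"], 2.0)
    assert de.loc[0, "fold_change"] == pytest.approx(2.0 ** 1.1, rel=1e-12)
    assert bool(de.loc[0, "called"]) and de.loc[0, "direction"] == "up"
    assert de.loc[1, "fold_change"] == 1.0 and not bool(de.loc[1, "called"])
    assert bool(de.loc[2, "called"]) and de.loc[2, "direction"] == "down"


def test_fold_change_screen_recovers_planted_mirna():
    """log2 fold 1.5 at noise 0.3, n = 24 vs 10, |fc|>2 screen: near-certain recovery."""
    hits = 0
    n_seeds = 30
    for seed in range(n_seeds):
        cfg = sm.CohortConfig(n_control=10, n_ns=24, n_s=2, days=(0,), n_genes=2,
                              n_mirna=60, n_protein=2, noise_sigma=0.3,
                              planted_mirna=(("syn-miR-0001", 1.5, "NSvsC"),),
                              seed=seed)
        cohort = sm.generate_cohort(cfg)
        proc = sm.process(cohort.mirna)
        ns = [s for s in proc.samples if s.startswith("NS")]
        c = [s for s in proc.samples if s.startswith("C")]
        de = sm.fold_change_screen(proc, ns, c, 2.0)
        hits += bool(de.set_index("feature").loc["syn-miR-0001", "called"])
    assert hits >= 0.95 * n_seeds


def test_fold_change_screen_rejects_tiny_groups(toy_matrix):
    with pytest.raises(sm.SeptimarkError):
        sm.fold_change_screen(toy_matrix, ["a0"], ["b0", "b1"])


# -- empirical-Bayes prior ---------------------------------------------------

def test_prior_recovery_from_simulated_variances():
    rng = np.random.default_rng(11)
    d0, s0_sq, df, n = 4.0, 1.0, 8, 5000
    s2 = s0_sq * (rng.chisquare(df, n) / df) / (rng.chisquare(d0, n) / d0)
    prior = sm.estimate_eb_prior(s2, df)
    assert abs(prior.d0 - d0) < 1.0
    assert abs(prior.s0_sq - s0_sq) < 0.1


def test_prior_degenerate_equal_variances():
    prior = sm.estimate_eb_prior(np.full(25, 0.5), 8)
    assert np.isinf(prior.d0)
    assert prior.s0_sq == 0.5


def test_prior_underdispersed_ensemble_gives_infinite_df():
    rng = np.random.default_rng(2)
    # spread far below what df = 8 sampling alone would produce
    v = 1.0 + 0.001 * rng.standard_normal(500)
    assert np.isinf(sm.estimate_eb_prior(v, 8).d0)


# -- moderated test ----------------------------------------------------------

def test_identical_groups_give_zero_statistic_and_p_one():
    arr = np.tile(np.arange(5, 11, dtype=float)[:, None], (1, 6))
    m = _matrix(arr, "imputed")
    de = sm.moderated_de(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
    assert (de["t_mod"] == 0).all()
    assert (de["p"] == 1).all()
    assert not de["called"].any()


def test_zero_prior_df_reduces_to_classical_pooled_t():
    rng = np.random.default_rng(21)
    for _ in range(20):
        X = rng.normal(0, rng.uniform(0.5, 2), size=(30, 10))
        m = _matrix(X, "imputed")
        ga, gb = [f"s{j}" for j in range(5)], [f"s{j}" for j in range(5, 10)]
        de = sm.moderated_de(m, ga, gb, prior=sm.EbPrior(0.0, 1.0))
        t, p = stats.ttest_ind(X[:, :5], X[:, 5:], axis=1, equal_var=True)
        assert np.allclose(de["t_mod"], t, rtol=1e-10, atol=1e-12)
        assert np.allclose(de["p"], p, rtol=1e-10, atol=1e-12)


def test_shrinkage_bounded_between_sample_and_prior_variance():
    rng = np.random.default_rng(5)
    X = rng.normal(10, rng.uniform(0.2, 3.0, size=(40, 1)), size=(40, 8))
    m = _matrix(X, "imputed")
    ga, gb = [f"s{j}" for j in range(4)], [f"s{j}" for j in range(4, 8)]
    d = 6
    A, B = X[:, :4], X[:, 4:]
    s2 = (((A - A.mean(1, keepdims=True)) ** 2).sum(1)
          + ((B - B.mean(1, keepdims=True)) ** 2).sum(1)) / d
    prior = sm.estimate_eb_prior(s2, d)
    de = sm.moderated_de(m, ga, gb, prior=prior)
    se = np.sqrt(1 / 4 + 1 / 4)
    s2_post = (de["log2fc"] / de["t_mod"]) ** 2 / se ** 2
    lo = np.minimum(s2, prior.s0_sq) - 1e-12
    hi = np.maximum(s2, prior.s0_sq) + 1e-12
    ok = de["t_mod"] != 0
    assert ((s2_post[ok] >= lo[ok]) & (s2_post[ok] <= hi[ok])).all()


def test_increasing_fc_threshold_never_enlarges_called_set(toy_matrix):
    ga, gb = ["a0", "a1", "a2"], ["b0", "b1", "b2"]
    called = None
    for fc in (1.1, 1.3, 1.8, 2.5):
        de = sm.moderated_de(toy_matrix, ga, gb, fc_threshold=fc, p_threshold=0.9)
        now = set(de.loc[de["called"], "feature"])
        if called is not None:
            assert now <= called
        called = now


def test_moderated_de_rejects_insufficient_samples(toy_matrix):
    with pytest.raises(sm.SeptimarkError):
        sm.moderated_de(toy_matrix, ["a0"], ["b0", "b1"])


# -- PCA ---------------------------------------------------------------------

def test_pca_separates_planted_groups_on_pc1():
    rng = np.random.default_rng(8)
    n_feat, n_per = 30, 10
    X = rng.normal(0, 1, size=(n_feat, 2 * n_per))
    X[:20, n_per:] += 3.0  # planted separation d = 3 on 20 features
    scores, frac = sm.pca_scores(_matrix(X, "imputed"), 2)
    pc1 = scores["PC1"].to_numpy()
    assert abs(pc1[:n_per].mean() - pc1[n_per:].mean()) > 3 * pc1[:n_per].std()
    assert frac[0] >= 0.3


def test_pca_invariant_to_per_feature_constant_shift(toy_matrix):
    scores, _ = sm.pca_scores(toy_matrix, 2)
    shifted = sm.AbundanceMatrix(toy_matrix.values + 100.0, "imputed")
    scores2, _ = sm.pca_scores(shifted, 2)
    assert np.allclose(np.abs(scores.to_numpy()), np.abs(scores2.to_numpy()), atol=1e-8)


def test_pca_variance_fractions_sum_to_one():
    rng = np.random.default_rng(13)
    m = _matrix(rng.normal(size=(20, 7)), "imputed")
    _, frac = sm.pca_scores(m, 6)
    assert frac.sum() == pytest.approx(1.0, abs=1e-10)
    assert (np.diff(frac) <= 1e-12).all()
    with pytest.raises(sm.ConfigError):
        sm.pca_scores(m, 0)
    with pytest.raises(sm.ConfigError):
        sm.pca_scores(m, 7)


# -- common features ---------------------------------------------------------

def test_common_features_exact_intersection_and_regions():
    sets = {"D1": {"a", "b", "c"}, "D3": {"b", "c"}, "D5": {"c"}}
    out = sm.common_features(sets)
    assert out.intersection == {"c"}
    assert out.regions == {"D1": 1, "D1&D3": 1, "D1&D3&D5": 1}
    same = sm.common_features({"x": {"a", "b"}, "y": {"a", "b"}})
    assert same.intersection == {"a", "b"}


@given(st.lists(st.sets(st.integers(0, 15)), min_size=2, max_size=4))
def test_common_features_matches_brute_force(sets):
    named = {f"k{i}": {str(v) for v in s} for i, s in enumerate(sets)}
    out = sm.common_features(named)
    universe = set().union(*named.values())
    brute = {f for f in universe if all(f in s for s in named.values())}
    assert set(out.intersection) == brute
    assert sum(out.regions.values()) == len(universe)
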