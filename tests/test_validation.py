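"""Two-group tests, ROC curves, AUC identities, and panel evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import septimark as sm


def pair_count_auc(scores, labels):
    """Oracle: concordant pairs plus half the ties over all pos-neg pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# -- group tests -------------------------------------------------------------

def test_identical_groups_are_not_significant():
    g = [1.0, 2.0, 3.0, 4.0]
    for method in ("t", "rank"):
        res = sm.group_test(g, g, method)
        assert res.pvalue >= 0.99


def test_t_statistic_matches_textbook_pooled_computation():
    a, b = [1.0, 2.0, 3.0], [11.0, 12.0, 13.0]
    res = sm.group_test(a, b, "t")
    # pooled variance = 1, se = sqrt(1 * (1/3 + 1/3)), diff = -10
    expected = -10.0 / np.sqrt(2.0 / 3.0)
    assert res.statistic == pytest.approx(expected, rel=1e-12)
    assert res.method == "t"


def test_rank_test_uses_normal_approximation_with_ties():
    a, b = [1.0, 1.0, 2.0, 5.0], [1.0, 3.0, 4.0, 6.0]
    res = sm.group_test(a, b, "rank")
    ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    assert res.statistic == pytest.approx(ref.statistic)
    assert res.pvalue == pytest.approx(ref.pvalue)


def test_auto_selection_falls_back_to_rank_for_skewed_data():
    rng = np.random.default_rng(0)
    skew = np.exp(rng.normal(0, 1.5, 40))
    normal = rng.normal(5, 1, 40)
    assert sm.group_test(skew, skew + 1, "auto").method == "rank"
    assert sm.group_test(normal, normal + 1, "auto").method == "t"


def test_group_test_type_one_error_calibrated_at_study_sizes():
    """Null rejection rate at n = 29 vs 16 stays near 5% (3 binomial SEs)."""
    rng = np.random.default_rng(99)
    n_sim, rejections = 400, 0
    for _ in range(n_sim):
        a, b = rng.normal(0, 1, 29), rng.normal(0, 1, 16)
        rejections += sm.group_test(a, b, "t").pvalue < 0.05
    rate = rejections / n_sim
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_sim)


def test_group_test_input_validation():
    with pytest.raises(sm.SeptimarkError):
        sm.group_test([1.0], [1.0, 2.0])
    with pytest.raises(sm.SeptimarkError):
        sm.group_test([1.0, 2.0], [1.0, 2.0], "wilcoxon")


# -- ROC / AUC ---------------------------------------------------------------

def test_roc_passes_upper_left_corner_for_perfect_separation():
    pts = sm.roc_curve([4.0, 3.0, 2.0, 1.0], [True, True, False, False])
    assert any(np.allclose(p, [0.0, 1.0]) for p in pts)
    assert np.allclose(pts[0], [0, 0]) and np.allclose(pts[-1], [1, 1])
    assert sm.auc([4.0, 3.0, 2.0, 1.0], [True, True, False, False]) == 1.0


def test_roc_all_tied_scores_is_the_diagonal():
    pts = sm.roc_curve([5.0] * 6, [True, False] * 3)
    assert pts.shape == (2, 2)
    assert np.allclose(pts, [[0, 0], [1, 1]])
    assert sm.auc([5.0] * 6, [True, False] * 3) == 0.5


def test_auc_small_example_three_of_four_pairs():
    # positives {1, 3}, negatives {2, 0}: 3 of 4 pairs concordant
    assert sm.auc([1.0, 3.0, 2.0, 0.0], [True, True, False, False]) == 0.75


def test_roc_rejects_single_class():
    with pytest.raises(sm.SeptimarkError):
        sm.roc_curve([1.0, 2.0], [True, True])


@given(st.data())
def test_roc_points_match_brute_force_threshold_sweep(data):
    n = data.draw(st.integers(4, 25))
    scores = np.array(data.draw(st.lists(
        st.integers(0, 8), min_size=n, max_size=n)), dtype=float)
    labels = np.array(data.draw(st.lists(st.booleans(), min_size=n, max_size=n)))
    if labels.all() or not labels.any():
        return
    pts = sm.roc_curve(scores, labels)
    n_pos, n_neg = labels.sum(), (~labels).sum()
    brute = {(0.0, 0.0)}
    for thr in np.unique(scores):
        tpr = (scores[labels] >= thr).sum() / n_pos
        fpr = (scores[~labels] >= thr).sum() / n_neg
        brute.add((fpr, tpr))
    assert {(round(f, 12), round(t, 12)) for f, t in pts} == \
        {(round(f, 12), round(t, 12)) for f, t in brute}
    # coordinate-wise non-decreasing
    assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()


@given(st.data())
def test_auc_equals_pair_counting_and_mann_whitney_u(data):
    n = data.draw(st.integers(4, 30))
    scores = np.array(data.draw(st.lists(
        st.floats(-5, 5, allow_nan=False), min_size=n, max_size=n)))
    labels = np.array(data.draw(st.lists(st.booleans(), min_size=n, max_size=n)))
    if labels.all() or not labels.any():
        return
    a = sm.auc(scores, labels)
    assert a == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)
    u = stats.mannwhitneyu(scores[labels], scores[~labels],
                           alternative="two-sided").statistic
    assert a * labels.sum() * (~labels).sum() == pytest.approx(u, abs=1e-9)


@given(st.data())
def test_auc_label_flip_and_monotone_transform_invariance(data):
    n = data.draw(st.integers(4, 20))
    # quantized scores so exp() preserves the tie structure in float precision
    scores = np.round(np.array(data.draw(st.lists(
        st.floats(-3, 3, allow_nan=False), min_size=n, max_size=n))), 3)
    labels = np.array(data.draw(st.lists(st.booleans(), min_size=n, max_size=n)))
    if labels.all() or not labels.any():
        return
    a = sm.auc(scores, labels)
    assert sm.auc(scores, ~labels) == pytest.approx(1 - a, abs=1e-12)
    assert sm.auc(np.exp(scores), labels) == pytest.approx(a, abs=1e-12)
    assert np.allclose(sm.roc_curve(np.exp(scores), labels),
                       sm.roc_curve(scores, labels))


# -- panel evaluation --------------------------------------------------------

def _panel_setup(seed=0, d1=1.0, d3=0.0, n_ns=29, n_s=16):
    rng = np.random.default_rng(seed)
    ids_ns = [f"NS{i:02d}" for i in range(n_ns)]
    ids_s = [f"S{i:02d}" for i in range(n_s)]
    rows = []
    mats = {}
    for day, d in ((1, d1), (3, d3)):
        cols = {f"{p}_D{day}": rng.normal(15 + (d if p in ids_s else 0), 1, 2)
                for p in ids_ns + ids_s}
        mats[day] = sm.AbundanceMatrix(
            pd.DataFrame(cols, index=["m1", "m2"]), state="imputed")
        rows += [{"sample_id": f"{p}_D{day}",
                  "group": "S" if p in ids_s else "NS", "day": day}
                 for p in ids_ns + ids_s]
    samples = pd.DataFrame(rows)
    return mats, samples


def test_evaluate_panel_shape_and_flags():
    mats, samples = _panel_setup(seed=1, d1=2.0, d3=0.0)
    report = sm.evaluate_panel(["m1", "m2"], mats, samples)
    assert len(report.table) == 4  # 2 features x 2 days
    assert set(report.day1_exceeds_day3) == {"m1", "m2"}
    day1 = report.table[report.table["day"] == 1].set_index("feature")
    assert (day1["n_s"] == 16).all() and (day1["n_ns"] == 29).all()


def test_planted_day1_marker_discriminates_day1_better_than_day3():
    wins = 0
    for seed in range(40):
        mats, samples = _panel_setup(seed=seed, d1=1.0, d3=0.0)
        report = sm.evaluate_panel(["m1"], mats, samples)
        wins += report.day1_exceeds_day3["m1"]
    assert wins >= 0.9 * 40


def test_null_feature_has_chance_auc():
    aucs = []
    for seed in range(30):
        mats, samples = _panel_setup(seed=seed, d1=0.0, d3=0.0)
        report = sm.evaluate_panel(["m1"], mats, samples)
        aucs.append(report.table.loc[report.table["day"] == 1, "auc"].iloc[0])
    assert abs(np.mean(aucs) - 0.5) < 0.08


def test_evaluate_panel_missing_feature_lists_absentees():
    mats, samples = _panel_setup()
    with pytest.raises(sm.SeptimarkError, match="nope"):
        sm.evaluate_panel(["m1", "nope"], mats, samples)
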