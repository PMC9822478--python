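"""Mondrian ICP core: p-value counting, aggregation, prediction sets,
the external-score path, and the ensemble model/results objects."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toxcp.conformal import (
    CalibrationTable,
    MondrianConformalClassifier,
    Outcome,
    PValueMatrix,
    build_calibration_table,
    calibrate_external_scores,
    fit_predict_ensemble,
    median_aggregate,
    nonconformity,
    p_value,
    predict_set,
    predict_sets,
)
from toxcp.featurize import FeatureMatrix
from toxcp.splits import make_splits
from toxcp.synthetic import SyntheticConfig, generate_tabular


def brute_force_p(alpha_test, cal):
    """Independent loop-based counting oracle."""
    count = sum(1 for a in cal if a >= alpha_test)
    return (count + 1) / (len(cal) + 1)


# ---------------------------------------------------------------------------
# nonconformity


def test_nonconformity_definition():
    assert nonconformity(0.9) == pytest.approx(0.1)
    assert nonconformity(0.5) == 0.5
    assert nonconformity(1.0) == 0.0


def test_nonconformity_rejects_out_of_range():
    with pytest.raises(ValueError):
        nonconformity(1.2)
    with pytest.raises(ValueError):
        nonconformity(-0.1)


# ---------------------------------------------------------------------------
# calibration table


def test_build_table_by_construction():
    scores = np.array([[0.1, 0.9], [0.4, 0.6], [0.8, 0.2]])
    labels = [1, 1, 0]
    table = build_calibration_table(scores, labels)
    assert sorted(table.alphas[1]) == pytest.approx([0.1, 0.4])
    assert sorted(table.alphas[0]) == pytest.approx([0.2])
    assert table.n(1) == 2 and table.n(0) == 1


def test_single_class_calibration_is_error():
    scores = np.array([[0.2, 0.8], [0.3, 0.7]])
    with pytest.raises(ValueError, match="class-0"):
        build_calibration_table(scores, [1, 1])


def test_table_conserves_count():
    rng = np.random.default_rng(0)
    scores = rng.random((100, 1))
    scores = np.column_stack([scores, 1 - scores])
    labels = rng.integers(0, 2, 100)
    table = build_calibration_table(scores, labels)
    assert table.n(0) + table.n(1) == 100


# ---------------------------------------------------------------------------
# p-values


@pytest.mark.parametrize(
    "alpha_test,expected",
    [(0.5, 1 / 5), (0.0, 5 / 5), (0.25, 3 / 5)],
)
def test_p_value_counting_examples(alpha_test, expected):
    table = CalibrationTable(alphas={0: np.array([0.1, 0.2, 0.3, 0.4]),
                                     1: np.array([0.5])})
    assert p_value(alpha_test, 0, table) == pytest.approx(expected)


def test_p_value_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(123)
    for _ in range(200):
        n = rng.integers(1, 60)
        cal = np.round(rng.random(n), 2)  # rounding forces ties
        table = CalibrationTable(alphas={0: cal, 1: np.array([0.5])})
        at = float(np.round(rng.random(), 2))
        assert p_value(at, 0, table) == brute_force_p(at, cal)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    cal=st.lists(st.floats(0, 1, width=32), min_size=1, max_size=50),
    a1=st.floats(0, 1, width=32),
    a2=st.floats(0, 1, width=32),
)
def test_p_value_monotone_and_bounded(cal, a1, a2):
    """p in (0, 1], p >= 1/(n+1), and increasing nonconformity never
    increases p."""
    table = CalibrationTable(alphas={0: np.array(cal), 1: np.array([0.5])})
    lo, hi = sorted([a1, a2])
    p_lo, p_hi = p_value(lo, 0, table), p_value(hi, 0, table)
    n = len(cal)
    for p in (p_lo, p_hi):
        assert 1 / (n + 1) <= p <= 1.0
    assert p_hi <= p_lo


def test_smoothed_p_value_seeded_and_bracketed():
    cal = np.array([0.2, 0.5, 0.5, 0.5, 0.9])
    table = CalibrationTable(alphas={0: cal, 1: np.array([0.5])})
    a, n = 0.5, len(cal)
    p1 = p_value(a, 0, table, smoothing=True, tie_seed=7)
    p2 = p_value(a, 0, table, smoothing=True, tie_seed=7)
    assert p1 == p2  # deterministic under seed
    n_gt, n_ge = 1, 4
    assert n_gt / (n + 1) < p1 <= (n_ge + 1) / (n + 1)


# ---------------------------------------------------------------------------
# aggregation


def test_median_odd_and_even_k():
    assert median_aggregate([[0.1], [0.9], [0.2]]) == pytest.approx([0.2])
    assert median_aggregate([[0.1], [0.3]]) == pytest.approx([0.2])


def test_median_matrix_matches_sort_oracle():
    rng = np.random.default_rng(5)
    members = [
        PValueMatrix(ids=["a", "b", "c"], p=rng.uniform(0.01, 1, (3, 2)))
        for _ in range(10)
    ]
    agg = median_aggregate(members)
    stacked = np.stack([m.p for m in members])
    for i in range(3):
        for c in range(2):
            col = np.sort(stacked[:, i, c])
            assert agg.p[i, c] == pytest.approx((col[4] + col[5]) / 2)


def test_median_ragged_ids_error():
    a = PValueMatrix(ids=["a"], p=[[0.5, 0.5]])
    b = PValueMatrix(ids=["b"], p=[[0.5, 0.5]])
    with pytest.raises(ValueError, match="disagree"):
        median_aggregate([a, b])


# ---------------------------------------------------------------------------
# prediction sets


@pytest.mark.parametrize(
    "p,expected_set,expected_outcome",
    [
        ((0.5, 0.05), {0}, Outcome.SINGLE_0),
        ((0.5, 0.5), {0, 1}, Outcome.BOTH),
        ((0.1, 0.1), set(), Outcome.EMPTY),
        ((0.2, 0.9), {1}, Outcome.SINGLE_1),  # p0 == eps excluded (strict)
    ],
)
def test_predict_set_outcomes(p, expected_set, expected_outcome):
    rec = predict_set(p, 0.2)
    assert rec.set == frozenset(expected_set)
    assert rec.outcome is expected_outcome


def test_predict_set_epsilon_range():
    with pytest.raises(ValueError):
        predict_set((0.5, 0.5), 0.0)


def test_nested_sets_across_epsilon(fitted_small):
    _, agg, _, _, _ = fitted_small
    grid = [0.05, 0.1, 0.2, 0.3, 0.5]
    sets_by_eps = {e: predict_sets(agg, e) for e in grid}
    for lo, hi in zip(grid, grid[1:]):
        for a, b in zip(sets_by_eps[lo], sets_by_eps[hi]):
            assert b.set <= a.set  # larger epsilon => smaller set


# ---------------------------------------------------------------------------
# external-score path


def test_external_score_alpha_mapping():
    pmat = calibrate_external_scores([0.2, 0.8], [0, 1], [0.9], test_ids=["x"])
    # alpha_1 = 1-s, alpha_0 = s; calib: class0 alpha0=0.2, class1 alpha1=0.2
    # test s=0.9: alpha1=0.1 -> p1=(1+1)/2=1.0; alpha0=0.9 -> p0=(0+1)/2=0.5
    assert pmat.p[0, 1] == pytest.approx(1.0)
    assert pmat.p[0, 0] == pytest.approx(0.5)


def test_external_path_equals_internal_machinery_bitwise():
    """Feeding class-1 probabilities through the score path reproduces
    build_calibration_table + p_value on the (1-s, s) matrix exactly."""
    rng = np.random.default_rng(21)
    s_cal, y_cal = rng.random(60), rng.integers(0, 2, 60)
    s_test = rng.random(25)
    pmat = calibrate_external_scores(s_cal, y_cal, s_test)
    table = build_calibration_table(np.column_stack([1 - s_cal, s_cal]), y_cal)
    expect = np.column_stack(
        [
            p_value(nonconformity(1 - s_test), 0, table),
            p_value(nonconformity(s_test), 1, table),
        ]
    )
    assert np.array_equal(pmat.p, expect)


def test_external_scores_single_class_error():
    with pytest.raises(ValueError, match="class-0"):
        calibrate_external_scores([0.9, 0.8], [1, 1], [0.5])


def test_external_scores_out_of_range_error():
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        calibrate_external_scores([0.2, 1.8], [0, 1], [0.5])


# ---------------------------------------------------------------------------
# ensemble model / results


def test_k1_aggregation_is_identity(small_vt_data):
    train, y_train, evalm, _ = small_vt_data
    model = MondrianConformalClassifier(train, y_train, n_members=1, master_seed=3)
    res = model.fit()
    agg, members = res.predict_p(evalm)
    assert len(members) == 1
    assert np.array_equal(agg.p, members[0].p)


def test_refit_same_seed_identical(small_vt_data):
    train, y_train, evalm, _ = small_vt_data
    out = []
    for _ in range(2):
        model = MondrianConformalClassifier(train, y_train, n_members=2, master_seed=17)
        agg, _ = model.fit().predict_p(evalm)
        out.append(agg.p)
    assert np.array_equal(out[0], out[1])


def test_separable_data_yields_single_labels():
    """With a huge class gap and a confidence-saturated scorer, the
    p-values are extreme and at eps=0.2 nearly every evaluation
    compound gets exactly one label.

    The saturation matters: a scorer with continuous output makes the
    true-class p-value uniform, so ~eps of compounds receive empty
    sets however separable the classes are.  A fully grown tree emits
    exact 0/1 probabilities on separable data, so the calibration
    nonconformities tie at zero and the conservative tie-counting
    drives the true-class p-values to 1.
    """
    from sklearn.tree import DecisionTreeClassifier

    fm, labels = generate_tabular(
        SyntheticConfig(n_total=1500, imbalance_ratio=3.0, dimension=8,
                        class_separation=6.0, seed=9)
    )
    train = FeatureMatrix(fm.ids[:1000], fm.names, fm.values[:1000])
    evalm = FeatureMatrix(fm.ids[1000:], fm.names, fm.values[1000:])
    model = MondrianConformalClassifier(
        train, labels[:1000], n_members=3, master_seed=1,
        base_learner=DecisionTreeClassifier(),
    )
    sets = model.fit().prediction_sets(evalm, 0.2)
    y_eval = labels[1000:]
    for c in (0, 1):
        singles = np.mean([r.is_single for r, y in zip(sets, y_eval) if y == c])
        assert singles >= 0.95


def test_fit_predict_ensemble_wrapper(small_vt_data):
    train, y_train, evalm, _ = small_vt_data
    splits = make_splits(train.ids, y_train, K=2, master_seed=6,
                         evaluation_ids=evalm.ids)
    agg, members, sets = fit_predict_ensemble(
        train, y_train, splits, epsilons=(0.1, 0.2),
        eval_features=evalm, eval_ids=evalm.ids,
    )
    assert len(members) == 2
    assert set(sets) == {0.1, 0.2}
    assert len(sets[0.2]) == evalm.n
    assert agg.ids == list(evalm.ids)


def test_pvalue_matrix_validation():
    with pytest.raises(ValueError, match=r"\(0, 1\]"):
        PValueMatrix(ids=["a"], p=[[0.0, 0.5]])
    with pytest.raises(ValueError, match="aligned"):
        PValueMatrix(ids=["a", "b"], p=[[0.5, 0.5]])
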