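"""Validity, efficiency, SE/SP/BA, contingency identities and the
report table."""

import numpy as np
import pandas as pd
import pytest

from toxcp.conformal import PredictionSetRecord
from toxcp.metrics import (
    confusion_metrics,
    efficiency,
    evaluate_sets,
    outcome_contingency,
    report_table,
    validity,
    validity_flag,
)


def mk(id, labels_in_set, eps=0.2):
    return PredictionSetRecord(id=id, set=frozenset(labels_in_set), epsilon=eps)


def test_validity_counts_both_correct_empty_error():
    sets = [mk("a", {1}), mk("b", {0, 1}), mk("c", set()), mk("d", {0})]
    y = {"a": 1, "b": 1, "c": 1, "d": 1}
    # contains 1: a yes, b yes (both always correct), c no (empty always
    # error), d no
    assert validity(sets, y, 1) == pytest.approx(0.5)


def test_validity_all_both_is_one():
    sets = [mk(str(i), {0, 1}) for i in range(6)]
    y = {str(i): i % 2 for i in range(6)}
    assert validity(sets, y, 0) == 1.0
    assert validity(sets, y, 1) == 1.0


def test_efficiency_counts_singles_regardless_of_correctness():
    sets = [mk("a", {0}), mk("b", {1}), mk("c", {0, 1}), mk("d", set())]
    y = {"a": 1, "b": 1, "c": 1, "d": 1}
    assert efficiency(sets, y, 1) == pytest.approx(0.5)


@pytest.mark.parametrize(
    "val,eps,expected",
    [(0.78, 0.2, True), (0.77, 0.2, False), (0.775, 0.2, True)],
)
def test_validity_flag_tolerance_boundary(val, eps, expected):
    """Error rate may exceed the significance level by at most 2.5
    points, inclusive."""
    assert validity_flag(val, eps) is expected


def test_confusion_metrics_example():
    sets = (
        [mk(f"tp{i}", {1}) for i in range(3)]
        + [mk("fn", {0})]
        + [mk(f"tn{i}", {0}) for i in range(4)]
        + [mk("fp", {1})]
        + [mk("ignored_both", {0, 1}), mk("ignored_empty", set())]
    )
    y = {f"tp{i}": 1 for i in range(3)}
    y.update({"fn": 1, "fp": 0, "ignored_both": 0, "ignored_empty": 1})
    y.update({f"tn{i}": 0 for i in range(4)})
    se, sp, ba, cont = confusion_metrics(sets, y)
    assert se == pytest.approx(0.75)
    assert sp == pytest.approx(0.8)
    assert ba == pytest.approx(0.775)
    # both/empty excluded from SE/SP but present in the contingency
    assert cont.loc[0, "both"] == 1 and cont.loc[1, "empty"] == 1


def test_ba_is_mean_of_se_sp():
    # e.g. a well-balanced imbalanced-endpoint model: SE .863, SP .878
    assert (0.863 + 0.878) / 2 == pytest.approx(0.8705)


def test_no_singles_means_undefined_not_zero():
    sets = [mk("a", {0, 1}), mk("b", set())]
    y = {"a": 0, "b": 1}
    se, sp, ba, _ = confusion_metrics(sets, y)
    assert se is None and sp is None and ba is None


def test_contingency_identities():
    """validity = (single_correct + both)/n_c and efficiency =
    singles/n_c, both recomputable from the 2x4 contingency."""
    rng = np.random.default_rng(3)
    sets, y = [], {}
    options = [{0}, {1}, {0, 1}, set()]
    for i in range(200):
        sets.append(mk(f"m{i}", options[rng.integers(4)]))
        y[f"m{i}"] = int(rng.integers(2))
    cont = outcome_contingency(sets, y)
    for c in (0, 1):
        n_c = cont.loc[c].sum()
        single_correct = cont.loc[c, f"single_{c}"]
        single_wrong = cont.loc[c, f"single_{1 - c}"]
        assert validity(sets, y, c) == pytest.approx(
            (single_correct + cont.loc[c, "both"]) / n_c
        )
        assert efficiency(sets, y, c) == pytest.approx(
            (single_correct + single_wrong) / n_c
        )
        assert n_c == sum(1 for s in sets if y[s.id] == c)


def test_id_mismatch_hard_error():
    with pytest.raises(ValueError, match="no true label"):
        validity([mk("a", {0})], {"b": 0}, 0)


def test_report_table_layout_and_blanking():
    sets_good = [mk(f"g{i}", {i % 2}) for i in range(40)]
    y_good = {f"g{i}": i % 2 for i in range(40)}
    good = evaluate_sets(sets_good, y_good, 0.2, dataset="d", method="good")
    sets_bad = [mk(f"b{i}", set()) for i in range(40)]  # all empty: invalid
    bad = evaluate_sets(sets_bad, {f"b{i}": i % 2 for i in range(40)}, 0.2,
                        dataset="d", method="bad")
    df = report_table([good, bad])
    assert list(df.columns) == [
        "dataset", "method", "significance",
        "validity_1", "validity_0", "efficiency_1", "efficiency_0",
        "SE", "SP", "BA",
    ]
    assert df.loc[0, "BA"] == pytest.approx(1.0)
    # invalid row keeps validity but blanks efficiency/SE/SP/BA
    assert df.loc[1, "validity_1"] == 0.0
    assert df.loc[1, ["efficiency_1", "efficiency_0", "SE", "SP", "BA"]].isna().all()


def test_report_table_empty_is_header_only():
    df = report_table([])
    assert len(df) == 0 and list(df.columns)[0] == "dataset"
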