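"""Mondrian inductive conformal classification with median aggregation.

The predictor wraps any probabilistic binary base classifier.  For each
ensemble member, the base learner is fitted on a proper-training part
and its predicted class probabilities on a held-out calibration part
are turned into class-conditional (Mondrian) nonconformity scores
``alpha = 1 - P(class)``.  A test compound's conformal p-value for a
candidate class c is the calibrated rank of its nonconformity among the
class-c calibration scores,

    p_c = (#{alpha_i >= alpha_test} + 1) / (n_c + 1),

optionally smoothed so that ties contribute a seeded uniform fraction.
Because calibration is per class, the coverage guarantee holds for each
class independently — the property that makes conformal prediction
robust to class imbalance without any resampling or reweighting.

An ensemble of K members is combined by taking, per compound and class,
the median of the K p-values (even K: mean of the two central order
statistics).  A label enters the prediction set iff its aggregated
p-value strictly exceeds the significance level epsilon, giving the
four possible outcomes of binary conformal classification: one label,
the other label, both, or empty.

The module follows the statsmodels model/results idiom:
:class:`MondrianConformalClassifier` holds the training data and
configuration; ``fit()`` returns :class:`ConformalResults`, which
carries the fitted members and exposes prediction, evaluation and a
``summary()`` table.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import RandomForestClassifier

from .splits import DEFAULT_FRACTIONS, DatasetSplit, make_splits

CLASSES = (0, 1)


# ---------------------------------------------------------------------------
# Nonconformity and calibration


def nonconformity(class_score):
    """Inverse-probability nonconformity: ``alpha = 1 - score``.

    ``class_score`` is the predicted probability of the candidate class;
    scalar or array.  Scores outside [0, 1] are a hard error.
    """
    score = np.asarray(class_score, dtype=float)
    if np.any((score < 0) | (score > 1) | ~np.isfinite(score)):
        raise ValueError("class scores must lie in [0, 1]")
    alpha = 1.0 - score
    return float(alpha) if np.isscalar(class_score) else alpha


@dataclass(frozen=True)
class CalibrationTable:
    """Per-class multisets of calibration nonconformity scores.

    ``alphas[c]`` holds, sorted ascending, the nonconformity of every
    calibration compound whose true label is ``c``, computed against its
    own class score.  Both classes must be represented.
    """

    alphas: dict[int, np.ndarray]

    def __post_init__(self):
        for c in CLASSES:
            a = np.asarray(self.alphas.get(c, ()), dtype=float)
            if a.size < 1:
                raise ValueError(f"calibration set has no class-{c} members")
            if not np.all(np.isfinite(a)):
                raise ValueError(f"non-finite nonconformity scores for class {c}")
            object.__setattr__(
                self, "alphas", {**self.alphas, c: np.sort(a)}
            )

    def n(self, c: int) -> int:
        return int(self.alphas[c].size)


def build_calibration_table(
    class_scores: np.ndarray, labels: Sequence[int]
) -> CalibrationTable:
    """Build the Mondrian calibration table.

    Parameters
    ----------
    class_scores
        (n, 2) matrix of predicted class probabilities, column ``c``
        being the score for class ``c``.
    labels
        True labels of the calibration compounds.
    """
    scores = np.asarray(class_scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("class_scores must be an (n, 2) matrix")
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels length mismatch")
    alphas = {}
    for c in CLASSES:
        mask = labels == c
        if not mask.any():
            raise ValueError(f"calibration set has no class-{c} members")
        alphas[c] = nonconformity(scores[mask, c])
    return CalibrationTable(alphas=alphas)


def p_value(
    alpha_test,
    c: int,
    table: CalibrationTable,
    smoothing: bool = False,
    tie_seed: Optional[int] = None,
):
    """Mondrian conformal p-value(s) for candidate class ``c``.

    Without smoothing (the default), ties count as ``>=`` and

        p = (#{alpha_i >= alpha_test} + 1) / (n_c + 1),

    which is conservative and deterministic.  With smoothing, each tie
    (and the +1 for the test point itself) contributes a uniform
    fraction drawn from ``tie_seed``, giving exactly-valid p-values.
    Always in (0, 1].
    """
    cal = table.alphas[c]
    n_c = cal.size
    at = np.atleast_1d(np.asarray(alpha_test, dtype=float))
    n_ge = n_c - np.searchsorted(cal, at, side="left")
    if smoothing:
        n_gt = n_c - np.searchsorted(cal, at, side="right")
        ties = n_ge - n_gt
        tau = np.random.default_rng(tie_seed).uniform(size=at.shape)
        p = (n_gt + tau * (ties + 1)) / (n_c + 1)
    else:
        p = (n_ge + 1.0) / (n_c + 1.0)
    return float(p[0]) if np.isscalar(alpha_test) else p


# ---------------------------------------------------------------------------
# P-value containers and aggregation


@dataclass
class PValueMatrix:
    """Per-compound, per-class conformal p-values (columns = classes 0, 1)."""

    ids: list[str]
    p: np.ndarray

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(self.ids), 2):
            raise ValueError("p must be (n, 2) aligned with ids")
        if np.any((self.p <= 0) | (self.p > 1)):
            raise ValueError("conformal p-values must lie in (0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "p0": self.p[:, 0], "p1": self.p[:, 1]})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PValueMatrix":
        df = pd.read_csv(path, dtype={"id": str})
        return cls(ids=list(df["id"]), p=df[["p0", "p1"]].to_numpy())


def median_aggregate(p_members):
    """Median-aggregate p-values across ensemble members.

    Accepts either a list of :class:`PValueMatrix` over identical ids
    (returns an aggregated :class:`PValueMatrix`) or a (K, ...) array of
    p-values for one compound (returns the per-class medians).  Even K
    uses the arithmetic mean of the two central order statistics.
    """
    if isinstance(p_members, (list, tuple)) and p_members and isinstance(
        p_members[0], PValueMatrix
    ):
        ids = p_members[0].ids
        for m in p_members[1:]:
            if m.ids != ids:
                raise ValueError("ensemble members disagree on compound ids")
        stacked = np.stack([m.p for m in p_members])
        return PValueMatrix(ids=list(ids), p=np.median(stacked, axis=0))
    arr = np.asarray(p_members, dtype=float)
    if arr.size == 0:
        raise ValueError("no ensemble members to aggregate")
    return np.median(arr, axis=0)


# ---------------------------------------------------------------------------
# Prediction sets


class Outcome(str, enum.Enum):
    SINGLE_0 = "single_0"
    SINGLE_1 = "single_1"
    BOTH = "both"
    EMPTY = "empty"


_OUTCOME_BY_SET = {
    frozenset(): Outcome.EMPTY,
    frozenset({0}): Outcome.SINGLE_0,
    frozenset({1}): Outcome.SINGLE_1,
    frozenset({0, 1}): Outcome.BOTH,
}


@dataclass(frozen=True)
class PredictionSetRecord:
    """The label set assigned to one compound at significance epsilon."""

    id: str
    set: frozenset
    epsilon: float

    @property
    def outcome(self) -> Outcome:
        return _OUTCOME_BY_SET[self.set]

    @property
    def is_single(self) -> bool:
        return len(self.set) == 1


def predict_set(p: Sequence[float], epsilon: float, id: str = "") -> PredictionSetRecord:
    """Assign the prediction set: class c is included iff ``p_c > epsilon``
    (strict — a p-value exactly at epsilon is excluded)."""
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie in (0, 1)")
    labels = frozenset(c for c in CLASSES if p[c] > epsilon)
    return PredictionSetRecord(id=id, set=labels, epsilon=float(epsilon))


def predict_sets(pmat: PValueMatrix, epsilon: float) -> list[PredictionSetRecord]:
    return [
        predict_set(pmat.p[i], epsilon, id=pmat.ids[i]) for i in range(len(pmat.ids))
    ]


def prediction_sets_to_frame(records: Sequence[PredictionSetRecord]) -> pd.DataFrame:
    """Serialize sets as "0", "1", "01", or ""."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "epsilon": [r.epsilon for r in records],
            "set": ["".join(str(c) for c in sorted(r.set)) for r in records],
            "outcome": [r.outcome.value for r in records],
        }
    )


# ---------------------------------------------------------------------------
# External-score calibration (the score-file path)


def calibrate_external_scores(
    calib_scores,
    calib_labels,
    test_scores,
    test_ids: Optional[Sequence[str]] = None,
    smoothing: bool = False,
    tie_seed: Optional[int] = None,
) -> PValueMatrix:
    """Convert externally produced class-1 scores into conformal p-values.

    For a class-1 score ``s`` in [0, 1] the nonconformity is ``1 - s``
    for class 1 and ``s`` for class 0 — i.e. the scores are treated as
    the (s, 1-s) probability pair and run through the same Mondrian
    machinery as the internal path.  This is how predictions from
    models trained outside the pipeline (e.g. fine-tuned language
    models) are calibrated into prediction sets.
    """
    calib_scores = np.asarray(calib_scores, dtype=float)
    test_scores = np.asarray(test_scores, dtype=float)
    for name, arr in (("calibration", calib_scores), ("test", test_scores)):
        if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
            bad = np.flatnonzero((arr < 0) | (arr > 1) | ~np.isfinite(arr))
            raise ValueError(f"{name} scores outside [0, 1] at rows {bad[:10].tolist()}")
    calib_pair = np.column_stack([1.0 - calib_scores, calib_scores])
    table = build_calibration_table(calib_pair, calib_labels)
    ids = (
        [str(i) for i in test_ids]
        if test_ids is not None
        else [str(i) for i in range(len(test_scores))]
    )
    p = np.column_stack(
        [
            p_value(nonconformity(1.0 - test_scores), 0, table, smoothing, tie_seed),
            p_value(
                nonconformity(test_scores),
                1,
                table,
                smoothing,
                None if tie_seed is None else tie_seed + 1,
            ),
        ]
    )
    return PValueMatrix(ids=ids, p=p)


# ---------------------------------------------------------------------------
# Model / Results


def _default_base_learner() -> BaseEstimator:
    # Default options of the scikit-learn random forest, per the
    # standard QSAR-CP practice.
    return RandomForestClassifier()


@dataclass
class _Member:
    """One fitted ensemble member."""

    index: int
    learner: BaseEstimator
    table: CalibrationTable
    split: DatasetSplit
    seed: int

    def class_scores(self, X: np.ndarray) -> np.ndarray:
        """(n, 2) class-probability matrix in class order (0, 1)."""
        proba = self.learner.predict_proba(X)
        cols = {int(c): j for j, c in enumerate(self.learner.classes_)}
        out = np.zeros((X.shape[0], 2))
        for c in CLASSES:
            if c in cols:
                out[:, c] = proba[:, cols[c]]
        return out


class MondrianConformalClassifier:
    """Mondrian aggregated conformal predictor over a training pool.

    Parameters
    ----------
    features
        (n, D) feature matrix of the training pool (or a
        :class:`~toxcp.featurize.FeatureMatrix`).
    labels
        Binary labels aligned with the features.
    ids
        Compound ids; defaults to row indices.  Required when
        ``features`` is a bare array and splits are supplied externally.
    n_members
        Ensemble size K (default 10).
    fractions
        (proper_train, dl_validation, calibration) split fractions;
        the validation part is folded into proper training for
        non-deep base learners.
    base_learner
        A scikit-learn classifier prototype exposing ``predict_proba``;
        cloned per member.  Default: random forest with default options.
    smoothing
        Smoothed p-values (seeded tie-breaking).  Off by default.
    master_seed
        Single seed from which all member split/learner/tie seeds
        derive.
    """

    def __init__(
        self,
        features,
        labels,
        ids: Optional[Sequence[str]] = None,
        *,
        n_members: int = 10,
        fractions: Sequence[float] = DEFAULT_FRACTIONS,
        base_learner: Optional[BaseEstimator] = None,
        smoothing: bool = False,
        master_seed: int = 0,
    ):
        if hasattr(features, "values") and hasattr(features, "ids"):
            if ids is None:
                ids = features.ids
            features = features.values
        self.X = np.asarray(features, dtype=float)
        self.y = np.asarray(labels, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("features and labels length mismatch")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        self.ids = (
            [str(i) for i in ids] if ids is not None else [str(i) for i in range(len(self.y))]
        )
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("duplicate ids in training pool")
        self.n_members = int(n_members)
        self.fractions = tuple(fractions)
        self.base_learner = base_learner
        self.smoothing = bool(smoothing)
        self.master_seed = int(master_seed)
        self._row_of = {i: r for r, i in enumerate(self.ids)}

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_col: str = "label", id_col: str = "id", **kwargs
    ) -> "MondrianConformalClassifier":
        feat_cols = [c for c in df.columns if c not in (label_col, id_col)]
        return cls(
            df[feat_cols].to_numpy(dtype=float),
            df[label_col].to_numpy(dtype=int),
            ids=df[id_col].astype(str).tolist() if id_col in df.columns else None,
            **kwargs,
        )

    def _rows(self, ids: Sequence[str]) -> np.ndarray:
        try:
            return np.asarray([self._row_of[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise ValueError(f"unknown compound id {exc.args[0]!r}") from None

    def fit(self, splits: Optional[Sequence[DatasetSplit]] = None) -> "ConformalResults":
        """Train and calibrate every ensemble member.

        If ``splits`` is omitted, K stratified partitions of the pool
        are drawn from ``master_seed``.
        """
        if splits is None:
            splits = make_splits(
                self.ids,
                self.y,
                fractions=self.fractions,
                K=self.n_members,
                master_seed=self.master_seed,
            )
        members = []
        for k, sp in enumerate(splits):
            train_ids = list(sp.proper_train_ids) + list(sp.dl_validation_ids)
            tr = self._rows(train_ids)
            ca = self._rows(sp.calibration_ids)
            proto = (
                self.base_learner if self.base_learner is not None else _default_base_learner()
            )
            learner = clone(proto)
            if "random_state" in learner.get_params():
                learner.set_params(random_state=sp.seed)
            try:
                learner.fit(self.X[tr], self.y[tr])
            except Exception as exc:
                raise RuntimeError(f"base learner failed on member {k}: {exc}") from exc
            member = _Member(index=k, learner=learner, table=None, split=sp, seed=sp.seed)
            scores = member.class_scores(self.X[ca])
            member.table = build_calibration_table(scores, self.y[ca])
            members.append(member)
        return ConformalResults(model=self, members=members)


class ConformalResults:
    """Fitted Mondrian aggregated conformal predictor.

    Produced by :meth:`MondrianConformalClassifier.fit`.  Carries the
    fitted members (base learner + calibration table per member) and
    turns new feature matrices into p-values, prediction sets and
    evaluation reports.
    """

    def __init__(self, model: MondrianConformalClassifier, members: list[_Member]):
        self.model = model
        self.members = members

    @property
    def n_members(self) -> int:
        return len(self.members)

    def predict_p(
        self, features, ids: Optional[Sequence[str]] = None
    ) -> tuple[PValueMatrix, list[PValueMatrix]]:
        """Per-class conformal p-values for new compounds.

        Returns the median-aggregated matrix and the per-member
        matrices.
        """
        if hasattr(features, "values") and hasattr(features, "ids"):
            if ids is None:
                ids = features.ids
            features = features.values
        X = np.asarray(features, dtype=float)
        ids = (
            [str(i) for i in ids] if ids is not None else [str(i) for i in range(X.shape[0])]
        )
        per_member = []
        for m in self.members:
            scores = m.class_scores(X)
            p = np.column_stack(
                [
                    p_value(
                        nonconformity(scores[:, c]),
                        c,
                        m.table,
                        smoothing=self.model.smoothing,
                        tie_seed=(m.seed * 2 + c) % (2**31),
                    )
                    for c in CLASSES
                ]
            )
            per_member.append(PValueMatrix(ids=list(ids), p=p))
        return median_aggregate(per_member), per_member

    def prediction_sets(
        self, features, epsilon: float, ids: Optional[Sequence[str]] = None
    ) -> list[PredictionSetRecord]:
        agg, _ = self.predict_p(features, ids)
        return predict_sets(agg, epsilon)

    def evaluate(
        self,
        features,
        labels,
        epsilons: Sequence[float] = (0.2,),
        ids: Optional[Sequence[str]] = None,
        dataset: str = "eval",
        method: str = "rf",
    ):
        """Score the predictor on labelled evaluation data.

        Returns one :class:`~toxcp.metrics.CPMetricsReport` per epsilon.
        """
        from . import metrics

        agg, _ = self.predict_p(features, ids)
        labels = np.asarray(labels, dtype=int)
        reports = []
        for eps in epsilons:
            sets = predict_sets(agg, eps)
            reports.append(
                metrics.evaluate_sets(
                    sets, dict(zip(agg.ids, labels)), eps, dataset=dataset, method=method
                )
            )
        return reports

    def summary(
        self,
        features,
        labels,
        epsilons: Sequence[float] = (0.1, 0.15, 0.2, 0.25, 0.3),
        ids: Optional[Sequence[str]] = None,
        dataset: str = "eval",
        method: str = "rf",
    ) -> str:
        """Text summary of validity/efficiency/SE/SP/BA across epsilons."""
        from . import metrics

        reports = self.evaluate(features, labels, epsilons, ids, dataset, method)
        table = metrics.report_table(reports, blank_invalid=False)
        header = (
            f"Mondrian aggregated conformal predictor "
            f"(K={self.n_members}, smoothing={'on' if self.model.smoothing else 'off'}, "
            f"master_seed={self.model.master_seed})"
        )
        return header + "\n" + table.to_string(index=False, float_format=lambda v: f"{v:.3f}")


def fit_predict_ensemble(
    features,
    labels,
    splits: Sequence[DatasetSplit],
    base_learner: Optional[BaseEstimator] = None,
    epsilons: Sequence[float] = (0.2,),
    eval_features=None,
    eval_ids: Optional[Sequence[str]] = None,
    smoothing: bool = False,
    master_seed: int = 0,
    ids: Optional[Sequence[str]] = None,
):
    """Functional wrapper: fit the ensemble on explicit splits and emit
    evaluation p-values and prediction sets.

    Returns ``(aggregated PValueMatrix, per-member list, {epsilon:
    prediction-set records})``.
    """
    model = MondrianConformalClassifier(
        features,
        labels,
        ids=ids,
        n_members=len(splits),
        base_learner=base_learner,
        smoothing=smoothing,
        master_seed=master_seed,
    )
    res = model.fit(splits=splits)
    agg, per_member = res.predict_p(eval_features, ids=eval_ids)
    sets = {float(e): predict_sets(agg, e) for e in epsilons}
    return agg, per_member, sets
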