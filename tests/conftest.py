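import numpy as np
import pytest

from toxcp.conformal import MondrianConformalClassifier
from toxcp.featurize import FeatureMatrix
from toxcp.synthetic import SyntheticConfig, generate_tabular


@pytest.fixture(scope="session")
def small_vt_data():
    """Small imbalanced exchangeable dataset split into pool/eval."""
    fm, labels = generate_tabular(
        SyntheticConfig(n_total=1800, imbalance_ratio=11.0, dimension=12,
                        class_separation=1.8, seed=42)
    )
    n_train = 1200
    train = FeatureMatrix(fm.ids[:n_train], fm.names, fm.values[:n_train])
    evalm = FeatureMatrix(fm.ids[n_train:], fm.names, fm.values[n_train:])
    return train, labels[:n_train], evalm, labels[n_train:]


@pytest.fixture(scope="session")
def fitted_small(small_vt_data):
    """A fitted 3-member ensemble on the small dataset (shared across
    tests to keep the suite fast)."""
    train, y_train, evalm, y_eval = small_vt_data
    model = MondrianConformalClassifier(
        train, y_train, n_members=3, master_seed=11
    )
    res = model.fit()
    agg, members = res.predict_p(evalm)
    return res, agg, members, evalm, y_eval
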