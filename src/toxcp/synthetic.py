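"""Synthetic data with the statistical structure the pipeline assumes.

Three generators:

* :func:`generate_tabular` — exchangeable (i.i.d.) feature/label draws
  from two Gaussian class-conditionals at controllable imbalance and
  class separation.  Gaussians rather than simulated molecules because
  the conformal machinery is feature-agnostic and Gaussians give
  closed-form control over problem difficulty; molecular realism lives
  in the toy SMILES fixture instead.
* :func:`generate_score_fixture` — Beta-distributed class-1 scores of
  tunable quality, emulating prediction files from externally trained
  models for the score-calibration path.
* :func:`toy_smiles_fixture` — a hand-curated set of SMILES covering
  salts, charged species, stereocentres, tautomer pairs and every
  exclusion reason, for exercising standardization and featurization
  without any download.

The default regimes mirror the two acute-toxicity endpoints the
pipeline targets: a near-balanced one (majority:minority ~1.6:1) and a
heavily imbalanced one (~11:1).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np

from .featurize import FeatureMatrix


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic tabular dataset.

    Parameters
    ----------
    n_total
        Number of compounds drawn.
    imbalance_ratio
        Majority:minority class ratio (class 0 is the majority); 11
        emulates the very-toxic endpoint, 1.6 the non-toxic one.
    dimension
        Feature dimensionality D.
    class_separation
        Distance between the two class mean vectors in units of the
        (identity) within-class standard deviation; 0 means the classes
        are indistinguishable.
    label_noise
        Independent label-flip probability in [0, 0.5).
    seed
        Random seed; same config + seed reproduces the dataset exactly.
    """

    n_total: int = 7000
    imbalance_ratio: float = 11.0
    dimension: int = 32
    class_separation: float = 1.5
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_total < 1 or self.imbalance_ratio < 1 or self.dimension < 1:
            raise ValueError("n_total, imbalance_ratio and dimension must be >= 1")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")

    def manifest(self) -> dict:
        return asdict(self)


def vt_like(n_total: int = 7000, seed: int = 0, **kwargs) -> SyntheticConfig:
    """Heavily imbalanced regime (~11:1), emulating a very-toxic
    endpoint."""
    kwargs.setdefault("imbalance_ratio", 11.0)
    return SyntheticConfig(n_total=n_total, seed=seed, **kwargs)


def nt_like(n_total: int = 7000, seed: int = 0, **kwargs) -> SyntheticConfig:
    """Near-balanced regime (~1.6:1), emulating a non-toxic endpoint."""
    kwargs.setdefault("imbalance_ratio", 1.6)
    return SyntheticConfig(n_total=n_total, seed=seed, **kwargs)


def generate_tabular(config: SyntheticConfig) -> tuple[FeatureMatrix, np.ndarray]:
    """Draw an exchangeable synthetic dataset.

    Features are multivariate normal with identity covariance within
    each class; the class-1 mean sits ``class_separation`` away from
    the class-0 mean along a random unit direction.  Rows are i.i.d.,
    so any later split of them is exchangeable — the precondition of
    the conformal coverage guarantee.

    Returns ``(FeatureMatrix, labels)`` with ids ``m000000`` ...
    A minority class below 10 members is a hard error.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_total
    n_minority = int(round(n / (config.imbalance_ratio + 1)))
    if n_minority < 10:
        raise ValueError(
            f"minority class would have {n_minority} members (< 10); "
            "calibration would be meaningless"
        )
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=n_minority, replace=False)] = 1

    direction = rng.normal(size=config.dimension)
    direction /= np.linalg.norm(direction)
    X = rng.normal(size=(n, config.dimension))
    X[labels == 1] += config.class_separation * direction

    if config.label_noise > 0:
        flips = rng.random(n) < config.label_noise
        labels = np.where(flips, 1 - labels, labels)

    ids = [f"m{i:06d}" for i in range(n)]
    names = [f"x{j:03d}" for j in range(config.dimension)]
    return FeatureMatrix(ids=ids, names=names, values=X).validate(), labels


def generate_score_fixture(
    labels: Sequence[int], quality: float, seed: Optional[int] = None
) -> np.ndarray:
    """Beta-distributed class-1 scores of tunable quality.

    ``quality`` in [0, 1] separates the score distributions of the two
    classes: at 0 both classes draw from the same uniform distribution
    (an uninformative scorer); at 1 scores concentrate near the true
    label (a near-perfect scorer).  Internally, class y draws from a
    Beta with mean ``0.5 + (2y-1) * 0.48 * quality`` and concentration
    ``2 + 100 * quality**2``.
    """
    if not 0 <= quality <= 1:
        raise ValueError("quality must lie in [0, 1]")
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    means = np.clip(0.5 + (2 * labels - 1) * 0.48 * quality, 0.02, 0.98)
    conc = 2.0 + 100.0 * quality**2
    return rng.beta(means * conc, (1.0 - means) * conc)


#: Hand-curated SMILES fixture.  Each entry is
#: (id, smiles, label, expected) where ``expected`` is the chemically
#: expected standardized structure (any valid SMILES spelling; compare
#: after canonicalization), the name of an exclusion reason, or a
#: ``pair:<tag>`` marker meaning "must standardize identically to the
#: other member of the tautomer pair <tag>".
TOY_SMILES: list[tuple[str, str, int, str]] = [
    ("t01", "CCO", 0, "CCO"),
    ("t02", "[Na+].CC(=O)[O-]", 0, "CC(=O)O"),
    ("t03", "C[C@H](N)C(=O)O", 0, "CC(N)C(=O)O"),
    ("t04", "c1ccccc1", 0, "c1ccccc1"),
    ("t05", "CC(=O)Oc1ccccc1C(=O)O", 1, "CC(=O)Oc1ccccc1C(=O)O"),
    ("t06", "Cl.CCN", 0, "CCN"),
    ("t07", "[O-]C(=O)c1ccccc1", 0, "OC(=O)c1ccccc1"),
    ("t08", "CC[NH3+]", 0, "CCN"),
    ("t09", "C[N+](C)(C)C", 1, "C[N+](C)(C)C"),
    ("t10", "CN1C=NC2=C1C(=O)N(C(=O)N2C)C", 0, "CN1C=NC2=C1C(=O)N(C(=O)N2C)C"),
    ("t11", "CC(C)Cc1ccc(cc1)[C@@H](C)C(=O)O", 1, "CC(C)Cc1ccc(C(C)C(=O)O)cc1"),
    ("t12", "C/C=C/C", 0, "CC=CC"),
    ("t13", "[NH3+]CC(=O)[O-]", 0, "NCC(=O)O"),
    ("t14", "Oc1ccccc1", 1, "Oc1ccccc1"),
    ("t15", "c1ccsc1", 0, "c1ccsc1"),
    ("t16", "Fc1ccccc1", 1, "Fc1ccccc1"),
    ("t17", "CC(O)=CC(C)=O", 0, "pair:acac"),
    ("t18", "CC(=O)CC(C)=O", 0, "pair:acac"),
    ("t19", "Oc1ccccn1", 1, "pair:pyridone"),
    ("t20", "O=c1cccc[nH]1", 1, "pair:pyridone"),
    ("t21", "O=[Si]=O", 0, "inorganic"),
    ("t22", "[Na+].[Cl-]", 0, "empty_after_salt_strip"),
    ("t23", "not_a_smiles(((", 1, "parse_failure"),
    ("t24", "C" * 250, 0, "too_long"),
    ("t25", "c1cc[se]c1", 1, "inorganic"),
    ("t26", "OCC(O)C(O)C(O)C(O)CO", 0, "OCC(O)C(O)C(O)C(O)CO"),
]


def toy_smiles_fixture() -> list[tuple[str, str, int, str]]:
    """The curated (id, smiles, label, expected) fixture; see
    :data:`TOY_SMILES`."""
    return list(TOY_SMILES)
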