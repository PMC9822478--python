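"""Physico-chemical descriptor calculation and external feature ingestion.

The internal arm computes a fixed panel of RDKit descriptors per
standardized molecule (default: the 96-name panel shipped in
``data/descriptors.yaml``).  The external arm loads any precomputed
numeric feature table (e.g. autoencoder embeddings) keyed by molecule
id.  Either way the result is a :class:`FeatureMatrix` whose entries
are guaranteed finite and whose row order matches its id order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.ML.Descriptors.MoleculeDescriptors import MolecularDescriptorCalculator

from .standardize import MoleculeRecord

logger = logging.getLogger(__name__)

_KNOWN_DESCRIPTORS = frozenset(name for name, _ in Descriptors._descList)


@dataclass
class FeatureMatrix:
    """An (n x D) descriptor table with aligned ids and column names.

    Invariants (checked in :meth:`validate`): all values finite, row
    count equals id count, column count equals name count.
    """

    ids: list[str]
    names: list[str]
    values: np.ndarray

    def validate(self) -> "FeatureMatrix":
        if self.values.ndim != 2:
            raise ValueError("feature values must be a 2-D matrix")
        if self.values.shape != (len(self.ids), len(self.names)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape}, "
                f"{len(self.ids)} ids x {len(self.names)} names"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            r, c = bad[0]
            raise ValueError(
                f"non-finite feature value at id={self.ids[r]!r}, "
                f"column={self.names[c]!r} ({len(bad)} total)"
            )
        return self

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def dim(self) -> int:
        return len(self.names)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, "id", self.ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_descriptor_names() -> list[str]:
    """The shipped 96-descriptor physico-chemical panel."""
    text = resources.files("toxcp.data").joinpath("descriptors.yaml").read_text()
    names = yaml.safe_load(text)["descriptors"]
    return list(names)


def load_descriptor_config(path: str | Path) -> list[str]:
    """Read a YAML descriptor list (either a bare list or a mapping
    with a ``descriptors`` key)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    names = doc["descriptors"] if isinstance(doc, dict) else doc
    if not isinstance(names, list) or not all(isinstance(n, str) for n in names):
        raise ValueError(f"{path}: expected a YAML list of descriptor names")
    return names


def compute_descriptors(
    records: Sequence[MoleculeRecord],
    descriptor_names: Sequence[str] | None = None,
) -> tuple[FeatureMatrix, list[str]]:
    """Compute the descriptor panel for standardized molecules.

    Unknown descriptor names fail immediately.  Molecules for which any
    descriptor comes back non-finite (or whose standardized SMILES no
    longer parses) are dropped — never imputed, since silently filled
    values would break the exchangeability the downstream calibration
    relies on — and returned as the second element.

    Returns
    -------
    (matrix, failed_ids)
    """
    names = list(descriptor_names) if descriptor_names is not None else default_descriptor_names()
    unknown = [n for n in names if n not in _KNOWN_DESCRIPTORS]
    if unknown:
        raise ValueError(f"unknown descriptor names: {unknown}")
    not_std = [r.id for r in records if r.smiles_std is None]
    if not_std:
        raise ValueError(f"records not standardized: {not_std[:5]}")

    calc = MolecularDescriptorCalculator(names)
    ids: list[str] = []
    rows: list[tuple] = []
    failed: list[str] = []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles_std)
        if mol is None:
            failed.append(rec.id)
            continue
        vals = calc.CalcDescriptors(mol)
        if not all(isinstance(v, (int, float)) and math.isfinite(v) for v in vals):
            failed.append(rec.id)
            continue
        ids.append(rec.id)
        rows.append(vals)
    if failed:
        logger.warning("descriptor calculation dropped %d molecules: %s",
                       len(failed), failed[:10])
    values = np.asarray(rows, dtype=float).reshape(len(ids), len(names))
    return FeatureMatrix(ids=ids, names=names, values=values).validate(), failed


def load_external_features(
    path: str | Path, expected_ids: Sequence[str]
) -> FeatureMatrix:
    """Load a precomputed feature CSV (first column ``id``, remaining
    columns numeric) and reorder its rows to ``expected_ids``.

    Missing ids, NaNs, and non-numeric cells are hard errors naming the
    offending rows/columns.
    """
    df = pd.read_csv(path, dtype={0: str})
    id_col = df.columns[0]
    if id_col != "id":
        raise ValueError(f"{path}: first column must be 'id', found {id_col!r}")
    df["id"] = df["id"].astype(str)
    feat_cols = [c for c in df.columns if c != "id"]
    if not feat_cols:
        raise ValueError(f"{path}: no feature columns")
    for col in feat_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric or missing value at row id="
                f"{df.loc[bad[0], 'id']!r}, column {col!r}"
            )
        df[col] = numeric

    index = pd.Index(df["id"])
    if index.has_duplicates:
        raise ValueError(f"{path}: duplicate ids")
    expected = [str(i) for i in expected_ids]
    missing = [i for i in expected if i not in set(index)]
    if missing:
        raise ValueError(f"{path}: missing ids {missing[:10]}"
                         + (" ..." if len(missing) > 10 else ""))
    ordered = df.set_index("id").loc[expected, feat_cols]
    return FeatureMatrix(
        ids=expected, names=feat_cols, values=ordered.to_numpy(dtype=float)
    ).validate()
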