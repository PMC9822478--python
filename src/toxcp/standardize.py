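"""SMILES structure standardization.

Normalizes raw SMILES the way toxicity-modelling pipelines prepare
structures before descriptor calculation: keep the largest organic
fragment (salt stripping), drop stereochemistry, reject molecules with
elements outside a configurable organic set, neutralize simple
protonation charges, and emit the canonical tautomer's canonical
SMILES.  Every step is deterministic, so standardization is idempotent
on its own output.

A molecule is never lost silently: records that cannot be standardized
carry an explicit exclusion reason (parse failure, inorganic, empty
after salt stripping, or over the SMILES length limit).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: Elements accepted by the organic filter.  Carbon is additionally
#: required to be present (a molecule of pure H/O, say, is not organic).
DEFAULT_ORGANIC_ELEMENTS = frozenset(
    ["H", "B", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I"]
)

# Charged atoms that can be neutralized by (de)protonation: positive
# atoms carrying at least one H that are not counter-balanced by an
# adjacent negative atom, and negative atoms not adjacent to a positive
# one.  Quaternary ammonium and internal zwitterion pairs are left alone.
_NEUTRALIZE_PATTERN = Chem.MolFromSmarts(
    "[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]"
)

_TAUTOMER_ENUMERATOR: Optional[rdMolStandardize.TautomerEnumerator] = None


class ExclusionReason(str, enum.Enum):
    """Why a molecule was dropped during standardization."""

    NONE = "none"
    PARSE_FAILURE = "parse_failure"
    INORGANIC = "inorganic"
    EMPTY_AFTER_SALT_STRIP = "empty_after_salt_strip"
    TOO_LONG = "too_long"


@dataclass(frozen=True)
class StandardizationConfig:
    """Settings for the standardization chain.

    Parameters
    ----------
    organic_elements
        Element symbols the organic filter accepts (carbon must also be
        present in the molecule).
    max_smiles_len
        Maximum length of the *standardized* SMILES string; longer
        molecules are excluded (a stand-in for sequence-length limits of
        downstream SMILES language models).
    """

    organic_elements: frozenset = DEFAULT_ORGANIC_ELEMENTS
    max_smiles_len: int = 200


@dataclass
class MoleculeRecord:
    """One compound travelling through the pipeline."""

    id: str
    smiles_raw: str
    label: int
    smiles_std: Optional[str] = None
    excluded_reason: ExclusionReason = ExclusionReason.NONE

    @property
    def kept(self) -> bool:
        return self.excluded_reason is ExclusionReason.NONE


def _tautomer_enumerator() -> rdMolStandardize.TautomerEnumerator:
    global _TAUTOMER_ENUMERATOR
    if _TAUTOMER_ENUMERATOR is None:
        _TAUTOMER_ENUMERATOR = rdMolStandardize.TautomerEnumerator()
    return _TAUTOMER_ENUMERATOR


def _largest_organic_fragment(mol: Chem.Mol) -> Optional[Chem.Mol]:
    """Salt stripping: among multi-fragment inputs, keep the largest
    (heavy-atom count) carbon-containing fragment; return ``None`` when
    counter-ion removal leaves nothing organic.  Single-fragment inputs
    pass through untouched (the organic filter judges them later).
    Ties are broken by lexicographically smallest canonical SMILES so
    the choice is deterministic."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) <= 1:
        return mol
    organic = [f for f in frags if any(a.GetSymbol() == "C" for a in f.GetAtoms())]
    if not organic:
        return None
    keyed = []
    for f in organic:
        try:
            smi = Chem.MolToSmiles(f)
        except Exception:
            smi = ""
        keyed.append((-f.GetNumHeavyAtoms(), smi, f))
    keyed.sort(key=lambda t: (t[0], t[1]))
    return keyed[0][2]


def _neutralize(mol: Chem.Mol) -> Chem.Mol:
    """Protonate/deprotonate simple charged centres in place."""
    matches = mol.GetSubstructMatches(_NEUTRALIZE_PATTERN)
    if not matches:
        return mol
    mol = Chem.RWMol(mol)
    for (idx,) in matches:
        atom = mol.GetAtomWithIdx(idx)
        charge = atom.GetFormalCharge()
        n_h = atom.GetTotalNumHs()
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(n_h - charge)
        atom.UpdatePropertyCache()
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out


def standardize_smiles(
    smiles_raw: str, config: StandardizationConfig | None = None
) -> tuple[Optional[str], ExclusionReason]:
    """Standardize a single SMILES string.

    Applies, in order: largest organic fragment + stereo stripping,
    organic element filter, charge neutralization, tautomer
    canonicalization, and the length filter.

    Returns
    -------
    (smiles_std, reason)
        ``smiles_std`` is the canonical standardized SMILES, or ``None``
        with a non-``NONE`` reason when the molecule is excluded.
        Unparsable input yields ``PARSE_FAILURE``, never an exception.
    """
    if config is None:
        config = StandardizationConfig()
    if not isinstance(smiles_raw, str) or not smiles_raw.strip():
        return None, ExclusionReason.PARSE_FAILURE

    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        return None, ExclusionReason.PARSE_FAILURE
    if mol.GetNumAtoms() == 0:
        return None, ExclusionReason.EMPTY_AFTER_SALT_STRIP

    mol = _largest_organic_fragment(mol)
    if mol is None or mol.GetNumAtoms() == 0:
        return None, ExclusionReason.EMPTY_AFTER_SALT_STRIP

    Chem.RemoveStereochemistry(mol)

    symbols = {a.GetSymbol() for a in mol.GetAtoms()}
    if "C" not in symbols or not symbols <= set(config.organic_elements) | {"H"}:
        return None, ExclusionReason.INORGANIC

    try:
        mol = _neutralize(mol)
        mol = _tautomer_enumerator().Canonicalize(mol)
        smiles_std = Chem.MolToSmiles(mol)
    except Exception:
        return None, ExclusionReason.PARSE_FAILURE

    if len(smiles_std) > config.max_smiles_len:
        return None, ExclusionReason.TOO_LONG
    return smiles_std, ExclusionReason.NONE


@dataclass
class ExclusionReport:
    """Batch standardization outcome: per-reason counts plus the
    excluded ``(id, reason)`` pairs.  Counts (kept included under
    ``"none"``) conserve the input size."""

    counts: dict[str, int] = field(
        default_factory=lambda: {r.value: 0 for r in ExclusionReason}
    )
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.excluded, columns=["id", "reason"]).to_csv(
            path, index=False
        )


def standardize_dataset(
    records: Sequence[MoleculeRecord], config: StandardizationConfig | None = None
) -> tuple[list[MoleculeRecord], ExclusionReport]:
    """Standardize a batch, preserving order.

    Returns the kept records (with ``smiles_std`` filled in) and an
    :class:`ExclusionReport`.  Duplicate ids are a hard error.
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate molecule ids: {dupes}")

    kept: list[MoleculeRecord] = []
    report = ExclusionReport()
    for rec in records:
        smi, reason = standardize_smiles(rec.smiles_raw, config)
        report.counts[reason.value] += 1
        if reason is ExclusionReason.NONE:
            kept.append(replace(rec, smiles_std=smi, excluded_reason=reason))
        else:
            report.excluded.append((rec.id, reason.value))
    return kept, report


# ---------------------------------------------------------------------------
# CSV I/O

def read_molecule_csv(path: str | Path) -> list[MoleculeRecord]:
    """Read ``id,smiles,label`` CSV (header required) into records."""
    df = pd.read_csv(path, dtype={"id": str})
    missing = {"id", "smiles", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return [
        MoleculeRecord(id=str(r.id), smiles_raw=str(r.smiles), label=int(r.label))
        for r in df.itertuples()
    ]


def write_standardized_csv(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"id": r.id, "smiles": r.smiles_std, "label": r.label} for r in records],
        columns=["id", "smiles", "label"],
    ).to_csv(path, index=False)
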