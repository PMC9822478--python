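"""Stratified training-pool partitions for aggregated conformal prediction.

Each ensemble member gets its own random, label-stratified partition of
the training pool into proper-training / (optional) deep-learning
validation / calibration parts.  Child seeds derive deterministically
from one master seed, so a run is reproducible end to end.

Default fractions (0.72, 0.08, 0.20) follow the benchmark's published
split sizes (6004 / 662 / 1670 of an 8336-compound pool).  For base
learners with no validation stage, set the middle fraction to 0 — the
validation ids fold into proper training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_FRACTIONS = (0.72, 0.08, 0.20)

_PART_NAMES = ("train", "dl_val", "calib")


@dataclass(frozen=True)
class DatasetSplit:
    """One ensemble member's partition of the training pool."""

    proper_train_ids: tuple[str, ...]
    dl_validation_ids: tuple[str, ...]
    calibration_ids: tuple[str, ...]
    evaluation_ids: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        parts = [
            set(self.proper_train_ids),
            set(self.dl_validation_ids),
            set(self.calibration_ids),
            set(self.evaluation_ids),
        ]
        total = sum(len(p) for p in parts)
        if len(set().union(*parts)) != total:
            raise ValueError("split parts are not pairwise disjoint")


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer part sizes summing exactly to n."""
    exact = np.asarray(fractions, dtype=float) * n
    base = np.floor(exact).astype(int)
    short = n - int(base.sum())
    order = np.argsort(-(exact - base), kind="stable")
    for i in order[:short]:
        base[i] += 1
    return base.tolist()


def make_splits(
    pool_ids: Sequence[str],
    labels: Sequence[int],
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    K: int = 10,
    master_seed: int = 0,
    evaluation_ids: Sequence[str] = (),
) -> list[DatasetSplit]:
    """Draw ``K`` independent stratified partitions of the pool.

    Parameters
    ----------
    pool_ids, labels
        The training pool and its binary labels (aligned).
    fractions
        (proper_train, dl_validation, calibration) fractions; must sum
        to 1.  A zero dl_validation fraction yields empty validation
        parts.
    K
        Ensemble size (one split per member).
    master_seed
        Seed of the whole ensemble; per-member child seeds are spawned
        from it.
    evaluation_ids
        Held-out evaluation ids, recorded on every split (never drawn
        from the pool).

    Raises
    ------
    ValueError
        If fractions do not sum to 1, the pool overlaps the evaluation
        set, or any part would receive fewer than 2 members of either
        class (calibration with a near-empty class is meaningless).
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if K < 1:
        raise ValueError("K must be >= 1")
    pool_ids = [str(i) for i in pool_ids]
    labels = np.asarray(labels, dtype=int)
    if len(pool_ids) != len(labels):
        raise ValueError("pool_ids and labels length mismatch")
    eval_ids = tuple(str(i) for i in evaluation_ids)
    if set(pool_ids) & set(eval_ids):
        raise ValueError("evaluation ids overlap the training pool")

    by_class = {c: np.flatnonzero(labels == c) for c in (0, 1)}
    nonzero_fracs = [i for i, f in enumerate(fractions) if f > 0]
    for c, idx in by_class.items():
        sizes = _largest_remainder(len(idx), fractions)
        for i in nonzero_fracs:
            if sizes[i] < 2:
                raise ValueError(
                    f"class {c} would contribute {sizes[i]} member(s) to part "
                    f"{_PART_NAMES[i]!r}; need >= 2"
                )

    children = np.random.SeedSequence(master_seed).spawn(K)
    splits = []
    for child in children:
        member_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(child)
        parts: list[list[str]] = [[], [], []]
        for c in (0, 1):
            idx = rng.permutation(by_class[c])
            sizes = _largest_remainder(len(idx), fractions)
            offset = 0
            for part, size in zip(parts, sizes):
                part.extend(pool_ids[j] for j in idx[offset : offset + size])
                offset += size
        splits.append(
            DatasetSplit(
                proper_train_ids=tuple(parts[0]),
                dl_validation_ids=tuple(parts[1]),
                calibration_ids=tuple(parts[2]),
                evaluation_ids=eval_ids,
                seed=member_seed,
            )
        )
    return splits


def splits_to_manifest(splits: Sequence[DatasetSplit]) -> pd.DataFrame:
    """Long-format manifest: one row per (id, member, part)."""
    rows = []
    for k, sp in enumerate(splits):
        for part, ids in zip(
            _PART_NAMES,
            (sp.proper_train_ids, sp.dl_validation_ids, sp.calibration_ids),
        ):
            rows.extend({"id": i, "member_index": k, "part": part} for i in ids)
    return pd.DataFrame(rows, columns=["id", "member_index", "part"])


def write_split_manifest(splits: Sequence[DatasetSplit], path: str | Path) -> None:
    splits_to_manifest(splits).to_csv(path, index=False)


def read_split_manifest(
    path: str | Path, evaluation_ids: Sequence[str] = ()
) -> list[DatasetSplit]:
    df = pd.read_csv(path, dtype={"id": str})
    splits = []
    for k in sorted(df["member_index"].unique()):
        sub = df[df["member_index"] == k]
        get = lambda part: tuple(sub.loc[sub["part"] == part, "id"])
        splits.append(
            DatasetSplit(
                proper_train_ids=get("train"),
                dl_validation_ids=get("dl_val"),
                calibration_ids=get("calib"),
                evaluation_ids=tuple(str(i) for i in evaluation_ids),
                seed=int(k),
            )
        )
    return splits
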