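"""End-to-end experiment orchestration.

``run_experiment`` executes the full chain — data (synthetic or CSV of
SMILES), standardization, featurization, per-member splits, Mondrian
aggregated conformal prediction, metrics — for each configured method
arm, writes every intermediate file under the output directory, and
records a run manifest so every published number is traceable to one
config + seed.

Two method-arm kinds are supported: ``internal`` (descriptor matrix +
probabilistic base learner trained inside the pipeline) and ``scores``
(a per-compound class-1 score file produced by an external model,
calibrated into conformal p-values per member and median-aggregated).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .conformal import (
    MondrianConformalClassifier,
    calibrate_external_scores,
    median_aggregate,
    predict_sets,
    prediction_sets_to_frame,
)
from .featurize import (
    FeatureMatrix,
    compute_descriptors,
    load_descriptor_config,
    load_external_features,
)
from .metrics import CPMetricsReport, evaluate_sets, render_report_text, write_report_csv
from .splits import make_splits, write_split_manifest
from .standardize import (
    StandardizationConfig,
    read_molecule_csv,
    standardize_dataset,
    write_standardized_csv,
)
from .synthetic import SyntheticConfig, generate_tabular

DEFAULT_EPSILONS = (0.1, 0.15, 0.2, 0.25, 0.3)


@dataclass
class RunManifest:
    """Provenance record of one experiment run."""

    config: dict
    master_seed: int
    package_version: str = __version__
    created_utc: str = ""
    input_digests: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.created_utc:
            self.created_utc = time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "package_version": self.package_version,
                    "created_utc": self.created_utc,
                    "master_seed": self.master_seed,
                    "config": self.config,
                    "input_digests": self.input_digests,
                    "stage_counts": self.stage_counts,
                },
                fh,
                sort_keys=False,
            )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _prepare_csv_dataset(cfg: dict, outdir: Path, manifest: RunManifest):
    """Standardize + featurize train/eval CSVs of (id, smiles, label)."""
    std_config = StandardizationConfig(max_smiles_len=int(cfg.get("max_smiles_len", 200)))
    descriptors = (
        load_descriptor_config(cfg["descriptors"]) if cfg.get("descriptors") else None
    )
    out = {}
    for part in ("train", "eval"):
        path = cfg[f"{part}_csv"]
        manifest.input_digests[str(path)] = _sha256(path)
        records = read_molecule_csv(path)
        kept, report = standardize_dataset(records, std_config)
        write_standardized_csv(kept, outdir / f"{part}_std.csv")
        report.to_csv(outdir / f"{part}_exclusions.csv")
        fm, failed = compute_descriptors(kept, descriptors)
        fm.to_csv(outdir / f"{part}_features.csv")
        labels = {r.id: r.label for r in kept}
        y = np.asarray([labels[i] for i in fm.ids], dtype=int)
        manifest.stage_counts[part] = {
            "input": len(records),
            "standardized": len(kept),
            "featurized": fm.n,
            "descriptor_failures": len(failed),
            **{f"excluded_{k}": v for k, v in report.counts.items() if k != "none" and v},
        }
        out[part] = (fm, y)
    return out["train"], out["eval"]


def _prepare_synthetic_dataset(cfg: dict, seed: int, outdir: Path, manifest: RunManifest):
    n_train = int(cfg.get("n_train", 5000))
    n_eval = int(cfg.get("n_eval", 2000))
    config = SyntheticConfig(
        n_total=n_train + n_eval,
        imbalance_ratio=float(cfg.get("imbalance_ratio", 11.0)),
        dimension=int(cfg.get("dimension", 32)),
        class_separation=float(cfg.get("class_separation", 1.5)),
        label_noise=float(cfg.get("label_noise", 0.0)),
        seed=seed,
    )
    fm, labels = generate_tabular(config)
    # rows are i.i.d., so a prefix/suffix split is itself exchangeable
    train = FeatureMatrix(fm.ids[:n_train], fm.names, fm.values[:n_train])
    evalm = FeatureMatrix(fm.ids[n_train:], fm.names, fm.values[n_train:])
    manifest.stage_counts["synthetic"] = {
        "n_train": n_train,
        "n_eval": n_eval,
        **{k: (v if not isinstance(v, float) else float(v)) for k, v in config.manifest().items()},
    }
    pd.DataFrame({"id": fm.ids, "label": labels}).to_csv(outdir / "labels.csv", index=False)
    return (train, labels[:n_train]), (evalm, labels[n_train:])


def run_experiment(
    config: dict | str | Path,
    outdir: str | Path,
    seed: Optional[int] = None,
) -> tuple[list[CPMetricsReport], RunManifest]:
    """Run every configured method arm end to end.

    Parameters
    ----------
    config
        A config mapping or path to a YAML file.  Keys: ``master_seed``,
        ``dataset`` (kind ``synthetic`` or ``csv``), ``conformal``
        (K, fractions, smoothing, epsilons), ``arms`` (list of
        ``{name, kind}`` with kind ``internal`` or ``scores``).
    outdir
        Output directory (created if needed); intermediate CSVs, the
        report and the manifest land here.
    seed
        Overrides ``master_seed`` from the config when given.

    Returns the metric reports (one per arm x epsilon) and the run
    manifest.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    master_seed = int(seed if seed is not None else config.get("master_seed", 0))
    manifest = RunManifest(config=config, master_seed=master_seed)

    ds_cfg = dict(config.get("dataset", {}))
    kind = ds_cfg.get("kind", "synthetic")
    tag = ds_cfg.get("tag", kind)
    if kind == "synthetic":
        (train_fm, y_train), (eval_fm, y_eval) = _prepare_synthetic_dataset(
            ds_cfg, master_seed, outdir, manifest
        )
    elif kind == "csv":
        (train_fm, y_train), (eval_fm, y_eval) = _prepare_csv_dataset(
            ds_cfg, outdir, manifest
        )
    else:
        raise ValueError(f"unknown dataset kind {kind!r}")

    cp_cfg = dict(config.get("conformal", {}))
    K = int(cp_cfg.get("K", 10))
    fractions = tuple(cp_cfg.get("fractions", (0.72, 0.08, 0.20)))
    smoothing = bool(cp_cfg.get("smoothing", False))
    epsilons = [float(e) for e in cp_cfg.get("epsilons", DEFAULT_EPSILONS)]

    splits = make_splits(
        train_fm.ids,
        y_train,
        fractions=fractions,
        K=K,
        master_seed=master_seed,
        evaluation_ids=eval_fm.ids,
    )
    write_split_manifest(splits, outdir / "splits.csv")

    arms = config.get("arms") or [{"name": "rf", "kind": "internal"}]
    reports: list[CPMetricsReport] = []
    for arm in arms:
        name, akind = arm.get("name", arm.get("kind", "arm")), arm.get("kind", "internal")
        if akind == "internal":
            model = MondrianConformalClassifier(
                train_fm,
                y_train,
                n_members=K,
                fractions=fractions,
                smoothing=smoothing,
                master_seed=master_seed,
            )
            res = model.fit(splits=splits)
            agg, per_member = res.predict_p(eval_fm)
        elif akind == "scores":
            agg, per_member = _score_arm(
                arm, train_fm, y_train, eval_fm, splits, smoothing, manifest
            )
        else:
            raise ValueError(f"unknown arm kind {akind!r} for arm {name!r}")

        agg.to_csv(outdir / f"{name}_pvalues_agg.csv")
        for k, m in enumerate(per_member):
            m.to_csv(outdir / f"{name}_pvalues_member{k}.csv")
        labels_by_id = dict(zip(eval_fm.ids, (int(v) for v in y_eval)))
        for eps in epsilons:
            sets = predict_sets(agg, eps)
            prediction_sets_to_frame(sets).to_csv(
                outdir / f"{name}_sets_eps{eps:g}.csv", index=False
            )
            reports.append(
                evaluate_sets(sets, labels_by_id, eps, dataset=tag, method=name)
            )

    write_report_csv(reports, outdir / "report.csv")
    (outdir / "report.txt").write_text(render_report_text(reports) + "\n")
    manifest.stage_counts["evaluation"] = {"n_eval": eval_fm.n, "arms": len(arms)}
    manifest.to_yaml(outdir / "manifest.yaml")
    return reports, manifest


def _score_arm(arm, train_fm, y_train, eval_fm, splits, smoothing, manifest):
    """External-score arm: calibrate a score file per member split and
    median-aggregate."""
    def read_scores(path):
        manifest.input_digests[str(path)] = _sha256(path)
        df = pd.read_csv(path, dtype={"id": str})
        if not {"id", "score"} <= set(df.columns):
            raise ValueError(f"{path}: need columns id,score, found {list(df.columns)}")
        return dict(zip(df["id"], df["score"].astype(float)))

    scores = read_scores(arm["scores_csv"])
    missing = [i for i in list(train_fm.ids) + list(eval_fm.ids) if i not in scores]
    if missing:
        raise ValueError(f"score file missing ids {missing[:10]}")
    y_by_id = dict(zip(train_fm.ids, (int(v) for v in y_train)))
    eval_scores = np.asarray([scores[i] for i in eval_fm.ids])
    per_member = []
    for k, sp in enumerate(splits):
        calib_ids = list(sp.calibration_ids)
        pmat = calibrate_external_scores(
            [scores[i] for i in calib_ids],
            [y_by_id[i] for i in calib_ids],
            eval_scores,
            test_ids=eval_fm.ids,
            smoothing=smoothing,
            tie_seed=(sp.seed * 2) % (2**31),
        )
        per_member.append(pmat)
    return median_aggregate(per_member), per_member


# ---------------------------------------------------------------------------
# CATMoS ingestion adapter

_ID_GUESSES = ("dtxsid", "dsstox_substance_id", "casrn", "id", "chid")
_SMILES_GUESSES = ("qsar_ready_smiles", "canonical_smiles", "smiles")
_LABEL_GUESSES = {
    "nt": ("nontoxic", "non_toxic", "nt", "catmos_nt"),
    "vt": ("very_toxic", "verytoxic", "vt", "catmos_vt"),
}
_SPLIT_GUESSES = ("split", "set", "subset", "tr_tst")

_TRUTHY = {"1", "1.0", "true", "yes", "y", "positive", "active", "toxic"}
_FALSY = {"0", "0.0", "false", "no", "n", "negative", "inactive", "nontoxic", "non-toxic"}


def _coerce_label(v) -> int:
    s = str(v).strip().lower()
    if s in _TRUTHY:
        return 1
    if s in _FALSY:
        return 0
    raise ValueError(f"cannot interpret label value {v!r} as binary")


def ingest_catmos(
    path: str | Path,
    endpoint: str = "vt",
    column_map: Optional[dict] = None,
) -> pd.DataFrame:
    """Map a locally downloaded acute-toxicity benchmark file onto the
    pipeline's ``id,smiles,label[,split]`` layout.

    The benchmark ships two binary endpoints — non-toxic (``nt``,
    roughly balanced) and very-toxic (``vt``, ~11:1 imbalanced) — and a
    predefined train/evaluation assignment, which is preserved when a
    split column is present.  Distribution file layouts vary by
    version, so columns are located by a set of common-name guesses;
    pass ``column_map`` with keys ``id``, ``smiles``, ``label`` (and
    optionally ``split``) to override.  Never downloads anything.
    """
    if endpoint not in ("nt", "vt"):
        raise ValueError("endpoint must be 'nt' or 'vt'")
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep=None, engine="python")
    lower = {c.lower(): c for c in df.columns}
    column_map = column_map or {}

    def find(key, guesses):
        if key in column_map:
            if column_map[key] not in df.columns:
                raise ValueError(
                    f"mapped column {column_map[key]!r} for {key!r} not in file; "
                    f"found columns: {list(df.columns)}"
                )
            return column_map[key]
        for g in guesses:
            if g in lower:
                return lower[g]
        raise ValueError(
            f"could not locate a column for {key!r}; found columns: {list(df.columns)}"
        )

    id_col = find("id", _ID_GUESSES)
    smiles_col = find("smiles", _SMILES_GUESSES)
    label_col = find("label", _LABEL_GUESSES[endpoint])

    out = pd.DataFrame(
        {
            "id": df[id_col].astype(str),
            "smiles": df[smiles_col].astype(str),
            "label": [_coerce_label(v) for v in df[label_col]],
        }
    )
    split_col = None
    if "split" in column_map:
        split_col = find("split", ())
    else:
        for g in _SPLIT_GUESSES:
            if g in lower:
                split_col = lower[g]
                break
    if split_col is not None:
        vals = df[split_col].astype(str).str.lower()
        out["split"] = np.where(
            vals.str.contains("train"), "train",
            np.where(vals.str.contains("eval") | vals.str.contains("test"), "eval", "other"),
        )
    return out
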