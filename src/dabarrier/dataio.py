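"""Dataset schema, delimited-text I/O and the end-to-end pipeline.

On-disk format: plain CSV with a column-name header followed by a units
line (``#units,...``) so files are self-describing and diff-able.  Unknown
columns are preserved verbatim on round trips.  Every dataset write can
carry a JSON sidecar (``<name>.meta.json``) recording provenance (seed,
generator parameters).

``run_pipeline`` chains simulate -> featurize -> train -> explain from a
single master seed and writes a manifest of the stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .descriptors import (
    ElectronicRecord,
    FULL_FEATURES,
    REDUCED_FEATURES,
    assemble_features,
    classify_da_type,
)
from .reaction_space import DEFAULT_ALPHABETS, POSITIONS, ReactionSpec

log = logging.getLogger("dabarrier")

__all__ = [
    "KEY_COLUMNS",
    "UNITS",
    "write_dataset",
    "read_dataset",
    "featurize_dataframe",
    "run_pipeline",
]

#: Mandatory reaction-key columns of the shared schema.
KEY_COLUMNS: List[str] = [
    "r1", "r2", "r3", "r4", "r5", "r6", "orient1", "orient4",
    "canonical_key", "n_pathways",
]

TARGET_COLUMN = "dg_act_min"


def _default_units() -> Dict[str, str]:
    units: Dict[str, str] = {c: "label" for c in KEY_COLUMNS}
    units["n_pathways"] = "count"
    for f in FULL_FEATURES:
        if f.startswith(("homo", "lumo", "gap", "min_lumo")):
            units[f] = "eV"
        elif f.startswith("vol"):
            units[f] = "A^3"
        elif f.startswith(("npa", "pz")):
            units[f] = "e"
        else:
            units[f] = "dimensionless"
    units[TARGET_COLUMN] = "kcal/mol"
    units["da_type"] = "label"
    return units


UNITS = _default_units()


def write_dataset(
    df: pd.DataFrame,
    path,
    metadata: Optional[Mapping] = None,
    units: Optional[Mapping[str, str]] = None,
) -> Path:
    """Write a dataset as CSV with a units header line; optional JSON
    sidecar with provenance metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    units = dict(units or UNITS)
    # units line: '#units:<unit of col 1>,<unit of col 2>,...'
    unit_row = ",".join(
        ["#units:" + units.get(df.columns[0], "unknown")]
        + [units.get(c, "unknown") for c in df.columns[1:]]
    )
    with open(path, "w") as fh:
        fh.write(",".join(df.columns) + "\n")
        fh.write(unit_row + "\n")
        df.to_csv(fh, index=False, header=False, lineterminator="\n")
    if metadata is not None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(metadata, indent=2, sort_keys=True))
    log.info("wrote dataset rows=%d path=%s", len(df), path)
    return path


class DatasetValidationError(ValueError):
    """Schema violations, with per-row line numbers where applicable."""


def read_dataset(
    path,
    require_target: bool = False,
    validate_labels: bool = True,
    column_mapping: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Read and validate a dataset written by :func:`write_dataset`.

    ``column_mapping`` renames external columns onto the schema (for
    user-supplied files in other layouts).  Row-level label violations are
    collected with 1-based data line numbers.  Unknown columns pass
    through untouched.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        second = fh.readline()
    has_units = second.startswith("#units")
    df = pd.read_csv(path, skiprows=[1] if has_units else [], header=0)
    if column_mapping:
        df = df.rename(columns=dict(column_mapping))
    missing = [c for c in ("r1", "r2", "r3", "r4", "r5", "r6") if c not in df.columns]
    if missing:
        raise DatasetValidationError(f"missing mandatory columns: {missing}")
    if require_target and TARGET_COLUMN not in df.columns:
        raise DatasetValidationError(
            f"dataset has no {TARGET_COLUMN!r} column but the target is required"
        )
    if validate_labels:
        errors = []
        for i, row in df.iterrows():
            for pos, col in zip(POSITIONS, ("r1", "r2", "r3", "r4", "r5", "r6")):
                if row[col] not in DEFAULT_ALPHABETS[pos]:
                    errors.append(f"line {i + 1}: label {row[col]!r} invalid at {pos}")
        if errors:
            raise DatasetValidationError("; ".join(errors[:20]))
    return df


def featurize_dataframe(df: pd.DataFrame, feature_set: str = "full") -> pd.DataFrame:
    """Recompute descriptor columns from labels + electronic columns.

    Electronic quantities (orbital energies, NPA, pz) must already be
    present; gaps, min_lumo_homo, substituent-constant columns and
    ``da_type`` are (re)derived.  Missing electronic fields raise an error
    naming the field.
    """
    needed = ["homo_diene", "lumo_diene", "homo_dienophile", "lumo_dienophile"]
    needed += [f"npa_{p}" for p in POSITIONS] + [f"pz_{p}" for p in POSITIONS]
    for col in needed:
        if col not in df.columns:
            raise DatasetValidationError(f"missing electronic field: {col}")
    out_rows = []
    for _, row in df.iterrows():
        spec = ReactionSpec(*(row[c] for c in ("r1", "r2", "r3", "r4", "r5", "r6")),
                            orient1=row.get("orient1", "trans"),
                            orient4=row.get("orient4", "trans"))
        e = ElectronicRecord(
            homo_diene=row["homo_diene"],
            lumo_diene=row["lumo_diene"],
            homo_dienophile=row["homo_dienophile"],
            lumo_dienophile=row["lumo_dienophile"],
            npa_charges=tuple(row[f"npa_{p}"] for p in POSITIONS),
            pz_populations=tuple(row[f"pz_{p}"] for p in POSITIONS),
        )
        feats = assemble_features(spec, e, feature_set="full")
        feats["da_type"] = classify_da_type(feats)
        out_rows.append(feats)
    feats_df = pd.DataFrame(out_rows, index=df.index)
    out = df.copy()
    for c in feats_df.columns:
        out[c] = feats_df[c]
    if feature_set == "reduced13":
        keep = [c for c in out.columns if c not in set(FULL_FEATURES) - set(REDUCED_FEATURES)]
        out = out[keep]
    return out


def _config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


DEFAULT_PIPELINE_CONFIG: Dict = {
    "n": 1000,
    "seed": 0,
    "feature_set": "reduced13",
    "model": "rf",
    "n_explain": 64,
    "background_size": 50,
    "split_fraction": 0.2,
    "n_iter": 10,
}


def run_pipeline(config: Optional[Mapping] = None, outdir="pipeline_run") -> Path:
    """Execute simulate -> featurize -> train -> explain -> report.

    All stages derive their randomness from ``config['seed']``.  Artifacts
    (dataset, featurized dataset, model, evaluation report, attribution
    export and the run manifest) land in *outdir*; any stage failure
    aborts with the stage name while earlier outputs remain on disk.
    """
    from .attribution import export_summary
    from .model import BarrierModel, ModelConfig
    from .synthetic import generate_dataset

    cfg = dict(DEFAULT_PIPELINE_CONFIG)
    cfg.update(config or {})
    seed = int(cfg["seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "version": __version__,
        "stages": {},
    }
    stage = "simulate"
    try:
        df, meta = generate_dataset(cfg["n"], seed=seed)
        data_path = write_dataset(df, outdir / "dataset.csv", metadata=meta)
        manifest["stages"]["simulate"] = {"path": data_path.name, "rows": len(df)}
        log.info("stage=simulate seed=%d rows=%d", seed, len(df))

        stage = "featurize"
        feat_df = featurize_dataframe(df, feature_set=cfg["feature_set"])
        feat_path = write_dataset(feat_df, outdir / "features.csv")
        manifest["stages"]["featurize"] = {"path": feat_path.name, "rows": len(feat_df)}

        stage = "train"
        features = list(REDUCED_FEATURES if cfg["feature_set"] == "reduced13" else FULL_FEATURES)
        bm = BarrierModel(feat_df, features=features,
                          config=ModelConfig(model=cfg["model"], seed=seed))
        report = bm.evaluate_repeated_splits(
            n_iter=cfg["n_iter"], split_fraction=cfg["split_fraction"], seed=seed
        )
        results = bm.fit(seed=seed)
        import joblib

        model_path = outdir / "model.joblib"
        joblib.dump(results.estimator, model_path)
        report_payload = {
            "r2_train": report.r2_train,
            "r2_validation": report.r2_validation,
            "r2_oob": report.r2_oob,
            "mae_test": report.mae_test,
            "n_iterations": report.n_iterations,
            "fit_r2_train": results.r2_train,
            "fit_r2_oob": results.r2_oob,
        }
        (outdir / "eval_report.json").write_text(json.dumps(report_payload, indent=2))
        manifest["stages"]["train"] = {
            "path": model_path.name, "report": "eval_report.json", **report_payload,
        }
        log.info("stage=train seed=%d r2_val=%.3f", seed, report.r2_validation)

        stage = "explain"
        attr = results.shapley_values(
            n_explain=cfg["n_explain"], background_size=cfg["background_size"], seed=seed
        )
        summary = export_summary(attr, outdir / "shap_summary.csv")
        imp_path = outdir / "global_importance.json"
        imp_path.write_text(json.dumps(attr.global_importance, indent=2, sort_keys=True))
        manifest["stages"]["explain"] = {
            "path": "shap_summary.csv",
            "importance": imp_path.name,
            "rows": len(summary),
        }

        stage = "report"
        manifest["stages"]["report"] = {"path": "manifest.json"}
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str)
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return outdir
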