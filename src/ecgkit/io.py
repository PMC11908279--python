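"""Readers, writers and run configuration.

Waveforms travel as a delimited numeric matrix (one column per lead,
one row per sample, millivolts) with a JSON sidecar next to it carrying
sampling rate, lead names, units and demographics — the sidecar is
mandatory, a bare matrix has no physical meaning. Prediction sets are
CSV triplets (scores, labels, metadata) keyed by record id. Reference
profiles, harmonization logs and audit reports serialize to JSON.

Conventions used throughout the package: sample indexing is 0-based,
intervals are half-open, waveform unit is millivolts.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .fairness import FairnessReport
from .harmonize import HarmonizationLog, HarmonizeConfig, ReferenceProfile
from .metrics import PredictionSet
from .privacy import AttackReport
from .records import ECGRecord
from .spectral import ArtifactPeak

__all__ = [
    "RunConfig",
    "read_record",
    "write_record",
    "read_prediction_set",
    "write_prediction_set",
    "profile_to_json",
    "profile_from_json",
    "log_to_json",
    "log_from_json",
    "report_to_dict",
]

SCHEMA_VERSION = 1


def _sidecar_path(data_path: Path) -> Path:
    return data_path.with_suffix(".json")


def write_record(record: ECGRecord, path: str | Path) -> Path:
    """Write a record as a delimited matrix + JSON sidecar; returns the matrix path."""
    path = Path(path)
    df = pd.DataFrame(record.waveform.T, columns=record.lead_names)
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "fs": record.fs,
        "lead_names": record.lead_names,
        "units": "mV",
        "age": record.age,
        "sex": record.sex,
        "source_id": record.source_id,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_record(path: str | Path) -> ECGRecord:
    """Read a delimited waveform matrix with its mandatory JSON sidecar.

    The sidecar (same stem, ``.json``) must provide the sampling rate,
    lead names and units; a matrix without it is rejected because the
    numbers alone carry no physical scale.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise ValueError(
            f"no sidecar {sidecar_path.name} next to {path.name}: a delimited "
            "waveform needs a JSON sidecar with fs, lead names and units"
        )
    meta = json.loads(sidecar_path.read_text())
    for key in ("fs", "lead_names", "units"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar_path.name} missing key {key!r}")
    if meta["units"] not in ("mV", "millivolt", "millivolts"):
        raise ValueError(f"unsupported waveform unit {meta['units']!r} (use mV)")
    df = pd.read_csv(path)
    waveform = df.to_numpy(dtype=float).T
    if np.isnan(waveform).any():
        lead, sample = np.argwhere(np.isnan(waveform))[0]
        raise ValueError(
            f"NaN in waveform at lead {lead} ({df.columns[lead]!r}), "
            f"sample {sample}"
        )
    return ECGRecord(
        waveform=waveform,
        fs=float(meta["fs"]),
        lead_names=list(meta["lead_names"]),
        age=meta.get("age"),
        sex=meta.get("sex"),
        source_id=meta.get("source_id", str(path)),
    )


def write_prediction_set(
    predset: PredictionSet, prefix: str | Path
) -> tuple[Path, Path, Path]:
    """Write scores/labels/meta CSVs as ``<prefix>_{scores,labels,meta}.csv``."""
    prefix = Path(prefix)
    paths = tuple(
        prefix.parent / f"{prefix.name}_{kind}.csv"
        for kind in ("scores", "labels", "meta")
    )
    ids = pd.Series(predset.record_ids, name="record_id")
    pd.concat(
        [ids, pd.DataFrame(predset.scores, columns=predset.label_names)], axis=1
    ).to_csv(paths[0], index=False, float_format="%.17g")
    pd.concat(
        [ids, pd.DataFrame(predset.labels, columns=predset.label_names)], axis=1
    ).to_csv(paths[1], index=False)
    meta = pd.DataFrame({"record_id": ids})
    meta["age"] = predset.age if predset.age is not None else np.nan
    meta["sex"] = predset.sex if predset.sex is not None else ""
    meta.to_csv(paths[2], index=False)
    return paths


def read_prediction_set(
    scores_path: str | Path,
    labels_path: str | Path,
    meta_path: str | Path | None = None,
) -> PredictionSet:
    """Assemble a validated PredictionSet from CSV files keyed by record_id."""
    scores_df = pd.read_csv(scores_path)
    labels_df = pd.read_csv(labels_path)
    for name, df in (("scores", scores_df), ("labels", labels_df)):
        if "record_id" not in df.columns:
            raise ValueError(f"{name} file lacks a record_id column")
    if list(scores_df["record_id"]) != list(labels_df["record_id"]):
        mismatched = sorted(
            set(scores_df["record_id"]).symmetric_difference(labels_df["record_id"])
        )
        raise ValueError(f"record_id mismatch between scores and labels: {mismatched}")
    label_names = [c for c in scores_df.columns if c != "record_id"]
    if label_names != [c for c in labels_df.columns if c != "record_id"]:
        raise ValueError("score and label files disagree on label columns")
    age = sex = None
    if meta_path is not None:
        meta_df = pd.read_csv(meta_path)
        if "record_id" not in meta_df.columns:
            raise ValueError("meta file lacks a record_id column")
        missing = sorted(set(scores_df["record_id"]) - set(meta_df["record_id"]))
        if missing:
            raise ValueError(f"meta file missing record ids: {missing}")
        meta_df = meta_df.set_index("record_id").loc[scores_df["record_id"]]
        if "age" in meta_df.columns and meta_df["age"].notna().any():
            age = meta_df["age"].to_numpy(dtype=float)
        if "sex" in meta_df.columns and meta_df["sex"].notna().any():
            sex = meta_df["sex"].astype(str).to_numpy()
    return PredictionSet(
        scores=scores_df[label_names].to_numpy(dtype=float),
        labels=labels_df[label_names].to_numpy(),
        record_ids=[str(r) for r in scores_df["record_id"]],
        label_names=label_names,
        age=age,
        sex=sex,
    )


def profile_to_json(profile: ReferenceProfile, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "schema_version": SCHEMA_VERSION,
                "p1": profile.p1.tolist(),
                "p99": profile.p99.tolist(),
                "stat_band": list(profile.stat_band),
                "provenance": profile.provenance,
            },
            indent=2,
        )
    )


def profile_from_json(path: str | Path) -> ReferenceProfile:
    d = json.loads(Path(path).read_text())
    return ReferenceProfile(
        p1=d["p1"],
        p99=d["p99"],
        stat_band=tuple(d.get("stat_band", (2.0, 40.0))),
        provenance=d.get("provenance", ""),
    )


def log_to_json(log: HarmonizationLog, path: str | Path) -> None:
    d = dataclasses.asdict(log)
    Path(path).write_text(json.dumps({"schema_version": SCHEMA_VERSION, **d}, indent=2))


def log_from_json(path: str | Path) -> HarmonizationLog:
    d = json.loads(Path(path).read_text())
    d.pop("schema_version", None)
    d["peaks_removed"] = [ArtifactPeak(**p) for p in d["peaks_removed"]]
    return HarmonizationLog(**d)


def report_to_dict(report: FairnessReport | AttackReport) -> dict[str, Any]:
    """JSON-serializable dict of an audit report."""
    d = dataclasses.asdict(report)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
        elif isinstance(v, tuple):
            d[k] = list(v)
    d["schema_version"] = SCHEMA_VERSION
    return d


@dataclasses.dataclass
class RunConfig:
    """Effective configuration of a CLI run, serialized next to outputs.

    Unknown keys are rejected on load so config typos fail loudly
    instead of silently using defaults.
    """

    harmonize: HarmonizeConfig = dataclasses.field(default_factory=HarmonizeConfig)
    bootstrap_fraction: float = 0.7
    bootstrap_iterations: int = 1000
    mia_trees: int = 50
    mia_split: float = 0.8
    mia_seeds: tuple[int, ...] = tuple(range(10))
    lime_segments: int = 10
    lime_perturbations: int = 500
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "harmonize" in d and isinstance(d["harmonize"], dict):
            hz_known = {f.name for f in dataclasses.fields(HarmonizeConfig)}
            hz_unknown = set(d["harmonize"]) - hz_known
            if hz_unknown:
                raise ValueError(
                    f"unknown harmonize configuration keys: {sorted(hz_unknown)}"
                )
            d["harmonize"] = HarmonizeConfig(**{
                k: tuple(v) if k == "candidate_bases" else v
                for k, v in d["harmonize"].items()
            })
        if "mia_seeds" in d:
            d["mia_seeds"] = tuple(d["mia_seeds"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
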