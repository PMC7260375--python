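"""Delimited-text readers and writers for cohorts, registries and recordings.

File schemas
------------
subjects file (CSV):
    subject_id,group,age,sex,dominant_side,stereo_deficit,fma_ue,arat,nhpt
    (clinical columns may be empty)
metrics file (CSV):
    subject_id,side,session,repetition,peg,metric_name,value
metric registry (YAML): list of MetricDescriptor entries.
recording file (CSV): t,x,y,z,grip_force,active_peg[,fz] with a YAML
    geometry sidecar (peg/hole coordinates, tolerance radius, force threshold).
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import (
    IntegrityError,
    MetricDescriptor,
    OBSERVATION_COLUMNS,
    SchemaError,
    SubjectRecord,
    check_integrity,
    validate_observations,
)

SUBJECT_COLUMNS = (
    "subject_id",
    "group",
    "age",
    "sex",
    "dominant_side",
    "stereo_deficit",
    "fma_ue",
    "arat",
    "nhpt",
)

_BOOL = {"true": True, "false": False, "1": True, "0": False}


def _parse_bool(raw, where: str) -> bool:
    try:
        return _BOOL[str(raw).strip().lower()]
    except KeyError:
        raise SchemaError(f"cannot parse boolean {raw!r} in {where}") from None


def read_subjects(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path, dtype=str)
    missing = set(SUBJECT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"subjects file missing columns: {sorted(missing)}")
    subjects = []
    for i, row in df.iterrows():
        scores = {}
        for name, caster in (("fma_ue", int), ("arat", int), ("nhpt", float)):
            raw = row[name]
            if isinstance(raw, str) and raw.strip():
                try:
                    scores[name] = caster(float(raw))
                except ValueError:
                    raise SchemaError(
                        f"non-numeric {name} {raw!r} in subjects row {i}"
                    ) from None
        try:
            age = float(row["age"])
        except (TypeError, ValueError):
            raise SchemaError(
                f"non-numeric age {row['age']!r} in subjects row {i}"
            ) from None
        subjects.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                age=age,
                sex=str(row["sex"]),
                dominant_side=str(row["dominant_side"]),
                stereo_deficit=_parse_bool(row["stereo_deficit"], f"row {i}"),
                clinical_scores=scores,
            )
        )
    return subjects


def read_observations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = set(OBSERVATION_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"metrics file missing columns: {sorted(missing)}")
    out = df.copy()
    for col, caster in (("repetition", "Int64"), ("peg", "Int64")):
        try:
            out[col] = pd.to_numeric(out[col]).astype(caster)
        except ValueError:
            raise SchemaError(f"non-integer {col} in metrics file") from None
    values = pd.to_numeric(out["value"], errors="coerce")
    bad = values.isna() | ~np.isfinite(values)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise SchemaError(
            f"non-numeric value {df['value'].iloc[i]!r} in metrics row {i}"
        )
    out["value"] = values.astype(float)
    return validate_observations(out)


def read_cohort(
    subjects_path: str | Path, metrics_path: str | Path
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Read subject demographics and per-trial observations together.

    Raises :class:`SchemaError` for malformed files and
    :class:`IntegrityError` when observations reference unknown subjects.
    """
    subjects = read_subjects(subjects_path)
    obs = read_observations(metrics_path)
    check_integrity(subjects, obs)
    return subjects, obs


def write_cohort(
    subjects: list[SubjectRecord],
    obs: pd.DataFrame,
    subjects_path: str | Path,
    metrics_path: str | Path,
) -> None:
    rows = []
    for s in subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": repr(s.age),
                "sex": s.sex,
                "dominant_side": s.dominant_side,
                "stereo_deficit": str(s.stereo_deficit).lower(),
                "fma_ue": s.clinical_scores.get("fma_ue", ""),
                "arat": s.clinical_scores.get("arat", ""),
                "nhpt": s.clinical_scores.get("nhpt", ""),
            }
        )
    pd.DataFrame(rows, columns=list(SUBJECT_COLUMNS)).to_csv(
        subjects_path, index=False
    )
    out = obs[list(OBSERVATION_COLUMNS)].copy()
    # repr round-trips doubles exactly through decimal text
    out["value"] = out["value"].map(repr)
    out.to_csv(metrics_path, index=False)


def write_metric_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.reset_index()
    for col in table.columns:
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else repr(v))
    out.to_csv(path, index=False)


def read_metric_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df.set_index(["subject_id", "side", "session"])


def read_metric_registry(path: str | Path) -> dict[str, MetricDescriptor]:
    """Read a YAML list of metric descriptors keyed by metric name."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    registry = {}
    for e in entries:
        d = MetricDescriptor(
            metric_name=e["metric_name"],
            family=e["family"],
            phase=e["phase"],
            worse_direction=e["worse_direction"],
            support_min=float(e.get("support_min", -math.inf)),
            support_max=float(e.get("support_max", math.inf)),
        )
        if d.metric_name in registry:
            raise SchemaError(f"duplicate registry entry {d.metric_name!r}")
        registry[d.metric_name] = d
    return registry


def write_metric_registry(
    registry: dict[str, MetricDescriptor], path: str | Path
) -> None:
    entries = []
    for d in registry.values():
        e = {
            "metric_name": d.metric_name,
            "family": d.family,
            "phase": d.phase,
            "worse_direction": d.worse_direction,
        }
        if math.isfinite(d.support_min):
            e["support_min"] = float(d.support_min)
        if math.isfinite(d.support_max):
            e["support_max"] = float(d.support_max)
        entries.append(e)
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)
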