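"""Core domain types and trial-to-subject aggregation.

The package keeps per-trial metric values in a long-format observation table
(one row per subject x side x session x repetition x peg x metric) and
collapses them to a wide *metric table* (one row per subject x side x session,
one column per metric) by taking the grand median across pegs and repetitions.
All downstream analyses treat each tested body side as an analysis unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

GROUPS = ("intact", "stroke", "ms", "arsacs")
SIDES = ("left", "right")
SESSIONS = ("test", "retest")

METRIC_FAMILIES = (
    "smoothness",
    "efficiency",
    "curvature",
    "speed",
    "endpoint_error",
    "haptic",
    "counts",
    "drops",
    "gf_scaling",
    "gf_coordination",
    "overall",
    "control",
)

PHASES = (
    "transport",
    "return",
    "peg_approach",
    "hole_approach",
    "buildup",
    "release",
    "whole_trial",
)

#: Columns of the long-format observation table.
OBSERVATION_COLUMNS = (
    "subject_id",
    "side",
    "session",
    "repetition",
    "peg",
    "metric_name",
    "value",
)

#: Index levels of the aggregated metric table.
UNIT_INDEX = ("subject_id", "side", "session")


class SchemaError(ValueError):
    """A delimited-text input does not conform to the documented schema."""


class IntegrityError(ValueError):
    """Referential integrity between subjects and observations is violated."""


@dataclass(frozen=True)
class SubjectRecord:
    """Demographics and clinical scores for one participant.

    ``clinical_scores`` may hold ``fma_ue`` (0-66, stroke), ``arat``
    (0-57, multiple sclerosis) and ``nhpt`` (seconds, ARSACS).
    """

    subject_id: str
    group: str
    age: float
    sex: str
    dominant_side: str
    stereo_deficit: bool
    clinical_scores: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.dominant_side not in SIDES:
            raise ValueError(f"unknown dominant side {self.dominant_side!r}")
        if not np.isfinite(self.age) or self.age <= 0:
            raise ValueError("age must be a positive number of years")
        cs = self.clinical_scores
        if "fma_ue" in cs and not 0 <= cs["fma_ue"] <= 66:
            raise ValueError("FMA-UE outside [0, 66]")
        if "arat" in cs and not 0 <= cs["arat"] <= 57:
            raise ValueError("ARAT outside [0, 57]")
        if "nhpt" in cs and not cs["nhpt"] > 0:
            raise ValueError("NHPT must be > 0 s")

    def dominant_tested(self, side: str) -> bool:
        """Whether testing ``side`` uses the dominant hand."""
        return side == self.dominant_side


@dataclass(frozen=True)
class MetricDescriptor:
    """Registry entry declaring how a metric behaves in the pipeline.

    ``worse_direction`` orients normalization and the ROC analysis so that
    "higher = worse task performance" holds for every metric; it must be
    declared for every metric entering selection.
    """

    metric_name: str
    family: str
    phase: str
    worse_direction: str  # "higher_is_worse" | "lower_is_worse"
    support_min: float = -np.inf
    support_max: float = np.inf

    def __post_init__(self):
        if self.family not in METRIC_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.worse_direction not in ("higher_is_worse", "lower_is_worse"):
            raise ValueError(f"unknown worse_direction {self.worse_direction!r}")

    @property
    def sign(self) -> int:
        """+1 if larger raw values mean worse performance, else -1."""
        return 1 if self.worse_direction == "higher_is_worse" else -1


def validate_observations(obs: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format observation table and return it.

    Checks column presence, finite values, categorical levels and uniqueness
    of the (subject, side, session, repetition, peg, metric) key.
    """
    missing = set(OBSERVATION_COLUMNS) - set(obs.columns)
    if missing:
        raise SchemaError(f"observation table missing columns: {sorted(missing)}")
    if not np.isfinite(obs["value"].to_numpy(dtype=float)).all():
        bad = obs.index[~np.isfinite(obs["value"].to_numpy(dtype=float))][0]
        raise SchemaError(f"non-finite metric value at row {bad}")
    for col, levels in (("side", SIDES), ("session", SESSIONS)):
        unknown = set(obs[col].unique()) - set(levels)
        if unknown:
            raise SchemaError(f"unknown {col} levels: {sorted(unknown)}")
    key = list(OBSERVATION_COLUMNS[:-1])
    if obs.duplicated(subset=key).any():
        dup = obs[obs.duplicated(subset=key, keep=False)].iloc[0]
        raise SchemaError(
            "duplicate observation key "
            f"({dup['subject_id']}, {dup['side']}, {dup['session']}, "
            f"rep {dup['repetition']}, peg {dup['peg']}, {dup['metric_name']})"
        )
    return obs


def check_integrity(subjects: list[SubjectRecord], obs: pd.DataFrame) -> None:
    """Every observation must reference a known subject."""
    known = {s.subject_id for s in subjects}
    unknown = set(obs["subject_id"].unique()) - known
    if unknown:
        raise IntegrityError(
            f"observations reference unknown subject ids: {sorted(unknown)}"
        )


def aggregate_trials(obs: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-trial observations to the grand median per unit.

    Returns a wide table indexed by (subject_id, side, session) with one
    column per metric.  The median is taken over all available
    (repetition, peg) trials; even-length groups use the mean of the two
    middle order statistics, missing trials are simply absent.
    """
    if len(obs) == 0:
        raise ValueError("no observations to aggregate")
    validate_observations(obs)
    wide = (
        obs.groupby(list(UNIT_INDEX) + ["metric_name"], sort=True)["value"]
        .median()
        .unstack("metric_name")
    )
    wide.columns.name = None
    return wide


def subjects_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Subject records as a DataFrame indexed by subject_id."""
    rows = []
    for s in subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": s.age,
                "sex": s.sex,
                "dominant_side": s.dominant_side,
                "stereo_deficit": s.stereo_deficit,
                "fma_ue": s.clinical_scores.get("fma_ue", np.nan),
                "arat": s.clinical_scores.get("arat", np.nan),
                "nhpt": s.clinical_scores.get("nhpt", np.nan),
            }
        )
    df = pd.DataFrame(rows).set_index("subject_id")
    if df.index.duplicated().any():
        raise IntegrityError("duplicate subject ids")
    return df


def design_row(subject: SubjectRecord, side: str) -> np.ndarray:
    """Covariate vector (age, sex, tested side, handedness, stereo deficit).

    Categorical coding: sex male=0/female=1; side left=0/right=1;
    handedness = 1 when the tested side is the dominant one; stereo
    deficit true=1.  Reference level is therefore a male, left-side-tested,
    non-dominant-tested subject without stereo deficits.
    """
    return np.array(
        [
            subject.age,
            1.0 if subject.sex == "female" else 0.0,
            1.0 if side == "right" else 0.0,
            1.0 if subject.dominant_tested(side) else 0.0,
            1.0 if subject.stereo_deficit else 0.0,
        ]
    )


CONFOUND_NAMES = ("age", "sex", "tested_side", "handedness", "stereo_deficit")


def design_matrix(
    subjects: list[SubjectRecord], units: pd.MultiIndex | pd.Index
) -> pd.DataFrame:
    """Covariate matrix aligned to the rows of a metric table.

    ``units`` carries at least the (subject_id, side) levels of the
    aggregated table index.
    """
    by_id = {s.subject_id: s for s in subjects}
    rows = []
    for key in units:
        sid, side = key[0], key[1]
        rows.append(design_row(by_id[sid], side))
    return pd.DataFrame(rows, index=units, columns=CONFOUND_NAMES)
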