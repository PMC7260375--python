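"""Synthetic cohorts and scripted recordings with known ground truth.

The cohort generator emulates the statistical structure the selection
framework assumes: per-metric values arise in a transformed (latent) space
from an intercept, linear demographic confound effects, a subject random
intercept, a stable per-unit (subject x side) trait, a session shift
(controls the learning slope) and session noise (controls test-retest
reliability); affected cohorts add a severity shift calibrated through the
binormal identity ``AUC = Phi(delta / (sqrt(2) * sigma))``.  A pure-noise
control metric is drawn log-normally (mean 46.0, sd 32.2 on the original
scale, matching a total-time distribution) independently per unit, so it
carries no subject signal at all.

The recording generator scripts pick-and-place trials from minimum-jerk
segments between board waypoints and sigmoidal grip-force profiles crossing
the 2 N grasp threshold at scripted times, optionally with superimposed
submovements and sub-threshold force dips; it returns the exact phase
intervals implied by the phase definitions as ground truth.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .confounds import BoxCoxTransform
from .data import (
    MetricDescriptor,
    OBSERVATION_COLUMNS,
    SubjectRecord,
    design_row,
)
from .trajectories import (
    BoardGeometry,
    DEFAULT_GEOMETRY,
    PhaseSegmentation,
    Recording,
)

__all__ = [
    "MetricSpec",
    "CohortConfig",
    "GroundTruth",
    "gen_cohort",
    "default_metric_specs",
    "lognormal_params",
    "PegTransfer",
    "simple_script",
    "gen_recording",
]

NOISE_METRIC = "simulated_noise"
NOISE_MEAN = 46.0
NOISE_SD = 32.2


# ---------------------------------------------------------------------------
# Cohort-level generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricSpec:
    """Planted generative parameters of one synthetic metric.

    The latent between-unit variance is fixed at 1; ``icc`` sets the session
    noise via ``sigma_w^2 = 2 (1 - icc) / icc - shift^2 / 2`` (ICC(A,2)
    identity) and ``auc`` sets the affected severity shift via the binormal
    formula.  ``session_shift`` is the retest-minus-test mean change in
    latent units (negative = improvement, i.e. task learning).
    """

    name: str
    betas: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)  # age, sex, side, handed, stereo
    icc: float = 0.80
    auc: float = 0.85
    session_shift: float = -0.10
    trial_sd: float = 0.30
    intercept: float = 3.0
    link_lambda: float = 0.0  # observed = inverse Box-Cox of the latent value
    latent_scale: float = 0.20  # latent sd unit on the transformed scale
    worse_direction: str = "higher_is_worse"
    factor: int | None = None
    factor_loading: float = 0.6

    def session_noise_var(self) -> float:
        if not 0.0 < self.icc <= 1.0:
            raise ValueError("icc must be in (0, 1]")
        v = 2.0 * (1.0 - self.icc) / self.icc - self.session_shift**2 / 2.0
        if v < 0:
            raise ValueError("session shift too large for the target ICC")
        return v

    def affected_shift(self) -> float:
        sig = math.sqrt(1.0 + self.session_noise_var())
        return float(stats.norm.ppf(self.auc) * math.sqrt(2.0) * sig)


def default_metric_specs() -> list[MetricSpec]:
    """Planted metrics emulating the study's survivor-grade properties."""
    return [
        MetricSpec("log_jerk_transport", betas=(0.02, 0.2, 0.1, -0.15, 0.0),
                   icc=0.80, auc=0.80, factor=0),
        MetricSpec("sparc_return", betas=(0.015, 0.0, 0.1, 0.0, 0.0),
                   icc=0.76, auc=0.75, factor=0),
        MetricSpec("path_length_ratio_transport",
                   betas=(0.01, 0.1, 0.0, -0.1, 0.0),
                   icc=0.76, auc=0.89, factor=1,
                   worse_direction="lower_is_worse"),
        MetricSpec("velocity_max_return", betas=(0.02, 0.2, 0.0, 0.0, 0.0),
                   icc=0.86, auc=0.76, factor=1,
                   worse_direction="lower_is_worse"),
        MetricSpec("gf_rate_sparc_transport", betas=(0.01, 0.0, 0.0, 0.0, 0.0),
                   icc=0.82, auc=0.74, factor=2),
        MetricSpec("gf_rate_n_peaks_hole_approach",
                   betas=(0.02, 0.1, 0.0, 0.0, 0.0),
                   icc=0.81, auc=0.91, factor=2),
    ]


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort.

    Defaults mirror the normative study design: 120 intact subjects tested on
    both sides, the first 60 with a retest session, and affected cohorts of
    53 stroke, 28 MS and 8 ARSACS subjects (tested on the affected side).
    """

    n_intact: int = 120
    n_retest: int = 60
    n_affected: dict = field(
        default_factory=lambda: {"stroke": 53, "ms": 28, "arsacs": 8}
    )
    metrics: list = field(default_factory=default_metric_specs)
    include_noise_metric: bool = True
    subject_tau2: float = 0.5  # share of between-unit variance common to sides
    n_repetitions: int = 5
    n_pegs: int = 9
    severity_gradient: float = 0.0  # couples affected shift to clinical score
    group_shifts: dict | None = None  # optional per-group latent shifts
    seed: int = 0

    def validate(self):
        if self.n_retest > self.n_intact:
            raise ValueError("n_retest cannot exceed n_intact")
        if not 0.0 <= self.subject_tau2 < 1.0:
            raise ValueError("subject_tau2 must be in [0, 1)")
        names = [m.name for m in self.metrics]
        if len(set(names)) != len(names):
            raise ValueError("duplicate metric names in config")


@dataclass
class GroundTruth:
    """Planted parameters mirrored back for recovery tests."""

    metrics: dict
    noise_metric: dict | None
    config: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"metrics": self.metrics, "noise_metric": self.noise_metric,
                 "config": self.config},
                fh, indent=2, default=str,
            )


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of log-values for a log-normal with given mean/sd."""
    s2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - s2 / 2.0, math.sqrt(s2)


def _gen_subjects(cfg: CohortConfig, rng: np.random.Generator
                  ) -> list[SubjectRecord]:
    subjects = []
    for i in range(cfg.n_intact):
        subjects.append(
            SubjectRecord(
                subject_id=f"HC{i + 1:03d}",
                group="intact",
                age=float(np.clip(rng.normal(50.0, 15.0), 20.0, 85.0)),
                sex="female" if rng.random() < 0.5 else "male",
                dominant_side="right" if rng.random() < 0.9 else "left",
                stereo_deficit=bool(rng.random() < 0.1),
            )
        )
    makers = {
        "stroke": lambda: (
            float(np.clip(rng.normal(58.0, 12.0), 25.0, 90.0)),
            {"fma_ue": int(np.clip(round(rng.normal(55.0, 9.0)), 20, 66))},
        ),
        "ms": lambda: (
            float(np.clip(rng.normal(52.0, 12.0), 20.0, 80.0)),
            {"arat": int(np.clip(round(rng.normal(50.0, 8.0)), 15, 57))},
        ),
        "arsacs": lambda: (
            float(rng.uniform(27.0, 58.0)),
            {"nhpt": float(np.exp(rng.normal(*lognormal_params(46.0, 25.0))))},
        ),
    }
    tags = {"stroke": "ST", "ms": "MS", "arsacs": "AR"}
    for group, n in cfg.n_affected.items():
        for i in range(n):
            age, scores = makers[group]()
            subjects.append(
                SubjectRecord(
                    subject_id=f"{tags[group]}{i + 1:03d}",
                    group=group,
                    age=age,
                    sex="female" if rng.random() < 0.5 else "male",
                    dominant_side="right" if rng.random() < 0.9 else "left",
                    stereo_deficit=bool(rng.random() < 0.1),
                    clinical_scores=scores,
                )
            )
    return subjects


def _severity_z(subject: SubjectRecord) -> float:
    """Crude impairment z-score from the disease-appropriate clinical scale."""
    cs = subject.clinical_scores
    if "fma_ue" in cs:
        return (55.0 - cs["fma_ue"]) / 9.0
    if "arat" in cs:
        return (50.0 - cs["arat"]) / 8.0
    if "nhpt" in cs:
        return (cs["nhpt"] - 46.0) / 25.0
    return 0.0


def gen_cohort(cfg: CohortConfig | None = None,
               seed: int | None = None
               ) -> tuple[list[SubjectRecord], pd.DataFrame, GroundTruth]:
    """Generate a full synthetic cohort with per-trial observation rows.

    Returns subject records, a long-format observation table (both sessions
    for retest subjects) and the planted ground truth.
    """
    cfg = cfg if cfg is not None else CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    subjects = _gen_subjects(cfg, rng)

    # analysis units: intact subjects on both sides, affected on one side
    units: list[tuple[SubjectRecord, str, list[str]]] = []
    for s in subjects:
        if s.group == "intact":
            i = int(s.subject_id[2:]) - 1
            sessions = ["test", "retest"] if i < cfg.n_retest else ["test"]
            for side in ("left", "right"):
                units.append((s, side, sessions))
        else:
            side = "right" if rng.random() < 0.6 else "left"
            units.append((s, side, ["test"]))

    n_factors = 1 + max(
        (m.factor for m in cfg.metrics if m.factor is not None), default=-1
    )
    subj_ids = sorted({s.subject_id for s, _, _ in units})
    trials = cfg.n_repetitions * cfg.n_pegs
    rows: list[tuple] = []
    truth_metrics: dict = {}

    for spec in cfg.metrics:
        sw2 = spec.session_noise_var()
        shift_a = spec.affected_shift()
        W = dict(zip(
            subj_ids,
            rng.normal(scale=math.sqrt(cfg.subject_tau2), size=len(subj_ids)),
        ))
        unit_sd2 = 1.0 - cfg.subject_tau2
        lam = spec.factor_loading if spec.factor is not None else 0.0
        lam = min(lam, math.sqrt(unit_sd2) - 1e-9) if lam else 0.0
        uniq_sd = math.sqrt(max(unit_sd2 - lam**2, 0.0))
        truth_metrics[spec.name] = {
            "betas": list(spec.betas),
            "icc": spec.icc,
            "auc": spec.auc,
            "session_shift": spec.session_shift,
            "affected_shift": shift_a,
            "session_noise_var": sw2,
            "worse_direction": spec.worse_direction,
            "factor": spec.factor,
        }
        sign = 1.0 if spec.worse_direction == "higher_is_worse" else -1.0
        link = BoxCoxTransform(lmbda=spec.link_lambda)
        scale = spec.latent_scale
        for s, side, sessions in units:
            x = design_row(s, side)
            base = spec.intercept + float(np.dot(spec.betas, x)) * sign
            f_scores = None
            if spec.factor is not None:
                f_scores = _unit_factors(s.subject_id, side, n_factors,
                                         cfg.seed if seed is None else seed)
            trait = W[s.subject_id] + (
                lam * f_scores[spec.factor] if f_scores is not None else 0.0
            ) + rng.normal(scale=uniq_sd)
            sev = shift_a
            if cfg.group_shifts is not None:
                sev = cfg.group_shifts.get(s.group, shift_a)
            if cfg.severity_gradient:
                sev = sev * (1.0 + cfg.severity_gradient * _severity_z(s))
            for session in sessions:
                val = base + sign * scale * trait
                if s.group != "intact":
                    val += sign * scale * sev
                if session == "retest":
                    val += sign * scale * spec.session_shift
                val += sign * scale * rng.normal(scale=math.sqrt(sw2))
                noise = rng.normal(scale=spec.trial_sd, size=trials)
                obs_vals = link.inverse(val + sign * scale * noise)
                k = 0
                for rep in range(1, cfg.n_repetitions + 1):
                    for peg in range(1, cfg.n_pegs + 1):
                        rows.append((s.subject_id, side, session, rep, peg,
                                     spec.name, float(obs_vals[k])))
                        k += 1

    noise_truth = None
    if cfg.include_noise_metric:
        mu, sig = lognormal_params(NOISE_MEAN, NOISE_SD)
        noise_truth = {"mean": NOISE_MEAN, "sd": NOISE_SD,
                       "log_mu": mu, "log_sigma": sig}
        for s, side, sessions in units:
            for session in sessions:
                val = float(np.exp(rng.normal(mu, sig)))
                for rep in range(1, cfg.n_repetitions + 1):
                    for peg in range(1, cfg.n_pegs + 1):
                        rows.append((s.subject_id, side, session, rep, peg,
                                     NOISE_METRIC, val))

    obs = pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))
    truth = GroundTruth(
        metrics=truth_metrics,
        noise_metric=noise_truth,
        config={k: v for k, v in asdict(cfg).items() if k != "metrics"},
    )
    return subjects, obs, truth


def _unit_factors(subject_id: str, side: str, k: int, seed: int) -> np.ndarray:
    """Deterministic common-factor scores per unit (shared across metrics)."""
    h = zlib.crc32(f"{subject_id}|{side}|{int(seed)}".encode()) % (2**31)
    return np.random.default_rng(h).standard_normal(k)


def cohort_registry(cfg: CohortConfig) -> dict[str, MetricDescriptor]:
    """Metric descriptors matching a cohort config (orientation registry)."""
    reg = {}
    for m in cfg.metrics:
        reg[m.name] = MetricDescriptor(
            metric_name=m.name, family="smoothness", phase="whole_trial",
            worse_direction=m.worse_direction,
        )
    if cfg.include_noise_metric:
        reg[NOISE_METRIC] = MetricDescriptor(
            metric_name=NOISE_METRIC, family="control", phase="whole_trial",
            worse_direction="higher_is_worse",
        )
    return reg


# ---------------------------------------------------------------------------
# Recording-level generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PegTransfer:
    """Scripted timing of one peg transfer (seconds from recording start)."""

    peg: int  # 1..9
    grasp_time: float
    transport_start: float
    transport_end: float
    insert_time: float
    n_submovements: int = 0
    submovement_amplitude: float = 0.02  # m, out-and-back corrective bump
    force_dip_times: tuple = ()

    def validate(self):
        if not (self.grasp_time < self.transport_start < self.transport_end
                < self.insert_time):
            raise ValueError("transfer event times must be ordered")


def simple_script(pegs=range(1, 10), cycle: float = 2.2) -> list[PegTransfer]:
    """A clean evenly paced script: one transfer every ``cycle`` seconds."""
    out = []
    for i, p in enumerate(pegs):
        b = i * cycle
        out.append(PegTransfer(
            peg=int(p), grasp_time=b + 0.6, transport_start=b + 0.8,
            transport_end=b + 1.3, insert_time=b + 1.6,
        ))
    return out


def _minjerk(tau: np.ndarray) -> np.ndarray:
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


_MJ_ONSET_TAU = None


def _minjerk_threshold_tau(frac: float = 0.1) -> float:
    """Normalized time at which min-jerk speed first reaches frac * peak."""
    global _MJ_ONSET_TAU
    if _MJ_ONSET_TAU is None:
        tau = np.linspace(0, 0.5, 200001)
        v = 30 * tau**2 * (1 - tau) ** 2
        _MJ_ONSET_TAU = float(tau[np.searchsorted(v, frac * 1.875)])
    return _MJ_ONSET_TAU


def gen_recording(
    script: list[PegTransfer],
    geometry: BoardGeometry = DEFAULT_GEOMETRY,
    fs: float = 1000.0,
    position_noise_sd: float = 0.0,
    force_noise_sd: float = 0.0,
    seed: int = 0,
    start_offset: np.ndarray | None = None,
) -> tuple[Recording, PhaseSegmentation]:
    """Synthesize a recording from a script, with ground-truth phases.

    Movements are minimum-jerk segments between waypoints; the grip force is
    a sigmoid crossing the grasp threshold exactly at the scripted grasp and
    insert times.  Ground-truth transport/return intervals use the ballistic
    definition (10% of peak speed), evaluated analytically on the noise-free
    profile.
    """
    script = sorted(script, key=lambda e: e.grasp_time)
    for a, b in zip(script, script[1:]):
        a.validate()
        if a.insert_time >= b.grasp_time:
            raise ValueError("overlapping transfer events")
    script[-1].validate()
    rng = np.random.default_rng(seed)
    T = script[-1].insert_time + 0.8
    n = int(round(T * fs)) + 1
    t = np.arange(n) / fs
    pos = np.zeros((n, 3))
    gf = np.full(n, 0.5)
    active = np.zeros(n, dtype=int)

    start = (geometry.pegs[script[0].peg - 1]
             + (np.array([-0.05, 0.02, 0.0]) if start_offset is None
                else start_offset))

    def add_move(t0, t1, a, b):
        tau = (t - t0) / (t1 - t0)
        w = (t >= t0) & (t <= t1)
        shape = _minjerk(tau[w])
        pos[w] += np.outer(shape, b - a)
        pos[t > t1] += (b - a)

    def add_bump(t0, t1, direction, amp):
        # out-and-back submovement: net displacement zero, two speed bumps
        mid = 0.5 * (t0 + t1)
        add_move(t0, mid, np.zeros(3), amp * direction)
        add_move(mid, t1, amp * direction, np.zeros(3))

    pos += start
    # initial approach to the first peg
    first_peg = geometry.pegs[script[0].peg - 1]
    approach_end = script[0].grasp_time - 0.1
    add_move(0.1, max(approach_end, 0.2), start, first_peg)

    sig_w = 0.05  # s, force sigmoid time constant
    off = sig_w * math.log(
        (5.0 - 0.5) / (geometry.force_threshold - 0.5) - 1.0
    )  # sigmoid offset putting the threshold crossing at the scripted time

    truth = PhaseSegmentation(fs=fs)
    tau_on = _minjerk_threshold_tau(0.1)
    lifts = []
    for i, ev in enumerate(script):
        peg_xyz = geometry.pegs[ev.peg - 1]
        hole_xyz = geometry.holes[ev.peg - 1]
        add_move(ev.transport_start, ev.transport_end, peg_xyz, hole_xyz)
        direction = (hole_xyz - peg_xyz)
        direction = direction / np.linalg.norm(direction)
        # corrective submovements: late, perpendicular to the main direction,
        # so they appear as distinct speed peaks rather than merging
        perp = np.cross(direction, np.array([0.0, 0.0, 1.0]))
        if np.linalg.norm(perp) < 1e-9:
            perp = np.array([1.0, 0.0, 0.0])
        perp = perp / np.linalg.norm(perp)
        # placed in the deceleration tail (may spill slightly past the
        # scripted transport end, like a real terminal correction); slow
        # enough (~3 Hz content) to survive the 8 Hz preprocessing filter
        for k in range(ev.n_submovements):
            dur = ev.transport_end - ev.transport_start
            t0 = ev.transport_start + (0.85 - 0.12 * k) * dur
            t1 = min(t0 + 0.7 * dur, ev.insert_time - 0.05)
            add_bump(t0, t1, perp, ev.submovement_amplitude)
        # grasp / release sigmoids crossing the threshold at scripted times
        gf += (5.0 - 0.5) / (1.0 + np.exp(-(t - ev.grasp_time - off) / sig_w))
        gf -= (5.0 - 0.5) / (1.0 + np.exp(-(t - ev.insert_time + off) / sig_w))
        for td in ev.force_dip_times:
            gf -= 4.0 * np.exp(-((t - td) ** 2) / (2 * 0.03**2))
        lift = (t >= ev.grasp_time) & (t < ev.insert_time)
        active[lift] = ev.peg
        lifts.append((ev.peg, ev.grasp_time, ev.insert_time))

        dur = ev.transport_end - ev.transport_start
        tr = (ev.transport_start + tau_on * dur,
              ev.transport_end - tau_on * dur)
        ph = {
            "transport": _to_idx(tr, fs),
            "hole_approach": _to_idx((tr[1], ev.insert_time), fs),
        }
        if i + 1 < len(script):
            nxt = script[i + 1]
            next_peg = geometry.pegs[nxt.peg - 1]
            r0, r1 = ev.insert_time + 0.1, min(ev.insert_time + 0.7,
                                               nxt.grasp_time - 0.1)
            add_move(r0, r1, hole_xyz, next_peg)
            rdur = r1 - r0
            ret = (r0 + tau_on * rdur, r1 - tau_on * rdur)
            ph["return"] = _to_idx(ret, fs)
            truth.phases.setdefault(nxt.peg, {})["peg_approach"] = _to_idx(
                (ret[1], nxt.grasp_time), fs
            )
        truth.phases.setdefault(ev.peg, {}).update(ph)
    # first-peg approach ground truth: end of initial approach to grasp
    adur = max(approach_end, 0.2) - 0.1
    truth.phases.setdefault(script[0].peg, {}).setdefault(
        "peg_approach",
        _to_idx((max(approach_end, 0.2) - tau_on * adur, script[0].grasp_time),
                fs),
    )
    truth._lifts = [
        (p, int(round(a * fs)), int(round(b * fs))) for p, a, b in lifts
    ]

    if position_noise_sd > 0:
        pos = pos + rng.normal(scale=position_noise_sd, size=pos.shape)
    if force_noise_sd > 0:
        gf = gf + rng.normal(scale=force_noise_sd, size=gf.shape)
    rec = Recording(
        time=t, position=pos, grip_force=gf, active_peg=active,
        geometry=geometry,
    )
    return rec, truth


def _to_idx(interval: tuple[float, float], fs: float) -> tuple[int, int]:
    return int(round(interval[0] * fs)), int(round(interval[1] * fs))
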