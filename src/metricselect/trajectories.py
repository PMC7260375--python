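"""Kinematic and kinetic metric extraction from raw pick-and-place recordings.

A recording holds time, 3-D cursor position (metres), grip force (N), an
active-peg indicator (0 = no peg lifted) and optionally a vertical
interaction-force channel, nominally sampled at 1 kHz.  Preprocessing
resamples to a uniform grid (linearly bridging dropouts), builds the 1-D
distance trajectory d(t) from the 3-D path and low-pass filters every signal
with a zero-phase 4th-order Butterworth at 8 Hz before and after each time
derivative (velocity = first, jerk = third derivative of d).

Each peg transfer is segmented into transport (ballistic carry to the hole),
hole approach (end of transport until insertion), return (ballistic move to
the next peg) and peg approach (end of return until the next pickup), plus
grip-force buildup and release intervals around the extrema of the grip
force rate between approach and insertion.  Ballistic onsets/ends are the
crossings of 10% of the segment's peak speed.

Per-phase metrics cover movement smoothness (dimensionless jerk, log jerk,
spectral arc length, velocity-peak count, time/distance to peak velocity),
efficiency (path length ratio, throughput), curvature (trajectory error,
initial movement angles), speed, endpoint error, haptic collisions, grip
force scaling and coordination, object drops, movement counts and the task
completion time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .data import OBSERVATION_COLUMNS

__all__ = [
    "BoardGeometry",
    "DEFAULT_GEOMETRY",
    "Recording",
    "Signals",
    "PhaseSegmentation",
    "preprocess",
    "segment_phases",
    "sparc",
    "dimensionless_jerk",
    "kinematic_metrics",
    "kinetic_metrics",
    "extract_trial_metrics",
    "recording_to_observations",
    "read_recording",
    "write_recording",
]

SPEED_ONSET_FRACTION = 0.1  # ballistic start/end: 10% of segment peak speed
PEAK_PROMINENCE_FRACTION = 0.05
SPARC_FC = 20.0  # Hz
SPARC_AMP_THRESHOLD = 0.05
FILTER_CUTOFF_HZ = 8.0
GAP_SAMPLES = 50


@dataclass(frozen=True)
class BoardGeometry:
    """Peg/hole coordinates (metres) with tolerance radius and grasp threshold."""

    pegs: np.ndarray  # (9, 3)
    holes: np.ndarray  # (9, 3)
    tolerance: float = 0.003  # m
    force_threshold: float = 2.0  # N


def _grid(x0: float) -> np.ndarray:
    xs = [x0, x0 + 0.03, x0 + 0.06]
    ys = [-0.04, 0.0, 0.04]
    return np.array([[x, y, 0.0] for y in ys for x in xs])


DEFAULT_GEOMETRY = BoardGeometry(pegs=_grid(-0.10), holes=_grid(0.04))


@dataclass
class Recording:
    """Raw sensor data of one repetition (all nine pegs once)."""

    time: np.ndarray
    position: np.ndarray  # (n, 3) metres
    grip_force: np.ndarray  # N
    active_peg: np.ndarray  # int, 0 = none
    geometry: BoardGeometry = DEFAULT_GEOMETRY
    interaction_force_z: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.time)
        if not (len(self.position) == len(self.grip_force)
                == len(self.active_peg) == n):
            raise ValueError("channel lengths differ")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        fs = 1.0 / np.median(np.diff(self.time))
        if not 100.0 <= fs <= 2000.0:
            raise ValueError(f"sample rate {fs:.0f} Hz outside [100, 2000]")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))


@dataclass
class Signals:
    """Preprocessed, uniformly sampled signals of one recording."""

    t: np.ndarray
    fs: float
    position: np.ndarray
    distance: np.ndarray  # cumulative path distance d(t)
    speed: np.ndarray  # d'
    jerk: np.ndarray  # d'''
    grip_force: np.ndarray
    grip_force_rate: np.ndarray
    active_peg: np.ndarray
    interaction_force_z: np.ndarray | None = None


@dataclass
class PhaseSegmentation:
    """Half-open sample intervals per peg and phase (0-based indices)."""

    phases: dict = field(default_factory=dict)  # peg -> {phase: (start, end)}
    fs: float = 1000.0

    def interval(self, peg: int, phase: str):
        return self.phases.get(peg, {}).get(phase)

    def pegs(self):
        return sorted(self.phases)


def _lowpass(x: np.ndarray, fs: float, fc: float = FILTER_CUTOFF_HZ) -> np.ndarray:
    b, a = sps.butter(4, fc / (fs / 2.0))
    padlen = min(3 * max(len(a), len(b)), len(x) - 1)
    return sps.filtfilt(b, a, x, padlen=padlen)


def _derivative(x: np.ndarray, fs: float) -> np.ndarray:
    return _lowpass(np.gradient(x) * fs, fs)


def preprocess(recording: Recording) -> Signals:
    """Resample to a uniform grid, filter, and derive speed/jerk/force rate.

    Temporal gaps larger than ``GAP_SAMPLES`` nominal samples are bridged by
    the linear resampling; continuous channels are interpolated linearly and
    the active-peg indicator by previous-sample hold.
    """
    t = recording.time
    if t[-1] - t[0] < 1.0:
        raise ValueError("need at least 1 s of data")
    dt = float(np.median(np.diff(t)))
    tu = np.arange(t[0], t[-1] + dt / 2, dt)
    fs = 1.0 / dt

    pos = np.column_stack(
        [np.interp(tu, t, recording.position[:, k]) for k in range(3)]
    )
    gf = np.interp(tu, t, recording.grip_force)
    idx_prev = np.searchsorted(t, tu, side="right") - 1
    peg = recording.active_peg[np.clip(idx_prev, 0, len(t) - 1)]
    fz = None
    if recording.interaction_force_z is not None:
        fz = _lowpass(np.interp(tu, t, recording.interaction_force_z), fs)

    pos_f = np.column_stack([_lowpass(pos[:, k], fs) for k in range(3)])
    step = np.linalg.norm(np.diff(pos_f, axis=0), axis=1)
    d = np.r_[0.0, np.cumsum(step)]
    d = _lowpass(d, fs)
    v = _derivative(d, fs)
    a = _derivative(v, fs)
    j = _derivative(a, fs)
    gf_f = _lowpass(gf, fs)
    gfr = _derivative(gf_f, fs)
    return Signals(
        t=tu, fs=fs, position=pos_f, distance=d, speed=v, jerk=j,
        grip_force=gf_f, grip_force_rate=gfr, active_peg=peg,
        interaction_force_z=fz,
    )


def _ballistic(speed: np.ndarray, start: int, end: int):
    """(onset, end) of the ballistic portion within [start, end)."""
    if end - start < 3:
        return None
    seg = np.abs(speed[start:end])
    peak = seg.max()
    if peak <= 0:
        return None
    thr = SPEED_ONSET_FRACTION * peak
    ipk = int(np.argmax(seg))
    below_before = np.flatnonzero(seg[: ipk + 1] < thr)
    onset = int(below_before[-1]) + 1 if below_before.size else 0
    below_after = np.flatnonzero(seg[ipk:] < thr)
    stop = ipk + int(below_after[0]) if below_after.size else len(seg)
    return start + onset, start + stop


def _rate_extremum_interval(rate: np.ndarray, start: int, end: int, sign: int):
    """Contiguous interval around the signed grip-force-rate extremum."""
    if end - start < 3:
        return None
    seg = sign * rate[start:end]
    ipk = int(np.argmax(seg))
    peak = seg[ipk]
    if peak <= 0:
        return None
    thr = SPEED_ONSET_FRACTION * peak
    below_before = np.flatnonzero(seg[: ipk + 1] < thr)
    onset = int(below_before[-1]) + 1 if below_before.size else 0
    below_after = np.flatnonzero(seg[ipk:] < thr)
    stop = ipk + int(below_after[0]) if below_after.size else len(seg)
    return start + onset, start + stop


def segment_phases(recording: Recording, signals: Signals | None = None
                   ) -> PhaseSegmentation:
    """Segment each peg transfer into its task phases.

    Pickup/insertion events come from the active-peg indicator (rising and
    falling edges of each peg id); a recording in which no grasp ever crosses
    the force threshold yields zero transports.
    """
    s = signals if signals is not None else preprocess(recording)
    peg = np.asarray(s.active_peg, dtype=int)
    edges = np.flatnonzero(np.diff(peg) != 0) + 1
    events = []  # (sample, peg, kind)
    for e in edges:
        if peg[e] != 0:
            events.append((int(e), int(peg[e]), "pickup"))
        if peg[e - 1] != 0 and peg[e] != peg[e - 1]:
            events.append((int(e), int(peg[e - 1]), "insert"))
    if peg[0] != 0:
        events.insert(0, (0, int(peg[0]), "pickup"))
    if peg[-1] != 0:
        events.append((len(peg), int(peg[-1]), "insert"))

    lifts = []  # (peg, pickup_idx, insert_idx)
    open_pick = {}
    for idx, p, kind in events:
        if kind == "pickup":
            open_pick[p] = idx
        elif p in open_pick:
            lifts.append((p, open_pick.pop(p), idx))
    lifts.sort(key=lambda x: x[1])

    seg = PhaseSegmentation(fs=s.fs)
    n = len(peg)
    for li, (p, pick, ins) in enumerate(lifts):
        ph: dict[str, tuple[int, int]] = {}
        ball = _ballistic(s.speed, pick, ins)
        if ball is not None:
            ph["transport"] = ball
            ph["hole_approach"] = (ball[1], ins)
        ret_end = lifts[li + 1][1] if li + 1 < len(lifts) else n
        if ret_end - ins > 2:
            ball_r = _ballistic(s.speed, ins, ret_end)
            if ball_r is not None:
                ph["return"] = ball_r
                if li + 1 < len(lifts):
                    # approach to the *next* peg
                    nxt = lifts[li + 1][0]
                    seg.phases.setdefault(nxt, {})["peg_approach"] = (
                        ball_r[1], lifts[li + 1][1],
                    )
        approach_start = seg.phases.get(p, {}).get("peg_approach", (max(pick - int(s.fs), 0),))[0]
        bu = _rate_extremum_interval(s.grip_force_rate, approach_start, ins, +1)
        rl = _rate_extremum_interval(
            s.grip_force_rate, approach_start,
            min(ins + int(0.25 * s.fs), n), -1,
        )
        if bu is not None:
            ph["buildup"] = bu
        if rl is not None:
            ph["release"] = rl
        seg.phases.setdefault(p, {}).update(ph)
    # first peg approach: from recording start to first pickup
    if lifts:
        p0, pick0, _ = lifts[0]
        if "peg_approach" not in seg.phases.get(p0, {}) and pick0 > 2:
            ball0 = _ballistic(s.speed, 0, pick0)
            start0 = ball0[1] if ball0 is not None else 0
            seg.phases.setdefault(p0, {})["peg_approach"] = (start0, pick0)
    seg._lifts = lifts
    return seg


# ---------------------------------------------------------------------------
# Smoothness primitives
# ---------------------------------------------------------------------------


def sparc(speed, fs: float, padlevel: int = 4,
          fc: float = SPARC_FC, amp_threshold: float = SPARC_AMP_THRESHOLD
          ) -> float:
    """Spectral arc length of a speed profile (negative; 0 would be ideal).

    Arc length of the amplitude-normalized magnitude spectrum up to ``fc``,
    restricted to the adaptive band where the spectrum exceeds
    ``amp_threshold``; more submovements lengthen the spectrum's arc and make
    the value more negative.
    """
    v = np.asarray(speed, dtype=float)
    if v.size < 4 or np.max(np.abs(v)) == 0:
        return np.nan
    nfft = int(2 ** math.ceil(math.log2(v.size) + padlevel))
    f = np.arange(nfft) * (fs / nfft)
    mag = np.abs(np.fft.fft(v, nfft))
    mag = mag / mag.max()
    sel = f <= fc
    f_sel, m_sel = f[sel], mag[sel]
    above = np.flatnonzero(m_sel >= amp_threshold)
    band = slice(above[0], above[-1] + 1)
    f_b, m_b = f_sel[band], m_sel[band]
    if f_b.size < 2:
        return 0.0
    df = np.diff(f_b) / (f_b[-1] - f_b[0])
    return -float(np.sum(np.sqrt(df**2 + np.diff(m_b) ** 2)))


def dimensionless_jerk(jerk, duration: float, length: float, fs: float) -> float:
    """Time-integrated squared jerk scaled by duration^5 / length^2."""
    if length <= 0 or duration <= 0:
        return np.nan
    j = np.asarray(jerk, dtype=float)
    return float(np.sum(j**2) / fs * duration**5 / length**2)


def _horizontal(vec: np.ndarray) -> np.ndarray:
    return vec[..., :2]


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return np.nan
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return math.degrees(math.acos(c))


def _line_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray
                   ) -> np.ndarray:
    ab = b - a
    denom = np.dot(ab, ab)
    if denom == 0:
        return np.linalg.norm(points - a, axis=1)
    tt = (points - a) @ ab / denom
    proj = a + np.outer(tt, ab)
    return np.linalg.norm(points - proj, axis=1)


# ---------------------------------------------------------------------------
# Per-phase metric computation
# ---------------------------------------------------------------------------


def kinematic_metrics(
    s: Signals, start: int, end: int, target: np.ndarray | None = None,
    geometry: BoardGeometry = DEFAULT_GEOMETRY, throughput_shannon: bool = False,
) -> dict:
    """Kinematic metrics on one segment ``[start, end)``.

    ``target`` (3-vector) enables throughput and the initial-movement-angle
    and trajectory-error metrics, which need the ideal straight path.
    """
    if end - start < 10:
        return {}
    sl = slice(start, end)
    speed = np.abs(s.speed[sl])
    pos = s.position[sl]
    t = s.t[sl]
    duration = float(t[-1] - t[0])
    # path length from the filtered position steps: chord <= path by construction
    path = float(np.sum(np.linalg.norm(np.diff(pos, axis=0), axis=1)))
    straight = float(np.linalg.norm(pos[-1] - pos[0]))
    out = {}
    out["jerk"] = dimensionless_jerk(s.jerk[sl], duration, path, s.fs)
    out["log_jerk"] = float(np.log(out["jerk"])) if out["jerk"] and out["jerk"] > 0 else np.nan
    out["sparc"] = sparc(speed, s.fs)
    peaks, _ = sps.find_peaks(
        speed, prominence=PEAK_PROMINENCE_FRACTION * speed.max()
    )
    out["n_velocity_peaks"] = max(int(peaks.size), 1 if speed.max() > 0 else 0)
    ipk = int(np.argmax(speed))
    out["time_to_max_velocity"] = float(ipk / max(end - start - 1, 1))
    covered = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(pos, axis=0), axis=1))]
    out["distance_to_max_velocity"] = (
        float(covered[ipk] / path) if path > 0 else np.nan
    )
    out["velocity_mean"] = float(np.mean(speed))
    out["velocity_max"] = float(np.max(speed))
    out["path_length_ratio"] = straight / path if path > 0 else np.nan

    if target is not None:
        a, b = pos[0], np.asarray(target, dtype=float)
        D = float(np.linalg.norm(b - a))
        W = 2.0 * geometry.tolerance
        if duration > 0 and D > 0:
            out["throughput"] = (
                math.log2(D / W + 1.0) / duration
                if throughput_shannon
                else (D / W) / duration
            )
        err = _line_distance(pos, a, b)
        out["trajectory_error_mean"] = float(np.mean(err))
        out["trajectory_error_max"] = float(np.max(err))
        ideal = _horizontal(b - a)
        disp = np.linalg.norm(_horizontal(pos - a), axis=1)
        for name, cond in (
            ("theta1", disp >= 0.2 * D),
            ("theta2", covered >= 0.2 * path),
        ):
            hit = np.flatnonzero(cond)
            idx = int(hit[0]) if hit.size else len(pos) - 1
            out[f"initial_angle_{name}"] = _angle_between(
                _horizontal(pos[idx] - a), ideal
            )
        out["initial_angle_theta3"] = _angle_between(
            _horizontal(pos[ipk] - a), ideal
        )
    if s.interaction_force_z is not None:
        fz = np.abs(s.interaction_force_z[sl])
        out["haptic_collisions_mean"] = float(np.mean(fz))
        out["haptic_collisions_max"] = float(np.max(fz))
    return out


def position_error(s: Signals, start: int, end: int, target: np.ndarray
                   ) -> float:
    """Horizontal cursor-to-target distance summed over the phase samples."""
    if end - start < 1:
        return np.nan
    d = np.linalg.norm(
        _horizontal(s.position[start:end]) - _horizontal(np.asarray(target)),
        axis=1,
    )
    return float(np.sum(d))


def kinetic_metrics(s: Signals, start: int, end: int) -> dict:
    """Grip-force scaling and coordination metrics on one segment."""
    if end - start < 10:
        return {}
    sl = slice(start, end)
    gf = s.grip_force[sl]
    gfr = s.grip_force_rate[sl]
    out = {
        "gf_mean": float(np.mean(gf)),
        "gf_max": float(np.max(gf)),
        "gf_rate_mean": float(np.mean(np.abs(gfr))),
        "gf_rate_max": float(np.max(np.abs(gfr))),
    }
    scale = np.max(np.abs(gfr))
    if scale > 0:
        prom = PEAK_PROMINENCE_FRACTION * scale
        pos_pk, _ = sps.find_peaks(gfr, prominence=prom)
        neg_pk, _ = sps.find_peaks(-gfr, prominence=prom)
        out["gf_rate_n_peaks"] = int(pos_pk.size + neg_pk.size)
        out["gf_rate_sparc"] = sparc(np.abs(gfr), s.fs)
    else:
        out["gf_rate_n_peaks"] = 0
        out["gf_rate_sparc"] = np.nan
    return out


def count_dropped_pegs(s: Signals, seg: PhaseSegmentation,
                       threshold: float = 2.0) -> int:
    """Grip-force dips below threshold while a peg is lifted.

    A dip counts only if the force recovers above the threshold before the
    lift ends (the terminal release is the insertion, not a drop).
    """
    drops = 0
    for _, pick, ins in getattr(seg, "_lifts", []):
        gf = s.grip_force[pick:ins]
        below = gf < threshold
        falls = np.flatnonzero(np.diff(below.astype(int)) == 1)
        rises = np.flatnonzero(np.diff(below.astype(int)) == -1)
        for f in falls:
            if np.any(rises > f):
                drops += 1
    return drops


_PHASE_SUFFIX = {
    "transport": "transport",
    "return": "return",
    "peg_approach": "peg_approach",
    "hole_approach": "hole_approach",
    "buildup": "buildup",
    "release": "release",
}


def extract_trial_metrics(recording: Recording,
                          throughput_shannon: bool = False) -> dict:
    """All per-phase metrics of one recording, keyed by metric name.

    Per-peg values are averaged over pegs here only for the trial-level
    counters; phase metrics are returned per peg under
    ``(metric_name, peg)`` so that the caller can emit trial-granular
    observation rows.
    """
    s = preprocess(recording)
    seg = segment_phases(recording, s)
    geom = recording.geometry
    per_peg: dict[tuple[str, int], float] = {}
    n_onsets = 0
    n_ends = 0
    for p in seg.pegs():
        for phase in ("transport", "return"):
            iv = seg.interval(p, phase)
            if iv is None:
                continue
            n_onsets += 1
            n_ends += 1
            target = geom.holes[p - 1] if phase == "transport" else None
            if phase == "return":
                nxt = p + 1
                if nxt <= len(geom.pegs):
                    target = geom.pegs[nxt - 1]
            km = kinematic_metrics(s, *iv, target=target, geometry=geom,
                                   throughput_shannon=throughput_shannon)
            for name, val in km.items():
                per_peg[(f"{name}_{_PHASE_SUFFIX[phase]}", p)] = val
            for name, val in kinetic_metrics(s, *iv).items():
                per_peg[(f"{name}_{_PHASE_SUFFIX[phase]}", p)] = val
        for phase, target in (
            ("peg_approach", geom.pegs[p - 1]),
            ("hole_approach", geom.holes[p - 1]),
        ):
            iv = seg.interval(p, phase)
            if iv is None:
                continue
            km = kinematic_metrics(s, *iv, target=None, geometry=geom)
            for name in ("jerk", "log_jerk", "sparc"):
                if name in km:
                    per_peg[(f"{name}_{_PHASE_SUFFIX[phase]}", p)] = km[name]
            per_peg[(f"position_error_{_PHASE_SUFFIX[phase]}", p)] = (
                position_error(s, *iv, target=target)
            )
            for name, val in kinetic_metrics(s, *iv).items():
                per_peg[(f"{name}_{_PHASE_SUFFIX[phase]}", p)] = val
        for phase in ("buildup", "release"):
            iv = seg.interval(p, phase)
            if iv is None:
                continue
            for name, val in kinetic_metrics(s, *iv).items():
                if name.startswith("gf_rate_"):
                    per_peg[(f"{name}_{phase}", p)] = val
            per_peg[(f"gf_{phase}_duration", p)] = (iv[1] - iv[0]) / s.fs

    trial: dict[str, float] = {
        "n_movement_onsets": float(n_onsets),
        "n_movement_ends": float(n_ends),
        "n_dropped_pegs": float(
            count_dropped_pegs(s, seg, geom.force_threshold)
        ),
    }
    lifts = getattr(seg, "_lifts", [])
    if lifts:
        first = seg.interval(lifts[0][0], "transport")
        start = first[0] if first is not None else lifts[0][1]
        trial["task_completion_time"] = float(s.t[lifts[-1][2] - 1] - s.t[start])
    return {"per_peg": per_peg, "trial": trial, "segmentation": seg}


def recording_to_observations(
    recording: Recording, subject_id: str, side: str, session: str,
    repetition: int,
) -> pd.DataFrame:
    """Emit observation-table rows compatible with the core data layer.

    Trial-level metrics (counts, task completion time) are attached to peg 1.
    """
    res = extract_trial_metrics(recording)
    rows = []
    for (name, peg), value in res["per_peg"].items():
        if np.isfinite(value):
            rows.append((subject_id, side, session, repetition, peg, name, value))
    for name, value in res["trial"].items():
        rows.append((subject_id, side, session, repetition, 1, name, value))
    return pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))


# ---------------------------------------------------------------------------
# Delimited-text recording I/O
# ---------------------------------------------------------------------------


def write_recording(recording: Recording, path, geometry_path=None) -> None:
    import yaml

    cols = {
        "t": recording.time,
        "x": recording.position[:, 0],
        "y": recording.position[:, 1],
        "z": recording.position[:, 2],
        "grip_force": recording.grip_force,
        "active_peg": recording.active_peg.astype(int),
    }
    if recording.interaction_force_z is not None:
        cols["fz"] = recording.interaction_force_z
    pd.DataFrame(cols).to_csv(path, index=False)
    if geometry_path is not None:
        g = recording.geometry
        with open(geometry_path, "w") as fh:
            yaml.safe_dump(
                {
                    "pegs": g.pegs.tolist(),
                    "holes": g.holes.tolist(),
                    "tolerance": g.tolerance,
                    "force_threshold": g.force_threshold,
                },
                fh,
            )


def read_recording(path, geometry_path=None) -> Recording:
    import yaml

    df = pd.read_csv(path)
    geom = DEFAULT_GEOMETRY
    if geometry_path is not None:
        with open(geometry_path) as fh:
            raw = yaml.safe_load(fh)
        geom = BoardGeometry(
            pegs=np.asarray(raw["pegs"], dtype=float),
            holes=np.asarray(raw["holes"], dtype=float),
            tolerance=float(raw["tolerance"]),
            force_threshold=float(raw["force_threshold"]),
        )
    return Recording(
        time=df["t"].to_numpy(float),
        position=df[["x", "y", "z"]].to_numpy(float),
        grip_force=df["grip_force"].to_numpy(float),
        active_peg=df["active_peg"].to_numpy(int),
        geometry=geom,
        interaction_force_z=(
            df["fz"].to_numpy(float) if "fz" in df.columns else None
        ),
    )
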