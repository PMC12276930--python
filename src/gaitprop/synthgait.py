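"""Seeded synthetic gait-session simulator.

Produces multi-rate wearable-sensor recordings of treadmill walking —
per-foot pressure-insole frames (233 sensels + centre of pressure, 50 Hz),
per-segment IMU channels (100 Hz) and force-plate ground truth (2000 Hz) —
for virtual healthy and clinical (hemiparetic) subjects, together with exact
ground-truth gait events and per-stride propulsion metrics.

The generative model is deliberately parametric and closed-form so that the
downstream pipeline can be tested against analytic oracles:

* anterior-posterior GRF per stance = negative half-sine braking lobe over
  the first half of stance followed by a positive half-sine propulsion lobe
  over the second half (true impulse = 2 A d / pi);
* vertical GRF = an M-shaped double hump, zero in swing;
* stride period T(v) = T_REF * (v / V_REF) ** -0.4, clamped to [0.8, 2.0] s;
* per-stride latent factors z_k (kinematic, visible in IMU pitch range) and
  z_l (loading, visible in insole/vertical load) both modulate the
  propulsion amplitude, so neither sensing modality alone determines AP GRF
  — the construction that makes sensor fusion strictly more informative.

All randomness flows from one seed per call; identical seeds give
bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

# ---------------------------------------------------------------------------
# constants

G = 9.81  # m/s^2

FORCEPLATE_HZ = 2000
IMU_HZ = 100
INSOLE_HZ = 50

N_SENSELS = 233
GRID_ROWS, GRID_COLS = 31, 11  # native bounding grid of the insole layout

T_REF = 1.1   # s, stride period at the reference speed
V_REF = 1.0   # m/s
T_MIN, T_MAX = 0.8, 2.0
STANCE_FRACTION = 0.62

# latent loading coefficients (see module docstring)
CK_PROP = 0.08   # kinematic latent -> propulsion amplitude
CL_PROP = 0.08   # loading latent  -> propulsion amplitude
CL_VERT = 0.08   # loading latent  -> vertical GRF amplitude
CK_PITCH = 0.08  # kinematic latent -> segment pitch range

INSOLE_GAIN = 0.40         # arbitrary pressure units per %BW of vertical load
STRIDE_TIME_CV = 0.02      # stride-period coefficient of variation

COHORTS = ("clinical", "healthy")
SIDES = ("left", "right")

CLINICAL_CENTERS_PCT = tuple(range(70, 131, 10))          # %CWS
HEALTHY_CENTERS_MS = (0.6, 0.8, 1.0, 1.2, 1.4)            # m/s


# ---------------------------------------------------------------------------
# sensel layout

def _build_layout() -> np.ndarray:
    """Fixed foot-shaped mask of exactly 233 sensels on a 31 x 11 grid.

    Returns (row, col) coordinates, 0-based, row 0 = heel, sorted
    lexicographically.  The mask is the 233 cells with the highest value of
    a smooth foot-shape score (half-width minus axis distance), which gives
    a rounded heel, narrower arch and wide forefoot.
    """
    rows = np.arange(GRID_ROWS, dtype=float)
    # half-width profile along the foot axis
    heel = 3.6 * np.sqrt(np.clip(1.0 - ((rows - 4.5) / 5.5) ** 2, 0.0, None))
    fore = 4.6 * np.sqrt(np.clip(1.0 - ((rows - 23.0) / 9.0) ** 2, 0.0, None))
    arch = 2.9 * np.exp(-((rows - 14.0) / 6.0) ** 2)
    half_width = np.maximum(np.maximum(heel, fore), arch)
    axis = 5.0 + 0.015 * (rows - 15.0)  # nearly straight axis
    score = np.empty((GRID_ROWS, GRID_COLS))
    for c in range(GRID_COLS):
        score[:, c] = half_width - np.abs(c - axis)
    order = np.argsort(-score, axis=None, kind="stable")[:N_SENSELS]
    rr, cc = np.unravel_index(order, score.shape)
    coords = np.stack([rr, cc], axis=1)
    idx = np.lexsort((coords[:, 1], coords[:, 0]))
    return coords[idx]


SENSEL_LAYOUT: np.ndarray = _build_layout()
"""(233, 2) array of (row, col) coordinates of the insole sensels."""


def layout_mask() -> np.ndarray:
    """Boolean (31, 11) foot mask of the sensel layout."""
    mask = np.zeros((GRID_ROWS, GRID_COLS), dtype=bool)
    mask[SENSEL_LAYOUT[:, 0], SENSEL_LAYOUT[:, 1]] = True
    return mask


def layout_to_csv(path) -> None:
    """Write the sensel (row, col) coordinates as a two-column CSV."""
    np.savetxt(path, SENSEL_LAYOUT, fmt="%d", delimiter=",",
               header="row,col", comments="")


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class NoiseLevels:
    """Per-modality sensor noise (standard deviations unless noted)."""

    insole_pressure: float = 0.10     # a.u., white noise per sensel
    insole_offset: float = 1.5        # a.u., max of per-sensel constant offset
    imu_accel: float = 0.05           # m/s^2
    imu_gyro: float = 1.0             # deg/s
    imu_angle: float = 0.2            # deg
    stride_time_cv: float = STRIDE_TIME_CV

    def scaled(self, factor: float) -> "NoiseLevels":
        return NoiseLevels(self.insole_pressure * factor, self.insole_offset * factor,
                           self.imu_accel * factor, self.imu_gyro * factor,
                           self.imu_angle * factor,
                           self.stride_time_cv * (factor if factor < 1 else 1.0))


@dataclass(frozen=True)
class ClockOffsets:
    """Constant clock offsets (s) of each stream relative to the force plate.

    A stream sample stamped t was truly acquired at t + offset.  Defaults are
    within the sub-40 ms range typical of independently started recorders.
    """

    insole: float = 0.025
    imu: float = 0.015
    forceplate: float = 0.0


@dataclass(frozen=True)
class SubjectSpec:
    subject_id: str
    bodyweight: float            # kg
    cws: float                   # comfortable walking speed, m/s
    cohort: str = "healthy"
    paretic_side: str = "none"   # left | right | none
    impairment: float = 0.0      # in [0, 1]; scales paretic propulsion deficit
    noise: NoiseLevels = field(default_factory=NoiseLevels)

    def __post_init__(self):
        if self.bodyweight <= 0 or self.cws <= 0:
            raise ValueError("bodyweight and cws must be strictly positive")
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if not 0.0 <= self.impairment <= 1.0:
            raise ValueError("impairment must lie in [0, 1]")
        if self.cohort == "healthy":
            if self.paretic_side != "none" or self.impairment != 0.0:
                raise ValueError("healthy subjects must have paretic_side='none' "
                                 "and impairment=0")
        elif self.paretic_side not in SIDES:
            raise ValueError("clinical subjects need paretic_side 'left' or 'right'")

    def impairment_of(self, side: str) -> float:
        return self.impairment if side == self.paretic_side else 0.0


@dataclass(frozen=True)
class TreadmillProfile:
    """Commanded treadmill speed profile of one bout."""

    t1: float
    t4: float
    v1: float
    v2: float
    v3: float
    a1_sign: int
    hold: float
    times: np.ndarray    # s, uniform grid
    speeds: np.ndarray   # m/s

    def speed(self, t) -> np.ndarray:
        return np.interp(t, self.times, self.speeds)

    @property
    def duration(self) -> float:
        return self.t4

    @property
    def ramp_slope(self) -> float:
        return (self.v2 - self.v1) / 30.0


@dataclass
class ForcePlateStream:
    timestamps: np.ndarray
    ap_grf: np.ndarray      # Newtons, anterior positive
    v_grf: np.ndarray       # Newtons, >= 0
    side: str
    units: str = "N"


@dataclass
class InsoleStream:
    timestamps: np.ndarray
    pressure: np.ndarray            # (frames, 233), arbitrary units
    cop: np.ndarray                 # (frames, 2) grid (row, col)
    side: str
    sensel_layout: np.ndarray = field(default_factory=lambda: SENSEL_LAYOUT.copy())


@dataclass
class ImuStream:
    timestamps: np.ndarray
    channels: dict                  # name -> 1-D array
    side: str

    @property
    def channel_names(self) -> list:
        return list(self.channels)


@dataclass
class GroundTruthEvents:
    heel_strike_times: np.ndarray
    toe_off_times: np.ndarray
    peak_propulsion: np.ndarray     # %BW per stride
    impulse: np.ndarray             # %BW*s per stride
    peak_time: np.ndarray           # s, instant of the propulsion peak


@dataclass
class StridePlan:
    """Internal per-stride generative state of one side of one bout."""

    heel_strike: np.ndarray   # s
    period: np.ndarray        # s
    stance: np.ndarray        # s
    speed: np.ndarray         # m/s at heel strike
    z_k: np.ndarray           # kinematic latent
    z_l: np.ndarray           # loading latent
    impairment: float

    @property
    def n(self) -> int:
        return len(self.heel_strike)

    def a_prop(self) -> np.ndarray:
        """Propulsion-lobe amplitude per stride, %BW (clamped >= 0)."""
        base = (4.0 + 8.0 * self.speed) * (1.0 - self.impairment)
        return np.clip(base * (1.0 + CK_PROP * self.z_k + CL_PROP * self.z_l), 0.0, None)

    def a_brake(self) -> np.ndarray:
        base = 3.0 + 7.0 * self.speed
        return np.clip(base * (1.0 + 0.04 * self.z_k + 0.04 * self.z_l), 0.0, None)

    def v_amp(self) -> np.ndarray:
        base = 100.0 + 10.0 * self.speed
        return np.clip(base * (1.0 + CL_VERT * self.z_l), 0.0, None)

    def pitch_gain(self) -> np.ndarray:
        return np.clip(1.0 + CK_PITCH * self.z_k, 0.0, None)


@dataclass
class Kinetics:
    """Force-plate stream + exact ground truth for one side of one bout."""

    force_plate: ForcePlateStream
    events: GroundTruthEvents
    plan: StridePlan
    duration: float
    profile: TreadmillProfile
    subject: SubjectSpec
    side: str


@dataclass
class Bout:
    profile: TreadmillProfile
    center: float                 # commanded centre (%CWS or m/s, as given)
    kinetics: dict                # side -> Kinetics
    insole: dict                  # side -> InsoleStream
    imu: dict                     # side -> ImuStream
    start_time: float = 0.0


@dataclass
class RawSession:
    subject: SubjectSpec
    bouts: list
    seed: int
    offsets: ClockOffsets = field(default_factory=ClockOffsets)
    bout_order: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# speed profiles

def make_speed_profile(cohort: str, cws: float, center, a1_sign: int,
                       seed: int = 0) -> TreadmillProfile:
    """Commanded treadmill profile: constant lead-in, then +/- speed ramps.

    ``center`` is a percentage of CWS for the clinical cohort (70..130 step
    10) and an absolute speed in m/s for the healthy cohort (0.6..1.4 step
    0.2).  Ramps change speed by (v2 - v1) in 30 s; extremes are held 15 s
    (clinical) or 60 s (healthy).  ``seed`` is accepted for interface
    uniformity; the commanded profile is deterministic.
    """
    del seed
    if a1_sign not in (1, -1):
        raise ValueError("a1_sign must be +1 or -1")
    if cohort == "clinical":
        if not any(abs(center - c) < 1e-9 for c in CLINICAL_CENTERS_PCT):
            raise ValueError(f"clinical center must be one of {CLINICAL_CENTERS_PCT} %CWS, "
                             f"got {center}")
        v2 = center / 100.0 * cws
        dv = 0.20 * cws
        t1, t4, hold = 120.0, 240.0, 15.0
    elif cohort == "healthy":
        if not any(abs(center - c) < 1e-9 for c in HEALTHY_CENTERS_MS):
            raise ValueError(f"healthy center must be one of {HEALTHY_CENTERS_MS} m/s, "
                             f"got {center}")
        v2 = float(center)
        dv = 0.20
        t1, t4, hold = 180.0, 600.0, 60.0
    else:
        raise ValueError(f"unknown cohort {cohort!r}")

    v1, v3 = v2 - dv, v2 + dv
    ramp = 30.0  # s for a v2 -> extreme transition; v1 <-> v3 takes 60 s
    # piecewise-linear knots: constant at v2, then cycle between extremes
    knots_t = [0.0, t1]
    knots_v = [v2, v2]
    target = v3 if a1_sign > 0 else v1
    t = t1 + ramp
    knots_t.append(t)
    knots_v.append(target)
    while t < t4:
        t += hold
        knots_t.append(t)
        knots_v.append(target)
        if t >= t4:
            break
        target = v1 + v3 - target  # swap extreme
        t += 2 * ramp
        knots_t.append(t)
        knots_v.append(target)
    times = np.arange(0.0, t4 + 1e-9, 0.01)
    speeds = np.interp(times, knots_t, knots_v)
    return TreadmillProfile(t1=t1, t4=t4, v1=v1, v2=v2, v3=v3, a1_sign=a1_sign,
                            hold=hold, times=times, speeds=speeds)


# ---------------------------------------------------------------------------
# kinetics

def _plan_strides(profile: TreadmillProfile, subject: SubjectSpec, side: str,
                  rng: np.random.Generator) -> StridePlan:
    start = 0.05 if side == "left" else 0.05 + 0.5 * _stride_period(profile.speed(0.0))
    hs, periods, stances, speeds = [], [], [], []
    t = float(start)
    cv = subject.noise.stride_time_cv
    while True:
        v = float(profile.speed(t))
        if v < 0.05:  # belt effectively stopped: no stepping
            t += 0.5
            if t > profile.duration:
                break
            continue
        period = _stride_period(v) * (1.0 + cv * rng.standard_normal())
        period = float(np.clip(period, T_MIN, T_MAX))
        if t + period > profile.duration:
            break
        hs.append(t)
        periods.append(period)
        stances.append(STANCE_FRACTION * period)
        speeds.append(v)
        t += period
    n = len(hs)
    z_k = rng.standard_normal(n)
    z_l = rng.standard_normal(n)
    return StridePlan(np.array(hs), np.array(periods), np.array(stances),
                      np.array(speeds), z_k, z_l,
                      impairment=subject.impairment_of(side))


def _stride_period(v) -> float:
    return float(np.clip(T_REF * (max(v, 1e-6) / V_REF) ** -0.4, T_MIN, T_MAX))


def eval_grf_pctbw(plan: StridePlan, t: np.ndarray):
    """Analytic AP and vertical GRF (%BW) plus stride phase at times ``t``.

    Returns (ap, vert, phase, stride_index); outside stance both forces are
    exactly zero.  ``stride_index`` is clipped to the plan so that phase is
    defined (by extrapolation) before the first and after the last stride.
    """
    t = np.asarray(t, dtype=float)
    ap = np.zeros_like(t)
    vert = np.zeros_like(t)
    if plan.n == 0:
        return ap, vert, np.zeros_like(t), np.zeros(t.shape, dtype=int)
    k = np.clip(np.searchsorted(plan.heel_strike, t, side="right") - 1, 0, plan.n - 1)
    s = t - plan.heel_strike[k]
    phase = s / plan.period[k]
    stance = plan.stance[k]
    in_stance = (s >= 0) & (s < stance)
    u = np.where(in_stance, s / np.where(stance > 0, stance, 1.0), 0.0)
    a_br = plan.a_brake()[k]
    a_pr = plan.a_prop()[k]
    v_am = plan.v_amp()[k]
    first = in_stance & (u < 0.5)
    second = in_stance & (u >= 0.5)
    ap[first] = -a_br[first] * np.sin(2.0 * np.pi * u[first])
    ap[second] = a_pr[second] * np.sin(2.0 * np.pi * (u[second] - 0.5))
    vert[in_stance] = (v_am[in_stance] * np.sin(np.pi * u[in_stance])
                       * (1.0 + 0.3 * np.cos(2.0 * np.pi * u[in_stance])))
    vert = np.clip(vert, 0.0, None)
    return ap, vert, phase, k


def _ground_truth(plan: StridePlan) -> GroundTruthEvents:
    a_pr = plan.a_prop()
    d2 = 0.5 * plan.stance                      # propulsion-lobe duration, s
    impulse = 2.0 * a_pr * d2 / np.pi           # closed-form half-sine integral
    peak_time = plan.heel_strike + 0.75 * plan.stance
    return GroundTruthEvents(heel_strike_times=plan.heel_strike.copy(),
                             toe_off_times=plan.heel_strike + plan.stance,
                             peak_propulsion=a_pr,
                             impulse=impulse,
                             peak_time=peak_time)


def _render_forceplate(plan: StridePlan, duration: float, subject: SubjectSpec,
                       side: str) -> ForcePlateStream:
    t = np.arange(0.0, duration, 1.0 / FORCEPLATE_HZ)
    ap, vert, _, _ = eval_grf_pctbw(plan, t)
    to_newton = subject.bodyweight * G / 100.0
    return ForcePlateStream(timestamps=t, ap_grf=ap * to_newton,
                            v_grf=vert * to_newton, side=side)


def simulate_kinetics(profile: TreadmillProfile, subject: SubjectSpec, side: str,
                      seed) -> Kinetics:
    """Simulate one side's force-plate ground truth for one bout."""
    rng = np.random.default_rng(seed)
    plan = _plan_strides(profile, subject, side, rng)
    stream = _render_forceplate(plan, profile.duration, subject, side)
    return Kinetics(force_plate=stream, events=_ground_truth(plan), plan=plan,
                    duration=profile.duration, profile=profile, subject=subject,
                    side=side)


# ---------------------------------------------------------------------------
# insole

_BLOB_SIGMA_R = 3.2
_BLOB_SIGMA_C = 1.8
_STATIC_SIGMA_C = 2.6


def _insole_templates(n_frames_phase: np.ndarray):
    """Spatial pressure weights per frame: travelling heel->toe blob mixed
    with a broad static foot-shaped component.  ``n_frames_phase`` is the
    within-stance phase u in [0, 1] per frame."""
    u = n_frames_phase[:, None]
    rows = SENSEL_LAYOUT[:, 0].astype(float)[None, :]
    cols = SENSEL_LAYOUT[:, 1].astype(float)[None, :]
    r0 = 3.0 + 24.0 * (3 * u ** 2 - 2 * u ** 3)      # smoothstep heel -> toe
    c0 = 5.0 + 0.8 * np.sin(np.pi * u)
    blob = np.exp(-((rows - r0) ** 2 / (2 * _BLOB_SIGMA_R ** 2)
                    + (cols - c0) ** 2 / (2 * _BLOB_SIGMA_C ** 2)))
    static = np.exp(-((cols - 5.0) ** 2) / (2 * _STATIC_SIGMA_C ** 2))
    static = np.broadcast_to(static, blob.shape)
    w = 0.55 * blob / np.clip(blob.sum(1, keepdims=True), 1e-12, None) \
        + 0.45 * static / static.sum(1, keepdims=True)
    return w


def simulate_insole(kinetics: Kinetics, subject: SubjectSpec, side: str, seed,
                    clock_offset: float = 0.0) -> InsoleStream:
    """Render the 50 Hz insole stream of one side of one bout.

    Frame total pressure is proportional to the (latent-modulated) vertical
    GRF; the pressure centroid travels heel to toe across stance.  The CoP
    channel is the exact pressure-weighted centroid before offset and noise.
    A frame stamped t is rendered at true time t + clock_offset.
    """
    rng = np.random.default_rng(seed)
    stamps = np.arange(0.0, kinetics.duration, 1.0 / INSOLE_HZ)
    t_true = stamps + clock_offset
    plan = kinetics.plan
    _, vert, _, k = eval_grf_pctbw(plan, t_true)
    if plan.n:
        s = t_true - plan.heel_strike[k]
        stance = plan.stance[k]
        u = np.clip(np.where(stance > 0, s / np.where(stance > 0, stance, 1.0), 0.0), 0.0, 1.0)
    else:
        u = np.zeros_like(t_true)
    weights = _insole_templates(u)
    pressure = (INSOLE_GAIN * vert)[:, None] * weights
    total = pressure.sum(axis=1)
    cop = np.full((len(stamps), 2), [GRID_ROWS / 2.0, GRID_COLS / 2.0])
    loaded = total > 1e-9
    coords = SENSEL_LAYOUT.astype(float)
    cop[loaded] = (pressure[loaded] @ coords) / total[loaded, None]
    noise = subject.noise
    offsets = rng.uniform(0.0, noise.insole_offset, size=N_SENSELS)
    pressure = pressure + offsets[None, :]
    if noise.insole_pressure > 0:
        pressure = pressure + rng.normal(0.0, noise.insole_pressure, size=pressure.shape)
    pressure = np.clip(pressure, 0.0, None).astype(np.float32)
    return InsoleStream(timestamps=stamps, pressure=pressure, cop=cop, side=side)


# ---------------------------------------------------------------------------
# IMU

IMU_SEGMENTS = ("foot", "shank", "thigh")


def imu_channel_names(side: str = "left") -> list:
    """The 21 retained channels per side, in canonical order."""
    del side
    names = []
    for seg in ("foot", "shank"):
        names += [f"{seg}_acc_{ax}" for ax in "xyz"]
    for seg in IMU_SEGMENTS:
        names += [f"{seg}_gyro_{ax}" for ax in ("roll", "pitch", "yaw")]
    for seg in IMU_SEGMENTS:
        names += [f"{seg}_pitch", f"{seg}_roll"]
    return names


_SEG_PITCH = {  # mean deg, base range deg at v=0, range slope deg per m/s
    "foot": (-10.0, 20.0, 12.0),
    "shank": (5.0, 25.0, 15.0),
    "thigh": (2.0, 15.0, 8.0),
}
_SEG_PHASE = {"foot": 0.0, "shank": 0.9, "thigh": 1.9}


def _pitch_shape(phi: np.ndarray, phase: float) -> np.ndarray:
    return -0.5 * np.cos(2 * np.pi * phi + phase) + 0.18 * np.sin(4 * np.pi * phi + phase + 0.8)


def simulate_imu(kinetics: Kinetics, subject: SubjectSpec, side: str, seed,
                 clock_offset: float = 0.0) -> ImuStream:
    """Render the 100 Hz IMU stream (21 channels) of one side of one bout.

    Segment pitch is a smooth periodic function of stride phase with a
    speed- and latent-dependent range; angular-rate channels are the exact
    central finite differences of the (noise-free) sampled angles;
    accelerations combine the gravity projection through segment pitch/roll
    with a motion term proportional to belt speed, so a zero-speed
    extension yields accelerometer norm exactly g.
    """
    rng = np.random.default_rng(seed)
    stamps = np.arange(0.0, kinetics.duration, 1.0 / IMU_HZ)
    t_true = stamps + clock_offset
    plan = kinetics.plan
    dt = 1.0 / IMU_HZ
    noise = subject.noise
    if plan.n:
        k = np.clip(np.searchsorted(plan.heel_strike, t_true, side="right") - 1,
                    0, plan.n - 1)
        phi = (t_true - plan.heel_strike[k]) / plan.period[k]
        v = plan.speed[k]
        gain = plan.pitch_gain()[k]
    else:
        phi = np.zeros_like(t_true)
        v = np.zeros_like(t_true)
        gain = np.ones_like(t_true)

    channels: dict = {}
    angles: dict = {}
    for seg in IMU_SEGMENTS:
        mean, r0, r1 = _SEG_PITCH[seg]
        rng_range = (r0 + r1 * v) * gain * np.where(v > 0, 1.0, 0.0)
        pitch = mean + rng_range * _pitch_shape(phi, _SEG_PHASE[seg])
        roll = (2.5 * np.sin(2 * np.pi * phi + _SEG_PHASE[seg] + 0.5)
                * np.where(v > 0, 1.0, 0.0))
        angles[seg] = (pitch, roll)
        channels[f"{seg}_gyro_roll"] = np.gradient(roll, dt)
        channels[f"{seg}_gyro_pitch"] = np.gradient(pitch, dt)
        channels[f"{seg}_gyro_yaw"] = 8.0 * v * np.sin(2 * np.pi * phi + 2.2)
        channels[f"{seg}_pitch"] = pitch
        channels[f"{seg}_roll"] = roll

    for seg in ("foot", "shank"):
        pitch, roll = angles[seg]
        th = np.deg2rad(pitch)
        ro = np.deg2rad(roll)
        motion_x = v * (2.0 * np.sin(2 * np.pi * phi + 0.3) + 0.8 * np.sin(4 * np.pi * phi))
        motion_y = v * 0.6 * np.sin(2 * np.pi * phi + 1.1)
        motion_z = v * (1.5 * np.sin(2 * np.pi * phi + 4.0) + 0.5 * np.sin(6 * np.pi * phi))
        channels[f"{seg}_acc_x"] = -G * np.sin(th) + motion_x
        channels[f"{seg}_acc_y"] = G * np.cos(th) * np.sin(ro) + motion_y
        channels[f"{seg}_acc_z"] = G * np.cos(th) * np.cos(ro) + motion_z

    if noise.imu_accel > 0 or noise.imu_gyro > 0 or noise.imu_angle > 0:
        for name in channels:
            if "_acc_" in name:
                std = noise.imu_accel
            elif "_gyro_" in name:
                std = noise.imu_gyro
            else:
                std = noise.imu_angle
            if std > 0:
                channels[name] = channels[name] + rng.normal(0.0, std, size=len(stamps))

    ordered = {name: channels[name] for name in imu_channel_names(side)}
    return ImuStream(timestamps=stamps, channels=ordered, side=side)


# ---------------------------------------------------------------------------
# sessions

_STREAM_CODE = {"kinetics": 0, "insole": 1, "imu": 2}


def _sub_seed(seed: int, bout: int, side: str, stream: str) -> np.random.SeedSequence:
    return np.random.SeedSequence((int(seed), int(bout), SIDES.index(side),
                                   _STREAM_CODE[stream]))


def _render_bout(subject: SubjectSpec, profile: TreadmillProfile, center,
                 bout_index: int, seed: int, offsets: ClockOffsets) -> Bout:
    kin, ins, imu = {}, {}, {}
    for side in SIDES:
        k = simulate_kinetics(profile, subject, side,
                              _sub_seed(seed, bout_index, side, "kinetics"))
        kin[side] = k
        ins[side] = simulate_insole(k, subject, side,
                                    _sub_seed(seed, bout_index, side, "insole"),
                                    clock_offset=offsets.insole)
        imu[side] = simulate_imu(k, subject, side,
                                 _sub_seed(seed, bout_index, side, "imu"),
                                 clock_offset=offsets.imu)
    return Bout(profile=profile, center=center, kinetics=kin, insole=ins, imu=imu)


def simulate_session(subject: SubjectSpec, bout_plan: Sequence, seed: int,
                     offsets: ClockOffsets | None = None) -> RawSession:
    """Simulate a full walking session.

    ``bout_plan`` is a sequence of (center, a1_sign) pairs — centres in %CWS
    for clinical subjects, m/s for healthy — or of ready TreadmillProfile
    objects paired with a nominal centre.  Bout order is randomized (and
    recorded); everything is deterministic given ``seed``.
    """
    offsets = offsets or ClockOffsets()
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 987654321)))
    order = rng.permutation(len(bout_plan)).tolist()
    bouts = []
    t0 = 0.0
    for slot, plan_idx in enumerate(order):
        entry = bout_plan[plan_idx]
        if isinstance(entry[0], TreadmillProfile):
            profile, center = entry
        else:
            center, a1 = entry
            profile = make_speed_profile(subject.cohort, subject.cws, center, a1)
        bout = _render_bout(subject, profile, center, slot, seed, offsets)
        bout.start_time = t0
        t0 += profile.duration
        bouts.append(bout)
    return RawSession(subject=subject, bouts=bouts, seed=int(seed),
                      offsets=offsets, bout_order=order)


def session_hash(session: RawSession) -> str:
    """Deterministic content hash over all stream arrays (for tests)."""
    import hashlib
    h = hashlib.sha256()
    for bout in session.bouts:
        for side in SIDES:
            fp = bout.kinetics[side].force_plate
            for arr in (fp.ap_grf, fp.v_grf, bout.insole[side].pressure,
                        bout.insole[side].cop):
                h.update(np.ascontiguousarray(arr).tobytes())
            for ch in bout.imu[side].channels.values():
                h.update(np.ascontiguousarray(ch).tobytes())
    return h.hexdigest()


def perturb_propulsion(session: RawSession, window: tuple, delta: float) -> RawSession:
    """Shift the propulsion-lobe amplitude by ``delta`` %BW inside ``window``.

    ``window`` = (start, end) in session time (bouts laid end to end).  The
    shift is injected through the two latent factors in equal parts, so the
    change is consistently visible in the kinetics, the insole stream and
    the IMU stream; ground-truth metrics are recomputed.  Negative deltas
    are bounded so the propulsion amplitude never goes below zero.
    """
    lo, hi = float(window[0]), float(window[1])
    span = sum(b.profile.duration for b in session.bouts)
    if not (0.0 <= lo < hi <= span + 1e-9):
        raise ValueError(f"window {window} outside session span [0, {span:.1f}] s")
    if delta == 0.0:
        return session
    new_bouts = []
    for slot, bout in enumerate(session.bouts):
        touched = False
        new_kin = {}
        for side in SIDES:
            kin = bout.kinetics[side]
            plan = kin.plan
            abs_hs = plan.heel_strike + bout.start_time
            sel = (abs_hs >= lo) & (abs_hs < hi)
            if not np.any(sel):
                new_kin[side] = kin
                continue
            touched = True
            base = (4.0 + 8.0 * plan.speed) * (1.0 - plan.impairment)
            a_old = plan.a_prop()
            a_new = np.where(sel, np.clip(a_old + delta, 0.0, None), a_old)
            # distribute the required amplitude change over both latents
            with np.errstate(divide="ignore", invalid="ignore"):
                d = np.where(base > 0, (a_new - a_old) / np.where(base > 0, base, 1.0), 0.0)
            z_k = plan.z_k + d / (2.0 * CK_PROP)
            z_l = plan.z_l + d / (2.0 * CL_PROP)
            new_plan = replace(plan, z_k=z_k, z_l=z_l)
            stream = _render_forceplate(new_plan, kin.duration, session.subject, side)
            new_kin[side] = Kinetics(force_plate=stream, events=_ground_truth(new_plan),
                                     plan=new_plan, duration=kin.duration,
                                     profile=kin.profile, subject=session.subject,
                                     side=side)
        if not touched:
            new_bouts.append(bout)
            continue
        ins, imu = {}, {}
        for side in SIDES:
            ins[side] = simulate_insole(new_kin[side], session.subject, side,
                                        _sub_seed(session.seed, slot, side, "insole"),
                                        clock_offset=session.offsets.insole)
            imu[side] = simulate_imu(new_kin[side], session.subject, side,
                                     _sub_seed(session.seed, slot, side, "imu"),
                                     clock_offset=session.offsets.imu)
        nb = Bout(profile=bout.profile, center=bout.center, kinetics=new_kin,
                  insole=ins, imu=imu, start_time=bout.start_time)
        new_bouts.append(nb)
    return RawSession(subject=session.subject, bouts=new_bouts, seed=session.seed,
                      offsets=session.offsets, bout_order=list(session.bout_order))


def export_streams_csv(session: RawSession, directory) -> list:
    """Optionally dump per-stream CSV files (one per bout/side/stream).

    Returns the written paths.  Intended for quick inspection with external
    tools; the HDF5 form is the canonical on-disk format.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for i, bout in enumerate(session.bouts):
        for side in SIDES:
            fp = bout.kinetics[side].force_plate
            path = directory / f"bout{i}_{side}_forceplate.csv"
            np.savetxt(path, np.column_stack([fp.timestamps, fp.ap_grf, fp.v_grf]),
                       delimiter=",", header="time_s,ap_grf_n,v_grf_n", comments="")
            written.append(path)
            ins = bout.insole[side]
            path = directory / f"bout{i}_{side}_insole_total_cop.csv"
            np.savetxt(path, np.column_stack([ins.timestamps, ins.pressure.sum(1),
                                              ins.cop]),
                       delimiter=",", header="time_s,total_pressure,cop_row,cop_col",
                       comments="")
            written.append(path)
            imu = bout.imu[side]
            path = directory / f"bout{i}_{side}_imu.csv"
            np.savetxt(path, np.column_stack([imu.timestamps]
                                             + list(imu.channels.values())),
                       delimiter=",", header=",".join(["time_s"] + list(imu.channels)),
                       comments="")
            written.append(path)
    return written


# ---------------------------------------------------------------------------
# HDF5 persistence

def save_session(session: RawSession, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        s = session.subject
        f.attrs.update({"subject_id": s.subject_id, "bodyweight": s.bodyweight,
                        "cws": s.cws, "cohort": s.cohort,
                        "paretic_side": s.paretic_side, "impairment": s.impairment,
                        "seed": session.seed,
                        "offset_insole": session.offsets.insole,
                        "offset_imu": session.offsets.imu,
                        "offset_forceplate": session.offsets.forceplate,
                        "bout_order": np.asarray(session.bout_order, dtype=np.int64)})
        nz = s.noise
        f.attrs["noise"] = np.array([nz.insole_pressure, nz.insole_offset,
                                     nz.imu_accel, nz.imu_gyro, nz.imu_angle,
                                     nz.stride_time_cv])
        f.create_dataset("sensel_layout", data=SENSEL_LAYOUT)
        for i, bout in enumerate(session.bouts):
            g = f.create_group(f"bouts/{i}")
            p = bout.profile
            g.attrs.update({"t1": p.t1, "t4": p.t4, "v1": p.v1, "v2": p.v2,
                            "v3": p.v3, "a1_sign": p.a1_sign, "hold": p.hold,
                            "center": bout.center, "start_time": bout.start_time})
            g.create_dataset("profile_times", data=p.times)
            g.create_dataset("profile_speeds", data=p.speeds)
            for side in SIDES:
                gs = g.create_group(side)
                kin = bout.kinetics[side]
                gs.create_dataset("fp_ap", data=kin.force_plate.ap_grf)
                gs.create_dataset("fp_v", data=kin.force_plate.v_grf)
                plan = kin.plan
                for name in ("heel_strike", "period", "stance", "speed", "z_k", "z_l"):
                    gs.create_dataset(f"plan/{name}", data=getattr(plan, name))
                gs.attrs["impairment"] = plan.impairment
                gs.create_dataset("insole_pressure", data=bout.insole[side].pressure,
                                  dtype="f4")
                gs.create_dataset("insole_cop", data=bout.insole[side].cop)
                imu = bout.imu[side]
                gs.create_dataset("imu", data=np.stack(list(imu.channels.values()), 1))
                gs.attrs["imu_channels"] = list(imu.channels)


def load_session(path) -> RawSession:
    import h5py

    with h5py.File(path, "r") as f:
        nz = f.attrs["noise"]
        subject = SubjectSpec(subject_id=str(f.attrs["subject_id"]),
                              bodyweight=float(f.attrs["bodyweight"]),
                              cws=float(f.attrs["cws"]),
                              cohort=str(f.attrs["cohort"]),
                              paretic_side=str(f.attrs["paretic_side"]),
                              impairment=float(f.attrs["impairment"]),
                              noise=NoiseLevels(*[float(x) for x in nz]))
        offsets = ClockOffsets(insole=float(f.attrs["offset_insole"]),
                               imu=float(f.attrs["offset_imu"]),
                               forceplate=float(f.attrs["offset_forceplate"]))
        bouts = []
        for i in range(len(f["bouts"])):
            g = f[f"bouts/{i}"]
            profile = TreadmillProfile(t1=float(g.attrs["t1"]), t4=float(g.attrs["t4"]),
                                       v1=float(g.attrs["v1"]), v2=float(g.attrs["v2"]),
                                       v3=float(g.attrs["v3"]),
                                       a1_sign=int(g.attrs["a1_sign"]),
                                       hold=float(g.attrs["hold"]),
                                       times=g["profile_times"][:],
                                       speeds=g["profile_speeds"][:])
            kin, ins, imu = {}, {}, {}
            for side in SIDES:
                gs = g[side]
                plan = StridePlan(heel_strike=gs["plan/heel_strike"][:],
                                  period=gs["plan/period"][:],
                                  stance=gs["plan/stance"][:],
                                  speed=gs["plan/speed"][:],
                                  z_k=gs["plan/z_k"][:], z_l=gs["plan/z_l"][:],
                                  impairment=float(gs.attrs["impairment"]))
                n_fp = len(gs["fp_ap"])
                fp = ForcePlateStream(timestamps=np.arange(n_fp) / FORCEPLATE_HZ,
                                      ap_grf=gs["fp_ap"][:], v_grf=gs["fp_v"][:],
                                      side=side)
                kin[side] = Kinetics(force_plate=fp, events=_ground_truth(plan),
                                     plan=plan, duration=profile.duration,
                                     profile=profile, subject=subject, side=side)
                pressure = gs["insole_pressure"][:]
                ins[side] = InsoleStream(timestamps=np.arange(len(pressure)) / INSOLE_HZ,
                                         pressure=pressure, cop=gs["insole_cop"][:],
                                         side=side)
                mat = gs["imu"][:]
                names = list(gs.attrs["imu_channels"])
                imu[side] = ImuStream(timestamps=np.arange(mat.shape[0]) / IMU_HZ,
                                      channels={n: mat[:, j] for j, n in enumerate(names)},
                                      side=side)
            bouts.append(Bout(profile=profile, center=float(g.attrs["center"]),
                              kinetics=kin, insole=ins, imu=imu,
                              start_time=float(g.attrs["start_time"])))
        return RawSession(subject=subject, bouts=bouts, seed=int(f.attrs["seed"]),
                          offsets=offsets,
                          bout_order=[int(x) for x in f.attrs["bout_order"]])
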