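"""Parametric kinematic treadmill walker with known ground truth.

The walker is a planar-dominant sinusoidal gait model: the pelvis stays in
the treadmill frame (small mediolateral sway and vertical heave), legs are
2-link pendula driven by inverse kinematics from scheduled foot
trajectories, and the head/trunk/arms are oscillating rigid segments.  Every
explanatory gait variable of the feature pipeline is either a direct
parameter (cadence, stride-time CV, swing asymmetry, toe clearance, toe-off
angle, arm-swing angles, head tilt/yaw, lumbar flexion amplitude, rib and
trochanter widths) or an analytic consequence of the schedule, so the
generator can record the ground-truth value of every feature it controls.

All generated signals are band-limited well below the pipeline's 6 Hz
low-pass cut-off by construction (quintic smoothsteps, Gaussian mid-swing
dip), and the pelvis-relative foot excursions form symmetric +-v corners at
foot contact and toe-off, so sub-frame event refinement is unbiased.

Gait-cycle timing convention (right-contact anchored, phases of one stride):
right contact 0%, left toe-off 10%, left contact ``10% + 40% * asymmetry``
(50% when symmetric), right toe-off 60%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ..trajectories import MarkerTrajectories

BELT_SPEED = 1.0  # m/s, treadmill speed used for all trials


@dataclass
class WalkerParams:
    """Ground-truth parameters of one synthetic walker trial."""

    cadence_target: float = 112.0          # steps/min
    stride_time_cv: float = 0.02
    arm_swing_backward_offset_deg: float = 5.0
    arm_swing_amplitude_deg: float = 15.0
    head_tilt_deg: float = 6.0             # mean forward neck angle, + forward
    head_yaw_amplitude_deg: float = 4.0
    lumbar_flex_amplitude_deg: float = 2.3
    toe_clearance_m: float = 0.02          # minimum swing-phase toe height
    toe_off_angle_deg: float = 40.0
    swing_time_asymmetry: float = 1.0      # left/right mean swing time, >= 1
    height_m: float = 1.65
    weight_kg: float = 55.0
    rib_width_m: float = 0.25
    trochanter_width_m: float = 0.36
    leg_extension: float = 0.97            # peak leg reach / anatomical leg length
    noise_sd_m: float = 0.0                # iid marker jitter per coordinate
    seed: int = 0

    def validate(self) -> None:
        if self.cadence_target <= 0:
            raise ValueError("cadence_target must be positive")
        if self.stride_time_cv < 0:
            raise ValueError("stride_time_cv must be >= 0")
        if not 1.0 <= self.swing_time_asymmetry <= 1.4:
            raise ValueError("swing_time_asymmetry must be in [1, 1.4]")
        if self.toe_clearance_m < 0:
            raise ValueError("toe_clearance_m must be >= 0")
        for name in ("height_m", "weight_kg", "rib_width_m", "trochanter_width_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.80 <= self.leg_extension <= 0.995:
            raise ValueError("leg_extension must be in [0.80, 0.995]")

    @property
    def stride_period_s(self) -> float:
        return 120.0 / self.cadence_target  # two steps per stride

    @property
    def bmi(self) -> float:
        return self.weight_kg / self.height_m**2


@dataclass
class StrideSchedule:
    """Realized event times (seconds) of a generated trial."""

    contacts: dict[str, np.ndarray]
    toe_offs: dict[str, np.ndarray]
    right_contacts_all: np.ndarray  # including events outside [0, duration]


@dataclass
class SyntheticTrial:
    """Generated trajectories plus everything needed to test recovery."""

    params: WalkerParams
    trajectories: MarkerTrajectories
    schedule: StrideSchedule
    ground_truth: dict[str, float]
    true_joint_centers: dict[str, np.ndarray] = field(default_factory=dict)


# -- anthropometry -----------------------------------------------------------


def anthropometry(height_m: float) -> dict[str, float]:
    """Segment lengths as standard fractions of body height."""
    h = height_m
    return {
        "thigh": 0.245 * h,
        "shank": 0.246 * h,
        "foot": 0.152 * h,       # heel-toe marker distance
        "head": 0.130 * h,       # neck joint to head-top
        "upper_arm": 0.186 * h,
        "forearm": 0.146 * h,
        "lower_trunk": 0.140 * h,
        "upper_trunk": 0.205 * h,
        "shoulder_width": 0.240 * h,
        "asis_width": 0.240,
        "heel_strike_deg": 8.0,  # foot dorsiflexion at heel strike
    }


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u**3 * (6.0 * u**2 - 15.0 * u + 10.0)


# -- stride schedule ---------------------------------------------------------


def _build_schedule(params: WalkerParams, duration: float, rng: np.random.Generator):
    """Right-contact times spanning [-2T, duration + 2T] plus in-window events."""
    t0 = params.stride_period_s
    n = int(math.ceil((duration + 5 * t0) / t0)) + 2
    z = rng.standard_normal(n)
    z = np.clip(z, -3.0, 3.0)
    periods = t0 * (1.0 + params.stride_time_cv * z)
    periods = np.maximum(periods, 0.5 * t0)
    rc = np.concatenate([[-2.0 * t0], -2.0 * t0 + np.cumsum(periods)])

    c_phase = 0.1 + 0.4 * params.swing_time_asymmetry  # left-contact phase
    events = {"L": {"contact": [], "toe_off": []}, "R": {"contact": [], "toe_off": []}}
    for k in range(len(rc) - 1):
        tk = rc[k + 1] - rc[k]
        events["R"]["contact"].append(rc[k])
        events["L"]["toe_off"].append(rc[k] + 0.1 * tk)
        events["L"]["contact"].append(rc[k] + c_phase * tk)
        events["R"]["toe_off"].append(rc[k] + 0.6 * tk)
    events["R"]["contact"].append(rc[-1])

    # events closer than `margin` to the recording boundary cannot be seen
    # by any extremum-based detector, so the recorded schedule (and hence
    # the timing ground truths derived from it) excludes them
    margin = 0.25

    def in_window(ts):
        ts = np.asarray(ts)
        return ts[(ts >= margin) & (ts <= duration - margin)]

    sched = StrideSchedule(
        contacts={s: in_window(events[s]["contact"]) for s in ("L", "R")},
        toe_offs={s: in_window(events[s]["toe_off"]) for s in ("L", "R")},
        right_contacts_all=rc,
    )
    full = {
        s: {kind: np.asarray(events[s][kind]) for kind in ("contact", "toe_off")}
        for s in ("L", "R")
    }
    return sched, full, rc


def _phase(t: np.ndarray, rc: np.ndarray) -> np.ndarray:
    """Continuous stride phase: integer at each right contact."""
    k = np.clip(np.searchsorted(rc, t, side="right") - 1, 0, len(rc) - 2)
    return k + (t - rc[k]) / (rc[k + 1] - rc[k])


# -- foot trajectory ---------------------------------------------------------


def _foot_series(
    t: np.ndarray,
    contacts: np.ndarray,
    toe_offs: np.ndarray,
    params: WalkerParams,
    anthro: dict[str, float],
):
    """Toe y/z and foot pitch (rad) for one foot over all frames.

    Stance: toe moves backward at belt speed, flat foot mid-stance, smooth
    heel rise to the toe-off angle (zero angular velocity at toe-off).
    Swing: monotone forward toe motion whose endpoint slopes equal the belt
    speed (symmetric corners at the events), a plateau-plus-Gaussian-dip
    height profile whose mid-swing minimum equals ``toe_clearance_m``, and a
    smooth pitch reversal to the heel-strike angle.
    """
    a_to = math.radians(params.toe_off_angle_deg)
    a_hs = math.radians(anthro["heel_strike_deg"])
    z_hs = anthro["foot"] * math.sin(a_hs)  # toe height when the heel lands
    c_min = params.toe_clearance_m
    h_p = c_min + 0.025

    toe_y = np.zeros_like(t)
    toe_z = np.zeros_like(t)
    pitch = np.zeros_like(t)

    # build per-cycle: contact -> toe-off (stance) -> next contact (swing)
    for i, fc in enumerate(contacts[:-1]):
        nxt = contacts[i + 1]
        tos = toe_offs[(toe_offs > fc) & (toe_offs < nxt)]
        if len(tos) != 1:
            continue
        to = tos[0]
        t_st, t_sw = to - fc, nxt - to
        d_st = BELT_SPEED * t_st

        m = (t >= fc) & (t < to)
        u = (t[m] - fc) / t_st
        toe_y[m] = 0.5 * d_st - BELT_SPEED * (t[m] - fc)
        toe_z[m] = z_hs * (1.0 - _smoothstep(u / 0.15))
        pitch[m] = -a_hs * (1.0 - _smoothstep(u / 0.15)) + a_to * _smoothstep(
            (u - 0.55) / 0.45
        )

        m = (t >= to) & (t < nxt)
        u = (t[m] - to) / t_sw
        d_next = BELT_SPEED * _stance_duration(nxt, contacts, toe_offs)
        y0, y1 = -0.5 * d_st, 0.5 * d_next
        slope = BELT_SPEED * t_sw / (y1 - y0)  # end slopes match the belt speed
        f = slope * u + (1.0 - slope) * _smoothstep(u)
        toe_y[m] = y0 + (y1 - y0) * f
        rise = h_p * _smoothstep(u / 0.3) - (h_p - z_hs) * _smoothstep((u - 0.7) / 0.3)
        dip = (h_p - c_min) * np.exp(-(((u - 0.5) / 0.16) ** 2))
        toe_z[m] = rise - dip
        pitch[m] = a_to - (a_to + a_hs) * _smoothstep(u)
    return toe_y, toe_z, pitch


def _stance_duration(fc: float, contacts: np.ndarray, toe_offs: np.ndarray) -> float:
    after = toe_offs[toe_offs > fc]
    if not after.size:
        return 0.6 * (contacts[-1] - contacts[-2]) if len(contacts) >= 2 else 0.6
    return after[0] - fc


# -- generator ---------------------------------------------------------------


def generate_walker_trajectories(
    params: WalkerParams,
    duration: float = 12.0,
    rate: float = 100.0,
) -> SyntheticTrial:
    """Simulate one treadmill trial of the parametric walker.

    Returns a :class:`SyntheticTrial` whose ``trajectories`` carry all 42
    canonical markers and whose ``ground_truth`` maps every
    generator-controlled feature name to its true value.
    """
    params.validate()
    t0 = params.stride_period_s
    if duration < 2.0 * t0:
        raise ValueError(
            f"duration {duration:.2f} s too short: one stride lasts {t0:.2f} s "
            f"(need >= 2 strides, >= 5 recommended)"
        )
    if rate < 50.0:
        raise ValueError("sampling rate must be at least 50 Hz for this gait content")

    anthro = anthropometry(params.height_m)
    rng = np.random.default_rng(params.seed)
    sched, full_events, rc = _build_schedule(params, duration, rng)
    n_frames = int(round(duration * rate))
    t = np.arange(n_frames) / rate
    phi = _phase(t, rc)

    w_tro = params.trochanter_width_m
    w_asis = min(anthro["asis_width"], 0.9 * w_tro)
    hip_half = 0.5 * w_tro - 0.25 * w_asis  # hip = trochanter shifted medially

    # feet (toe position relative to the foot's own mean y)
    foot = {}
    for side in ("L", "R"):
        ty, tz, pit = _foot_series(
            t, full_events[side]["contact"], full_events[side]["toe_off"], params, anthro
        )
        sx = -1.0 if side == "L" else 1.0
        foot[side] = {"x": sx * hip_half, "toe_y": ty, "toe_z": tz, "pitch": pit}

    lf = anthro["foot"]
    markers: dict[str, np.ndarray] = {}
    centers: dict[str, np.ndarray] = {}

    ankles = {}
    for side in ("L", "R"):
        f = foot[side]
        cp, sp = np.cos(f["pitch"]), np.sin(f["pitch"])
        heel_y = f["toe_y"] - lf * cp
        heel_z = f["toe_z"] + lf * sp
        # ankle sits above/forward of the heel in the foot frame
        d_ay, d_az = 0.04, 0.062
        ank_y = heel_y + d_ay * cp + d_az * sp
        ank_z = heel_z - d_ay * sp + d_az * cp
        x = np.full(n_frames, f["x"])
        markers[f"{side}_toe"] = np.column_stack([x, f["toe_y"], f["toe_z"]])
        markers[f"{side}_calcaneus"] = np.column_stack([x, heel_y, heel_z])
        ankle = np.column_stack([x, ank_y, ank_z])
        ankles[side] = ankle
        sx = -1.0 if side == "L" else 1.0
        lat = np.array([sx * 0.04, 0.0, 0.0])
        markers[f"{side}_ankle_out"] = ankle + lat
        markers[f"{side}_ankle_in"] = ankle - lat
        centers[f"{side}_ankle"] = ankle
        centers[f"{side}_toe"] = markers[f"{side}_toe"]
        centers[f"{side}_heel"] = markers[f"{side}_calcaneus"]

    # pelvis height: peak leg reach is leg_extension * anatomical leg length
    l_leg = anthro["thigh"] + anthro["shank"]
    heave = 0.008 * np.cos(4.0 * np.pi * phi)
    reach_target = params.leg_extension * l_leg

    def max_reach(z0: float) -> float:
        r = 0.0
        for side in ("L", "R"):
            dz = z0 + heave - ankles[side][:, 2]
            dy = ankles[side][:, 1]  # hip y = 0
            r = max(r, float(np.max(np.hypot(dy, dz))))
        return r

    lo, hi = 0.5 * l_leg, 1.2 * l_leg
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if max_reach(mid) < reach_target:
            lo = mid
        else:
            hi = mid
    hip_z = 0.5 * (lo + hi)

    # legs by 2-link sagittal IK, knee anterior
    lt, ls = anthro["thigh"], anthro["shank"]
    for side in ("L", "R"):
        sx = -1.0 if side == "L" else 1.0
        hip = np.column_stack(
            [np.full(n_frames, sx * hip_half), np.zeros(n_frames), hip_z + heave]
        )
        centers[f"{side}_hip"] = hip
        ank = ankles[side]
        dy = ank[:, 1] - hip[:, 1]
        dz = ank[:, 2] - hip[:, 2]
        d = np.hypot(dy, dz)
        d = np.minimum(d, 0.9995 * (lt + ls))
        cosb = np.clip((lt**2 + d**2 - ls**2) / (2.0 * lt * d), -1.0, 1.0)
        beta = np.arccos(cosb)
        # rotate the hip->ankle unit vector by +-beta in the sagittal plane;
        # pick the anterior (larger y) knee of the two candidates
        uy, uz = dy / d, dz / d
        ky1 = hip[:, 1] + lt * (uy * np.cos(beta) + uz * np.sin(beta))
        kz1 = hip[:, 2] + lt * (uz * np.cos(beta) - uy * np.sin(beta))
        ky2 = hip[:, 1] + lt * (uy * np.cos(beta) - uz * np.sin(beta))
        kz2 = hip[:, 2] + lt * (uz * np.cos(beta) + uy * np.sin(beta))
        pick1 = ky1 >= ky2
        ky = np.where(pick1, ky1, ky2)
        kz = np.where(pick1, kz1, kz2)
        knee = np.column_stack([hip[:, 0], ky, kz])
        centers[f"{side}_knee"] = knee
        lat = np.array([sx * 0.05, 0.0, 0.0])
        markers[f"{side}_knee_out"] = knee + lat
        markers[f"{side}_knee_in"] = knee - lat
        markers[f"{side}_femur"] = hip + 0.55 * (knee - hip) + np.array([sx * 0.03, 0, 0])
        markers[f"{side}_shank"] = knee + 0.5 * (ank - knee) + np.array([sx * 0.03, 0, 0])
        # trochanter: hip displaced laterally along the inter-ASIS axis
        markers[f"{side}_trochanter"] = hip + np.array([sx * 0.25 * w_asis, 0.0, 0.0])

    # pelvis cluster (no pelvic rotation in this planar model)
    pelvis = np.column_stack([np.zeros(n_frames), np.zeros(n_frames), hip_z + 0.02 + heave])
    markers["L_ASIS"] = pelvis + np.array([-w_asis / 2, 0.09, 0.02])
    markers["R_ASIS"] = pelvis + np.array([+w_asis / 2, 0.09, 0.02])
    markers["L_PSIS"] = pelvis + np.array([-0.045, -0.10, 0.04])
    markers["R_PSIS"] = pelvis + np.array([+0.045, -0.10, 0.04])
    ls_joint = pelvis + np.array([0.0, -0.005, 0.03])
    centers["lumbosacral"] = ls_joint

    # trunk: lower segment upright, upper segment oscillates in the sagittal plane
    sway = 0.015 * np.sin(2.0 * np.pi * phi)
    a_lum = math.radians(params.lumbar_flex_amplitude_deg)
    theta_tl = a_lum * np.sin(2.0 * np.pi * phi)  # + = posterior lean
    tl_joint = ls_joint + np.array([0.0, 0.0, 1.0]) * anthro["lower_trunk"]
    tl_joint = tl_joint + np.column_stack([sway, np.zeros(n_frames), np.zeros(n_frames)])
    lu = anthro["upper_trunk"]
    ct, st = np.cos(theta_tl), np.sin(theta_tl)
    up = np.column_stack([np.zeros(n_frames), -st, ct])       # upper-trunk long axis
    fwd = np.column_stack([np.zeros(n_frames), ct, st])       # upper-trunk forward
    neck = tl_joint + lu * up
    centers["neck"] = neck

    def trunk_pt(x: float, y: float, z: float) -> np.ndarray:
        return tl_joint + np.column_stack(
            [np.full(n_frames, x), np.zeros(n_frames), np.zeros(n_frames)]
        ) + y * fwd + z * up

    markers["STER"] = trunk_pt(0.0, 0.055, lu)
    markers["C7"] = trunk_pt(0.0, -0.055, lu)
    markers["XIPH"] = trunk_pt(0.0, 0.07, 0.55 * lu)
    markers["T8"] = trunk_pt(0.0, -0.08, 0.55 * lu)
    markers["T12"] = trunk_pt(0.0, -0.07, 0.10 * lu)
    markers["L_rib"] = trunk_pt(-params.rib_width_m / 2, 0.02, 0.35 * lu)
    markers["R_rib"] = trunk_pt(+params.rib_width_m / 2, 0.02, 0.35 * lu)
    centers["thoracolumbar"] = np.mean(
        [markers[m] for m in ("STER", "T8", "T12", "L_rib", "R_rib")], axis=0
    )

    # arms: rigid upper arm swinging about a fixed shoulder, constant elbow flexion
    off = math.radians(params.arm_swing_backward_offset_deg)
    amp = math.radians(params.arm_swing_amplitude_deg)
    c_phase = 0.1 + 0.4 * params.swing_time_asymmetry
    lua, lfa = anthro["upper_arm"], anthro["forearm"]
    w_sh = anthro["shoulder_width"]
    for side in ("L", "R"):
        sx = -1.0 if side == "L" else 1.0
        lag = 0.0 if side == "R" else c_phase
        th = off + amp * np.cos(2.0 * np.pi * (phi - lag))  # + = arm posterior
        shoulder = trunk_pt(sx * w_sh / 2, 0.0, lu - 0.02)
        centers[f"{side}_shoulder"] = shoulder
        arm_dir = np.column_stack([np.zeros(n_frames), -np.sin(th), -np.cos(th)])
        elbow = shoulder + lua * arm_dir
        centers[f"{side}_elbow"] = elbow
        lat = np.array([sx * 0.045, 0.0, 0.0])
        markers[f"{side}_elbow_out"] = elbow + lat
        markers[f"{side}_elbow_in"] = elbow - lat
        ua_marker = shoulder + 0.45 * lua * arm_dir + np.array([sx * 0.03, 0.0, 0.0])
        markers[f"{side}_upper_arm"] = ua_marker
        # acromion above the shoulder by the inverse of the joint-center rule
        delta = 0.05
        for _ in range(4):
            acr = shoulder + np.array([0.0, 0.0, delta])
            delta = 0.17 * float(np.mean(np.linalg.norm(acr - ua_marker, axis=1)))
        markers[f"{side}_acromion"] = shoulder + np.array([0.0, 0.0, delta])
        th_f = th - math.radians(20.0)  # constant 20 deg elbow flexion, forearm forward
        markers[f"{side}_wrist"] = elbow + lfa * np.column_stack(
            [np.zeros(n_frames), -np.sin(th_f), -np.cos(th_f)]
        )

    # head: forward tilt (constant) + horizontal yaw oscillation
    tau = math.radians(params.head_tilt_deg)
    psi = math.radians(params.head_yaw_amplitude_deg) * np.cos(2.0 * np.pi * phi)
    lh = anthro["head"]
    cpsi, spsi = np.cos(psi), np.sin(psi)
    # head axis = Rz(psi) @ (0, sin tau, cos tau); forward tilt -> top anterior
    axis = np.column_stack([-spsi * math.sin(tau), cpsi * math.sin(tau),
                            np.full(n_frames, math.cos(tau))])
    head_top = neck + lh * axis
    markers["head_top"] = head_top
    centers["head_top"] = head_top
    for side, sx in (("L", -1.0), ("R", 1.0)):
        # ear offset in the head frame, tilted about x then yawed about z;
        # the interaural x-axis is unaffected by the tilt, so the measured
        # ear-line heading equals the yaw angle exactly
        ex, ey0, ez0 = sx * 0.075, 0.01, 0.06
        ey = ey0 * math.cos(tau) + ez0 * math.sin(tau)
        ez = -ey0 * math.sin(tau) + ez0 * math.cos(tau)
        markers[f"{side}_ear"] = neck + np.column_stack(
            [ex * cpsi - ey * spsi, ex * spsi + ey * cpsi, np.full(n_frames, ez)]
        )
    centers["L_ear"] = markers["L_ear"]
    centers["R_ear"] = markers["R_ear"]

    truth = _ground_truth(params, sched, centers, anthro, duration)

    if params.noise_sd_m > 0:
        for k in markers:
            markers[k] = markers[k] + rng.normal(0.0, params.noise_sd_m, markers[k].shape)

    traj = MarkerTrajectories(rate=rate, positions=markers)
    return SyntheticTrial(
        params=params,
        trajectories=traj,
        schedule=sched,
        ground_truth=truth,
        true_joint_centers=centers,
    )


# -- ground truth ------------------------------------------------------------


def _window_indices(ranges) -> np.ndarray:
    idx: set[int] = set()
    for lo, hi in ranges:
        idx.update(range(int(lo), int(hi) + 1))
    return np.asarray(sorted(idx))


def _ground_truth(params, sched, centers, anthro, duration) -> dict[str, float]:
    g: dict[str, float] = {}
    g["bmi"] = params.bmi
    g["whr"] = params.rib_width_m / params.trochanter_width_m
    g["toe_off_angle"] = params.toe_off_angle_deg
    g["clearance"] = params.toe_clearance_m / params.height_m
    g["lumbar_curvature"] = params.lumbar_flex_amplitude_deg * 2.0 / math.pi
    g["backward_arm_swing"] = anthro["upper_arm"] * math.sin(
        math.radians(params.arm_swing_backward_offset_deg + params.arm_swing_amplitude_deg)
    )

    # realized timing quantities from the schedule
    times = np.sort(np.concatenate([sched.contacts["L"], sched.contacts["R"]]))
    g["cadence"] = 60.0 * (len(times) - 1) / (times[-1] - times[0])
    rcs = sched.contacts["R"]
    durs = np.diff(rcs)
    g["stride_cv"] = float(durs.std(ddof=1) / durs.mean()) if len(durs) >= 3 else 0.0
    sw = {}
    for side in ("L", "R"):
        vals = []
        for to in sched.toe_offs[side]:
            nxt = sched.contacts[side][sched.contacts[side] > to]
            if nxt.size:
                vals.append(nxt[0] - to)
        sw[side] = np.mean(vals)
    g["symmetry"] = max(sw["L"], sw["R"]) / min(sw["L"], sw["R"])

    # head tilt: mean -A_neck over a dense cycle grid (yaw slightly shortens
    # the sagittal projection, so this is not exactly r*sin(tau))
    phi_g = np.linspace(0.0, 1.0, 721, endpoint=False)
    tau = math.radians(params.head_tilt_deg)
    psi = math.radians(params.head_yaw_amplitude_deg) * np.cos(2 * np.pi * phi_g)
    dy = np.cos(psi) * math.sin(tau)
    dz = math.cos(tau)
    theta = np.arctan2(-dy, dz)
    g["forward_head_tilt"] = float(np.mean(-anthro["head"] * np.sin(theta)))

    # horizontal head shake: F of the yaw angle on the contact windows
    idx = _window_indices([(0, 10), (40, 60), (90, 100)])
    psi_deg = params.head_yaw_amplitude_deg * np.cos(2 * np.pi * idx / 100.0)
    psi_full = params.head_yaw_amplitude_deg * np.cos(2 * np.pi * np.arange(101) / 100.0)
    g["horizontal_head_shake"] = float(np.mean(np.abs(psi_deg - psi_full.mean())))

    # knee extension: windows of the generator's own knee/ankle series
    rcs_in = sched.contacts["R"]
    vals = []
    n_frames = centers["L_knee"].shape[0]
    t = np.linspace(0.0, duration, n_frames, endpoint=False)
    for s, e in zip(rcs_in, rcs_in[1:]):
        per_cycle = 0.0
        ok = True
        for side, window in (("L", (0, 10)), ("R", (50, 60))):
            knee, ank = centers[f"{side}_knee"], centers[f"{side}_ankle"]
            d = ank - knee
            theta = np.arctan2(-d[:, 1], -d[:, 2])
            r = float(np.mean(np.linalg.norm(d, axis=1)))
            a = r * np.sin(theta)
            ph_t = s + (e - s) * np.arange(101) / 100.0
            if ph_t[-1] > t[-1]:
                ok = False
                break
            a_ph = np.interp(ph_t, t, a)
            widx = _window_indices([window])
            per_cycle += float(np.mean(-a_ph[widx]))
        if ok:
            vals.append(per_cycle)
    if vals:
        g["knee_extension"] = float(np.mean(vals))
    return {k: float(v) for k, v in g.items()}


# -- static calibration pose -------------------------------------------------


def generate_static_pose(
    params: WalkerParams, duration: float = 1.0, rate: float = 100.0
) -> MarkerTrajectories:
    """A standing calibration pose containing all markers (incl. medial)."""
    p = replace(
        params,
        stride_time_cv=0.0,
        swing_time_asymmetry=1.0,
        arm_swing_amplitude_deg=0.0,
        head_yaw_amplitude_deg=0.0,
        lumbar_flex_amplitude_deg=0.0,
        noise_sd_m=0.0,
        cadence_target=params.cadence_target,
    )
    # a slow "gait" whose first frames approximate standing is unnecessary;
    # instead take a single mid-stance frame of a zero-variability walk and
    # hold it for the requested duration
    trial = generate_walker_trajectories(p, duration=max(4.0 * p.stride_period_s, 5.0), rate=rate)
    traj = trial.trajectories
    # frame where both feet are flat: 30% into the first full right stance
    frame = int(0.3 * p.stride_period_s * rate)
    n = int(round(duration * rate))
    positions = {k: np.repeat(v[frame : frame + 1], n, axis=0) for k, v in traj.positions.items()}
    return MarkerTrajectories(rate=rate, positions=positions)
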