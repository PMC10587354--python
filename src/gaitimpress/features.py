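"""Explanatory gait variables: physique, silhouette, and health factors.

Per trial the pipeline produces one :class:`GaitFeatureSet` with

* physique: BMI (kg/m^2) and the marker-based waist-to-hip ratio
  ``WHR = d_rib / d_tro`` (horizontal left-right rib / trochanter marker
  distances);
* gait silhouette: lumbar curvature (mean sagittal flexibility of the
  thoracolumbar joint), backward arm swing (peak posterior upper-arm
  alignment), forward head tilt (mean ``-A_neck``), horizontal head shake
  (head-yaw flexibility around the foot contacts, 0-10 / 40-60 / 90-100%
  of the cycle);
* health: stride-time CV, cadence (steps/min), height-normalized toe
  clearance, swing-time symmetry ratio (>= 1, larger = more asymmetric),
  push-off knee extension, and toe-off angle.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .angles import JointAngleSeries, alignment_A, compute_joint_angles, flexibility_F
from .gait_cycle import (
    GaitCycleSet,
    GaitEvents,
    HEAD_SHAKE_WINDOWS,
    PUSHOFF_WINDOW_LEFT,
    PUSHOFF_WINDOW_RIGHT,
    detect_gait_events,
    normalize_to_cycle,
    phase_window_indices,
    segment_cycles,
)
from .joint_centers import JointCenterPolicy, compute_joint_centers
from .trajectories import MarkerTrajectories, fill_short_gaps


@dataclass
class GaitFeatureSet:
    """One trial's explanatory variables."""

    walker_id: str
    trial_id: str
    condition: str
    height_m: float
    weight_kg: float
    bmi: float
    whr: float
    lumbar_curvature: float       # degrees
    backward_arm_swing: float     # meters
    forward_head_tilt: float      # meters
    horizontal_head_shake: float  # degrees
    stride_cv: float
    cadence: float                # steps/min
    clearance: float              # height-normalized
    symmetry: float               # ratio >= 1
    knee_extension: float         # meters
    toe_off_angle: float          # degrees

    def to_dict(self) -> dict:
        return asdict(self)


FEATURE_COLUMNS = [f.name for f in GaitFeatureSet.__dataclass_fields__.values()]
FEATURE_NAMES = FEATURE_COLUMNS[5:]  # numeric explanatory variables incl. bmi/whr


def features_to_frame(feature_sets: list[GaitFeatureSet]) -> pd.DataFrame:
    """Tidy table, one row per (walker, trial, condition)."""
    return pd.DataFrame([fs.to_dict() for fs in feature_sets], columns=FEATURE_COLUMNS)


# -- helpers -----------------------------------------------------------------


def _retained_mask(cycles: GaitCycleSet, n_frames: int, rate: float) -> np.ndarray:
    mask = np.zeros(n_frames, dtype=bool)
    for s, e in cycles.cycles:
        mask[int(np.ceil(s * rate)) : int(np.floor(e * rate)) + 1] = True
    if not mask.any():
        raise ValueError("no retained-cycle frames")
    return mask


def _cycle_window_mean(
    series: np.ndarray,
    cycles: GaitCycleSet,
    rate: float,
    windows: list[tuple[float, float]],
) -> float:
    """Mean of a series over phase windows of 101-point normalized cycles."""
    idx = phase_window_indices(windows)
    vals = [normalize_to_cycle(series, cyc, rate)[idx].mean() for cyc in cycles.cycles]
    return float(np.mean(vals))


# -- physique ----------------------------------------------------------------


def compute_bmi(height_m: float, weight_kg: float) -> float:
    if height_m <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return weight_kg / height_m**2


def compute_whr(traj: MarkerTrajectories) -> float:
    """Waist-to-hip ratio from horizontal rib / trochanter marker distances.

    d_rib and d_tro are the per-frame horizontal-plane (x, y) distances
    between the left and right rib and greater-trochanter markers; the
    per-frame ratio is averaged over the trial.  Invariant to rigid
    rotations about the vertical axis.
    """
    traj.require("L_rib", "R_rib", "L_trochanter", "R_trochanter")
    d_rib = np.linalg.norm((traj["R_rib"] - traj["L_rib"])[:, :2], axis=1)
    d_tro = np.linalg.norm((traj["R_trochanter"] - traj["L_trochanter"])[:, :2], axis=1)
    if np.any(d_tro < 1e-9):
        raise ValueError("degenerate trochanter marker separation")
    return float(np.mean(d_rib / d_tro))


# -- silhouette --------------------------------------------------------------


def lumbar_curvature(angles: JointAngleSeries, cycles: GaitCycleSet) -> float:
    """Mean sagittal flexibility of the thoracolumbar joint (degrees)."""
    theta = angles.sagittal_deg["thoracolumbar"]
    mask = _retained_mask(cycles, len(theta), angles.rate)
    f = flexibility_F(theta, mean=float(theta[mask].mean()))
    return float(f[mask].mean())


def backward_arm_swing(angles: JointAngleSeries, cycles: GaitCycleSet) -> float:
    """Peak posterior upper-arm alignment over the cycle, L/R averaged (m)."""
    vals = []
    for side in ("L", "R"):
        a = alignment_A(
            angles.sagittal_deg[f"{side}_shoulder"],
            angles.segment_length_m[f"{side}_upper_arm"],
        )
        mask = _retained_mask(cycles, len(a), angles.rate)
        vals.append(a[mask].max())
    return float(np.mean(vals))


def forward_head_tilt(angles: JointAngleSeries, cycles: GaitCycleSet) -> float:
    """Mean of ``-A_neck`` over retained cycles (m); positive = forward tilt."""
    a = alignment_A(angles.sagittal_deg["neck"], angles.segment_length_m["head"])
    mask = _retained_mask(cycles, len(a), angles.rate)
    return float(-(a[mask].mean()))


def horizontal_head_shake(angles: JointAngleSeries, cycles: GaitCycleSet) -> float:
    """Head-yaw flexibility around the foot contacts (degrees).

    F of the horizontal-plane neck angle (mean over retained frames removed,
    so a constant head turn contributes nothing), averaged over the
    0-10 / 40-60 / 90-100% phase windows of each retained cycle.
    """
    psi = angles.horizontal_deg["neck"]
    mask = _retained_mask(cycles, len(psi), angles.rate)
    f = flexibility_F(psi, mean=float(psi[mask].mean()))
    return _cycle_window_mean(f, cycles, angles.rate, HEAD_SHAKE_WINDOWS)


# -- health ------------------------------------------------------------------


def stride_cv(cycles: GaitCycleSet) -> float:
    """Sample SD / mean of retained stride durations."""
    d = cycles.durations
    if len(d) < 3:
        raise ValueError("stride CV needs at least 3 retained cycles")
    return float(d.std(ddof=1) / d.mean())


def cadence(events: GaitEvents) -> float:
    """Steps per minute: contacts of both feet over the contact-to-contact span."""
    times = np.sort(
        np.concatenate([events.contact_times["L"], events.contact_times["R"]])
    )
    if len(times) < 2:
        raise ValueError("cadence needs at least 2 foot contacts")
    span = times[-1] - times[0]
    return float(60.0 * (len(times) - 1) / span)


def clearance(
    traj: MarkerTrajectories,
    events: GaitEvents,
    height_m: float,
    swing_core: tuple[float, float] = (0.2, 0.8),
    floor_percentile: float = 50.0,
    smooth_cutoff_hz: float | None = 10.0,
) -> float:
    """Height-normalized minimum swing-phase toe height above the floor.

    The minimum is taken over the middle portion of each swing (default
    20-80%), i.e. the mid-swing local minimum: at toe-off itself the toe is
    still at floor height by definition.  The floor reference is the median
    of stance-phase toe height (the foot is flat for most of stance, and
    unlike a low percentile the median is not biased by marker jitter or
    filter undershoot); the per-side summary is the
    median over swings, and the feature the mean of the two sides.  Toe
    height is low-passed first (zero-phase, 10 Hz: wide enough to keep the
    mid-swing dip, narrow enough that marker jitter does not bias the
    minimum).
    """
    if height_m <= 0:
        raise ValueError("height must be positive")
    from .filtering import lowpass_zero_phase

    t = traj.times
    per_side = []
    for side in ("L", "R"):
        z = traj[f"{side}_toe"][:, 2]
        if smooth_cutoff_hz is not None:
            z = lowpass_zero_phase(z, traj.rate, smooth_cutoff_hz)
        swing_mask = np.zeros(len(z), dtype=bool)
        minima = []
        for to in events.toe_off_times[side]:
            nxt = events.contact_times[side][events.contact_times[side] > to]
            if not nxt.size:
                continue
            fc = nxt[0]
            dur = fc - to
            core = (t >= to + swing_core[0] * dur) & (t <= to + swing_core[1] * dur)
            swing_mask |= (t > to) & (t < fc)
            if core.any():
                minima.append(z[core].min())
        if not minima:
            raise ValueError(f"side {side}: no complete swing phase")
        stance = ~swing_mask
        floor = np.percentile(z[stance], floor_percentile)
        per_side.append(max(float(np.median(minima) - floor), 0.0))
    return float(np.mean(per_side) / height_m)


def symmetry(events: GaitEvents) -> float:
    """Ratio of mean left/right swing times, larger over smaller (>= 1)."""
    sw = {side: events.swing_times(side) for side in ("L", "R")}
    for side, s in sw.items():
        if len(s) < 2:
            raise ValueError(f"side {side}: needs at least 2 swings")
    m = [sw["L"].mean(), sw["R"].mean()]
    return float(max(m) / min(m))


def knee_extension(
    angles: JointAngleSeries,
    cycles: GaitCycleSet,
    negate: bool = True,
) -> float:
    """Push-off knee-extension parameter (meters).

    Mean over cycles of [mean ``(-1)*A_knee_L`` over the left push-off
    window (0-10% of the right-anchored cycle) + mean ``(-1)*A_knee_R``
    over the right push-off window (50-60%)].  ``negate=False`` selects the
    sign-free variant.
    """
    sgn = -1.0 if negate else 1.0
    idx_l = phase_window_indices([PUSHOFF_WINDOW_LEFT])
    idx_r = phase_window_indices([PUSHOFF_WINDOW_RIGHT])
    a = {
        side: alignment_A(
            angles.sagittal_deg[f"{side}_knee"], angles.segment_length_m[f"{side}_shank"]
        )
        for side in ("L", "R")
    }
    vals = []
    for cyc in cycles.cycles:
        al = normalize_to_cycle(a["L"], cyc, angles.rate)
        ar = normalize_to_cycle(a["R"], cyc, angles.rate)
        vals.append(sgn * al[idx_l].mean() + sgn * ar[idx_r].mean())
    return float(np.mean(vals))


def toe_off_angle(traj: MarkerTrajectories, events: GaitEvents) -> float:
    """Heel-toe segment elevation above the horizontal at toe-off (degrees).

    Positive when the heel is above the toe (heel raised for push-off);
    per-leg mean over steps, then L/R averaged.
    """
    t = traj.times
    per_side = []
    for side in ("L", "R"):
        toe = traj[f"{side}_toe"]
        heel = traj[f"{side}_calcaneus"]
        angs = []
        for to in events.toe_off_times[side]:
            if to < t[0] or to > t[-1]:
                continue
            pt = np.array([np.interp(to, t, toe[:, j]) for j in range(3)])
            ph = np.array([np.interp(to, t, heel[:, j]) for j in range(3)])
            dz = ph[2] - pt[2]
            dh = np.linalg.norm((ph - pt)[:2])
            angs.append(np.degrees(np.arctan2(dz, dh)))
        if not angs:
            raise ValueError(f"side {side}: no toe-off events in range")
        per_side.append(np.mean(angs))
    return float(np.mean(per_side))


# -- orchestration -----------------------------------------------------------


@dataclass
class ExtractionReport:
    """Provenance of a feature extraction run."""

    n_cycles_retained: int
    n_cycles_excluded: int
    excluded: list[tuple[float, float, str]]


def extract_features(
    traj: MarkerTrajectories,
    height_m: float,
    weight_kg: float,
    walker_id: str = "walker",
    trial_id: str = "trial",
    condition: str = "barefoot",
    policy: JointCenterPolicy | None = None,
    calibration: MarkerTrajectories | None = None,
    knee_sign_negate: bool = True,
    return_report: bool = False,
):
    """Run the full chain: preprocessing -> events -> cycles -> features.

    ``calibration`` (a static pose containing the medial markers) is only
    needed when the trial lacks the medial knee/ankle/elbow markers.
    """
    stage = "preprocessing"
    try:
        if any(not np.all(np.isfinite(p)) for p in traj.positions.values()):
            traj = fill_short_gaps(traj)
        missing_medial = [
            m for m in ("L_knee_in", "R_knee_in", "L_ankle_in", "R_ankle_in",
                        "L_elbow_in", "R_elbow_in")
            if m not in traj
        ]
        if missing_medial:
            if calibration is None:
                raise ValueError(
                    f"medial markers missing ({missing_medial}) and no calibration pose given"
                )
            from .reconstruction import reconstruct_medial_markers

            traj = reconstruct_medial_markers(traj, calibration)

        stage = "joint centers"
        jc = compute_joint_centers(traj, policy)
        stage = "event detection"
        events = detect_gait_events(jc, traj)
        stage = "cycle segmentation"
        cycles = segment_cycles(events)
        stage = "joint angles"
        angles = compute_joint_angles(jc)

        stage = "feature computation"
        fs = GaitFeatureSet(
            walker_id=walker_id,
            trial_id=trial_id,
            condition=condition,
            height_m=height_m,
            weight_kg=weight_kg,
            bmi=compute_bmi(height_m, weight_kg),
            whr=compute_whr(traj),
            lumbar_curvature=lumbar_curvature(angles, cycles),
            backward_arm_swing=backward_arm_swing(angles, cycles),
            forward_head_tilt=forward_head_tilt(angles, cycles),
            horizontal_head_shake=horizontal_head_shake(angles, cycles),
            stride_cv=stride_cv(cycles),
            cadence=cadence(events),
            clearance=clearance(traj, events, height_m),
            symmetry=symmetry(events),
            knee_extension=knee_extension(angles, cycles, negate=knee_sign_negate),
            toe_off_angle=toe_off_angle(traj, events),
        )
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    if return_report:
        report = ExtractionReport(
            n_cycles_retained=len(cycles),
            n_cycles_excluded=len(cycles.excluded),
            excluded=cycles.excluded,
        )
        return fs, report
    return fs
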