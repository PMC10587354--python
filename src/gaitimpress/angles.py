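"""Projection joint angles and the flexibility/alignment formalism.

Two scalar time-series primitives drive every silhouette feature:

* flexibility ``F_i = |theta_i - mean(theta_i)|`` -- the pointwise absolute
  deviation of a joint angle from its trial mean; identically zero for a
  completely immobile joint;
* alignment ``A_i = r_i * sin(theta_i)`` -- the anterior-posterior deviation
  of a segment's distal end, in meters, positive when the distal end lies
  posterior to the joint.

Angles are plane projections: sagittal (y-z) angles are measured from the
vertical, positive toward posterior (-y); horizontal (x-y) angles are
measured in the lab frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .joint_centers import JointCenters


def sagittal_projection_angle(
    proximal: np.ndarray,
    distal: np.ndarray,
    reference: str = "down",
) -> np.ndarray:
    """Signed sagittal-plane angle (degrees) of the proximal->distal vector.

    The vector is projected on the y-z plane and measured from the vertical:
    ``reference="down"`` for segments hanging below their joint (limbs),
    ``reference="up"`` for segments above (trunk, head).  Positive when the
    distal end lies posterior (-y) to the proximal.

    Frames where the sagittal projection vanishes are flagged (NaN) and
    linearly interpolated when isolated.
    """
    d = np.asarray(distal, dtype=float) - np.asarray(proximal, dtype=float)
    dy, dz = d[..., 1], d[..., 2]
    if reference == "down":
        ang = np.degrees(np.arctan2(-dy, -dz))
    elif reference == "up":
        ang = np.degrees(np.arctan2(-dy, dz))
    else:
        raise ValueError("reference must be 'down' or 'up'")
    tiny = np.hypot(dy, dz) < 1e-12
    if tiny.any():
        ang = ang.copy()
        ang[tiny] = np.nan
        idx = np.arange(len(ang))
        good = ~tiny
        if good.sum() < 2:
            raise ValueError("sagittal projection vanishes on (almost) every frame")
        ang[tiny] = np.interp(idx[tiny], idx[good], ang[good])
    return ang


def horizontal_heading_angle(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Horizontal-plane (lab frame) heading of a left->right marker axis, degrees.

    Zero when the body faces the walking direction (+y); positive for a
    counterclockwise (leftward) turn seen from above.  Used for head yaw via
    the ear markers, robust even when the segment's long axis is vertical.
    """
    r = np.asarray(right, dtype=float) - np.asarray(left, dtype=float)
    return np.degrees(np.arctan2(r[..., 1], r[..., 0]))


def flexibility_F(theta: np.ndarray, mean: float | None = None) -> np.ndarray:
    """Pointwise absolute deviation of an angle series from its mean (degrees).

    ``mean`` overrides the series mean, e.g. to use the mean over retained
    gait-cycle frames rather than the whole recording.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.size == 0:
        raise ValueError("empty angle series")
    m = theta.mean() if mean is None else mean
    return np.abs(theta - m)


def alignment_A(theta: np.ndarray, r: float) -> np.ndarray:
    """Alignment series ``A = r * sin(theta)`` in meters; positive = backward."""
    if r <= 0:
        raise ValueError("segment length must be positive")
    return r * np.sin(np.radians(np.asarray(theta, dtype=float)))


@dataclass
class JointAngleSeries:
    """Projection angles (degrees) and segment lengths for the feature set.

    sagittal_deg keys: ``neck``, ``thoracolumbar``, ``L_shoulder``,
    ``R_shoulder``, ``L_knee``, ``R_knee``.  horizontal_deg keys: ``neck``
    (ear-axis heading), ``thoracolumbar`` (acromion-axis heading).
    segment_length_m keys: ``head``, ``L_upper_arm``, ``R_upper_arm``,
    ``L_shank``, ``R_shank``.
    """

    rate: float
    sagittal_deg: dict[str, np.ndarray] = field(default_factory=dict)
    horizontal_deg: dict[str, np.ndarray] = field(default_factory=dict)
    segment_length_m: dict[str, float] = field(default_factory=dict)


def compute_joint_angles(jc: JointCenters) -> JointAngleSeries:
    """Build the angle series the silhouette/health features need.

    Segment lengths are trial means of the corresponding center distances;
    they must be near-constant (CV < 5%) for a rigid-segment model to hold,
    otherwise a warning-level ValueError is raised.
    """
    out = JointAngleSeries(rate=jc.rate)

    def seg_len(a: np.ndarray, b: np.ndarray, name: str) -> float:
        d = np.linalg.norm(b - a, axis=1)
        m = float(d.mean())
        if m <= 0:
            raise ValueError(f"degenerate segment {name!r}")
        if d.std() / m > 0.05:
            raise ValueError(f"segment {name!r} length CV exceeds 5% (non-rigid input?)")
        return m

    # head: neck center -> head-top marker, measured from upward vertical
    out.sagittal_deg["neck"] = sagittal_projection_angle(jc["neck"], jc["head_top"], "up")
    out.segment_length_m["head"] = seg_len(jc["neck"], jc["head_top"], "head")
    out.horizontal_deg["neck"] = horizontal_heading_angle(jc["L_ear"], jc["R_ear"])

    # upper trunk: thoracolumbar -> neck center
    out.sagittal_deg["thoracolumbar"] = sagittal_projection_angle(
        jc["thoracolumbar"], jc["neck"], "up"
    )

    for side in ("L", "R"):
        out.sagittal_deg[f"{side}_shoulder"] = sagittal_projection_angle(
            jc[f"{side}_shoulder"], jc[f"{side}_elbow"], "down"
        )
        out.segment_length_m[f"{side}_upper_arm"] = seg_len(
            jc[f"{side}_shoulder"], jc[f"{side}_elbow"], f"{side}_upper_arm"
        )
        out.sagittal_deg[f"{side}_knee"] = sagittal_projection_angle(
            jc[f"{side}_knee"], jc[f"{side}_ankle"], "down"
        )
        out.segment_length_m[f"{side}_shank"] = seg_len(
            jc[f"{side}_knee"], jc[f"{side}_ankle"], f"{side}_shank"
        )
    return out
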