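"""Joint-center geometry from marker positions.

Ankle, knee, and elbow centers are lateral-medial marker midpoints.  Hip and
trunk joints use calibration-free geometric rules gathered in
:class:`JointCenterPolicy`, so an alternative regression set can be swapped in
without touching the feature code.  After computation, every center series is
passed through the zero-phase 6 Hz low-pass filter (configurable), matching
the filter-after-centers processing order; a switch allows pre-filtering the
markers instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filtering import lowpass_zero_phase
from .markers import bilateral
from .trajectories import MarkerTrajectories

#: Joint labels produced for each side.
SIDED_JOINTS = ("ankle", "knee", "elbow", "hip", "shoulder", "toe", "heel")
MIDLINE_JOINTS = ("lumbosacral", "thoracolumbar", "neck", "head_top")


@dataclass
class JointCenterPolicy:
    """Geometric rules for joints without a lateral/medial marker pair.

    hip_medial_fraction
        Hip center = greater-trochanter marker displaced medially along the
        inter-ASIS axis by this fraction of the inter-ASIS distance.
    shoulder_drop_fraction
        Shoulder center = acromion displaced inferiorly (-z) by this
        fraction of the trial-mean acromion-to-upper-arm-marker distance.
    thoracolumbar_markers
        Markers whose centroid defines the thoracolumbar joint.
    filter_cutoff_hz / filter_order
        Zero-phase Butterworth applied to the computed center series
        (set ``filter_cutoff_hz=None`` to disable).
    filter_markers_first
        If True, filter raw marker series before computing centers instead
        of filtering the centers afterwards.
    """

    hip_medial_fraction: float = 0.25
    shoulder_drop_fraction: float = 0.17
    thoracolumbar_markers: tuple[str, ...] = ("STER", "T8", "T12", "L_rib", "R_rib")
    filter_cutoff_hz: float | None = 6.0
    filter_order: int = 4
    filter_markers_first: bool = False


@dataclass
class JointCenters:
    """Joint-center time series with the same frame count/rate as the source."""

    rate: float
    centers: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def frames(self) -> int:
        return next(iter(self.centers.values())).shape[0]

    def __getitem__(self, key: str) -> np.ndarray:
        return self.centers[key]

    def __contains__(self, key: str) -> bool:
        return key in self.centers


def _midpoint(traj: MarkerTrajectories, a: str, b: str) -> np.ndarray:
    traj.require(a, b)
    return 0.5 * (traj[a] + traj[b])


def compute_joint_centers(
    traj: MarkerTrajectories,
    policy: JointCenterPolicy | None = None,
) -> JointCenters:
    """Compute all joint centers used by the feature set.

    Rules (see :class:`JointCenterPolicy` for the configurable ones):

    * ankle / knee / elbow: lateral-medial midpoints (medial markers must
      already be reconstructed);
    * hip: greater trochanter displaced medially along the inter-ASIS axis;
    * lumbosacral: midpoint of the ASIS-pair and PSIS-pair centroids;
    * thoracolumbar: centroid of sternum, T8, T12, and rib markers;
    * neck: midpoint of C7 and sternum;
    * shoulder: acromion displaced inferiorly;
    * head_top / toe / heel: marker pass-through.
    """
    policy = policy or JointCenterPolicy()

    src = traj
    if policy.filter_markers_first and policy.filter_cutoff_hz is not None:
        src = MarkerTrajectories(
            rate=traj.rate,
            positions={
                k: lowpass_zero_phase(v, traj.rate, policy.filter_cutoff_hz, policy.filter_order)
                for k, v in traj.positions.items()
            },
        )

    c: dict[str, np.ndarray] = {}
    for side in ("L", "R"):
        for joint in ("ankle", "knee", "elbow"):
            c[f"{side}_{joint}"] = _midpoint(src, f"{side}_{joint}_out", f"{side}_{joint}_in")

    # hip: trochanter displaced medially along the inter-ASIS axis
    src.require("L_ASIS", "R_ASIS", "L_trochanter", "R_trochanter")
    asis_axis = src["R_ASIS"] - src["L_ASIS"]
    asis_dist = np.linalg.norm(asis_axis, axis=1, keepdims=True)
    asis_unit = asis_axis / asis_dist
    shift = policy.hip_medial_fraction * asis_dist
    c["L_hip"] = src["L_trochanter"] + asis_unit * shift   # medial for left = toward right
    c["R_hip"] = src["R_trochanter"] - asis_unit * shift

    src.require("L_PSIS", "R_PSIS")
    asis_mid = 0.5 * (src["L_ASIS"] + src["R_ASIS"])
    psis_mid = 0.5 * (src["L_PSIS"] + src["R_PSIS"])
    c["lumbosacral"] = 0.5 * (asis_mid + psis_mid)

    src.require(*policy.thoracolumbar_markers)
    c["thoracolumbar"] = np.mean([src[m] for m in policy.thoracolumbar_markers], axis=0)

    c["neck"] = _midpoint(src, "C7", "STER")

    for side in ("L", "R"):
        src.require(f"{side}_acromion", f"{side}_upper_arm")
        acr = src[f"{side}_acromion"]
        dist = np.linalg.norm(acr - src[f"{side}_upper_arm"], axis=1).mean()
        drop = np.array([0.0, 0.0, policy.shoulder_drop_fraction * dist])
        c[f"{side}_shoulder"] = acr - drop

    src.require("head_top", "L_ear", "R_ear", "L_toe", "R_toe", "L_calcaneus", "R_calcaneus")
    c["head_top"] = src["head_top"].copy()
    for side in ("L", "R"):
        c[f"{side}_toe"] = src[f"{side}_toe"].copy()
        c[f"{side}_heel"] = src[f"{side}_calcaneus"].copy()
    c["L_ear"] = src["L_ear"].copy()
    c["R_ear"] = src["R_ear"].copy()

    if not policy.filter_markers_first and policy.filter_cutoff_hz is not None:
        c = {
            k: lowpass_zero_phase(v, traj.rate, policy.filter_cutoff_hz, policy.filter_order)
            for k, v in c.items()
        }
    return JointCenters(rate=traj.rate, centers=c)
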