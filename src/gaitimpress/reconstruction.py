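"""Medial-marker reconstruction by three-point (rigid local frame) interpolation.

Medial joint markers (elbow-in, knee-in, ankle-in) are removed during walking
trials because they interfere with natural arm/leg motion.  They are present
in a static calibration pose, from which each medial marker's coordinates are
expressed in the local rigid frame of three same-segment reference markers;
that fixed local offset is then re-applied at every trial frame.
"""

from __future__ import annotations

import numpy as np

from .trajectories import MarkerTrajectories

#: Default reference triads: medial marker -> three markers rigid with it.
DEFAULT_TRIADS: dict[str, tuple[str, str, str]] = {}
for _side in ("L", "R"):
    DEFAULT_TRIADS[f"{_side}_elbow_in"] = (
        f"{_side}_upper_arm",
        f"{_side}_elbow_out",
        f"{_side}_wrist",
    )
    DEFAULT_TRIADS[f"{_side}_knee_in"] = (
        f"{_side}_femur",
        f"{_side}_knee_out",
        f"{_side}_shank",
    )
    DEFAULT_TRIADS[f"{_side}_ankle_in"] = (
        f"{_side}_knee_out",
        f"{_side}_shank",
        f"{_side}_ankle_out",
    )


def _local_frame(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray):
    """Orthonormal frame from a marker triad; works on (..., 3) stacks.

    Origin p1; x along p1->p2; z normal to the triad plane; y completes.
    Raises if the triad is (near-)collinear.
    """
    e1 = p2 - p1
    n1 = np.linalg.norm(e1, axis=-1, keepdims=True)
    v = p3 - p1
    cross = np.cross(e1, v)
    n3 = np.linalg.norm(cross, axis=-1, keepdims=True)
    if np.any(n1 < 1e-12) or np.any(n3 < 1e-9 * np.maximum(n1, 1e-12)):
        raise ValueError("collinear (or coincident) reference triad")
    e1 = e1 / n1
    e3 = cross / n3
    e2 = np.cross(e3, e1)
    # rotation matrices with columns e1, e2, e3
    return p1, np.stack([e1, e2, e3], axis=-1)


def reconstruct_medial_markers(
    traj: MarkerTrajectories,
    calibration: MarkerTrajectories,
    triads: dict[str, tuple[str, str, str]] | None = None,
    overwrite: bool = False,
) -> MarkerTrajectories:
    """Add medial-marker series to ``traj`` from a static calibration pose.

    For each medial marker present in ``calibration`` (and absent from the
    trial unless ``overwrite``), its mean position in the calibration local
    frame of the reference triad is computed and re-applied rigidly at every
    trial frame.  The operation commutes with rigid motions of the whole
    body between calibration and trial.
    """
    triads = triads or DEFAULT_TRIADS
    out = traj.copy()
    for medial, (a, b, c) in triads.items():
        if medial not in calibration.positions:
            continue
        if medial in out.positions and not overwrite:
            continue
        calibration.require(a, b, c)
        traj.require(a, b, c)

        origin_c, rot_c = _local_frame(
            calibration[a], calibration[b], calibration[c]
        )
        # local coordinates, averaged over calibration frames
        rel = calibration[medial] - origin_c
        local = np.einsum("fij,fi->fj", rot_c, rel).mean(axis=0)

        origin_t, rot_t = _local_frame(traj[a], traj[b], traj[c])
        out.positions[medial] = origin_t + np.einsum("fij,j->fi", rot_t, local)
    return out
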