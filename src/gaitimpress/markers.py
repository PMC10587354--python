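"""Canonical marker vocabulary for the 42-marker full-body set.

The set follows a standard treadmill gait protocol: a single head-top marker,
midline trunk markers (sternum, xiphoid, C7/T8/T12 vertebrae), and bilateral
markers on the head (ears), upper limbs, pelvis, and lower limbs. Bilateral
labels carry an ``L_``/``R_`` prefix.

Coordinate convention used throughout the package: ``x`` mediolateral,
``y`` anterior-posterior with +y the walking direction, ``z`` vertical up,
expressed in the treadmill frame in meters.
"""

from __future__ import annotations

# Midline (unilateral) markers
MIDLINE_MARKERS = (
    "head_top",   # top of the head
    "STER",       # upper margin of the sternum
    "XIPH",       # sternum-xiphoid process
    "C7",
    "T8",
    "T12",
)

# Bilateral markers (each exists with an L_ and R_ prefix)
BILATERAL_MARKERS = (
    "ear",
    "acromion",
    "upper_arm",
    "elbow_in",    # humerus-medial epicondyle
    "elbow_out",   # humerus-lateral epicondyle
    "wrist",
    "rib",         # lowest edge of rib
    "ASIS",        # anterior superior iliac spine
    "PSIS",        # posterior superior iliac spine
    "trochanter",  # greater trochanter
    "femur",
    "knee_out",    # lateral knee joint space
    "knee_in",     # medial knee joint space
    "shank",
    "ankle_out",   # malleolus lateralis
    "ankle_in",    # malleolus medialis
    "toe",
    "calcaneus",
)

#: Medial markers that interfere with natural walking; removed during trials
#: and reconstructed offline by three-point interpolation.
MEDIAL_MARKERS = ("elbow_in", "knee_in", "ankle_in")


def bilateral(name: str) -> tuple[str, str]:
    """Return the (left, right) labels of a bilateral marker."""
    return f"L_{name}", f"R_{name}"


CANONICAL_MARKERS: tuple[str, ...] = MIDLINE_MARKERS + tuple(
    f"{side}_{name}" for name in BILATERAL_MARKERS for side in ("L", "R")
)

assert len(CANONICAL_MARKERS) == 42

# Default alias table mapping common vendor spellings to canonical labels.
# Users can extend this via MarkerTrajectories readers (``aliases=`` argument).
DEFAULT_ALIASES: dict[str, str] = {
    "HeadTop": "head_top",
    "Sternum": "STER",
    "Xiphoid": "XIPH",
    "c7": "C7",
    "t8": "T8",
    "t12": "T12",
}
for _name in BILATERAL_MARKERS:
    for _side in ("L", "R"):
        _canon = f"{_side}_{_name}"
        DEFAULT_ALIASES[f"{_name}_{_side}"] = _canon
        DEFAULT_ALIASES[f"{_side}{_name.capitalize()}"] = _canon
        DEFAULT_ALIASES[_canon.lower()] = _canon
for _name in MIDLINE_MARKERS:
    DEFAULT_ALIASES[_name.lower()] = _name


def canonicalize(label: str, aliases: dict[str, str] | None = None) -> str | None:
    """Map a raw label to the canonical vocabulary, or None if unknown."""
    table = dict(DEFAULT_ALIASES)
    if aliases:
        table.update(aliases)
    if label in CANONICAL_MARKERS:
        return label
    if label in table:
        return table[label]
    stripped = label.strip().replace("-", "_").replace(" ", "_")
    if stripped in CANONICAL_MARKERS:
        return stripped
    if stripped in table:
        return table[stripped]
    return None
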