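"""Labeled 3D marker trajectories and plain-text readers/writers (TRC, CSV).

A :class:`MarkerTrajectories` holds a uniformly sampled time series of 3D
positions (meters) per canonical marker label.  Readers validate labels
against the canonical 42-marker vocabulary via a configurable alias table,
convert units to meters, and optionally fill short interior gaps.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import CANONICAL_MARKERS, canonicalize

_UNIT_SCALE = {"m": 1.0, "meters": 1.0, "mm": 1e-3, "millimeters": 1e-3, "cm": 1e-2}


class MarkerValidationError(ValueError):
    """Raised when a marker file fails strict-mode validation."""


@dataclass
class MarkerTrajectories:
    """Uniformly sampled marker position time series.

    Parameters
    ----------
    rate : float
        Sampling rate in Hz.
    positions : dict[str, ndarray]
        Map canonical label -> (n_frames, 3) array of positions in meters,
        ordered x (mediolateral), y (anterior-posterior, +y walking
        direction), z (vertical up).
    """

    rate: float
    positions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {v.shape[0] for v in self.positions.values()}
        if len(lengths) > 1:
            raise ValueError(f"marker series have unequal lengths: {sorted(lengths)}")
        for label, arr in self.positions.items():
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"marker {label!r}: expected (n, 3) array, got {arr.shape}")

    @property
    def frames(self) -> int:
        if not self.positions:
            return 0
        return next(iter(self.positions.values())).shape[0]

    @property
    def labels(self) -> list[str]:
        return list(self.positions)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.frames) / self.rate

    def __getitem__(self, label: str) -> np.ndarray:
        return self.positions[label]

    def __contains__(self, label: str) -> bool:
        return label in self.positions

    def copy(self) -> "MarkerTrajectories":
        return MarkerTrajectories(
            rate=self.rate,
            positions={k: v.copy() for k, v in self.positions.items()},
        )

    def require(self, *labels: str) -> None:
        """Raise naming the first missing marker label."""
        for label in labels:
            if label not in self.positions:
                raise MarkerValidationError(f"required marker missing: {label!r}")

    def translated(self, v) -> "MarkerTrajectories":
        """Return a copy rigidly translated by vector ``v`` (3,)."""
        v = np.asarray(v, dtype=float)
        return MarkerTrajectories(
            rate=self.rate,
            positions={k: p + v for k, p in self.positions.items()},
        )

    def validate(self, strict: bool = True, required: tuple[str, ...] | None = None) -> None:
        """Check finiteness and (strict) full canonical coverage."""
        for label, arr in self.positions.items():
            if not np.all(np.isfinite(arr)):
                raise MarkerValidationError(f"non-finite values in marker {label!r}")
        wanted = required if required is not None else (CANONICAL_MARKERS if strict else ())
        missing = [m for m in wanted if m not in self.positions]
        if missing:
            raise MarkerValidationError(f"missing markers: {missing}")

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_arrays(cls, rate: float, positions: dict[str, np.ndarray]) -> "MarkerTrajectories":
        return cls(rate=rate, positions={k: np.asarray(v, dtype=float) for k, v in positions.items()})


def fill_short_gaps(traj: MarkerTrajectories, max_gap: int = 10) -> MarkerTrajectories:
    """Fill interior NaN gaps of at most ``max_gap`` frames by cubic interpolation.

    Longer gaps, or gaps touching either end of the recording, raise.
    """
    from scipy.interpolate import CubicSpline

    out = traj.copy()
    for label, arr in out.positions.items():
        bad = ~np.all(np.isfinite(arr), axis=1)
        if not bad.any():
            continue
        # locate runs of bad frames
        idx = np.flatnonzero(bad)
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in runs:
            if len(run) > max_gap:
                raise ValueError(
                    f"marker {label!r}: gap of {len(run)} frames exceeds max_gap={max_gap}"
                )
            if run[0] == 0 or run[-1] == arr.shape[0] - 1:
                raise ValueError(f"marker {label!r}: gap touches recording boundary")
        good = ~bad
        t = np.arange(arr.shape[0], dtype=float)
        spline = CubicSpline(t[good], arr[good])
        arr[bad] = spline(t[bad])
    return out


# -- long-form CSV -----------------------------------------------------------


def write_csv(traj: MarkerTrajectories, path: str | os.PathLike, units: str = "m") -> None:
    """Write long-form CSV: frame, time, marker, x, y, z."""
    scale = 1.0 / _UNIT_SCALE[units]
    rows = []
    t = traj.times
    for label in traj.labels:
        p = traj[label] * scale
        rows.append(
            pd.DataFrame(
                {
                    "frame": np.arange(traj.frames),
                    "time": t,
                    "marker": label,
                    "x": p[:, 0],
                    "y": p[:, 1],
                    "z": p[:, 2],
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(f"# rate_hz={traj.rate} units={units}\n")
        df.to_csv(fh, index=False)


def read_csv(
    path: str | os.PathLike,
    units: str | None = None,
    rate: float | None = None,
    strict: bool = True,
    aliases: dict[str, str] | None = None,
) -> MarkerTrajectories:
    """Read a long-form CSV (frame, time, marker, x, y, z).

    Units and rate are taken from a leading ``# rate_hz=... units=...``
    comment when not given explicitly.  Labels are canonicalized; in strict
    mode an unmappable label raises naming the offender.
    """
    header_units, header_rate = None, None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                if tok.startswith("rate_hz="):
                    header_rate = float(tok.split("=", 1)[1])
                elif tok.startswith("units="):
                    header_units = tok.split("=", 1)[1]
            body = fh.read()
        else:
            body = first + fh.read()
    df = pd.read_csv(io.StringIO(body))
    units = units or header_units
    rate = rate or header_rate
    if units is None or rate is None:
        raise ValueError("CSV must declare units and rate (header comment or arguments)")
    scale = _UNIT_SCALE[units]

    positions: dict[str, np.ndarray] = {}
    for label, grp in df.groupby("marker", sort=False):
        canon = canonicalize(str(label), aliases)
        if canon is None:
            if strict:
                raise MarkerValidationError(f"unknown marker label: {label!r}")
            continue
        grp = grp.sort_values("frame")
        t = grp["time"].to_numpy()
        if len(t) > 1:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], atol=1e-6):
                raise ValueError(f"non-uniform timestamps for marker {label!r}")
        positions[canon] = grp[["x", "y", "z"]].to_numpy(dtype=float) * scale
    return MarkerTrajectories(rate=rate, positions=positions)


# -- TRC ---------------------------------------------------------------------


def write_trc(traj: MarkerTrajectories, path: str | os.PathLike, units: str = "m") -> None:
    """Write a TRC file (the plain-text mocap interchange format)."""
    scale = 1.0 / _UNIT_SCALE[units]
    labels = traj.labels
    n = traj.frames
    with open(path, "w") as fh:
        name = os.path.basename(str(path))
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{name}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(f"{traj.rate}\t{traj.rate}\t{n}\t{len(labels)}\t{units}\t{traj.rate}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(labels) + "\t\t\t\n")
        comps = "\t".join(f"X{i + 1}\tY{i + 1}\tZ{i + 1}" for i in range(len(labels)))
        fh.write("\t\t" + comps + "\n")
        t = traj.times
        data = np.column_stack([traj[lbl] * scale for lbl in labels])
        for i in range(n):
            vals = "\t".join(f"{v:.8f}" for v in data[i])
            fh.write(f"{i + 1}\t{t[i]:.6f}\t{vals}\n")


def read_trc(
    path: str | os.PathLike,
    strict: bool = True,
    aliases: dict[str, str] | None = None,
) -> MarkerTrajectories:
    """Read a TRC file; rate and units come from its header."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 5:
        raise ValueError("TRC file too short")
    meta = lines[2].split("\t")
    rate = float(meta[0])
    units = meta[4].strip().lower()
    if units not in _UNIT_SCALE:
        raise ValueError(f"TRC declares unsupported units: {units!r}")
    scale = _UNIT_SCALE[units]
    raw_labels = [s for s in lines[3].split("\t")[2:] if s.strip()]

    labels: list[str | None] = []
    for lbl in raw_labels:
        canon = canonicalize(lbl, aliases)
        if canon is None and strict:
            raise MarkerValidationError(f"unknown marker label: {lbl!r}")
        labels.append(canon)

    rows = []
    for line in lines[5:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        rows.append([float(p) if p.strip() else np.nan for p in parts[2:]])
    data = np.asarray(rows, dtype=float)
    if data.shape[1] < 3 * len(raw_labels):
        raise ValueError("TRC data rows shorter than marker count implies")

    positions = {}
    for j, canon in enumerate(labels):
        if canon is None:
            continue
        positions[canon] = data[:, 3 * j : 3 * j + 3] * scale
    return MarkerTrajectories(rate=rate, positions=positions)


def read_marker_file(
    path: str | os.PathLike,
    fmt: str | None = None,
    strict: bool = True,
    aliases: dict[str, str] | None = None,
    **kwargs,
) -> MarkerTrajectories:
    """Read TRC or long-form CSV by extension or explicit ``fmt``.

    C3D is a binary vendor format and is not supported; convert to TRC/CSV
    upstream.
    """
    fmt = (fmt or os.path.splitext(str(path))[1].lstrip(".")).lower()
    if fmt == "trc":
        return read_trc(path, strict=strict, aliases=aliases)
    if fmt == "csv":
        return read_csv(path, strict=strict, aliases=aliases, **kwargs)
    if fmt == "c3d":
        raise NotImplementedError("C3D is not supported; export TRC or CSV instead")
    raise ValueError(f"unknown marker file format: {fmt!r}")
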