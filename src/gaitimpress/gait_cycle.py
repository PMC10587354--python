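"""Gait event detection, stride segmentation, and cycle normalization.

Treadmill convention: the stride (gait cycle) is anchored at RIGHT foot
contact, so 0%/100% are right contacts, the left contact falls near 50%, the
left push-off window is 0-10% and the right push-off window 50-60% of the
cycle.

Events are detected from pelvis-relative foot-marker excursions, which is
robust for treadmill data without force plates: foot contact is the local
maximum of the heel (calcaneus) marker's anterior position relative to the
pelvis centroid, and toe-off the local minimum of the toe marker's relative
anterior position.  Event times are refined to sub-frame precision with a
parabolic fit around each extremum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .filtering import lowpass_zero_phase
from .joint_centers import JointCenters
from .trajectories import MarkerTrajectories


class EventDetectionError(RuntimeError):
    pass


@dataclass
class GaitEvents:
    """Per-side foot-contact and toe-off events.

    ``*_frames`` are integer frame indices; ``*_times`` are the parabolic
    sub-frame refinements in seconds (same ordering).
    """

    rate: float
    contact_frames: dict[str, np.ndarray] = field(default_factory=dict)
    toe_off_frames: dict[str, np.ndarray] = field(default_factory=dict)
    contact_times: dict[str, np.ndarray] = field(default_factory=dict)
    toe_off_times: dict[str, np.ndarray] = field(default_factory=dict)

    def swing_times(self, side: str) -> np.ndarray:
        """Durations toe-off -> next same-side contact, in seconds."""
        to = self.toe_off_times[side]
        fc = self.contact_times[side]
        out = []
        for t in to:
            nxt = fc[fc > t]
            if nxt.size:
                out.append(nxt[0] - t)
        return np.asarray(out)

    def validate(self) -> None:
        """Contacts and toe-offs must strictly alternate within each side."""
        for side in ("L", "R"):
            merged = sorted(
                [(t, "c") for t in self.contact_times[side]]
                + [(t, "t") for t in self.toe_off_times[side]]
            )
            kinds = [k for _, k in merged]
            for a, b in zip(kinds, kinds[1:]):
                if a == b:
                    raise EventDetectionError(
                        f"side {side}: events do not alternate (double {a!r})"
                    )
        for side in ("L", "R"):
            sw = self.swing_times(side)
            if sw.size and sw.min() <= 0:
                raise EventDetectionError(f"side {side}: non-positive swing duration")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for side in ("L", "R"):
            for f, t in zip(self.contact_frames[side], self.contact_times[side]):
                rows.append((side, "foot_contact", int(f), float(t)))
            for f, t in zip(self.toe_off_frames[side], self.toe_off_times[side]):
                rows.append((side, "toe_off", int(f), float(t)))
        df = pd.DataFrame(rows, columns=["side", "event_type", "frame", "time_s"])
        return df.sort_values("time_s").reset_index(drop=True)


@dataclass
class GaitCycleSet:
    """Retained right-contact-to-right-contact strides with landmarks."""

    rate: float
    cycles: list[tuple[float, float]]            # (start_time, end_time), seconds
    left_contact_phase: list[float]              # % of cycle
    toe_off_phase: list[dict[str, float]]        # per cycle {side: %}
    excluded: list[tuple[float, float, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cycles)

    @property
    def durations(self) -> np.ndarray:
        return np.asarray([e - s for s, e in self.cycles])


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-frame vertex of a parabola through (i-1, i, i+1); clipped to +-0.5."""
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if abs(denom) < 1e-15:
        return float(i)
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(i) + float(np.clip(delta, -0.5, 0.5))


def _extrema(signal: np.ndarray, rate: float, min_period_s: float, kind: str):
    y = signal if kind == "max" else -signal
    dist = max(2, int(round(min_period_s * rate)))
    peaks, _ = find_peaks(y, distance=dist, prominence=0.1 * np.ptp(y))
    times = np.array([_parabolic_refine(y, int(p)) / rate for p in peaks])
    return peaks.astype(int), times


def _dominant_period(y: np.ndarray, rate: float) -> float:
    """Stride period estimate from the autocorrelation of a pelvis-relative signal."""
    y = y - y.mean()
    ac = np.correlate(y, y, mode="full")[len(y) - 1 :]
    lo = int(0.4 * rate)          # strides shorter than 0.4 s are not human walking
    hi = min(len(ac) - 1, int(3.0 * rate))
    if hi <= lo:
        raise EventDetectionError("recording too short to estimate a stride period")
    lag = lo + int(np.argmax(ac[lo:hi]))
    return lag / rate


def detect_gait_events(
    jc: JointCenters,
    traj: MarkerTrajectories,
    smooth_cutoff_hz: float | None = 6.0,
    boundary_margin_s: float = 0.25,
) -> GaitEvents:
    """Detect foot contacts and toe-offs from pelvis-relative foot markers.

    The raw heel/toe markers from ``traj`` are used (lightly smoothed for
    noise robustness) rather than the filtered joint-center pass-throughs,
    so detection does not depend on the feature-filter settings.  Extrema
    within ``boundary_margin_s`` of either end of the recording are
    discarded: edge peaks lack a full flank and are unreliable.
    """
    traj.require("L_calcaneus", "R_calcaneus", "L_toe", "R_toe", "L_ASIS", "R_ASIS", "L_PSIS", "R_PSIS")
    pelvis_y = np.mean(
        [traj[m][:, 1] for m in ("L_ASIS", "R_ASIS", "L_PSIS", "R_PSIS")], axis=0
    )

    def rel_y(label: str) -> np.ndarray:
        y = traj[label][:, 1] - pelvis_y
        if smooth_cutoff_hz is not None:
            y = lowpass_zero_phase(y, traj.rate, smooth_cutoff_hz)
        return y

    period = _dominant_period(rel_y("R_calcaneus"), traj.rate)
    min_sep = 0.65 * period

    t_end = traj.frames / traj.rate

    def trim(frames, times):
        keep = (times >= boundary_margin_s) & (times <= t_end - boundary_margin_s)
        return frames[keep], times[keep]

    ev = GaitEvents(rate=traj.rate)
    for side in ("L", "R"):
        cf, ct = trim(*_extrema(rel_y(f"{side}_calcaneus"), traj.rate, min_sep, "max"))
        tf, tt = trim(*_extrema(rel_y(f"{side}_toe"), traj.rate, min_sep, "min"))
        if len(cf) < 2 or len(tf) < 2:
            raise EventDetectionError(
                f"side {side}: fewer than 2 strides detected "
                f"({len(cf)} contacts, {len(tf)} toe-offs)"
            )
        ev.contact_frames[side], ev.contact_times[side] = cf, ct
        ev.toe_off_frames[side], ev.toe_off_times[side] = tf, tt
    ev.validate()
    return ev


def segment_cycles(
    events: GaitEvents,
    left_contact_band: tuple[float, float] = (30.0, 70.0),
) -> GaitCycleSet:
    """One candidate cycle per consecutive right-contact pair.

    Cycles whose left contact does not fall inside ``left_contact_band``
    (percent of cycle) are excluded and logged, never repaired: silently
    fixing a landmark would bias stride-variability and symmetry measures.
    """
    rc = events.contact_times["R"]
    if len(rc) < 2:
        raise EventDetectionError("no complete right-contact-to-right-contact cycle")
    cycles, lphase, tophase, excluded = [], [], [], []
    for s, e in zip(rc, rc[1:]):
        dur = e - s
        lc = events.contact_times["L"]
        inside = lc[(lc > s) & (lc < e)]
        if len(inside) != 1:
            excluded.append((s, e, f"{len(inside)} left contacts inside cycle"))
            continue
        phase = 100.0 * (inside[0] - s) / dur
        if not (left_contact_band[0] < phase < left_contact_band[1]):
            excluded.append((s, e, f"left contact at {phase:.1f}%"))
            continue
        tos = {}
        ok = True
        for side in ("L", "R"):
            t = events.toe_off_times[side]
            inside_to = t[(t > s) & (t < e)]
            if len(inside_to) != 1:
                ok = False
                excluded.append((s, e, f"{len(inside_to)} {side} toe-offs inside cycle"))
                break
            tos[side] = 100.0 * (inside_to[0] - s) / dur
        if not ok:
            continue
        cycles.append((float(s), float(e)))
        lphase.append(float(phase))
        tophase.append(tos)
    if not cycles:
        raise EventDetectionError("all candidate cycles were excluded")
    return GaitCycleSet(
        rate=events.rate,
        cycles=cycles,
        left_contact_phase=lphase,
        toe_off_phase=tophase,
        excluded=excluded,
    )


def normalize_to_cycle(
    series: np.ndarray,
    cycle: tuple[float, float],
    rate: float,
) -> np.ndarray:
    """Linearly interpolate a time series onto 101 phase points (0..100%).

    ``series`` may be (n,) or (n, k); cycle bounds are in seconds.
    """
    series = np.asarray(series, dtype=float)
    s, e = cycle
    if e - s < 2.0 / rate:
        raise ValueError("cycle shorter than 2 frames")
    n = series.shape[0]
    if s < 0 or e > (n - 1) / rate + 1e-9:
        raise ValueError("cycle outside series bounds")
    t = np.arange(n) / rate
    phase_t = np.linspace(s, e, 101)
    if series.ndim == 1:
        return np.interp(phase_t, t, series)
    return np.column_stack([np.interp(phase_t, t, series[:, j]) for j in range(series.shape[1])])


def phase_window_indices(ranges: list[tuple[float, float]]) -> np.ndarray:
    """Closed-interval index set on the 101-point phase grid for given % ranges."""
    idx: set[int] = set()
    for lo, hi in ranges:
        if not (0 <= lo < hi <= 100):
            raise ValueError(f"invalid phase range ({lo}, {hi})")
        idx.update(range(int(np.ceil(lo)), int(np.floor(hi)) + 1))
    return np.asarray(sorted(idx), dtype=int)


#: The paper-defined phase windows.
PUSHOFF_WINDOW_LEFT = (0.0, 10.0)
PUSHOFF_WINDOW_RIGHT = (50.0, 60.0)
HEAD_SHAKE_WINDOWS = [(0.0, 10.0), (40.0, 60.0), (90.0, 100.0)]
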