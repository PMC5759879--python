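"""Kinematic endpoint extraction from marker and centre-of-pressure data.

This module turns one recorded trial (15 named 3-D marker trajectories,
optionally a 2-D centre-of-pressure trace) into the scalar screening
endpoints: posture geometry from quiet stance, convex-hull sway area and
95th-percentile sway velocity from CoP traces, and side-bending depth
from the fingertip trajectories.

Coordinate frame (fixed throughout the package): X = anterior (+),
Y = vertical up (+), Z = subject's left (+).  Units are centimetres,
degrees, seconds.  Frames are 0-based; analysis windows are half-open
``[start, end)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from scipy import signal

from .variables import VARIABLE_NAMES, variable

__all__ = [
    "MARKER_NAMES",
    "MarkerTrajectorySet",
    "CoPTrace",
    "FilterSpec",
    "StanceWindow",
    "VariablePanel",
    "InsufficientDataError",
    "MissingMarkerError",
    "InvalidConfigError",
    "WindowTooShortError",
    "lowpass_filter",
    "detect_single_leg_window",
    "cop_velocity",
    "max_sway_velocity",
    "sway_area",
    "convex_hull",
    "posture_variables",
    "balance_variables",
    "side_bend_variables",
    "extract_panel",
    "pct_left_leg",
]

#: The 15 marker labels every trial must carry.
MARKER_NAMES: tuple[str, ...] = (
    "head_top",
    "acromion_l", "acromion_r",
    "c7",
    "fingertip_l", "fingertip_r",
    "trochanter_l", "trochanter_r",
    "mid_pelvic",
    "knee_lat_l", "knee_med_l", "knee_lat_r", "knee_med_r",
    "malleolus_l", "malleolus_r",
)


class InvalidConfigError(ValueError):
    """A parameter is outside its admissible range."""


class InsufficientDataError(ValueError):
    """Too few frames/points for the requested quantity."""


class MissingMarkerError(KeyError):
    """A required marker label is absent from the trajectory set."""


class WindowTooShortError(InsufficientDataError):
    """Less than the minimum analysable hold remains after the stance event.

    Downstream this maps to a missing-trial outcome, not a crash.
    """


@dataclass
class MarkerTrajectorySet:
    """Named 3-D marker trajectories for one trial.

    ``data`` maps marker name -> (frames, 3) array in cm, all markers
    sharing one frame count; ``rate`` is the sampling rate in Hz.
    """

    data: dict[str, np.ndarray]
    rate: float

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise InvalidConfigError(f"sampling rate must be > 0, got {self.rate}")
        counts = set()
        for name, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise InvalidConfigError(f"marker {name!r} must be (frames, 3)")
            if not np.all(np.isfinite(arr)):
                raise InvalidConfigError(f"marker {name!r} has non-finite samples")
            self.data[name] = arr
            counts.add(arr.shape[0])
        if len(counts) > 1:
            raise InvalidConfigError(f"markers disagree on frame count: {sorted(counts)}")

    @property
    def n_frames(self) -> int:
        return next(iter(self.data.values())).shape[0]

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.data[name]
        except KeyError:
            raise MissingMarkerError(name) from None

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.data]
        if missing:
            raise MissingMarkerError(", ".join(missing))


@dataclass
class CoPTrace:
    """Centre-of-pressure trace: anterior-posterior and medio-lateral series (cm).

    ``ml`` is signed towards the subject's left (+Z of the lab frame).
    """

    ap: np.ndarray
    ml: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.ap = np.asarray(self.ap, dtype=float).ravel()
        self.ml = np.asarray(self.ml, dtype=float).ravel()
        if self.rate <= 0:
            raise InvalidConfigError(f"sampling rate must be > 0, got {self.rate}")
        if self.ap.shape != self.ml.shape:
            raise InvalidConfigError("ap and ml series must have equal length")
        if not (np.all(np.isfinite(self.ap)) and np.all(np.isfinite(self.ml))):
            raise InvalidConfigError("CoP trace has non-finite samples")

    @property
    def n_frames(self) -> int:
        return self.ap.shape[0]

    def axis(self, which: str) -> np.ndarray:
        if which not in ("ap", "ml"):
            raise InvalidConfigError(f"axis must be 'ap' or 'ml', got {which!r}")
        return self.ap if which == "ap" else self.ml

    def crop(self, window: "StanceWindow") -> "CoPTrace":
        return CoPTrace(self.ap[window.start:window.end],
                        self.ml[window.start:window.end], self.rate)


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth filter settings (7 Hz cut-off by default)."""

    cutoff: float = 7.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, rate: float) -> None:
        if not 0 < self.cutoff < rate / 2:
            raise InvalidConfigError(
                f"cutoff {self.cutoff} Hz must lie in (0, Nyquist={rate / 2} Hz)")
        if self.order < 1:
            raise InvalidConfigError("filter order must be >= 1")


@dataclass(frozen=True)
class StanceWindow:
    """Half-open frame window ``[start, end)`` of a single-leg hold."""

    start: int
    end: int
    rate: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InvalidConfigError("window must satisfy 0 <= start < end")

    @property
    def n_frames(self) -> int:
        return self.end - self.start

    @property
    def duration(self) -> float:
        return self.n_frames / self.rate


@dataclass
class VariablePanel:
    """The 18 screening endpoints for one subject-session.

    Missing endpoints are ``nan`` with the reason under ``missing``;
    ``source_trial`` records which trial served each endpoint.
    """

    values: dict[str, float] = field(default_factory=dict)
    source_trial: dict[str, int] = field(default_factory=dict)
    missing: dict[str, str] = field(default_factory=dict)
    subject: str | None = None
    occasion: int | None = None
    device: str | None = None

    def __post_init__(self) -> None:
        for name in VARIABLE_NAMES:
            self.values.setdefault(name, math.nan)

    def set(self, name: str, value: float, trial: int | None = None) -> None:
        variable(name)  # raises on unknown endpoint
        self.values[name] = float(value)
        if trial is not None:
            self.source_trial[name] = trial

    def mark_missing(self, name: str, reason: str) -> None:
        variable(name)
        self.values[name] = math.nan
        self.missing[name] = reason

    def __getitem__(self, name: str) -> float:
        return self.values[name]


# ---------------------------------------------------------------------------
# signal primitives


def lowpass_filter(series: np.ndarray, spec: FilterSpec, rate: float) -> np.ndarray:
    """Butterworth low-pass filter a 1-D series, preserving length and DC gain.

    Zero-phase mode runs the filter forward and backward (``filtfilt``)
    with reflective padding, squaring the magnitude response; single-pass
    mode applies ``lfilter`` once (order-4 gain 1/sqrt(2) at the cut-off).
    """
    series = np.asarray(series, dtype=float).ravel()
    spec.validate(rate)
    min_len = 3 * spec.order + 1
    if series.size <= min_len:
        raise InsufficientDataError(
            f"need > {min_len} samples for an order-{spec.order} filter, got {series.size}")
    b, a = signal.butter(spec.order, spec.cutoff, btype="low", fs=rate)
    if spec.zero_phase:
        return signal.filtfilt(b, a, series, padtype="even")
    # prepend a reflected ramp so the single pass starts settled, then drop it
    pad = min(series.size - 1, 3 * max(len(a), len(b)))
    padded = np.concatenate([2 * series[0] - series[pad:0:-1], series])
    return signal.lfilter(b, a, padded)[pad:]


def detect_single_leg_window(swing_ankle_ap: np.ndarray, rate: float,
                             hold: float = 5.0) -> StanceWindow:
    """Locate the single-leg analysis window from the swinging ankle.

    The hold starts at the frame where the swinging-leg ankle reaches its
    anterior (A/P) maximum — the earliest such frame on ties — and lasts
    ``hold`` seconds (3-5 s; 90-150 frames at 30 Hz), truncated to the
    recording but never below 3 s of data.
    """
    x = np.asarray(swing_ankle_ap, dtype=float).ravel()
    if x.size == 0:
        raise InsufficientDataError("empty swing-ankle series")
    if not 3.0 <= hold <= 5.0:
        raise InvalidConfigError(f"hold must lie in [3, 5] s, got {hold}")
    start = int(np.argmax(x))  # argmax returns the first of equal maxima
    end = start + round(hold * rate)
    end = min(end, x.size)
    if (end - start) / rate < 3.0:
        raise WindowTooShortError(
            f"only {(x.size - start) / rate:.2f} s of data after the stance "
            f"event at frame {start}; need >= 3 s")
    return StanceWindow(start, end, rate)


def cop_velocity(trace: CoPTrace, axis: str) -> np.ndarray:
    """Per-axis sway speed series v_i = |s_{i+1} - s_i| * rate (cm/s).

    Each axis is differenced separately (no resultant-path speed); output
    is one sample shorter than the input.
    """
    s = trace.axis(axis)
    if s.size < 2:
        raise InsufficientDataError("need >= 2 frames for a velocity")
    return np.abs(np.diff(s)) * trace.rate


def max_sway_velocity(velocities: np.ndarray, percentile: float = 95.0) -> float:
    """Maximal sway velocity as a high percentile of the speed series.

    The 95th percentile replaces the absolute maximum to suppress
    numerical outliers of the CoP computation.  The quantile uses the
    linear-interpolation definition between order statistics
    (``numpy.percentile`` default).
    """
    v = np.asarray(velocities, dtype=float).ravel()
    if v.size == 0:
        raise InsufficientDataError("empty velocity series")
    if not 0 <= percentile <= 100:
        raise InvalidConfigError(f"percentile must lie in [0, 100], got {percentile}")
    return float(np.percentile(np.abs(v), percentile))


def convex_hull(points: np.ndarray) -> np.ndarray:
    """Convex hull of 2-D points by Andrew's monotone chain.

    Returns hull vertices in counter-clockwise order without repeating
    the first vertex.  Collinear points on hull edges are dropped.
    """
    pts = np.unique(np.asarray(points, dtype=float).reshape(-1, 2), axis=0)
    if pts.shape[0] <= 2:
        return pts

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    def half(seq):
        chain: list[np.ndarray] = []
        for p in seq:
            while len(chain) >= 2 and cross(chain[-2], chain[-1], p) <= 0:
                chain.pop()
            chain.append(p)
        return chain

    lower = half(pts)
    upper = half(pts[::-1])
    return np.array(lower[:-1] + upper[:-1])


def sway_area(trace: CoPTrace | np.ndarray) -> float:
    """Sway area (cm^2): area of the convex hull of the CoP point cloud.

    Computed by the monotone-chain hull followed by the shoelace formula;
    degenerate (collinear or repeated) point sets have area 0.
    """
    if isinstance(trace, CoPTrace):
        pts = np.column_stack([trace.ap, trace.ml])
    else:
        pts = np.asarray(trace, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 3:
        raise InsufficientDataError("need >= 3 CoP samples for a sway area")
    hull = convex_hull(pts)
    if hull.shape[0] < 3:
        return 0.0
    x, y = hull[:, 0], hull[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


# ---------------------------------------------------------------------------
# endpoint geometry


def pct_left_leg(ml: float, ankle_mid_z: float, left_ankle_z: float) -> float:
    """Map a medio-lateral position to the %-left-leg scale.

    50% at the ankle midpoint, 100% at the left malleolus, linear in
    between and extrapolated beyond (values outside [0, 100] indicate a
    CoP beyond the ankle span and are preserved, never clamped).
    """
    half_span = left_ankle_z - ankle_mid_z
    if half_span == 0:
        raise InvalidConfigError("ankle markers coincide; %-left-leg undefined")
    return 50.0 + 50.0 * (ml - ankle_mid_z) / half_span


def _mean_pos(markers: MarkerTrajectorySet, name: str) -> np.ndarray:
    return markers[name].mean(axis=0)


def posture_variables(markers: MarkerTrajectorySet, cop: CoPTrace | None,
                      height_reported: float, *,
                      head_top_offset: float = 0.0,
                      frontal_reference: str = "shoulders",
                      filter_spec: FilterSpec = FilterSpec()) -> dict[str, float]:
    """Posture endpoints from a quiet double-leg stance trial.

    All offsets are time means over the whole (filtered) trial:

    * ``P-HL`` head-top Z offset from the ankle midpoint (cm, + = left);
    * ``P-HF`` head-top X offset from the shoulder midpoint (cm,
      + = anterior); ``frontal_reference="feet"`` switches the reference
      to the ankle midpoint;
    * ``P-NA`` signed sagittal angle (deg) between the spine line
      (mid-hip -> mid-shoulder) and the neck line (mid-shoulder -> head
      top), positive when the head end leans anterior;
    * ``P-PP`` trochanter-midpoint Z offset from the ankle midpoint (cm);
    * ``P-HS`` estimated standing height (mean vertical head-top position
      plus ``head_top_offset``) minus the reported height (cm);
    * ``P-WB`` mean CoP M/L position on the %-left-leg scale (requires a
      CoP trace; omitted otherwise).
    """
    markers.require("head_top", "acromion_l", "acromion_r",
                    "trochanter_l", "trochanter_r", "mid_pelvic",
                    "malleolus_l", "malleolus_r")
    if markers.n_frames < markers.rate:
        raise InsufficientDataError("need >= 1 s of stance data")
    if height_reported <= 0:
        raise InvalidConfigError("reported height must be > 0")

    head = _mean_pos(markers, "head_top")
    sh_mid = (_mean_pos(markers, "acromion_l") + _mean_pos(markers, "acromion_r")) / 2
    hip_mid = (_mean_pos(markers, "trochanter_l") + _mean_pos(markers, "trochanter_r")) / 2
    ank_l = _mean_pos(markers, "malleolus_l")
    ank_r = _mean_pos(markers, "malleolus_r")
    ank_mid = (ank_l + ank_r) / 2

    out: dict[str, float] = {}
    out["P-HL"] = float(head[2] - ank_mid[2])
    if frontal_reference == "shoulders":
        out["P-HF"] = float(head[0] - sh_mid[0])
    elif frontal_reference == "feet":
        out["P-HF"] = float(head[0] - ank_mid[0])
    else:
        raise InvalidConfigError(f"frontal_reference must be 'shoulders' or 'feet'")

    # sagittal (X, Y) plane angle between spine and neck lines, signed so
    # that an anteriorly displaced head gives a positive angle
    spine = sh_mid - hip_mid
    neck = head - sh_mid
    a_spine = math.atan2(spine[0], spine[1])
    a_neck = math.atan2(neck[0], neck[1])
    out["P-NA"] = math.degrees(a_neck - a_spine)

    out["P-PP"] = float(hip_mid[2] - ank_mid[2])
    out["P-HS"] = float(head[1] + head_top_offset - height_reported)

    if cop is not None:
        ml = cop.ml
        if ml.size > 3 * filter_spec.order + 1:
            ml = lowpass_filter(ml, filter_spec, cop.rate)
        out["P-WB"] = pct_left_leg(float(ml.mean()), float(ank_mid[2]), float(ank_l[2]))
    return out


def balance_variables(trace: CoPTrace, window: StanceWindow | None = None, *,
                      filter_spec: FilterSpec = FilterSpec(),
                      percentile: float = 95.0) -> dict[str, float]:
    """Sway endpoints {SA, SVAP, SVML} for one stance trial.

    The trace is low-pass filtered, cropped to ``window`` (whole trial
    when ``None``), then summarised as convex-hull area and per-axis
    percentile sway velocity.  An all-constant trace is a legitimate
    perfectly-still record and yields zeros.
    """
    if np.ptp(trace.ap) == 0.0 and np.ptp(trace.ml) == 0.0:
        # a perfectly still record is legitimate at sensor resolution
        return {"SA": 0.0, "SVAP": 0.0, "SVML": 0.0}
    ap = lowpass_filter(trace.ap, filter_spec, trace.rate)
    ml = lowpass_filter(trace.ml, filter_spec, trace.rate)
    filt = CoPTrace(ap, ml, trace.rate)
    if window is not None:
        if window.end > filt.n_frames:
            raise InvalidConfigError("window extends beyond the trace")
        filt = filt.crop(window)
    return {
        "SA": sway_area(filt),
        "SVAP": max_sway_velocity(cop_velocity(filt, "ap"), percentile),
        "SVML": max_sway_velocity(cop_velocity(filt, "ml"), percentile),
    }


def side_bend_variables(markers: MarkerTrajectorySet, cop: CoPTrace | None,
                        height_reported: float, side: str, *,
                        filter_spec: FilterSpec = FilterSpec()) -> dict[str, float]:
    """Side-bending endpoints for one bend trial.

    ``SB-LF``/``SB-RF``: minimal fingertip height over the trial divided
    by the reported body height, in % (a *lower* value means a deeper
    bend).  ``SB-%BW`` (left bends only, with a CoP trace): the CoP M/L
    position at the frame of maximal leftward excursion, on the
    %-left-leg scale.
    """
    if side not in ("left", "right"):
        raise InvalidConfigError(f"side must be 'left' or 'right', got {side!r}")
    if height_reported <= 0:
        raise InvalidConfigError("reported height must be > 0")
    tip = "fingertip_l" if side == "left" else "fingertip_r"
    markers.require(tip)
    y = markers[tip][:, 1]
    if y.size > 3 * filter_spec.order + 1:
        y = lowpass_filter(y, filter_spec, markers.rate)
    out = {("SB-LF" if side == "left" else "SB-RF"):
           float(100.0 * y.min() / height_reported)}
    if side == "left" and cop is not None:
        markers.require("malleolus_l", "malleolus_r")
        ml = cop.ml
        if ml.size > 3 * filter_spec.order + 1:
            ml = lowpass_filter(ml, filter_spec, cop.rate)
        ank_l = _mean_pos(markers, "malleolus_l")
        ank_mid = (ank_l + _mean_pos(markers, "malleolus_r")) / 2
        out["SB-%BW"] = pct_left_leg(float(ml.max()), float(ank_mid[2]), float(ank_l[2]))
    return out


# ---------------------------------------------------------------------------
# panel assembly


def _extract_task(trial, panel: VariablePanel, trial_no: int, *,
                  percentile: float, filter_spec: FilterSpec,
                  height_reported: float) -> None:
    """Fill the endpoints one trial contributes; raises on invalid data."""
    task = trial.task
    if task == "stand":
        post = posture_variables(trial.markers, trial.cop, height_reported,
                                 filter_spec=filter_spec)
        for k, v in post.items():
            panel.set(k, v, trial_no)
        if trial.cop is not None:
            bal = balance_variables(trial.cop, None, filter_spec=filter_spec,
                                    percentile=percentile)
            for k, v in bal.items():
                panel.set(f"DS-{k}", v, trial_no)
    elif task in ("single_left", "single_right"):
        if trial.cop is None:
            raise InsufficientDataError("single-leg trial without a CoP trace")
        swing = "malleolus_r" if task == "single_left" else "malleolus_l"
        window = detect_single_leg_window(trial.markers[swing][:, 0],
                                          trial.markers.rate, hold=5.0)
        if trial.cop.rate != trial.markers.rate:
            scale = trial.cop.rate / trial.markers.rate
            window = StanceWindow(round(window.start * scale),
                                  round(window.end * scale), trial.cop.rate)
        prefix = "SSL" if task == "single_left" else "SSR"
        bal = balance_variables(trial.cop, window, filter_spec=filter_spec,
                                percentile=percentile)
        for k, v in bal.items():
            panel.set(f"{prefix}-{k}", v, trial_no)
    elif task == "side_bend":
        for side in ("left", "right"):
            res = side_bend_variables(trial.markers, trial.cop, height_reported,
                                      side, filter_spec=filter_spec)
            for k, v in res.items():
                panel.set(k, v, trial_no)
    else:
        raise InvalidConfigError(f"unknown task {task!r}")


_TASK_ENDPOINTS = {
    "stand": ("P-HL", "P-HF", "P-NA", "P-PP", "P-HS", "P-WB",
              "DS-SA", "DS-SVAP", "DS-SVML"),
    "single_left": ("SSL-SA", "SSL-SVAP", "SSL-SVML"),
    "single_right": ("SSR-SA", "SSR-SVAP", "SSR-SVML"),
    "side_bend": ("SB-LF", "SB-RF", "SB-%BW"),
}


def extract_panel(session: Iterable, height_reported: float, *,
                  percentile: float = 95.0,
                  filter_spec: FilterSpec = FilterSpec()) -> VariablePanel:
    """Assemble the 18-endpoint panel for one subject-session.

    ``session`` holds trial recordings (objects with ``task``, ``markers``,
    ``cop``, and optionally ``trial`` and ``valid`` attributes).  Per task
    the third trial is preferred, then the second, then the first; a trial
    that raises (or is flagged invalid by the recording source) falls back
    to the next one, and a task with no usable trial leaves its endpoints
    explicitly missing.
    """
    trials = list(session)
    if not trials:
        raise InvalidConfigError("empty session")
    panel = VariablePanel()
    by_task: dict[str, list] = {}
    for i, t in enumerate(trials):
        by_task.setdefault(t.task, []).append((getattr(t, "trial", i + 1), t))
    for task, entries in by_task.items():
        entries.sort(key=lambda e: e[0], reverse=True)  # trial 3 -> 2 -> 1
        last_err = "no valid trial"
        for trial_no, trial in entries:
            if not getattr(trial, "valid", True):
                last_err = "trial flagged invalid by source"
                continue
            try:
                _extract_task(trial, panel, trial_no, percentile=percentile,
                              filter_spec=filter_spec,
                              height_reported=height_reported)
                break
            except (InsufficientDataError, MissingMarkerError, InvalidConfigError) as e:
                last_err = f"{type(e).__name__}: {e}"
        else:
            for name in _TASK_ENDPOINTS.get(task, ()):
                panel.mark_missing(name, last_err)
    for task in _TASK_ENDPOINTS:
        if task not in by_task:
            for name in _TASK_ENDPOINTS[task]:
                panel.mark_missing(name, "task not recorded")
    return panel
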