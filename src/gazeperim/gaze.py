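"""Gaze-trace analysis: saccade detection and response classification.

In button-free perimetry the response to a light stimulus is the eye itself:
a saccade from fixation toward the stimulated location, landing close to its
angle, counts as "seen".  This module turns a gaze-angle time series plus
the stimulus event log into per-event seen/not-seen verdicts with latency
and landing error, and tallies the exam's reliability indices:

* false positives — qualifying eye movements with no stimulus present
  (responses to catch trials, or stray fixation-break saccades in silent
  gaps: the habitual responding the randomized schedule is designed to
  expose);
* false negatives — full-brightness stimuli that drew no response.

Verdicts depend only on event onsets and the trace, never on event order.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scheduler import StimulusEvent

__all__ = [
    "GazeSample",
    "GazeTrace",
    "SaccadeEvent",
    "ResponseRecord",
    "detect_saccades",
    "classify_response",
    "classify_schedule",
    "tally_errors",
    "response_accuracy_vs_duration",
]

# verdict bases
SACCADE_TOWARD = "saccade_toward"
NO_MOVEMENT = "no_movement"
BLINK_GAP = "blink_gap"
CATCH = "catch"

DEFAULT_WINDOW = (0.15, 1.5)  # seconds after onset
DEFAULT_TOLERANCE = 5.0  # degrees on the stimulated axis
DEFAULT_VEL_THRESHOLD = 30.0  # deg/s
DEFAULT_MIN_AMPLITUDE = 2.0  # degrees
FIXATION_RADIUS = 5.0  # a "from fixation" saccade starts within this radius


@dataclass(frozen=True)
class GazeSample:
    t: float
    azimuth: float
    elevation: float
    valid: bool = True


class GazeTrace:
    """Time-ordered gaze angles at a fixed nominal sampling rate.

    Stored as parallel numpy arrays (``t``, ``azimuth``, ``elevation``,
    ``valid``); invalid samples mark blinks or frames where no eye was
    detected and are excluded from all kinematic computations.
    """

    def __init__(self, t, azimuth, elevation, valid=None, rate: float = 60.0):
        self.t = np.asarray(t, dtype=float)
        self.azimuth = np.asarray(azimuth, dtype=float)
        self.elevation = np.asarray(elevation, dtype=float)
        if valid is None:
            valid = np.ones_like(self.t, dtype=bool)
        self.valid = np.asarray(valid, dtype=bool)
        if rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not (len(self.t) == len(self.azimuth) == len(self.elevation) == len(self.valid)):
            raise ValueError("trace arrays must have equal length")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        bad = self.valid & ~(
            np.isfinite(self.azimuth) & np.isfinite(self.elevation)
        )
        if bad.any():
            raise ValueError("valid samples must carry finite angles")
        self.rate = float(rate)

    def __len__(self) -> int:
        return len(self.t)

    @classmethod
    def from_samples(cls, samples: list[GazeSample], rate: float = 60.0) -> "GazeTrace":
        return cls(
            [s.t for s in samples],
            [s.azimuth for s in samples],
            [s.elevation for s in samples],
            [s.valid for s in samples],
            rate=rate,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "azimuth_deg": self.azimuth,
                "elevation_deg": self.elevation,
                "valid": self.valid,
            }
        )

    def to_csv(self, path=None) -> str:
        text = self.to_frame().to_csv(index=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_csv(cls, source, rate: float | None = None) -> "GazeTrace":
        if isinstance(source, str) and "\n" in source:
            source = io.StringIO(source)
        df = pd.read_csv(source)
        t = df["t_s"].to_numpy()
        if rate is None:
            rate = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 60.0
        return cls(
            t, df["azimuth_deg"], df["elevation_deg"], df["valid"], rate=float(rate)
        )

    def angle_at(self, t: float, axis: str) -> float:
        """Gaze component at time ``t`` (last valid sample at or before it)."""
        vals = self.azimuth if axis == "azimuth" else self.elevation
        idx = np.searchsorted(self.t, t, side="right") - 1
        while idx >= 0 and not self.valid[idx]:
            idx -= 1
        if idx < 0:
            raise ValueError(f"no valid sample at or before t={t}")
        return float(vals[idx])


@dataclass(frozen=True)
class SaccadeEvent:
    """One rapid gaze shift: bounding samples, amplitude and peak velocity."""

    t_start: float
    t_end: float
    start_angle: tuple[float, float]
    end_angle: tuple[float, float]
    amplitude: float
    peak_velocity: float

    def displacement(self) -> np.ndarray:
        return np.asarray(self.end_angle) - np.asarray(self.start_angle)


@dataclass(frozen=True)
class ResponseRecord:
    """Verdict for one scheduled event.

    ``landing_angle`` is the post-saccade gaze position along the stimulated
    axis; ``landing_error`` its absolute distance from the stimulus angle.
    Catch trials never carry ``seen=True`` — a qualifying movement on a
    catch trial raises ``false_positive`` instead.
    """

    event_id: int
    seen: bool
    latency: float | None = None
    landing_angle: float | None = None
    landing_error: float | None = None
    verdict_basis: str = NO_MOVEMENT
    false_positive: bool = False
    needs_repeat: bool = False

    def __post_init__(self) -> None:
        if self.seen and (self.latency is None or self.landing_error is None):
            raise ValueError("a seen verdict requires latency and landing error")
        if self.verdict_basis == CATCH and self.seen:
            raise ValueError("catch trials cannot be 'seen'")


def detect_saccades(
    tr: GazeTrace,
    vel_threshold: float = DEFAULT_VEL_THRESHOLD,
    min_amplitude: float = DEFAULT_MIN_AMPLITUDE,
    merge_gap: float = 0.02,
) -> list[SaccadeEvent]:
    """Velocity-threshold saccade detection on the valid samples.

    Angular speed is computed by central differences over the valid samples
    only; maximal runs of samples at or above ``vel_threshold`` deg/s are
    merged when separated by less than ``merge_gap`` seconds and kept when
    the net amplitude reaches ``min_amplitude`` degrees.
    """
    vidx = np.flatnonzero(tr.valid)
    if len(vidx) < 2:
        raise ValueError("trace needs at least 2 valid samples")
    t = tr.t[vidx]
    pos = np.stack([tr.azimuth[vidx], tr.elevation[vidx]], axis=1)
    n = len(t)
    vel = np.zeros((n, 2))
    vel[1:-1] = (pos[2:] - pos[:-2]) / (t[2:] - t[:-2])[:, None]
    vel[0] = (pos[1] - pos[0]) / (t[1] - t[0])
    vel[-1] = (pos[-1] - pos[-2]) / (t[-1] - t[-2])
    speed = np.linalg.norm(vel, axis=1)

    fast = speed >= vel_threshold
    runs: list[list[int]] = []
    i = 0
    while i < n:
        if fast[i]:
            j = i
            while j + 1 < n and fast[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    # merge runs separated by sub-merge_gap pauses (e.g. a mid-flight dip)
    merged: list[list[int]] = []
    for run in runs:
        if merged and t[run[0]] - t[merged[-1][1]] < merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    out = []
    for i0, i1 in merged:
        a, b = max(i0 - 1, 0), min(i1 + 1, n - 1)  # bracket with the flanking slow samples
        start, end = pos[a], pos[b]
        amplitude = float(np.linalg.norm(end - start))
        if amplitude < min_amplitude:
            continue
        out.append(
            SaccadeEvent(
                t_start=float(t[i0]),
                t_end=float(t[i1]),
                start_angle=(float(start[0]), float(start[1])),
                end_angle=(float(end[0]), float(end[1])),
                amplitude=amplitude,
                peak_velocity=float(speed[i0 : i1 + 1].max()),
            )
        )
    return out


def _axis_index(axis: str) -> int:
    return 0 if axis == "azimuth" else 1


def _qualifies(
    sac: SaccadeEvent, target_angle: float, axis: str, tolerance: float
) -> bool:
    """Does a saccade move toward, and land near, the stimulus angle?"""
    ai = _axis_index(axis)
    disp = sac.displacement()
    toward = disp[ai] * np.sign(target_angle - sac.start_angle[ai])
    if toward < 0.5 * sac.amplitude:
        return False
    landing = sac.end_angle[ai]
    return abs(landing - target_angle) <= tolerance


def classify_response(
    ev: StimulusEvent,
    saccades: list[SaccadeEvent],
    tr: GazeTrace,
    window: tuple[float, float] = DEFAULT_WINDOW,
    tolerance: float = DEFAULT_TOLERANCE,
    max_invalid_frac: float = 0.3,
) -> ResponseRecord:
    """Seen/not-seen verdict for one stimulus presentation.

    ``seen`` requires a saccade starting inside ``[onset+t_min, onset+t_max]``
    whose displacement component along the stimulated axis, signed toward
    the stimulus, is at least half its amplitude, and whose landing position
    on that axis lies within ``tolerance`` degrees of the stimulus angle.
    If more than ``max_invalid_frac`` of the window's samples are invalid
    the event is blink-contaminated: verdict ``blink_gap``, flagged for
    re-presentation.
    """
    if ev.is_catch:
        raise ValueError("classify_response takes stimulus events; see tally_errors")
    t0, t1 = ev.onset_s + window[0], ev.onset_s + window[1]
    in_win = (tr.t >= t0) & (tr.t <= t1)
    if in_win.any():
        invalid_frac = float(np.mean(~tr.valid[in_win]))
        if invalid_frac > max_invalid_frac:
            return ResponseRecord(
                ev.event_id, seen=False, verdict_basis=BLINK_GAP, needs_repeat=True
            )
    axis = ev.location.axis
    target = ev.location.angle
    for sac in saccades:
        if not t0 <= sac.t_start <= t1:
            continue
        if _qualifies(sac, target, axis, tolerance):
            landing = sac.end_angle[_axis_index(axis)]
            return ResponseRecord(
                ev.event_id,
                seen=True,
                latency=sac.t_start - ev.onset_s,
                landing_angle=landing,
                landing_error=abs(landing - target),
                verdict_basis=SACCADE_TOWARD,
            )
    return ResponseRecord(ev.event_id, seen=False, verdict_basis=NO_MOVEMENT)


def _catch_record(
    ev: StimulusEvent,
    saccades: list[SaccadeEvent],
    window: tuple[float, float],
    min_amplitude: float,
    fixation_radius: float,
) -> ResponseRecord:
    t0, t1 = ev.onset_s + window[0], ev.onset_s + window[1]
    fp = any(
        t0 <= s.t_start <= t1
        and s.amplitude >= min_amplitude
        and np.linalg.norm(s.start_angle) <= fixation_radius
        for s in saccades
    )
    return ResponseRecord(ev.event_id, seen=False, verdict_basis=CATCH, false_positive=fp)


def classify_schedule(
    schedule: list[StimulusEvent],
    tr: GazeTrace,
    window: tuple[float, float] = DEFAULT_WINDOW,
    tolerance: float = DEFAULT_TOLERANCE,
    vel_threshold: float = DEFAULT_VEL_THRESHOLD,
    min_amplitude: float = DEFAULT_MIN_AMPLITUDE,
) -> list[ResponseRecord]:
    """Classify every event of a schedule against one gaze trace."""
    saccades = detect_saccades(tr, vel_threshold, min_amplitude)
    out = []
    for ev in schedule:
        if ev.is_catch:
            out.append(
                _catch_record(ev, saccades, window, min_amplitude, FIXATION_RADIUS)
            )
        else:
            out.append(classify_response(ev, saccades, tr, window, tolerance))
    return out


def tally_errors(
    records: list[ResponseRecord],
    schedule: list[StimulusEvent],
    saccades: list[SaccadeEvent] | None = None,
    window: tuple[float, float] = DEFAULT_WINDOW,
    min_amplitude: float = DEFAULT_MIN_AMPLITUDE,
    fixation_radius: float = FIXATION_RADIUS,
    suprathreshold_db: float = 0.0,
) -> tuple[int, int]:
    """Reliability indices ``(false_positives, false_negatives)``.

    False positives: catch trials answered with a qualifying saccade, plus
    (when ``saccades`` is given) fixation-break saccades of at least
    ``min_amplitude`` starting outside every response window — the patient
    moving the eye when nothing was shown.  A fixation-break saccade is one
    starting within ``fixation_radius`` of the fixation point, so the
    return sweep of an out-and-back excursion is not double-counted.

    False negatives: full-brightness stimuli (attenuation at or below
    ``suprathreshold_db``) with no response.  Blink-contaminated events are
    excluded — they are re-presented, not misses.
    """
    by_id = {ev.event_id: ev for ev in schedule}
    if set(r.event_id for r in records) - set(by_id):
        raise ValueError("records refer to events absent from the schedule")
    fp = sum(1 for r in records if r.false_positive)
    fn = 0
    for r in records:
        ev = by_id[r.event_id]
        if ev.is_catch or r.verdict_basis == BLINK_GAP:
            continue
        if ev.attenuation_db <= suprathreshold_db + 1e-9 and not r.seen:
            fn += 1
    if saccades is not None:
        windows = [
            (ev.onset_s + window[0], ev.onset_s + window[1]) for ev in by_id.values()
        ]
        for s in saccades:
            if s.amplitude < min_amplitude:
                continue
            if np.linalg.norm(s.start_angle) > fixation_radius:
                continue
            if not any(t0 <= s.t_start <= t1 for t0, t1 in windows):
                fp += 1
    return fp, fn


def response_accuracy_vs_duration(
    records: list[ResponseRecord], schedule: list[StimulusEvent]
) -> tuple[float, float]:
    """OLS slope and intercept of mean landing error vs stimulus duration.

    Groups seen responses by their event's stimulus duration and regresses
    the group-mean landing error (degrees) on duration (seconds).  A
    negative slope reflects better localization of longer flashes.
    """
    by_id = {ev.event_id: ev for ev in schedule}
    groups: dict[float, list[float]] = {}
    for r in records:
        if r.seen and r.landing_error is not None:
            groups.setdefault(by_id[r.event_id].duration_s, []).append(r.landing_error)
    if len(groups) < 2:
        raise ValueError("need responses at >= 2 distinct stimulus durations")
    durations = np.array(sorted(groups))
    means = np.array([np.mean(groups[d]) for d in durations])
    slope, intercept = np.polyfit(durations, means, 1)
    return float(slope), float(intercept)


def records_to_csv(records: list[ResponseRecord], path=None) -> str:
    df = pd.DataFrame(
        [
            {
                "event_id": r.event_id,
                "seen": r.seen,
                "latency_s": r.latency,
                "landing_error_deg": r.landing_error,
                "verdict_basis": r.verdict_basis,
                "false_positive": r.false_positive,
            }
            for r in records
        ]
    )
    text = df.to_csv(index=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
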