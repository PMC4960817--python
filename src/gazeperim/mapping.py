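"""Sensitivity-threshold estimation and visual-field map assembly.

Per-location sensitivity is expressed as stimulus attenuation in decibels
below the colour's maximum intensity, 10·log10(I_max/I), on a 0–25 dB
scale: the dimmest attenuation the eye still responds to.  Higher dB means
better sensitivity; 0 dB means even the brightest stimulus went unseen.

Thresholds are bracketed by a two-reversal 4–2 dB staircase: a seen
presentation dims the next one by the current step, a miss brightens it,
the step halves from 4 to 2 dB at the first reversal, and the procedure
stops at the second reversal (or a presentation cap), reporting the
midpoint of the final seen/unseen bracket.  A run that never misses clips
to the 25 dB ceiling; one that never responds at full brightness scores 0.

``run_exam`` interleaves one staircase per location in random order —
locations with unfinished staircases re-enter the random pool, so the
patient cannot predict where the next stimulus will appear — and tallies
false positives/negatives along the way.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .geometry import ArmGeometry, StimulusLocation, build_default_device
from .gaze import BLINK_GAP, ResponseRecord
from .scheduler import (
    ACCURATE,
    FAST,
    ColourSpec,
    Protocol,
    StimulusEvent,
    attenuate,
    sample_intensity,
    sample_interval,
)

__all__ = [
    "DB_CEILING",
    "Staircase",
    "SensitivityMap",
    "MapComparison",
    "attenuation_to_intensity",
    "staircase_step",
    "run_exam",
    "compare_maps",
]

DB_CEILING = 25.0
DEFECT_MIDPOINT_DB = DB_CEILING / 2.0  # defect edge = crossing of 12.5 dB

Responder = Callable[[StimulusEvent], ResponseRecord]


def attenuation_to_intensity(colour: ColourSpec, a: float) -> float:
    """Stimulus intensity (mcd) at ``a`` dB attenuation below the colour max."""
    return attenuate(colour, a)


@dataclass
class Staircase:
    """Adaptive 4–2 dB threshold staircase for one stimulus location.

    Starts at 0 dB (full brightness).  ``step_sizes`` gives the step after
    0, 1, … reversals; the run terminates after ``len(step_sizes)``
    reversals or ``max_presentations`` presentations, whichever comes
    first, and additionally as soon as the outcome is forced: a seen
    presentation pinned at the ceiling (threshold = ceiling) or a second
    miss at full brightness (threshold = 0, absolute defect).

    The presentation cap defaults to 10: bracketing a threshold near the
    top of the scale takes up to seven 4-dB ascents plus two 2-dB probes.
    """

    location: StimulusLocation
    step_sizes: tuple[float, ...] = (4.0, 2.0)
    db_ceiling: float = DB_CEILING
    max_presentations: int = 10
    current_attenuation: float = 0.0
    reversals: int = 0
    presentations: int = 0
    state: str = "running"
    final_threshold: float | None = None
    _last_seen: float | None = field(default=None, repr=False)
    _last_unseen: float | None = field(default=None, repr=False)
    _prev_seen: bool | None = field(default=None, repr=False)
    _floor_misses: int = field(default=0, repr=False)

    @property
    def step(self) -> float:
        return self.step_sizes[min(self.reversals, len(self.step_sizes) - 1)]

    def _finish(self) -> None:
        self.state = "done"
        if self._last_seen is not None and self._last_unseen is not None:
            thr = 0.5 * (self._last_seen + self._last_unseen)
        elif self._last_seen is not None:  # never missed
            thr = self.db_ceiling
        else:  # never seen
            thr = 0.0
        self.final_threshold = float(np.clip(thr, 0.0, self.db_ceiling))


def staircase_step(s: Staircase, seen: bool) -> Staircase:
    """Record one presentation outcome and update the staircase in place.

    Seen ⇒ the last attenuation was perceptible, so probe dimmer (higher
    dB); not seen ⇒ probe brighter.  The attenuation is clipped to
    [0, ceiling] throughout.
    """
    if s.state != "running":
        raise ValueError("cannot step a finished staircase")
    a = s.current_attenuation
    s.presentations += 1
    if seen:
        s._last_seen = a
        s._floor_misses = 0
    else:
        s._last_unseen = a
        if a <= 0.0:
            s._floor_misses += 1

    if s._prev_seen is not None and seen != s._prev_seen:
        s.reversals += 1
    s._prev_seen = seen

    forced_ceiling = seen and a >= s.db_ceiling
    forced_floor = (not seen) and s._floor_misses >= 2
    if (
        s.reversals >= len(s.step_sizes)
        or s.presentations >= s.max_presentations
        or forced_ceiling
        or forced_floor
    ):
        s._finish()
        return s

    delta = s.step if seen else -s.step
    s.current_attenuation = float(np.clip(a + delta, 0.0, s.db_ceiling))
    return s


@dataclass
class SensitivityMap:
    """Per-location thresholds (dB) plus exam bookkeeping.

    ``thresholds`` maps ``(arm, angle)`` to a threshold in [0, 25] dB, or
    None where no value could be determined.  Fast-mode exams encode
    seen/not-seen as 25/0 dB so both modes share one map type.
    """

    thresholds: dict[tuple[str, float], float | None]
    mode: str
    false_positives: int = 0
    false_negatives: int = 0
    exam_start: float = 0.0
    exam_stop: float = 0.0
    fixation_losses: int = 0

    def determined(self) -> dict[tuple[str, float], float]:
        return {k: v for k, v in self.thresholds.items() if v is not None}

    def arm_profile(self, arm: str) -> tuple[np.ndarray, np.ndarray]:
        """(angles, thresholds) for one arm, ascending, determined only."""
        items = sorted(
            (ang, v) for (a, ang), v in self.thresholds.items() if a == arm and v is not None
        )
        if not items:
            return np.array([]), np.array([])
        angles, values = zip(*items)
        return np.asarray(angles, dtype=float), np.asarray(values, dtype=float)

    def to_json(self) -> str:
        d = {
            "mode": self.mode,
            "false_positives": self.false_positives,
            "false_negatives": self.false_negatives,
            "exam_start_s": self.exam_start,
            "exam_stop_s": self.exam_stop,
            "fixation_losses": self.fixation_losses,
            "thresholds": [
                {"arm": arm, "angle_deg": ang, "threshold_db": v}
                for (arm, ang), v in sorted(self.thresholds.items())
            ],
        }
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SensitivityMap":
        d = json.loads(text)
        return cls(
            thresholds={
                (e["arm"], float(e["angle_deg"])): e["threshold_db"]
                for e in d["thresholds"]
            },
            mode=d["mode"],
            false_positives=d["false_positives"],
            false_negatives=d["false_negatives"],
            exam_start=d["exam_start_s"],
            exam_stop=d["exam_stop_s"],
            fixation_losses=d.get("fixation_losses", 0),
        )

    def to_csv(self, path=None) -> str:
        df = pd.DataFrame(
            [
                {"arm": arm, "angle_deg": ang, "threshold_db": v}
                for (arm, ang), v in sorted(self.thresholds.items())
            ]
        )
        text = df.to_csv(index=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_csv(cls, source, mode: str = "accurate") -> "SensitivityMap":
        if isinstance(source, str) and "\n" in source:
            source = io.StringIO(source)
        df = pd.read_csv(source)
        thr = {}
        for row in df.itertuples(index=False):
            v = None if pd.isna(row.threshold_db) else float(row.threshold_db)
            thr[(row.arm, float(row.angle_deg))] = v
        return cls(thresholds=thr, mode=mode)


def _location_key(loc: StimulusLocation) -> tuple[str, float]:
    return (loc.arm, loc.angle)


def run_exam(
    protocol: Protocol,
    responder: Responder,
    arms: tuple[ArmGeometry, ArmGeometry] | None = None,
    max_presentations: int = 10,
) -> SensitivityMap:
    """Run a full simulated or replayed exam and assemble the map.

    ``responder`` maps each :class:`StimulusEvent` to a
    :class:`ResponseRecord` — a simulated patient, a phantom, or playback
    of a recorded trace.  Fast mode presents each (sub-sampled) location
    once at full brightness and encodes seen/not-seen as 25/0 dB; accurate
    mode drives one staircase per location, randomly interleaved.  Events
    lost to blinks are re-presented once before counting as unseen.
    Timestamps are exam-clock seconds accumulated from the scheduled
    intervals.
    """
    if arms is None:
        arms = build_default_device()
    locations = protocol.resolved_locations(arms)
    if not locations:
        raise ValueError("no locations to test")
    colour = protocol.colour
    rng = protocol.rng()
    records: list[ResponseRecord] = []
    fp = fn = fixation_losses = 0
    t = 0.0
    eid = 0
    # fast-mode stimuli are jittered inside the colour range, so anything up
    # to the range's own span above 0 dB still counts as full brightness
    supra_db = 10.0 * np.log10(colour.max_mcd / colour.intensity_mcd[0]) + 1e-9

    def emit_catch() -> None:
        nonlocal t, eid, fp
        ev = StimulusEvent(eid, None, colour.name, 0.0, 0.0, t, protocol.stimulus_duration)
        rec = responder(ev)
        records.append(rec)
        if rec.false_positive:
            fp += 1

    if protocol.mode == FAST:
        thresholds: dict[tuple[str, float], float | None] = {}
        pending = [(locations[i], 0) for i in rng.permutation(len(locations)).tolist()]
        while pending:
            loc, attempts = pending.pop(0)
            t += sample_interval(protocol, rng)
            if protocol.catch_rate > 0 and rng.random() < protocol.catch_rate:
                emit_catch()
                eid += 1
                t += sample_interval(protocol, rng)
            mcd, db = sample_intensity(colour, FAST, rng)
            ev = StimulusEvent(
                eid, loc, colour.name, mcd, db, t, protocol.stimulus_duration
            )
            rec = responder(ev)
            records.append(rec)
            eid += 1
            if rec.verdict_basis == BLINK_GAP and attempts < 1:
                fixation_losses += 1
                pending.append((loc, attempts + 1))
                continue
            thresholds[_location_key(loc)] = DB_CEILING if rec.seen else 0.0
            if not rec.seen and db <= supra_db:
                fn += 1
        return SensitivityMap(
            thresholds, FAST, fp, fn, 0.0, t, fixation_losses
        )

    # accurate mode: one staircase per location, randomly interleaved
    staircases = {
        _location_key(loc): Staircase(loc, max_presentations=max_presentations)
        for loc in locations
    }
    blink_retries: dict[tuple[str, float], int] = {k: 0 for k in staircases}
    pool = list(staircases)
    prev_key: tuple[str, float] | None = None
    while pool:
        t += sample_interval(protocol, rng)
        if protocol.catch_rate > 0 and rng.random() < protocol.catch_rate:
            emit_catch()
            eid += 1
            continue
        candidates = [k for k in pool if k != prev_key] if len(pool) > 1 else pool
        key = candidates[int(rng.integers(len(candidates)))]
        sc = staircases[key]
        db = sc.current_attenuation
        mcd = attenuate(colour, db)
        ev = StimulusEvent(
            eid, sc.location, colour.name, mcd, db, t, protocol.stimulus_duration
        )
        rec = responder(ev)
        records.append(rec)
        eid += 1
        prev_key = key
        if rec.verdict_basis == BLINK_GAP and blink_retries[key] < 1:
            fixation_losses += 1
            blink_retries[key] += 1
            continue
        blink_retries[key] = 0
        if not rec.seen and db <= 1e-9:
            fn += 1
        staircase_step(sc, rec.seen)
        if sc.state == "done":
            pool.remove(key)
    thresholds = {k: sc.final_threshold for k, sc in staircases.items()}
    return SensitivityMap(thresholds, ACCURATE, fp, fn, 0.0, t, fixation_losses)


def _defect_edges(angles: np.ndarray, values: np.ndarray) -> list[float]:
    """Angles where the threshold profile crosses the defect midpoint.

    The profile is smoothed with a 3-point running median first: a
    two-reversal staircase occasionally leaves an isolated wild threshold
    (a lapse early in the run), and a single-location spike is not a
    defect edge.  Genuine step edges pass through a width-3 median intact.
    """
    if len(values) >= 3:
        from scipy.ndimage import median_filter as _mf

        values = _mf(values, size=3, mode="nearest")
    edges = []
    for i in range(len(angles) - 1):
        v0, v1 = values[i] - DEFECT_MIDPOINT_DB, values[i + 1] - DEFECT_MIDPOINT_DB
        if v0 == 0.0:
            edges.append(float(angles[i]))
        elif v0 * v1 < 0:
            frac = -v0 / (v1 - v0)
            edges.append(float(angles[i] + frac * (angles[i + 1] - angles[i])))
    if len(values) and values[-1] == DEFECT_MIDPOINT_DB:
        edges.append(float(angles[-1]))
    return edges


@dataclass(frozen=True)
class MapComparison:
    mae_db: float
    differences: dict[tuple[str, float], float]
    boundary_error_deg: float | None
    edges_estimated: dict[str, list[float]]
    edges_reference: dict[str, list[float]]


def compare_maps(estimated: SensitivityMap, reference: SensitivityMap) -> MapComparison:
    """Agreement between an estimated map and a reference map.

    Mean absolute error over locations determined in both maps, the
    per-location signed differences, and the defect-boundary error: for
    each arm, the mean absolute angular offset between matching crossings
    of the 12.5 dB defect midpoint in the two profiles (None when neither
    map has a defect edge).
    """
    if set(estimated.thresholds) != set(reference.thresholds):
        raise ValueError("maps cover different geometries")
    est, ref = estimated.determined(), reference.determined()
    common = sorted(set(est) & set(ref))
    if not common:
        raise ValueError("no locations determined in both maps")
    differences = {k: est[k] - ref[k] for k in common}
    mae = float(np.mean([abs(d) for d in differences.values()]))

    edge_errors = []
    edges_e: dict[str, list[float]] = {}
    edges_r: dict[str, list[float]] = {}
    for arm in sorted({a for a, _ in common}):
        ea = _defect_edges(*estimated.arm_profile(arm))
        ra = _defect_edges(*reference.arm_profile(arm))
        edges_e[arm], edges_r[arm] = ea, ra
        if len(ea) == len(ra):
            edge_errors.extend(abs(x - y) for x, y in zip(sorted(ea), sorted(ra)))
        elif ea and ra:
            # unequal counts: score each edge of the smaller set against
            # its nearest counterpart rather than mispairing by rank
            small, large = (ea, ra) if len(ea) < len(ra) else (ra, ea)
            edge_errors.extend(min(abs(x - y) for y in large) for x in small)
    boundary = float(np.mean(edge_errors)) if edge_errors else None
    return MapComparison(mae, differences, boundary, edges_e, edges_r)
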