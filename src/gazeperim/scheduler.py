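"""Randomized exam protocol generation.

Stimulus order, per-colour brightness, and the gap between successive
presentations are all randomized so the patient cannot anticipate the next
stimulus: predictable schedules invite habitual responses and inflate the
false-positive count.  Inter-stimulus intervals are drawn uniformly from
0.5–5 s.  A configurable fraction of events are catch trials — scheduled
slots with no stimulus at all — used downstream to detect false positives.

Two exam modes exist.  *Fast* mode presents each (sub-sampled) location once
at full brightness with a random intensity jitter inside the colour's range,
giving a pass/fail screen in about a minute of scheduled time.  *Accurate*
mode drives every location with an adaptive staircase (see
:mod:`gazeperim.mapping`); there the scheduler supplies intervals, catch
trials and interleaving while the staircase dictates each attenuation.

All randomness flows through a single numpy generator seeded by the
protocol, so identical protocols serialize to byte-identical schedules.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    ArmGeometry,
    StimulusLocation,
    build_default_device,
    enumerate_locations,
)

__all__ = [
    "ColourSpec",
    "RED",
    "GREEN",
    "BLUE",
    "COLOURS",
    "Protocol",
    "StimulusEvent",
    "sample_interval",
    "sample_intensity",
    "generate_schedule",
    "fast_mode_locations",
    "attenuate",
    "schedule_to_csv",
    "schedule_from_csv",
]

FAST = "fast"
ACCURATE = "accurate"


@dataclass(frozen=True)
class ColourSpec:
    """One LED colour channel: wavelength band and luminous-intensity range (mcd)."""

    name: str
    wavelength_nm: tuple[float, float]
    intensity_mcd: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.intensity_mcd[0] < self.intensity_mcd[1]:
            raise ValueError("intensity range must satisfy min < max")

    @property
    def max_mcd(self) -> float:
        return self.intensity_mcd[1]


# RGB LED channels of the stimulus strips.
RED = ColourSpec("red", (620.0, 630.0), (550.0, 700.0))
GREEN = ColourSpec("green", (515.0, 530.0), (1100.0, 1400.0))
BLUE = ColourSpec("blue", (465.0, 475.0), (200.0, 400.0))
COLOURS = {c.name: c for c in (RED, GREEN, BLUE)}


def attenuate(colour: ColourSpec, db: float) -> float:
    """Intensity (mcd) of ``colour`` dimmed ``db`` decibels below its maximum.

    I = I_max · 10^(−dB/10).  Attenuation may take the intensity below the
    colour's nominal minimum: threshold estimation needs dimmer stimuli than
    the fast-mode jitter range provides.
    """
    if db < 0:
        raise ValueError("attenuation must be non-negative")
    return colour.max_mcd * 10.0 ** (-db / 10.0)


@dataclass(frozen=True)
class StimulusEvent:
    """A commanded flash — or, when ``location`` is None, a catch trial."""

    event_id: int
    location: StimulusLocation | None
    colour: str
    intensity_mcd: float
    attenuation_db: float
    onset_s: float
    duration_s: float

    @property
    def is_catch(self) -> bool:
        return self.location is None


@dataclass(frozen=True)
class Protocol:
    """Exam protocol: mode, tested locations, timing and colour configuration.

    ``catch_rate`` is the fraction of scheduled events that carry no
    stimulus.  The seed makes every stochastic draw reproducible.
    """

    mode: str = FAST
    locations: tuple[StimulusLocation, ...] | None = None
    interval_range: tuple[float, float] = (0.5, 5.0)
    stimulus_duration: float = 0.2
    catch_rate: float = 0.1
    colour: ColourSpec = RED
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.interval_range
        if not (0.5 <= lo <= hi <= 5.0):
            raise ValueError("interval_range must lie within [0.5, 5.0] s")
        if not 0 <= self.catch_rate < 0.5:
            raise ValueError("catch_rate must be in [0, 0.5)")
        if self.mode not in (FAST, ACCURATE):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.stimulus_duration <= 0:
            raise ValueError("stimulus_duration must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def resolved_locations(
        self, arms: tuple[ArmGeometry, ArmGeometry] | None = None
    ) -> list[StimulusLocation]:
        """Locations to test: explicit list, or mode defaults on the device."""
        if self.locations is not None:
            return list(self.locations)
        if arms is None:
            arms = build_default_device()
        if self.mode == FAST:
            return fast_mode_locations(arms)
        return [loc for g in arms for loc in enumerate_locations(g)]

    def to_json(self) -> str:
        d = {
            "mode": self.mode,
            "interval_range_s": list(self.interval_range),
            "stimulus_duration_s": self.stimulus_duration,
            "catch_rate": self.catch_rate,
            "colour": self.colour.name,
            "seed": self.seed,
            "locations": None
            if self.locations is None
            else [[l.arm, l.angle] for l in self.locations],
        }
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Protocol":
        d = json.loads(text)
        locations = None
        if d.get("locations") is not None:
            arms = {g.arm: g for g in build_default_device()}
            from .geometry import angle_to_index

            locations = tuple(
                StimulusLocation(arm, angle, angle_to_index(arms[arm], angle))
                for arm, angle in d["locations"]
            )
        return cls(
            mode=d.get("mode", FAST),
            locations=locations,
            interval_range=tuple(d.get("interval_range_s", (0.5, 5.0))),
            stimulus_duration=d.get("stimulus_duration_s", 0.2),
            catch_rate=d.get("catch_rate", 0.1),
            colour=COLOURS[d.get("colour", "red")],
            seed=d.get("seed", 0),
        )


def fast_mode_locations(
    arms: tuple[ArmGeometry, ArmGeometry], step_deg: float = 10.0
) -> list[StimulusLocation]:
    """Sub-sample each arm every ``step_deg`` degrees for the fast screen."""
    out = []
    for g in arms:
        for loc in enumerate_locations(g):
            if math.isclose(loc.angle % step_deg, 0.0, abs_tol=1e-9) or math.isclose(
                loc.angle % step_deg, step_deg, abs_tol=1e-9
            ):
                out.append(loc)
    return out


def sample_interval(p: Protocol, rng: np.random.Generator) -> float:
    """One inter-stimulus gap, uniform on the protocol's interval range."""
    lo, hi = p.interval_range
    return float(rng.uniform(lo, hi))


def sample_intensity(
    colour: ColourSpec,
    mode: str,
    rng: np.random.Generator,
    attenuation_db: float | None = None,
) -> tuple[float, float]:
    """Stimulus intensity for one presentation, as ``(mcd, dB attenuation)``.

    Fast mode draws the intensity uniformly inside the colour's range and
    reports the implied attenuation below the colour maximum.  Accurate mode
    applies the staircase-requested attenuation to the colour maximum.
    """
    if mode == FAST:
        lo, hi = colour.intensity_mcd
        mcd = float(rng.uniform(lo, hi))
        return mcd, 10.0 * math.log10(colour.max_mcd / mcd)
    if attenuation_db is None:
        raise ValueError("accurate mode requires a requested attenuation")
    if attenuation_db < 0:
        raise ValueError("attenuation must be non-negative")
    return attenuate(colour, attenuation_db), float(attenuation_db)


def generate_schedule(
    p: Protocol, arms: tuple[ArmGeometry, ArmGeometry] | None = None
) -> list[StimulusEvent]:
    """Full randomized schedule for a fixed-presentation (fast-style) exam.

    Locations appear exactly once each, in a uniform random permutation;
    catch trials are interleaved at the protocol's catch rate at random
    slots; onsets grow by independent draws from the interval range.
    Accurate-mode interleaving with staircase-driven repeats lives in
    :func:`gazeperim.mapping.run_exam`, which consumes the same primitives.
    """
    locations = p.resolved_locations(arms)
    if not locations:
        raise ValueError("protocol has no stimulus locations")
    rng = p.rng()
    order = [locations[i] for i in rng.permutation(len(locations))]
    n_stim = len(order)
    n_catch = int(round(n_stim * p.catch_rate / (1.0 - p.catch_rate)))
    # catch=True markers dropped into random slots of the event stream
    slots = [False] * n_stim + [True] * n_catch
    slots = [slots[i] for i in rng.permutation(len(slots))]

    events: list[StimulusEvent] = []
    t = 0.0
    it = iter(order)
    for eid, is_catch in enumerate(slots):
        t += sample_interval(p, rng)
        if is_catch:
            events.append(
                StimulusEvent(eid, None, p.colour.name, 0.0, 0.0, t, p.stimulus_duration)
            )
        else:
            if p.mode == ACCURATE:
                mcd, db = sample_intensity(p.colour, ACCURATE, rng, attenuation_db=0.0)
            else:
                mcd, db = sample_intensity(p.colour, FAST, rng)
            events.append(
                StimulusEvent(eid, next(it), p.colour.name, mcd, db, t, p.stimulus_duration)
            )
    return events


_CSV_COLUMNS = [
    "event_id",
    "onset_s",
    "duration_s",
    "arm",
    "angle_deg",
    "colour",
    "intensity_mcd",
    "attenuation_db",
    "is_catch",
]


def schedule_to_frame(events: list[StimulusEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append(
            {
                "event_id": ev.event_id,
                "onset_s": ev.onset_s,
                "duration_s": ev.duration_s,
                "arm": "" if ev.is_catch else ev.location.arm,
                "angle_deg": np.nan if ev.is_catch else ev.location.angle,
                "colour": ev.colour,
                "intensity_mcd": ev.intensity_mcd,
                "attenuation_db": ev.attenuation_db,
                "is_catch": ev.is_catch,
            }
        )
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def schedule_to_csv(events: list[StimulusEvent], path=None) -> str:
    """Serialize a schedule to CSV; returns the text (also written to ``path``)."""
    text = schedule_to_frame(events).to_csv(index=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def schedule_from_csv(source) -> list[StimulusEvent]:
    """Read a schedule from a CSV path, file object, or literal text."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source)
    arms = {g.arm: g for g in build_default_device()}
    from .geometry import angle_to_index

    events = []
    for row in df.itertuples(index=False):
        if bool(row.is_catch):
            loc = None
        else:
            g = arms[row.arm]
            angle = float(row.angle_deg)
            loc = StimulusLocation(row.arm, angle, angle_to_index(g, angle))
        events.append(
            StimulusEvent(
                int(row.event_id),
                loc,
                str(row.colour),
                float(row.intensity_mcd),
                float(row.attenuation_db),
                float(row.onset_s),
                float(row.duration_s),
            )
        )
    return events
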