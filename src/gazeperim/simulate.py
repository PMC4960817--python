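"""Synthetic test bed: simulated patient, static phantom, and frame renderer.

The simulated patient is a frequency-of-seeing model over a ground-truth
sensitivity map: the probability of perceiving a presentation at
attenuation *a* dB at a location with true sensitivity *t* dB is

    P(seen) = (1 − lapse) · Φ((t − a) / slope)

with Φ the standard normal CDF, ``slope`` the psychometric spread in dB and
``lapse`` the rate of attention lapses on clearly visible stimuli.  Around
the perceptual decisions the simulator generates oculomotor behaviour:
saccades toward seen stimuli after a Gaussian latency, landing scatter that
shrinks linearly with stimulus duration (longer flashes are localized
better), slow fixation drift, blinks, and habitual stimulus-free saccades
at a Poisson rate — the behaviour catch trials exist to expose.

The static phantom — an artificial head whose eye never moves — is the
hardware-free control: every stimulus is a false negative, and no false
positives can occur.

``render_frame`` draws synthetic eye-camera frames (bright sclera, dark
pupil displacing linearly with gaze angle, optional shading gradient and
pixel noise) so the full image chain can be exercised without a camera.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .frames import EyeFrame
from .gaze import (
    CATCH,
    NO_MOVEMENT,
    SACCADE_TOWARD,
    DEFAULT_WINDOW,
    GazeTrace,
    ResponseRecord,
)
from .geometry import ArmGeometry, StimulusLocation, build_default_device, enumerate_locations
from .mapping import DB_CEILING, SensitivityMap
from .scheduler import StimulusEvent

__all__ = [
    "PatientModel",
    "GroundTruthDefect",
    "RenderConfig",
    "respond",
    "make_responder",
    "phantom_responder",
    "always_seen_responder",
    "deterministic_responder",
    "generate_trace",
    "render_frame",
    "make_defect_map",
]


@dataclass(frozen=True)
class GroundTruthDefect:
    """A rectangular (1-D interval) sensitivity loss on one arm."""

    arm: str
    interval_deg: tuple[float, float]
    depth_db: float

    def __post_init__(self) -> None:
        lo, hi = self.interval_deg
        if lo > hi:
            raise ValueError("defect interval must be ordered (lo, hi)")
        if self.depth_db < 0:
            raise ValueError("defect depth must be non-negative")

    def covers(self, loc: StimulusLocation) -> bool:
        lo, hi = self.interval_deg
        return loc.arm == self.arm and lo <= loc.angle <= hi


def make_defect_map(
    base_db: float,
    defects: list[GroundTruthDefect],
    arms: tuple[ArmGeometry, ArmGeometry] | None = None,
) -> SensitivityMap:
    """Reference map: ``base_db`` everywhere, lowered inside each defect.

    Sensitivity inside a defect is ``base − depth``, floored at 0 dB (an
    absolute defect cannot go below "never sees the brightest stimulus").
    """
    if arms is None:
        arms = build_default_device()
    by_arm = {g.arm: g for g in arms}
    for d in defects:
        g = by_arm.get(d.arm)
        if g is None:
            raise ValueError(f"defect on unknown arm {d.arm!r}")
        lo, hi = d.interval_deg
        if lo < g.min_angle or hi > g.max_angle:
            raise ValueError(
                f"defect {d.interval_deg} outside arm range "
                f"[{g.min_angle}, {g.max_angle}]"
            )
    thresholds = {}
    for g in arms:
        for loc in enumerate_locations(g):
            v = base_db
            for d in defects:
                if d.covers(loc):
                    v = min(v, base_db - d.depth_db)
            thresholds[(loc.arm, loc.angle)] = float(np.clip(v, 0.0, DB_CEILING))
    return SensitivityMap(thresholds, mode="reference")


@dataclass(frozen=True)
class PatientModel:
    """Configurable simulated patient.

    Parameters
    ----------
    true_map : SensitivityMap
        Ground-truth per-location sensitivity in dB.
    psychometric_slope : float
        Spread of the frequency-of-seeing curve, dB.
    lapse_rate : float
        Probability of missing a clearly visible stimulus.
    habit_rate : float
        Habitual (stimulus-free) saccades per second.
    latency_mean, latency_sd : float
        Saccade latency distribution, seconds; the mean must sit inside the
        response window for the patient to be detectable.
    landing_noise_base : float
        Landing scatter (degrees, 1 SD) extrapolated to zero duration.
    landing_duration_gain : float
        Change of landing scatter per second of stimulus duration
        (degrees/s, negative: longer flashes are localized better).
    drift_sd : float
        Stationary SD of slow fixation drift, degrees per axis.
    blink_rate, blink_duration : float
        Blink Poisson rate (1/s) and blink length (s).
    seed : int
        Seed for every stochastic draw the patient makes.
    """

    true_map: SensitivityMap
    psychometric_slope: float = 1.0
    lapse_rate: float = 0.01
    habit_rate: float = 0.0
    latency_mean: float = 0.25
    latency_sd: float = 0.05
    landing_noise_base: float = 2.5
    landing_duration_gain: float = -5.0
    drift_sd: float = 0.3
    blink_rate: float = 0.1
    blink_duration: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.lapse_rate <= 1:
            raise ValueError("lapse_rate must be a probability")
        if self.psychometric_slope <= 0:
            raise ValueError("psychometric_slope must be positive")

    def sensitivity(self, loc: StimulusLocation) -> float:
        key = (loc.arm, loc.angle)
        try:
            v = self.true_map.thresholds[key]
        except KeyError:
            raise KeyError(f"location {key} outside the patient's true map")
        if v is None:
            raise KeyError(f"location {key} has no ground-truth sensitivity")
        return v

    def landing_sd(self, duration_s: float) -> float:
        """Landing scatter for a given stimulus duration.

        Linear in duration, floored at 0.1° so very long flashes keep a
        trace of scatter; a patient configured with zero base noise is
        genuinely noiseless.
        """
        raw = self.landing_noise_base + self.landing_duration_gain * duration_s
        return max(0.1, raw) if self.landing_noise_base > 0 else max(0.0, raw)

    @classmethod
    def uniform(cls, sensitivity_db: float = DB_CEILING, **kwargs) -> "PatientModel":
        """Patient with the same true sensitivity at every default location."""
        return cls(true_map=make_defect_map(sensitivity_db, []), **kwargs)

    @classmethod
    def static(cls, **kwargs) -> "PatientModel":
        """A motionless, noiseless eye (phantom-like trace source)."""
        defaults = dict(
            habit_rate=0.0, drift_sd=0.0, blink_rate=0.0,
            landing_noise_base=0.0, landing_duration_gain=0.0, latency_sd=0.0,
            lapse_rate=0.0,
        )
        defaults.update(kwargs)
        return cls.uniform(DB_CEILING, **defaults)


def respond(pm: PatientModel, ev: StimulusEvent, rng: np.random.Generator) -> bool:
    """One Bernoulli perceptual decision for a stimulus presentation.

    Catch trials are never "seen" through this path — false positives come
    only from habitual saccades in the generated trace.
    """
    if ev.is_catch:
        return False
    p = (1.0 - pm.lapse_rate) * norm.cdf(
        (pm.sensitivity(ev.location) - ev.attenuation_db) / pm.psychometric_slope
    )
    return bool(rng.random() < p)


def make_responder(pm: PatientModel, window=DEFAULT_WINDOW):
    """Event-by-event responder callback for :func:`gazeperim.mapping.run_exam`.

    Wraps the perceptual model with latency and landing-error draws so each
    stimulus event yields a complete :class:`ResponseRecord`; on catch
    trials a false positive fires with the probability that at least one
    habitual saccade falls inside the response window.
    """
    rng = np.random.default_rng(pm.seed)
    span = window[1] - window[0]
    p_fp = 1.0 - math.exp(-pm.habit_rate * span)

    def responder(ev: StimulusEvent) -> ResponseRecord:
        if ev.is_catch:
            fp = bool(rng.random() < p_fp)
            return ResponseRecord(ev.event_id, seen=False, verdict_basis=CATCH, false_positive=fp)
        if not respond(pm, ev, rng):
            return ResponseRecord(ev.event_id, seen=False, verdict_basis=NO_MOVEMENT)
        latency = float(np.clip(rng.normal(pm.latency_mean, pm.latency_sd), window[0], window[1]))
        err = float(rng.normal(0.0, pm.landing_sd(ev.duration_s)))
        landing = ev.location.angle + err
        return ResponseRecord(
            ev.event_id,
            seen=True,
            latency=latency,
            landing_angle=landing,
            landing_error=abs(err),
            verdict_basis=SACCADE_TOWARD,
        )

    return responder


def phantom_responder():
    """The static phantom: the eye never moves, nothing is ever seen."""

    def responder(ev: StimulusEvent) -> ResponseRecord:
        basis = CATCH if ev.is_catch else NO_MOVEMENT
        return ResponseRecord(ev.event_id, seen=False, verdict_basis=basis)

    return responder


def always_seen_responder(latency: float = 0.25):
    """Ideal responder that reports seeing every presented stimulus."""

    def responder(ev: StimulusEvent) -> ResponseRecord:
        if ev.is_catch:
            return ResponseRecord(ev.event_id, seen=False, verdict_basis=CATCH)
        return ResponseRecord(
            ev.event_id,
            seen=True,
            latency=latency,
            landing_angle=ev.location.angle,
            landing_error=0.0,
            verdict_basis=SACCADE_TOWARD,
        )

    return responder


def deterministic_responder(true_map: SensitivityMap, latency: float = 0.25):
    """Noiseless threshold responder: sees iff attenuation ≤ true sensitivity."""

    def responder(ev: StimulusEvent) -> ResponseRecord:
        if ev.is_catch:
            return ResponseRecord(ev.event_id, seen=False, verdict_basis=CATCH)
        t = true_map.thresholds[(ev.location.arm, ev.location.angle)]
        if t is not None and ev.attenuation_db <= t + 1e-9:
            return ResponseRecord(
                ev.event_id,
                seen=True,
                latency=latency,
                landing_angle=ev.location.angle,
                landing_error=0.0,
                verdict_basis=SACCADE_TOWARD,
            )
        return ResponseRecord(ev.event_id, seen=False, verdict_basis=NO_MOVEMENT)

    return responder


def generate_trace(
    pm: PatientModel,
    schedule: list[StimulusEvent],
    rate: float = 60.0,
    duration: float | None = None,
    responses: dict[int, bool] | None = None,
    habit_range_deg: float = 30.0,
) -> GazeTrace:
    """Simulate the gaze-angle time series for a whole exam.

    The trace starts at fixation and covers the schedule plus a 2 s tail
    (or an explicit ``duration`` — required when the schedule is empty,
    e.g. for a silent habitual-saccade recording).  For every stimulus the
    perceptual model (or the ``responses`` override, event_id → seen)
    decides whether a saccade is made; seen stimuli produce a step to the
    stimulus angle plus landing noise after a sampled latency, with a
    return to fixation 0.3–0.6 s later.  Habitual saccades arrive as a
    Poisson process toward uniform random angles within
    ±``habit_range_deg``; blinks appear as runs of invalid samples.
    Everything is reproducible from the patient's seed.
    """
    if rate <= 0:
        raise ValueError("sampling rate must be positive")
    if duration is None:
        if not schedule:
            raise ValueError("empty schedule requires an explicit duration")
        duration = max(ev.onset_s + ev.duration_s for ev in schedule) + 2.0
    rng = np.random.default_rng(pm.seed)
    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate

    # slow fixation drift: mean-reverting (OU) walk with stationary SD drift_sd
    az = np.zeros(n)
    el = np.zeros(n)
    if pm.drift_sd > 0:
        tau = 2.0  # drift correlation time, seconds
        rho = math.exp(-1.0 / (rate * tau))
        eps_sd = pm.drift_sd * math.sqrt(1.0 - rho * rho)
        steps = rng.normal(0.0, eps_sd, size=(n, 2))
        drift = np.empty((n, 2))
        drift[0] = 0.0
        for i in range(1, n):
            drift[i] = rho * drift[i - 1] + steps[i]
        az += drift[:, 0]
        el += drift[:, 1]

    # (t_go, t_back, az, el) excursions, applied in time order
    excursions: list[tuple[float, float, float, float]] = []
    for ev in schedule:
        if ev.is_catch:
            continue
        seen = (
            responses[ev.event_id]
            if responses is not None and ev.event_id in responses
            else respond(pm, ev, rng)
        )
        if not seen:
            continue
        latency = float(np.clip(rng.normal(pm.latency_mean, pm.latency_sd), 0.05, None))
        noise = float(rng.normal(0.0, pm.landing_sd(ev.duration_s)))
        target = ev.location.angle + noise
        t_go = ev.onset_s + latency
        t_back = t_go + float(rng.uniform(0.3, 0.6))
        if ev.location.axis == "azimuth":
            excursions.append((t_go, t_back, target, 0.0))
        else:
            excursions.append((t_go, t_back, 0.0, target))

    if pm.habit_rate > 0:
        n_habit = rng.poisson(pm.habit_rate * duration)
        for _ in range(n_habit):
            t_go = float(rng.uniform(0.0, duration))
            tgt = rng.uniform(-habit_range_deg, habit_range_deg, size=2)
            t_back = t_go + float(rng.uniform(0.3, 0.6))
            excursions.append((t_go, t_back, float(tgt[0]), float(tgt[1])))

    for t_go, t_back, x, y in sorted(excursions):
        mask = (t >= t_go) & (t < t_back)
        az[mask] = x
        el[mask] = y

    valid = np.ones(n, dtype=bool)
    if pm.blink_rate > 0:
        n_blinks = rng.poisson(pm.blink_rate * duration)
        for _ in range(n_blinks):
            b0 = float(rng.uniform(0.0, duration))
            valid[(t >= b0) & (t < b0 + pm.blink_duration)] = False

    return GazeTrace(t, az, el, valid, rate=rate)


@dataclass(frozen=True)
class RenderConfig:
    """Synthetic eye-camera rendering parameters.

    The pupil centre displaces linearly with gaze: ``gain_px_per_deg``
    pixels per degree, rightward for positive azimuth and upward (toward
    smaller row indices) for positive elevation.  That gain is the ground
    truth a fitted gaze calibration should recover.
    """

    shape: tuple[int, int] = (160, 160)
    ref_row: float = 80.0
    ref_col: float = 80.0
    gain_px_per_deg: float = 1.0
    pupil_radius: float = 10.0
    pupil_value: float = 0.05
    sclera_value: float = 0.9
    illumination_gradient: float = 0.0
    noise_sd: float = 0.0
    # static skin/sclera texture fixed to the head: identical in every
    # frame, so registration can lock onto it instead of the moving pupil
    head_texture_sd: float = 0.08
    texture_seed: int = 12345


def render_frame(
    gaze: tuple[float, float],
    cfg: RenderConfig = RenderConfig(),
    rng: np.random.Generator | None = None,
    timestamp: float = 0.0,
) -> EyeFrame:
    """Render one synthetic frame for a gaze angle (azimuth, elevation).

    Bright sclera, anti-aliased dark pupil disk, optional left-to-right
    additive illumination ramp and Gaussian pixel noise.  Raises if the
    pupil would leave the frame.
    """
    azimuth, elevation = gaze
    h, w = cfg.shape
    row = cfg.ref_row - cfg.gain_px_per_deg * elevation
    col = cfg.ref_col + cfg.gain_px_per_deg * azimuth
    r = cfg.pupil_radius
    if not (r <= row <= h - 1 - r and r <= col <= w - 1 - r):
        raise ValueError(f"gaze {gaze} puts the pupil outside the {h}x{w} frame")
    rows, cols = np.indices((h, w), dtype=float)
    dist = np.hypot(rows - row, cols - col)
    # anti-aliased disk edge: 1-px linear ramp
    blend = np.clip(dist - r + 0.5, 0.0, 1.0)
    px = cfg.pupil_value + (cfg.sclera_value - cfg.pupil_value) * blend
    if cfg.head_texture_sd:
        texture = np.random.default_rng(cfg.texture_seed).normal(
            0.0, cfg.head_texture_sd, size=(h, w)
        )
        px = px + texture
    if cfg.illumination_gradient:
        px = px + cfg.illumination_gradient * (cols / (w - 1) - 0.5)
    if cfg.noise_sd:
        if rng is None:
            rng = np.random.default_rng(0)
        px = px + rng.normal(0.0, cfg.noise_sd, size=px.shape)
    return EyeFrame(np.clip(px, 0.0, 1.0), timestamp=timestamp)
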