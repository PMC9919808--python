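"""Synthetic chest-worn accelerometer streams with per-sample activity labels.

The generator emulates a cheap tri-axial MEMS accelerometer strapped to the
chest, sampling at ~10 Hz inside a +/-2 g full-scale range.  Units are g
throughout (1 g ~= 9.81 m/s^2).

Axis convention (device on the sternum):

* +Y points head-ward when the wearer stands or sits upright,
* +Z points out of the chest,
* +X points to the wearer's left.

At rest the sensor reads the reaction to gravity, a unit vector: upright
posture gives ~(0, 1, 0) g and a supine posture ~(0, 0, 1) g.  A "tilt"
angle rotates the gravity reading from +Y toward +Z (forward pitch of the
torso / lying down) and a "lean" angle rotates it toward +X (sideways).

Activity phenomenology:

``sit``
    Static gravity vector for a roughly upright torso, plus sensor noise
    and occasional short posture-shift fidgets (nobody sits perfectly
    still).
``walk``
    Upright gravity plus a sinusoidal gait oscillation along the vertical
    axis with phase-coupled lateral sway and fore-aft components.
``sleep``
    Gravity rotated to a near-horizontal orientation, low movement, with
    rare brief turn-over movements.
``cough``
    A coughing fit on a base posture: short (2-5 sample) high-amplitude
    expulsive bursts at a configurable rate, riding on a continuous
    low-amplitude respiratory-effort tremor that spans the fit.  The
    gravity component of the base posture is kept, so a cough on a
    sleeping posture still reads as a lying orientation.
``fall``
    A brief free-fall-like drop of the magnitude toward 0 g, an impact
    spike near the full-scale range, then a transition of the gravity
    vector from upright to horizontal where it remains, with a decaying
    recovery tremor (a fallen person is not instantly motionless).

Measurement artefacts: additive Gaussian noise per axis, isolated
single-sample spikes of uniform sign on a random axis, and hard clipping
to the configured full-scale range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidInputError
from .taxonomy import ACTIVITIES

__all__ = [
    "SimConfig",
    "ActivityScriptSegment",
    "LabeledStream",
    "simulate_segment",
    "simulate_scenario",
    "make_confusable_benchmark",
    "DEFAULT_PARAMS",
]


@dataclass(frozen=True)
class SimConfig:
    """Sensor-level simulation settings.

    Defaults model the deployment regime the classifiers assume: ~10 Hz
    sampling, +/-2 g full scale, a noise floor of 0.08 g per axis and an
    occasional single-sample spike — realistic for a cheap consumer MEMS
    part worn on clothing.
    """

    sampling_rate_hz: float = 10.0
    accel_range_g: float = 2.0
    noise_sd_g: float = 0.08
    spike_prob: float = 0.01
    spike_magnitude_g: float = 1.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise InvalidConfigError("sampling_rate_hz must be positive")
        if self.accel_range_g <= 0:
            raise InvalidConfigError("accel_range_g must be positive")
        if self.noise_sd_g < 0:
            raise InvalidConfigError("noise_sd_g must be non-negative")
        if not 0.0 <= self.spike_prob <= 1.0:
            raise InvalidConfigError("spike_prob must be a probability")
        if self.spike_magnitude_g <= 0:
            raise InvalidConfigError("spike_magnitude_g must be positive")


#: Per-activity signal parameters.  Overridable per segment via
#: :attr:`ActivityScriptSegment.params`.
DEFAULT_PARAMS: dict[str, dict[str, float]] = {
    "sit": {
        "tilt_deg": 12.0,
        "lean_deg": 0.0,
        "tilt_jitter_deg": 6.0,
        "lean_jitter_deg": 4.0,
        "fidget_rate_hz": 0.3,
        "fidget_amp_g": 0.25,
    },
    "walk": {
        "tilt_deg": 12.0,
        "lean_deg": 0.0,
        "tilt_jitter_deg": 6.0,
        "lean_jitter_deg": 4.0,
        "gait_freq_hz": 2.0,
        "gait_amp_g": 0.25,
    },
    "sleep": {
        "tilt_deg": 85.0,
        "lean_deg": 0.0,
        "tilt_jitter_deg": 8.0,
        "lean_jitter_deg": 15.0,
        "turnover_rate_hz": 0.05,
        "turnover_amp_g": 0.3,
    },
    "cough": {
        "tilt_deg": 12.0,
        "lean_deg": 0.0,
        "tilt_jitter_deg": 6.0,
        "lean_jitter_deg": 4.0,
        "gait_amp_g": 0.0,  # >0 superimposes a walking base
        "gait_freq_hz": 2.0,
        "burst_rate_hz": 0.8,
        "burst_amp_g": 0.6,
        "effort_amp_g": 0.15,
    },
    "fall": {
        "tilt_deg": 12.0,
        "lean_deg": 0.0,
        "tilt_jitter_deg": 6.0,
        "lean_jitter_deg": 4.0,
        "impact_amp_g": 1.9,
        "freefall_s": 0.4,
        "lying_tilt_deg": 88.0,
        "recovery_amp_g": 0.25,
        "stumble_amp_g": 0.3,
    },
}


@dataclass(frozen=True)
class ActivityScriptSegment:
    """One scripted stretch of a single activity."""

    activity: str
    duration_s: float
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise InvalidConfigError(f"unknown activity {self.activity!r}")
        if self.duration_s <= 0:
            raise InvalidConfigError("duration_s must be positive")

    def resolved_params(self) -> dict[str, float]:
        merged = dict(DEFAULT_PARAMS[self.activity])
        merged.update(self.params)
        return merged


@dataclass(frozen=True)
class LabeledStream:
    """An ordered acceleration stream with one activity label per sample."""

    t: np.ndarray          # seconds, strictly increasing
    xyz: np.ndarray        # (n, 3) accelerations in g
    labels: np.ndarray     # (n,) activity strings
    config: SimConfig

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.xyz) == len(self.labels)):
            raise InvalidInputError("t, xyz and labels must have equal length")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "x": self.xyz[:, 0],
                "y": self.xyz[:, 1],
                "z": self.xyz[:, 2],
                "label": self.labels,
            }
        )


def _gravity(tilt_deg: float, lean_deg: float) -> np.ndarray:
    """Unit gravity-reaction vector for a torso tilted/leaned from upright."""
    tilt = math.radians(tilt_deg)
    lean = math.radians(lean_deg)
    return np.array(
        [math.sin(lean), math.cos(tilt) * math.cos(lean), math.sin(tilt) * math.cos(lean)]
    )


def _forward_axis(g0: np.ndarray) -> np.ndarray:
    """Unit vector orthogonal to gravity, approximating the fore-aft axis."""
    fwd = np.cross(g0, np.array([1.0, 0.0, 0.0]))
    n = np.linalg.norm(fwd)
    if n < 1e-9:  # gravity along X: pick the chest normal instead
        return np.array([0.0, 0.0, 1.0])
    return fwd / n


def _static_posture(n: int, tilt: float, lean: float) -> np.ndarray:
    return np.tile(_gravity(tilt, lean), (n, 1))


def _posture_series(
    n: int,
    rate: float,
    tilt: float,
    lean: float,
    rng: np.random.Generator,
    drift_deg: float,
    breath_deg: float,
    breath_hz: float = 0.25,
) -> np.ndarray:
    """Gravity reading of a held posture with slow orientation drift.

    A torso is never rigidly fixed: the tilt wanders by a few degrees over
    a segment and oscillates slightly with breathing.  ``drift_deg`` is
    the s.d. of the net tilt drift across the segment.
    """
    if drift_deg <= 0 and breath_deg <= 0:
        return _static_posture(n, tilt, lean)
    tt = np.arange(n) / rate
    tilts = (
        tilt
        + np.linspace(0.0, rng.uniform(-drift_deg, drift_deg), n)
        + breath_deg * np.sin(2.0 * math.pi * breath_hz * tt + rng.uniform(0, 2 * math.pi))
    )
    leans = lean + np.linspace(0.0, rng.uniform(-0.6 * drift_deg, 0.6 * drift_deg), n)
    tr = np.radians(tilts)
    lr = np.radians(leans)
    return np.column_stack(
        [np.sin(lr), np.cos(tr) * np.cos(lr), np.sin(tr) * np.cos(lr)]
    )


def _sparse_movement_bursts(
    xyz: np.ndarray,
    rate: float,
    event_rate_hz: float,
    amp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inject short (2-5 sample) movement bursts in random directions.

    Models involuntary micro-movements of nominally static activities:
    posture-shift fidgets while sitting, turn-overs while sleeping.
    """
    n = len(xyz)
    p_start = min(1.0, event_rate_hz / rate)
    i = 0
    while i < n:
        if rng.random() < p_start:
            direction = rng.normal(0.0, 1.0, 3)
            direction /= np.linalg.norm(direction)
            length = int(rng.integers(2, 6))
            sign = 1.0
            for k in range(i, min(i + length, n)):
                xyz[k] = xyz[k] + sign * amp * rng.uniform(0.6, 1.2) * direction
                sign = -sign
            i += length
        else:
            i += 1
    return xyz


def _walk_signal(n: int, rate: float, p: Mapping[str, float], base: np.ndarray,
                 g0: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    fwd = _forward_axis(g0)
    lat = np.array([1.0, 0.0, 0.0])
    tt = np.arange(n) / rate
    f = p["gait_freq_hz"]
    amp = p["gait_amp_g"]
    ph = rng.uniform(0.0, 2.0 * math.pi)
    vert = amp * np.sin(2.0 * math.pi * f * tt + ph)
    sway = 0.4 * amp * np.sin(math.pi * f * tt + ph / 2.0)  # half-frequency side sway
    bob = 0.3 * amp * np.sin(2.0 * math.pi * f * tt + ph + math.pi / 2.0)
    return base + vert[:, None] * g0 + sway[:, None] * lat + bob[:, None] * fwd


def _cough_signal(n: int, rate: float, p: Mapping[str, float], base: np.ndarray,
                  g0: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if p.get("gait_amp_g", 0.0) > 0:
        xyz = _walk_signal(n, rate, p, base, g0, rng)
    else:
        xyz = base.copy()
    fwd = _forward_axis(g0)
    # expulsive jerk: mostly fore-aft with a downward (anti-gravity) component
    jerk_dir = fwd * 0.8 - g0 * 0.6
    jerk_dir = jerk_dir / np.linalg.norm(jerk_dir)
    p_start = min(1.0, p["burst_rate_hz"] / rate)
    burst_starts: list[int] = []
    i = 0
    while i < n:
        if rng.random() < p_start:
            burst_starts.append(i)
            i += int(rng.integers(2, 6))
        else:
            i += 1
    if not burst_starts:  # a cough segment always coughs at least once
        burst_starts.append(int(rng.integers(0, max(1, n - 2))))
    for start in burst_starts:
        length = int(rng.integers(2, 6))
        sign = 1.0
        for k in range(start, min(start + length, n)):
            mag = p["burst_amp_g"] * rng.uniform(0.7, 1.3)
            xyz[k] = xyz[k] + sign * mag * jerk_dir
            sign = -sign  # oscillatory recoil
    # forced respiratory effort between expulsions spans the whole fit
    effort = p.get("effort_amp_g", 0.0)
    if effort > 0:
        xyz = xyz + rng.normal(0.0, effort, n)[:, None] * jerk_dir
    return xyz


def _fall_signal(n: int, rate: float, p: Mapping[str, float], tilt: float, lean: float,
                 rng: np.random.Generator) -> np.ndarray:
    g0 = _gravity(tilt, lean)
    fwd = _forward_axis(g0)
    n_pre = max(1, int(round(0.2 * n)))
    n_ff = max(2, int(round(p["freefall_s"] * rate)))
    n_imp = 2
    n_pre = min(n_pre, max(1, n - n_ff - n_imp - 1))
    n_ff = min(n_ff, max(1, n - n_pre - n_imp))
    n_lie = max(0, n - n_pre - n_ff - n_imp)
    # lead-in: the precipitating stumble, a ramping loss-of-balance sway
    pre = _static_posture(n_pre, tilt, lean)
    stumble = p.get("stumble_amp_g", 0.0)
    if stumble > 0:
        ramp = np.linspace(0.2, 1.0, n_pre) * stumble
        sway = np.sin(2.0 * math.pi * 1.5 * np.arange(n_pre) / rate + rng.uniform(0, 2 * math.pi))
        pre = pre + (ramp * sway)[:, None] * np.array([1.0, 0.0, 0.0])
    parts = [pre]
    # free fall: measured specific force collapses toward 0 g
    fade = np.linspace(0.6, 0.05, n_ff)
    parts.append(fade[:, None] * g0)
    # impact: one hard spike near full scale, one rebound
    imp_dir = 0.5 * g0 + fwd + rng.normal(0.0, 0.15, 3)
    imp_dir = imp_dir / np.linalg.norm(imp_dir)
    impact = np.vstack([imp_dir * p["impact_amp_g"], -imp_dir * 0.5 * p["impact_amp_g"]])
    parts.append(impact[: n - n_pre - n_ff])
    if n_lie > 0:
        lying_tilt = p["lying_tilt_deg"] + rng.uniform(-6.0, 6.0)
        lying_lean = rng.uniform(-15.0, 15.0)
        lying = _static_posture(n_lie, lying_tilt, lying_lean)
        # decaying recovery movement: the person stirs after the impact
        rec = p.get("recovery_amp_g", 0.0)
        if rec > 0:
            decay = np.exp(-np.arange(n_lie) / max(1.0, 4.0 * rate))
            lying = lying + (rec * decay * rng.normal(0.0, 1.0, n_lie))[:, None] * fwd
        parts.append(lying)
    return np.vstack(parts)[:n]


def simulate_segment(
    segment: ActivityScriptSegment,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    t0: float = 0.0,
) -> LabeledStream:
    """Generate one labeled segment of a single activity.

    ``rng`` lets :func:`simulate_scenario` thread a single generator through
    consecutive segments; when omitted, a fresh generator is derived from
    ``config.seed`` so a standalone segment is reproducible on its own.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = int(round(segment.duration_s * config.sampling_rate_hz))
    if n <= 0:
        raise InvalidConfigError("segment too short for the sampling rate")
    p = segment.resolved_params()
    # bounded posture variation: jitter spans +/-1.7x the nominal scale
    tilt = p["tilt_deg"] + rng.uniform(-1.7, 1.7) * p["tilt_jitter_deg"]
    lean = p["lean_deg"] + rng.uniform(-1.7, 1.7) * p["lean_jitter_deg"]
    rate = config.sampling_rate_hz

    act = segment.activity
    # noise_sd_g == 0 requests an idealised signal: involuntary
    # micro-movements (fidgets, turn-overs, posture drift, breathing) are
    # suppressed along with the sensor noise, so static activities reduce
    # to a constant unit gravity vector
    idealised = config.noise_sd_g == 0
    drift = 0.0 if idealised else 5.0
    breath = 0.0 if idealised else 1.5
    g0 = _gravity(tilt, lean)
    base = _posture_series(n, rate, tilt, lean, rng, drift, breath)
    if act == "sit":
        xyz = base.copy()
        if not idealised:
            xyz = _sparse_movement_bursts(
                xyz, rate, p["fidget_rate_hz"], p["fidget_amp_g"], rng
            )
    elif act == "sleep":
        xyz = base.copy()
        if not idealised:
            xyz = _sparse_movement_bursts(
                xyz, rate, p["turnover_rate_hz"], p["turnover_amp_g"], rng
            )
    elif act == "walk":
        xyz = _walk_signal(n, rate, p, base, g0, rng)
    elif act == "cough":
        xyz = _cough_signal(n, rate, p, base, g0, rng)
    else:  # fall
        xyz = _fall_signal(n, rate, p, tilt, lean, rng)

    if config.noise_sd_g > 0:
        xyz = xyz + rng.normal(0.0, config.noise_sd_g, xyz.shape)
    if config.spike_prob > 0:
        hits = np.flatnonzero(rng.random(n) < config.spike_prob)
        for i in hits:
            axis = int(rng.integers(0, 3))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            xyz[i, axis] += sign * config.spike_magnitude_g
    xyz = np.clip(xyz, -config.accel_range_g, config.accel_range_g)

    t = t0 + np.arange(n) / rate
    labels = np.array([act] * n, dtype=object)
    return LabeledStream(t=t, xyz=xyz, labels=labels, config=config)


def simulate_scenario(
    segments: Sequence[ActivityScriptSegment], config: SimConfig
) -> LabeledStream:
    """Concatenate scripted segments into one continuous labeled stream.

    Timestamps are continuous across segment boundaries at the configured
    rate, and the whole stream is a deterministic function of
    (script, config, seed).
    """
    if len(segments) == 0:
        raise InvalidInputError("scenario script must contain at least one segment")
    rng = np.random.default_rng(config.seed)
    parts: list[LabeledStream] = []
    t0 = 0.0
    for seg in segments:
        part = simulate_segment(seg, config, rng=rng, t0=t0)
        parts.append(part)
        t0 = part.t[-1] + 1.0 / config.sampling_rate_hz
    return LabeledStream(
        t=np.concatenate([p.t for p in parts]),
        xyz=np.vstack([p.xyz for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        config=config,
    )


def make_confusable_benchmark(
    config: SimConfig, n_per_class: int, seed: int
) -> LabeledStream:
    """Balanced 5-class benchmark with deliberate class overlap.

    Designed so a single flat 5-class model faces genuine ambiguity while
    the two-level grouping retains signal: sleep and sit torso tilts are
    drawn from overlapping distributions (a reclined sit can resemble a
    propped-up sleep), cough bursts ride on sit-, walk- and sleep-like base
    postures but stay labeled cough, and fall segments include the upright
    lead-in and the motionless lying aftermath under the fall label.
    """
    if n_per_class < 50:
        raise InvalidConfigError("n_per_class must be at least 50")
    rng = np.random.default_rng(seed)
    rate = config.sampling_rate_hz

    def segs_for(activity: str) -> list[ActivityScriptSegment]:
        out: list[ActivityScriptSegment] = []
        made = 0
        k = 0
        while made < n_per_class:
            dur = 3.0 if activity == "fall" else 10.0
            if activity == "sit":
                params = {"tilt_deg": float(np.clip(rng.normal(18.0, 12.0), 0.0, 45.0))}
            elif activity == "sleep":
                params = {"tilt_deg": float(np.clip(rng.normal(70.0, 15.0), 40.0, 95.0))}
            elif activity == "walk":
                params = {
                    "gait_freq_hz": float(rng.uniform(1.6, 2.4)),
                    "gait_amp_g": float(rng.uniform(0.15, 0.3)),
                }
            elif activity == "cough":
                base = ("sit", "walk", "sleep")[k % 3]
                params = {
                    "tilt_deg": float(np.clip(rng.normal(18.0, 12.0), 0.0, 45.0))
                    if base != "sleep"
                    else float(np.clip(rng.normal(70.0, 15.0), 40.0, 95.0)),
                    "gait_amp_g": float(rng.uniform(0.15, 0.3)) if base == "walk" else 0.0,
                }
            else:  # fall
                params = {"impact_amp_g": float(rng.uniform(1.5, 2.0))}
            out.append(ActivityScriptSegment(activity, dur, params))
            made += int(round(dur * rate))
            k += 1
        return out

    streams: list[LabeledStream] = []
    t0 = 0.0
    for activity in ACTIVITIES:
        script = segs_for(activity)
        parts: list[LabeledStream] = []
        for seg in script:
            part = simulate_segment(seg, config, rng=rng, t0=0.0)
            parts.append(part)
        xyz = np.vstack([p.xyz for p in parts])[:n_per_class]
        labels = np.concatenate([p.labels for p in parts])[:n_per_class]
        t = t0 + np.arange(n_per_class) / rate
        streams.append(LabeledStream(t=t, xyz=xyz, labels=labels, config=config))
        t0 = t[-1] + 1.0 / rate

    return LabeledStream(
        t=np.concatenate([s.t for s in streams]),
        xyz=np.vstack([s.xyz for s in streams]),
        labels=np.concatenate([s.labels for s in streams]),
        config=config,
    )
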