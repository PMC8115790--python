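"""Synthetic rigging-crew sessions: labeled accelerometer streams plus
matching time-study logs.

No field recordings are distributed with the package, so every downstream
stage is exercised on simulated sessions that reproduce the statistical
structure of observed cable-logging work:

* per-episode durations are lognormal, moment-matched to the published
  per-element mean/SD summaries (durations are positive and right-skewed,
  with medians well below means);
* the choker setter handles several chokers per turn, so each cycle
  contains a random number of (travel to log, set choker) visits —
  1 + Poisson(0.84), i.e. 1.84 on average — before travelling away and
  waiting in the clear.  This multiplicity is what reconciles the
  per-episode duration means with the observed activity time shares
  (73.04% clear for choker setters).  Chaser cycles are strict
  4-element cycles, consistent with their near-equal element frequencies;
* each activity draws its signal from one of three regimes — gait
  (sinusoidal arm swing), manipulation (sparse large pulses) or quiescent
  (low-variance noise) — with a ``separability`` dial that interpolates
  every activity toward one common noise law, so the no-signal null
  (separability 0) is available for calibration checks.

The regime waveforms are admitted inventions: the field study reports no
signal-level description of the activities, only their durations and
labels.  All regime parameters are exposed on the profiles.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .io import ACTIVITIES, CHASER, CHOKER_SETTER, AccelStream, Episode, TimeStudyLog

GAIT = "gait"
MANIPULATION = "manipulation"
QUIESCENT = "quiescent"

#: Noise level (mgn) shared by every activity when separability = 0.
NEUTRAL_NOISE_SD = 60.0

#: Fixed per-axis amplitude fractions for the gait sinusoid (wrist swing
#: dominates one axis).
GAIT_AXIS_WEIGHTS = (1.0, 0.6, 0.35)

#: Mean (travel-to-log, set-choker) visits per choker-setter cycle implied
#: jointly by the published per-element duration means and time shares.
CHOKER_SET_REPEATS_MEAN = 1.84


@dataclasses.dataclass
class ActivityProfile:
    """Duration distribution and signal regime of one work element."""

    activity: str
    duration_mean: float  # s
    duration_sd: float  # s
    regime: str
    base_amplitude: float  # mgn
    dominant_freq: float = 2.0  # Hz (gait) / pulse rate scale otherwise
    noise_sd: float = 60.0  # mgn
    pulse_rate: float = 2.0  # pulses per second (manipulation/quiescent)

    def __post_init__(self):
        if self.duration_mean <= 0:
            raise ValueError("duration_mean must be positive")
        if self.duration_sd < 0:
            raise ValueError("duration_sd must be nonnegative")
        if self.regime not in (GAIT, MANIPULATION, QUIESCENT):
            raise ValueError(f"unknown regime {self.regime!r}")


def default_profiles(worker_type: str) -> dict[str, ActivityProfile]:
    """Profiles with published duration moments and plausible kinematics.

    Travel elements are 2-Hz-ish gait; set/unhook are pulse bursts from
    handling chokers; clear is low-variance quiescence with sporadic small
    movements (noise at a quarter of the travel amplitude scale).
    """
    if worker_type == CHOKER_SETTER:
        durs = {
            "travel_to_log": (17.27, 12.30),
            "set_choker": (19.80, 16.06),
            "travel_away": (13.11, 6.83),
            "clear": (220.31, 519.17),
        }
        manipulation = "set_choker"
    elif worker_type == CHASER:
        durs = {
            "travel_to_log": (4.59, 4.42),
            "unhook": (8.00, 6.42),
            "travel_away": (6.69, 3.73),
            "clear": (264.48, 481.49),
        }
        manipulation = "unhook"
    else:
        raise ValueError(f"unknown worker_type {worker_type!r}")
    profiles = {
        "travel_to_log": ActivityProfile(
            "travel_to_log", *durs["travel_to_log"], regime=GAIT,
            base_amplitude=500.0, dominant_freq=2.0, noise_sd=120.0,
        ),
        manipulation: ActivityProfile(
            manipulation, *durs[manipulation], regime=MANIPULATION,
            base_amplitude=900.0, noise_sd=80.0, pulse_rate=2.0,
        ),
        "travel_away": ActivityProfile(
            "travel_away", *durs["travel_away"], regime=GAIT,
            base_amplitude=260.0, dominant_freq=1.8, noise_sd=60.0,
        ),
        "clear": ActivityProfile(
            "clear", *durs["clear"], regime=QUIESCENT,
            base_amplitude=125.0, noise_sd=30.0, pulse_rate=0.1,
        ),
    }
    return profiles


@dataclasses.dataclass
class SimulationConfig:
    """Everything needed to generate one worker session."""

    worker_type: str
    n_cycles: int
    rate_hz: float = 25.0
    seed: int = 0
    profiles: dict[str, ActivityProfile] | None = None
    separability: float = 1.0
    set_repeats_mean: float | None = None  # visits per cycle; None = worker default
    session_id: str = "synthetic"
    start_t_ms: int = 0

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not 0.0 <= self.separability <= 1.0:
            raise ValueError("separability must be in [0, 1]")
        if self.profiles is None:
            self.profiles = default_profiles(self.worker_type)
        expected = set(ACTIVITIES[self.worker_type])
        if set(self.profiles) != expected:
            raise ValueError(
                f"profiles must cover exactly {sorted(expected)}"
            )
        if self.set_repeats_mean is None:
            self.set_repeats_mean = (
                CHOKER_SET_REPEATS_MEAN if self.worker_type == CHOKER_SETTER else 1.0
            )
        if self.set_repeats_mean < 1:
            raise ValueError("set_repeats_mean must be >= 1")


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given arithmetic mean and SD."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def sample_durations(
    profile: ActivityProfile, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw n episode durations (s) from the profile's lognormal.

    The lognormal is moment-matched: its arithmetic mean and SD equal the
    profile's duration_mean/duration_sd.  duration_sd = 0 degenerates to
    constant durations.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if profile.duration_sd == 0:
        return np.full(n, profile.duration_mean)
    mu, sigma = lognormal_params(profile.duration_mean, profile.duration_sd)
    return rng.lognormal(mu, sigma, size=n)


def _episode_signal(
    profile: ActivityProfile,
    n: int,
    rate_hz: float,
    separability: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One episode's (n, 3) body-movement signal, before the gravity offset.

    The activity-specific regime waveform is blended with a common
    Gaussian noise law: at separability 0 every activity emits the same
    law; at 1 the full regime contrast is present.
    """
    s = separability
    noise_sd = (1.0 - s) * NEUTRAL_NOISE_SD + s * profile.noise_sd
    sig = rng.normal(0.0, noise_sd, size=(n, 3))
    if s == 0.0:
        return sig
    t = np.arange(n) / rate_hz
    if profile.regime == GAIT:
        phases = rng.uniform(0, 2 * np.pi, size=3)
        for ax, w in enumerate(GAIT_AXIS_WEIGHTS):
            sig[:, ax] += s * w * profile.base_amplitude * np.sin(
                2 * np.pi * profile.dominant_freq * t + phases[ax]
            )
    else:
        # sparse pulses: sample-scale impulses pass the bandpass nearly intact
        n_pulses = rng.poisson(profile.pulse_rate * n / rate_hz)
        if n_pulses > 0:
            pos = rng.integers(0, n, size=n_pulses)
            amps = rng.exponential(profile.base_amplitude, size=n_pulses)
            signs = rng.choice([-1.0, 1.0], size=n_pulses)
            weights = rng.dirichlet(np.ones(3), size=n_pulses)
            for k in range(n_pulses):
                pulse = s * signs[k] * amps[k] * weights[k]
                sig[pos[k]] += pulse
                if pos[k] + 1 < n:
                    sig[pos[k] + 1] += 0.5 * pulse
    return sig


def generate_time_study(config: SimulationConfig) -> TimeStudyLog:
    """Generate only the time-study log (no accelerometer signal).

    Same cycle structure and duration distributions as
    :func:`generate_worker_session`, for studies of cycle-time statistics
    where the signal is not needed (the RNG stream differs, since no
    signal draws are interleaved).
    """
    rng = np.random.default_rng(config.seed)
    travel_in, handle, travel_out, clear = ACTIVITIES[config.worker_type]
    activities: list[str] = []
    for _ in range(config.n_cycles):
        k = 1 + rng.poisson(config.set_repeats_mean - 1.0)
        for _ in range(k):
            activities.extend([travel_in, handle])
        activities.extend([travel_out, clear])
    dt_ms = 1000.0 / config.rate_hz
    episodes: list[Episode] = []
    cursor = 0
    for act in activities:
        dur = float(sample_durations(config.profiles[act], 1, rng)[0])
        n = max(2, int(round(dur * config.rate_hz)))
        start = config.start_t_ms + int(round(cursor * dt_ms))
        stop = config.start_t_ms + int(round((cursor + n) * dt_ms))
        episodes.append(Episode(act, start, stop))
        cursor += n
    return TimeStudyLog(worker_type=config.worker_type, episodes=episodes)


def generate_worker_session(config: SimulationConfig) -> tuple[AccelStream, TimeStudyLog]:
    """Generate one simulated session: accelerometer stream + time-study log.

    Each cycle is k visits of (travel to log, set/unhook) with
    k = 1 + Poisson(set_repeats_mean - 1), then travel away, then clear.
    The stream and the log share the time base exactly: episode boundaries
    fall on sample boundaries, so labeling by timestamp recovers the
    generating labels without loss.  A 1000-mgn gravity offset sits on the
    z axis.
    """
    rng = np.random.default_rng(config.seed)
    order = ACTIVITIES[config.worker_type]
    travel_in, handle, travel_out, clear = order

    activities: list[str] = []
    for _ in range(config.n_cycles):
        k = 1 + rng.poisson(config.set_repeats_mean - 1.0)
        for _ in range(k):
            activities.extend([travel_in, handle])
        activities.extend([travel_out, clear])

    dt_ms = 1000.0 / config.rate_hz
    episodes: list[Episode] = []
    chunks: list[np.ndarray] = []
    sample_cursor = 0
    for act in activities:
        prof = config.profiles[act]
        dur = float(sample_durations(prof, 1, rng)[0])
        n = max(2, int(round(dur * config.rate_hz)))
        chunks.append(
            _episode_signal(prof, n, config.rate_hz, config.separability, rng)
        )
        start = config.start_t_ms + int(round(sample_cursor * dt_ms))
        stop = config.start_t_ms + int(round((sample_cursor + n) * dt_ms))
        episodes.append(Episode(act, start, stop))
        sample_cursor += n

    sig = np.concatenate(chunks, axis=0)
    sig[:, 2] += 1000.0  # gravity on z, in mgn
    t = config.start_t_ms + np.round(np.arange(len(sig)) * dt_ms).astype(np.int64)
    stream = AccelStream(
        session_id=config.session_id,
        rate_hz=config.rate_hz,
        t=t,
        ax=sig[:, 0],
        ay=sig[:, 1],
        az=sig[:, 2],
    )
    return stream, TimeStudyLog(worker_type=config.worker_type, episodes=episodes)


def activity_time_shares(log: TimeStudyLog) -> dict[str, float]:
    """Fraction of logged time spent in each activity."""
    totals: dict[str, float] = {}
    for ep in log.episodes:
        totals[ep.activity] = totals.get(ep.activity, 0.0) + (ep.stop - ep.start)
    grand = sum(totals.values())
    return {a: v / grand for a, v in totals.items()}
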