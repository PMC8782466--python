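"""Synthetic paired manic/euthymic actigraphy cohorts.

Real per-minute activity counts are non-negative, right-skewed, and ride on
a ~24-h sleep/wake cycle with a ~4-h ultradian oscillation and bursty
daytime noise.  The generator is phenomenological, not physiological:

    counts[t] = gate(t) * max(0, mesor + A_c sin(2*pi*t/1440 + phi)
                                       + A_u sin(2*pi*t/240 + psi))
                        * noise(t) * event(t)

where ``gate`` drops activity to ``sleep_level`` inside a nightly sleep
window, ``noise`` is unit-mean log-normal with coefficient of variation
``noise_dispersion`` and AR(1) persistence ``noise_smoothness`` on the log
scale (human activity is right-skewed *and* sticky from minute to minute —
without that persistence the strong lag-1 autocorrelation and the dense
similarity graphs of real actigraphy cannot arise), and rare ``event``
factors inject bursts or drops at per-minute probability ``irregularity``.

The mood-state presets encode the direction of the manic-vs-euthymic
contrasts the analysis is meant to detect: mania has an attenuated circadian
cycle (shallower, shorter sleep; smaller 24-h amplitude) and noisier,
burstier minute-to-minute dynamics.  Together these lower the relative SD,
raise sample entropy (the tolerance r shrinks with the SD), thin out the
similarity graph (fewer edges and triangles) and leave more bridges.
Everything is deterministic in the seed (numpy PCG64; draw order: ultradian
phase, log-noise innovations, event positions, event types, event factors).
"""

from __future__ import annotations

import copy
import os
from dataclasses import dataclass, field, replace
from datetime import datetime

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .preprocess import ActivitySeries, RawAccelSeries, write_minute_csv

__all__ = [
    "SimParams",
    "StatePreset",
    "euthymic_preset",
    "manic_preset",
    "simulate_recording",
    "simulate_cohort",
    "simulate_raw",
    "write_cohort_csv",
]

MINUTES_PER_DAY = 1440
ULTRADIAN_PERIOD = 240  # ~4-h ultradian rest-activity oscillation


@dataclass(frozen=True)
class SimParams:
    """Generator parameters for one recording.

    minutes : series length (1190, one full analysis epoch).
    mesor : baseline level, counts/min.
    circadian_amplitude, ultradian_amplitude : counts/min of the 24-h and
        4-h sinusoids.
    start_minute_of_day : clock minute of the first sample (recordings start
        around midday).
    sleep_start, sleep_duration : clock minute and length of the nightly
        low-activity gate; duration 0 disables the gate.
    sleep_level : fraction of activity retained during sleep.
    noise_dispersion : stationary coefficient of variation of the
        multiplicative unit-mean log-normal noise; 0 disables noise.
    noise_smoothness : AR(1) coefficient of the log-noise in [0, 1);
        larger = stickier minute-to-minute activity.
    irregularity : per-minute probability of a burst/drop event.
    seed : PRNG seed.
    """

    minutes: int = 1190
    mesor: float = 320.0
    circadian_amplitude: float = 185.0
    ultradian_amplitude: float = 60.0
    start_minute_of_day: int = 780  # 13:00
    sleep_start: int = 1380  # 23:00
    sleep_duration: int = 450
    sleep_level: float = 0.05
    noise_dispersion: float = 0.55
    noise_smoothness: float = 0.9
    irregularity: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        if self.minutes < 3:
            raise ValueError("minutes must be >= 3")
        if self.mesor < 0 or self.circadian_amplitude < 0 or self.ultradian_amplitude < 0:
            raise ValueError("mesor and amplitudes must be >= 0")
        if not 0 <= self.irregularity <= 1:
            raise ValueError("irregularity must be in [0, 1]")
        if not 0 <= self.sleep_start < MINUTES_PER_DAY:
            raise ValueError("sleep_start must be a minute of day in [0, 1440)")
        if not 0 <= self.sleep_duration <= MINUTES_PER_DAY:
            raise ValueError("sleep_duration must be in [0, 1440]")
        if not 0 <= self.sleep_level <= 1:
            raise ValueError("sleep_level must be in [0, 1]")
        if self.noise_dispersion < 0:
            raise ValueError("noise_dispersion must be >= 0")
        if not 0 <= self.noise_smoothness < 1:
            raise ValueError("noise_smoothness must be in [0, 1)")


@dataclass(frozen=True)
class StatePreset:
    """A mood-state label with its generator parameters."""

    label: str
    params: SimParams


def euthymic_preset() -> StatePreset:
    """Remitted state: pronounced circadian cycle, consolidated deep sleep."""
    return StatePreset("euthymic", SimParams())


def manic_preset() -> StatePreset:
    """Manic state: attenuated circadian cycle, fragmented shallow sleep,
    noisier and burstier daytime activity."""
    return StatePreset(
        "manic",
        replace(
            SimParams(),
            mesor=340.0,
            circadian_amplitude=70.0,
            ultradian_amplitude=80.0,
            sleep_duration=300,
            sleep_level=0.35,
            noise_dispersion=0.7,
            noise_smoothness=0.85,
            irregularity=0.025,
        ),
    )


def _gate(params: SimParams) -> np.ndarray:
    t_mod = (params.start_minute_of_day + np.arange(params.minutes)) % MINUTES_PER_DAY
    if params.sleep_duration == 0:
        return np.ones(params.minutes)
    rel = (t_mod - params.sleep_start) % MINUTES_PER_DAY
    asleep = rel < params.sleep_duration
    return np.where(asleep, params.sleep_level, 1.0)


def simulate_recording(params: SimParams, state: str = "unlabelled",
                       subject_id: str | None = None) -> ActivitySeries:
    """Generate one per-minute recording, fully determined by ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    t = params.start_minute_of_day + np.arange(params.minutes, dtype=float)
    # circadian trough centred in the sleep window
    trough = (params.sleep_start + params.sleep_duration / 2) % MINUTES_PER_DAY
    phi = -2 * np.pi * trough / MINUTES_PER_DAY - np.pi / 2
    psi = rng.uniform(0, 2 * np.pi)
    base = (
        params.mesor
        + params.circadian_amplitude * np.sin(2 * np.pi * t / MINUTES_PER_DAY + phi)
        + params.ultradian_amplitude * np.sin(2 * np.pi * t / ULTRADIAN_PERIOD + psi)
    )
    np.maximum(base, 0.0, out=base)
    d = params.noise_dispersion
    if d > 0:
        # unit-mean log-normal with stationary CV = d and AR(1) log dynamics
        sigma = np.sqrt(np.log(1.0 + d**2))
        rho = params.noise_smoothness
        eps = rng.normal(0.0, sigma, size=params.minutes)
        log_noise = np.empty(params.minutes)
        log_noise[0] = eps[0]
        if params.minutes > 1:
            innov_sd = np.sqrt(1.0 - rho**2)
            log_noise[1:] = lfilter([1.0], [1.0, -rho], innov_sd * eps[1:],
                                    zi=np.array([rho * log_noise[0]]))[0]
        noise = np.exp(log_noise - sigma**2 / 2.0)
    else:
        noise = np.ones(params.minutes)
    counts = _gate(params) * base * noise
    if params.irregularity > 0:
        events = rng.random(params.minutes) < params.irregularity
        bursts = rng.random(params.minutes) < 0.5
        factors = np.where(
            bursts, rng.uniform(3.0, 6.0, params.minutes), rng.uniform(0.0, 0.15, params.minutes)
        )
        counts = np.where(events, counts * factors, counts)
    start = datetime(2024, 1, 1) + pd.Timedelta(minutes=params.start_minute_of_day)
    return ActivitySeries(counts=counts, start_time=start.to_pydatetime()
                          if hasattr(start, "to_pydatetime") else start,
                          subject_id=subject_id, state=state)


def simulate_cohort(
    n_pairs: int,
    manic: StatePreset | None = None,
    euthymic: StatePreset | None = None,
    seed: int = 0,
) -> list[ActivitySeries]:
    """Generate a paired cohort: one manic and one euthymic recording per subject.

    Subject-level random effects (log-normal multipliers on mesor and
    amplitudes, a normal shift of the sleep window) are shared across the two
    states of a subject, so within-subject contrasts isolate the state effect.
    Deterministic in ``seed``.
    """
    if n_pairs < 2:
        raise ValueError(f"n_pairs must be >= 2, got {n_pairs}")
    manic = manic or manic_preset()
    euthymic = euthymic or euthymic_preset()
    rng = np.random.default_rng(seed)
    recordings: list[ActivitySeries] = []
    for i in range(n_pairs):
        subject = f"S{i + 1:02d}"
        mesor_mult = rng.lognormal(mean=0.0, sigma=0.12)
        amp_mult = rng.lognormal(mean=0.0, sigma=0.15)
        sleep_shift = int(round(rng.normal(0.0, 30.0)))
        for preset in (manic, euthymic):
            p = preset.params
            p = replace(
                p,
                mesor=p.mesor * mesor_mult,
                circadian_amplitude=p.circadian_amplitude * amp_mult,
                ultradian_amplitude=p.ultradian_amplitude * amp_mult,
                sleep_start=(p.sleep_start + sleep_shift) % MINUTES_PER_DAY,
                seed=int(rng.integers(2**31)),
            )
            recordings.append(simulate_recording(p, state=preset.label, subject_id=subject))
    return recordings


def simulate_raw(params: SimParams, sampling_rate: float = 32.0) -> RawAccelSeries:
    """Expand a per-minute target series into 32 Hz tri-axial samples.

    Each minute's samples point in random directions with magnitudes
    ``1 + c * e`` where the non-negative factors ``e`` are rescaled to unit
    block mean, so the per-minute mean of |magnitude - 1| reproduces the
    per-minute target count exactly (up to float rounding).
    """
    target = simulate_recording(params).counts
    rng = np.random.default_rng(params.seed + 1 if params.seed < 2**31 - 1 else 0)
    spm = int(round(sampling_rate * 60))
    n = len(target) * spm
    e = rng.gamma(shape=4.0, scale=0.25, size=(len(target), spm))
    e /= e.mean(axis=1, keepdims=True)
    dev = (target[:, None] * e).ravel()
    mag = 1.0 + dev
    vec = rng.normal(size=(n, 3))
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    vec *= mag[:, None]
    return RawAccelSeries(
        x=vec[:, 0], y=vec[:, 1], z=vec[:, 2],
        sampling_rate=sampling_rate,
        start_time=datetime(2024, 1, 1),
    )


def write_cohort_csv(recordings: list[ActivitySeries], out_dir,
                     header_comment: str | None = None) -> str:
    """Write per-minute CSVs plus a ``manifest.csv`` (subject, state, file)."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.subject_id}_{rec.state}.csv"
        write_minute_csv(rec, os.path.join(out_dir, fname), header_comment=header_comment)
        rows.append({"subject_id": rec.subject_id, "state": rec.state, "file": fname})
    manifest = os.path.join(out_dir, "manifest.csv")
    with open(manifest, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)
    return manifest
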