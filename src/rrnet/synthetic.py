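"""Synthetic RR-interval cohorts with class-distinct rhythm statistics.

Generates labelled tachograms for three rhythm classes:

* **NSR** — regular sinus rhythm: near-constant intervals with a slow
  sinusoidal modulation emulating respiratory sinus arrhythmia plus small
  Gaussian jitter.
* **AFIB** — atrial fibrillation: independent, right-skewed interval draws
  (Gamma law) at a fast ventricular rate (150-220 bpm) with a large
  coefficient of variation, mimicking the irregularly irregular pulse.
* **AFL** — atrial flutter: the atrium cycles at 240-360 bpm and the AV node
  conducts every 2nd/3rd/4th atrial beat, so ventricular intervals are
  (near) integer multiples of the atrial cycle, following a Markov chain
  over the conduction ratios.

A toy single-lead ECG synthesiser (`synth_ecg`) produces a spike train with
ground-truth beat locations so the QRS detector can be validated without any
external recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CLASSES",
    "RhythmParams",
    "RRBlock",
    "nsr_params",
    "afib_params",
    "afl_params",
    "default_params",
    "simulate_block",
    "simulate_cohort",
    "synth_ecg",
]

#: Canonical class order used throughout the package (confusion-matrix order).
CLASSES = ("AFIB", "AFL", "NSR")

#: Shortest physiological RR interval (s): the ventricular refractory period.
MIN_RR = 0.25


@dataclass(frozen=True)
class RhythmParams:
    """Generative parameters for one rhythm class.

    Parameters
    ----------
    rhythm_class
        One of ``"NSR"``, ``"AFIB"``, ``"AFL"``.
    mean_rate
        Mean ventricular rate in beats/minute (for AFL this is the atrial
        rate divided by the mean conduction ratio; it is implied by
        ``atrial_cycle`` and ``conduction_ratios`` and ignored if those are
        set).
    rate_jitter
        Coefficient of variation of the beat-to-beat interval (dimensionless).
    modulation_depth
        Fractional amplitude of the slow sinusoidal modulation (NSR only).
    modulation_freq_hz
        Frequency of the slow modulation in Hz (NSR only).
    atrial_cycle
        Atrial cycle length in seconds (AFL only); 0.2 s corresponds to the
        typical 300 bpm flutter rate.
    conduction_ratios
        AV conduction ratios (small integers); each ventricular interval is
        ``k * atrial_cycle`` for a ratio ``k`` drawn from a Markov chain.
    conduction_stay_prob
        Probability that the Markov chain keeps the current conduction ratio
        at the next beat; the remainder is split evenly over the others.
    """

    rhythm_class: str
    mean_rate: float = 70.0
    rate_jitter: float = 0.03
    modulation_depth: float = 0.0
    modulation_freq_hz: float = 0.25
    atrial_cycle: float = 0.2
    conduction_ratios: tuple[int, ...] = (2, 3, 4)
    conduction_stay_prob: float = 0.7

    def validate(self) -> None:
        if self.rhythm_class not in CLASSES:
            raise ValueError(f"unknown rhythm class {self.rhythm_class!r}")
        if not self.mean_rate > 0:
            raise ValueError("mean_rate must be positive")
        if not 0 <= self.rate_jitter < 1:
            raise ValueError("rate_jitter must lie in [0, 1)")
        if self.rhythm_class == "AFL":
            if not self.conduction_ratios:
                raise ValueError("conduction_ratios must be non-empty")
            if not set(self.conduction_ratios) <= {2, 3, 4}:
                raise ValueError("conduction_ratios must be a subset of {2,3,4}")
            if not self.atrial_cycle > 0:
                raise ValueError("atrial_cycle must be positive")
            if not 0 < self.conduction_stay_prob <= 1:
                raise ValueError("conduction_stay_prob must lie in (0, 1]")


@dataclass(frozen=True, eq=False)
class RRBlock:
    """One patient's labelled RR-interval sequence (unit of partitioning)."""

    patient_id: str
    label: str
    rr: np.ndarray  # seconds, 1-D
    duration: float  # seconds

    def __post_init__(self) -> None:
        rr = np.asarray(self.rr, dtype=float)
        object.__setattr__(self, "rr", rr)
        if rr.ndim != 1 or rr.size < 1:
            raise ValueError("rr must be a non-empty 1-D sequence")
        if not np.all(rr > 0):
            raise ValueError("all RR intervals must be positive")

    @property
    def n_beats(self) -> int:
        """Number of beats implied by the intervals (fenceposts)."""
        return self.rr.size + 1


def nsr_params(mean_rate: float = 70.0, rate_jitter: float = 0.02,
               modulation_depth: float = 0.04) -> RhythmParams:
    """Default normal-sinus-rhythm parameters (~70 bpm, mild variability)."""
    return RhythmParams("NSR", mean_rate=mean_rate, rate_jitter=rate_jitter,
                        modulation_depth=modulation_depth)


def afib_params(mean_rate: float = 185.0, rate_jitter: float = 0.25) -> RhythmParams:
    """Default atrial-fibrillation parameters: fast (150-220 bpm) and chaotic."""
    return RhythmParams("AFIB", mean_rate=mean_rate, rate_jitter=rate_jitter)


def afl_params(atrial_cycle: float = 0.2,
               conduction_ratios: tuple[int, ...] = (2, 3, 4),
               conduction_stay_prob: float = 0.7,
               rate_jitter: float = 0.02) -> RhythmParams:
    """Default atrial-flutter parameters: 300 bpm atrial rate, 2:1/3:1/4:1 AV block."""
    return RhythmParams("AFL", rate_jitter=rate_jitter, atrial_cycle=atrial_cycle,
                        conduction_ratios=conduction_ratios,
                        conduction_stay_prob=conduction_stay_prob)


def default_params(rhythm_class: str) -> RhythmParams:
    if rhythm_class == "NSR":
        return nsr_params()
    if rhythm_class == "AFIB":
        return afib_params()
    if rhythm_class == "AFL":
        return afl_params()
    raise ValueError(f"unknown rhythm class {rhythm_class!r}")


def _nsr_intervals(params: RhythmParams, duration: float,
                   rng: np.random.Generator) -> np.ndarray:
    base = 60.0 / params.mean_rate
    # upper bound on beat count; base > 0 and modulation depth < 1
    n_max = int(np.ceil(duration / (base * (1 - min(params.modulation_depth, 0.9))))) + 2
    phase0 = rng.uniform(0, 2 * np.pi)
    rr = np.empty(n_max)
    t = 0.0
    for i in range(n_max):
        mod = 1.0 + params.modulation_depth * np.sin(
            2 * np.pi * params.modulation_freq_hz * t + phase0)
        iv = base * mod
        if params.rate_jitter > 0:
            iv *= 1.0 + params.rate_jitter * rng.standard_normal()
        rr[i] = max(iv, 0.05)
        t += rr[i]
    return rr


def _afib_intervals(params: RhythmParams, duration: float,
                    rng: np.random.Generator) -> np.ndarray:
    mean = 60.0 / params.mean_rate
    cv = max(params.rate_jitter, 0.15)
    # Gamma with mean m and CV c: shape k = 1/c^2, scale = m*c^2
    shape = 1.0 / cv**2
    scale = mean * cv**2
    n_max = int(np.ceil(duration / mean * 3)) + 4
    # ventricular refractoriness lower-bounds physiological RR intervals
    return np.maximum(rng.gamma(shape, scale, size=n_max), MIN_RR)


def _afl_intervals(params: RhythmParams, duration: float,
                   rng: np.random.Generator) -> np.ndarray:
    ratios = np.asarray(sorted(params.conduction_ratios))
    n_max = int(np.ceil(duration / (params.atrial_cycle * ratios.min()))) + 2
    k_idx = rng.integers(len(ratios))
    rr = np.empty(n_max)
    stay = params.conduction_stay_prob
    for i in range(n_max):
        rr[i] = ratios[k_idx] * params.atrial_cycle
        if params.rate_jitter > 0:
            rr[i] *= 1.0 + params.rate_jitter * rng.standard_normal()
            rr[i] = max(rr[i], 0.05)
        if len(ratios) > 1 and rng.uniform() >= stay:
            others = [j for j in range(len(ratios)) if j != k_idx]
            k_idx = others[rng.integers(len(others))]
    return rr


def simulate_block(params: RhythmParams, duration: float = 10.0,
                   seed: int | np.random.Generator | None = 0,
                   patient_id: str = "synthetic") -> RRBlock:
    """Simulate one patient's RR block of the given duration.

    Beats are emitted until their cumulative time exceeds ``duration``; the
    final partial interval is dropped, so ``sum(rr) <= duration``. Identical
    seeds yield identical blocks.
    """
    params.validate()
    if not duration > 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gen = {"NSR": _nsr_intervals, "AFIB": _afib_intervals, "AFL": _afl_intervals}
    rr = gen[params.rhythm_class](params, duration, rng)
    # extend until the cumulative time covers the duration
    while rr.sum() < duration:
        rr = np.concatenate([rr, gen[params.rhythm_class](params, duration, rng)])
    keep = np.cumsum(rr) <= duration
    rr = rr[keep]
    if rr.size == 0:  # first interval alone exceeds the block
        raise ValueError("duration too short to hold a single beat interval")
    return RRBlock(patient_id=patient_id, label=params.rhythm_class,
                   rr=rr, duration=duration)


def simulate_cohort(n_per_class: Sequence[int] | dict[str, int],
                    duration: float = 10.0, seed: int = 0,
                    params_by_class: dict[str, RhythmParams] | None = None,
                    ) -> list[RRBlock]:
    """Simulate a labelled cohort, one block per synthetic patient.

    ``n_per_class`` is either a mapping class -> count or a triple of counts
    in canonical (AFIB, AFL, NSR) order. Patient ids are unique within the
    cohort and encode the class for readability.
    """
    if not isinstance(n_per_class, dict):
        counts = dict(zip(CLASSES, n_per_class))
    else:
        counts = dict(n_per_class)
    if any(c < 0 for c in counts.values()):
        raise ValueError("class counts must be non-negative")
    params_by_class = params_by_class or {}
    root = np.random.default_rng(seed)
    blocks: list[RRBlock] = []
    for cls in CLASSES:
        n = counts.get(cls, 0)
        params = params_by_class.get(cls, default_params(cls))
        child = np.random.default_rng(root.integers(2**31))
        for i in range(n):
            blocks.append(simulate_block(params, duration,
                                         seed=np.random.default_rng(child.integers(2**31)),
                                         patient_id=f"{cls}-{i:05d}"))
    return blocks


def synth_ecg(block: RRBlock, fs: float = 500.0,
              r_width: float = 0.012, r_amp: float = 1.0,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Render a toy single-lead ECG trace for a block.

    Each beat contributes a narrow Gaussian R spike plus smaller, wider P and
    T bumps. Beats sit at the cumulative beat times of the block (the first
    beat at t=0), so a block with ``len(rr)`` intervals implies
    ``len(rr)+1`` beats.

    Returns
    -------
    trace : ndarray of shape (round(duration*fs),)
    beat_idx : ndarray of int
        Ground-truth R-peak sample indices, clipped to the trace.
    """
    if fs < 100:
        raise ValueError("fs must be at least 100 Hz")
    if block.rr.size == 0:
        raise ValueError("empty block")
    n = int(round(block.duration * fs))
    t = np.arange(n) / fs
    beat_times = np.concatenate([[0.0], np.cumsum(block.rr)])
    trace = np.zeros(n)
    for bt in beat_times:
        # R spike
        trace += r_amp * np.exp(-0.5 * ((t - bt) / r_width) ** 2)
        # T wave ~200 ms after R, P wave ~160 ms before the next R
        trace += 0.15 * r_amp * np.exp(-0.5 * ((t - bt - 0.20) / 0.05) ** 2)
        trace += 0.10 * r_amp * np.exp(-0.5 * ((t - bt + 0.16) / 0.04) ** 2)
    beat_idx = np.minimum(np.round(beat_times * fs).astype(int), n - 1)
    return trace, beat_idx
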