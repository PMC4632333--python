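"""Seeded generator of PD-like and ET-like multi-task tremor recordings.

Tremor is modeled as an amplitude- and phase-modulated sinusoid (not an
AR draw, so the AR spectral stage is tested on signals it did not
assume) plus broadband noise. The kinetic task adds a high-amplitude
sub-2-Hz voluntary-movement component that the 3 Hz high-pass edge of
the preprocessing filter must remove — the filter is load-bearing.

Class defaults are package configuration for synthetic experiments, not
estimates of any clinical quantity:

* PD-like: rest-dominant amplitude (rest/kinetic = 10) and a lower
  resting center frequency than the kinetic task.
* ET-like: action-dominant amplitude (rest/kinetic = 0.05) and a stable
  center frequency across tasks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError
from .fluctuation import LABEL_ET, LABEL_PD, CohortSubject
from .recording import DEFAULT_SAMPLING_RATE, TASKS, TremorRecording, validate_task

#: Relative amplitude of the y and z channels (scaled copies of x).
_CROSS_AXIS_GAINS = (0.35, 0.2)


@dataclass(frozen=True)
class TremorProfile:
    """Per-class signal-generation parameters for one subject."""

    label: str
    rest_amp: float
    kinetic_amp: float
    postural_amp: float
    rest_freq: float
    kinetic_freq: float
    postural_freq: float
    frequency_jitter_sd: float = 0.1
    amplitude_modulation_depth: float = 0.3
    amplitude_modulation_rate: float = 0.8
    broadband_noise_sd: float = 0.002
    voluntary_motion_amp: float = 3.0
    voluntary_motion_freq: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in (LABEL_PD, LABEL_ET):
            raise ParameterError(f"label must be PD or ET, got {self.label!r}")
        for name in ("rest_amp", "kinetic_amp", "postural_amp"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")
        for name in ("rest_freq", "kinetic_freq", "postural_freq"):
            freq = getattr(self, name)
            if not 3.0 < freq < 10.0:
                raise ParameterError(f"{name} must lie in (3, 10) Hz, got {freq}")
        if not 0 <= self.amplitude_modulation_depth < 1:
            raise ParameterError("amplitude_modulation_depth must be in [0, 1)")
        if self.frequency_jitter_sd < 0 or self.broadband_noise_sd < 0:
            raise ParameterError("jitter and noise standard deviations must be >= 0")
        if self.voluntary_motion_amp < 0:
            raise ParameterError("voluntary_motion_amp must be nonnegative")
        if not 0 < self.voluntary_motion_freq < 2.0:
            raise ParameterError("voluntary_motion_freq must lie in (0, 2) Hz")

    def amplitude_for(self, task: str) -> float:
        return {
            "resting": self.rest_amp,
            "kinetic": self.kinetic_amp,
            "postural": self.postural_amp,
        }[task]

    def frequency_for(self, task: str) -> float:
        return {
            "resting": self.rest_freq,
            "kinetic": self.kinetic_freq,
            "postural": self.postural_freq,
        }[task]


PD_DEFAULT_PROFILE = TremorProfile(
    label=LABEL_PD,
    rest_amp=1.0,
    kinetic_amp=0.1,
    postural_amp=0.4,
    rest_freq=4.5,
    kinetic_freq=6.5,
    postural_freq=5.5,
)

# ET frequencies sit at 5 Hz: stable across tasks, and well away from
# 6.25 Hz where a 20-sample difference spans a full period and the
# embedding's second coordinate nearly vanishes.
ET_DEFAULT_PROFILE = TremorProfile(
    label=LABEL_ET,
    rest_amp=0.05,
    kinetic_amp=1.0,
    postural_amp=0.8,
    rest_freq=5.0,
    kinetic_freq=5.0,
    postural_freq=5.0,
)


@dataclass(frozen=True)
class CohortSpec:
    """Shape, seed, and between-subject variability of a synthetic cohort."""

    n_pd: int
    n_et: int
    seed: int
    duration: float = 10.0
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    amplitude_variability: float = 0.15  # lognormal sigma on each amplitude
    frequency_variability: float = 0.2  # Hz, additive, clipped to the valid band
    swap_amplitudes: bool = False  # exchange the class amplitude structures

    def __post_init__(self) -> None:
        if self.n_pd < 0 or self.n_et < 0:
            raise ParameterError("subject counts must be nonnegative")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ParameterError("duration and sampling_rate must be positive")
        if self.amplitude_variability < 0 or self.frequency_variability < 0:
            raise ParameterError("variability scales must be nonnegative")


def generate_recording(
    profile: TremorProfile,
    task: str,
    seed: int | np.random.SeedSequence,
    subject_id: str = "synthetic",
    duration: float = 10.0,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> TremorRecording:
    """One deterministic task recording for a profile.

    x-channel = voluntary component (kinetic task only)
              + amplitude-modulated sinusoid with slow phase noise
              + white noise;
    y and z are scaled-down copies of the tremor with independent noise.
    """
    validate_task(task)
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate

    amp = profile.amplitude_for(task)
    freq = profile.frequency_for(task) + rng.normal(0.0, profile.frequency_jitter_sd)
    freq = float(np.clip(freq, 3.05, 9.95))

    # slow phase wobble: integrated white noise, lightly scaled so the peak
    # frequency stays near the profile's center
    phase_noise = np.cumsum(rng.normal(0.0, 0.02, n))
    envelope = 1.0 + profile.amplitude_modulation_depth * np.sin(
        2 * np.pi * profile.amplitude_modulation_rate * t + rng.uniform(0, 2 * np.pi)
    )
    tremor = amp * envelope * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi) + phase_noise)

    x = tremor.copy()
    if task == "kinetic" and profile.voluntary_motion_amp > 0:
        x = x + profile.voluntary_motion_amp * np.sin(
            2 * np.pi * profile.voluntary_motion_freq * t + rng.uniform(0, 2 * np.pi)
        )
    x = x + rng.normal(0.0, profile.broadband_noise_sd, n)

    channels = [x]
    for gain in _CROSS_AXIS_GAINS:
        channels.append(gain * tremor + rng.normal(0.0, profile.broadband_noise_sd, n))
    samples = np.column_stack(channels)
    return TremorRecording(
        subject_id=subject_id,
        task=task,
        samples=samples,
        sampling_rate=sampling_rate,
    )


def _perturb_profile(
    base: TremorProfile, spec: CohortSpec, rng: np.random.Generator
) -> TremorProfile:
    """Draw one subject's profile around the class default."""
    amp_mults = rng.lognormal(0.0, spec.amplitude_variability, 3)
    freq_shifts = rng.normal(0.0, spec.frequency_variability, 3)
    clip = lambda f: float(np.clip(f, 3.2, 9.8))
    return replace(
        base,
        rest_amp=base.rest_amp * amp_mults[0],
        kinetic_amp=base.kinetic_amp * amp_mults[1],
        postural_amp=base.postural_amp * amp_mults[2],
        rest_freq=clip(base.rest_freq + freq_shifts[0]),
        kinetic_freq=clip(base.kinetic_freq + freq_shifts[1]),
        postural_freq=clip(base.postural_freq + freq_shifts[2]),
    )


def _swap_amplitude_structure(
    pd_profile: TremorProfile, et_profile: TremorProfile
) -> tuple[TremorProfile, TremorProfile]:
    """Give each class the other's per-task amplitude triple (sanity-check mode)."""
    amp_fields = ("rest_amp", "kinetic_amp", "postural_amp")
    pd_amps = {name: getattr(pd_profile, name) for name in amp_fields}
    et_amps = {name: getattr(et_profile, name) for name in amp_fields}
    return replace(pd_profile, **et_amps), replace(et_profile, **pd_amps)


def generate_cohort(spec: CohortSpec) -> list[CohortSubject]:
    """n_pd + n_et subjects, each with all three task recordings.

    The whole cohort is a deterministic function of ``spec.seed``.
    """
    pd_base, et_base = PD_DEFAULT_PROFILE, ET_DEFAULT_PROFILE
    if spec.swap_amplitudes:
        pd_base, et_base = _swap_amplitude_structure(pd_base, et_base)

    root = np.random.SeedSequence(spec.seed)
    n_total = spec.n_pd + spec.n_et
    subject_seeds = root.spawn(n_total)

    cohort: list[CohortSubject] = []
    for i in range(n_total):
        is_pd = i < spec.n_pd
        base = pd_base if is_pd else et_base
        label = base.label
        subject_id = f"{label.lower()}{(i if is_pd else i - spec.n_pd) + 1:03d}"
        profile_seq, *task_seqs = subject_seeds[i].spawn(1 + len(TASKS))
        profile = _perturb_profile(base, spec, np.random.default_rng(profile_seq))
        recordings = {
            task: generate_recording(
                profile,
                task,
                seed=task_seq,
                subject_id=subject_id,
                duration=spec.duration,
                sampling_rate=spec.sampling_rate,
            )
            for task, task_seq in zip(TASKS, task_seqs)
        }
        cohort.append(CohortSubject(subject_id=subject_id, label=label, recordings=recordings))
    return cohort
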