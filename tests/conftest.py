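import numpy as np
import pytest

from tremorflux import CohortSpec, TremorRecording, generate_cohort

FS = 125.0


def sine(freq: float, duration: float = 10.0, fs: float = FS, amplitude: float = 1.0,
         phase: float = 0.0) -> np.ndarray:
    t = np.arange(int(round(duration * fs))) / fs
    return amplitude * np.sin(2 * np.pi * freq * t + phase)


def make_recording(x: np.ndarray, y: np.ndarray | None = None, z: np.ndarray | None = None,
                   task: str = "resting", subject_id: str = "s1",
                   fs: float = FS) -> TremorRecording:
    if y is None:
        y = np.zeros_like(x)
    if z is None:
        z = np.zeros_like(x)
    return TremorRecording(
        subject_id=subject_id, task=task,
        samples=np.column_stack([x, y, z]), sampling_rate=fs,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Seeded 32 PD-like + 20 ET-like cohort shared across slow tests."""
    return generate_cohort(CohortSpec(n_pd=32, n_et=20, seed=42))
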