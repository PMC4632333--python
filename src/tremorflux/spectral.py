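"""Autoregressive peak-frequency characterization of tremor subsequences.

Each 10-s filtered signal is split into ten equal-sized contiguous
subsequences; each subsequence is modeled as a 7th-order AR process via
Yule-Walker (biased autocorrelation estimator, mean removed), the
parametric power spectrum is evaluated on a frequency grid, and the peak
frequency is taken as the argmax within the 3-10 Hz band. The ten peaks
are averaged into one representative frequency per recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from statsmodels.regression.linear_model import yule_walker

from .errors import DegenerateSignalError, LengthError, ParameterError

DEFAULT_SUBSEQUENCES = 10
DEFAULT_AR_ORDER = 7
DEFAULT_GRID_POINTS = 512
DEFAULT_BAND = (3.0, 10.0)


@dataclass(frozen=True)
class PeakFrequencyProfile:
    """Per-subsequence spectral peaks and their mean for one recording."""

    subsequence_peaks: tuple[float, ...]
    average_peak: float
    axis: str | None = None
    task: str | None = None

    def __post_init__(self) -> None:
        if not np.isclose(self.average_peak, np.mean(self.subsequence_peaks)):
            raise ParameterError("average_peak must equal the mean of the peaks")


def partition_equal(signal: np.ndarray, k: int = DEFAULT_SUBSEQUENCES) -> list[np.ndarray]:
    """Split a signal into ``k`` contiguous subsequences in order.

    The first ``k - 1`` pieces have length ``len(signal) // k``; any
    remainder goes to the final piece.
    """
    x = np.asarray(signal, dtype=float)
    if not (isinstance(k, (int, np.integer)) and k > 0):
        raise ParameterError("k must be a positive integer")
    if len(x) < k:
        raise LengthError(f"signal of length {len(x)} cannot be split into {k} pieces")
    base = len(x) // k
    bounds = [i * base for i in range(k)] + [len(x)]
    return [x[bounds[i] : bounds[i + 1]] for i in range(k)]


def ar_psd(
    subseq: np.ndarray,
    sampling_rate: float,
    order: int = DEFAULT_AR_ORDER,
    n_grid: int = DEFAULT_GRID_POINTS,
) -> tuple[np.ndarray, np.ndarray]:
    """Yule-Walker AR power spectrum on ``n_grid`` points over [0, Nyquist].

    Returns ``(frequencies_hz, power)`` with ``power >= 0`` everywhere.

    Raises
    ------
    ParameterError
        ``order >= len(subseq)``.
    DegenerateSignalError
        Constant subsequence (singular autocorrelation).
    """
    x = np.asarray(subseq, dtype=float)
    if x.ndim != 1:
        raise ParameterError("subsequence must be 1-D")
    if not (isinstance(order, (int, np.integer)) and order > 0):
        raise ParameterError("order must be a positive integer")
    if len(x) <= order:
        raise ParameterError(
            f"AR order {order} requires more than {order} samples, got {len(x)}"
        )
    x = x - x.mean()
    if not np.any(x):
        raise DegenerateSignalError("constant subsequence: autocorrelation is singular")

    # method="mle" selects the biased autocorrelation estimator, which keeps
    # the Yule-Walker system positive definite
    rho, sigma = yule_walker(x, order=order, method="mle", demean=False)
    freqs = np.linspace(0.0, sampling_rate / 2, n_grid)
    _, response = sps.freqz(1.0, np.concatenate(([1.0], -rho)), worN=freqs, fs=sampling_rate)
    power = (sigma**2) * np.abs(response) ** 2
    return freqs, power


def peak_frequency(
    frequencies: np.ndarray,
    power: np.ndarray,
    band: tuple[float, float] = DEFAULT_BAND,
) -> float:
    """Frequency of maximum power within ``band``; ties go to the lower frequency."""
    freqs = np.asarray(frequencies, dtype=float)
    pwr = np.asarray(power, dtype=float)
    if freqs.shape != pwr.shape:
        raise ParameterError("frequencies and power must have the same shape")
    low, high = band
    if not low < high:
        raise ParameterError(f"band must satisfy low < high, got {band}")
    mask = (freqs >= low) & (freqs <= high)
    if not mask.any():
        raise ParameterError(f"frequency grid does not intersect the band {band}")
    band_freqs = freqs[mask]
    band_power = pwr[mask]
    return float(band_freqs[np.argmax(band_power)])  # argmax: first (lowest) on ties


def average_peak_frequency(
    signal: np.ndarray,
    sampling_rate: float,
    k: int = DEFAULT_SUBSEQUENCES,
    order: int = DEFAULT_AR_ORDER,
    band: tuple[float, float] = DEFAULT_BAND,
    n_grid: int = DEFAULT_GRID_POINTS,
    axis: str | None = None,
    task: str | None = None,
) -> PeakFrequencyProfile:
    """Partition -> AR spectrum -> band-limited peak, averaged over subsequences.

    The signal is expected to be band-pass filtered already.
    """
    peaks = []
    for piece in partition_equal(signal, k):
        freqs, power = ar_psd(piece, sampling_rate, order=order, n_grid=n_grid)
        peaks.append(peak_frequency(freqs, power, band))
    return PeakFrequencyProfile(
        subsequence_peaks=tuple(peaks),
        average_peak=float(np.mean(peaks)),
        axis=axis,
        task=task,
    )
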