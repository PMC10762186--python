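"""Preprocessing and pulse detection for vocal traces.

Implements the fixed preprocessing chain applied to every recording —
natural hydrophone calls and fictive vocal-nerve volleys alike:

    lowpass (1 kHz) -> [optional rectify] -> moving average -> normalise
    -> peak detection above 25% of the segment maximum

plus response-latency measurement relative to an injection-artifact marker.
Only pulse (peak) times and amplitudes matter downstream; no spectral
analysis is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "Trace",
    "PulseSeries",
    "lowpass_filter",
    "moving_average",
    "normalize_trace",
    "detect_pulses",
    "preprocess",
    "measure_latency",
]


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled single-channel waveform.

    Parameters
    ----------
    samples : ndarray of float
        The waveform, one value per sample.
    sample_rate : float
        Sampling rate in Hz; must be positive.
    stimulus_time : float, optional
        Time (s) of an injection-artifact marker, when present.
    """

    samples: np.ndarray = field(repr=False)
    sample_rate: float
    stimulus_time: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=float)
        )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("Trace requires a 1-D sample array")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("Trace samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace extent in seconds."""
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


@dataclass(frozen=True)
class PulseSeries:
    """Detected (or ground-truth) pulse peak times and amplitudes."""

    times: np.ndarray
    amps: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.amps, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("times and amps must be 1-D and equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("pulse times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amps", a)

    def __len__(self) -> int:
        return self.times.size


def lowpass_filter(trace: Trace, cutoff: float = 1000.0, order: int = 4) -> Trace:
    """Zero-phase Butterworth lowpass.

    Applied forward and backward (``sosfiltfilt``) so peak times are not
    shifted. The default 1 kHz cutoff sits far above the pulse repetition
    rates of interest (tens to low hundreds of Hz) and strips wide-band
    noise before smoothing.
    """
    nyquist = trace.sample_rate / 2.0
    if cutoff >= nyquist:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below Nyquist ({nyquist} Hz)"
        )
    sos = sps.butter(order, cutoff, btype="low", fs=trace.sample_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, trace.samples)
    return replace(trace, samples=filtered)


def moving_average(trace: Trace, window: float = 0.001) -> Trace:
    """Centred boxcar mean of the given window length (seconds).

    Edge samples are averaged over the part of the window that overlaps the
    trace, so the output has the same length and constant traces pass
    through unchanged. The window is rounded to an odd sample count so the
    boxcar is symmetric about each sample and peaks are not shifted.
    """
    n = max(int(round(window * trace.sample_rate)), 1)
    if n % 2 == 0:
        n += 1
    if n > trace.n_samples:
        raise ValueError("smoothing window longer than trace")
    if n == 1:
        return trace
    kernel = np.ones(n)
    sums = np.convolve(trace.samples, kernel, mode="same")
    counts = np.convolve(np.ones(trace.n_samples), kernel, mode="same")
    return replace(trace, samples=sums / counts)


def normalize_trace(trace: Trace) -> Trace:
    """Scale so the maximum absolute amplitude is exactly 1."""
    peak = np.max(np.abs(trace.samples)) if trace.n_samples else 0.0
    if peak == 0.0:
        raise ValueError("cannot normalise an all-zero trace")
    return replace(trace, samples=trace.samples / peak)


def detect_pulses(
    trace: Trace,
    threshold_frac: float = 0.25,
    min_separation: float = 0.002,
) -> PulseSeries:
    """Find local maxima above ``threshold_frac`` of the segment maximum.

    Expects a preprocessed (filtered, smoothed, normalised) trace. The
    threshold reference is the global maximum of the analysed segment, so
    after normalisation ``threshold_frac`` is an absolute level. Peaks
    closer than ``min_separation`` are pruned keeping the larger, which
    suppresses double-counting of biphasic pulse ringing.

    An empty series is a valid result (all-subthreshold segment).
    """
    x = trace.samples
    if x.size == 0 or np.max(x) <= 0:
        return PulseSeries(np.empty(0), np.empty(0))
    height = threshold_frac * np.max(x)
    distance = max(int(round(min_separation * trace.sample_rate)), 1)
    # strict inequality: peaks must exceed the threshold
    idx, _ = sps.find_peaks(x, height=np.nextafter(height, np.inf), distance=distance)
    return PulseSeries(idx / trace.sample_rate, x[idx])


def preprocess(
    trace: Trace,
    cutoff: float = 1000.0,
    smooth_window: float = 0.001,
    rectify: bool = False,
) -> Trace:
    """The order-fixed chain: lowpass -> (rectify) -> smooth -> normalise.

    ``rectify`` takes the absolute value before smoothing and is the default
    treatment for fictive vocal-nerve volleys, whose spikes are biphasic;
    hydrophone traces are analysed on positive-going peaks only.
    """
    out = lowpass_filter(trace, cutoff=cutoff)
    if rectify:
        out = replace(out, samples=np.abs(out.samples))
    out = moving_average(out, window=smooth_window)
    return normalize_trace(out)


def measure_latency(pulses: PulseSeries, stimulus_time: float) -> float | None:
    """Latency from the injection artifact to the first following pulse.

    Measured from the stimulus-marker time to the first pulse strictly
    after it. Returns ``None`` (no-response sentinel) when no pulse follows
    the stimulus; a pulse exactly at the stimulus time is the artifact
    itself and is excluded.
    """
    after = pulses.times[pulses.times > stimulus_time]
    if after.size == 0:
        return None
    return float(after[0] - stimulus_time)
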