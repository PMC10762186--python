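"""Call and bout analysis on detected pulse series.

Groups pulses into calls by a maximum intra-call gap, computes the six
per-call temporal features used for embedding and statistics, summarises
bout inter-grunt-interval (IGI) structure, assigns rule-based call-type
labels, and bins call rates per minute.

Conventions:

* a call is *analysable* only if it has more than one pulse; single-pulse
  events are kept for counting/rates but excluded from features;
* instantaneous pulse repetition rate PRR_i = 1 / (t_{i+1} - t_i); the
  mean PRR is the arithmetic mean of the instantaneous rates (not pulse
  count over duration — the two differ for variable trains);
* all coefficients of variation use the sample (n-1) standard deviation;
* percent changes are relative increases from the low value (lowest peak
  amplitude; slowest inter-pulse gap, i.e. lowest instantaneous PRR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal import PulseSeries

__all__ = [
    "Call",
    "Bout",
    "CallFeatures",
    "segment_calls",
    "call_duration_total",
    "extract_features",
    "bout_igi_profile",
    "classify_call",
    "call_rate_per_min",
    "features_table",
]

#: default maximum intra-call gap (s). Grunts last hundreds of ms with
#: within-call PRR of tens of Hz, so intra-call gaps are well below 150 ms
#: while inter-grunt intervals are larger.
MAX_INTRA_CALL_GAP = 0.150


class ExcludedCallError(ValueError):
    """Raised when a single-pulse call is passed to feature extraction."""


class InsufficientBoutError(ValueError):
    """Raised when a bout has fewer than 3 calls (2 IGIs)."""


@dataclass(frozen=True)
class Call:
    """A contiguous group of pulses."""

    pulse_times: np.ndarray
    pulse_amps: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "pulse_times", np.asarray(self.pulse_times, dtype=float)
        )
        object.__setattr__(
            self, "pulse_amps", np.asarray(self.pulse_amps, dtype=float)
        )

    @property
    def n_pulses(self) -> int:
        return self.pulse_times.size

    @property
    def analysable(self) -> bool:
        """True when the call has more than one pulse."""
        return self.n_pulses >= 2

    @property
    def onset(self) -> float:
        return float(self.pulse_times[0])

    @property
    def offset(self) -> float:
        return float(self.pulse_times[-1])

    @property
    def duration(self) -> float:
        """Last minus first pulse time; 0 for single-pulse events."""
        return self.offset - self.onset

    @property
    def prr_series(self) -> np.ndarray:
        """Instantaneous PRR (Hz) per inter-pulse interval."""
        return 1.0 / np.diff(self.pulse_times)


@dataclass(frozen=True)
class Bout:
    """An ordered sequence of calls with their inter-grunt intervals.

    IGI convention: last pulse of call n to first pulse of call n+1.
    """

    calls: tuple[Call, ...]

    @property
    def igis(self) -> np.ndarray:
        ons = np.array([c.onset for c in self.calls[1:]])
        offs = np.array([c.offset for c in self.calls[:-1]])
        return ons - offs

    @property
    def n_calls(self) -> int:
        return len(self.calls)


@dataclass(frozen=True)
class CallFeatures:
    """The six per-call variables used for embedding and statistics."""

    duration: float  # s
    cv_amp: float
    mean_prr: float  # Hz
    cv_prr: float
    pct_change_amp: float  # percent, lowest -> highest peak
    pct_change_prr: float  # percent, slowest -> fastest gap

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.duration,
                self.cv_amp,
                self.mean_prr,
                self.cv_prr,
                self.pct_change_amp,
                self.pct_change_prr,
            ]
        )


FEATURE_NAMES = (
    "duration",
    "cv_amp",
    "mean_prr",
    "cv_prr",
    "pct_change_amp",
    "pct_change_prr",
)


def segment_calls(
    pulses: PulseSeries, max_intra_call_gap: float = MAX_INTRA_CALL_GAP
) -> list[Call]:
    """Partition a pulse series into calls.

    Consecutive pulses separated by at most ``max_intra_call_gap`` belong
    to the same call. The partition is exhaustive and order-preserving;
    single-pulse groups are returned (flagged non-analysable via
    ``Call.analysable``).
    """
    t, a = pulses.times, pulses.amps
    if t.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(t) > max_intra_call_gap) + 1
    return [
        Call(t[lo:hi], a[lo:hi])
        for lo, hi in zip(
            np.concatenate([[0], breaks]), np.concatenate([breaks, [t.size]])
        )
    ]


def call_duration_total(calls: list[Call]) -> float:
    """Span from the first pulse of the first call to the last pulse of
    the last call — the total-response duration convention for evoked
    fictive calling."""
    if not calls:
        raise ValueError("no calls")
    return calls[-1].offset - calls[0].onset


def extract_features(call: Call) -> CallFeatures:
    """Compute the six acoustic features of an analysable call."""
    if not call.analysable:
        raise ExcludedCallError(
            "call has fewer than two pulses; excluded from feature analysis"
        )
    prr = call.prr_series
    amps = call.pulse_amps
    mean_prr = float(np.mean(prr))
    cv_prr = float(np.std(prr, ddof=1) / mean_prr) if prr.size > 1 else 0.0
    mean_amp = float(np.mean(amps))
    cv_amp = float(np.std(amps, ddof=1) / mean_amp)
    pct_amp = 100.0 * (np.max(amps) - np.min(amps)) / np.min(amps)
    pct_prr = 100.0 * (np.max(prr) - np.min(prr)) / np.min(prr)
    return CallFeatures(
        duration=call.duration,
        cv_amp=cv_amp,
        mean_prr=mean_prr,
        cv_prr=cv_prr,
        pct_change_amp=float(pct_amp),
        pct_change_prr=float(pct_prr),
    )


def bout_igi_profile(
    bout: Bout, stable_cv_bound: float = 0.15
) -> tuple[float, float, str]:
    """Mean, SD, and trend class of a bout's inter-grunt intervals.

    ``trend`` is ``"rise_fall"`` iff the first differences of the IGI
    sequence change sign exactly once, from + to - (the hindbrain-evoked
    pattern: IGIs increase then decrease over the bout); ``"stable"`` iff
    the IGI coefficient of variation is below ``stable_cv_bound``;
    otherwise ``"other"``. rise_fall is checked first: a rising-falling
    bout with small modulation is still rise_fall.
    """
    if bout.n_calls < 3:
        raise InsufficientBoutError("need >= 3 calls (>= 2 IGIs)")
    igis = bout.igis
    mean = float(np.mean(igis))
    sd = float(np.std(igis, ddof=1))

    diffs = np.diff(igis)
    signs = np.sign(diffs[diffs != 0])
    changes = np.flatnonzero(np.diff(signs) != 0)
    if signs.size and changes.size == 1 and signs[0] > 0 and signs[-1] < 0:
        trend = "rise_fall"
    elif mean > 0 and sd / mean < stable_cv_bound:
        trend = "stable"
    else:
        trend = "other"
    return mean, sd, trend


@dataclass(frozen=True)
class ClassifierRules:
    """Thresholds for the rule-based call-type cascade."""

    grunt_max_duration: float = 0.5  # s
    variability_bound: float = 0.1  # CV bound separating growls


def classify_call(
    features: CallFeatures,
    rules: ClassifierRules = ClassifierRules(),
    has_onset_ramp: bool | None = None,
) -> str:
    """Deterministic rule cascade over (duration, cv_prr, cv_amp).

    grunt: brief. growl: long with variable PRR or amplitude. Long stable
    calls split into hum_like when an onset-ramp flag is available and
    set, buzz_like otherwise (hums show a gradual amplitude rise at onset;
    buzzes do not).
    """
    if features.duration < rules.grunt_max_duration:
        return "grunt"
    if (
        features.cv_prr > rules.variability_bound
        or features.cv_amp > rules.variability_bound
    ):
        return "growl"
    if has_onset_ramp:
        return "hum_like"
    return "buzz_like"


def call_rate_per_min(calls: list[Call], span_s: float) -> np.ndarray:
    """Integer call counts per 1-minute bin over ``[0, span_s)``.

    Calls are assigned to bins by onset time with half-open bins
    ``[k*60, (k+1)*60)``, so an onset exactly on an edge belongs to the
    later bin. Empty bins are zero-filled.
    """
    n_bins = int(np.ceil(span_s / 60.0))
    if n_bins < 1:
        raise ValueError("span must cover at least one minute bin")
    onsets = np.array([c.onset for c in calls])
    counts, _ = np.histogram(onsets, bins=np.arange(n_bins + 1) * 60.0)
    return counts.astype(int)


def features_table(
    calls: list[Call],
    animal_id: str = "a0",
    source: str = "synthetic-class",
    call_type: str | None = None,
    bout_id: int = 0,
) -> pd.DataFrame:
    """Per-call feature table (analysable calls only) with provenance.

    Columns: call_id, bout_id, animal_id, source, call_type, onset_s,
    n_pulses, and the six features.
    """
    rows = []
    for i, call in enumerate(calls):
        if not call.analysable:
            continue
        f = extract_features(call)
        row = {
            "call_id": i,
            "bout_id": bout_id,
            "animal_id": animal_id,
            "source": source,
            "call_type": call_type
            if call_type is not None
            else classify_call(f),
            "onset_s": call.onset,
            "n_pulses": call.n_pulses,
        }
        row.update(zip(FEATURE_NAMES, f.as_array()))
        rows.append(row)
    return pd.DataFrame(rows)
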