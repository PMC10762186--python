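"""Seeded synthetic vocal signals and catFISH cell populations.

Every downstream stage of the pipeline is exercised against this module's
output, which carries exact ground truth: pulse times/amplitudes for each
synthetic call, inter-grunt intervals for each bout, and the generating
joint activation probabilities for catFISH cell tables.

Call classes emulated (temporal structure only, no spectral realism):

* **grunt** — brief (hundreds of ms) pulse burst; trains of grunts form
  bouts with a characteristic inter-grunt interval (IGI).
* **growl** — long agonistic call with substantial pulse-repetition-rate
  (PRR) and amplitude variability.
* **hum** — long courtship call; amplitude ramps up gradually at onset,
  then PRR and amplitude are stable. Natural hums last up to hours; the
  generator caps duration at 60 s (desk-scale).
* **buzz** — long call with stable PRR and amplitude throughout.

Each pulse is rendered as a Ricker (Mexican-hat) wavelet whose positive
peak sits exactly at the ground-truth pulse time; only peak times matter
downstream, so pulse morphology is a free choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal import PulseSeries, Trace

__all__ = [
    "CallSpec",
    "BoutSpec",
    "CatfishSpec",
    "GRUNT",
    "GROWL",
    "HUM",
    "BUZZ",
    "synth_call",
    "synth_bout",
    "add_noise",
    "add_stimulus_artifact",
    "synth_catfish_cells",
]

HUM_DURATION_CAP = 60.0  # s; natural hums run far longer, desk-scale cap

#: amplitude at the very start of the onset ramp (hums); ends at 1.0
ONSET_RAMP_START = 0.3


@dataclass(frozen=True)
class CallSpec:
    """Generating parameters for one synthetic call.

    ``prr_cv`` and ``amp_cv`` are coefficients of variation (sd/mean) of
    the instantaneous pulse rate and of pulse amplitude about the unit
    envelope. ``onset_ramp_frac`` is the fraction of the call over which
    amplitude ramps linearly from ``ONSET_RAMP_START`` to 1 (hums).
    """

    call_type: str  # grunt | growl | hum | buzz
    duration: float  # s
    prr_mean: float  # Hz
    prr_cv: float = 0.0
    amp_cv: float = 0.0
    onset_ramp_frac: float = 0.0
    pulse_shape_width: float = 0.002  # s

    def __post_init__(self) -> None:
        if self.call_type not in ("grunt", "growl", "hum", "buzz"):
            raise ValueError(f"unknown call_type {self.call_type!r}")
        if self.duration <= 0 or self.prr_mean <= 0:
            raise ValueError("duration and prr_mean must be positive")
        if self.prr_cv < 0 or self.amp_cv < 0:
            raise ValueError("prr_cv and amp_cv must be non-negative")
        if not 0 <= self.onset_ramp_frac < 1:
            raise ValueError("onset_ramp_frac must be in [0, 1)")
        if self.pulse_shape_width <= 0:
            raise ValueError("pulse_shape_width must be positive")
        if self.duration < 2.0 / self.prr_mean:
            raise ValueError(
                "duration too short for two pulses; only calls with more "
                "than one pulse are analysable"
            )
        if self.call_type == "hum" and self.duration > HUM_DURATION_CAP:
            raise ValueError(f"hum duration capped at {HUM_DURATION_CAP} s")


@dataclass(frozen=True)
class BoutSpec:
    """A bout (train) of identical-spec calls with a given IGI profile.

    ``igi_profile``:

    * ``"stable"`` — IGIs i.i.d. around ``igi_mean`` (natural and
      midbrain-evoked grunt trains);
    * ``"rise_fall"`` — IGIs increase then decrease across the bout
      (hindbrain-evoked trains).

    The IGI convention is peak of the last pulse of call *n* to the peak of
    the first pulse of call *n* + 1.
    """

    n_calls: int
    igi_mean: float  # s
    igi_sd: float = 0.0
    igi_profile: str = "stable"
    call_spec: CallSpec | None = None

    def __post_init__(self) -> None:
        if self.n_calls < 1:
            raise ValueError("n_calls must be >= 1")
        if self.igi_mean <= 0 or self.igi_sd < 0:
            raise ValueError("igi_mean must be > 0 and igi_sd >= 0")
        if self.igi_profile not in ("stable", "rise_fall"):
            raise ValueError(f"unknown igi_profile {self.igi_profile!r}")


@dataclass(frozen=True)
class CatfishSpec:
    """Two-period bivariate-Bernoulli activation of a cell population.

    ``p1``/``p2`` are the marginal activation probabilities in behavioural
    periods 1 and 2; ``overlap`` is P(active in 2 | active in 1). A cell
    active in period 1 carries cytoplasmic (coding) label, one active in
    period 2 carries nuclear (intronic) label.
    """

    n_cells: int
    p1: float
    p2: float
    overlap: float
    zone: str = "PAGcs"

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "overlap"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        # P(2 | not 1) must be a valid probability for the joint to exist
        p_both = self.p1 * self.overlap
        if self.p1 < 1:
            q = (self.p2 - p_both) / (1 - self.p1)
            if not -1e-12 <= q <= 1 + 1e-12:
                raise ValueError(
                    "(p1, p2, overlap) admit no valid joint distribution"
                )
        elif abs(self.p2 - self.overlap) > 1e-12:
            raise ValueError("with p1=1, p2 must equal overlap")

    @property
    def expected_index(self) -> float:
        """Expected reactivation index, percent: 100·P(active1 | active2)."""
        if self.p2 == 0:
            return float("nan")
        return 100.0 * self.p1 * self.overlap / self.p2


# Convenience default specs for the four call classes. PRR and CV values
# are generator choices, not measured values: the source recordings are
# described only qualitatively (grunts brief and broadband; growls with
# variable PRR/AMP; hums and buzzes long and stable).
GRUNT = CallSpec("grunt", duration=0.2, prr_mean=100.0, prr_cv=0.05, amp_cv=0.10)
GROWL = CallSpec("growl", duration=3.0, prr_mean=80.0, prr_cv=0.30, amp_cv=0.30)
HUM = CallSpec(
    "hum", duration=10.0, prr_mean=100.0, prr_cv=0.02, amp_cv=0.02,
    onset_ramp_frac=0.1,
)
BUZZ = CallSpec("buzz", duration=5.0, prr_mean=120.0, prr_cv=0.02, amp_cv=0.02)


def _draw_pulse_times(spec: CallSpec, rng: np.random.Generator) -> np.ndarray:
    """Pulse times on [0, duration] with inter-pulse-interval CV = prr_cv."""
    mean_ipi = 1.0 / spec.prr_mean
    times = [0.0]
    while True:
        if spec.prr_cv == 0:
            ipi = mean_ipi
        else:
            ipi = rng.normal(mean_ipi, spec.prr_cv * mean_ipi)
            ipi = max(ipi, 0.1 * mean_ipi)  # keep intervals positive
        t = times[-1] + ipi
        if t > spec.duration + 1e-12:
            break
        times.append(t)
    return np.asarray(times)


def _envelope(spec: CallSpec, times: np.ndarray) -> np.ndarray:
    """Unit amplitude envelope with optional linear onset ramp."""
    env = np.ones_like(times)
    ramp_len = spec.onset_ramp_frac * spec.duration
    if ramp_len > 0:
        in_ramp = times < ramp_len
        env[in_ramp] = ONSET_RAMP_START + (1 - ONSET_RAMP_START) * (
            times[in_ramp] / ramp_len
        )
    return env


def _ricker(t: np.ndarray, width: float) -> np.ndarray:
    # Mexican-hat wavelet, unit peak at t = 0; `width` spans the central lobe
    a = width / 4.0
    u = (t / a) ** 2
    return (1 - u) * np.exp(-u / 2)


def _render(
    pulse_times: np.ndarray,
    pulse_amps: np.ndarray,
    sample_rate: float,
    width: float,
    pad: float,
) -> np.ndarray:
    n = int(round((pulse_times[-1] + 2 * pad) * sample_rate)) + 1
    samples = np.zeros(n)
    half = int(np.ceil(2 * width * sample_rate))
    support = np.arange(-half, half + 1)
    shape = _ricker(support / sample_rate, width)
    for t, a in zip(pulse_times, pulse_amps):
        centre = int(round((t + pad) * sample_rate))
        lo, hi = centre - half, centre + half + 1
        s0 = max(0, -lo)
        s1 = shape.size - max(0, hi - n)
        samples[max(lo, 0) : min(hi, n)] += a * shape[s0:s1]
    return samples


def synth_call(
    spec: CallSpec,
    sample_rate: float = 10_000.0,
    seed: int = 0,
    pad: float = 0.05,
    t_offset: float = 0.0,
) -> tuple[Trace, PulseSeries]:
    """Render one synthetic call and return it with its ground truth.

    The trace starts ``pad`` seconds before the first pulse; ground-truth
    times are trace-relative (first pulse at ``pad + t_offset``). Identical
    ``(spec, sample_rate, seed)`` give bit-identical output.
    """
    if sample_rate < 20 * spec.prr_mean:
        raise ValueError(
            f"sample_rate {sample_rate} Hz too low; need >= 20 x prr_mean"
        )
    rng = np.random.default_rng(seed)
    rel_times = _draw_pulse_times(spec, rng)
    amps = _envelope(spec, rel_times)
    if spec.amp_cv > 0:
        amps = amps * np.clip(
            rng.normal(1.0, spec.amp_cv, rel_times.size), 0.05, None
        )
    samples = _render(rel_times, amps, sample_rate, spec.pulse_shape_width, pad)
    trace = Trace(samples, sample_rate)
    truth = PulseSeries(rel_times + pad + t_offset, amps)
    return trace, truth


def synth_bout(
    spec: BoutSpec,
    sample_rate: float = 10_000.0,
    seed: int = 0,
    pad: float = 0.05,
) -> tuple[Trace, list[PulseSeries], np.ndarray]:
    """Render a bout of calls separated by the spec's IGI profile.

    Returns the rendered trace, one ground-truth PulseSeries per call
    (times trace-relative), and the ground-truth IGI array of length
    ``n_calls - 1``.
    """
    call_spec = spec.call_spec if spec.call_spec is not None else GRUNT
    rng = np.random.default_rng(seed)

    n_igis = spec.n_calls - 1
    if n_igis == 0:
        igis = np.empty(0)
    elif spec.igi_profile == "stable":
        igis = rng.normal(spec.igi_mean, spec.igi_sd, n_igis)
        igis = np.clip(igis, 0.1 * spec.igi_mean, None)
    else:  # rise_fall: unimodal triangular profile, peak mid-bout
        # Modulation spans ±50% of the mean so the single sign change in
        # the IGI first differences survives additive jitter.
        k = np.arange(n_igis)
        peak = (n_igis - 1) / 2.0
        tri = 1.0 - np.abs(k - peak) / max(peak, 1.0)
        igis = spec.igi_mean * (0.5 + 1.0 * tri)
        if spec.igi_sd > 0:
            igis = igis + rng.normal(0.0, spec.igi_sd, n_igis)
            igis = np.clip(igis, 0.05 * spec.igi_mean, None)

    per_call: list[tuple[np.ndarray, np.ndarray]] = []
    onset = 0.0  # first-pulse time of current call, bout-relative
    truths: list[PulseSeries] = []
    for i in range(spec.n_calls):
        call_rng = np.random.default_rng(rng.integers(2**31))
        rel = _draw_pulse_times(call_spec, call_rng)
        amps = _envelope(call_spec, rel)
        if call_spec.amp_cv > 0:
            amps = amps * np.clip(
                call_rng.normal(1.0, call_spec.amp_cv, rel.size), 0.05, None
            )
        per_call.append((rel + onset, amps))
        if i < n_igis:
            onset = onset + rel[-1] + igis[i]

    all_times = np.concatenate([t for t, _ in per_call])
    all_amps = np.concatenate([a for _, a in per_call])
    samples = _render(
        all_times, all_amps, sample_rate, call_spec.pulse_shape_width, pad
    )
    trace = Trace(samples, sample_rate)
    truths = [PulseSeries(t + pad, a) for t, a in per_call]
    return trace, truths, igis


def add_noise(trace: Trace, snr_db: float, seed: int = 0) -> Trace:
    """Add zero-mean Gaussian white noise at the requested SNR.

    ``snr_db`` is the ratio of signal RMS to noise RMS in dB;
    ``snr_db=inf`` is the no-noise sentinel (returns the input). The noise
    is white by design: the downstream 1 kHz lowpass makes the exact noise
    spectrum immaterial for peak detection at the SNRs tested.
    """
    if trace.n_samples == 0:
        raise ValueError("cannot add noise to an empty trace")
    if not np.isfinite(snr_db):
        if snr_db > 0:
            return trace
        raise ValueError("snr_db must be finite or +inf")
    signal_rms = float(np.sqrt(np.mean(trace.samples**2)))
    noise_rms = signal_rms / 10 ** (snr_db / 20.0)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_rms, trace.n_samples)
    return Trace(trace.samples + noise, trace.sample_rate, trace.stimulus_time)


def add_stimulus_artifact(
    trace: Trace, stimulus_time: float, amplitude: float = 5.0
) -> Trace:
    """Insert a single large-amplitude artifact sample at ``stimulus_time``.

    Mimics the mechanical artifact created by the first injection pulse,
    used as the zero point for latency measurement.
    """
    idx = int(round(stimulus_time * trace.sample_rate))
    if not 0 <= idx < trace.n_samples:
        raise ValueError("stimulus_time outside trace extent")
    samples = trace.samples.copy()
    samples[idx] += amplitude
    return Trace(samples, trace.sample_rate, stimulus_time)


def synth_feature_table(
    spec: CallSpec,
    n_calls: int,
    n_animals: int = 3,
    seed: int = 0,
    source: str = "synthetic-class",
    animal_sd: float = 0.1,
    duration_scale: float = 1.0,
):
    """Seeded per-call feature table for one call class.

    Draws ground-truth pulse series (no waveform rendering — features are
    pure functions of pulse times/amplitudes) and featurises them. Calls
    are assigned round-robin to ``n_animals`` animals; each animal carries
    a lognormal multiplicative effect of scale ``animal_sd`` on call
    duration, giving the between-animal variance the mixed-model harness
    needs. ``duration_scale`` applies a group-level duration effect.
    """
    from dataclasses import replace as _replace

    import pandas as pd

    from .calls import Call, extract_features, FEATURE_NAMES

    rng = np.random.default_rng(seed)
    animal_mult = np.exp(rng.normal(0.0, animal_sd, n_animals))
    rows = []
    for i in range(n_calls):
        animal = i % n_animals
        dur = spec.duration * duration_scale * animal_mult[animal]
        call_spec = _replace(spec, duration=dur)
        call_rng = np.random.default_rng(rng.integers(2**31))
        times = _draw_pulse_times(call_spec, call_rng)
        amps = _envelope(call_spec, times)
        if call_spec.amp_cv > 0:
            amps = amps * np.clip(
                call_rng.normal(1.0, call_spec.amp_cv, times.size), 0.05, None
            )
        f = extract_features(Call(times, amps))
        row = {
            "call_id": i,
            "bout_id": 0,
            "animal_id": f"{source}_a{animal}",
            "source": source,
            "call_type": spec.call_type,
            "onset_s": 0.0,
            "n_pulses": times.size,
        }
        row.update(zip(FEATURE_NAMES, f.as_array()))
        rows.append(row)
    return pd.DataFrame(rows)


def synth_catfish_cells(spec: CatfishSpec, seed: int = 0):
    """Draw a per-cell two-period activation table.

    Returns a pandas DataFrame with columns ``cell_id``, ``zone``,
    ``nuclear`` (0/1, active in period 2) and ``cytoplasmic`` (0/1, active
    in period 1), following the catFISH labelling logic: nuclear intronic
    signal marks recent (period-2) transcription, cytoplasmic coding
    signal marks earlier (period-1) transcription.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    active1 = rng.random(spec.n_cells) < spec.p1
    if spec.p1 < 1:
        q = (spec.p2 - spec.p1 * spec.overlap) / (1 - spec.p1)
        q = min(max(q, 0.0), 1.0)
    else:
        q = 0.0
    p_active2 = np.where(active1, spec.overlap, q)
    active2 = rng.random(spec.n_cells) < p_active2
    return pd.DataFrame(
        {
            "cell_id": np.arange(spec.n_cells),
            "zone": spec.zone,
            "nuclear": active2.astype(int),
            "cytoplasmic": active1.astype(int),
        }
    )
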