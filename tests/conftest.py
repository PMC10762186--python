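import numpy as np
import pytest

import pagvocal as pv

FS = 10_000.0


@pytest.fixture(scope="session")
def grunt_train():
    """Noiseless 6-call x 20-pulse grunt train with ground truth.

    duration 0.19 s at 100 Hz with zero rate CV gives exactly 20 pulses
    per call (0, 0.01, ..., 0.19 s); unit amplitudes.
    """
    spec = pv.BoutSpec(
        n_calls=6,
        igi_mean=0.5,
        igi_sd=0.0,
        igi_profile="stable",
        call_spec=pv.CallSpec("grunt", duration=0.19, prr_mean=100.0),
    )
    trace, truths, igis = pv.synth_bout(spec, FS, seed=1)
    return spec, trace, truths, igis


@pytest.fixture(scope="session")
def detected_grunt_train(grunt_train):
    _, trace, _, _ = grunt_train
    return pv.detect_pulses(pv.preprocess(trace))


@pytest.fixture()
def alternating_train():
    """Pulse train with amplitudes alternating 1.0 / 0.2 (20 ms apart)."""
    n_pulses, ipi = 10, 0.02
    times = np.arange(n_pulses) * ipi
    amps = np.where(np.arange(n_pulses) % 2 == 0, 1.0, 0.2)
    from pagvocal.synth import _render

    samples = _render(times, amps, FS, 0.002, pad=0.05)
    return pv.Trace(samples, FS), times, amps
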