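import numpy as np
import pytest

import nanokin as nk


@pytest.fixture
def two_state():
    """Reference reversible-binding scheme: I_p=120 pA, I_b=60 pA (dI=-60),
    k_on = 1e4 /M/s, k_off = 5 /s (K_b = 2000 /M)."""
    return nk.two_state_scheme(120.0, 60.0, 1e4, 5.0)


@pytest.fixture
def quiet_noise():
    return nk.NoiseModel()


@pytest.fixture
def snr10_noise():
    """White baseline noise giving |dI|/sd = 10 for the reference scheme."""
    return nk.NoiseModel(baseline_sd=6.0)


def make_acq(duration, corner=1000.0, fs=25_000.0, order=4):
    return nk.AcquisitionSettings(
        sampling_rate=fs, analog_corner=corner, analog_filter_order=order, duration=duration
    )


@pytest.fixture
def acq_factory():
    return make_acq


@pytest.fixture
def snr10_trace(two_state, snr10_noise):
    """60 s filtered trace at 1 mM with ground truth (SNR 10)."""
    return nk.simulate_trace(two_state, 1e-3, snr10_noise, make_acq(60.0), seed=11)


@pytest.fixture
def calibration_baseline(two_state, snr10_noise):
    """Baseline from a short analyte-free recording (static protocol)."""
    cal = nk.simulate_trace(two_state, 0.0, snr10_noise, make_acq(5.0), seed=12)
    return nk.estimate_baseline(cal)


def match_boundaries(detected_starts, truth_starts, fs):
    """Per-truth-event boundary error in samples (nearest detected start)."""
    errs = []
    for t0 in truth_starts:
        j = int(np.argmin(np.abs(detected_starts - t0)))
        errs.append((detected_starts[j] - t0) * fs)
    return np.array(errs)
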