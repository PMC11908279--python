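import numpy as np
import pytest

import ecgkit as ek


@pytest.fixture(scope="session")
def clean_record():
    """Default 12-lead, 10 s, 500 Hz pseudo-ECG."""
    return ek.generate_record(ek.SynthConfig(rng_seed=42))


@pytest.fixture(scope="session")
def small_record():
    """Light 2-lead, 100 Hz record for perturbation-heavy tests."""
    return ek.generate_record(ek.SynthConfig(fs=100, duration_s=10, n_leads=2, rng_seed=7))


def band_power(record, lo=2.0, hi=30.0):
    """Total Welch power per lead inside [lo, hi] Hz."""
    spec = ek.power_spectrum(record)
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    return spec.power[:, mask].sum(axis=1)


@pytest.fixture
def contaminated_pair():
    """(clean, contaminated) pair: half-scale + strong wander + 50 Hz tone."""

    def make(seed):
        clean = ek.generate_record(ek.SynthConfig(rng_seed=seed))
        rms = clean.waveform.std()
        contam = clean.copy(waveform=0.5 * clean.waveform)
        contam = ek.inject_baseline_wander(contam, 0.3, 100 * rms)
        contam = ek.inject_mains(contam, 50.0, 1, 0.5)
        return clean, contam

    return make
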