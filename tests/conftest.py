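import numpy as np
import pytest
from hypothesis import settings

import qctscreen as q

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def two_vertebra_clean():
    """Noise-free two-vertebra volume, densities 100/100, identity HU model."""
    specs = [
        q.VertebraSpec(level="L1", trabecular_density=100.0),
        q.VertebraSpec(level="L2", trabecular_density=100.0),
    ]
    return q.generate_vertebra_volume(specs, noise_sigma=0.0, seed=11)


@pytest.fixture(scope="session")
def two_vertebra_noisy():
    """Two-vertebra volume with sigma = 10 HU noise, densities 60/160."""
    specs = [
        q.VertebraSpec(level="L1", trabecular_density=60.0),
        q.VertebraSpec(level="L2", trabecular_density=160.0),
    ]
    return q.generate_vertebra_volume(specs, noise_sigma=10.0, seed=12)


@pytest.fixture(scope="session")
def esp_clean():
    return q.generate_esp_volume(noise_sigma=0.0, n_slices=20, seed=21)


@pytest.fixture(scope="session")
def esp_noisy():
    return q.generate_esp_volume(noise_sigma=5.0, n_slices=20, seed=22)


@pytest.fixture(scope="session")
def identity_model(esp_clean):
    """Conversion model calibrated on a noise-free identity phantom."""
    samples = q.extract_insert_hu(esp_clean)
    candidates, _ = q.fit_conversion(samples)
    model = q.select_model(candidates)
    assert not isinstance(model, q.RecalibrationNeeded)
    return model


def trimmed_median_oracle(values, trim_fraction, tail="symmetric"):
    """Independent sort-and-trim oracle for the representative HU."""
    arr = sorted(float(v) for v in np.asarray(values).ravel())
    n = len(arr)
    if tail == "symmetric":
        k = int(np.floor(trim_fraction / 2.0 * n))
        kept = arr[k: n - k] if k else arr
    else:
        k = int(np.floor(trim_fraction * n))
        kept = arr[: n - k] if k else arr
    m = len(kept)
    if m % 2:
        return kept[m // 2], n, m
    return (kept[m // 2 - 1] + kept[m // 2]) / 2.0, n, m
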