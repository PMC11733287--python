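import numpy as np
import pytest

from iaprec.synth import SynthConfig, generate_dataset

FS = 5000.0


@pytest.fixture(scope="session")
def small_dataset():
    """A small diverse synthetic dataset shared across test modules."""
    return generate_dataset(SynthConfig(n_pairs=60, seed=7))


@pytest.fixture(scope="session")
def clean_config():
    """Near-noiseless configuration (drift off, very high S/N)."""
    return SynthConfig(
        n_pairs=30,
        seed=3,
        drift_amp=0.0,
        snr_db_range=(115.0, 120.0),
        eap_snr_range=(500.0, 600.0),
    )


def make_ap_window(
    width_s: float = 0.4,
    fs: float = FS,
    n: int = 8000,
    peak: int = 1000,
    shape: str = "rect",
) -> np.ndarray:
    """Simple analytic AP-like windows with known widths."""
    v = np.zeros(n)
    w = int(round(width_s * fs))
    if shape == "rect":
        v[peak : peak + w] = 1.0
    elif shape == "triangle":
        half = w // 2
        v[peak - half : peak] = np.linspace(0, 1, half, endpoint=False)
        v[peak : peak + half + 1] = np.linspace(1, 0, half + 1)
    else:
        raise ValueError(shape)
    return v
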