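import struct

import numpy as np
import pytest

from cpcca.io import DEFAULT_CHANNELS
from cpcca.simulate import SimConfig, generate_dataset, moderate_snr_config

PAPER_FREQS = (6.67, 7.5, 8.57, 10.0, 12.0)


@pytest.fixture(scope="session")
def default_dataset():
    """50-epoch dataset at the default recording regime."""
    return generate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def moderate_dataset():
    """Dataset at the stated moderate-noise comparison condition."""
    return generate_dataset(moderate_snr_config(21))


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small, fast dataset: 3 trials per class."""
    return generate_dataset(SimConfig(seed=2, n_trials_per_class=3))


@pytest.fixture()
def channels():
    return DEFAULT_CHANNELS


def write_minimal_edf(path, data, fs, labels):
    """Write a minimal plain-EDF file (16-bit), for exercising the reader.

    Synthetic test artifact: one data record holding the whole recording.
    """
    data = np.asarray(data, dtype=float)
    ns, n = data.shape
    phys_min, phys_max = -500.0, 500.0
    dig_min, dig_max = -32768, 32767
    seconds = n / fs

    def pad(s, width):
        return s[:width].ljust(width).encode("ascii")

    hdr = b"".join(
        [
            pad("0", 8),
            pad("X", 80),
            pad("X", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(str(256 * (ns + 1)), 8),
            pad("", 44),
            pad("1", 8),
            pad(f"{seconds:g}", 8),
            pad(str(ns), 4),
        ]
    )
    fields = [
        [pad(lab, 16) for lab in labels],
        [pad("", 80)] * ns,
        [pad("uV", 8)] * ns,
        [pad(f"{phys_min:g}", 8)] * ns,
        [pad(f"{phys_max:g}", 8)] * ns,
        [pad(str(dig_min), 8)] * ns,
        [pad(str(dig_max), 8)] * ns,
        [pad("", 80)] * ns,
        [pad(str(n), 8)] * ns,
        [pad("", 32)] * ns,
    ]
    body = b"".join(b"".join(col) for col in fields)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.clip(np.round((data - phys_min) / gain) + dig_min, dig_min, dig_max)
    samples = b"".join(
        struct.pack(f"<{n}h", *digital[c].astype(int)) for c in range(ns)
    )
    with open(path, "wb") as fh:
        fh.write(hdr + body + samples)
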