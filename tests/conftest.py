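import numpy as np
import pytest

from rna6ma import RnaWindow, generate_synthetic, planted_profile


def make_window(sequence: str, label: int = 1, wid: str = "w") -> RnaWindow:
    return RnaWindow(wid, sequence, label)


@pytest.fixture
def homopolymer_window() -> RnaWindow:
    return make_window("A" * 41)


@pytest.fixture
def small_dataset():
    """60 windows with a deterministic planted motif: perfectly separable."""
    return generate_synthetic(30, 30, bias=planted_profile(1.0), seed=11)


@pytest.fixture
def random_windows():
    """20 seeded random valid windows (uniform background, both labels)."""
    rng = np.random.default_rng(202)
    out = []
    for i in range(20):
        seq = "".join(rng.choice(list("ACGU"), size=41))
        seq = seq[:20] + "A" + seq[21:]
        out.append(RnaWindow(f"r{i}", seq, int(i % 2)))
    return out
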