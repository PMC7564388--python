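import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from eegarousal.preproc.recording import SMALL_MONTAGE
from eegarousal.synthetic import SynthesisConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)


@pytest.fixture
def fast_config():
    """Reduced montage + 200 Hz: fast but preserves every signal path."""
    return SynthesisConfig(sampling_rate=200, channel_names=SMALL_MONTAGE)


def random_stage_sequences(seed: int, n: int):
    """Mixed-flavour random label sequences for oracle-equivalence tests."""
    from eegarousal.stages import LABELS

    rng = np.random.default_rng(seed)
    out = []
    for trial in range(n):
        style = trial % 4
        if style == 0:
            probs = rng.dirichlet(np.ones(len(LABELS)))
            labels = list(rng.choice(LABELS, size=1200, p=probs))
        elif style == 1:
            labels = list(rng.choice(["0", "A1", "A2", "A3"], size=1200))
        elif style == 2:
            labels = list(
                rng.choice(["A1", "B1", "B2/3"], size=1200, p=[0.85, 0.1, 0.05])
            )
        else:
            labels = ["A1"] * 1200
            for _ in range(int(rng.integers(0, 5))):
                pos = int(rng.integers(0, 1200))
                labels[pos] = str(rng.choice(["C", "B1", "ARTIFACT"]))
        out.append(labels)
    return out
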