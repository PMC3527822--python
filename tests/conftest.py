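import numpy as np
import pytest

import cortexstate as cs
from cortexstate.config import anesthetized


@pytest.fixture(scope="session")
def dataset():
    """Default anesthetized dataset: 600 s, full 16-channel probe."""
    cfg = anesthetized(seed=7, duration_s=600.0, lfp_fs=250.0)
    return cs.generate_dataset(cfg)


@pytest.fixture(scope="session")
def segmented(dataset):
    """Power series + state segmentation (with up/down) of `dataset`."""
    ps = cs.compute_low_freq_power(dataset.recording)
    seg = cs.classify_states(ps)
    cs.detect_updown(dataset.unit_table, seg)
    return ps, seg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def seg_from_labels(labels, bin_s=1.0):
    """StateSegmentation built directly from per-bin labels (ground truth)."""
    from cortexstate.datatypes import StateSegmentation
    labels = np.asarray(labels, dtype=object)
    epochs = []
    start = 0
    for i in range(1, labels.size + 1):
        if i == labels.size or labels[i] != labels[start]:
            epochs.append((labels[start], start * bin_s, i * bin_s))
            start = i
    return StateSegmentation(bin_start_s=np.arange(labels.size) * bin_s,
                             bin_labels=labels, epochs=epochs, bin_s=bin_s)
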