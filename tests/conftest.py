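import numpy as np
import pytest

from dabis.data import DatasetManifest, LabeledSample


@pytest.fixture
def rng():
    return np.random.default_rng(1)


def random_binary_scores(rng, n=30):
    """Random scores/labels with both classes present and some ties."""
    scores = np.round(rng.normal(size=n), 1)  # rounding induces ties
    labels = rng.integers(0, 2, size=n)
    labels[0], labels[1] = 0, 1
    return scores, labels


def brute_force_auroc(scores, labels):
    """Pair-counting oracle: P(random positive ranked above random
    negative), ties counted 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return (greater + 0.5 * equal) / (len(pos) * len(neg))


def inline_manifest(rng, n_patients=30, shape=(1, 6, 6), modality="image2d",
                    separation=2.0, prefix="p"):
    """Tiny two-class manifest with inline arrays: class 1 shifted by
    ``separation`` in one fixed corner block (structural, equal-area)."""
    records = []
    for c in range(2):
        for p in range(n_patients):
            arr = rng.normal(0, 1, shape)
            block = max(1, shape[1] // 3)
            if len(shape) == 3:
                if c == 0:
                    arr[:, :block, :] += separation
                else:
                    arr[:, :, :block] += separation
            else:
                if c == 0:
                    arr[:, :block] += separation
                else:
                    arr[:, -block:] += separation
            pid = f"{prefix}{c}_{p}"
            records.append(LabeledSample(f"{pid}_s0", pid, f"class{c}",
                                         site_id="s", data=arr))
    return DatasetManifest(records, modality, ("class0", "class1"), "toy")
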