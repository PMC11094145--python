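"""Structure-destroying shuffle transforms.

Randomly permuting every element of a sample along its structured
(spatial/temporal) axes destroys structural and semantic features —
anatomy in an X-ray, QRS complexes in an ECG, word order in a note —
while leaving the per-channel value histogram exactly intact.  A model
trained and evaluated on shuffled data can therefore only exploit
histogram-level signal, which is the fingerprint of acquisition bias.

Channels are never shuffled across (leads of an ECG carry independent
acquisition biases); by default one flat permutation is drawn per sample
and applied identically to every channel.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
import zlib
from typing import Optional, Sequence, Union

import numpy as np

#: epoch index reserved for the single fixed shuffle of evaluation splits
EVAL_EPOCH = 2 ** 30


@dataclasses.dataclass(frozen=True)
class ShuffleSpec:
    """How to shuffle one sample.

    Parameters
    ----------
    axes
        Structured axes of the sample (axis 0 is the channel axis and can
        never be permuted).  ``None`` means all structured axes, permuted
        jointly as one flattened block.
    channel_policy
        ``"shared"``: one permutation per sample applied to every channel.
        ``"independent"``: a fresh permutation per channel.
    reshuffle_each_epoch
        Draw new permutations every training epoch.
    base_seed
        Root of the permutation seed stream; the permutation for a sample
        is keyed by (base_seed, epoch, sample_id) so reordering the dataset
        does not silently change permutations.
    """

    axes: Optional[tuple] = None
    channel_policy: str = "shared"
    reshuffle_each_epoch: bool = True
    base_seed: int = 0

    def __post_init__(self):
        if self.channel_policy not in ("shared", "independent"):
            raise ValueError("channel_policy must be 'shared' or 'independent'")
        if self.axes is not None:
            axes = tuple(int(a) for a in self.axes)
            if len(axes) == 0:
                raise ValueError("at least one structured axis must be selected")
            if 0 in axes:
                raise ValueError("the channel axis (0) cannot be permuted")
            object.__setattr__(self, "axes", axes)


def sample_rng(base_seed: int, epoch: int, sample_id) -> np.random.Generator:
    """Permutation RNG keyed by (base seed, epoch, sample id)."""
    key = zlib.crc32(str(sample_id).encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, int(epoch), key]))


def shuffle_array_sample(sample: np.ndarray, spec: ShuffleSpec,
                         rng: np.random.Generator) -> np.ndarray:
    """Permute one ``channels x structured-axes`` array.

    The selected structured axes are flattened jointly and permuted with a
    single random permutation; under the shared channel policy the same
    permutation is applied to every channel of the sample.
    """
    sample = np.asarray(sample)
    if sample.ndim < 2:
        raise ValueError("sample must have a channel axis plus >= 1 structured axis")
    if sample.size == 0:
        raise ValueError("cannot shuffle an empty array")
    axes = spec.axes if spec.axes is not None else tuple(range(1, sample.ndim))
    if any(a < 1 or a >= sample.ndim for a in axes):
        raise ValueError(f"axes {axes} out of range for sample of ndim {sample.ndim}")
    unselected = [a for a in range(1, sample.ndim) if a not in axes]
    order = [0] + unselected + list(axes)
    moved = np.transpose(sample, order)
    lead_shape = moved.shape[: 1 + len(unselected)]
    m = int(np.prod(moved.shape[1 + len(unselected):]))
    flat = moved.reshape(lead_shape + (m,))
    out = np.empty_like(flat)
    if spec.channel_policy == "shared":
        perm = rng.permutation(m)
        out[...] = flat[..., perm]
    else:
        for ch in range(flat.shape[0]):
            perm = rng.permutation(m)
            out[ch] = flat[ch][..., perm]
    restored = out.reshape(moved.shape)
    return np.transpose(restored, np.argsort(order))


def shuffle_batch(batch: Union[np.ndarray, Sequence[np.ndarray]],
                  spec: ShuffleSpec, rng: np.random.Generator):
    """Shuffle each sample of a batch with an independently drawn permutation.

    Labels are not part of the batch and are untouched by construction.
    """
    samples = list(batch)
    if len(samples) == 0:
        raise ValueError("batch must be non-empty")
    shapes = {np.asarray(s).shape for s in samples}
    if len(shapes) > 1:
        raise ValueError(f"heterogeneous sample shapes within batch: {sorted(shapes)}")
    shuffled = [shuffle_array_sample(np.asarray(s), spec, rng) for s in samples]
    if isinstance(batch, np.ndarray):
        return np.stack(shuffled)
    return shuffled


def shuffle_text(document: str, rng: np.random.Generator) -> str:
    """Permute word order and, within each word, letter order.

    Words are whitespace-delimited; punctuation travels with its word.
    Whitespace runs stay exactly in place, so the character multiset and
    the whitespace count of the document are preserved.  An empty document
    (no words) is returned unchanged with a warning.
    """
    parts = re.split(r"(\s+)", document)
    word_slots = [i for i, p in enumerate(parts) if p and not p.isspace()]
    if not word_slots:
        warnings.warn("shuffle_text called on a document with no words")
        return document
    words = [parts[i] for i in word_slots]
    order = rng.permutation(len(words))
    for slot, j in zip(word_slots, order):
        chars = list(words[j])
        perm = rng.permutation(len(chars))
        parts[slot] = "".join(chars[k] for k in perm)
    return "".join(parts)


def shuffle_sample(data, spec: ShuffleSpec, rng: np.random.Generator):
    """Dispatch on sample type: arrays are permuted, strings word/letter-shuffled."""
    if isinstance(data, str):
        return shuffle_text(data, rng)
    return shuffle_array_sample(data, spec, rng)


def epoch_view(samples: Sequence, sample_ids: Sequence, spec: ShuffleSpec,
               epoch: int) -> list:
    """Shuffled view of a dataset for one epoch.

    Permutations derive from ``(spec.base_seed, epoch, sample_id)``: the
    same epoch always reproduces the same view, different epochs draw
    different permutations.
    """
    if not spec.reshuffle_each_epoch and epoch != EVAL_EPOCH and epoch != 0:
        raise ValueError(
            "epoch_view beyond epoch 0 requires reshuffle_each_epoch=True")
    if len(samples) != len(sample_ids):
        raise ValueError("samples and sample_ids must align")
    out = []
    for data, sid in zip(samples, sample_ids):
        rng = sample_rng(spec.base_seed, epoch, sid)
        out.append(shuffle_sample(data, spec, rng))
    return out
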