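"""Training harness: patient-level splits, early stopping on validation
AUROC, and the end-to-end external-accuracy estimation driver.

The driver runs the same supervised training twice on one dataset — once
on the plain data (``P_Source``) and once on per-epoch shuffled data
(``P_DABIS``) — then reports the calibrated external estimate
``P_Est = P_Source - P_DABIS + O_bar`` with its ROC-curve analogue.
All splitting happens at the patient level so no patient ever appears in
two splits.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

from . import calibration, shuffle as shuffle_mod
from .calibration import BiasAuditResult, estimate_with_ci
from .data import DatasetManifest, LabeledSample, encode_text
from .roc_metrics import (AurocEstimate, DegenerateLabelsError, ScoreSet,
                          bootstrap_ci, mean_roc_curve, multiclass_auroc)
from .shuffle import EVAL_EPOCH, ShuffleSpec, epoch_view

SPLITS = ("train", "val", "test")


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Supervised-training hyperparameters.

    Adam with betas (0.9, 0.999); the learning rate is divided by
    ``lr_reduction`` whenever validation AUROC has not improved for
    ``floor(max_epochs / 3)`` consecutive epochs, and training stops once
    the no-improvement counter reaches ``patience``.
    """

    max_epochs: int = 20
    patience: int = 5
    lr: float = 1e-3
    lr_reduction: float = 10.0
    betas: tuple = (0.9, 0.999)
    batch_size: int = 32
    seed: int = 0
    ratios: tuple = (0.7, 0.1, 0.2)
    n_bootstrap: int = 1000
    text_max_len: int = 256

    def __post_init__(self):
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclasses.dataclass
class SplitAssignment:
    """Per-patient train/val/test assignment."""

    assignment: Dict[str, str]

    def __post_init__(self):
        bad = set(self.assignment.values()) - set(SPLITS)
        if bad:
            raise ValueError(f"unknown split names {bad}")

    def split_of(self, patient_id: str) -> str:
        return self.assignment[patient_id]

    def indices(self, manifest: DatasetManifest, split: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(manifest.records)
                         if self.assignment[r.patient_id] == split], dtype=int)


def make_splits(manifest: DatasetManifest, ratios: Sequence[float] = (0.7, 0.1, 0.2),
                seed: int = 0) -> SplitAssignment:
    """Patient-level split, deterministic under ``seed``.

    Patients are grouped before assignment so all samples of a patient
    land in one split; proportions are within one patient of the
    requested ratios.  If any class is missing from any split the draw is
    retried with a derived seed, up to 20 times.
    """
    ratios = tuple(ratios)
    if len(ratios) != len(SPLITS) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must be (train, val, test) summing to 1")
    patients = sorted({r.patient_id for r in manifest.records})
    if len(patients) < 3:
        raise ValueError("need at least 3 patients to split")
    labels_by_patient: Dict[str, set] = {}
    for r in manifest.records:
        labels_by_patient.setdefault(r.patient_id, set()).add(r.label)
    seeds = np.random.SeedSequence(seed).spawn(20)
    for attempt, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        order = list(rng.permutation(patients))
        n = len(order)
        n_train = round(ratios[0] * n)
        n_val = round(ratios[1] * n)
        groups = {"train": order[:n_train],
                  "val": order[n_train:n_train + n_val],
                  "test": order[n_train + n_val:]}
        covered = True
        for split_name, grp in groups.items():
            if ratios[SPLITS.index(split_name)] == 0.0:
                continue  # explicitly empty split (e.g. no validation set)
            present = set().union(*(labels_by_patient[p] for p in grp)) \
                if grp else set()
            if not grp or not set(manifest.class_names) <= present:
                covered = False
                break
        if covered:
            assignment = {p: s for s, grp in groups.items() for p in grp}
            return SplitAssignment(assignment)
    raise RuntimeError(
        "could not produce splits covering every class in every split "
        "after 20 attempts")


@dataclasses.dataclass(frozen=True)
class NormStats:
    """Population mean/std normalisation statistics (train split only).

    Images and volumes use a single population mean/std; 1-D signals are
    normalised per channel.  The same statistics are reused for shuffled
    runs — shuffling commutes with per-channel affine normalisation.
    """

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, arrays: Sequence[np.ndarray], per_channel: bool) -> "NormStats":
        stacked = np.stack(arrays)
        if per_channel:
            axes = (0,) + tuple(range(2, stacked.ndim))
            mean = stacked.mean(axis=axes)
            std = stacked.std(axis=axes)
        else:
            mean = np.asarray(stacked.mean())
            std = np.asarray(stacked.std())
        std = np.maximum(std, 1e-8)
        return cls(mean=mean, std=std)

    def apply(self, arr: np.ndarray) -> np.ndarray:
        if self.mean.ndim == 1:  # per channel
            shape = (-1,) + (1,) * (arr.ndim - 1)
            return (arr - self.mean.reshape(shape)) / self.std.reshape(shape)
        return (arr - self.mean) / self.std


class Dataloaders:
    """Split arrays plus optional per-epoch shuffling.

    Training batches are drawn in seeded random order; when a
    ``ShuffleSpec`` is attached, training data is reshuffled every epoch
    while validation and test splits receive a single fixed shuffle
    (keyed by :data:`~dabis.shuffle.EVAL_EPOCH`) so early stopping is
    comparable across epochs.
    """

    def __init__(self, raw: Dict[str, list], ids: Dict[str, list],
                 labels: Dict[str, np.ndarray], batch_size: int,
                 seed: int, shuffle_spec: Optional[ShuffleSpec] = None,
                 encode: Optional[Callable] = None):
        self.raw, self.ids, self.labels = raw, ids, labels
        self.batch_size = batch_size
        self.shuffle_spec = shuffle_spec
        self.encode = encode or (lambda d: np.asarray(d, dtype=float))
        self._order_rng = np.random.default_rng(
            np.random.SeedSequence([seed & 0x7FFFFFFF, 0xB47C]))
        self._eval_cache: Dict[str, np.ndarray] = {}

    def _materialise(self, split: str, epoch: int) -> np.ndarray:
        samples = self.raw[split]
        if self.shuffle_spec is not None:
            samples = epoch_view(samples, self.ids[split], self.shuffle_spec, epoch)
        return np.stack([self.encode(s) for s in samples])

    def train_batches(self, epoch: int):
        x = self._materialise("train", epoch)
        y = self.labels["train"]
        order = self._order_rng.permutation(len(y))
        for start in range(0, len(y), self.batch_size):
            idx = order[start:start + self.batch_size]
            yield x[idx], y[idx]

    def eval_arrays(self, split: str):
        if split not in self._eval_cache:
            self._eval_cache[split] = self._materialise(split, EVAL_EPOCH)
        return self._eval_cache[split], self.labels[split]


def train_and_test(model, loaders: Dataloaders, config: TrainConfig,
                   class_names: Sequence[str], seed: Optional[int] = None):
    """Supervised training with validation-AUROC early stopping.

    Restores the best-validation-AUROC weights before computing the test
    AUROC with its bootstrap interval.  Returns ``(estimate, test_scores,
    trace)`` where ``trace`` is the per-epoch validation AUROC list.
    """
    from .nn import Adam

    opt = Adam(lr=config.lr, betas=config.betas)
    best_auc = 0.0
    best_weights = model.get_weights()
    counter = 0
    trace: List[float] = []
    interval = max(1, config.max_epochs // 3)
    x_val, y_val = loaders.eval_arrays("val")
    if np.unique(y_val).size < 2:
        raise DegenerateLabelsError("validation split contains a single class")
    for epoch in range(config.max_epochs):
        for xb, yb in loaders.train_batches(epoch):
            loss = model.train_step(xb, yb, opt)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss {loss} at epoch {epoch}")
        val_auc = multiclass_auroc(
            ScoreSet(model.scores(x_val), y_val, tuple(class_names)))
        trace.append(float(val_auc))
        if val_auc > best_auc:
            best_auc = val_auc
            best_weights = model.get_weights()
            counter = 0
        else:
            counter += 1
        if counter > 0 and counter % interval == 0:
            opt.lr /= config.lr_reduction
        if counter >= config.patience:
            break
    model.set_weights(best_weights)
    x_test, y_test = loaders.eval_arrays("test")
    test_scores = ScoreSet(model.scores(x_test), y_test, tuple(class_names))
    estimate = bootstrap_ci(test_scores, n_bootstrap=config.n_bootstrap,
                            seed=seed if seed is not None else config.seed)
    return estimate, test_scores, trace


def _build_loaders(manifest: DatasetManifest, split: SplitAssignment,
                   config: TrainConfig, norm: Optional[NormStats],
                   shuffle_spec: Optional[ShuffleSpec]) -> Dataloaders:
    data = manifest.load_data()
    labels = manifest.label_indices()
    raw, ids, labs = {}, {}, {}
    for s in SPLITS:
        idx = split.indices(manifest, s)
        raw[s] = [data[i] for i in idx]
        ids[s] = [manifest.sample_ids[i] for i in idx]
        labs[s] = labels[idx]
    if manifest.modality == "text":
        encode = lambda d: encode_text(d, max_len=config.text_max_len)  # noqa: E731
    elif norm is not None:
        encode = norm.apply
    else:
        encode = lambda d: np.asarray(d, dtype=float)  # noqa: E731
    return Dataloaders(raw, ids, labs, config.batch_size, config.seed,
                       shuffle_spec=shuffle_spec, encode=encode)


def _assert_no_leakage(manifest: DatasetManifest, split: SplitAssignment) -> None:
    seen: Dict[str, str] = {}
    for rec in manifest.records:
        s = split.split_of(rec.patient_id)
        if seen.setdefault(rec.patient_id, s) != s:
            raise AssertionError(
                f"patient {rec.patient_id!r} appears in two splits")


def estimate_external_accuracy(manifest: DatasetManifest,
                               model_factory: Callable[[], object],
                               config: TrainConfig,
                               shuffle_spec: Optional[ShuffleSpec] = None,
                               o_bar: float = 0.5) -> BiasAuditResult:
    """Run the full audit on one dataset.

    Trains a fresh model on the plain data (``P_Source``), re-initialises
    and trains on per-epoch-shuffled data (``P_DABIS``), then reports the
    calibrated estimate and calibrated ROC curve.  The trained models and
    normalisation statistics ride along in ``result.attachments`` for
    subsequent external validation.
    """
    if shuffle_spec is None:
        shuffle_spec = ShuffleSpec(base_seed=config.seed)
    split = make_splits(manifest, config.ratios, seed=config.seed)
    _assert_no_leakage(manifest, split)
    norm = None
    if manifest.modality != "text":
        data = manifest.load_data()
        train_idx = split.indices(manifest, "train")
        norm = NormStats.fit([np.asarray(data[i], dtype=float) for i in train_idx],
                             per_channel=(manifest.modality == "signal1d"))
    ss = np.random.SeedSequence(config.seed).spawn(2)
    boot_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss]

    source_model = model_factory()
    plain = _build_loaders(manifest, split, config, norm, shuffle_spec=None)
    p_source, scores_source, trace_source = train_and_test(
        source_model, plain, config, manifest.class_names, seed=boot_seeds[0])

    dabis_model = model_factory()
    shuffled = _build_loaders(manifest, split, config, norm,
                              shuffle_spec=shuffle_spec)
    p_dabis, scores_dabis, trace_dabis = train_and_test(
        dabis_model, shuffled, config, manifest.class_names, seed=boot_seeds[1])

    roc_source = mean_roc_curve(scores_source)
    roc_dabis = mean_roc_curve(scores_dabis)
    roc_est = calibration.calibrate_roc(roc_source, roc_dabis)
    p_est = estimate_with_ci(p_source, p_dabis, o_bar)
    result = BiasAuditResult(
        p_source=p_source, p_dabis=p_dabis, p_est=p_est, o_bar=o_bar,
        roc_source=roc_source, roc_dabis=roc_dabis, roc_est=roc_est)
    result.attachments.update({
        "source_model": source_model, "dabis_model": dabis_model,
        "norm": norm, "config": config, "shuffle_spec": shuffle_spec,
        "class_names": manifest.class_names,
        "trace_source": trace_source, "trace_dabis": trace_dabis,
        "split": split})
    return result


def external_validate(audit: BiasAuditResult, external_manifest: DatasetManifest,
                      shuffled: bool = False,
                      label_map: Optional[Dict[str, str]] = None,
                      seed: Optional[int] = None) -> AurocEstimate:
    """Score an audited model on an external-site dataset.

    Plain mode scores the source model (``P_Ext``); shuffled mode scores
    the shuffled-arm model on once-shuffled external data.  External
    labels must map onto the source class names — pass ``label_map`` for
    harmonisation; unmapped labels raise with the offending names.
    """
    class_names = audit.attachments["class_names"]
    label_map = label_map or {}
    mapped = [label_map.get(r.label, r.label) for r in external_manifest.records]
    unmapped = sorted({lab for lab in mapped if lab not in class_names})
    if unmapped:
        raise ValueError(
            f"external labels {unmapped} cannot be harmonised onto source "
            f"classes {list(class_names)}")
    lut = {name: i for i, name in enumerate(class_names)}
    y = np.array([lut[lab] for lab in mapped], dtype=int)
    config: TrainConfig = audit.attachments["config"]
    norm: Optional[NormStats] = audit.attachments["norm"]
    data = external_manifest.load_data()
    if shuffled:
        spec: ShuffleSpec = audit.attachments["shuffle_spec"]
        data = epoch_view(data, external_manifest.sample_ids, spec, EVAL_EPOCH)
        model = audit.attachments["dabis_model"]
    else:
        model = audit.attachments["source_model"]
    if external_manifest.modality == "text":
        x = np.stack([encode_text(d, max_len=config.text_max_len) for d in data])
    else:
        arrays = [np.asarray(d, dtype=float) for d in data]
        x = np.stack([norm.apply(a) for a in arrays] if norm is not None
                     else arrays)
    scoreset = ScoreSet(model.scores(x), y, tuple(class_names))
    est = bootstrap_ci(scoreset, n_bootstrap=config.n_bootstrap,
                       seed=config.seed if seed is None else seed)
    if shuffled:
        audit.p_shuffled_ext = est
    else:
        audit.p_ext = est
    return est


def combine_datasets(manifests: Sequence[DatasetManifest],
                     name: Optional[str] = None) -> DatasetManifest:
    """Pool datasets with identical class sets into one manifest.

    Sample and patient ids are prefixed with the dataset name so records
    stay unique and patients from different datasets are never merged;
    each record keeps its origin in ``provenance`` (and ``site_id`` when
    previously unset).
    """
    if not manifests:
        raise ValueError("no manifests to combine")
    class_names = manifests[0].class_names
    modality = manifests[0].modality
    for m in manifests[1:]:
        if tuple(m.class_names) != tuple(class_names):
            raise ValueError(
                f"class mismatch: {m.name} has {m.class_names}, "
                f"expected {class_names}")
        if m.modality != modality:
            raise ValueError("cannot combine datasets of different modalities")
    if len({m.name for m in manifests}) != len(manifests):
        raise ValueError("combined datasets must have distinct names")
    records = []
    seen = set()
    for m in manifests:
        for r in m.records:
            if r.sample_id in seen:
                raise ValueError(f"duplicate sample_id {r.sample_id!r} "
                                 "across datasets")
            seen.add(r.sample_id)
            records.append(LabeledSample(
                sample_id=f"{m.name}/{r.sample_id}",
                patient_id=f"{m.name}/{r.patient_id}",
                label=r.label, site_id=r.site_id or m.name,
                data=r.data, path=r.path, provenance=m.name))
    return DatasetManifest(records, modality, class_names,
                           name or "+".join(m.name for m in manifests))
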