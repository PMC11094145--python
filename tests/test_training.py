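import dataclasses

import numpy as np
import pytest

from dabis.data import DatasetManifest, LabeledSample
from dabis.models import model_factory
from dabis.roc_metrics import DegenerateLabelsError
from dabis.shuffle import ShuffleSpec
from dabis.synthetic import SyntheticConfig, generate
from dabis.training import (Dataloaders, NormStats, TrainConfig,
                            _build_loaders, combine_datasets,
                            estimate_external_accuracy, external_validate,
                            make_splits, train_and_test)

from conftest import inline_manifest


class TestMakeSplits:
    def test_eight_two_patient_split(self, rng):
        manifest = inline_manifest(rng, n_patients=5)  # 10 patients total
        split = make_splits(manifest, (0.8, 0.0, 0.2), seed=1)
        counts = {s: 0 for s in ("train", "val", "test")}
        for s in split.assignment.values():
            counts[s] += 1
        assert counts == {"train": 8, "val": 0, "test": 2}

    def test_patient_samples_never_straddle_splits(self, rng):
        records = []
        for c in range(2):
            for p in range(15):
                pid = f"m{c}_{p}"
                for k in range(5):
                    records.append(LabeledSample(
                        f"{pid}_s{k}", pid, f"class{c}",
                        data=rng.normal(size=(1, 4, 4))))
        manifest = DatasetManifest(records, "image2d", ("class0", "class1"))
        split = make_splits(manifest, seed=0)
        for s in ("train", "val", "test"):
            idx = split.indices(manifest, s)
            pids = {manifest.records[i].patient_id for i in idx}
            for other in ("train", "val", "test"):
                if other != s:
                    other_pids = {manifest.records[i].patient_id
                                  for i in split.indices(manifest, other)}
                    assert not pids & other_pids

    def test_deterministic_under_seed(self, rng):
        manifest = inline_manifest(rng, n_patients=20)
        assert make_splits(manifest, seed=4).assignment == \
            make_splits(manifest, seed=4).assignment

    def test_class_proportions_roughly_stratified(self):
        rng = np.random.default_rng(0)
        records = []
        for p in range(1000):
            c = int(rng.random() < 0.3)
            records.append(LabeledSample(f"s{p}", f"p{p}", f"class{c}",
                                         data=rng.normal(size=(1, 2, 2))))
        manifest = DatasetManifest(records, "image2d", ("class0", "class1"))
        split = make_splits(manifest, seed=1)
        global_frac = np.mean([r.label == "class1" for r in manifest.records])
        for s in ("train", "val", "test"):
            idx = split.indices(manifest, s)
            frac = np.mean([manifest.records[i].label == "class1"
                            for i in idx])
            assert abs(frac - global_frac) < 0.05

    def test_uncoverable_class_raises_after_retries(self, rng):
        # one class held by a single patient cannot appear in all 3 splits
        records = [LabeledSample(f"s{p}", f"p{p}", "class0",
                                 data=rng.normal(size=(1, 2, 2)))
                   for p in range(9)]
        records.append(LabeledSample("s9", "p9", "class1",
                                     data=rng.normal(size=(1, 2, 2))))
        manifest = DatasetManifest(records, "image2d", ("class0", "class1"))
        with pytest.raises(RuntimeError, match="every class"):
            make_splits(manifest, seed=0)


class ScriptedModel:
    """Stub obeying the fit-step/score contract whose validation AUROC
    follows a predefined per-epoch script (val labels must be [0,0,1,1])."""

    SCORES = {1.0: np.array([0.1, 0.2, 0.8, 0.9]),
              0.75: np.array([0.1, 0.5, 0.4, 0.9]),
              0.5: np.array([0.5, 0.5, 0.5, 0.5])}

    def __init__(self, script, n_batches):
        self.script = script
        self.n_batches = n_batches
        self.steps = 0
        self.restored = None

    @property
    def epoch(self):
        return self.steps // self.n_batches - 1

    def train_step(self, x, y, opt):
        self.steps += 1
        return 0.1

    def scores(self, x):
        auc = self.script[min(self.epoch, len(self.script) - 1)]
        col = self.SCORES[auc][:x.shape[0]]
        if col.size < x.shape[0]:  # test split may be larger: recycle
            col = np.resize(col, x.shape[0])
        return np.column_stack([1 - col, col])

    def get_weights(self):
        return [{"epoch": np.array([float(self.epoch)])}]

    def set_weights(self, weights):
        self.restored = float(weights[0]["epoch"][0])


class TestTrainAndTest:
    def _loaders(self, batch_size=2):
        rng = np.random.default_rng(0)
        raw = {"train": [rng.normal(size=(1, 2)) for _ in range(4)],
               "val": [rng.normal(size=(1, 2)) for _ in range(4)],
               "test": [rng.normal(size=(1, 2)) for _ in range(4)]}
        ids = {s: [f"{s}{i}" for i in range(4)] for s in raw}
        labels = {s: np.array([0, 0, 1, 1]) for s in raw}
        return Dataloaders(raw, ids, labels, batch_size, seed=0)

    def test_early_stopping_restores_best_epoch_weights(self):
        """Validation AUROC rises then falls; with patience 1 training
        runs exactly 3 epochs and the 2nd epoch's weights come back."""
        model = ScriptedModel(script=[0.75, 1.0, 0.5, 0.5, 0.5], n_batches=2)
        config = TrainConfig(max_epochs=10, patience=1, n_bootstrap=5, seed=0)
        _, _, trace = train_and_test(model, self._loaders(), config,
                                     ("a", "b"))
        assert len(trace) == 3
        assert trace == [0.75, 1.0, 0.5]
        assert model.restored == 1.0  # 0-indexed epoch 1 == 2nd epoch

    def test_degenerate_validation_labels_rejected(self):
        loaders = self._loaders()
        loaders.labels["val"] = np.array([1, 1, 1, 1])
        model = ScriptedModel(script=[1.0], n_batches=2)
        with pytest.raises(DegenerateLabelsError):
            train_and_test(model, loaders, TrainConfig(seed=0), ("a", "b"))

    def test_separable_task_sanity(self, rng):
        manifest = inline_manifest(rng, n_patients=40, separation=3.0)
        config = TrainConfig(max_epochs=15, patience=5, seed=2, n_bootstrap=20)
        split = make_splits(manifest, config.ratios, seed=2)
        data = manifest.load_data()
        idx = split.indices(manifest, "train")
        norm = NormStats.fit([data[i] for i in idx], per_channel=False)
        loaders = _build_loaders(manifest, split, config, norm, None)
        factory = model_factory("mlp", (1, 6, 6), 2, seed=1)
        est, _, _ = train_and_test(factory(), loaders, config,
                                   manifest.class_names)
        assert est.value >= 0.95

    def test_permuted_labels_give_chance(self):
        rng = np.random.default_rng(8)
        records = [LabeledSample(f"s{p}", f"p{p}",
                                 f"class{int(rng.random() < 0.5)}",
                                 data=rng.normal(size=(1, 6, 6)))
                   for p in range(300)]
        manifest = DatasetManifest(records, "image2d", ("class0", "class1"))
        config = TrainConfig(max_epochs=10, patience=5, seed=2, n_bootstrap=20)
        split = make_splits(manifest, config.ratios, seed=2)
        loaders = _build_loaders(manifest, split, config, None, None)
        factory = model_factory("mlp", (1, 6, 6), 2, seed=1)
        est, _, _ = train_and_test(factory(), loaders, config,
                                   manifest.class_names)
        assert 0.4 <= est.value <= 0.6


class TestEstimateExternalAccuracy:
    def test_full_pipeline_reproducible(self, rng):
        cfg = SyntheticConfig(n_patients=30, delta_struct=1.0,
                              shape=(1, 8, 8), seed=5)
        src, _, _ = generate(cfg)
        tc = TrainConfig(max_epochs=6, patience=3, seed=9, n_bootstrap=30)
        results = []
        for _ in range(2):
            factory = model_factory("mlp", (1, 8, 8), 2, seed=1)
            audit = estimate_external_accuracy(src, factory, tc,
                                               ShuffleSpec(base_seed=9))
            results.append((audit.p_source.value, audit.p_dabis.value,
                            audit.p_est.value))
        assert results[0] == results[1]

    def test_calibration_identity_with_o_bar(self, rng):
        cfg = SyntheticConfig(n_patients=30, delta_struct=1.0,
                              shape=(1, 8, 8), seed=5)
        src, _, _ = generate(cfg)
        tc = TrainConfig(max_epochs=4, patience=2, seed=9, n_bootstrap=20)
        factory = model_factory("mlp", (1, 8, 8), 2, seed=1)
        audit = estimate_external_accuracy(src, factory, tc)
        expect = np.clip(audit.p_source.value - audit.p_dabis.value + 0.5,
                         0, 1)
        assert audit.p_est.value == pytest.approx(expect)
        assert audit.roc_est is not None


class TestExternalValidate:
    def _audit(self, seed=5):
        cfg = SyntheticConfig(n_patients=40, delta_struct=1.5,
                              shape=(1, 8, 8), seed=seed)
        src, ext, _ = generate(cfg)
        tc = TrainConfig(max_epochs=8, patience=4, seed=3, n_bootstrap=30)
        factory = model_factory("mlp", (1, 8, 8), 2, seed=1)
        return estimate_external_accuracy(src, factory, tc), ext

    def test_iid_external_control(self):
        """External data drawn from the same bias-free distribution scores
        within the source test interval (plus sampling slack)."""
        audit, ext = self._audit()
        p_ext = external_validate(audit, ext)
        assert p_ext.value >= audit.p_source.ci_low - 0.05

    def test_unmapped_label_lists_offenders(self):
        audit, ext = self._audit()
        bad = DatasetManifest(
            [LabeledSample(r.sample_id, r.patient_id, "mystery",
                           data=r.data) for r in ext.records[:10]],
            "image2d", ("mystery",))
        with pytest.raises(ValueError, match="mystery"):
            external_validate(audit, bad)

    def test_label_harmonisation_map(self):
        audit, ext = self._audit()
        renamed = DatasetManifest(
            [LabeledSample(r.sample_id, r.patient_id,
                           r.label.replace("class", "grade"), data=r.data)
             for r in ext.records],
            "image2d", ("grade0", "grade1"))
        est = external_validate(audit, renamed,
                                label_map={"grade0": "class0",
                                           "grade1": "class1"})
        assert 0.0 <= est.value <= 1.0


class TestCombineDatasets:
    def _manifest(self, rng, name, n, prefix):
        return inline_manifest(rng, n_patients=n, prefix=prefix).subset(
            range(2 * n), name=name)

    def test_counts_and_provenance(self, rng):
        a = self._manifest(rng, "A", 5, "a")
        b = self._manifest(rng, "B", 8, "b")
        combined = combine_datasets([a, b])
        assert len(combined) == len(a) + len(b)
        counts = {}
        for r in combined.records:
            counts[r.provenance] = counts.get(r.provenance, 0) + 1
        assert counts == {"A": len(a), "B": len(b)}

    def test_duplicate_sample_id_rejected(self, rng):
        a = self._manifest(rng, "A", 5, "x")
        b = self._manifest(rng, "B", 5, "x")  # same record ids
        with pytest.raises(ValueError, match="duplicate"):
            combine_datasets([a, b])

    def test_class_mismatch_rejected(self, rng):
        a = self._manifest(rng, "A", 5, "a")
        other = DatasetManifest(
            [LabeledSample("z0", "zp0", "weird",
                           data=rng.normal(size=(1, 6, 6)))],
            "image2d", ("weird",), "B")
        with pytest.raises(ValueError, match="class"):
            combine_datasets([a, other])


class TestNormStats:
    def test_per_channel_signal_normalisation(self, rng):
        arrays = [rng.normal([0.0, 5.0], [1.0, 2.0], size=(100, 2)).T
                  for _ in range(50)]
        stats = NormStats.fit(arrays, per_channel=True)
        assert stats.mean == pytest.approx([0.0, 5.0], abs=0.1)
        out = stats.apply(arrays[0])
        assert abs(out.mean()) < 0.5

    def test_shuffling_commutes_with_normalisation(self, rng):
        x = rng.normal(size=(2, 5, 5))
        stats = NormStats.fit([x], per_channel=False)
        spec = ShuffleSpec(base_seed=0)
        from dabis.shuffle import sample_rng, shuffle_array_sample
        a = stats.apply(shuffle_array_sample(x, spec, sample_rng(0, 0, "s")))
        b = shuffle_array_sample(stats.apply(x), spec, sample_rng(0, 0, "s"))
        assert np.allclose(a, b)
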