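"""Downstream harness: splits, oversampling, online augmentation, formulas."""

import numpy as np
import pytest

from busynth import evalkit, phantom
from busynth.evalkit import ConfusionCounts


def _pairs(n_benign, n_malignant, size=16, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for label, n in (("benign", n_benign), ("malignant", n_malignant)):
        for _ in range(n):
            mask = np.zeros((size, size), dtype=np.uint8)
            mask[4:8, 4:8] = 1
            out.append(
                phantom.LabeledPair(image=rng.random((size, size)), mask=mask, class_label=label)
            )
    return out


class TestSplit:
    def test_stratified_counts(self):
        pairs = _pairs(10, 10)
        train, val, test = evalkit.split_dataset(pairs, evalkit.SplitPlan(seed=1))
        for subset, expect in ((train, 6), (val, 2), (test, 2)):
            for label in ("benign", "malignant"):
                assert sum(1 for p in subset if p.class_label == label) == expect

    def test_partition_is_exhaustive_and_disjoint(self):
        pairs = _pairs(13, 7)
        train, val, test = evalkit.split_dataset(pairs, evalkit.SplitPlan(seed=2))
        ids = [id(p) for p in train + val + test]
        assert sorted(ids) == sorted(id(p) for p in pairs)
        assert len(set(ids)) == len(pairs)

    def test_same_seed_identical_assignment(self):
        pairs = _pairs(9, 6)
        a = evalkit.split_dataset(pairs, evalkit.SplitPlan(seed=5))
        b = evalkit.split_dataset(pairs, evalkit.SplitPlan(seed=5))
        for sa, sb in zip(a, b):
            assert [id(p) for p in sa] == [id(p) for p in sb]

    def test_kfold_stratified_and_exhaustive(self):
        labels = ["benign"] * 9 + ["malignant"] * 6
        folds = evalkit.kfold_indices(labels, 3, seed=0)
        all_val = np.concatenate([v for _, v in folds])
        assert sorted(all_val.tolist()) == list(range(15))
        for train, val in folds:
            assert set(train) | set(val) == set(range(15))
            assert not set(train) & set(val)

    def test_kfold_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            evalkit.kfold_indices(["benign", "malignant"], 3)


class TestOversample:
    def test_busi_imbalance_balanced_to_majority(self):
        """487 benign / 210 malignant -> 487 / 487."""
        pairs = _pairs(487, 210)
        balanced = evalkit.oversample_balance(pairs, seed=0)
        counts = {
            label: sum(1 for p in balanced if p.class_label == label)
            for label in ("benign", "malignant")
        }
        assert counts == {"benign": 487, "malignant": 487}

    def test_already_balanced_unchanged(self):
        pairs = _pairs(5, 5)
        assert evalkit.oversample_balance(pairs) == pairs

    def test_singleton_repeated(self):
        pairs = _pairs(3, 1)
        balanced = evalkit.oversample_balance(pairs)
        malignant = [p for p in balanced if p.class_label == "malignant"]
        assert len(malignant) == 3
        assert all(p is malignant[0] for p in malignant)

    def test_majority_class_untouched(self):
        pairs = _pairs(6, 2)
        balanced = evalkit.oversample_balance(pairs)
        assert [p for p in balanced if p.class_label == "benign"] == [
            p for p in pairs if p.class_label == "benign"
        ]


class TestOnlineAugment:
    def test_p_zero_is_identity(self):
        pair = _pairs(1, 0)[0]
        cfg = evalkit.OnlineAugConfig(p=0.0)
        out = evalkit.online_augment(pair, cfg, np.random.default_rng(0))
        assert np.array_equal(out.image, pair.image)
        assert np.array_equal(out.mask, pair.mask)

    def test_hflip_involution(self):
        pair = _pairs(1, 0)[0]
        cfg = evalkit.OnlineAugConfig(p=1.0, ops=("hflip",))
        once = evalkit.online_augment(pair, cfg, np.random.default_rng(1))
        twice = evalkit.online_augment(once, cfg, np.random.default_rng(2))
        assert np.array_equal(once.image, pair.image[:, ::-1])
        assert np.array_equal(once.mask, pair.mask[:, ::-1])
        assert np.array_equal(twice.image, pair.image)

    def test_rotation_conserves_mask_area(self):
        spec = phantom.default_spec("benign", 64)
        rng = np.random.default_rng(3)
        mask = phantom.generate_mask(spec, rng)
        pair = phantom.LabeledPair(image=rng.random((64, 64)), mask=mask, class_label="benign")
        cfg = evalkit.OnlineAugConfig(p=1.0, ops=("rotation",))
        out = evalkit.online_augment(pair, cfg, np.random.default_rng(4))
        assert out.mask.sum() == pytest.approx(mask.sum(), rel=0.05)

    def test_geometric_ops_cotransform_mask(self):
        pair = _pairs(1, 0)[0]
        cfg = evalkit.OnlineAugConfig(p=1.0, ops=("translation",), shift_fraction=0.2)
        out = evalkit.online_augment(pair, cfg, np.random.default_rng(5))
        assert set(np.unique(out.mask)) <= {0, 1}
        assert out.mask.sum() > 0

    def test_intensity_ops_leave_mask(self):
        pair = _pairs(1, 0)[0]
        cfg = evalkit.OnlineAugConfig(p=1.0, ops=("gamma", "noise", "blur"))
        out = evalkit.online_augment(pair, cfg, np.random.default_rng(6))
        assert np.array_equal(out.mask, pair.mask)
        assert not np.array_equal(out.image, pair.image)


class TestFormulas:
    def test_confusion_perfect_and_inverted(self):
        true = np.array([1, 1, 1, 1, 1, 0, 0, 0])
        perfect = evalkit.confusion(true, true)
        assert (perfect.tp, perfect.tn, perfect.fp, perfect.fn) == (5, 3, 0, 0)
        inverted = evalkit.confusion(1 - true, true)
        assert (inverted.tp, inverted.tn, inverted.fp, inverted.fn) == (0, 0, 3, 5)

    def test_confusion_hand_enumerated(self):
        pred = np.array([1, 0, 1, 1, 0, 0])
        true = np.array([1, 1, 0, 1, 0, 1])
        c = evalkit.confusion(pred, true)
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 2, 1)
        assert c.total == 6

    def test_symmetric_case(self):
        c = ConfusionCounts(tp=8, fp=2, fn=2, tn=8)
        assert evalkit.precision(c) == pytest.approx(0.8)
        assert evalkit.recall(c) == pytest.approx(0.8)
        assert evalkit.accuracy(c) == pytest.approx(0.8)
        assert evalkit.f1_score(c) == pytest.approx(0.8)

    def test_half_recall_case(self):
        c = ConfusionCounts(tp=5, fp=0, fn=5, tn=0)
        assert evalkit.precision(c) == pytest.approx(1.0)
        assert evalkit.recall(c) == pytest.approx(0.5)
        assert evalkit.f1_score(c) == pytest.approx(2 / 3)

    def test_degenerate_denominators_zero_with_warning(self):
        c = ConfusionCounts(tp=0, fp=0, fn=0, tn=4)
        with pytest.warns(UserWarning):
            assert evalkit.precision(c) == 0.0
        with pytest.warns(UserWarning):
            assert evalkit.recall(c) == 0.0
        with pytest.warns(UserWarning):
            assert evalkit.f1_score(c) == 0.0
        assert evalkit.accuracy(c) == 1.0

    def test_dice_identical_disjoint_and_counts(self):
        a = np.zeros((8, 8), dtype=np.uint8)
        a[:4] = 1
        assert evalkit.dice(a, a) == 1.0
        b = np.zeros_like(a)
        b[6:] = 1
        assert evalkit.dice(a, b) == 0.0
        # constructed counts: TP=5, FP=3, FN=2 -> 10/15
        pred = np.zeros(10, dtype=bool)
        gt = np.zeros(10, dtype=bool)
        pred[:8] = True  # 8 predicted
        gt[:5] = True
        gt[8:] = True  # 5 overlap, 3 FP, 2 FN
        assert evalkit.dice(pred.reshape(2, 5), gt.reshape(2, 5)) == pytest.approx(10 / 15)

    def test_empty_vs_empty_dice_is_one(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        assert evalkit.dice(z, z) == 1.0


class TestExperiment:
    def test_leakage_detected(self):
        pairs = _pairs(6, 6)
        cfg = evalkit.ExperimentConfig(task="segmentation", epochs=1)
        with pytest.raises(RuntimeError, match="leakage"):
            evalkit.run_augmentation_experiment(pairs, pairs[:2], [], cfg)

    def test_zero_synthetic_reduces_to_ta(self, phantom_pairs):
        """With no synthetic pairs the TA+synthetic arm equals TA."""
        train, test = phantom_pairs[:24], phantom_pairs[24:32]
        cfg = evalkit.ExperimentConfig(task="segmentation", epochs=1, seed=3, model_width=4)
        report = evalkit.run_augmentation_experiment(train, test, [], cfg)
        ta = report["conditions"]["ta"]
        both = report["conditions"]["ta_synthetic"]
        assert ta["dice"] == pytest.approx(both["dice"], abs=1e-12)

    def test_synthetic_augmentation_not_worse_than_baseline(self):
        """Harness smoke property: with a large phantom study, mean Dice of
        the TA+synthetic condition is not materially below baseline
        (>= baseline - 0.02, mean over 3 seeds)."""
        rng = np.random.default_rng(42)
        specs = {l: phantom.default_spec(l, 64) for l in ("benign", "malignant")}
        pool = [
            phantom.generate_pair(specs[l], rng)
            for _ in range(180)
            for l in ("benign", "malignant")
        ]
        train, synthetic, test = pool[:300], pool[300:330], pool[330:360]
        base_scores, aug_scores = [], []
        for seed in range(3):
            cfg = evalkit.ExperimentConfig(task="segmentation", epochs=4, seed=seed)
            report = evalkit.run_augmentation_experiment(train, test, synthetic, cfg)
            base_scores.append(report["conditions"]["baseline"]["dice"])
            aug_scores.append(report["conditions"]["ta_synthetic"]["dice"])
        assert np.mean(aug_scores) >= np.mean(base_scores) - 0.02

    def test_report_reproducible(self, phantom_pairs):
        train, test = phantom_pairs[:16], phantom_pairs[16:24]
        cfg = evalkit.ExperimentConfig(task="classification", epochs=1, seed=4, k_folds=2, model_width=4)
        syn = phantom_pairs[24:32]
        a = evalkit.run_augmentation_experiment(train, test, syn, cfg)
        b = evalkit.run_augmentation_experiment(train, test, syn, cfg)
        assert a == b
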