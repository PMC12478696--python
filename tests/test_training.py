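"""Splits, augmentation, class weights, metrics, training loops."""

import numpy as np
import pytest
from scipy.stats import rankdata

import epiattend as ea
from epiattend.nn import EPINetwork
from epiattend.records import SequencePairRecord
from epiattend.synthetic import sample_background
from epiattend.training import (
    AugmentSpec, SplitSpec, TrainingError, augment_positives,
    augmentation_source_id, class_weights, evaluate, split, train,
    train_pooled_then_finetune, predict_network,
)


def make_records(n_pos, n_neg, enh_len=60, prom_len=40, cell="syn", prefix=""):
    rng = np.random.default_rng(hash((n_pos, n_neg, cell)) % (2**31))
    recs = []
    for i in range(n_pos + n_neg):
        recs.append(SequencePairRecord(
            f"{prefix}{cell}_{i}", sample_background(enh_len, rng),
            sample_background(prom_len, rng), int(i < n_pos), cell))
    return recs


def mann_whitney_auroc(scores, labels):
    """Oracle: AUROC = (U statistic) / (n_pos * n_neg) from midranks."""
    scores, labels = np.asarray(scores), np.asarray(labels)
    ranks = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


class TestSplit:
    def test_reference_sizes_n1000(self):
        recs = make_records(48, 952)
        tr, va, te = split(recs, SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (855, 45, 100)
        assert len({r.id for r in tr} | {r.id for r in va} | {r.id for r in te}) == 1000

    def test_stratification_within_one_record(self):
        recs = make_records(10, 200)
        tr, va, te = split(recs, SplitSpec(seed=1))
        for part in (tr, va, te):
            n_pos = sum(r.label for r in part)
            expected = len(part) * 10 / 210
            assert abs(n_pos - expected) <= 1

    def test_deterministic_membership(self):
        recs = make_records(10, 200)
        a = split(recs, SplitSpec(seed=3))
        b = split(recs, SplitSpec(seed=3))
        assert [[r.id for r in part] for part in a] == [[r.id for r in part] for part in b]
        c = split(recs, SplitSpec(seed=4))
        assert [[r.id for r in part] for part in a] != [[r.id for r in part] for part in c]

    def test_small_or_single_class_rejected(self):
        with pytest.raises(TrainingError):
            split(make_records(2, 10), SplitSpec())
        with pytest.raises(TrainingError):
            split(make_records(0, 30), SplitSpec())


class TestAugmentation:
    def test_plus_50_shift_moves_sequence_downstream(self):
        recs = make_records(1, 0, enh_len=3000, prom_len=2000)
        out = augment_positives(recs, AugmentSpec(shifts=(50,)))
        aug = out[-1]
        assert aug.enhancer[50:] == recs[0].enhancer[:2950]
        assert aug.promoter[50:] == recs[0].promoter[:1950]
        assert aug.enhancer[:50] == "N" * 50
        assert len(aug.enhancer) == 3000 and len(aug.promoter) == 2000

    def test_negative_shift_moves_upstream(self):
        recs = make_records(1, 0, enh_len=100, prom_len=80)
        out = augment_positives(recs, AugmentSpec(shifts=(-10,)))
        aug = out[-1]
        assert aug.enhancer[:90] == recs[0].enhancer[10:]
        assert aug.enhancer[90:] == "N" * 10

    @pytest.mark.parametrize("bad", [0, 5, 51, -9, -60])
    def test_out_of_band_shift_rejected(self, bad):
        with pytest.raises(TrainingError):
            AugmentSpec(shifts=(bad,))

    def test_counts_and_negatives_untouched(self):
        recs = make_records(5, 7)
        out = augment_positives(recs, AugmentSpec(shifts=(10, -10)))
        assert len(out) == 12 + 10
        assert [r for r in out if r.label == 0] == [r for r in recs if r.label == 0]
        new = out[12:]
        assert all(r.label == 1 for r in new)
        assert all(augmentation_source_id(r.id) in {x.id for x in recs} for r in new)


class TestClassWeights:
    def test_inverse_frequency_ratio(self):
        labels = [1] * 10 + [0] * 200
        cw = class_weights(labels)
        assert cw.w_pos / cw.w_neg == pytest.approx(20.0)

    def test_balanced_gives_unit_weights(self):
        cw = class_weights([0, 1, 0, 1])
        assert cw.w_pos == cw.w_neg == 1.0
        assert class_weights([0, 1]) == ea.ClassWeights(1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(TrainingError):
            class_weights([1, 1, 1])


class TestEvaluate:
    def test_perfect_and_inverted_rankings(self):
        labels = [0, 0, 1, 1]
        assert evaluate([0.1, 0.2, 0.8, 0.9], labels) == (1.0, 1.0)
        auroc, _ = evaluate([0.9, 0.8, 0.2, 0.1], labels)
        assert auroc == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(TrainingError):
            evaluate([0.1, 0.9], [1, 1])

    def test_auroc_equals_mann_whitney_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(10, 60))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0], labels[1] = 0, 1
            scores = rng.random(n)
            auroc, _ = evaluate(scores, labels)
            assert auroc == pytest.approx(mann_whitney_auroc(scores, labels), abs=1e-12)

    def test_random_ranker_null_at_one_to_twenty(self):
        rng = np.random.default_rng(42)
        n = 100_000
        labels = (rng.random(n) < 1 / 21).astype(int)
        scores = rng.random(n)
        auroc, aupr = evaluate(scores, labels)
        assert abs(auroc - 0.5) < 0.01
        assert abs(aupr - 1 / 21) < 0.005


class TestTrainLoop:
    def test_weighted_loss_matches_recomputation(self, scaled_cfg):
        net = EPINetwork(scaled_cfg, seed=0)
        rng = np.random.default_rng(1)
        probs = rng.uniform(0.01, 0.99, size=32)
        y = rng.integers(0, 2, size=32).astype(float)
        w = class_weights(y).per_sample(y)
        loss, _ = net.loss_and_grad(probs, y, w)
        manual = -np.mean([wi * (yi * np.log(pi) + (1 - yi) * np.log(1 - pi))
                           for wi, yi, pi in zip(w, y, probs)])
        assert loss == pytest.approx(manual, abs=1e-5)

    def test_loss_decreases_on_easy_task(self, trained):
        # learnable-signal sanity: loss falls over the first epochs and the
        # best epoch improves on the start
        hist = trained["history"]
        losses = hist["train_loss"]
        assert losses[0] > losses[1] > losses[2]
        assert min(losses) < 0.85 * losses[0]

    def test_augmented_copies_confined_to_training_split(self, small_dataset, scaled_cfg):
        records, _ = small_dataset
        tr, va, te = split(records, SplitSpec(seed=5))
        net = EPINetwork(scaled_cfg, seed=5)
        hist = train(net, tr, va, scaled_cfg, mode="augment",
                     augment_spec=AugmentSpec(shifts=(25,)), seed=5,
                     max_epochs=1, patience=1)
        train_ids = {r.id for r in tr}
        other_ids = {r.id for r in va} | {r.id for r in te}
        assert hist["augmented_ids"]
        for aug_id in hist["augmented_ids"]:
            assert augmentation_source_id(aug_id) in train_ids
            assert aug_id not in other_ids

    def test_reproducible_first_epoch(self, small_dataset, scaled_cfg):
        records, _ = small_dataset
        tr, va, _ = split(records, SplitSpec(seed=2))
        losses = []
        for _ in range(2):
            net = EPINetwork(scaled_cfg, seed=9)
            hist = train(net, tr, va, scaled_cfg, seed=9, max_epochs=1, patience=1)
            losses.append(hist["train_loss"][0])
        assert losses[0] == losses[1]

    def test_empty_train_and_bad_mode_rejected(self, scaled_cfg):
        net = EPINetwork(scaled_cfg, seed=0)
        with pytest.raises(TrainingError):
            train(net, [], [], scaled_cfg)
        with pytest.raises(TrainingError):
            train(net, make_records(2, 2, 300, 200), [], scaled_cfg, mode="smote")


class TestPooledThenFinetune:
    def _two_cell_data(self):
        cells = {}
        for cell in ("cellA", "cellB"):
            recs = make_records(6, 24, enh_len=300, prom_len=200, cell=cell)
            cells[cell] = (recs[:24], recs[24:])
        return cells

    def test_finetuned_models_start_from_pooled_weights(self, scaled_cfg):
        result = train_pooled_then_finetune(self._two_cell_data(), scaled_cfg,
                                            seed=0, max_epochs=0)
        pooled_w = result["pooled_weights"]
        # with zero fine-tuning epochs the per-cell weights must equal the
        # pooled stage-1 state they were cloned from
        for cell, (net, _) in result["cells"].items():
            for name, arr in net.get_weights().items():
                assert np.array_equal(arr, pooled_w[name])

    def test_overlapping_ids_rejected(self, scaled_cfg):
        cells = self._two_cell_data()
        a_train = cells["cellA"][0]
        cells["cellB"] = (a_train, cells["cellB"][1])
        with pytest.raises(TrainingError, match="appears in cells"):
            train_pooled_then_finetune(cells, scaled_cfg, seed=0, max_epochs=0)

    def test_requires_two_cells(self, scaled_cfg):
        with pytest.raises(TrainingError):
            train_pooled_then_finetune(
                {"only": (make_records(2, 4, 300, 200), [])}, scaled_cfg)
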