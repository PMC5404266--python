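"""Metrics arithmetic, ranking metrics vs brute force, and leakage-free CV."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npps import (
    ConfusionCounts,
    SVMConfig,
    SyntheticSpec,
    compute_metrics,
    generate,
    jackknife,
    kfold_cv,
    ranking_metrics,
)
from npps.exceptions import ContractError, ParameterError

SINGLE_POINT = SVMConfig(c_grid=(4.0,), gamma_grid=(0.05,))


def small_dataset(n_per_class=12, length=15, seed=5, strength=1.0):
    return generate(
        SyntheticSpec(
            n_pos=n_per_class,
            n_neg=n_per_class,
            window_length=length,
            motif_strength=strength,
            seed=seed,
        )
    )


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(5, 5, 0, 0))
        assert (m.sn, m.sp, m.acc, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_mcc_zero_when_products_cancel(self):
        # TP·TN − FP·FN = 3·2 − 2·3 = 0
        m = compute_metrics(ConfusionCounts(3, 2, 2, 3))
        assert m.acc == 0.5
        assert m.mcc == 0.0

    def test_balanced_set_identity_matches_published_roundings(self):
        # balanced 10,000/class with Sn 78.42% and Sp 80.87% → Acc 79.645%,
        # printed as 79.65%
        m = compute_metrics(ConfusionCounts(tp=7842, tn=8087, fp=1913, fn=2158))
        assert 100 * m.sn == pytest.approx(78.42, abs=1e-9)
        assert 100 * m.sp == pytest.approx(80.87, abs=1e-9)
        assert m.acc == pytest.approx((m.sn + m.sp) / 2, abs=1e-12)
        assert 100 * m.acc == pytest.approx(79.645, abs=1e-9)
        assert m.mcc == pytest.approx(0.59, abs=0.005)

    def test_empty_class_reports_absent_not_zero(self):
        m = compute_metrics(ConfusionCounts(tp=0, tn=3, fp=1, fn=0))
        assert m.sn is None
        assert m.sp == 0.75

    def test_zero_samples_is_contract_error(self):
        with pytest.raises(ContractError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ContractError):
            ConfusionCounts(-1, 0, 0, 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        tp=st.integers(0, 50),
        tn=st.integers(0, 50),
        fp=st.integers(0, 50),
        fn=st.integers(0, 50),
    )
    def test_mcc_invariant_under_class_swap(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        a = compute_metrics(ConfusionCounts(tp, tn, fp, fn)).mcc
        b = compute_metrics(ConfusionCounts(tn, tp, fn, fp)).mcc
        assert a == pytest.approx(b, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        tp=st.integers(0, 40), fn=st.integers(0, 40),
        tn=st.integers(0, 40), fp=st.integers(0, 40),
    )
    def test_balanced_sets_obey_acc_identity(self, tp, fn, tn, fp):
        # force balance: positives = tp+fn must equal negatives = tn+fp
        if tp + fn != tn + fp or tp + fn == 0:
            return
        m = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
        assert m.acc == pytest.approx((m.sn + m.sp) / 2, abs=1e-12)


class TestRankingMetrics:
    def test_perfect_ordering(self):
        auroc, auprc = ranking_metrics([1, 1, -1, -1], [4.0, 3.0, 2.0, 1.0])
        assert auroc == 1.0 and auprc == 1.0

    def test_all_ties_give_half(self):
        auroc, _ = ranking_metrics([1, -1, 1, -1], [0.5] * 4)
        assert auroc == 0.5

    def test_matches_exhaustive_pair_counting(self, rng):
        for _ in range(20):
            y = rng.choice([1, -1], size=12)
            if len(set(y)) < 2:
                continue
            s = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=12)
            auroc, _ = ranking_metrics(y, s)
            pairs = [
                1.0 if sp > sn else (0.5 if sp == sn else 0.0)
                for sp in s[y == 1]
                for sn in s[y == -1]
            ]
            assert auroc == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        y = np.array([1] * 30 + [-1] * 20)
        s = rng.normal(size=50) + (y == 1) * 0.8
        auroc, auprc = ranking_metrics(y, s)
        assert auroc == pytest.approx(roc_auc_score(y, s), abs=1e-12)
        assert 0.0 <= auprc <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ContractError):
            ranking_metrics([1, 1], [0.1, 0.2])


class TestKFoldCV:
    def test_fold_exclusivity_and_coverage(self):
        ds = small_dataset()
        res = kfold_cv(ds, k=4, intervals=[0, 1], svm_config=SINGLE_POINT, seed=2)
        seen = [i for f in res.folds for i in f.test_indices]
        assert sorted(seen) == list(range(len(ds)))
        assert len(set(seen)) == len(ds)

    def test_same_seed_reproduces_everything(self):
        ds = small_dataset()
        a = kfold_cv(ds, k=3, intervals=[0], svm_config=SINGLE_POINT, seed=9)
        b = kfold_cv(ds, k=3, intervals=[0], svm_config=SINGLE_POINT, seed=9)
        assert a.to_json() == b.to_json()
        assert a.pooled.acc == b.pooled.acc

    def test_stratification_balances_folds(self):
        ds = small_dataset(n_per_class=10)
        res = kfold_cv(ds, k=5, intervals=[0], svm_config=SINGLE_POINT, seed=0)
        y = ds.label_vector()
        for f in res.folds:
            fold_y = y[list(f.test_indices)]
            assert np.sum(fold_y == 1) == 2 and np.sum(fold_y == -1) == 2

    def test_class_smaller_than_k_rejected(self):
        ds = small_dataset(n_per_class=3)
        with pytest.raises(ParameterError):
            kfold_cv(ds, k=4, intervals=[0], svm_config=SINGLE_POINT)

    def test_pooled_counts_sum_over_folds(self):
        ds = small_dataset()
        res = kfold_cv(ds, k=4, intervals=[0, 1], svm_config=SINGLE_POINT, seed=1)
        total = sum((f.confusion for f in res.folds), ConfusionCounts(0, 0, 0, 0))
        assert total == res.pooled.confusion
        assert res.pooled.confusion.total == len(ds)

    def test_report_serialization(self, tmp_path):
        ds = small_dataset(n_per_class=6)
        res = kfold_cv(ds, k=3, intervals=[0], svm_config=SINGLE_POINT, seed=4)
        res.to_json(tmp_path / "cv.json")
        res.to_tsv(tmp_path / "cv.tsv")
        import json

        doc = json.loads((tmp_path / "cv.json").read_text())
        assert doc["k"] == 3 and len(doc["folds"]) == 3
        lines = (tmp_path / "cv.tsv").read_text().splitlines()
        assert lines[0].startswith("fold\t")
        assert lines[-1].startswith("pooled\t")


class TestJackknife:
    def test_equals_kfold_with_k_n(self):
        ds = small_dataset(n_per_class=5, length=9)
        jk = jackknife(ds, intervals=[0], svm_config=SINGLE_POINT)
        kf = kfold_cv(ds, k=len(ds), intervals=[0], svm_config=SINGLE_POINT)
        assert jk.pooled.confusion == kf.pooled.confusion
        assert len(jk.folds) == len(ds)

    def test_each_sample_held_out_exactly_once(self):
        ds = small_dataset(n_per_class=3, length=8)
        jk = jackknife(ds, intervals=[0], svm_config=SINGLE_POINT)
        assert [f.test_indices for f in jk.folds] == [(i,) for i in range(6)]

    def test_duplicated_sequence_counted_once_per_record(self):
        from conftest import make_dataset

        seq = "ACGUACGU"
        ds = make_dataset(
            [seq, "AAAAAAAA", "ACCCCCCA"], [seq, "UUUUUUUU", "UGGGGGGU"]
        )
        jk = jackknife(ds, intervals=[0], svm_config=SINGLE_POINT)
        assert jk.pooled.confusion.total == 6

    def test_too_small_dataset_rejected(self):
        from conftest import make_dataset

        ds = make_dataset(["ACGU"], ["UGCA"])
        with pytest.raises(ParameterError):
            jackknife(ds, intervals=[0], svm_config=SINGLE_POINT)


class TestLeakageFreedom:
    def test_shuffled_labels_give_chance_accuracy(self):
        """Label-permuted data must evaluate at chance; materially higher
        pooled accuracy would mean the encoder or hyperparameters leaked
        from validation folds. Small-n version of the detector."""
        rng = np.random.default_rng(42)
        ds = small_dataset(n_per_class=25, length=21, seed=3)
        # permute labels, keeping sequences
        from npps import SequenceDataset, SequenceRecord

        labels = [r.label for r in ds]
        rng.shuffle(labels)
        shuffled = SequenceDataset(
            [
                SequenceRecord(r.id, r.sequence, lab)
                for r, lab in zip(ds, labels)
            ],
            ds.window_length,
        )
        res = kfold_cv(
            shuffled, k=5, intervals=[0, 1], svm_config=SINGLE_POINT, seed=42
        )
        assert 0.3 <= res.pooled.acc <= 0.7
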