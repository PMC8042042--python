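"""Metric oracles, fold hygiene, CI arithmetic, augmentation cardinality."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crstress import evaluation
from crstress.evaluation import (EvalCell, FoldSplit, auprc, auroc,
                                 augment_with_crs, make_fold_split)


def _pair_counting_auroc(scores, labels):
    """Exhaustive concordant-pair oracle: P(pos > neg), ties half."""
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _stepwise_auprc(scores, labels):
    """Hand-stepped PR walk: sum precision * recall-increment over the
    score-descending sweep (average-precision form)."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    labels = np.asarray(labels)[order]
    scores = np.asarray(scores)[order]
    tp = fp = 0
    total_pos = labels.sum()
    area = 0.0
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and scores[j] == scores[i]:
            j += 1
        block_tp = labels[i:j].sum()
        tp += block_tp
        fp += (j - i) - block_tp
        if block_tp:
            area += (tp / (tp + fp)) * (block_tp / total_pos)
        i = j
    return area


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_inverted_labels_give_zero(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1]) == 0.0

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(6, 21)
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert auroc(scores, labels) == pytest.approx(
                _pair_counting_auroc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.5, 0.6], [1, 1])

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(12)
        labels = np.r_[np.ones(4), np.zeros(8)].astype(int)
        base = auroc(scores, labels)
        assert auroc(np.exp(3 * scores), labels) == pytest.approx(base)
        assert auroc(scores ** 3 + 5, labels) == pytest.approx(base)


class TestAuprc:
    def test_perfect_separation_any_prevalence(self):
        assert auprc([0.9, 0.8, 0.2, 0.1, 0.05], [1, 1, 0, 0, 0]) == 1.0

    def test_constant_scores_give_prevalence(self):
        scores = [0.5] * 10
        labels = [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]
        assert auprc(scores, labels) == pytest.approx(0.2)

    def test_matches_hand_stepped_walk(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = rng.integers(6, 13)
            scores = rng.choice([0.2, 0.4, 0.6, 0.8], n)
            labels = rng.integers(0, 2, n)
            if labels.sum() == 0:
                continue
            assert auprc(scores, labels) == pytest.approx(
                _stepwise_auprc(scores, labels), abs=1e-12)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            auprc([0.5, 0.6], [0, 0])


def test_curve_points_are_valid_coordinates():
    rng = np.random.default_rng(0)
    scores = rng.random(30)
    labels = (rng.random(30) < 0.3).astype(int)
    df = evaluation.curve_points(scores, labels)
    assert set(df["curve"]) == {"roc", "pr"}
    roc = df[df.curve == "roc"]
    assert roc["x"].is_monotonic_increasing
    assert roc.iloc[-1]["x"] == 1.0 and roc.iloc[-1]["y"] == 1.0
    pr = df[df.curve == "pr"]
    assert ((pr[["x", "y"]] >= 0) & (pr[["x", "y"]] <= 1)).all().all()


class TestEvalCell:
    def test_degenerate_identical_folds(self):
        cell = EvalCell(1, 1, [0.9] * 5, [0.7] * 5)
        assert cell.auroc_sd == 0.0
        assert cell.auroc_ci == (cell.auroc_mean, cell.auroc_mean)

    def test_hand_arithmetic_five_folds(self):
        """Fold AUROCs (0.86,0.87,0.88,0.86,0.88): mean 0.87, sample sd
        0.01, 95% CI 0.87 +/- 1.96*0.01/sqrt(5)."""
        vals = [0.86, 0.87, 0.88, 0.86, 0.88]
        cell = EvalCell(1, 1, vals, vals)
        assert cell.auroc_mean == pytest.approx(0.87)
        assert cell.auroc_sd == pytest.approx(0.01, rel=1e-9)
        half = 1.96 * 0.01 / np.sqrt(5)
        assert cell.auroc_ci[0] == pytest.approx(0.87 - half)
        assert cell.auroc_ci[1] == pytest.approx(0.87 + half)

    def test_ci_brackets_mean(self):
        rng = np.random.default_rng(2)
        vals = list(rng.uniform(0.6, 0.95, 5))
        cell = EvalCell(15, 50, vals, vals)
        assert cell.auroc_ci[0] <= cell.auroc_mean <= cell.auroc_ci[1]
        assert cell.auroc_sd >= 0


@pytest.fixture(scope="module")
def split():
    rng = np.random.default_rng(0)
    sids = [f"S{i:03d}" for i in range(100)]
    labels = (rng.random(100) < 0.2).astype(int)
    return make_fold_split(sids, labels, k=5, seed=1), sids


class TestFoldSplit:

    def test_test_sets_partition_cohort(self, split):
        fs, sids = split
        test_union = [s for f in fs.folds for s in f["test"]]
        assert sorted(test_union) == sorted(sids)

    def test_no_role_overlap_within_fold(self, split):
        fs, _ = split
        for f in fs.folds:
            assert not (set(f["train"]) & set(f["val"]))
            assert not (set(f["train"]) & set(f["test"]))
            assert not (set(f["val"]) & set(f["test"]))

    def test_seven_one_two_proportions(self, split):
        fs, sids = split
        for f in fs.folds:
            assert len(f["test"]) == pytest.approx(0.2 * len(sids), abs=1)
            assert len(f["val"]) == pytest.approx(0.1 * len(sids), abs=2)
            assert len(f["train"]) == pytest.approx(0.7 * len(sids), abs=2)

    def test_role_overlap_rejected(self):
        with pytest.raises(ValueError):
            FoldSplit(1, [{"train": ["a"], "val": ["a"], "test": ["b"]}])


class TestAugmentation:
    def _datasets(self, crs, n=10):
        from crstress.evaluation import SidePair
        from crstress.preprocess import SideInput

        def pair(sid, cr):
            px = np.full((8, 8), 0.5, np.float32)
            return SidePair(sid, SideInput(px, "left", 0, cr),
                            SideInput(px, "right", 0, cr), 0)

        sids = [f"S{i}" for i in range(n)]
        return {cr: {s: pair(s, cr) for s in sids} for cr in crs}, sids

    def test_single_cr_is_identity_cardinality(self):
        datasets, sids = self._datasets([1])
        out = augment_with_crs(datasets, [1], sids)
        assert len(out) == 2 * len(sids)

    def test_cardinality_multiplies(self):
        datasets, sids = self._datasets([1, 15, 50, 100])
        out = augment_with_crs(datasets, [1, 15, 50, 100], sids)
        assert len(out) == 2 * len(sids) * 4

    def test_empty_cr_list_rejected(self):
        datasets, sids = self._datasets([1])
        with pytest.raises(ValueError):
            augment_with_crs(datasets, [], sids)


class TestMaterialize:
    def test_cr1_uses_original_pixels(self, small_cohort):
        from crstress.preprocess import preprocess_study

        studies, _ = small_cohort
        datasets, stats = evaluation.materialize_cr_datasets(studies[:3], [1])
        ref_left, _ = preprocess_study(studies[0], 0.3)
        got = datasets[1][studies[0].subject_id].left
        np.testing.assert_array_equal(got.pixels, ref_left.pixels)
        assert stats == []

    def test_compressed_cr_recorded(self, small_cohort):
        studies, _ = small_cohort
        datasets, stats = evaluation.materialize_cr_datasets(studies[:3], [20])
        assert len(stats) == 3 * 4
        for row in stats:
            assert row["achieved_cr"] == pytest.approx(20, rel=0.1)
            assert row["psnr_db"] < 100
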