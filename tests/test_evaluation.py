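import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srs_chaos.core import AudioSegment
from srs_chaos.evaluation import (
    ConfusionMatrix,
    confusion,
    make_split,
    metrics,
    roc_one_vs_rest,
)
from srs_chaos.pipeline import verify_tables


def seg(subject, label):
    return AudioSegment(samples=np.zeros(3200), label=label, subject_id=subject)


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        y = ["snore"] * 3 + ["breathing"] * 2 + ["silence"]
        cm = confusion(y, y)
        assert np.array_equal(cm.counts, np.diag([3, 2, 1]))

    def test_empty_input_is_zero_matrix(self):
        cm = confusion([], [])
        assert cm.counts.sum() == 0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            confusion(["snore"], ["music"])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion(["snore"], ["snore", "silence"])

    def test_grand_total_counts_everything(self):
        rng = np.random.default_rng(0)
        labels = np.array(["snore", "breathing", "silence"])
        y = rng.choice(labels, 100)
        p = rng.choice(labels, 100)
        assert confusion(y, p).grand_total == 100


class TestMetrics:
    def test_identity_matrix_is_perfect(self):
        rep = metrics(ConfusionMatrix(np.diag([10, 20, 30])))
        assert all(v == 100.0 for v in rep.sensitivity_pct.values())
        assert all(v == 100.0 for v in rep.ppv_pct.values())
        assert rep.total_accuracy_pct == 100.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionMatrix(np.zeros((3, 3), dtype=int)))

    def test_empty_class_flagged_not_crashed(self):
        counts = np.array([[5, 0, 0], [0, 0, 0], [1, 0, 4]])
        rep = metrics(ConfusionMatrix(counts))
        assert math.isnan(rep.sensitivity_pct["breathing"])
        assert "breathing" in rep.undefined

    @given(st.lists(st.integers(0, 50), min_size=9, max_size=9))
    @settings(max_examples=50, deadline=None)
    def test_total_accuracy_is_recall_weighted_mean(self, flat):
        counts = np.array(flat).reshape(3, 3)
        if counts.sum() == 0:
            return
        rep = metrics(ConfusionMatrix(counts))
        weighted = sum(
            counts[i].sum() * (100.0 * counts[i, i] / counts[i].sum())
            for i in range(3)
            if counts[i].sum() > 0
        ) / counts.sum()
        assert np.isclose(rep.total_accuracy_pct, weighted)


class TestMakeSplit:
    def test_experiment1_first_half_ceil_trains(self):
        segments = [seg("a", "snore") for _ in range(3)] + [seg("a", "silence") for _ in range(4)]
        split = make_split(segments, "I")
        # snore: ceil(3/2)=2 train; silence: 2 train
        assert split.train_indices == [0, 1, 3, 4]
        assert split.test_indices == [2, 5, 6]

    def test_experiment1_keeps_all_subjects_both_sides(self, small_dataset):
        split = make_split(small_dataset, "I")
        train_subjects = {s.subject_id for s in split.train(small_dataset)}
        test_subjects = {s.subject_id for s in split.test(small_dataset)}
        assert train_subjects == test_subjects

    def test_experiment2_subjects_disjoint(self, small_dataset):
        split = make_split(small_dataset, "II", test_subjects={"s2"})
        assert {s.subject_id for s in split.train(small_dataset)} == {"s1"}
        assert {s.subject_id for s in split.test(small_dataset)} == {"s2"}

    def test_experiment2_single_subject_impossible(self):
        segments = [seg("only", "snore")]
        with pytest.raises(ValueError, match="disjoint"):
            make_split(segments, "II", test_subjects={"only"})

    def test_experiment2_requires_test_subjects(self):
        with pytest.raises(ValueError):
            make_split([seg("a", "snore")], "II", test_subjects=set())

    def test_unknown_experiment(self):
        with pytest.raises(ValueError):
            make_split([], "III")


class TestRoc:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.9, 1.0])
        labels = ["breathing", "breathing", "snore", "snore"]
        _, _, area = roc_one_vs_rest(scores, labels, "snore")
        assert area == 1.0

    def test_reversed_scores_complement(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=200)
        labels = np.where(rng.uniform(size=200) < 0.4, "snore", "silence")
        _, _, a = roc_one_vs_rest(scores, labels, "snore")
        _, _, b = roc_one_vs_rest(-scores, labels, "snore")
        assert np.isclose(a + b, 1.0)

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(2)
        n = 20_000
        scores = rng.normal(size=n)
        labels = np.where(rng.uniform(size=n) < 0.5, "snore", "silence")
        _, _, area = roc_one_vs_rest(scores, labels, "snore")
        assert abs(area - 0.5) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_one_vs_rest(np.array([1.0, 2.0]), ["snore", "snore"], "snore")


class TestFixtures:
    def test_table4a_test_snore_row(self, paper_fixtures):
        blk = paper_fixtures.blocks[("4a", "test")]
        assert blk.matrix.counts[0].tolist() == [1075, 42, 58]
        assert blk.matrix.row_totals[0] == 1175

    def test_table5a_test_silence_row(self, paper_fixtures):
        blk = paper_fixtures.blocks[("5a", "test")]
        assert blk.matrix.counts[2].tolist() == [14, 209, 1835]
        assert blk.matrix.row_totals[2] == 2058

    def test_all_blocks_row_sums_match_part_counts(self, paper_fixtures):
        # internal consistency enforced at load time; spot-check shapes here
        assert len(paper_fixtures.blocks) == 8
        for blk in paper_fixtures.blocks.values():
            assert blk.matrix.counts.shape == (3, 3)

    def test_missing_fixture_names_the_file(self):
        from srs_chaos.fixtures import _read_fixture

        with pytest.raises(FileNotFoundError, match="no_such_table.csv"):
            _read_fixture("no_such_table.csv")

    def test_verify_tables_all_cells_reproduce(self):
        df = verify_tables(tolerance=0.01)
        assert df["ok"].all(), df[~df["ok"]]

    def test_svm_blocks_exact_to_two_decimals(self, paper_fixtures):
        # the M-SVM tables reproduce exactly; only ANFIS cells carry the
        # published rounding drift
        for table in ("4a", "5a"):
            for block in ("training", "test"):
                blk = paper_fixtures.blocks[(table, block)]
                rep = metrics(blk.matrix)
                for c in ("snore", "breathing", "silence"):
                    assert round(rep.sensitivity_pct[c], 2) == blk.printed_sensitivity_pct[c]
                    assert round(rep.ppv_pct[c], 2) == blk.printed_ppv_pct[c]
                assert round(rep.total_accuracy_pct, 2) == blk.printed_total_accuracy_pct
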