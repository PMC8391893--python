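"""Partitioning, scrambling, round-robin windowing, puncturing, folds."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rrnet import (CLASSES, RRBlock, puncture, round_robin_window, scramble,
                   simulate_cohort, split_parts)


def toy_blocks(n, label="NSR", beats=4):
    return [RRBlock(patient_id=f"{label}{i}", label=label,
                    rr=np.full(beats, 0.8) + i * 1e-4, duration=10.0)
            for i in range(n)]


class TestSplitParts:
    def test_even_split_forty_blocks(self):
        blocks = toy_blocks(40) + toy_blocks(10, "AFIB") + toy_blocks(10, "AFL")
        parts = split_parts(blocks, n_parts=10, seed=0)
        assert all(len(p.blocks_by_class["NSR"]) == 4 for p in parts)

    def test_patient_disjoint_and_complete(self, small_cohort, small_parts):
        seen = Counter()
        for p in small_parts:
            for pid in p.patient_ids():
                seen[pid] += 1
        assert set(seen) == {b.patient_id for b in small_cohort}
        assert max(seen.values()) == 1

    def test_per_class_sizes_differ_by_at_most_one(self, small_parts):
        for cls in CLASSES:
            sizes = [len(p.blocks_by_class[cls]) for p in small_parts]
            assert max(sizes) - min(sizes) <= 1

    def test_rr_totals_conserved(self, small_cohort, small_parts):
        for cls in CLASSES:
            total = sum(b.rr.size for b in small_cohort if b.label == cls)
            assert sum(p.rr_count(cls) for p in small_parts) == total

    def test_small_class_raises_naming_class(self):
        blocks = toy_blocks(12) + toy_blocks(12, "AFIB") + toy_blocks(3, "AFL")
        with pytest.raises(ValueError, match="AFL"):
            split_parts(blocks, n_parts=10, seed=0)


class TestScramble:
    def test_triples_interval_count(self):
        blocks = toy_blocks(7, "AFL", beats=5)
        out = scramble(blocks, n_perms=3, seed=1)
        assert sum(b.rr.size for b in out) == 3 * 35

    def test_single_block_single_perm_is_identity(self):
        blocks = toy_blocks(1, "AFL")
        assert scramble(blocks, n_perms=1, seed=0) == blocks

    def test_interval_multiset_scales_exactly(self):
        blocks = toy_blocks(5, "AFL", beats=3)
        out = scramble(blocks, n_perms=3, seed=2)
        a = Counter(np.concatenate([b.rr for b in blocks]).tolist())
        b = Counter(np.concatenate([b.rr for b in out]).tolist())
        assert b == {k: 3 * v for k, v in a.items()}

    def test_within_block_order_preserved(self):
        blocks = [RRBlock(patient_id="p", label="AFL",
                          rr=np.array([0.4, 0.6, 0.8]), duration=10.0)]
        out = scramble(blocks * 1, n_perms=2, seed=0)
        for b in out:
            assert np.array_equal(b.rr, [0.4, 0.6, 0.8])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            scramble([], n_perms=3)


class TestRoundRobinWindow:
    def test_circular_three_samples(self):
        got = round_robin_window(np.array([1.0, 2.0, 3.0]), window=2)
        assert np.array_equal(got, [[1, 2], [2, 3], [3, 1]])

    def test_first_elements_reproduce_input(self):
        x = np.arange(37, dtype=float)
        assert np.array_equal(round_robin_window(x, 10)[:, 0], x)

    @given(st.integers(min_value=1, max_value=60),
           st.integers(min_value=1, max_value=130))
    def test_one_vector_per_sample(self, n, window):
        x = np.arange(n, dtype=float)
        vecs = round_robin_window(x, window)
        assert vecs.shape == (n, window)

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            round_robin_window(np.ones(5), window=0)


class TestPuncture:
    def test_exact_counts_and_order(self):
        v = np.arange(2651)
        out = puncture(v, 2015)
        assert out.size == 2015
        assert np.all(np.diff(out) > 0)

    def test_identity_at_full_target(self):
        v = np.arange(9)
        assert np.array_equal(puncture(v, 9), v)

    def test_floor_stride_rule_ten_to_seven(self):
        # brute enumeration of the rule: drop floor(j*10/3) for j=0..2
        expected_removed = {(j * 10) // 3 for j in range(3)}
        out = puncture(np.arange(10), 7)
        assert set(range(10)) - set(out.tolist()) == expected_removed
        assert expected_removed == {0, 3, 6}

    @given(st.integers(min_value=2, max_value=400),
           st.data())
    def test_removed_gaps_differ_by_at_most_one(self, n, data):
        target = data.draw(st.integers(min_value=1, max_value=n))
        out = puncture(np.arange(n), target)
        removed = sorted(set(range(n)) - set(out.tolist()))
        assert len(out) == target
        if len(removed) >= 2:
            gaps = np.diff(removed)
            assert gaps.max() - gaps.min() <= 1

    def test_target_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            puncture(np.arange(5), 6)
        with pytest.raises(ValueError):
            puncture(np.arange(5), 0)


class TestAssembleFolds:
    def test_one_fold_per_part(self, small_folds):
        assert [f.fold_index for f in small_folds] == list(range(1, 11))

    def test_training_classes_exactly_balanced(self, small_folds):
        for f in small_folds:
            counts = f.class_counts("train")
            assert len(set(counts.values())) == 1

    def test_window_length_and_vector_shape(self, small_folds):
        for f in small_folds[:3]:
            assert f.train_X.shape[1] == 100
            assert f.test_X.shape[1] == 100

    def test_test_vector_counts_match_part_sequences(self, small_parts,
                                                     small_folds):
        # unpunctured test windows: one vector per detrended sample
        for part, fold in zip(small_parts, small_folds):
            expect = {
                "NSR": part.rr_count("NSR"),
                "AFIB": part.rr_count("AFIB"),
                "AFL": 3 * part.rr_count("AFL"),
            }
            assert fold.class_counts("test") == expect

    def test_test_part_excluded_from_training(self, small_folds):
        for f in small_folds:
            assert f.test_part not in f.train_parts
            assert len(f.train_parts) == 9
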