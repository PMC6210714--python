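"""Random truncation and train/dev/test allocation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import emgforce as ef

from conftest import make_trapezoid_pool


def _pool_from_arrays(x, Q, subject=0, level=0.5):
    x = np.asarray(x, dtype=float)
    return ef.PairedSignal(x=x, y=x.copy(), Q=Q, subject_id=subject, level=level)


class TestRandomTruncation:
    def test_boundary_enumeration_p2_q4(self):
        """With P=2, Q=4 every start in [1,4] yields an in-bounds window."""
        pool = _pool_from_arrays(np.arange(8), Q=4)
        seen_starts = set()
        for seed in range(200):
            s = ef.random_truncation(pool, Q=4, R=1, seed=seed)
            start = int(s.starts[0])
            seen_starts.add(start)
            assert 1 <= start <= 4
            # 1-based start k covers samples k..k+3 of the 8-point record
            assert np.array_equal(s.x[0], np.arange(start - 1, start + 3))
        assert seen_starts == {1, 2, 3, 4}

    def test_largest_start_fits_exactly(self):
        P, Q = 5, 100
        pool = _pool_from_arrays(np.arange(P * Q), Q=Q)
        for seed in range(50):
            s = ef.random_truncation(pool, Q=Q, R=20, seed=seed)
            assert s.starts.max() <= (P - 1) * Q
            assert np.all(s.x[:, -1] == s.starts - 1 + Q - 1)  # window end index

    def test_zero_samples(self):
        pool = _pool_from_arrays(np.arange(8), Q=4)
        s = ef.random_truncation(pool, Q=4, R=0, seed=0)
        assert len(s) == 0

    def test_segments_share_index_windows(self):
        rng = np.random.default_rng(0)
        pool = ef.PairedSignal(x=rng.uniform(size=40), y=rng.uniform(size=40),
                               Q=10, subject_id=1, level=0.35)
        s = ef.random_truncation(pool, Q=10, R=30, seed=5)
        for i in range(30):
            s0 = int(s.starts[i]) - 1
            assert np.array_equal(s.x[i], pool.x[s0:s0 + 10])
            assert np.array_equal(s.y[i], pool.y[s0:s0 + 10])
            assert s.provenance[i] == (1, 0.35)

    def test_single_cycle_pool_rejected(self):
        pool = _pool_from_arrays(np.arange(4), Q=4)
        with pytest.raises(ValueError, match="P=2"):
            ef.random_truncation(pool, Q=4, R=1, seed=0)

    def test_mismatched_q_rejected(self):
        pool = _pool_from_arrays(np.arange(8), Q=4)
        with pytest.raises(ValueError):
            ef.random_truncation(pool, Q=5, R=1, seed=0)

    def test_deterministic(self):
        pool = _pool_from_arrays(np.arange(500), Q=100)
        a = ef.random_truncation(pool, 100, 50, seed=42)
        b = ef.random_truncation(pool, 100, 50, seed=42)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.starts, b.starts)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(P=st.integers(2, 8), Q=st.integers(2, 50), seed=st.integers(0, 10_000))
    def test_windows_always_in_bounds(self, P, Q, seed):
        pool = _pool_from_arrays(np.arange(P * Q), Q=Q)
        s = ef.random_truncation(pool, Q=Q, R=16, seed=seed)
        assert s.x.shape == (16, Q)
        assert np.all(s.starts >= 1) and np.all(s.starts <= (P - 1) * Q)
        assert np.all(np.isfinite(s.x))

    def test_multi_pool_draws_weighted_and_unmixed(self):
        a = _pool_from_arrays(np.zeros(40), Q=10, subject=0)
        b = _pool_from_arrays(np.ones(20), Q=10, subject=1)
        s = ef.random_truncation([a, b], Q=10, R=400, seed=1)
        frac_b = np.mean([p[0] == 1 for p in s.provenance])
        assert 0.15 < frac_b < 0.4          # (P_b-1)/(P_a-1+P_b-1) = 0.25
        for i in range(len(s)):
            assert np.ptp(s.x[i]) == 0.0    # windows never mix pools


class TestAllocate:
    @staticmethod
    def _subject(subject, n_cycles, Q=8, level=0.5):
        rng = np.random.default_rng(subject)
        x = rng.uniform(size=n_cycles * Q)
        return ef.PairedSignal(x=x, y=x + 1, Q=Q, subject_id=subject, level=level)

    def test_subject_dependent_80_10_10(self):
        alloc = ef.allocate([self._subject(0, 100)], "subject_dependent", seed=1)
        assert sum(p.n_cycles for p in alloc.train) == 80
        assert sum(p.n_cycles for p in alloc.dev) == 10
        assert sum(p.n_cycles for p in alloc.test[0]) == 10

    def test_split_is_a_partition_of_cycles(self):
        sig = self._subject(0, 40)
        alloc = ef.allocate([sig], "subject_dependent", seed=2)
        seen = np.concatenate([p.x for p in alloc.train]
                              + [p.x for p in alloc.dev]
                              + [p.x for p in alloc.test[0]])
        assert sorted(seen) == sorted(sig.x)

    def test_multi_subject_keeps_test_pools_separate(self):
        signals = [self._subject(i, 20) for i in range(8)]
        alloc = ef.allocate(signals, "multi_subject", seed=3)
        assert sorted(alloc.test) == list(range(8))
        assert sum(p.n_cycles for p in alloc.train) == 8 * 16

    def test_subject_independent_holds_out_subject(self):
        signals = [self._subject(i, 20) for i in range(4)]
        alloc = ef.allocate(signals, "subject_independent", subject=2, seed=4)
        held = set(signals[2].x)
        for p in alloc.train + alloc.dev:
            assert p.subject_id != 2
            assert not (set(p.x) & held)
        assert sum(p.n_cycles for p in alloc.test[2]) == 20
        # 90/10 split of the remaining three subjects
        assert sum(p.n_cycles for p in alloc.train) == 3 * 18
        assert sum(p.n_cycles for p in alloc.dev) == 3 * 2

    def test_missing_subject_rejected(self):
        signals = [self._subject(0, 10), self._subject(1, 10)]
        with pytest.raises(ValueError, match="not in the cohort"):
            ef.allocate(signals, "subject_independent", subject=5)
        with pytest.raises(ValueError, match="unknown circumstance"):
            ef.allocate(signals, "leave_two_out")

    def test_subject_independent_needs_two_subjects(self):
        with pytest.raises(ValueError, match="two subjects"):
            ef.allocate([self._subject(0, 10)], "subject_independent", subject=0)


class TestBuildSets:
    def test_default_sizes(self):
        pool = make_trapezoid_pool(6, Q=16)
        tr, dv, te = ef.build_standard_sets([pool], [pool], [pool], Q=16,
                                            sizes=(500, 100, 100), seed=0)
        assert (len(tr), len(dv), len(te)) == (500, 100, 100)
        assert (tr.role, dv.role, te.role) == ("train", "dev", "test")

    def test_small_sizes_arithmetic(self):
        pool = make_trapezoid_pool(4, Q=100)
        tr, dv, te = ef.build_standard_sets([pool], [pool], [pool], Q=100,
                                            sizes=(10, 2, 2), seed=1)
        assert len(tr) + len(dv) + len(te) == 14

    def test_same_seed_same_sets(self):
        pool = make_trapezoid_pool(5, Q=16)
        a = ef.build_standard_sets([pool], [pool], [pool], 16, (50, 5, 5), seed=9)
        b = ef.build_standard_sets([pool], [pool], [pool], 16, (50, 5, 5), seed=9)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.x, sb.x)


class TestFixedPattern:
    def test_one_sample_per_cycle(self):
        pool = make_trapezoid_pool(150, Q=16)
        s = ef.fixed_pattern_sets([pool], Q=16)
        assert len(s) == 150

    def test_samples_reconstruct_the_pool(self):
        pool = make_trapezoid_pool(7, Q=16, noise=0.1, seed=3)
        s = ef.fixed_pattern_sets([pool], Q=16)
        assert np.array_equal(np.concatenate(list(s.x)), pool.x)
        assert np.array_equal(np.concatenate(list(s.y)), pool.y)

    def test_wrong_cycle_length_rejected(self):
        pool = make_trapezoid_pool(4, Q=16)
        with pytest.raises(ValueError):
            ef.fixed_pattern_sets([pool], Q=8)


class TestResample:
    def test_cycle_resampled_to_q_points(self):
        seg = np.linspace(0.0, 1.0, 700)
        out = ef.resample_cycle(seg, 289)
        assert out.size == 289
        assert out[0] == 0.0 and out[-1] == 1.0
        assert np.all(np.diff(out) > 0)

    def test_make_paired_resample_and_crop(self):
        x = np.arange(20, dtype=float)
        bounds = [(0, 10), (10, 20)]
        p = ef.make_paired(x, x, bounds, Q=5, method="resample")
        assert p.n_cycles == 2 and p.x.size == 10
        c = ef.make_paired(x, x, bounds, Q=5, method="crop")
        assert np.array_equal(c.x[:5], np.arange(5))
        with pytest.raises(ValueError):
            ef.make_paired(x, x, bounds, Q=15, method="crop")
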