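import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssvepvote import (
    ChannelPool,
    DEFAULT_POOL_LABELS,
    SyntheticConfig,
    VoteMatrix,
    build_threshold_schedule,
    classify_dynamic,
    compute_psi,
    enumerate_votes_exact,
    extract_window,
    generate_epoch,
    normalize_votes,
    sample_channel_subsets,
    tally_votes,
)
from ssvepvote.vote_ensemble import SubsetSample


class TestSubsetSampling:
    def test_default_pool_is_the_21_posterior_electrodes(self):
        pool = ChannelPool()
        assert pool.size == 21
        assert set(pool.labels) >= {"OZ", "CB1", "CB2", "PO3", "P7", "POZ"}

    def test_singleton_pool_always_returns_the_singleton(self):
        out = sample_channel_subsets(ChannelPool(("OZ",)), 20, seed=0)
        assert all(s == ("OZ",) for s in out.subsets)

    def test_zero_draws_rejected(self):
        with pytest.raises(ValueError):
            sample_channel_subsets(ChannelPool(), 0, seed=0)

    def test_deterministic_under_seed(self):
        a = sample_channel_subsets(ChannelPool(), 100, seed=9)
        b = sample_channel_subsets(ChannelPool(), 100, seed=9)
        c = sample_channel_subsets(ChannelPool(), 100, seed=10)
        assert a.subsets == b.subsets
        assert a.subsets != c.subsets

    def test_all_subsets_non_empty_and_within_pool(self):
        pool = ChannelPool(("O1", "OZ", "O2"))
        out = sample_channel_subsets(pool, 500, seed=1)
        assert all(len(s) >= 1 and set(s) <= set(pool.labels) for s in out.subsets)


class TestTallyAndNormalize:
    def test_unanimous_callable(self, grid):
        ss = SubsetSample(subsets=(("A",), ("B",), ("A", "B"), ("B",)))
        V = tally_votes([lambda s: 3], ss, np.zeros((2, 10)), ("A", "B"), grid, 250.0)
        expected = np.zeros(40)
        expected[3] = 4
        assert np.array_equal(V.counts[0], expected)

    def test_rows_sum_to_R_with_real_scorers(self, grid, high_snr_epoch):
        pool = ChannelPool(("O1", "OZ", "O2", "POZ"))
        ss = sample_channel_subsets(pool, 16, seed=2)
        win = extract_window(high_snr_epoch, 0.7)[
            high_snr_epoch.channel_indices(pool.labels)
        ]
        V = tally_votes(["CCA", "MSI"], ss, win, pool.labels, grid, 250.0)
        assert np.all(V.counts.sum(axis=1) == 16)

    def test_counts_match_exhaustive_enumeration_on_toy_pool(self, grid, high_snr_epoch):
        """Tallying every subset of a 3-electrode pool once reproduces the
        exact power-set vote shares."""
        labels = ("O1", "OZ", "O2")
        pool = ChannelPool(labels)
        all_subsets = (
            ("O1",), ("OZ",), ("O2",),
            ("O1", "OZ"), ("O1", "O2"), ("OZ", "O2"),
            ("O1", "OZ", "O2"),
        )
        win = extract_window(high_snr_epoch, 0.7)[
            high_snr_epoch.channel_indices(labels)
        ]
        V = tally_votes(["CCA"], SubsetSample(all_subsets), win, labels, grid, 250.0)
        exact = enumerate_votes_exact(pool, "CCA", win, labels, grid, 250.0)
        assert np.allclose(V.counts[0] / 7, exact)

    def test_normalize_requires_matching_R(self, grid):
        V = VoteMatrix(counts=np.array([[0.0, 0, 4, 0]]), methods=("CCA",))
        shares = normalize_votes(V, 4)
        assert np.array_equal(shares.counts[0], [0, 0, 1, 0])
        with pytest.raises(ValueError):
            normalize_votes(V, 5)

    def test_uniform_random_classifier_concentrates_near_chance(self, grid):
        rng = np.random.default_rng(0)
        n = grid.n_targets
        ss = sample_channel_subsets(ChannelPool(), 20000, seed=3)
        V = tally_votes(
            [lambda s: int(rng.integers(0, n))], ss, np.zeros((21, 10)),
            DEFAULT_POOL_LABELS, grid, 250.0,
        )
        shares = normalize_votes(V, 20000).counts[0]
        assert np.abs(shares - 1.0 / n).max() < 0.01


class TestPsi:
    def test_worked_examples(self):
        one = normalize_votes(
            VoteMatrix(counts=np.array([[4.0, 0]]), methods=("a",)), 4
        )
        assert compute_psi(one)[0] == pytest.approx(1.0)
        three = VoteMatrix(
            counts=np.ones((3, 2)) * np.array([1.0, 0.0]),
            methods=("a", "b", "c"),
            normalized=True,
        )
        assert compute_psi(three)[0] == pytest.approx(np.sqrt(3) / 3)
        two = VoteMatrix(
            counts=np.array([[0.6, 0.4], [0.8, 0.2]]),
            methods=("a", "b"),
            normalized=True,
        )
        assert compute_psi(two)[0] == pytest.approx(0.5)
        assert compute_psi(two, norm="l1")[0] == pytest.approx(0.7)

    def test_requires_normalized_shares(self):
        V = VoteMatrix(counts=np.array([[4.0, 0]]), methods=("a",))
        with pytest.raises(ValueError):
            compute_psi(V)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        counts=st.lists(
            st.lists(st.integers(0, 15), min_size=4, max_size=4),
            min_size=1,
            max_size=4,
        )
    )
    def test_l2_psi_bounded_by_inverse_sqrt_K(self, counts):
        """max psi <= 1/sqrt(K), with equality only under unanimity."""
        C = np.asarray(counts, dtype=float)
        R = 60.0
        # pad each row to sum R by dumping the remainder on the last target
        C[:, -1] += R - C.sum(axis=1)
        shares = normalize_votes(
            VoteMatrix(counts=C, methods=tuple("m%d" % i for i in range(len(C)))), int(R)
        )
        psi = compute_psi(shares)
        K = C.shape[0]
        assert psi.max() <= 1.0 / np.sqrt(K) + 1e-12
        unanimous = np.any(np.all(shares.counts == 1.0, axis=0))
        assert (abs(psi.max() - 1.0 / np.sqrt(K)) < 1e-12) == unanimous


class TestThresholdSchedule:
    def test_default_has_fifteen_windows(self):
        s = build_threshold_schedule(0.135, 0.865)
        assert s.n_steps == 15
        assert s.window_lengths_s[0] == pytest.approx(0.7)
        assert s.window_lengths_s[-1] == pytest.approx(2.1)
        assert s.taus[0] == pytest.approx(0.865)
        assert s.taus[-1] == pytest.approx(0.135)
        spacing = np.diff(s.taus)
        assert np.allclose(spacing, -(0.865 - 0.135) / 14)

    def test_constant_majority_schedule(self):
        s = build_threshold_schedule(0.5, 0.5)
        assert all(t == 0.5 for t in s.taus)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            build_threshold_schedule(0.9, 0.1)

    def test_step_must_divide_range(self):
        with pytest.raises(ValueError):
            build_threshold_schedule(0.1, 0.9, 0.7, 2.0, 0.3)


class TestClassifyDynamic:
    def test_noiseless_unanimity_stops_at_first_window(self, grid, noiseless_epoch):
        res = classify_dynamic(
            noiseless_epoch,
            ["MEC", "MSI", "FBCCA"],
            grid,
            R=32,
            schedule=build_threshold_schedule(0.5, 0.5),
            seed=2,
        )
        assert res.target == 5
        assert res.window_s == pytest.approx(0.7)
        assert res.stopped_by == "threshold"
        # unanimity across 3 methods saturates the psi bound 1/sqrt(3)
        assert res.gamma == pytest.approx(np.sqrt(3) / 3)

    def test_unreachable_threshold_runs_to_max_window(self, grid):
        ep = generate_epoch(SyntheticConfig(snr_db=-100.0), 0, seed=4)
        res = classify_dynamic(
            ep, ["CCA"], grid, R=16,
            schedule=build_threshold_schedule(1.0, 1.0), seed=5,
        )
        assert res.stopped_by == "max_window"
        assert res.window_s == pytest.approx(2.1)
        assert len(res.psi_trace) == 15

    def test_bitwise_deterministic_under_seed(self, grid):
        ep = generate_epoch(SyntheticConfig(snr_db=-10.0), 9, seed=6)
        a = classify_dynamic(ep, ["CCA", "MSI"], grid, R=24, seed=7)
        b = classify_dynamic(ep, ["CCA", "MSI"], grid, R=24, seed=7)
        assert a.target == b.target and a.window_s == b.window_s
        for va, vb in zip(a.votes_trace, b.votes_trace):
            assert np.array_equal(va.counts, vb.counts)

    def test_psi_tie_breaks_to_lowest_target(self, grid):
        # two callable methods voting half for target 2, half for target 5
        ep = generate_epoch(SyntheticConfig(snr_db=np.inf), 0, seed=0)
        flip = {True: 2, False: 5}
        methods = [lambda s: flip[len(s) % 2 == 0], lambda s: flip[len(s) % 2 == 1]]
        res = classify_dynamic(
            ep, methods, grid, R=16,
            schedule=build_threshold_schedule(1.0, 1.0), seed=8,
        )
        psi = res.psi
        assert psi[2] == psi[5] == psi.max()
        assert res.target == 2

    def test_epoch_shorter_than_schedule_rejected(self, grid):
        ep = generate_epoch(SyntheticConfig(snr_db=np.inf, duration_s=1.5), 0)
        with pytest.raises(ValueError, match="schedule"):
            classify_dynamic(ep, ["CCA"], grid, R=4, seed=0)


class TestExactEnumeration:
    def test_denominator_is_power_set_size(self, grid):
        labels8 = tuple(str(i) for i in range(1, 9))
        shares = enumerate_votes_exact(
            ChannelPool(labels8),
            lambda s: 4 if set(s) in ({"1", "2", "3"}, {"7", "8"}) else 0,
            None, labels8, grid, 0.0,
        )
        assert shares[4] == pytest.approx(2 / 255)
        assert shares.sum() == pytest.approx(1.0)

    def test_single_electrode_pool_gives_unit_share(self, grid, high_snr_epoch):
        labels = ("OZ",)
        win = extract_window(high_snr_epoch, 0.7)[
            high_snr_epoch.channel_indices(labels)
        ]
        shares = enumerate_votes_exact(
            ChannelPool(labels), "CCA", win, labels, grid, 250.0
        )
        assert shares.max() == pytest.approx(1.0)
        assert shares[5] == pytest.approx(1.0)

    def test_large_pool_rejected(self, grid):
        with pytest.raises(ValueError, match="12"):
            enumerate_votes_exact(ChannelPool(), "CCA", None, DEFAULT_POOL_LABELS, grid, 250.0)
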