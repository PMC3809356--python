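"""Tests for stimulation-pattern generation and impulses I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mupool.stimulation import (
    StimulationError,
    StimulationSet,
    StimulusTrain,
    irregular_train,
    make_irregular_asynchronous,
    make_regular_asynchronous,
    make_synchronous,
    read_impulses,
    regular_train,
    size_principle_schedule,
    tc_scaled_mean_ipis,
    write_impulses,
)


class TestTrains:
    def test_regular_train_times(self):
        assert list(regular_train(0, 20, 3).times) == [0, 20, 40]

    def test_regular_50_pulses_at_20ms(self):
        tr = regular_train(0, 20, 50)
        assert len(tr) == 50
        assert tr.last_time == 980.0

    def test_empty_and_invalid(self):
        assert len(regular_train(0, 20, 0)) == 0
        with pytest.raises(StimulationError):
            regular_train(-1, 20, 3)
        with pytest.raises(StimulationError):
            regular_train(0, 0, 3)

    def test_irregular_ipis_within_bounds(self):
        tr = irregular_train(0, 16.6, 50, seed=1)
        ipis = np.diff(tr.times)
        assert np.all(ipis >= 0.5 * 16.6) and np.all(ipis <= 1.5 * 16.6)

    def test_degenerate_variability_reduces_to_regular(self):
        tr = irregular_train(0, 20, 10, variability=(1.0, 1.0), seed=3)
        np.testing.assert_allclose(tr.times, regular_train(0, 20, 10).times, atol=1e-9)

    def test_mean_ipi_law_of_large_numbers(self):
        tr = irregular_train(0, 20, 100_001, seed=5)
        assert np.diff(tr.times).mean() == pytest.approx(20.0, abs=0.1)

    def test_seed_determinism(self):
        a = irregular_train(0, 16.6, 50, seed=9)
        b = irregular_train(0, 16.6, 50, seed=9)
        np.testing.assert_array_equal(a.times, b.times)

    def test_invalid_variability(self):
        with pytest.raises(StimulationError, match="variability"):
            irregular_train(0, 20, 10, variability=(0.0, 1.5), seed=0)

    def test_strictly_increasing_enforced(self):
        with pytest.raises(StimulationError, match="strictly increasing"):
            StimulusTrain(np.array([0.0, 1.0, 1.0]))


class TestSets:
    def test_synchronous_copies(self):
        st_ = make_synchronous(30, regular_train(0, 1000 / 60, 50))
        assert len(st_) == 30
        for tr in st_.trains:
            np.testing.assert_array_equal(tr.times, st_.trains[0].times)

    def test_synchronous_empty_train(self):
        st_ = make_synchronous(3, StimulusTrain(np.empty(0)))
        assert all(len(tr) == 0 for tr in st_.trains)

    def test_regular_async_shifts_in_range(self):
        st_ = make_regular_asynchronous(30, 16.6, 50, max_shift=40, seed=7)
        firsts = np.array([tr.times[0] for tr in st_.trains])
        assert np.all((firsts >= 0) & (firsts <= 40))
        for tr in st_.trains:
            np.testing.assert_allclose(np.diff(tr.times), 16.6, rtol=1e-12)

    def test_zero_shift_is_synchronous(self):
        st_ = make_regular_asynchronous(5, 20, 10, max_shift=0, seed=1)
        sync = make_synchronous(5, regular_train(0, 20, 10))
        for a, b in zip(st_.trains, sync.trains):
            np.testing.assert_array_equal(a.times, b.times)

    def test_irregular_async_distinct_trains_and_determinism(self):
        means = np.linspace(10, 100, 30)
        a = make_irregular_asynchronous(30, means, 50, seed=11)
        b = make_irregular_asynchronous(30, means, 50, seed=11)
        assert len({tuple(tr.times) for tr in a.trains}) == 30
        for x, y in zip(a.trains, b.trains):
            np.testing.assert_array_equal(x.times, y.times)

    def test_mean_ipis_length_mismatch(self):
        with pytest.raises(StimulationError, match="one entry per MU"):
            make_irregular_asynchronous(3, [10, 20], 5, seed=0)


class TestTcScaling:
    def test_rule(self, tiny_pool):
        ipis = tc_scaled_mean_ipis(tiny_pool)
        np.testing.assert_allclose(ipis, 1.25 * tiny_pool.t_c)

    def test_rate_inversion_examples(self):
        # T_c = 20 ms -> 25 ms mean IPI -> 40 Hz; T_c = 33.06 -> ~24.2 Hz
        assert 1000.0 / (1.25 * 20.0) == pytest.approx(40.0)
        assert 1000.0 / (1.25 * 33.06) == pytest.approx(24.2, abs=0.05)


class TestSizePrinciple:
    def test_onsets_and_cutoffs_follow_rank(self, tiny_pool):
        delays = np.array([0.0, 100.0, 200.0])
        targets = np.array([900.0, 800.0, 700.0])
        st_ = size_principle_schedule(tiny_pool, delays, targets, [20, 20, 20], seed=0)
        onsets = np.array([tr.times[0] for tr in st_.trains])
        lasts = np.array([tr.last_time for tr in st_.trains])
        ranks = tiny_pool.fmax_rank()
        np.testing.assert_array_equal(onsets, delays[ranks])
        assert np.all(lasts <= targets[ranks])
        # onset strictly increasing, last impulse strictly decreasing with rank
        order = np.argsort(ranks)
        assert np.all(np.diff(onsets[order]) > 0)
        assert np.all(np.diff(lasts[order]) < 0)

    def test_single_mu_is_truncated_irregular_train(self, tiny_pool):
        from mupool.pool import MUPool

        one = MUPool((tiny_pool.members[0],))
        st_ = size_principle_schedule(one, [0.0], [500.0], [25.0], seed=4)
        assert st_.trains[0].times[0] == 0.0
        assert st_.trains[0].last_time <= 500.0

    def test_monotonicity_violations_rejected(self, tiny_pool):
        with pytest.raises(StimulationError, match="strictly increasing"):
            size_principle_schedule(tiny_pool, [0, 0, 1], [900, 800, 700], [20] * 3)
        with pytest.raises(StimulationError, match="strictly decreasing"):
            size_principle_schedule(tiny_pool, [0, 1, 2], [900, 900, 700], [20] * 3)
        with pytest.raises(StimulationError, match="after the matching"):
            size_principle_schedule(tiny_pool, [0, 100, 800], [900, 850, 700], [20] * 3)


class TestImpulsesIO:
    def test_delay_ipi_semantics(self, tmp_path):
        path = tmp_path / "impulses.txt"
        path.write_text("5\n20\n20\n")
        st_ = read_impulses(path, format="delay_ipi")
        np.testing.assert_allclose(st_.trains[0].times, [5, 25, 45])

    def test_times_round_trip(self, tmp_path):
        path = tmp_path / "impulses.txt"
        path.write_text("0\n20\n40\n")
        st_ = read_impulses(path, format="times")
        np.testing.assert_allclose(st_.trains[0].times, [0, 20, 40])

    def test_padding_sentinel_shortens_train(self, tmp_path):
        path = tmp_path / "impulses.txt"
        path.write_text("0 10\n20 30\n-1 50\n-1 -1\n")
        st_ = read_impulses(path, format="times")
        assert len(st_.trains[0]) == 2
        assert len(st_.trains[1]) == 3

    def test_ragged_file_rejected(self, tmp_path):
        path = tmp_path / "impulses.txt"
        path.write_text("0 10\n20\n")
        with pytest.raises(StimulationError, match="could not parse"):
            read_impulses(path, format="times")

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(StimulationError, match="unknown impulses format"):
            read_impulses(tmp_path / "x.txt", format="magic")

    @pytest.mark.parametrize("fmt", ["times", "delay_ipi"])
    def test_round_trip_mixed_lengths(self, tmp_path, fmt):
        trains = (
            StimulusTrain(np.array([0.0, 16.6, 40.0, 41.5]), 0),
            StimulusTrain(np.empty(0), 1),
            StimulusTrain(np.array([5.25]), 2),
        )
        st_ = StimulationSet(trains)
        path = tmp_path / f"impulses_{fmt}.txt"
        write_impulses(st_, path, format=fmt)
        back = read_impulses(path, format=fmt)
        assert len(back) == 3
        for a, b in zip(st_.trains, back.trains):
            np.testing.assert_allclose(b.times, a.times, rtol=1e-9, atol=1e-9)

    @pytest.mark.parametrize("fmt", ["times", "delay_ipi"])
    def test_excel_round_trip(self, tmp_path, fmt):
        st_ = make_regular_asynchronous(4, 16.6, 5, seed=2)
        path = tmp_path / "impulses.xlsx"
        write_impulses(st_, path, format=fmt)
        back = read_impulses(path, format=fmt)
        for a, b in zip(st_.trains, back.trains):
            np.testing.assert_allclose(b.times, a.times, rtol=1e-9, atol=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        n_mus=st.integers(1, 6),
        fmt=st.sampled_from(["times", "delay_ipi"]),
    )
    def test_round_trip_property(self, tmp_path_factory, seed, n_mus, fmt):
        rng = np.random.default_rng(seed)
        trains = []
        for i in range(n_mus):
            k = int(rng.integers(0, 12))
            times = np.cumsum(rng.uniform(0.5, 50.0, k)) if k else np.empty(0)
            trains.append(StimulusTrain(times, i))
        st_ = StimulationSet(tuple(trains))
        path = tmp_path_factory.mktemp("io") / "impulses.txt"
        write_impulses(st_, path, format=fmt)
        back = read_impulses(path, format=fmt)
        for a, b in zip(st_.trains, back.trains):
            np.testing.assert_allclose(b.times, a.times, rtol=1e-9, atol=1e-9)
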