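"""Firefly wrapper selection: movement rules, decoding, fitness, search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import planted_instance
from qsrr.firefly import (FireflyConfig, attractiveness, decode_mask, fitness,
                          move_firefly, select_descriptors)
from qsrr.svr import SVRConfig
from qsrr.validation import CVScheme

LKO = CVScheme("leave_k_percent_out", percent=10, seed=0)


class TestAttractiveness:
    def test_zero_distance(self):
        assert attractiveness(1.0, 0.01, 0.0) == 1.0

    def test_known_value(self):
        assert attractiveness(1.0, 0.01, 10.0) == pytest.approx(np.exp(-1))

    def test_large_absorption_limit(self):
        assert attractiveness(1.0, 1e9, 0.5) == pytest.approx(0.0, abs=1e-12)


class TestMove:
    def test_fixed_point_without_randomization(self, rng):
        x = rng.uniform(size=4)
        cfg = FireflyConfig(alpha=0.0)
        np.testing.assert_array_equal(move_firefly(x, x, cfg, rng), x)

    def test_full_attraction_limit(self, rng):
        cfg = FireflyConfig(alpha=0.0, beta0=1.0, gamma_abs=0.0)
        x_i = np.array([0.2, 0.8])
        x_j = np.array([0.6, 0.3])
        np.testing.assert_allclose(move_firefly(x_i, x_j, cfg, rng), x_j)

    def test_reproducible_with_seed(self):
        cfg = FireflyConfig(alpha=0.1)
        x_i = np.array([0.2, 0.8])
        x_j = np.array([0.6, 0.3])
        a = move_firefly(x_i, x_j, cfg, np.random.default_rng(3))
        b = move_firefly(x_i, x_j, cfg, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_result_stays_in_unit_box(self, rng):
        cfg = FireflyConfig(alpha=2.0)
        for _ in range(20):
            out = move_firefly(rng.uniform(size=3), rng.uniform(size=3),
                               cfg, rng)
            assert np.all((out >= 0) & (out <= 1))


class TestDecode:
    def test_threshold(self):
        np.testing.assert_array_equal(
            decode_mask(np.array([0.2, 0.9, 0.51])), [False, True, True])

    def test_forced_minimum_tie_breaks_low_index(self):
        mask = decode_mask(np.array([0.1, 0.1, 0.1]), min_descriptors=1)
        np.testing.assert_array_equal(mask, [True, False, False])

    def test_all_on(self):
        assert decode_mask(np.array([0.6, 0.7, 0.9])).all()

    def test_cap_keeps_top_coordinates(self):
        mask = decode_mask(np.array([0.9, 0.6, 0.8, 0.2]), max_descriptors=2)
        np.testing.assert_array_equal(mask, [True, False, True, False])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_min_bits_always_met(self, coords):
        mask = decode_mask(np.array(coords), min_descriptors=1)
        assert mask.sum() >= 1


class TestFitness:
    def test_true_mask_beats_noise_mask(self):
        ds, inf = planted_instance(0, n=40, p=12, k=3)
        true_mask = np.zeros(12, bool)
        true_mask[list(inf)] = True
        noise_mask = ~true_mask
        f_true = fitness(true_mask, ds, SVRConfig(), LKO)
        f_noise = fitness(noise_mask, ds, SVRConfig(), LKO)
        assert f_true < f_noise

    def test_noiseless_linear_target_realizable(self):
        """With the true mask, a linear-capable kernel and small epsilon the
        CV error on noiseless linear data is essentially zero."""
        ds, inf = planted_instance(1, n=30, p=8, k=2, noise_sd=0.0,
                                   link="linear")
        mask = np.zeros(8, bool)
        mask[list(inf)] = True
        cfg = SVRConfig(C=1000.0, epsilon=0.001, kernel="polynomial",
                        degree=1, gamma_kernel=1.0)
        f = fitness(mask, ds, cfg, LKO)
        assert f < 0.02 * np.std(ds.y)

    def test_cache_hit_returns_identical_value(self):
        ds, inf = planted_instance(2, n=30, p=8)
        mask = np.zeros(8, bool)
        mask[list(inf)] = True
        cache, counters = {}, {}
        f1 = fitness(mask, ds, SVRConfig(), LKO, cache, counters)
        f2 = fitness(mask, ds, SVRConfig(), LKO, cache, counters)
        assert f1 == f2 and counters["cache_hits"] == 1

    def test_empty_mask_rejected(self):
        ds, _ = planted_instance(3, n=20, p=6)
        with pytest.raises(ValueError):
            fitness(np.zeros(6, bool), ds, SVRConfig(), LKO)


class TestSelect:
    def test_single_firefly_single_generation(self):
        ds, _ = planted_instance(4, n=20, p=6)
        cfg = FireflyConfig(n_fireflies=1, generations=1, seed=4)
        res = select_descriptors(ds, cfg, SVRConfig(), LKO)
        assert len(res.selected_descriptor_names) >= 1
        assert np.isfinite(res.final_fitness)

    def test_deterministic_given_seed(self):
        ds, _ = planted_instance(5, n=24, p=8)
        cfg = FireflyConfig(n_fireflies=4, generations=5, seed=11)
        r1 = select_descriptors(ds, cfg, SVRConfig(), LKO)
        r2 = select_descriptors(ds, cfg, SVRConfig(), LKO)
        assert r1.selected_descriptor_names == r2.selected_descriptor_names
        assert r1.final_fitness == r2.final_fitness
        assert r1.history == r2.history

    def test_best_fitness_monotone_non_increasing(self):
        ds, _ = planted_instance(6, n=30, p=10)
        cfg = FireflyConfig(n_fireflies=5, generations=10, seed=6)
        res = select_descriptors(ds, cfg, SVRConfig(), LKO)
        assert all(a >= b for a, b in zip(res.history, res.history[1:]))

    def test_final_fitness_equals_recomputation(self):
        """No stale cache: the reported best equals a fresh evaluation."""
        ds, _ = planted_instance(7, n=30, p=10)
        cfg = FireflyConfig(n_fireflies=5, generations=8, seed=7)
        res = select_descriptors(ds, cfg, SVRConfig(), LKO)
        fresh = fitness(res.selected_mask, ds, SVRConfig(), LKO)
        assert fresh == pytest.approx(res.final_fitness, rel=1e-12)

    def test_stationary_single_firefly_without_randomization(self):
        ds, _ = planted_instance(8, n=20, p=6)
        cfg = FireflyConfig(n_fireflies=1, generations=5, alpha=0.0, seed=8)
        res = select_descriptors(ds, cfg, SVRConfig(), LKO)
        assert len(set(res.history)) == 1

    def test_no_descriptors_is_error(self):
        from qsrr.dataset import QSRRDataset, TRAIN
        ds = QSRRDataset(["a", "b", "c", "d"], [], np.empty((4, 0)),
                         np.array([0.1, 0.2, 0.3, 0.4]),
                         np.full(4, TRAIN, dtype=object))
        with pytest.raises(ValueError, match="no descriptors"):
            select_descriptors(ds, FireflyConfig(), SVRConfig(), LKO)

    def test_recovers_planted_descriptors_on_easy_instance(self):
        """One representative recovery run (the multi-seed version is the
        benchmark in the acceptance suite)."""
        ds, inf = planted_instance(0, n=40, p=20, k=3)
        cfg = FireflyConfig(n_fireflies=10, generations=30, seed=0)
        res = select_descriptors(ds, cfg, SVRConfig(), LKO)
        sel = set(int(i) for i in np.flatnonzero(res.selected_mask))
        assert len(sel & inf) >= 2
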