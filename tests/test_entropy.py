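"""Distribution entropy: embedding, distances, histogram, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from disten.entropy import (
    EmbeddingConfig,
    chebyshev,
    distance_distribution,
    distribution_entropy,
    embed,
    stability_profile,
)
from disten.synth import RRIGenParams

from .conftest import random_rri_series
from .oracles import disten_oracle, distance_probs_oracle


class TestEmbed:
    def test_index_range_matches_convention(self):
        # N=6, m=3, tau=1 -> vectors start at x1..x3 (1-based), i.e. 3 vectors
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        v = embed(x, EmbeddingConfig(m=3, tau=1))
        assert v.shape == (3, 3)
        np.testing.assert_array_equal(v, [[1, 2, 3], [2, 3, 4], [3, 4, 5]])

    def test_m1_gives_singletons(self):
        v = embed(np.arange(5.0), EmbeddingConfig(m=1, tau=1))
        assert v.shape == (4, 1)

    def test_all_vectors_switch_adds_one(self):
        x = np.arange(10.0)
        assert len(embed(x, EmbeddingConfig(m=3, tau=2, all_vectors=True))) == 1 + len(
            embed(x, EmbeddingConfig(m=3, tau=2))
        )

    def test_too_short_raises_with_minimum(self):
        with pytest.raises(ValueError, match="at least"):
            embed(np.array([1.0, 2.0, 3.0, 4.0]), EmbeddingConfig(m=3, tau=1))


class TestChebyshev:
    def test_examples(self):
        assert chebyshev((1, 2, 4), (2, 2, 1)) == 3.0
        assert chebyshev((5, 5), (5, 5)) == 0.0

    def test_mismatch_raises(self):
        with pytest.raises(ValueError):
            chebyshev((1, 2), (1, 2, 3))

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=3))
    def test_symmetric(self, u):
        v = [u[2], u[0], u[1]]
        assert chebyshev(u, v) == chebyshev(v, u)


class TestDistanceDistribution:
    def test_constant_series_single_bin(self):
        states = embed(np.full(30, 800.0))
        dist = distance_distribution(states, 256)
        assert dist.probabilities[0] == 1.0
        assert dist.probabilities[1:].sum() == 0.0

    def test_normalization_and_pair_count(self, rng):
        states = embed(random_rri_series(rng, 60))
        dist = distance_distribution(states, 64)
        assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        assert dist.n_pairs == len(states) * (len(states) - 1)

    def test_matches_enumeration_oracle(self):
        probs = distance_distribution(embed(np.arange(1.0, 9.0), EmbeddingConfig(m=2)), 4)
        expected = distance_probs_oracle(np.arange(1.0, 9.0), m=2, tau=1, bins=4)
        np.testing.assert_allclose(probs.probabilities, expected, rtol=0, atol=0)


class TestDistEn:
    def test_constant_series_is_exactly_zero(self):
        assert distribution_entropy(np.full(120, 850.0)).value == 0.0

    def test_hand_enumerated_small_case(self):
        x = np.arange(1.0, 9.0)
        cfg = EmbeddingConfig(m=2, tau=1, bins=4)
        assert distribution_entropy(x, cfg).value == pytest.approx(
            disten_oracle(x, m=2, tau=1, bins=4), rel=1e-14
        )

    def test_oracle_equivalence_on_random_series(self, rng):
        for _ in range(25):
            x = random_rri_series(rng)
            mine = distribution_entropy(x).value
            ref = disten_oracle(x)
            assert mine == pytest.approx(ref, rel=1e-12)

    def test_all_vectors_config_agrees_with_oracle(self, rng):
        x = random_rri_series(rng, 80)
        cfg = EmbeddingConfig(all_vectors=True)
        assert distribution_entropy(x, cfg).value == pytest.approx(
            disten_oracle(x, all_vectors=True), rel=1e-12
        )

    @pytest.mark.parametrize("a", [0.5, 2.0, 1000.0])
    @pytest.mark.parametrize("c", [-200.0, 0.0, 300.0])
    def test_affine_invariance_exact(self, rng, a, c):
        # integer-valued series keep a*x + c exactly representable, so the
        # scaled distance comparisons are bit-identical
        x = np.round(random_rri_series(rng, 100))
        assert distribution_entropy(a * x + c).value == distribution_entropy(x).value

    def test_range_on_stress_battery(self, rng):
        n = 100
        t = np.arange(n)
        battery = [
            np.full(n, 900.0),
            800.0 + 2.0 * t,
            np.where(t % 2 == 0, 700.0, 900.0),
            850.0 + rng.normal(0, 25, n),
            850.0 + np.cumsum(rng.normal(0, 5, n)),
            850.0 + 30 * np.sin(2 * np.pi * t / 5) + rng.normal(0, 5, n),
        ]
        for x in battery:
            v = distribution_entropy(np.clip(x, 428, 2000)).value
            assert 0.0 <= v <= 1.0

    def test_shuffling_changes_autocorrelated_series(self, rng):
        # DistEn reads temporal structure through the embedding: destroying
        # the autocorrelation of a smooth series shifts it beyond MC noise
        deltas = []
        for s in range(12):
            r = np.random.default_rng(s)
            x = 850 + 30 * np.sin(2 * np.pi * np.arange(120) / 4.7) + r.normal(0, 5, 120)
            shuffled = r.permutation(x)
            deltas.append(
                distribution_entropy(shuffled).value - distribution_entropy(x).value
            )
        assert abs(np.mean(deltas)) > 3 * np.std(deltas) / np.sqrt(len(deltas))

    @pytest.mark.parametrize("m", [2, 3, 4])
    @pytest.mark.parametrize("bins", [128, 256, 512])
    def test_rank_order_robust_to_parameters(self, m, bins):
        # a low- vs high-complexity process pair keeps its ordering across
        # reasonable embedding dimensions and bin counts
        from disten.synth import generate_rri, rri_params_for_complexity

        cfg = EmbeddingConfig(m=m, bins=bins)
        low = np.mean(
            [
                distribution_entropy(
                    np.asarray(generate_rri(rri_params_for_complexity(0.2, 845, 120, s))), cfg
                ).value
                for s in range(8)
            ]
        )
        high = np.mean(
            [
                distribution_entropy(
                    np.asarray(generate_rri(rri_params_for_complexity(0.8, 845, 120, s))), cfg
                ).value
                for s in range(8)
            ]
        )
        assert high > low


class TestStabilityProfile:
    def test_zero_reps_empty(self):
        table = stability_profile(RRIGenParams(), [60, 100], n_reps=0, seed=1)
        assert table.empty

    def test_seeded_determinism(self):
        p = RRIGenParams()
        t1 = stability_profile(p, [60, 100], n_reps=5, seed=9)
        t2 = stability_profile(p, [60, 100], n_reps=5, seed=9)
        assert t1.equals(t2)

    def test_short_length_rejected(self):
        with pytest.raises(ValueError):
            stability_profile(RRIGenParams(), [4], n_reps=2, seed=0)
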