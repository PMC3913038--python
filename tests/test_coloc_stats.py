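"""Binomial random-placement null: distances, area fraction, verdicts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ldbridges.coloc_stats import (
    aggregate_fields,
    analyze_field,
    binomial_null,
    coloc_verdict,
    dilated_area_fraction,
    naive_area_fraction,
    signed_nn_distances,
)
from ldbridges.errors import DegenerateVarianceError
from ldbridges.particles import ParticleSet

from _oracles import brute_force_signed_distances, mc_area_fraction


def pset(xy, radii, channel, w=20.0, h=20.0):
    return ParticleSet.from_arrays(xy, radii, channel, w, h, pixel_size_um=0.1)


class TestSignedDistances:
    def test_focus_inside_droplet_is_negative(self):
        foci = pset([(5.0, 5.0)], [0.1], "focus")
        lds = pset([(5.0, 5.0)], [0.5], "ld")
        assert signed_nn_distances(foci, lds) == pytest.approx([-0.6])

    def test_separated_focus_is_positive(self):
        foci = pset([(5.0, 5.0)], [0.1], "focus")
        lds = pset([(6.0, 5.0)], [0.5], "ld")
        assert signed_nn_distances(foci, lds) == pytest.approx([0.4])

    def test_no_droplets_gives_infinite_sentinel(self):
        foci = pset([(5.0, 5.0), (1.0, 1.0)], [0.1, 0.1], "focus")
        lds = pset([], [], "ld")
        assert np.all(np.isinf(signed_nn_distances(foci, lds)))

    def test_matches_brute_force_enumeration(self, rng):
        foci_xy = rng.uniform(0, 20, size=(12, 2))
        ld_xy = rng.uniform(0, 20, size=(7, 2))
        foci_r = rng.uniform(0.05, 0.3, size=12)
        ld_r = rng.uniform(0.3, 1.5, size=7)
        got = signed_nn_distances(pset(foci_xy, foci_r, "focus"), pset(ld_xy, ld_r, "ld"))
        want = brute_force_signed_distances(foci_xy, foci_r, ld_xy, ld_r)
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_pixel_size_mismatch_rejected(self):
        foci = ParticleSet.from_arrays([(1, 1)], [0.1], "focus", 20, 20, pixel_size_um=0.1)
        lds = ParticleSet.from_arrays([(1, 1)], [0.5], "ld", 20, 20, pixel_size_um=0.2)
        with pytest.raises(ValueError, match="pixel size"):
            signed_nn_distances(foci, lds)


class TestDilatedAreaFraction:
    def test_single_disk_area(self):
        lds = ParticleSet.from_arrays([(5.0, 5.0)], [1.0], "ld", 10.0, 10.0)
        assert dilated_area_fraction(lds, rA=0.0) == pytest.approx(np.pi / 100, rel=1e-3)

    def test_coincident_droplets_count_once(self):
        one = ParticleSet.from_arrays([(5.0, 5.0)], [1.0], "ld", 10.0, 10.0)
        two = ParticleSet.from_arrays([(5.0, 5.0)] * 2, [1.0, 1.0], "ld", 10.0, 10.0)
        assert dilated_area_fraction(two, 0.2) == pytest.approx(
            dilated_area_fraction(one, 0.2), rel=1e-9
        )

    def test_no_droplets_gives_zero(self):
        assert dilated_area_fraction(pset([], [], "ld"), 0.1) == 0.0

    def test_matches_monte_carlo_point_sampling(self, rng):
        ld_xy = rng.uniform(2, 38, size=(50, 2))
        ld_r = rng.uniform(0.4, 1.2, size=50)
        lds = ParticleSet.from_arrays(ld_xy, ld_r, "ld", 40.0, 40.0)
        rA = 0.2
        s = dilated_area_fraction(lds, rA)
        est, se = mc_area_fraction(ld_xy, ld_r, rA, 40.0, 40.0, seed=11)
        assert abs(s - est) < 3 * se

    def test_naive_sum_can_exceed_union(self, rng):
        ld_xy = np.tile([(5.0, 5.0)], (30, 1)) + rng.normal(0, 0.2, size=(30, 2))
        lds = ParticleSet.from_arrays(ld_xy, np.full(30, 1.5), "ld", 10.0, 10.0)
        assert naive_area_fraction(lds, 0.0) > 1.0
        assert dilated_area_fraction(lds, 0.0) <= 1.0


class TestBinomialNull:
    def test_direct_pmf_value(self):
        pmf, n_s = binomial_null(4, 0.25)
        assert pmf[1] == pytest.approx(4 * 0.25 * 0.75**3)  # 0.421875
        assert n_s == 1

    @pytest.mark.parametrize("s,expected_ns", [(0.0, 0), (1.0, 10)])
    def test_degenerate_probabilities(self, s, expected_ns):
        pmf, n_s = binomial_null(10, s)
        assert pmf[expected_ns] == pytest.approx(1.0)
        assert n_s == expected_ns

    @pytest.mark.parametrize("nA", [1, 17, 400, 10000])
    def test_pmf_sums_to_one(self, nA):
        pmf, _ = binomial_null(nA, 0.137)
        assert abs(pmf.sum() - 1.0) < 1e-12

    def test_mode_tie_broken_toward_smaller_n(self):
        # Binomial(3, 0.5) has equal pmf at n=1 and n=2
        _, n_s = binomial_null(3, 0.5)
        assert n_s == 1


class TestVerdict:
    def test_clear_enrichment(self):
        res = coloc_verdict(30, 100, 0.1)
        assert res.verdict == "enriched"
        assert res.tail_p < 1e-6

    def test_mode_is_random_consistent(self):
        _, n_s = binomial_null(50, 0.3)
        assert coloc_verdict(n_s, 50, 0.3).verdict == "random-consistent"

    def test_zero_observed_is_excluded(self):
        res = coloc_verdict(0, 50, 0.3)
        assert res.verdict == "excluded"
        assert res.tail_p == pytest.approx(0.7**50, rel=1e-9)  # ~1.8e-8

    def test_alpha_validation(self):
        with pytest.raises(ValueError, match="alpha"):
            coloc_verdict(1, 10, 0.1, alpha=1.5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        nA=st.integers(5, 200),
        s=st.floats(0.01, 0.99),
        alpha=st.floats(0.001, 0.1),
    )
    def test_verdict_monotone_in_n_exp(self, nA, s, alpha):
        order = {"excluded": 0, "random-consistent": 1, "enriched": 2}
        ranks = [order[coloc_verdict(n, nA, s, alpha).verdict] for n in range(nA + 1)]
        assert all(a <= b for a, b in zip(ranks, ranks[1:]))


class TestAggregate:
    def _results(self, n_exp_values, nA=50, s=0.1):
        return [coloc_verdict(n, nA, s) for n in n_exp_values]

    def test_enriched_fields_pool_to_enriched(self):
        agg = aggregate_fields(self._results([20, 25, 22, 27, 24, 23]))
        assert agg.pooled_verdict == "enriched"
        assert agg.p_value < 0.01

    def test_degenerate_differences_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            aggregate_fields(self._results([5, 5, 5]))

    def test_needs_two_fields(self):
        with pytest.raises(ValueError, match=">= 2"):
            aggregate_fields(self._results([5]))


def test_analyze_field_counts_overlaps(rng):
    lds = pset([(5.0, 5.0), (12.0, 12.0)], [1.0, 1.0], "ld")
    foci = pset([(5.2, 5.0), (12.0, 12.5), (18.0, 2.0)], [0.2] * 3, "focus")
    res = analyze_field(foci, lds)
    assert res.n_exp == 2
    assert res.nA == 3
    assert res.signed_distances_um is not None
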