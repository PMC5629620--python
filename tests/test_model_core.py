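import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurocascade import (
    ProgenyModel,
    build_transition_matrix,
    expected_divisions,
    progeny_distribution,
)

division_laws = st.tuples(
    st.integers(1, 3), st.integers(0, 5), st.floats(0.0, 1.0)
).map(lambda t: (t[0], t[0] + t[1], t[2]))


class TestProgenyLaw:
    def test_printed_pmf(self):
        pmf = progeny_distribution(1, 4, 0.1)
        assert pmf == pytest.approx({2: 0.9, 4: 0.09, 8: 0.009, 16: 0.001})

    def test_degenerate_when_bounds_equal(self):
        assert progeny_distribution(3, 3, 0.9) == {8: 1.0}
        assert expected_divisions(3, 3, 0.9) == 3.0

    @given(law=division_laws)
    @settings(max_examples=200, deadline=None)
    def test_pmf_normalized_over_powers_of_two(self, law):
        a, b, p = law
        pmf = progeny_distribution(a, b, p)
        assert sum(pmf.values()) == pytest.approx(1.0)
        assert set(pmf) <= {2**n for n in range(a, b + 1)}

    def test_expected_divisions_reported_values(self):
        assert expected_divisions(1, 4, 0.1) == pytest.approx(1.17, abs=5e-3)
        assert expected_divisions(2, 5, 0.57) == pytest.approx(3.57, abs=5e-3)

    @given(
        a=st.integers(1, 3),
        extra=st.integers(1, 5),
        p1=st.floats(0.0, 1.0),
        p2=st.floats(0.0, 1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_more_renewal_means_more_divisions(self, a, extra, p1, p2):
        lo, hi = sorted((p1, p2))
        b = a + extra
        assert expected_divisions(a, b, lo) <= expected_divisions(a, b, hi) + 1e-12

    @pytest.mark.parametrize("a,b", [(0, 2), (3, 2), (-1, 1)])
    def test_invalid_bounds_rejected(self, a, b):
        with pytest.raises(ValueError):
            ProgenyModel(a, b, 0.5)

    def test_conditioned_division_count(self):
        law = ProgenyModel(1, 4, 0.2)
        pmf = law.division_count_pmf(at_least=3)
        assert pmf == pytest.approx({3: 0.8, 4: 0.2})


def _random_params(base, rng):
    return base.replace_values(
        d_g1=rng.uniform(0, 0.99),
        d_s=rng.uniform(0, 0.99),
        d_g2m=rng.uniform(0, 0.99),
        d_anp=rng.uniform(0, 0.99),
        d_nb=rng.uniform(0.01, 0.99),
        renewal_prob_anp=rng.uniform(0, 1),
        renewal_prob_nsc=rng.uniform(0, 1),
    )


class TestTransitionMatrix:
    def test_published_structure_three_division_case(self, best_fit):
        """With a=1, b=3 and the IN stage enabled, the matrix reproduces the
        published 14-compartment structure entry for entry."""
        from neurocascade.params import StageSpec
        from neurocascade.distributions import ShiftedGamma
        from dataclasses import replace

        d_in = 0.25
        params = best_fit.replace_values(
            min_divisions_anp=1, max_divisions_anp=3
        )
        params = replace(
            params, in_stage=StageSpec("IN", ShiftedGamma(2.0, 10.0, 5.0), d_in)
        )
        tm = build_transition_matrix(
            params, include_nsc=False, include_absorbing=False, include_in=True
        )
        assert tm.labels == [
            "ANP_G1(1)", "ANP_S(1)", "ANP_G2M(1)",
            "ANP_G1(2)", "ANP_S(2)", "ANP_G2M(2)",
            "ANP_G1(3)", "ANP_S(3)", "ANP_G2M(3)",
            "ANP-NB", "NB", "IN", "ANP-Apop", "Apop",
        ]
        d = params.death_rates()
        dbar = {k: 1.0 - v for k, v in d.items()}
        p = params.anp_divisions.renewal_prob
        x = 2 * dbar["d_g2m"] * (1 - p) * dbar["d_anp"]
        y = 2 * dbar["d_g2m"] * (1 - p) * d["d_anp"]
        z = 2 * dbar["d_g2m"] * dbar["d_anp"]
        w = 2 * dbar["d_g2m"] * d["d_anp"]
        expect = np.zeros((14, 14))
        for g in range(3):
            expect[3 * g, 3 * g + 1] = dbar["d_g1"]
            expect[3 * g, 13] = d["d_g1"]
            expect[3 * g + 1, 3 * g + 2] = dbar["d_s"]
            expect[3 * g + 1, 13] = d["d_s"]
            expect[3 * g + 2, 13] = d["d_g2m"]
        for g in (0, 1):  # renewal-eligible, below the maximum
            expect[3 * g + 2, 3 * g + 3] = 2 * p * dbar["d_g2m"]
            expect[3 * g + 2, 9] = x
            expect[3 * g + 2, 12] = y
        expect[8, 9] = z
        expect[8, 12] = w
        expect[9, 10] = 1.0
        expect[10, 11] = dbar["d_nb"]
        expect[10, 13] = d["d_nb"]
        expect[11, 13] = d_in
        expect[12, 13] = 1.0
        np.testing.assert_allclose(tm.m, expect, atol=1e-12)

    def test_row_sum_identities_random_draws(self, best_fit):
        rng = np.random.default_rng(0)
        for _ in range(25):
            params = _random_params(best_fit, rng)
            tm = build_transition_matrix(params)
            sums = tm.m.sum(axis=1)
            d_g2m = params.anp_g2m.death_rate
            for i, lab in enumerate(tm.labels):
                if lab.startswith(("ANP_G1", "ANP_S", "NB", "ANP-")):
                    assert sums[i] == pytest.approx(1.0), lab
                elif lab.startswith("ANP_G2M"):
                    assert sums[i] == pytest.approx(2.0 - d_g2m), lab
                elif lab.startswith("NSC_G2M"):
                    assert sums[i] == pytest.approx(2.0), lab  # asymmetric split
                elif lab in ("Apop", "GC", "Astro"):
                    assert sums[i] == 0.0, lab
            assert np.all(tm.m >= 0)

    def test_no_renewal_cuts_next_generation(self, best_fit):
        params = best_fit.replace_values(renewal_prob_anp=0.0)
        tm = build_transition_matrix(params, include_nsc=False)
        a = params.anp_divisions.min_divisions
        b = params.anp_divisions.max_divisions
        for g in range(a, b):
            row = tm.index(f"ANP_G2M({g})")
            assert tm.m[row, tm.index(f"ANP_G1({g + 1})")] == 0.0

    def test_spectral_radius_below_one(self, best_fit):
        rng = np.random.default_rng(1)
        for _ in range(25):
            tm = build_transition_matrix(_random_params(best_fit, rng))
            assert tm.spectral_radius() < 1.0

    def test_nsc_death_rates_must_be_zero(self, best_fit):
        from dataclasses import replace
        from neurocascade.params import StageSpec

        with pytest.raises(ValueError, match="NSC"):
            replace(
                best_fit,
                nsc_g1=StageSpec("NSC_G1", best_fit.nsc_g1.duration, 0.1),
            )


def test_parameter_dict_round_trip(best_fit):
    d = best_fit.to_dict()
    from neurocascade import CascadeParameters

    again = CascadeParameters.from_dict(d)
    assert again.to_dict() == pytest.approx(d)
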