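import numpy as np
import pytest
from scipy import stats

from neurocascade import (
    LabeledCell,
    sample_initial_cohort,
    simulate_cell,
    simulate_labeling_curves,
)
from neurocascade.simulate import CascadeSimulator, _TraceRecorder


@pytest.fixture(scope="module")
def small_params(best_fit):
    # small influx keeps cohorts at a few dozen cells for cheap tests
    return best_fit.replace_values(influx=3.0, nsc_activation=0.15)


class TestCohortSampling:
    def test_zero_influx_gives_empty_cohort(self, best_fit):
        params = best_fit.replace_values(influx=0.0, nsc_activation=0.0)
        assert sample_initial_cohort(params, np.random.default_rng(0)) == []

    def test_poisson_mean_matches_stationary_occupancy(self, small_params):
        sim = CascadeSimulator(small_params)
        expect = sim.labeled_means().sum()
        rng = np.random.default_rng(1)
        sizes = [len(sim.sample_initial_cohort(rng)) for _ in range(400)]
        se = np.std(sizes, ddof=1) / np.sqrt(len(sizes))
        assert abs(np.mean(sizes) - expect) <= 3 * se

    def test_start_of_s_mode_draws_fresh_durations(self, small_params):
        sim = CascadeSimulator(small_params, residual_mode="start")
        rng = np.random.default_rng(2)
        rem = []
        for _ in range(300):
            rem += [
                c.exit_time - c.entry_time
                for c in sim.sample_initial_cohort(rng)
                if not c.is_nsc
            ]
        dist = small_params.anp_s.duration
        assert min(rem) >= dist.shift
        assert np.mean(rem) == pytest.approx(dist.mean, rel=0.05)

    def test_stationary_mode_residuals_shorter_on_average(self, small_params):
        rng = np.random.default_rng(3)
        rem = []
        for _ in range(300):
            rem += [
                c.exit_time - c.entry_time
                for c in sample_initial_cohort(small_params, rng)
                if not c.is_nsc
            ]
        dist = small_params.anp_s.duration
        resid_mean = (dist.var + dist.mean**2) / (2 * dist.mean)
        assert np.mean(rem) == pytest.approx(resid_mean, rel=0.05)


class TestSingleCellTraces:
    def test_certain_g1_death_goes_straight_to_apoptosis(self, best_fit):
        params = best_fit.replace_values(d_g1=1.0)
        cell = LabeledCell("ANP_G1(1)", 1, 1, 0.0, 5.0)
        for seed in range(10):
            events = simulate_cell(cell, params, np.random.default_rng(seed))
            assert [e[0] for e in events] == ["ANP_G1(1)", "Apop"]

    def test_certain_nb_death_never_reaches_granule_stage(self, best_fit):
        params = best_fit.replace_values(d_nb=1.0)
        rng = np.random.default_rng(4)
        for _ in range(50):
            cell = LabeledCell("ANP_S(1)", 1, 1, 0.0, 6.0)
            events = simulate_cell(cell, params, rng)
            assert all(e[0] != "GC" for e in events)

    def test_progeny_distribution_matches_division_law(self, best_fit):
        """With no deaths, the number of non-proliferating ANPs per founder
        clone realizes the progeny pmf over {2^a, ..., 2^b}."""
        params = best_fit.scale_death_rates(0.0)
        law = params.anp_divisions
        sim = CascadeSimulator(params)
        rng = np.random.default_rng(5)
        a, b, p = law.min_divisions, law.max_divisions, law.renewal_prob
        from neurocascade.simulate import _draw_target

        counts = {2**n: 0 for n in range(a, b + 1)}
        n_clones = 20_000
        for _ in range(n_clones):
            rec = _TraceRecorder(sim.tm.labels)
            target = _draw_target(rng, a, b, p, 1)
            sim._run_anp_clone(0.0, 1, 0, None, target, rec, rng)
            progeny = sum(1 for e in rec.events if e[0] == "ANP-NB")
            counts[progeny] += 1
        pmf = law.progeny_pmf()
        observed = np.array([counts[x] for x in sorted(pmf)])
        expected = n_clones * np.array([pmf[x] for x in sorted(pmf)])
        assert stats.chisquare(observed, expected).pvalue > 0.01

    def test_no_death_no_renewal_yields_two_to_the_a_granule_cells(self, best_fit):
        params = best_fit.scale_death_rates(0.0).replace_values(
            renewal_prob_anp=0.0, d_anp=0.0
        )
        a = params.anp_divisions.min_divisions
        rng = np.random.default_rng(6)
        for _ in range(20):
            cell = LabeledCell("ANP_S(1)", 1, a, 0.0, 6.0)
            events = simulate_cell(cell, params, rng)
            assert sum(1 for e in events if e[0] == "GC") == 2**a

    def test_lineage_conservation(self, best_fit):
        """Every lineage terminates in GC, Astro or cleared apoptosis: each
        stage exit either enters another recorded stage or ends a branch."""
        rng = np.random.default_rng(7)
        cell = LabeledCell("ANP_S(1)", 1, 3, 0.0, 6.0)
        events = simulate_cell(cell, best_fit, rng)
        terminal = [e for e in events if e[0] in ("GC", "Astro") or e[0] == "Apop"]
        assert terminal, "lineage must terminate"
        for lab, t0, t1 in events:
            assert t1 >= t0


class TestLabelingCurves:
    def test_empty_cohort_warns_and_zeroes(self, best_fit):
        params = best_fit.replace_values(influx=0.0, nsc_activation=0.0)
        with pytest.warns(UserWarning, match="empty"):
            curve = simulate_labeling_curves(params, [2.0, 24.0], 2, rng=0)
        assert np.all(curve.counts == 0)

    def test_total_at_origin_equals_cohort_size(self, small_params):
        curve = simulate_labeling_curves(small_params, [0.0, 24.0], 1, rng=8)
        obs = curve.observables()
        assert obs.Total.iloc[0] == curve.counts[0, 0].sum()
        assert obs.Total.iloc[0] > 0

    def test_total_is_sum_of_classes(self, small_params):
        curve = simulate_labeling_curves(small_params, [2.0, 48.0, 768.0], 3, rng=9)
        obs = curve.observables()
        parts = obs[["Apop", "NSC", "ANP", "NB", "GC", "Astro"]].sum(axis=1)
        np.testing.assert_allclose(obs.Total, parts, atol=1e-9)

    def test_granule_curve_monotone(self, small_params):
        tps = np.linspace(0.0, 768.0, 25)
        curve = simulate_labeling_curves(small_params, tps, 4, rng=10)
        gc = curve.counts[:, :, curve.classes.index("GC")]
        assert np.all(np.diff(gc, axis=1) >= 0)

    def test_seeded_runs_bit_reproducible(self, small_params):
        tps = [2.0, 24.0, 192.0]
        c1 = simulate_labeling_curves(small_params, tps, 3, rng=123)
        c2 = simulate_labeling_curves(small_params, tps, 3, rng=123)
        np.testing.assert_array_equal(c1.counts, c2.counts)

    def test_mean_curves_match_analytic_expectation(self, best_fit):
        """Simulated means vs the renewal-equation curves on the default
        cascade at reduced influx, within 3 Monte-Carlo standard errors."""
        from neurocascade.expectations import expected_labeling_curves

        params = best_fit.replace_values(influx=20.0, nsc_activation=1.0)
        tps = np.array([2.0, 24.0, 96.0, 360.0, 768.0])
        curve = simulate_labeling_curves(params, tps, 40, rng=11)
        ana = expected_labeling_curves(params, tps, step=0.1)
        obs, sem = curve.observables(), curve.observables_sem()
        for col in ("Total", "NSC", "ANP", "NB", "GC", "Astro"):
            ana_col = {"ANP": "ANP_all"}.get(col, col)
            diff = np.abs(obs[col].to_numpy() - ana[ana_col].to_numpy())
            bound = 3.0 * sem[col].to_numpy() + 0.05 * np.abs(ana[ana_col].to_numpy()) + 0.2
            assert np.all(diff <= bound), col
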