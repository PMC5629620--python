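import numpy as np
import pandas as pd
import pytest

from neurocascade import (
    GAConfig,
    ParameterCodec,
    calibrate_influx,
    objective,
    run_ga,
)
from neurocascade.inference import ContractError, ExpectationEngine


def meas_frame(rows):
    df = pd.DataFrame(rows, columns=["time_h", "cls", "mean", "sem"])
    return df


def curve_frame(times, **cols):
    df = pd.DataFrame({"time_h": times})
    for k, v in cols.items():
        df[k] = v
    return df


class TestObjective:
    def test_perfect_fit_scores_zero(self):
        obs = meas_frame([(24.0, "Total", 100.0, 10.0), (48.0, "NB", 40.0, 5.0)])
        sim = curve_frame([24.0, 48.0], Total=[100.0, 0.0], NB=[0.0, 40.0])
        assert objective(obs, sim) == 0.0

    def test_single_point_weighted_square(self):
        obs = meas_frame([(24.0, "Total", 10.0, 2.0)])
        sim = curve_frame([24.0], Total=[12.0])
        assert objective(obs, sim) == pytest.approx(1.0)

    def test_variance_floor(self):
        obs = meas_frame([(24.0, "Total", 10.0, 0.0)])
        sim = curve_frame([24.0], Total=[11.0])
        assert objective(obs, sim) == pytest.approx(1.0)  # sigma^2 floored at 1

    def test_missing_point_raises_contract_error(self):
        obs = meas_frame([(24.0, "Total", 10.0, 2.0), (48.0, "Total", 5.0, 2.0)])
        sim = curve_frame([24.0], Total=[10.0])
        with pytest.raises(ContractError, match="48"):
            objective(obs, sim)


class TestCalibration:
    def test_exact_multiple_recovers_scale(self):
        unit = curve_frame([2.0, 24.0], Total=[10.0, 20.0])
        obs = meas_frame([(2.0, "Total", 35.0, 2.0), (24.0, "Total", 70.0, 2.0)])
        lam, mu = calibrate_influx(obs, unit)
        assert lam == pytest.approx(3.5)
        assert mu == 0.0

    def test_zero_observation_gives_zero_scale(self):
        unit = curve_frame([2.0], Total=[10.0])
        obs = meas_frame([(2.0, "Total", 0.0, 1.0)])
        lam, _ = calibrate_influx(obs, unit)
        assert lam == 0.0

    def test_all_zero_unit_curve_rejected(self):
        unit = curve_frame([2.0], Total=[0.0])
        obs = meas_frame([(2.0, "Total", 5.0, 1.0)])
        with pytest.raises(ValueError, match="undefined"):
            calibrate_influx(obs, unit)

    def test_two_stream_separation(self):
        ua = curve_frame([2.0, 24.0], NSC=[0.0, 0.0], ANP=[10.0, 5.0])
        un = curve_frame([2.0, 24.0], NSC=[4.0, 2.0], ANP=[0.0, 1.0])
        obs = meas_frame(
            [
                (2.0, "ANP", 20.0, 1.0),
                (24.0, "ANP", 11.0, 1.0),
                (2.0, "NSC", 4.0, 1.0),
                (24.0, "NSC", 2.0, 1.0),
            ]
        )
        lam, mu = calibrate_influx(obs, ua, un)
        assert lam == pytest.approx(2.0, rel=1e-6)
        assert mu == pytest.approx(1.0, rel=1e-6)

    def test_calibrated_total_matches_two_hour_observation(self, best_fit):
        """Best-fit parameters with calibrated influx reproduce the observed
        total of 2690 BrdU+ cells at 2 h within two sem (320)."""
        from neurocascade import adjust_dataset, load_observed, measurements

        obs = load_observed()
        meas = measurements(obs, adjust_dataset(obs))
        eng = ExpectationEngine(np.unique(meas["time_h"]), step=0.5)
        lam, mu = calibrate_influx(meas, *eng.unit_curves(best_fit))
        fitted = eng.curves(best_fit, lam, mu)
        total_2h = float(fitted.loc[np.isclose(fitted.time_h, 2.0), "Total"].iloc[0])
        assert abs(total_2h - 2690.0) <= 2 * 320.0


class TestCodec:
    def test_round_trip_within_half_grid_step(self, best_fit):
        codec = ParameterCodec(best_fit)
        bits = codec.encode(best_fit)
        again = codec.decode(bits)
        d0, d1 = best_fit.to_dict(), again.to_dict()
        for name in codec.names:
            kind, lo, hi = codec.ranges[name]
            if kind == "int":
                assert d1[name] == round(d0[name])
            else:
                half_step = (hi - lo) / (2**codec.bits - 1) / 2
                assert abs(d1[name] - d0[name]) <= half_step + 1e-12

    def test_encode_decode_identity_on_grid(self, best_fit):
        codec = ParameterCodec(best_fit, names=["d_anp", "d_nb", "t_nb_mean"])
        rng = np.random.default_rng(0)
        for _ in range(20):
            bits = (rng.random(codec.n_bits) < 0.5).astype(np.uint8)
            params = codec.decode(bits)
            np.testing.assert_array_equal(codec.encode(params), bits)

    def test_death_rate_grid_stays_in_range(self, best_fit):
        codec = ParameterCodec(best_fit, names=["d_nb"], bits=8)
        for code in (0, 127, 255):
            bits = np.array([(code >> j) & 1 for j in range(8)], dtype=np.uint8)
            v = codec.decode(bits).nb.death_rate
            assert 0.0 <= v <= 0.99

    def test_single_bit_binary_range(self, best_fit):
        codec = ParameterCodec(best_fit, names=["d_s"], bits=1)
        vals = {codec.decode(np.array([b], dtype=np.uint8)).anp_s.death_rate
                for b in (0, 1)}
        assert vals == {0.0, 0.99}

    def test_out_of_range_parameter_named_in_error(self, best_fit):
        codec = ParameterCodec(best_fit, names=["t_nb_mean"])
        bad = best_fit.replace_values(t_nb_mean=500.0)
        with pytest.raises(ValueError, match="t_nb_mean"):
            codec.encode(bad)

    def test_division_bounds_kept_ordered(self, best_fit):
        codec = ParameterCodec(
            best_fit, names=["min_divisions_anp", "max_divisions_anp"], bits=3
        )
        rng = np.random.default_rng(1)
        for _ in range(50):
            bits = (rng.random(codec.n_bits) < 0.5).astype(np.uint8)
            law = codec.decode(bits).anp_divisions
            assert law.min_divisions <= law.max_divisions


@pytest.fixture(scope="module")
def tiny_problem(best_fit):
    """Noise-free synthetic measurements from known parameters, coarse engine."""
    truth = best_fit.replace_values(influx=30.0, nsc_activation=1.5, d_nb=0.8)
    tps = np.array([2.0, 24.0, 96.0, 360.0, 768.0])
    eng = ExpectationEngine(tps, step=2.0)
    fitted = eng.curves(truth, truth.influx, truth.nsc_activation_rate)
    rows = []
    for _, r in fitted.iterrows():
        for cls in ("Total", "NSC", "ANP", "NB", "GC"):
            if r[cls] > 0.5:
                rows.append((r.time_h, cls, r[cls], max(0.1 * r[cls], 1.0)))
    return truth, pd.DataFrame(rows, columns=["time_h", "cls", "mean", "sem"]), eng


class TestGeneticAlgorithm:
    def test_same_seed_identical_results(self, best_fit, tiny_problem):
        truth, meas, eng = tiny_problem
        codec = ParameterCodec(truth, names=["d_nb"])
        cfg = GAConfig(population=8, generations=3, seed=99)
        r1 = run_ga(cfg, meas, codec, engine=eng)
        r2 = run_ga(cfg, meas, codec, engine=eng)
        assert r1.objective == r2.objective
        assert r1.best_params.to_dict() == r2.best_params.to_dict()
        assert r1.history == r2.history

    def test_best_objective_history_non_increasing(self, tiny_problem):
        truth, meas, eng = tiny_problem
        codec = ParameterCodec(truth, names=["d_nb", "d_anp"])
        cfg = GAConfig(population=10, generations=5, seed=3, elitism=2)
        res = run_ga(cfg, meas, codec, engine=eng)
        assert all(b <= a + 1e-12 for a, b in zip(res.history, res.history[1:]))
        assert res.objective == res.history[-1]

    def test_truth_beats_death_rate_perturbations(self, tiny_problem):
        """Identifiability smoke test: on noise-free curves the generating
        parameters score at least as well as +/-0.2 death-rate shifts."""
        truth, meas, eng = tiny_problem
        obj_truth, _, _ = eng.evaluate(truth, meas)
        rng = np.random.default_rng(4)
        for _ in range(6):
            delta = rng.choice([-0.2, 0.2], size=2)
            pert = truth.replace_values(
                d_anp=float(np.clip(truth.d_anp + delta[0], 0, 0.99)),
                d_nb=float(np.clip(truth.nb.death_rate + delta[1], 0, 0.99)),
            )
            obj_pert, _, _ = eng.evaluate(pert, meas)
            assert obj_truth <= obj_pert + 1e-9
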