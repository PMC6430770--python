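import numpy as np
import pytest

import spatialflux as sf
from spatialflux.kfp import (
    A_EQ,
    FLUX_NAMES,
    FluxVector,
    ForcingSet,
    LabelingDataset,
    MassBalanceError,
    ModelConfig,
    _random_feasible_start,
    objective_ssr,
    simulate_labeling,
    simulate_labeling_euler,
)


@pytest.fixture(scope="module")
def cfg():
    return sf.default_synthetic_config(seed=1)


@pytest.fixture(scope="module")
def mcfg(cfg):
    return cfg.model_config()


@pytest.fixture(scope="module")
def forcings(cfg):
    return sf.generate_forcings(cfg)


class TestFluxVector:
    def test_balance_residuals_zero_for_default_truth(self, cfg):
        assert np.abs(cfg.true_fluxes.mass_balance_residuals()).max() < 1e-12

    def test_unbalanced_vector_rejected_by_simulator(self, mcfg, forcings):
        bad = FluxVector(1, 0, 0, 0, 0, 0, 0, 0, 0, 0)
        with pytest.raises(MassBalanceError):
            simulate_labeling(bad, mcfg, forcings, [5.0])

    def test_array_round_trip(self, cfg):
        x = cfg.true_fluxes.as_array()
        assert FluxVector.from_array(x).as_array() == pytest.approx(x)


class TestSimulateLabeling:
    def test_zero_forcings_give_zero_labeling(self, cfg, mcfg):
        times = np.array([0.0, 2.0, 30.0, 180.0])
        zero = ForcingSet(
            {k: (times, np.zeros_like(times)) for k in
             ("akg5_mito", "akg5_cyto", "mal_mito")}
        )
        y = simulate_labeling(cfg.true_fluxes, mcfg, zero, times)
        assert np.abs(y).max() == 0.0

    def test_constant_forcing_converges_to_linear_fixed_point(self, cfg, mcfg):
        # m+5 block with X_akg5 = 0.5 in both compartments, malate unlabeled
        const = ForcingSet(
            {
                "akg5_mito": ([0.0, 0.01], [0.0, 0.5]),
                "akg5_cyto": ([0.0, 0.01], [0.0, 0.5]),
                "mal_mito": ([0.0, 0.01], [0.0, 0.0]),
            }
        )
        v = cfg.true_fluxes
        y = simulate_labeling(v, mcfg, const, [5000.0])
        # oracle: steady state of dY/dt = A Y + F = 0 solved independently
        w = v.as_array() / 60.0
        s_red = w[5] + w[7]
        r_m = w[0] + s_red + w[2]
        r_c = w[1] + w[3]
        um, uc = mcfg.u_cit_mito, mcfg.u_cit_cyto
        a = np.array([[-r_m / um, w[2] / um], [w[1] / uc, -r_c / uc]])
        f5 = np.array([s_red * 0.5 / um, w[3] * 0.5 / uc])
        fixed = np.linalg.solve(a, -f5)
        assert abs(y[0, 1] - fixed[0]) < 1e-6
        assert abs(y[0, 3] - fixed[1]) < 1e-6

    def test_halving_pools_compresses_time_axis(self, cfg, forcings):
        # with forcings frozen at their plateaus the system is autonomous
        # after the knots; compare at late times against the rescaling law
        times = np.array([0.0, 1.0])
        plateau = ForcingSet(
            {
                "akg5_mito": (times, [0.0, 0.4]),
                "akg5_cyto": (times, [0.0, 0.3]),
                "mal_mito": (times, [0.0, 0.2]),
            }
        )
        base = cfg.model_config()
        half = cfg.model_config(
            u_cit_mito=base.u_cit_mito / 2, u_cit_cyto=base.u_cit_cyto / 2
        )
        t_late = np.array([40.0, 80.0])
        y_half = simulate_labeling(cfg.true_fluxes, half, plateau, t_late)
        y_base = simulate_labeling(cfg.true_fluxes, base, plateau, 2 * t_late)
        assert np.abs(y_half - y_base).max() < 5e-4

    @pytest.mark.parametrize("variant", ["WT", "SDHKO"])
    def test_matches_explicit_euler(self, cfg, forcings, variant):
        mcfg = cfg.model_config(variant=variant)
        rng = np.random.default_rng(3)
        t = np.array([2.0, 5.0, 10.0, 20.0, 30.0])
        for _ in range(3):
            x = _random_feasible_start(rng, mcfg)
            y = simulate_labeling(x, mcfg, forcings, t, check_balance=False)
            ye = simulate_labeling_euler(x, mcfg, forcings, t, dt=0.001)
            assert np.abs(y - ye).max() < 1e-4

    def test_labeling_bounded_by_max_forcing(self, cfg, mcfg, forcings):
        t = np.linspace(1, 180, 30)
        y = simulate_labeling(cfg.true_fluxes, mcfg, forcings, t)
        max_force = max(v.max() for _, v in forcings.curves.values())
        assert y.min() >= 0.0
        assert y.max() <= max_force + 1e-9


class TestObjective:
    def test_self_generated_data_scores_zero(self, cfg, mcfg, forcings):
        t = np.asarray(mcfg.fit_times)
        y = simulate_labeling(cfg.true_fluxes, mcfg, forcings, t)
        data = LabelingDataset(
            times=t,
            x_mito=y[:, :2],
            x_cyto=y[:, 2:],
            sd_mito=np.full((t.size, 2), 0.01),
            sd_cyto=np.full((t.size, 2), 0.01),
        )
        assert objective_ssr(cfg.true_fluxes, data, mcfg, forcings) == pytest.approx(
            0.0, abs=1e-16
        )

    def test_one_sigma_residuals_count_terms(self, cfg, mcfg, forcings):
        t = np.asarray(mcfg.fit_times)
        y = simulate_labeling(cfg.true_fluxes, mcfg, forcings, t)
        sd = 0.01
        data = LabelingDataset(
            times=t,
            x_mito=y[:, :2] + sd,
            x_cyto=y[:, 2:] + sd,
            sd_mito=np.full((t.size, 2), sd),
            sd_cyto=np.full((t.size, 2), sd),
        )
        # 7 times x 2 isotopomers x 2 compartments, each exactly 1 sigma off
        assert objective_ssr(cfg.true_fluxes, data, mcfg, forcings) == pytest.approx(
            28.0, rel=1e-9
        )
        wide = LabelingDataset(
            times=t,
            x_mito=data.x_mito,
            x_cyto=data.x_cyto,
            sd_mito=np.full((t.size, 2), 2 * sd),
            sd_cyto=np.full((t.size, 2), 2 * sd),
        )
        assert objective_ssr(cfg.true_fluxes, wide, mcfg, forcings) == pytest.approx(
            7.0, rel=1e-9
        )

    def test_invariant_to_timepoint_order(self, cfg, mcfg, forcings):
        t = np.asarray(mcfg.fit_times)
        y = simulate_labeling(cfg.true_fluxes, mcfg, forcings, t)
        perm = np.array([3, 0, 6, 1, 5, 2, 4])
        data = LabelingDataset(
            times=t[perm],
            x_mito=y[perm, :2] + 0.005,
            x_cyto=y[perm, 2:],
            sd_mito=np.full((t.size, 2), 0.01),
            sd_cyto=np.full((t.size, 2), 0.01),
        )
        sorted_data = LabelingDataset(
            times=t,
            x_mito=y[:, :2] + 0.005,
            x_cyto=y[:, 2:],
            sd_mito=np.full((t.size, 2), 0.01),
            sd_cyto=np.full((t.size, 2), 0.01),
        )
        a = objective_ssr(cfg.true_fluxes, data, mcfg, forcings)
        b = objective_ssr(cfg.true_fluxes, sorted_data, mcfg, forcings)
        assert a == pytest.approx(b, rel=1e-12)

    def test_missing_fit_time_raises(self, cfg, mcfg, forcings):
        t = np.asarray(mcfg.fit_times)[:-1]
        data = LabelingDataset(
            times=t,
            x_mito=np.zeros((t.size, 2)),
            x_cyto=np.zeros((t.size, 2)),
            sd_mito=np.full((t.size, 2), 0.01),
            sd_cyto=np.full((t.size, 2), 0.01),
        )
        with pytest.raises(ValueError, match="missing"):
            objective_ssr(cfg.true_fluxes, data, mcfg, forcings)


class TestFitAndProfile:
    @pytest.fixture(scope="class")
    def noiseless_fit(self, cfg, mcfg, forcings):
        t = np.asarray(mcfg.fit_times)
        y = simulate_labeling(cfg.true_fluxes, mcfg, forcings, t)
        data = LabelingDataset(
            times=t,
            x_mito=y[:, :2],
            x_cyto=y[:, 2:],
            sd_mito=np.full((t.size, 2), 0.003),
            sd_cyto=np.full((t.size, 2), 0.003),
        )
        fit = sf.fit_fluxes(data, mcfg, forcings, n_starts=5, seed=0)
        return data, fit

    def test_noiseless_recovery_of_identifiable_fluxes(self, cfg, noiseless_fit):
        _, fit = noiseless_fit
        true = cfg.true_fluxes
        est = fit.best
        assert fit.ssr < 1e-6
        for name in ("v_CS", "v_CIT_F", "v_CIT_B", "v_IDH1_R"):
            assert getattr(est, name) == pytest.approx(
                getattr(true, name), rel=0.02
            )
        assert est.v_IDH2_R + est.v_IDH3_R == pytest.approx(
            true.v_IDH2_R + true.v_IDH3_R, rel=0.02
        )

    def test_fit_is_reproducible(self, cfg, mcfg, forcings, noiseless_fit):
        data, fit = noiseless_fit
        again = sf.fit_fluxes(data, mcfg, forcings, n_starts=5, seed=0)
        assert again.ssr == fit.ssr
        assert np.array_equal(again.best.as_array(), fit.best.as_array())

    def test_boundary_truth_recovered(self, cfg, forcings):
        # reductive IDH1 switched off in the generating fluxes
        v0 = FluxVector(0.48, 0.62, 0.60, 0.0, 0.0, 0.08, 0.01, 0.01, 0.54, 0.02)
        v0.validate()
        mcfg = cfg.model_config(ratio_bounds={})
        t = np.asarray(mcfg.fit_times)
        y = simulate_labeling(v0, mcfg, forcings, t)
        data = LabelingDataset(
            times=t, x_mito=y[:, :2], x_cyto=y[:, 2:],
            sd_mito=np.full((t.size, 2), 0.003),
            sd_cyto=np.full((t.size, 2), 0.003),
        )
        fit = sf.fit_fluxes(data, mcfg, forcings, n_starts=8, seed=1)
        assert fit.best.v_IDH1_R < 0.01 * fit.best.v_CS

    def test_infeasible_ratio_bounds_rejected(self, cfg, mcfg, forcings, noiseless_fit):
        data, _ = noiseless_fit
        bad = cfg.model_config(ratio_bounds={"IDH2": (3.0, 1.0)})
        with pytest.raises(ValueError, match="infeasible"):
            sf.fit_fluxes(data, bad, forcings, n_starts=1, seed=0)

    def test_profile_interval_contains_mle(self, cfg, mcfg, forcings, noiseless_fit):
        data, fit = noiseless_fit
        ci = sf.profile_ci(fit, "v_CS", data, mcfg, forcings)
        assert ci.lower <= fit.best.v_CS <= ci.upper
        assert ci.upper > ci.lower
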