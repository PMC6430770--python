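import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spatialflux.deconvolution import (
    ContaminationModel,
    deconvolve_mid,
    deconvolve_pools,
    deconvolve_pools_mc,
)
from spatialflux.mid import MassIsotopomerDistribution

CM = ContaminationModel(alpha=0.13, beta=0.11, sd=0.03)


def symbolic_solve(p_m, p_c, alpha, beta):
    """Independent oracle: solve the 2x2 mixing system numerically."""
    a = np.array([[1.0, beta], [alpha, 1.0]])  # rows: P_c, P_m equations
    x_c, x_m = np.linalg.solve(a, np.array([p_c, p_m]))
    return x_m * (1 + beta), x_c * (1 + alpha)


class TestContaminationModel:
    @pytest.mark.parametrize(
        "kwargs", [{"alpha": -0.1}, {"beta": 1.0}, {"sd": -1.0}]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ContaminationModel(**kwargs)


class TestDeconvolvePools:
    def test_zero_contamination_is_identity(self):
        cm0 = ContaminationModel(alpha=0.0, beta=0.0, sd=0.0)
        dp = deconvolve_pools(0.3, 0.7, cm0)
        assert dp.p_mito == pytest.approx(0.3, abs=1e-15)
        assert dp.p_cyto == pytest.approx(0.7, abs=1e-15)

    def test_pure_cytosolic_species_has_zero_mito_pool(self):
        p_c = 0.8
        dp = deconvolve_pools(CM.alpha * p_c, p_c, CM)
        assert dp.p_mito == pytest.approx(0.0, abs=1e-12)

    def test_reference_values_for_equal_fraction_pools(self):
        # exact closed form: (0.5 - 0.13*0.5) * 1.11 / (1 - 0.0143) etc.
        dp = deconvolve_pools(0.5, 0.5, CM)
        assert dp.p_mito == pytest.approx(0.4898549, abs=1e-6)
        assert dp.p_cyto == pytest.approx(0.5101451, abs=1e-6)
        assert dp.p_mito + dp.p_cyto == pytest.approx(1.0, abs=1e-12)

    def test_negative_deconvolution_reported_and_clipped(self):
        with pytest.warns(UserWarning):
            dp = deconvolve_pools(0.01, 0.9, CM)
        assert dp.negative_flag
        assert dp.p_mito < 0
        assert dp.p_mito_clipped == 0.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=0.0, max_value=10.0),
        st.floats(min_value=0.0, max_value=10.0),
        st.floats(min_value=0.0, max_value=0.5),
        st.floats(min_value=0.0, max_value=0.5),
    )
    def test_matches_oracle_and_conserves_total(self, p_m, p_c, alpha, beta):
        cm = ContaminationModel(alpha=alpha, beta=beta, sd=0.0)
        dp = deconvolve_pools(p_m, p_c, cm)
        om, oc = symbolic_solve(p_m, p_c, alpha, beta)
        assert dp.p_mito == pytest.approx(om, abs=1e-9)
        assert dp.p_cyto == pytest.approx(oc, abs=1e-9)
        assert dp.p_mito + dp.p_cyto == pytest.approx(p_m + p_c, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=0.3, max_value=1.0),
        st.floats(min_value=0.01, max_value=0.2),
    )
    def test_monotone_in_measured_pools(self, p_m, delta):
        p_c = 0.5
        base = deconvolve_pools(p_m, p_c, CM).p_mito
        assert deconvolve_pools(p_m + delta, p_c, CM).p_mito > base
        assert deconvolve_pools(p_m, p_c + delta, CM).p_mito < base


class TestDeconvolvePoolsMC:
    def test_zero_noise_equals_deterministic(self):
        cm0 = ContaminationModel(alpha=0.13, beta=0.11, sd=0.0)
        det = deconvolve_pools(0.4, 0.6, cm0)
        mc = deconvolve_pools_mc(0.4, 0.6, (0.0, 0.0), cm0, n_draws=500, seed=3)
        assert mc.p_mito == pytest.approx(det.p_mito, abs=1e-12)
        assert mc.sd_mito == 0.0

    def test_mc_mean_converges_to_deterministic(self):
        det = deconvolve_pools(0.4, 0.6, CM)
        mc = deconvolve_pools_mc(0.4, 0.6, (0.02, 0.02), CM, n_draws=20_000, seed=7)
        tol = 3 * mc.sd_mito / np.sqrt(20_000)
        # small bias from truncation at 0 is far below this tolerance here
        assert abs(mc.p_mito - det.p_mito) < max(tol, 5e-3)
        assert mc.sd_mito > 0

    def test_same_seed_is_bit_identical(self):
        a = deconvolve_pools_mc(0.4, 0.6, (0.05, 0.05), CM, n_draws=2000, seed=11)
        b = deconvolve_pools_mc(0.4, 0.6, (0.05, 0.05), CM, n_draws=2000, seed=11)
        assert a.p_mito == b.p_mito and a.sd_mito == b.sd_mito

    def test_minimum_draws_enforced(self):
        with pytest.raises(ValueError):
            deconvolve_pools_mc(0.4, 0.6, (0.0, 0.0), CM, n_draws=10, seed=0)


class TestDeconvolveMID:
    def test_zero_contamination_returns_inputs(self):
        cm0 = ContaminationModel(alpha=0.0, beta=0.0, sd=0.0)
        im = MassIsotopomerDistribution("cit", [0.7, 0.2, 0.1])
        ic = MassIsotopomerDistribution("cit", [0.5, 0.4, 0.1])
        dm, dc = deconvolve_mid(im, ic, 0.3, 0.7, cm0)
        assert np.allclose(dm.fractions, im.fractions, atol=1e-12)
        assert np.allclose(dc.fractions, ic.fractions, atol=1e-12)

    def test_identical_composition_unchanged_by_contamination(self):
        mid = MassIsotopomerDistribution("cit", [0.6, 0.3, 0.1])
        dm, dc = deconvolve_mid(mid, mid, 0.3, 0.7, CM)
        assert np.allclose(dm.fractions, mid.fractions, atol=1e-12)
        assert np.allclose(dc.fractions, mid.fractions, atol=1e-12)

    def test_componentwise_oracle(self):
        im = MassIsotopomerDistribution("cit", [0.9, 0.1])
        ic = MassIsotopomerDistribution("cit", [0.5, 0.5])
        p_m, p_c = 0.3, 0.7
        with pytest.warns(UserWarning, match="clipping"):
            dm, dc = deconvolve_mid(im, ic, p_m, p_c, CM)
        vm_pools = []
        vc_pools = []
        for j in range(2):
            om, oc = symbolic_solve(
                im.fractions[j] * p_m, ic.fractions[j] * p_c, CM.alpha, CM.beta
            )
            vm_pools.append(om)
            vc_pools.append(oc)
        vm_pools = np.clip(vm_pools, 0, None)
        vc_pools = np.clip(vc_pools, 0, None)
        assert np.allclose(dm.fractions, vm_pools / vm_pools.sum(), atol=1e-9)
        assert np.allclose(dc.fractions, vc_pools / vc_pools.sum(), atol=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_round_trip_mix_then_deconvolve_recovers_truth(self, seed):
        rng = np.random.default_rng(seed)
        true_m = rng.dirichlet(np.ones(5))
        true_c = rng.dirichlet(np.ones(5))
        pm_true, pc_true = rng.uniform(0.1, 0.9, size=2)
        x_m = pm_true / (1 + CM.beta)
        x_c = pc_true / (1 + CM.alpha)
        p_m_meas = x_m + CM.alpha * x_c
        p_c_meas = x_c + CM.beta * x_m
        im = (x_m * true_m + CM.alpha * x_c * true_c) / p_m_meas
        ic = (x_c * true_c + CM.beta * x_m * true_m) / p_c_meas
        dm, dc = deconvolve_mid(
            MassIsotopomerDistribution("m", im),
            MassIsotopomerDistribution("m", ic),
            p_m_meas,
            p_c_meas,
            CM,
        )
        assert np.abs(dm.fractions - true_m).max() < 1e-9
        assert np.abs(dc.fractions - true_c).max() < 1e-9

    def test_strongly_negative_component_raises(self):
        im = MassIsotopomerDistribution("cit", [0.05, 0.95])
        ic = MassIsotopomerDistribution("cit", [0.95, 0.05])
        # mito fraction dominated by cytosolic contamination: impossible mix
        with pytest.raises(ValueError):
            deconvolve_mid(im, ic, 0.1, 1e-6, CM)
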