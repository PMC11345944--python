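"""Population PK core: covariate scaling, sampling, simulation, NCA, fitting."""

from __future__ import annotations

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given
from hypothesis import strategies as st
from scipy.linalg import expm

from gastropk import pkcore
from gastropk.pkcore import (
    CLINICAL_TIMES,
    ETA_ORDER,
    IndividualPKParams,
    PlasmaProfile,
    covariate_scale,
    default_poppk,
    nca,
    sample_individuals,
    simulate_plasma,
    two_compartment_oral_conc,
)


class TestCovariateScale:
    def test_reference_weight_recovers_typical_values(self, pop):
        ind = covariate_scale(pop, 70.0)
        assert ind.cl_f == pytest.approx(75.23)
        assert ind.v1_f == pytest.approx(86.69)
        assert ind.q_f == pytest.approx(41.43)
        assert ind.v2_f == pytest.approx(31.38)

    def test_power_law_on_clearance_and_central_volume_only(self, pop):
        ind = covariate_scale(pop, 84.0)
        assert ind.cl_f == pytest.approx(75.23 * 1.2**1.21)
        assert ind.v1_f == pytest.approx(86.69 * 1.2**0.73)
        # Q/F and V2/F carry no weight covariate
        assert ind.q_f == pytest.approx(41.43)
        assert ind.v2_f == pytest.approx(31.38)

    def test_zero_exponent_identity(self, pop):
        flat = replace(pop, beta_cl=0.0)
        assert covariate_scale(flat, 120.0).cl_f == pytest.approx(75.23)

    def test_formulation_absorption_parameters(self, pop):
        tab = covariate_scale(pop, 70.0, formulation="tablet")
        cap = covariate_scale(pop, 70.0, formulation="capsule")
        assert (tab.t_lag, tab.k_a) == pytest.approx((0.157, 5.08))
        assert (cap.t_lag, cap.k_a) == pytest.approx((0.36, 4.88))

    def test_eta_acts_multiplicatively_on_log_scale(self, pop):
        eta = np.array([0.0, 0.0, np.log(2.0), 0.0, 0.0, 0.0])
        assert covariate_scale(pop, 70.0, eta).cl_f == pytest.approx(2 * 75.23)

    def test_nonpositive_weight_rejected(self, pop):
        with pytest.raises(ValueError):
            covariate_scale(pop, 0.0)


class TestSampling:
    def test_seeded_reproducibility_and_default_weight(self, pop):
        a = sample_individuals(pop, 25, rng=123)
        b = sample_individuals(pop, 25, rng=123)
        assert all(x.cl_f == y.cl_f and x.k_a == y.k_a for x, y in zip(a, b))
        assert all(x.weight == 70.0 for x in a)

    def test_lognormal_cv_matches_published_variability(self, pop):
        # omega^2 = ln(1 + CV^2); check the realized CL/F spread at n=20000
        inds = sample_individuals(pop, 20_000, rng=7)
        cl = np.array([i.cl_f for i in inds])
        cv = cl.std(ddof=1) / cl.mean() * 100.0
        assert cv == pytest.approx(37.61, abs=1.5)
        sd_log = np.log(cl).std(ddof=1)
        assert sd_log == pytest.approx(np.sqrt(np.log1p(0.3761**2)), rel=0.03)

    def test_zero_bsv_collapses_to_typical(self, pop):
        flat = replace(
            pop,
            bsv={k: 0.0 for k in pop.bsv},
            absorption={
                k: replace(a, bsv_t_lag=0.0, bsv_k_a=0.0)
                for k, a in pop.absorption.items()
            },
        )
        inds = sample_individuals(flat, 5, rng=0)
        assert all(i.cl_f == pytest.approx(75.23) for i in inds)

    def test_non_psd_correlation_rejected(self, pop):
        bad = np.eye(len(ETA_ORDER))
        bad[0, 1] = bad[1, 0] = 1.5
        with pytest.raises(ValueError):
            replace(pop, eta_corr=bad)


def _expm_oracle(ind: IndividualPKParams, dose: float, times: np.ndarray) -> np.ndarray:
    """Independent matrix-exponential solution of the linear oral model."""
    k10, k12, k21 = ind.micro_constants
    m = np.array(
        [
            [-ind.k_a, 0.0, 0.0],
            [ind.k_a, -(k10 + k12), k21],
            [0.0, k12, -k21],
        ]
    )
    out = np.zeros_like(times, dtype=float)
    y0 = np.array([dose, 0.0, 0.0])
    for i, t in enumerate(times):
        if t > ind.t_lag:
            out[i] = (expm(m * (t - ind.t_lag)) @ y0)[1] / ind.v1_f * 1000.0
    return out


class TestSimulation:
    @pytest.mark.parametrize("formulation", ["tablet", "capsule"])
    def test_ode_analytic_and_expm_oracle_agree(self, pop, formulation):
        ind = covariate_scale(pop, 70.0, formulation=formulation)
        times = np.linspace(0.0, 24.0, 97)
        ode = simulate_plasma(ind, 100.0, times, formulation=formulation)
        ana = simulate_plasma(ind, 100.0, times, formulation=formulation, method="analytic")
        oracle = _expm_oracle(ind, 100.0, times)
        scale = oracle.max()
        assert np.allclose(ode.concentrations, oracle, atol=1e-6 * scale, rtol=1e-6)
        assert np.allclose(ana.concentrations, oracle, atol=1e-6 * scale, rtol=1e-6)

    def test_dose_linearity(self, typical):
        t = CLINICAL_TIMES
        c1 = simulate_plasma(typical, 50.0, t).concentrations
        c2 = simulate_plasma(typical, 100.0, t).concentrations
        assert np.allclose(2.0 * c1, c2, rtol=1e-7)

    def test_zero_dose_and_pre_lag_are_zero(self, typical):
        prof = simulate_plasma(typical, 0.0, CLINICAL_TIMES)
        assert np.all(prof.concentrations == 0.0)
        dense = simulate_plasma(typical, 100.0, np.linspace(0.0, 0.3, 10))
        assert np.all(dense.concentrations[dense.times <= typical.t_lag] == 0.0)

    @given(
        ka=st.floats(0.5, 20.0),
        cl=st.floats(10.0, 300.0),
        v1=st.floats(20.0, 300.0),
        q=st.floats(5.0, 150.0),
        v2=st.floats(10.0, 200.0),
        tlag=st.floats(0.0, 0.8),
    )
    def test_analytic_route_matches_ode_for_random_parameters(
        self, ka, cl, v1, q, v2, tlag
    ):
        ind = IndividualPKParams(
            subject="h", weight=70.0, t_lag=tlag, k_a=ka, cl_f=cl, v1_f=v1, q_f=q, v2_f=v2
        )
        times = np.linspace(0.1, 12.0, 40)
        ode = simulate_plasma(ind, 100.0, times).concentrations
        ana = two_compartment_oral_conc(times, ind, 100.0)
        assert np.all(np.isfinite(ana)) and np.all(ana >= 0.0)
        assert np.allclose(ode, ana, rtol=1e-5, atol=1e-5 * max(ana.max(), 1.0))


class TestResidualErrorAndNCA:
    def test_zero_sigma_is_identity(self, pop, typical):
        clean = simulate_plasma(typical, 100.0, CLINICAL_TIMES, method="analytic")
        noiseless = replace(pop, sigma_add=0.0, sigma_prop=0.0)
        noisy = pkcore.add_residual_error(clean, noiseless, rng=0)
        assert np.array_equal(noisy.concentrations, clean.concentrations)

    def test_monte_carlo_error_magnitude(self, pop, rng):
        # f = 10 everywhere: SD of y should be sqrt(sigma_add^2 + (f sigma_prop)^2)
        f = PlasmaProfile(np.arange(1.0, 20_001.0), np.full(20_000, 10.0))
        y = pkcore.add_residual_error(f, pop, rng).concentrations
        assert y.std(ddof=1) == pytest.approx(np.hypot(0.70, 10 * 0.12), rel=0.03)
        assert np.all(y >= 0.0)

    def test_nca_hand_example(self):
        prof = PlasmaProfile(np.array([0.0, 1.0, 2.0]), np.array([0.0, 2.0, 1.0]))
        res = nca(prof)
        assert res.auc_last == pytest.approx(2.5)
        assert res.c_max == pytest.approx(2.0)
        assert res.t_max == pytest.approx(1.0)
        # C(0.5 h) by linear interpolation
        assert res.c_half_hour == pytest.approx(1.0)

    def test_nca_tmax_earliest_tie_and_monotone_profile(self):
        tie = nca(PlasmaProfile(np.array([0.5, 1.0, 1.5]), np.array([3.0, 3.0, 1.0])))
        assert tie.t_max == pytest.approx(0.5)
        mono = nca(PlasmaProfile(np.array([0.5, 1.0, 2.0]), np.array([5.0, 4.0, 3.0])))
        assert mono.t_max == pytest.approx(0.5)

    def test_nca_flat_zero_profile(self):
        res = nca(PlasmaProfile(np.array([0.0, 1.0]), np.array([0.0, 0.0])))
        assert res.c_max == 0.0 and res.auc_last == 0.0


class TestFitIndividual:
    def test_noise_free_self_consistency(self, pop, typical_tablet):
        prof = simulate_plasma(
            typical_tablet, 100.0, CLINICAL_TIMES, formulation="tablet", method="analytic"
        )
        fit = pkcore.fit_individual(prof, typical_tablet)
        assert fit.converged
        for name in ("t_lag", "k_a", "cl_f", "v1_f", "q_f", "v2_f"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(typical_tablet, name), rel=1e-4
            )

    def test_noisy_median_clearance_within_ten_percent(self, pop):
        from gastropk import synthdata

        profiles, inds = synthdata.generate_poppk_trial(n=20, formulation="tablet", rng=11)
        typ = covariate_scale(pop, 70.0)
        ratios = [
            pkcore.fit_individual(p, typ).params.cl_f / ind.cl_f
            for p, ind in zip(profiles, inds)
        ]
        assert abs(np.median(ratios) - 1.0) < 0.10

    def test_tablet_reference_bounds_respected(self, pop, typical, typical_tablet):
        prof = simulate_plasma(typical, 100.0, CLINICAL_TIMES, method="analytic")
        noisy = pkcore.add_residual_error(prof, pop, rng=4)
        fit = pkcore.fit_individual(noisy, typical, tablet_ref=typical_tablet)
        for name in ("cl_f", "v1_f", "q_f", "v2_f"):
            ref = getattr(typical_tablet, name)
            assert 0.8 * ref - 1e-9 <= getattr(fit.params, name) <= 1.2 * ref + 1e-9

    def test_all_zero_observations_flagged_not_raised(self, typical):
        prof = PlasmaProfile(CLINICAL_TIMES, np.zeros_like(CLINICAL_TIMES))
        fit = pkcore.fit_individual(prof, typical)
        assert not fit.converged
        assert fit.message

    def test_too_few_points_rejected(self, typical):
        with pytest.raises(ValueError):
            pkcore.fit_individual(
                PlasmaProfile(np.array([0.5, 1.0, 2.0]), np.array([1.0, 2.0, 1.0])), typical
            )
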