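"""Estimation machinery: degenerate recovery, oracle likelihood, stepwise
covariate logic, bootstrap mechanics, shrinkage identities, pc-VPC."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from piperpk.estimation import (
    FitResult,
    _conc_batch,
    _Fitter,
    _LOG2PI,
    _make_spec,
    _Problem,
    bootstrap,
    covariate_step,
    fit,
    neg2ll,
    pcvpc,
    shrinkage,
)
from piperpk.population import PopulationParameters
from piperpk.synthetic import CohortSpec, generate


def gauss_hermite_neg2ll(dataset, pop, order=91):
    """Independent likelihood oracle: dense tensor Gauss-Hermite quadrature
    over (eta_CL, eta_V); requires gamma = 0 so the integral is 2-D."""
    assert pop.gamma_cl == 0.0
    from numpy.polynomial.hermite_e import hermegauss

    prob = _Problem(dataset)
    fitter = _Fitter(prob, _make_spec(prob, ("crcl",), {"crcl": pop.crcl_ref}))
    base_cl = fitter.base_cl(pop.theta_cl, np.array([pop.beta_crcl]))
    nodes, wts = hermegauss(order)
    wnorm = wts / np.sqrt(2 * np.pi)
    G = order
    cl_occ = np.repeat(
        base_cl[None, None] * np.exp(pop.omega_cl * nodes)[:, None, None, None], G, axis=1
    )
    v = pop.theta_v * np.exp(pop.omega_v * nodes)[None, :, None] * np.ones((G, G, prob.n))
    f = np.clip(_conc_batch(prob, cl_occ, v), 0, None)
    sig = pop.err_a + pop.err_b * f
    loglik = -0.5 * np.sum(
        (_LOG2PI + 2 * np.log(sig) + ((prob.y - f) / sig) ** 2) * prob.mask, axis=-1
    )
    shift = loglik.max(axis=(0, 1))
    lik = np.einsum("a,b,abn->n", wnorm, wnorm, np.exp(loglik - shift))
    return float(np.sum(-2.0 * (np.log(lik) + shift)))


class TestLikelihood:
    def test_laplace_matches_quadrature_oracle(self, toy_pop):
        spec = CohortSpec(
            n_subjects=4,
            n_occasions=1,
            occasion_days=(1,),
            frac_intensive_ei=1.0,
            frac_intensive_si=1.0,
            intensive_occasion=1,
        )
        for seed in (1, 2, 5):
            ds = generate(spec, toy_pop, seed=seed)
            lap = neg2ll(ds, toy_pop)
            gh = gauss_hermite_neg2ll(ds, toy_pop)
            assert lap == pytest.approx(gh, abs=0.1)

    def test_neg2ll_deterministic(self, toy_pop):
        ds = generate(CohortSpec(n_subjects=3), toy_pop, seed=2)
        assert neg2ll(ds, toy_pop) == pytest.approx(neg2ll(ds, toy_pop), abs=1e-6)


class TestFit:
    def test_noiseless_degenerate_recovery(self, pop_novar):
        # omega = gamma = residual = 0: the fixed effects are identified
        # exactly and the fit lands on them to < 0.1%
        ds = generate(CohortSpec(n_subjects=6), pop_novar, seed=3)
        res = fit(ds, compute_se=False, covariate_refs={"crcl": 99.3})
        assert res.params.theta_cl == pytest.approx(12.0, rel=1e-3)
        assert res.params.theta_v == pytest.approx(29.8, rel=1e-3)
        assert res.params.beta_crcl == pytest.approx(0.64, abs=5e-3)

    def test_fit_reports_ebes_and_shrinkage(self, pop):
        ds = generate(CohortSpec(n_subjects=20), pop, seed=6)
        res = fit(ds, compute_se=False)
        assert len(res.ebes) == 20
        assert set(res.shrinkage) == {"eta_cl", "eta_v", "kappa_cl"}
        assert res.objective > 0 and res.converged


class TestShrinkage:
    def _mk(self, ebes, omega_cl=0.3):
        params = PopulationParameters(omega_cl=omega_cl, omega_v=0.3, gamma_cl=0.0)
        return FitResult(
            params=params, objective=0.0, covariates=(), betas={}, converged=True,
            n_iter=0, message="", ebes=ebes,
        )

    def test_all_zero_ebes_full_shrinkage(self):
        ebes = pd.DataFrame({"ID": [1, 2, 3], "eta_cl": 0.0, "eta_v": 0.0})
        s = shrinkage(self._mk(ebes))
        assert s["eta_cl"] == pytest.approx(100.0)

    def test_sd_equal_omega_zero_shrinkage(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=2000)
        vals = 0.3 * (vals - vals.mean()) / vals.std(ddof=1)
        ebes = pd.DataFrame({"ID": np.arange(2000), "eta_cl": vals, "eta_v": vals})
        s = shrinkage(self._mk(ebes))
        assert s["eta_cl"] == pytest.approx(0.0, abs=1e-6)

    def test_zero_omega_undefined(self):
        ebes = pd.DataFrame({"ID": [1, 2], "eta_cl": [0.1, -0.1], "eta_v": [0.0, 0.0]})
        s = shrinkage(self._mk(ebes, omega_cl=0.0))
        assert np.isnan(s["eta_cl"])


class TestCovariateStep:
    def test_empty_candidates_returns_base(self, pop):
        ds = generate(CohortSpec(n_subjects=10), pop, seed=8)
        res = covariate_step(ds, candidates=())
        assert res.selected == ()
        assert res.steps.empty

    def test_strong_crcl_effect_selected(self, pop):
        # large cohort, true effect beta = 0.64: the forward step must pick
        # CrCL and backward must keep it (dOFV threshold 10.83)
        ds = generate(CohortSpec(n_subjects=100), pop, seed=1)
        res = covariate_step(ds, candidates=("crcl",))
        assert res.selected == ("crcl",)
        kept = res.steps[(res.steps["phase"] == "backward")]
        assert (kept["dofv"] >= 10.83).all()

    def test_null_covariate_not_selected(self, pop):
        # weight does not enter the generating model; with CrCL present it
        # should not survive selection
        ds = generate(CohortSpec(n_subjects=44), pop, seed=14)
        res = covariate_step(ds, candidates=("wt",))
        assert "wt" not in res.selected


class TestBootstrap:
    @pytest.fixture(scope="class")
    def small_ds(self, pop):
        return generate(CohortSpec(n_subjects=12), pop, seed=31)

    def test_percentiles_are_order_statistics(self, small_ds):
        res = bootstrap(small_ds, n_resamples=4, seed=5)
        assert (res["p2.5"] <= res["median"]).all()
        assert (res["median"] <= res["p97.5"]).all()
        assert (res["n_converged"] <= 4).all()

    def test_reproducible(self, small_ds):
        a = bootstrap(small_ds, n_resamples=2, seed=9)
        b = bootstrap(small_ds, n_resamples=2, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_resamples(self, small_ds):
        with pytest.raises(ValueError):
            bootstrap(small_ds, n_resamples=0)


class TestPcVpc:
    def test_identity_correction_when_predictions_equal(self, pop):
        # if every population prediction in a bin is identical the
        # correction factor is exactly 1
        ds = generate(CohortSpec(n_subjects=30), pop, seed=41)
        res = fit(ds, compute_se=False)
        v1 = pcvpc(ds, res, n_simulations=50, seed=1)
        t = v1.table
        assert (t["pi_low"] <= t["pi_high"]).all()
        assert t.groupby("bin")["percentile"].count().eq(3).all()
        # within each bin the observed percentiles are ordered like their
        # probability levels (correction is a common positive rescaling)
        for _, grp in t.groupby("bin"):
            obs = grp.sort_values("percentile")["observed"].to_numpy()
            assert np.all(np.diff(obs) >= 0)
        assert v1.n_simulations == 50

    def test_self_simulated_data_within_bands(self, pop):
        # simulate a dataset, fit it, and check the fitted model's VPC
        ds = generate(CohortSpec(n_subjects=44), pop, seed=17)
        res = fit(ds, compute_se=False)
        v = pcvpc(ds, res, n_simulations=300, seed=3)
        assert v.coverage() >= 0.8
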