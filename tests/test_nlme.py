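"""Estimation engine: likelihoods, OFV, LRT, mixture, SIR."""

import math

import numpy as np
import pytest
from scipy import optimize, stats

from poppkgx import (
    CovariateModel,
    ErrorModel,
    MixtureSpec,
    PKDataset,
    PopPKModel,
    RandomEffectsSpec,
    StructuralParams,
    fit,
    individual_neg2ll,
    lrt,
    mixture_marginal_neg2ll,
    ofv,
    sir_ci,
)
from poppkgx.nlme import (
    _dims,
    _joint_neg2ll,
    _laplace_component,
    _predict_subject,
    _sir_core,
    covariate_search,
    CovariateEffect,
)
from poppkgx.synth import (
    SimulationDesign,
    default_truth_model,
    simulate_pk,
    simulate_subjects,
)


def quadrature_neg2ll(model, subj, geno="C/C"):
    """Adaptive-quadrature oracle for the 1-eta marginal -2 log-likelihood.

    Integrates exp(-g/2) over the random effect with scipy.integrate.quad
    centered at the conditional mode.
    """
    from scipy.integrate import quad

    dims = _dims(model, subj)
    assert len(dims) == 1
    g = lambda e: _joint_neg2ll(model, subj, geno, dims, np.array([e]))
    res = optimize.minimize_scalar(g, bounds=(-3, 3), method="bounded",
                                   options={"xatol": 1e-10})
    g0, mode = float(res.fun), float(res.x)
    val, _ = quad(lambda e: math.exp(-(g(e) - g0) / 2.0), mode - 3, mode + 3,
                  limit=200, epsabs=1e-12, epsrel=1e-10)
    return g0 - 2.0 * math.log(val)


@pytest.fixture(scope="module")
def toy_model():
    return PopPKModel(
        theta=StructuralParams(CL=0.732, Vc=12.2, Vp=5.87, Q=1.5, MTT=1.8, ka=1.2, NN=4),
        re=RandomEffectsSpec(bsv={"CL": 0.09}),
        error=ErrorModel(prop_sd=0.10, add_sd=0.006),
    )


@pytest.fixture(scope="module")
def toy_data(toy_model):
    design = SimulationDesign(n_intensive=4, n_sparse=0, fraction_ungenotyped=0.0)
    return simulate_pk(design, toy_model, simulate_subjects(4, seed=7), None, seed=8)


class TestErrorModel:
    def test_additive_floor_enforced(self):
        with pytest.raises(ValueError):
            ErrorModel(prop_sd=0.1, add_sd=0.001, lloq=0.030)

    def test_floor_is_20pct_of_lloq(self):
        # exactly at the floor is allowed
        ErrorModel(prop_sd=0.1, add_sd=0.006, lloq=0.030)


class TestIndividualNeg2ll:
    def test_zero_residual_leaves_constant(self, toy_model, toy_data):
        """Observation equal to prediction contributes log(2*pi*var) each."""
        import dataclasses

        subj = toy_data.subjects[0]
        dims = _dims(toy_model, subj)
        pred = _predict_subject(toy_model, subj, "C/C", dims, np.zeros(len(dims)))
        exact = dataclasses.replace(subj, obs_dv=pred.copy())
        n2 = individual_neg2ll(toy_model, exact)
        v = (toy_model.error.prop_sd * pred) ** 2 + toy_model.error.add_sd**2
        assert n2 == pytest.approx(float(np.sum(np.log(2 * np.pi * v))), rel=1e-12)

    def test_matches_hand_computed_gaussian_sum(self, toy_model, toy_data):
        subj = toy_data.subjects[1]
        dims = _dims(toy_model, subj)
        pred = _predict_subject(toy_model, subj, "C/C", dims, np.zeros(len(dims)))
        v = (toy_model.error.prop_sd * pred) ** 2 + toy_model.error.add_sd**2
        hand = -2.0 * np.sum(stats.norm.logpdf(subj.obs_dv, pred, np.sqrt(v)))
        assert individual_neg2ll(toy_model, subj) == pytest.approx(hand, rel=1e-12)

    def test_zero_prediction_variance_floor(self, toy_model):
        """At pred = 0 the variance is add_sd^2 >= (0.2 * LLOQ)^2."""
        err = toy_model.error
        v = (err.prop_sd * 0.0) ** 2 + err.add_sd**2
        assert v >= (0.2 * err.lloq) ** 2


class TestOFV:
    def test_degenerate_hierarchy_equals_sum_of_conditionals(self, toy_model, toy_data):
        """All variances at zero: OFV = sum of individual -2LL at eta = 0."""
        m = toy_model.copy()
        m.re = RandomEffectsSpec(bsv={}, bov={})
        expected = sum(individual_neg2ll(m, s) for s in toy_data.subjects)
        assert ofv(m, toy_data) == pytest.approx(expected, rel=1e-12)

    def test_laplace_close_to_quadrature(self, toy_model, toy_data):
        """Laplace vs adaptive quadrature within 0.05 per 1-eta subject."""
        for subj in toy_data.subjects:
            lap, _ = _laplace_component(toy_model, subj, "C/C")
            quad = quadrature_neg2ll(toy_model, subj)
            assert abs(lap - quad) < 0.05

    def test_fixed_null_parameter_leaves_ofv_unchanged(self, toy_model, toy_data):
        base = ofv(toy_model, toy_data)
        m = toy_model.copy()
        m.covariates.effects = [CovariateEffect("CL", "ARM", theta=0.0)]
        assert ofv(m, toy_data) == pytest.approx(base, rel=1e-12)

    def test_nested_model_never_beats_full(self, toy_model, toy_data):
        """OFV monotonicity under nesting (up to optimizer tolerance)."""
        reduced = fit(toy_model, toy_data, ["CL", "bsv_CL"], seed=0, maxiter=200)
        full = fit(toy_model, toy_data, ["CL", "Vc", "bsv_CL"], seed=0, maxiter=300)
        assert reduced.ofv >= full.ofv - 0.1


class TestFit:
    def test_noiseless_zero_variance_recovery(self):
        """Zero residual error and zero variances: exact identifiability."""
        truth = PopPKModel(
            theta=StructuralParams(CL=0.9, Vc=14.0, Vp=5.0, Q=1.2, MTT=1.5, ka=1.0, NN=4),
            re=RandomEffectsSpec(),
            error=ErrorModel(prop_sd=1e-3, add_sd=0.006),
        )
        design = SimulationDesign(n_intensive=6, n_sparse=0, fraction_ungenotyped=0.0)
        subjects = simulate_subjects(6, seed=21)
        data = simulate_pk(design, truth, subjects, None, seed=22)
        res = fit(
            truth, data, ["CL", "Vc"],
            init={"CL": 1.3, "Vc": 10.0}, seed=0, fatol=1e-6, xatol=1e-7,
        )
        assert res.estimates["CL"] == pytest.approx(0.9, rel=2e-3)
        assert res.estimates["Vc"] == pytest.approx(14.0, rel=2e-3)

    def test_requires_two_subjects(self, toy_model, toy_data):
        one = PKDataset(toy_data.df[toy_data.df.ID == toy_data.df.ID.iloc[0]])
        with pytest.raises(ValueError):
            fit(toy_model, one, ["CL"])

    def test_deterministic_given_seed(self, toy_model, toy_data):
        r1 = fit(toy_model, toy_data, ["CL"], seed=3, maxiter=60)
        r2 = fit(toy_model, toy_data, ["CL"], seed=3, maxiter=60)
        assert r1.ofv == r2.ofv
        assert np.array_equal(r1.x, r2.x)


class TestLRT:
    def test_published_threshold(self):
        """An OFV decrease of 3.84 with 1 df sits at P = 0.05."""
        assert lrt(100.0, 96.16, 1) == pytest.approx(0.05, abs=5e-4)

    def test_zero_delta_is_p_one(self):
        assert lrt(100.0, 100.0, 1) == 1.0

    def test_large_delta_two_df(self):
        """A 24.7-unit decrease on 2 df is significant below 1e-5."""
        assert lrt(100.0, 75.3, 2) < 1e-5

    def test_rejects_negative_df(self):
        with pytest.raises(ValueError):
            lrt(10.0, 9.0, 0)

    def test_rejects_inverted_ofvs(self):
        with pytest.raises(ValueError):
            lrt(90.0, 100.0, 1)


class TestMixture:
    def test_degenerate_mixture_equals_single_category(self, toy_data):
        m = PopPKModel(
            theta=StructuralParams(CL=0.78, Vc=12.2, Vp=5.87, Q=1.5, MTT=1.8, ka=1.2, NN=4),
            re=RandomEffectsSpec(bsv={"CL": 0.09}),
            covariates=CovariateModel(genotype_cl={"C/T": 0.892, "T/T": 0.741}),
        )
        subj = toy_data.subjects[0]
        mix = MixtureSpec(probs=(1.0, 0.0, 0.0))
        n2_mix, post = mixture_marginal_neg2ll(m, subj, mix)
        n2_cc, _ = _laplace_component(m, subj, "C/C")
        assert n2_mix == pytest.approx(n2_cc, abs=1e-10)
        assert post["C/C"] == pytest.approx(1.0)

    def test_three_term_sum_matches_hand_computation(self, toy_data):
        """Marginal likelihood equals the explicit 3-term weighted sum."""
        m = PopPKModel(
            theta=StructuralParams(CL=0.78, Vc=12.2, Vp=5.87, Q=1.5, MTT=1.8, ka=1.2, NN=4),
            re=RandomEffectsSpec(bsv={}),  # degenerate: conditional likelihoods exact
            covariates=CovariateModel(genotype_cl={"C/T": 0.892, "T/T": 0.741}),
        )
        subj = toy_data.subjects[2]
        probs = (0.35, 0.48, 0.17)
        mix = MixtureSpec(probs=probs)
        n2_mix, post = mixture_marginal_neg2ll(m, subj, mix)
        comps = [individual_neg2ll(m, subj, geno=g) for g in ("C/C", "C/T", "T/T")]
        total = sum(p * math.exp(-0.5 * c) for p, c in zip(probs, comps))
        assert n2_mix == pytest.approx(-2.0 * math.log(total), abs=1e-10)
        hand_post = [p * math.exp(-0.5 * c) / total for p, c in zip(probs, comps)]
        for g, hp in zip(("C/C", "C/T", "T/T"), hand_post):
            assert post[g] == pytest.approx(hp, abs=1e-12)

    def test_posteriors_form_simplex(self, toy_data):
        m = PopPKModel(
            theta=StructuralParams(CL=0.78, Vc=12.2, Vp=5.87, Q=1.5, MTT=1.8, ka=1.2, NN=4),
            re=RandomEffectsSpec(bsv={"CL": 0.09}),
            covariates=CovariateModel(genotype_cl={"C/T": 0.892, "T/T": 0.741}),
        )
        _, post = mixture_marginal_neg2ll(m, toy_data.subjects[1], MixtureSpec())
        assert sum(post.values()) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_simplex_rejected(self):
        with pytest.raises(ValueError):
            MixtureSpec(probs=(0.5, 0.2, 0.2))


class TestSIR:
    def test_linear_gaussian_matches_wald(self):
        """On an exactly quadratic -2 log-likelihood, SIR reproduces Wald CIs."""
        truth_mean, truth_sd = 1.5, 0.2
        n2 = lambda x: ((x[0] - truth_mean) / truth_sd) ** 2
        draws = _sir_core(
            n2, np.array([truth_mean]), np.array([[truth_sd**2]]),
            n_samples=4000, n_resamples=1000, seed=5,
        )
        lo, hi = np.percentile(draws[:, 0], [2.5, 97.5])
        assert lo == pytest.approx(truth_mean - 1.96 * truth_sd, abs=0.04)
        assert hi == pytest.approx(truth_mean + 1.96 * truth_sd, abs=0.04)

    def test_single_resample_degenerates_to_mode_region(self):
        n2 = lambda x: (x[0] / 0.1) ** 2
        draws = _sir_core(n2, np.array([0.0]), np.array([[0.01]]), 200, 1, seed=2)
        assert draws.shape == (1, 1)

    def test_reproducible_under_seed(self, toy_model, toy_data):
        res = fit(toy_model, toy_data, ["CL"], seed=0, maxiter=60)
        ci1 = sir_ci(res, toy_data, n_samples=50, n_resamples=20, seed=9)
        ci2 = sir_ci(res, toy_data, n_samples=50, n_resamples=20, seed=9)
        assert ci1 == ci2
        lo, hi = ci1["CL"]
        assert lo < res.estimates["CL"] < hi


class TestCovariateSearch:
    def test_null_data_selects_nothing(self, toy_model):
        design = SimulationDesign(n_intensive=10, n_sparse=0, fraction_ungenotyped=0.0)
        truth = toy_model.copy()
        data = simulate_pk(design, truth, simulate_subjects(10, seed=31), None, seed=32)
        selected, audit = covariate_search(
            toy_model, data, [("CL", "ARM")], ["CL", "bsv_CL"], maxiter=120,
        )
        assert selected.covariates.effects == []
        assert any(a["step"] == "forward" for a in audit)

    def test_genuine_effect_retained(self):
        """A 30% CL shift on one arm survives forward + backward selection."""
        truth = PopPKModel(
            theta=StructuralParams(CL=0.732, Vc=12.2, Vp=5.87, Q=1.5, MTT=1.8, ka=1.2, NN=4),
            re=RandomEffectsSpec(bsv={"CL": 0.02}),
            error=ErrorModel(prop_sd=0.08, add_sd=0.006),
        )
        truth.covariates.effects = [CovariateEffect("CL", "ARM", theta=0.30)]
        design = SimulationDesign(n_intensive=14, n_sparse=0, fraction_ungenotyped=0.0)
        data = simulate_pk(design, truth, simulate_subjects(14, seed=41), None, seed=42)
        base = truth.copy()
        base.covariates.effects = []
        selected, audit = covariate_search(
            base, data, [("CL", "ARM")], ["CL", "bsv_CL"], maxiter=150,
        )
        assert [(e.parameter, e.covariate) for e in selected.covariates.effects] == [
            ("CL", "ARM")
        ]
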