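"""Estimation machinery: oracles, cross-method checks, model search."""

import math
from dataclasses import replace as drep

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from ratiopkpd import (AdultDesign, DEFAULT_ADULT_INIT, DEFAULT_PAED_INIT,
                       ErrorModel, FitSettings, PaediatricDesign,
                       PopulationSpec, StudyDataset, TruthSpec,
                       apply_adult_inclusion_rules, compute_ofv,
                       correlation_test_random_effects, estimate_rse,
                       fit_curve_mle, fit_population,
                       generate_adult_study, generate_paediatric_study,
                       lrt_stepwise_covariates)
from ratiopkpd.estimation import (LRT_THRESHOLD_P01, build_adapter,
                                  _ghq_neg_loglik)
from ratiopkpd.simulate import inject_blq


def _pk_only_init():
    init = DEFAULT_ADULT_INIT
    return PopulationSpec(
        fixed={p: v for p, v in init.fixed.items()
               if p in ("k_tr", "mtt", "k_a", "cl_f", "v1_f", "q_f",
                        "v2_f")},
        iiv={p: v for p, v in init.iiv.items()
             if p in ("k_tr", "mtt", "cl_f", "v1_f")},
        correlations=init.correlations,
        errors={"pk": init.errors["pk"]})


class TestCurveMle:
    def test_one_compartment_bolus_matches_nls_oracle(self):
        # no IIV, additive error, noiseless data: ML == least squares
        def model(p, t):
            cl, v = p
            return 100.0 / v * np.exp(-cl / v * t)

        t = np.linspace(0.1, 24, 200)
        y = model([5.0, 40.0], t)
        est, ofv = fit_curve_mle(model, t, y,
                                 ErrorModel("combined", a=0.1, b=0.0),
                                 init=[2.0, 20.0])
        popt, _ = optimize.curve_fit(
            lambda t, cl, v: model([cl, v], t), t, y, p0=[2.0, 20.0])
        np.testing.assert_allclose(est, popt, rtol=1e-4)
        np.testing.assert_allclose(est, [5.0, 40.0], rtol=1e-4)


class TestComputeOfv:
    def test_no_iiv_collapses_to_direct_sum(self, paediatric_truth):
        ds = generate_paediatric_study(PaediatricDesign(n_subjects=30),
                                       paediatric_truth, seed=1)
        spec = PopulationSpec(fixed=paediatric_truth.spec.fixed, iiv={},
                              errors=paediatric_truth.spec.errors)
        adapter = build_adapter("paed_direct", ds)
        ofv, se = compute_ofv(adapter, None, spec, nmc=50, seed=0)
        vals = {p: np.full(adapter.n_subjects, v)
                for p, v in spec.fixed.items()}
        direct = -2.0 * adapter.loglik(vals, spec.errors).sum()
        assert se == 0.0
        assert ofv == pytest.approx(direct, rel=1e-12)

    def test_importance_sampling_matches_quadrature_oracle(
            self, paediatric_truth):
        # deterministic Gauss-Hermite marginal likelihood vs Monte-Carlo
        # importance sampling: two independent routes to the same OFV
        ds = generate_paediatric_study(PaediatricDesign(n_subjects=100),
                                       paediatric_truth, seed=3)
        fit = fit_population(ds, "paed_direct", DEFAULT_PAED_INIT)
        adapter = build_adapter("paed_direct", ds)
        ofv_is, se = compute_ofv(adapter, None, fit.spec, nmc=400, seed=1)
        assert abs(ofv_is - fit.ofv) < 3 * max(se, 0.5)

    def test_doubling_nmc_is_consistent(self, paediatric_truth):
        ds = generate_paediatric_study(PaediatricDesign(n_subjects=50),
                                       paediatric_truth, seed=5)
        fit = fit_population(ds, "paed_direct", DEFAULT_PAED_INIT)
        adapter = build_adapter("paed_direct", ds)
        o1, s1 = compute_ofv(adapter, None, fit.spec, nmc=300, seed=1)
        o2, s2 = compute_ofv(adapter, None, fit.spec, nmc=600, seed=2)
        assert abs(o1 - o2) < 3 * math.hypot(max(s1, 0.2), max(s2, 0.2))


class TestPaediatricFit:
    def test_seeded_determinism(self, paediatric_truth):
        ds = generate_paediatric_study(PaediatricDesign(n_subjects=60),
                                       paediatric_truth, seed=8)
        f1 = fit_population(ds, "paed_direct", DEFAULT_PAED_INIT,
                            FitSettings(seed=3))
        f2 = fit_population(ds, "paed_direct", DEFAULT_PAED_INIT,
                            FitSettings(seed=3))
        assert f1.spec.fixed == f2.spec.fixed
        assert f1.spec.iiv == f2.spec.iiv
        assert f1.ofv == f2.ofv

    def test_saem_cross_checks_the_ghq_route(self, paediatric_truth):
        ds = generate_paediatric_study(PaediatricDesign(n_subjects=80),
                                       paediatric_truth, seed=9)
        ghq = fit_population(ds, "paed_direct", DEFAULT_PAED_INIT)
        saem = fit_population(ds, "paed_direct", DEFAULT_PAED_INIT,
                              FitSettings(n_explore=200, n_smooth=100,
                                          seed=1), method="saem")
        for p in ("e0", "ic50"):
            assert saem.spec.fixed[p] == pytest.approx(
                ghq.spec.fixed[p], rel=0.10)

    def test_nonidentifiable_spec_warns_not_silently(self,
                                                     paediatric_truth):
        ds = generate_paediatric_study(PaediatricDesign(n_subjects=3),
                                       paediatric_truth, seed=2)
        init = PopulationSpec(fixed={"e0": 0.1, "ic50": 3.0},
                              iiv={"e0": 0.4, "ic50": 0.4},
                              errors={"pd": ErrorModel("proportional",
                                                       b=0.2)})
        fit = fit_population(ds, "paed_direct", init,
                             FitSettings(n_explore=30, n_smooth=10,
                                         seed=0), method="saem")
        assert fit.messages  # loud diagnostics attached


class TestRse:
    def test_rich_low_noise_data_give_small_rse(self, paediatric_truth):
        spec = PopulationSpec(fixed=paediatric_truth.spec.fixed,
                              iiv={"ic50": 0.05},
                              errors={"pd": ErrorModel("proportional",
                                                       b=0.02)})
        truth = drep(paediatric_truth, spec=spec)
        ds = generate_paediatric_study(
            PaediatricDesign(n_subjects=400, visits_per_subject=4),
            truth, seed=1)
        fit = fit_population(ds, "paed_direct", DEFAULT_PAED_INIT)
        rse = estimate_rse(fit, ds, method="fim", seed=0)
        assert all(v < 5.0 for v in rse.values())

    def test_bootstrap_and_fim_agree_within_factor_two(
            self, paediatric_truth):
        ds = generate_paediatric_study(PaediatricDesign(n_subjects=60),
                                       paediatric_truth, seed=4)
        fit = fit_population(ds, "paed_direct", DEFAULT_PAED_INIT)
        fim = estimate_rse(fit, ds, method="fim", seed=0)
        boot = estimate_rse(fit, ds, method="bootstrap", B=20, seed=0)
        for p in fim:
            if p in boot:
                ratio = boot[p] / fim[p]
                assert 0.5 <= ratio <= 2.0

    def test_small_bootstrap_warns(self, paediatric_truth):
        ds = generate_paediatric_study(PaediatricDesign(n_subjects=30),
                                       paediatric_truth, seed=4)
        fit = fit_population(ds, "paed_direct", DEFAULT_PAED_INIT)
        with pytest.warns(UserWarning, match="bootstrap"):
            estimate_rse(fit, ds, method="bootstrap", B=5, seed=0)

    def test_adult_fit_reports_finite_rse_for_all_fixed_effects(
            self, adult_recovery_fits):
        ds, fit = adult_recovery_fits[0]
        rse = estimate_rse(fit, ds, method="fim", seed=0)
        assert len(rse) == 11
        assert all(np.isfinite(v) and v >= 0 for v in rse.values())


class TestCovariateSearch:
    def test_threshold_equals_chi_square_quantile(self):
        assert LRT_THRESHOLD_P01 == pytest.approx(
            stats.chi2.ppf(0.99, 1))
        assert LRT_THRESHOLD_P01 == pytest.approx(6.635, abs=1e-3)

    def test_screening_skips_constant_covariates(self, paediatric_truth):
        ds = generate_paediatric_study(PaediatricDesign(n_subjects=40),
                                       paediatric_truth, seed=6)
        # make 'ross' constant across subjects
        from dataclasses import replace
        subs = tuple(replace(s, covariates={**s.covariates, "ross": 3})
                     for s in ds.subjects)
        ds = StudyDataset("paediatric", subs, ds.assay)
        fit = fit_population(ds, "paed_direct", DEFAULT_PAED_INIT)
        selected, log = lrt_stepwise_covariates(
            ds, fit, candidates=("ross",), seed=0)
        assert selected == ()
        assert not len(log)  # constant candidate never reaches a refit


class TestCovariateSearchPower:
    def test_strong_weight_effect_on_clearance_is_detected(
            self, adult_truth):
        from ratiopkpd import CovariateLink
        spec2 = drep(adult_truth.spec, covariate_links=(
            CovariateLink("cl_f", "weight", "power_scaled", 1.5,
                          reference=70.0),))
        ds = generate_adult_study(
            AdultDesign(n_subjects=20, missing_plan={}),
            drep(adult_truth, spec=spec2), seed=77)
        ds, _ = apply_adult_inclusion_rules(ds)
        fit = fit_population(ds, "adult_pkpd", DEFAULT_ADULT_INIT,
                             FitSettings(n_explore=150, n_smooth=80))
        selected, log = lrt_stepwise_covariates(ds, fit, seed=0)
        pairs = {(l.parameter, l.covariate) for l in selected}
        assert ("cl_f", "weight") in pairs
        hit = next(l for l in selected
                   if (l.parameter, l.covariate) == ("cl_f", "weight"))
        assert hit.coefficient > 0.3  # correct sign, meaningful size


class TestCorrelationTest:
    def _fit_with_ebes(self, ebes):
        from ratiopkpd.estimation import FitResult
        spec = PopulationSpec(fixed={"a": 1.0, "b": 1.0},
                              iiv={"a": 0.3, "b": 0.3}, errors={})
        return FitResult(spec=spec, model_config=None, method="saem",
                         adapter_kind="synthetic", ofv=None, ofv_se=None,
                         ebes=ebes, trace=None,
                         settings=FitSettings(), seed=0, converged=True)

    def test_independent_ebes_rarely_flagged(self):
        rng = np.random.default_rng(0)
        flags = 0
        for rep in range(20):
            ebes = {f"s{i}": {"a": rng.standard_normal(),
                              "b": rng.standard_normal()}
                    for i in range(40)}
            out = correlation_test_random_effects(self._fit_with_ebes(
                ebes))
            flags += int(out["significant"].iloc[0])
        assert flags <= 3  # nominal 1% rate, generous margin

    def test_correlated_ebes_detected_near_r(self):
        rng = np.random.default_rng(1)
        cov = [[1.0, 0.84], [0.84, 1.0]]
        z = rng.multivariate_normal([0, 0], cov, size=40)
        ebes = {f"s{i}": {"a": z[i, 0], "b": z[i, 1]} for i in range(40)}
        out = correlation_test_random_effects(self._fit_with_ebes(ebes))
        assert bool(out["significant"].iloc[0])
        assert out["r"].iloc[0] == pytest.approx(0.84, abs=0.15)

    def test_constant_ebe_vector_warns(self):
        rng = np.random.default_rng(2)
        ebes = {f"s{i}": {"a": 0.0, "b": rng.standard_normal()}
                for i in range(10)}
        with pytest.warns(UserWarning, match="constant"):
            out = correlation_test_random_effects(self._fit_with_ebes(
                ebes))
        assert np.isnan(out["r"].iloc[0])

    def test_too_few_subjects_is_an_error(self):
        ebes = {"s0": {"a": 0.1, "b": 0.2}, "s1": {"a": 0.0, "b": 0.1}}
        with pytest.raises(ValueError):
            correlation_test_random_effects(self._fit_with_ebes(ebes))


class TestCensoringMatters:
    def test_dropping_blq_biases_clearance_upward(self, adult_truth):
        # censor the PK stream hard (3 ug/L), then fit with the interval
        # likelihood vs simply discarding the BLQ records
        ds0 = generate_adult_study(
            AdultDesign(n_subjects=20, missing_plan={}), adult_truth,
            seed=31)
        ds1, _ = apply_adult_inclusion_rules(ds0)
        subs_c, subs_d = [], []
        for s in ds1.subjects:
            pk = [drep(o, value=(o.value if not o.censored else 0.3),
                       censored=False, lower=0.0)
                  for o in s.observations if o.analyte == "ENALAPRILAT"]
            other = [o for o in s.observations
                     if o.analyte != "ENALAPRILAT"]
            pk_c = inject_blq(pk, 3.0, "censor_interval")
            subs_c.append(drep(s, observations=tuple(pk_c + other)))
            subs_d.append(drep(s, observations=tuple(
                [o for o in pk_c if not o.censored] + other)))
        ds_c = StudyDataset("adult", tuple(subs_c), ds1.assay)
        ds_d = StudyDataset("adult", tuple(subs_d), ds1.assay)
        st = FitSettings(n_explore=150, n_smooth=60, seed=2)
        f_c = fit_population(ds_c, "adult_pk", _pk_only_init(), st)
        f_d = fit_population(ds_d, "adult_pk", _pk_only_init(), st)
        bias = f_d.spec.fixed["cl_f"] - f_c.spec.fixed["cl_f"]
        print(f"CL/F bias from dropping BLQ: {bias:+.2f} L/h")
        assert bias > 0
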