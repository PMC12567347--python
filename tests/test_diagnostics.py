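"""Diagnostics: VPC machinery, GoF tables, hysteresis, effect summaries."""

import inspect
import math
from dataclasses import replace as drep

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from ratiopkpd import (AdultDesign, DoseEvent, ErrorModel, FitSettings,
                       Observation, PAEDIATRIC_ASSAY, PaediatricDesign,
                       PopulationSpec, Regimen, StudyDataset,
                       SubjectRecord, TruthSpec,
                       apply_adult_inclusion_rules,
                       apply_paediatric_exclusion_rules,
                       comparison_overlay, concentration_profile,
                       effect_site_profile, generate_adult_study,
                       generate_paediatric_study, gof, hysteresis_metric,
                       imax_ratio, percent_change_4h, vpc)
from ratiopkpd.estimation import FitResult


def _fit_stub(spec, adapter_kind, model_config=None, ebes=None,
              subject_ids=()):
    """FitResult wrapper around known parameters (no estimation)."""
    return FitResult(spec=spec, model_config=model_config, method="saem",
                     adapter_kind=adapter_kind, ofv=None, ofv_se=None,
                     ebes=ebes if ebes is not None
                     else {sid: {} for sid in subject_ids},
                     trace=None, settings=FitSettings(), seed=0,
                     converged=True)


@pytest.fixture(scope="module")
def paed_fit_stub(paed_study_n27):
    ds, _ = apply_paediatric_exclusion_rules(paed_study_n27)
    spec = TruthSpec.paediatric().spec
    return ds, _fit_stub(spec, "paed_direct",
                         subject_ids=[s.id for s in ds.subjects])


class TestVpc:
    def test_default_nsim_is_500_and_recorded(self, paed_fit_stub):
        assert inspect.signature(vpc).parameters["nsim"].default == 500
        ds, fit = paed_fit_stub
        res = vpc(ds, fit, nsim=150, seed=1)
        assert res["pd"].nsim == 150
        assert res["pd"].metadata["percentile_definition"].startswith(
            "linear")

    def test_zero_variability_bands_degenerate_to_population_curve(
            self, paediatric_truth):
        spec = PopulationSpec(fixed=paediatric_truth.spec.fixed, iiv={},
                              errors={"pd": ErrorModel("proportional",
                                                       b=1e-9)})
        truth = drep(paediatric_truth, spec=spec)
        ds = generate_paediatric_study(PaediatricDesign(n_subjects=40),
                                       truth, seed=3)
        fit = _fit_stub(spec, "paed_direct",
                        subject_ids=[s.id for s in ds.subjects])
        res = vpc(ds, fit, nsim=120, seed=0)["pd"]
        for p in res.percentiles:
            np.testing.assert_allclose(res.pi_low[p], res.pi_high[p],
                                       rtol=1e-5)

    def test_invariant_to_relabelling_and_observation_order(
            self, paed_fit_stub):
        ds, fit = paed_fit_stub
        relabelled = []
        for k, s in enumerate(ds.subjects):
            new_id = f"Z{k:03d}"
            obs = tuple(drep(o, subject_id=new_id)
                        for o in reversed(s.observations))
            doses = tuple(drep(d, subject_id=new_id) for d in s.doses)
            relabelled.append(drep(s, id=new_id, observations=obs,
                                   doses=doses))
        ds2 = StudyDataset("paediatric", tuple(relabelled), ds.assay)
        a = vpc(ds, fit, nsim=120, seed=7)["pd"].to_frame()
        b = vpc(ds2, fit, nsim=120, seed=7)["pd"].to_frame()
        for col in ("observed", "pi_low", "pi_high"):
            np.testing.assert_allclose(a[col], b[col], rtol=1e-9)

    def test_thin_bins_are_merged_with_a_log(self, paed_fit_stub):
        ds, fit = paed_fit_stub
        res = vpc(ds, fit, nsim=120, seed=2, n_bins=30)["pd"]
        assert all(n >= 3 for n in res.bin_n)
        assert res.metadata["merge_log"]

    def test_small_nsim_rejected(self, paed_fit_stub):
        ds, fit = paed_fit_stub
        with pytest.raises(ValueError):
            vpc(ds, fit, nsim=50)


class TestGof:
    def _exact_paed_ds(self):
        e0, ic50 = 0.19, 1.19
        subs = []
        for i, concs in enumerate([(0.0, 1.0, 3.0, 9.0),
                                   (0.0, 0.5, 2.0, 6.0),
                                   (0.0, 4.0, 8.0, 15.0)]):
            sid = f"P{i}"
            obs = []
            for t, c in enumerate(concs):
                r = e0 * (1 - c / (c + ic50))
                obs.append(Observation(sid, float(t), "ENALAPRILAT", c))
                obs.append(Observation(sid, float(t), "RATIO", r))
            subs.append(SubjectRecord(sid, {}, (DoseEvent(sid, 0.0, 1e3),),
                                      tuple(obs)))
        return StudyDataset("paediatric", tuple(subs), PAEDIATRIC_ASSAY)

    def test_noiseless_data_at_generating_parameters_has_zero_iwres(
            self):
        ds = self._exact_paed_ds()
        spec = PopulationSpec(fixed={"e0": 0.19, "ic50": 1.19},
                              iiv={"ic50": 0.3},
                              errors={"pd": ErrorModel("proportional",
                                                       b=0.37)})
        fit = _fit_stub(spec, "paed_direct",
                        ebes={s.id: {"ic50": 0.0} for s in ds.subjects})
        table = gof(ds, fit).table
        assert np.allclose(table["iwres"], 0.0, atol=1e-12)
        assert np.allclose(table["observed"], table["ipred"])

    def test_correct_model_iwres_tail_is_gaussian_or_shrunk(
            self, paed_recovery_fits):
        ds, fit = paed_recovery_fits[0]
        g = gof(ds, fit)
        # P(|Z| > 2) = 4.55% for a standard normal; individual
        # predictions at the posterior-mode random effects absorb part
        # of the noise, so the empirical tail sits at or below that
        assert 0.0 < g.frac_large_iwres < 0.0455 + 0.02
        assert g.table["iwres"].abs().median() < 2.0

    def test_censored_records_split_into_their_own_table(
            self, adult_truth):
        ds = generate_adult_study(AdultDesign(), adult_truth, seed=12)
        ds, _ = apply_adult_inclusion_rules(ds)
        fit = _fit_stub(adult_truth.spec, "adult_pkpd",
                        model_config=adult_truth.model,
                        subject_ids=[s.id for s in ds.subjects])
        g = gof(ds, fit)
        assert len(g.censored) > 0
        assert "iwres" not in g.censored.columns
        n_pk_unc = len([o for o in ds.observations("ENALAPRILAT")
                        if not o.censored])
        assert (g.table["stream"] == "pk").sum() == n_pk_unc

    def test_missing_ebes_is_an_error(self, adult_truth):
        ds = generate_adult_study(AdultDesign(), adult_truth, seed=12)
        fit = _fit_stub(adult_truth.spec, "adult_pkpd",
                        model_config=adult_truth.model)
        fit.ebes = None
        with pytest.raises(ValueError, match="empirical Bayes"):
            gof(ds, fit)


class TestHysteresis:
    def _loop(self, k_e0):
        p = TruthSpec.adult().spec.fixed
        times = np.linspace(0.1, 24, 240)
        conc = concentration_profile(
            drep_params(p), Regimen.single(20000), times)
        ce = effect_site_profile(np.concatenate([[0.0], times]),
                                 np.concatenate([[0.0], conc]),
                                 k_e0)[1:]
        ratio = imax_ratio(ce, p["e0"], p["ic50"], gamma=p["gamma"])
        return conc, ratio

    def test_clockwise_at_published_ke0(self):
        conc, ratio = self._loop(0.48)
        area, direction = hysteresis_metric(conc, ratio)
        assert direction == "clockwise" and area < 0

    def test_loop_collapses_as_ke0_grows(self):
        a_slow, _ = hysteresis_metric(*self._loop(0.48))
        a_fast, _ = hysteresis_metric(*self._loop(1e4))
        assert abs(a_fast) < 1e-2 * abs(a_slow)

    def test_exact_retrace_classified_as_none(self):
        conc = np.array([0.0, 1.0, 2.0, 3.0, 2.0, 1.0, 0.0])
        eff = 0.1 / (1 + conc)
        area, direction = hysteresis_metric(conc, eff)
        assert direction == "none" and area == pytest.approx(0.0,
                                                             abs=1e-15)

    def test_reversal_flips_the_sign_exactly(self):
        conc, ratio = self._loop(0.48)
        a_fwd, _ = hysteresis_metric(conc, ratio)
        a_rev, _ = hysteresis_metric(conc[::-1], ratio[::-1])
        assert a_rev == pytest.approx(-a_fwd, rel=1e-12)

    def test_unordered_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            hysteresis_metric([1, 2, 3, 4], [1, 2, 3, 4],
                              times=[0, 2, 1, 3])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            hysteresis_metric([1, 2, 3], [1, 2, 3])


def drep_params(fixed):
    from ratiopkpd import AdultStructuralParams
    return AdultStructuralParams(
        k_tr=fixed["k_tr"], mtt=fixed["mtt"], k_a=fixed["k_a"],
        cl_f=fixed["cl_f"], v1_f=fixed["v1_f"], q_f=fixed["q_f"],
        v2_f=fixed["v2_f"], k_e0=fixed["k_e0"], gamma=fixed["gamma"],
        e0=fixed["e0"], ic50=fixed["ic50"])


class TestPercentChange:
    def test_no_change_is_zero(self):
        out = percent_change_4h([(0.2, 0.2)])
        assert out["median"] == 0.0

    def test_eighty_percent_decrease(self):
        out = percent_change_4h([(0.20, 0.04)])
        assert out["median"] == pytest.approx(80.0)

    def test_median_matches_brute_force(self):
        pairs = [(0.2, 0.04), (0.3, 0.09), (0.1, 0.05)]
        out = percent_change_4h(pairs)
        brute = sorted(100 * (a - b) / a for a, b in pairs)[1]
        assert out["median"] == pytest.approx(brute) == pytest.approx(70.0)
        assert (out["min"], out["max"]) == (pytest.approx(50.0),
                                            pytest.approx(80.0))

    def test_zero_predose_pair_rejected_with_warning(self):
        with pytest.warns(UserWarning):
            out = percent_change_4h([(0.0, 0.1), (0.2, 0.1)])
        assert out["n"] == 1 and out["n_rejected"] == 1

    @hsettings(derandomize=True, max_examples=30)
    @given(st.floats(0.1, 10.0))
    def test_scale_invariance(self, c):
        pairs = [(0.2, 0.04), (0.3, 0.09), (0.1, 0.05)]
        scaled = [(a * c, b * c) for a, b in pairs]
        a = percent_change_4h(pairs)
        b = percent_change_4h(scaled)
        assert a["median"] == pytest.approx(b["median"], rel=1e-9)
        assert a["min"] == pytest.approx(b["min"], rel=1e-9)


@pytest.fixture(scope="module")
def overlay_result(adult_study_n9, paed_study_n27, adult_truth):
    adult_ds, _ = apply_adult_inclusion_rules(adult_study_n9)
    paed_ds, _ = apply_paediatric_exclusion_rules(paed_study_n27)
    fit = _fit_stub(adult_truth.spec, "adult_pkpd",
                    model_config=adult_truth.model,
                    subject_ids=[s.id for s in adult_ds.subjects])
    return comparison_overlay(fit, adult_ds, paed_ds, nsim=150,
                              seed=4), paed_ds


class TestOverlay:
    def test_every_point_carries_one_of_six_symbol_classes(
            self, overlay_result):
        overlay, _ = overlay_result
        symbols = set(overlay["points"]["symbol"])
        allowed = {f"{d}/{b}" for d in ("predose_first", "post_first",
                                        "post_repeated")
                   for b in ("quantified", "substituted")}
        assert symbols <= allowed
        assert overlay["points"]["symbol"].notna().all()

    def test_predose_first_records_sit_at_time_zero(self, overlay_result):
        overlay, _ = overlay_result
        pts = overlay["points"]
        pre = pts[pts["dose_class"] == "predose_first"]
        assert len(pre) == 16
        assert (pre["time_since_last_dose"] == 0.0).all()

    def test_values_never_altered(self, overlay_result):
        overlay, paed_ds = overlay_result
        dv = sorted(o.value for s in paed_ds.subjects
                    for o in s.observations if o.analyte == "RATIO")
        assert sorted(overlay["points"]["ratio"]) == pytest.approx(dv)

    def test_paediatric_baseline_sits_above_adult_median_band(
            self, overlay_result):
        overlay, _ = overlay_result
        bands = overlay["bands"]
        first = bands[(bands["percentile"] == 50)].iloc[0]
        pre = overlay["points"].query("dose_class == 'predose_first'")
        assert pre["ratio"].median() > first["pi_high"]
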