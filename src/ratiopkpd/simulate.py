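"""Synthetic study generation.

The clinical datasets behind the two analyses (a single-dose
rich-sampling study in healthy adults and a sparse repeated-dose study
in infants with heart failure) are not publicly available, so this
module generates design-faithful stand-ins:

* :func:`generate_adult_study` — 9 subjects (default), one 20 mg oral
  dose of enalapril maleate, 34 scheduled PK samples per subject
  including predose (every 10 min to 3 h, every 20 min to 6 h, every
  30 min to 7.5 h, then 24/48/72 h) and 13 PD samples; lognormal IIV
  with the V1/F-CL/F random-effect correlation, combined residual error
  on concentrations (censored below the 0.70 µg/L LLOQ) and
  proportional error on the ratio; a configurable missing-sample plan
  (default: 9 samples lost across 2 subjects).

* :func:`generate_paediatric_study` — 27 subjects (default) with
  weight-based twice-daily dosing and the study's record structure:
  16 predose-first-dose, 12 post-first-dose and 26 post-repeated-dose
  analysable records plus 33 tagged excluded records (10/10/8/2/1/2 by
  category).  Enalaprilat concentrations are drawn from a seeded
  lognormal attached to time-since-dose through a unimodal template —
  the paediatric analysis treats concentrations as input data, so any
  generator spanning the observed range (capped at the highest observed
  18.3 µg/L) exercises it.  Ratios follow the direct Imax model with
  IIV on IC50; ANG II values falling below the LLOQ are replaced by
  LLOQ/2 exactly as the analysis prescribes.

With a subject count other than 27 the paediatric generator switches to
a dense recovery plan (predose + three post-dose visits per subject, no
exclusion injection) suitable for parameter-recovery experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .config import adult_final_spec, paediatric_final_spec
from .datasets import (ADULT_ASSAY, PAEDIATRIC_ASSAY, DoseEvent,
                       Observation, StudyDataset, SubjectRecord,
                       compute_ratio)
from .population import PopulationSpec
from .structural import ModelConfig, Regimen, imax_ratio, predict_profiles

__all__ = [
    "AdultDesign",
    "PaediatricDesign",
    "TruthSpec",
    "adult_pk_schedule",
    "adult_pd_schedule",
    "draw_individual_parameters",
    "generate_adult_study",
    "generate_paediatric_study",
    "inject_blq",
]


def adult_pk_schedule() -> np.ndarray:
    """34 scheduled PK sampling times (h) including predose."""
    t = [0.0]
    t += list(np.arange(1, 19) / 6.0)       # every 10 min to 3 h
    t += list(np.arange(10, 19) / 3.0)      # every 20 min to 6 h
    t += [6.5, 7.0, 7.5]                    # every 30 min block
    t += [24.0, 48.0, 72.0]
    return np.asarray(t)


def adult_pd_schedule() -> np.ndarray:
    """13 scheduled PD sampling times (h) including predose."""
    return np.asarray([0.0, 0.5, 1, 2, 3, 4, 5, 6, 7, 8, 24, 48, 72],
                      dtype=float)


@dataclass(frozen=True)
class AdultDesign:
    """Single-dose rich-sampling adult design."""

    n_subjects: int = 9
    dose_ug: float = 20000.0
    pk_times: tuple[float, ...] = tuple(adult_pk_schedule())
    pd_times: tuple[float, ...] = tuple(adult_pd_schedule())
    #: subject index -> number of scheduled post-dose PK samples lost
    missing_plan: Mapping[int, int] = field(
        default_factory=lambda: {0: 5, 1: 4})

    def __post_init__(self) -> None:
        if np.any(np.diff(self.pk_times) <= 0) or \
                np.any(np.diff(self.pd_times) <= 0):
            raise ValueError("schedule times must be strictly increasing")
        if any(i >= self.n_subjects for i in self.missing_plan):
            raise ValueError("missing plan refers to unknown subjects")
        n_post = sum(1 for t in self.pk_times if t > 0)
        if any(c > n_post for c in self.missing_plan.values()):
            raise ValueError("missing plan exceeds the schedule")


@dataclass(frozen=True)
class PaediatricDesign:
    """Sparse repeated-dose paediatric design.

    With the default 27 subjects the generator reproduces the study's
    record accounting (87 records: 54 analysable in 16/12/26 classes
    plus 33 tagged excluded); any other subject count selects a dense
    recovery plan of ``visits_per_subject`` post-dose visits plus a
    predose record per subject, with no exclusion injection.
    """

    n_subjects: int = 27
    age_range_y: tuple[float, float] = (0.07, 2.24)
    weight_range_kg: tuple[float, float] = (3.2, 13.0)
    first_dose_mgkg: tuple[float, float] = (0.03, 0.08)
    daily_dose_mgkg: tuple[float, float] = (0.06, 0.27)
    dose_interval_h: float = 12.0
    visits_per_subject: int = 3
    class_counts: tuple[int, int, int] = (16, 12, 26)
    exclusion_counts: Mapping[str, int] = field(default_factory=lambda: {
        "ANGI_ULOQ": 10, "THERAPY_STOPPED": 10, "STOP_UNCLEAR": 8,
        "BOTH_BLQ": 2, "GT24H": 1, "OTHER": 2})
    include_raw_angiotensins: bool = False

    @property
    def study_plan(self) -> bool:
        return self.n_subjects == 27

    def __post_init__(self) -> None:
        n_pre, n_first, n_rep = self.class_counts
        if self.study_plan:
            if n_pre > self.n_subjects or n_first > self.n_subjects:
                raise ValueError(
                    "per-subject record classes exceed the subject count")
            budget = n_rep + sum(self.exclusion_counts.values())
            if budget > 20 * self.n_subjects:
                raise ValueError("requested record counts exceed the "
                                 "record budget")


@dataclass(frozen=True)
class TruthSpec:
    """Generating truth: population spec + concentration generator.

    The paediatric concentration generator is a seeded lognormal
    (median ``conc_median_ugl``, geometric SD ``conc_gsd``) scaled by a
    unimodal time-since-dose template peaking at ``conc_peak_h`` and
    truncated at ``conc_max_ugl`` (the highest observed paediatric
    enalaprilat concentration).  ANG I values are lognormal around
    ``angi_median_pgml`` with a feedback rise as ANG II falls
    (exponent ``angi_feedback`` of the inhibition-driven ANG II drop),
    mirroring the loss of negative feedback on renin secretion.
    """

    spec: PopulationSpec
    model: ModelConfig
    conc_median_ugl: float = 3.0
    conc_gsd: float = 2.5
    conc_max_ugl: float = 18.3
    conc_peak_h: float = 3.5
    angi_median_pgml: float = 250.0
    angi_gsd: float = 1.85
    angi_feedback: float = 0.5

    @classmethod
    def adult(cls, **kw) -> "TruthSpec":
        spec, model = adult_final_spec()
        return cls(spec=spec, model=model, **kw)

    @classmethod
    def paediatric(cls, **kw) -> "TruthSpec":
        spec, model = paediatric_final_spec()
        return cls(spec=spec, model=model, **kw)


def draw_individual_parameters(spec: PopulationSpec, n: int,
                               rng: np.random.Generator,
                               covariates: Mapping[str, np.ndarray]
                               | None = None) -> dict[str, np.ndarray]:
    """Sample n subjects' parameters from the population model."""
    names = spec.random_parameters
    omega = spec.omega_matrix()
    if names:
        eta = rng.multivariate_normal(np.zeros(len(names)), omega, size=n,
                                      method="cholesky") \
            if np.any(omega) else np.zeros((n, len(names)))
    else:
        eta = np.zeros((n, 0))
    out = {}
    for p, v in spec.fixed.items():
        if p in names:
            out[p] = v * np.exp(eta[:, names.index(p)])
        else:
            out[p] = np.full(n, float(v))
    for link in spec.covariate_links:
        if covariates is None or link.covariate not in covariates:
            raise ValueError(f"covariate {link.covariate!r} required")
        out[link.parameter] = out[link.parameter] * \
            np.asarray(link.factor(covariates[link.covariate]))
    # a valid transit chain needs k_tr*Mtt > 1: redraw the far tail
    if "k_tr" in out and "mtt" in out and names:
        bad = np.asarray(out["k_tr"] * out["mtt"] <= 1.05)
        while bad.any():
            eta_b = rng.multivariate_normal(np.zeros(len(names)), omega,
                                            size=int(bad.sum()),
                                            method="cholesky")
            for p in spec.fixed:
                if p in names:
                    out[p][bad] = spec.fixed[p] * \
                        np.exp(eta_b[:, names.index(p)])
            bad = np.asarray(out["k_tr"] * out["mtt"] <= 1.05)
    return out


def _positive_proportional_noise(rng, f, b):
    """f * (1 + b*eps) with eps redrawn until the result is positive."""
    if b == 0:
        return np.array(f, dtype=float, copy=True)
    y = f * (1.0 + b * rng.standard_normal(np.shape(f)))
    bad = y <= 0
    while bad.any():
        y[bad] = f[bad] * (1.0 + b * rng.standard_normal(bad.sum()))
        bad = y <= 0
    return y


def _adult_covariates(n: int, rng) -> list[dict]:
    """Adult demographics within the study's ranges (2:1 male:female)."""
    n_f = max(1, round(n / 3))
    sex = np.array([1] * n_f + [0] * (n - n_f))
    rng.shuffle(sex)
    return [{"age": float(rng.integers(19, 31)),
             "weight": float(np.round(rng.uniform(47, 88), 1)),
             "bmi": float(np.round(rng.uniform(18, 25), 1)),
             "sex": int(s)} for s in sex]


def generate_adult_study(design: AdultDesign = AdultDesign(),
                         truth: TruthSpec | None = None,
                         seed: int = 0) -> StudyDataset:
    """Simulate one adult study; deterministic given the seed."""
    truth = truth or TruthSpec.adult()
    spec = truth.spec
    needed = set(spec.random_parameters)
    model_params = {"k_tr", "mtt", "k_a", "cl_f", "v1_f", "q_f", "v2_f",
                    "k_e0", "gamma", "e0", "ic50", "imax", "tlag"}
    if not needed <= model_params:
        raise ValueError(f"IIV on parameters absent from the structural "
                         f"model: {sorted(needed - model_params)}")
    rng = np.random.default_rng(seed)
    n = design.n_subjects
    covs = _adult_covariates(n, rng)
    cov_arrays = {k: np.array([c[k] for c in covs], dtype=float)
                  for k in ("age", "weight", "bmi", "sex")}
    params = draw_individual_parameters(spec, n, rng,
                                        covariates=cov_arrays)
    regimen = Regimen.single(design.dose_ug)
    pk_post = np.asarray([t for t in design.pk_times if t > 0])
    times = np.unique(np.concatenate([pk_post, np.asarray(design.pd_times)]))
    prof = predict_profiles(params, regimen, times, truth.model)
    idx_pk = np.searchsorted(times, pk_post)
    idx_pd = np.searchsorted(times, np.asarray(design.pd_times))
    err_pk = spec.errors["pk"]
    err_pd = spec.errors["pd"]
    lloq = ADULT_ASSAY.limits["ENALAPRILAT"].lloq
    subjects = []
    for i in range(n):
        sid = f"A{i + 1:02d}"
        obs: list[Observation] = []
        # predose PK sample: drug-naive, below LLOQ by construction
        obs.append(Observation(sid, 0.0, "ENALAPRILAT", lloq,
                               censored=True))
        f_pk = prof["conc"][i, idx_pk]
        eps = rng.standard_normal(f_pk.size)
        y_pk = f_pk + err_pk.sd(f_pk) * eps
        keep = np.ones(f_pk.size, dtype=bool)
        if i in design.missing_plan:
            drop = rng.choice(f_pk.size, size=design.missing_plan[i],
                              replace=False)
            keep[drop] = False
        for t, y in zip(pk_post[keep], y_pk[keep]):
            if y < lloq:
                obs.append(Observation(sid, float(t), "ENALAPRILAT", lloq,
                                       censored=True))
            else:
                obs.append(Observation(sid, float(t), "ENALAPRILAT",
                                       float(y)))
        ce = np.clip(prof["ce"][i, idx_pd], 0.0, None)
        f_pd = imax_ratio(ce, params["e0"][i], params["ic50"][i],
                          imax=params.get("imax", np.ones(n))[i],
                          gamma=params.get("gamma", np.ones(n))[i])
        y_pd = _positive_proportional_noise(rng, np.asarray(f_pd), err_pd.b)
        for t, y in zip(design.pd_times, y_pd):
            obs.append(Observation(sid, float(t), "RATIO", float(y)))
        subjects.append(SubjectRecord(
            sid, covs[i], doses=(DoseEvent(sid, 0.0, design.dose_ug),),
            observations=tuple(obs)))
    return StudyDataset("adult", tuple(subjects), ADULT_ASSAY)


# ---------------------------------------------------------------------------
# paediatric generation


def _paediatric_covariates(n: int, rng, design: PaediatricDesign
                           ) -> list[dict]:
    lo_a, hi_a = design.age_range_y
    lo_w, hi_w = design.weight_range_kg
    age = np.clip(0.36 * np.exp(0.8 * rng.standard_normal(n)), lo_a, hi_a)
    wt = np.clip(4.8 * (age / 0.36) ** 0.35 *
                 np.exp(0.15 * rng.standard_normal(n)), lo_w, hi_w)
    n_dcm = max(1, round(n * 3 / 27)) if n >= 9 else 0
    aet = np.array(["DCM"] * n_dcm + ["CHD"] * (n - n_dcm))
    rng.shuffle(aet)
    n_f = round(n * 15 / 27)
    sex = np.array([1] * n_f + [0] * (n - n_f))
    rng.shuffle(sex)
    return [{"age": float(np.round(age[i], 2)),
             "weight": float(np.round(wt[i], 1)),
             "sex": int(sex[i]),
             "ross": int(rng.integers(0, 10)),
             "aetiology": str(aet[i])} for i in range(n)]


def _conc_at(rng, truth: TruthSpec, tsld: float) -> float:
    """Enalaprilat concentration (µg/L) at a given time since dose."""
    tp = truth.conc_peak_h
    template = (tsld / tp) * math.exp(1.0 - tsld / tp) if tsld > 0 else 0.0
    draw = truth.conc_median_ugl * math.exp(
        math.log(truth.conc_gsd) * rng.standard_normal())
    return min(draw * template, truth.conc_max_ugl)


def _ratio_record(rng, truth: TruthSpec, ic50_i: float, conc: float
                  ) -> tuple[float, bool, float, float]:
    """(recorded ratio, substituted?, ANG I, ANG II) for one visit.

    The true ratio follows the direct Imax model with proportional
    noise; raw angiotensins are reconstructed around it (ANG I with a
    feedback rise as inhibition deepens) and the ANG II below-LLOQ
    substitution is applied exactly as in the analysis dataset.
    """
    spec = truth.spec
    f = imax_ratio(conc, spec.fixed["e0"], ic50_i)
    y = float(_positive_proportional_noise(
        rng, np.asarray([f]), spec.errors["pd"].b)[0])
    feedback = (spec.fixed["e0"] / max(f, 1e-6)) ** truth.angi_feedback
    ang1 = truth.angi_median_pgml * feedback * math.exp(
        math.log(truth.angi_gsd) * rng.standard_normal())
    ang1 = float(np.clip(ang1, PAEDIATRIC_ASSAY.limits["ANGI"].lloq * 1.01,
                         PAEDIATRIC_ASSAY.limits["ANGI"].uloq * 0.99))
    ang2 = y * ang1
    res = compute_ratio(ang2, ang1, PAEDIATRIC_ASSAY)
    if res.excluded:  # ANG I clipped above LLOQ, so this cannot happen
        raise AssertionError("unreachable: ANG I kept quantifiable")
    return float(res.value), res.substituted, ang1, ang2


def _paediatric_visit_obs(rng, truth, sid, t, tsld, ic50_i, design,
                          tag=None) -> list[Observation]:
    conc = _conc_at(rng, truth, tsld) if tsld is not None else 0.0
    ratio, subst, ang1, ang2 = _ratio_record(rng, truth, ic50_i, conc)
    obs = [Observation(sid, t, "ENALAPRILAT", conc, excluded=tag),
           Observation(sid, t, "RATIO", ratio, substituted=subst,
                       excluded=tag)]
    if design.include_raw_angiotensins:
        obs += [Observation(sid, t, "ANGI", ang1, excluded=tag),
                Observation(sid, t, "ANGII", ang2, excluded=tag)]
    return obs


def generate_paediatric_study(design: PaediatricDesign = PaediatricDesign(),
                              truth: TruthSpec | None = None,
                              seed: int = 0) -> StudyDataset:
    """Simulate one paediatric study; deterministic given the seed."""
    truth = truth or TruthSpec.paediatric()
    spec = truth.spec
    rng = np.random.default_rng(seed)
    n = design.n_subjects
    covs = _paediatric_covariates(n, rng, design)
    om = spec.iiv.get("ic50", 0.0)
    ic50 = spec.fixed["ic50"] * np.exp(om * rng.standard_normal(n))
    wt = np.array([c["weight"] for c in covs])
    first_mgkg = rng.uniform(*design.first_dose_mgkg, size=n)
    daily_mgkg = rng.uniform(*design.daily_dose_mgkg, size=n)
    qd_subject = int(rng.integers(0, n)) if n > 1 else 0
    interval = np.full(n, design.dose_interval_h)
    interval[qd_subject] = 24.0
    daily_mgkg[qd_subject] = design.daily_dose_mgkg[0]

    def dose_events(i: int, horizon: float) -> tuple[DoseEvent, ...]:
        sid = f"P{i + 1:02d}"
        amt_first = first_mgkg[i] * wt[i] * 1000.0
        amt_maint = daily_mgkg[i] * wt[i] * 1000.0 / (24.0 / interval[i])
        times = [0.0]
        t = interval[i]
        while t <= horizon + interval[i]:
            times.append(t)
            t += interval[i]
        return tuple(DoseEvent(sid, t, amt_first if t == 0 else amt_maint)
                     for t in times)

    visit_lists: dict[int, list] = {i: [] for i in range(n)}
    if design.study_plan:
        n_pre, n_first, n_rep = design.class_counts
        for i in range(n_pre):
            visit_lists[i].append(("predose_first", 0.0, None, None))
        for i in range(n_first):
            visit_lists[i].append(("post_first", 4.0, 4.0, None))
        rep_days = np.sort(rng.uniform(3.9, 355.0, size=n_rep))
        for k in range(n_rep):
            i = k % n
            tsld = float(rng.uniform(0.5, min(12.0, interval[i])))
            visit_lists[i].append(("post_repeated", rep_days[k], tsld,
                                   None))
        tags = [t for t, c in design.exclusion_counts.items()
                for _ in range(c)]
        for k, tag in enumerate(tags):
            i = (n - 1 - k) % n
            day = float(rng.uniform(4.0, 300.0))
            tsld = float(rng.uniform(0.5, min(12.0, interval[i])))
            visit_lists[i].append(("excluded", day, tsld, tag))
    else:
        for i in range(n):
            visit_lists[i].append(("predose_first", 0.0, None, None))
            visit_lists[i].append(("post_first", 4.0, 4.0, None))
            for _ in range(design.visits_per_subject - 1):
                day = float(rng.uniform(4.0, 120.0))
                tsld = float(rng.uniform(0.5, min(12.0, interval[i])))
                visit_lists[i].append(("post_repeated", day, tsld, None))

    subjects = []
    for i in range(n):
        sid = f"P{i + 1:02d}"
        obs: list[Observation] = []
        times_used = set()
        horizon = 24.0
        planned = []
        for kind, when, tsld, tag in visit_lists[i]:
            if kind == "predose_first":
                planned.append((0.0, None, tag))
            elif kind == "post_first":
                planned.append((when, when, tag))
            else:
                # align the visit to the dosing grid: dose at k*interval,
                # sample tsld hours later
                base = math.floor(when * 24.0 / interval[i]) * interval[i]
                base = max(base, interval[i])
                planned.append((base + tsld, tsld, tag))
        for t, tsld, tag in planned:
            horizon = max(horizon, t)
        doses = dose_events(i, horizon)
        for t, tsld, tag in sorted(planned):
            while t in times_used:  # keep records at distinct times
                t += 0.25
            times_used.add(t)
            obs.extend(_paediatric_visit_obs(rng, truth, sid, t, tsld,
                                             ic50[i], design, tag=tag))
        subjects.append(SubjectRecord(sid, covs[i], doses=doses,
                                      observations=tuple(obs)))
    return StudyDataset("paediatric", tuple(subjects), PAEDIATRIC_ASSAY)


def inject_blq(series: Sequence[Observation], lloq: float, mode: str
               ) -> list[Observation]:
    """Apply a below-LLOQ treatment to an observation series.

    Modes: ``censor_interval`` (interval-censor on [0, LLOQ]),
    ``substitute_half`` (replace by LLOQ/2, flag substituted),
    ``exclude_both`` (tag the record excluded).  The raw value is
    compared strictly against the LLOQ.
    """
    if lloq <= 0:
        raise ValueError("lloq must be positive")
    if mode not in ("censor_interval", "substitute_half", "exclude_both"):
        raise ValueError(f"unknown BLQ mode {mode!r}")
    out = []
    for ob in series:
        if ob.censored or not ob.value < lloq:
            out.append(ob)
        elif mode == "censor_interval":
            out.append(replace(ob, value=lloq, censored=True, lower=0.0))
        elif mode == "substitute_half":
            out.append(replace(ob, value=lloq / 2.0, substituted=True))
        else:
            out.append(replace(ob, excluded="BOTH_BLQ"))
    return out
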