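"""End-to-end workflows: staged fits, model search, diagnostics, manifests.

The adult workflow mirrors the staged analysis of the rich single-dose
study: a PK-only fit first, whose estimates initialise the simultaneous
PK/PD fit; then the covariate search, the random-effect correlation
test, uncertainty quantification, and goodness-of-fit/VPC diagnostics.
The paediatric workflow applies the exclusion rules, fits the direct
full-inhibition Imax model (IIV on IC50 only, proportional error),
reports the predose-to-4-h percent change in the ratio, and can overlay
the paediatric observations on an adult VPC.

Every run is driven by a config mapping with explicit seeds and is
summarised in a :class:`RunManifest` so that outputs are re-derivable
from (config, seeds, code version).
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .config import dump_population_spec, load_population_spec
from .datasets import (StudyDataset, apply_adult_inclusion_rules,
                       apply_paediatric_exclusion_rules,
                       dataset_fingerprint, read_dataset)
from .diagnostics import comparison_overlay, gof, percent_change_4h, vpc
from .estimation import (FitResult, FitSettings, build_adapter, compute_ofv,
                         correlation_test_random_effects, estimate_rse,
                         fit_population, lrt_stepwise_covariates)
from .population import ErrorModel, PopulationSpec, omega_to_cv
from .simulate import (AdultDesign, PaediatricDesign, TruthSpec,
                       generate_adult_study, generate_paediatric_study)

__all__ = [
    "RunManifest",
    "DEFAULT_ADULT_INIT",
    "DEFAULT_PAED_INIT",
    "dataset_fingerprint",
    "run_adult_workflow",
    "run_paediatric_workflow",
    "compare_models",
]

#: Neutral round-number initial estimates for the adult model.
DEFAULT_ADULT_INIT = PopulationSpec(
    fixed={"k_tr": 3.0, "mtt": 1.0, "k_a": 1.0, "cl_f": 20.0,
           "v1_f": 150.0, "q_f": 4.0, "v2_f": 80.0, "k_e0": 1.0,
           "gamma": 1.5, "e0": 0.1, "ic50": 10.0},
    iiv={"k_tr": 0.3, "mtt": 0.3, "cl_f": 0.3, "v1_f": 0.3,
         "e0": 0.5, "ic50": 0.5},
    correlations=(("v1_f", "cl_f", 0.3),),
    errors={"pk": ErrorModel("combined", a=1.0, b=0.2),
            "pd": ErrorModel("proportional", b=0.3)})

#: Neutral initial estimates for the paediatric direct model.
DEFAULT_PAED_INIT = PopulationSpec(
    fixed={"e0": 0.1, "ic50": 3.0}, iiv={"ic50": 0.4},
    errors={"pd": ErrorModel("proportional", b=0.2)})


@dataclass
class RunManifest:
    """Ordered record of the stages of one workflow run."""

    workflow: str
    config: dict
    version: str = _version
    stages: list = field(default_factory=list)

    def add(self, name: str, seed: int | None, **info) -> None:
        self.stages.append({"stage": name, "seed": seed,
                            "timestamp": _time.time(), **info})

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.floating, np.integer)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)
        return json.dumps({"workflow": self.workflow,
                           "version": self.version,
                           "config": self.config,
                           "stages": self.stages},
                          indent=2, default=default)


class StageError(RuntimeError):
    """A workflow stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_or_generate(config: Mapping, population: str):
    src = config.get("dataset", {})
    if "path" in src:
        return read_dataset(src["path"], population=population), None
    seed = int(src.get("seed", config.get("seed", 0)))
    if population == "adult":
        design = AdultDesign(
            n_subjects=int(src.get("n_subjects", 9)),
            missing_plan=src.get("missing_plan", {0: 5, 1: 4})
            if int(src.get("n_subjects", 9)) == 9 else {})
        truth_name = src.get("truth", "adult_final")
        spec, model, _ = load_population_spec(truth_name)
        return generate_adult_study(design, TruthSpec(spec, model),
                                    seed=seed), seed
    design = PaediatricDesign(n_subjects=int(src.get("n_subjects", 27)))
    truth_name = src.get("truth", "paediatric_final")
    spec, model, _ = load_population_spec(truth_name)
    return generate_paediatric_study(design, TruthSpec(spec, model),
                                     seed=seed), seed


def _settings_from(config: Mapping, default_seed: int = 0) -> FitSettings:
    s = config.get("settings", {})
    return FitSettings(
        n_explore=int(s.get("n_explore", 300)),
        n_smooth=int(s.get("n_smooth", 100)),
        mcmc_transitions=int(s.get("mcmc_transitions", 2)),
        seed=int(s.get("seed", config.get("seed", default_seed))))


def _fit_tables(fit: FitResult) -> dict:
    return {"estimates": fit.estimates_table(),
            "spec_yaml": dump_population_spec(
                fit.spec, "adult" if fit.adapter_kind.startswith("adult")
                else "paediatric", fit.model_config)}


def run_adult_workflow(config: Mapping) -> dict:
    """Staged adult analysis; returns an artefact bundle.

    Config keys (all optional): ``dataset`` (path, or generation seed /
    n_subjects / truth), ``init`` (config path; defaults to neutral
    round numbers), ``settings`` (SAEM iterations, seed), ``stages``
    (bools: covariate_search, correlation_test, rse, vpc, gof),
    ``vpc_nsim``, ``seed``.
    """
    manifest = RunManifest("adult", dict(config))
    bundle: dict = {"manifest": manifest}
    stages = dict(config.get("stages", {}))
    try:
        ds_raw, gen_seed = _load_or_generate(config, "adult")
        ds, audit = apply_adult_inclusion_rules(ds_raw)
        manifest.add("data", gen_seed, audit=audit,
                     fingerprint=dataset_fingerprint(ds))
        bundle["dataset"] = ds
        bundle["audit"] = audit
    except Exception as e:
        raise StageError("data", e) from e

    if "init" in config:
        init, _, _ = load_population_spec(config["init"])
    else:
        init = DEFAULT_ADULT_INIT
    settings = _settings_from(config)

    try:
        pk_init = PopulationSpec(
            fixed={p: v for p, v in init.fixed.items()
                   if p in ("k_tr", "mtt", "k_a", "cl_f", "v1_f", "q_f",
                            "v2_f")},
            iiv={p: v for p, v in init.iiv.items()
                 if p in ("k_tr", "mtt", "cl_f", "v1_f")},
            correlations=[c for c in init.correlations
                          if c[0] != "e0" and c[1] != "e0"],
            errors={"pk": init.errors["pk"]})
        fit_pk = fit_population(ds, "adult_pk", pk_init, settings)
        manifest.add("fit_pk", settings.seed,
                     estimates=dict(fit_pk.spec.fixed))
        bundle["fit_pk"] = fit_pk
    except Exception as e:
        raise StageError("fit_pk", e) from e

    try:
        # stage-2 initialisation: PK estimates carried over verbatim
        pkpd_init = PopulationSpec(
            fixed={**init.fixed, **fit_pk.spec.fixed},
            iiv={**init.iiv, **fit_pk.spec.iiv},
            correlations=fit_pk.spec.correlations or init.correlations,
            errors={"pk": fit_pk.spec.errors["pk"],
                    "pd": init.errors["pd"]})
        fit = fit_population(ds, "adult_pkpd", pkpd_init,
                             replace(settings, seed=settings.seed + 1))
        manifest.add("fit_pkpd", settings.seed + 1,
                     init=dict(pkpd_init.fixed),
                     estimates=dict(fit.spec.fixed))
        bundle["fit"] = fit
    except Exception as e:
        raise StageError("fit_pkpd", e) from e

    if stages.get("covariate_search", True):
        try:
            selected, log = lrt_stepwise_covariates(
                ds, fit, seed=settings.seed)
            manifest.add("covariate_search", settings.seed,
                         n_selected=len(selected))
            bundle["covariates"] = {"selected": selected, "log": log}
        except Exception as e:
            raise StageError("covariate_search", e) from e

    if stages.get("correlation_test", True):
        try:
            bundle["correlation_test"] = \
                correlation_test_random_effects(fit)
            manifest.add("correlation_test", None)
        except Exception as e:
            raise StageError("correlation_test", e) from e

    if stages.get("rse", False):
        try:
            bundle["rse"] = estimate_rse(fit, ds, method=config.get(
                "rse_method", "fim"), seed=settings.seed)
            manifest.add("rse", settings.seed)
        except Exception as e:
            raise StageError("rse", e) from e

    if stages.get("gof", True):
        try:
            bundle["gof"] = gof(ds, fit)
            manifest.add("gof", None)
        except Exception as e:
            raise StageError("gof", e) from e

    if stages.get("vpc", True):
        try:
            nsim = int(config.get("vpc_nsim", 500))
            bundle["vpc"] = vpc(ds, fit, nsim=nsim,
                                seed=settings.seed + 2)
            manifest.add("vpc", settings.seed + 2, nsim=nsim)
        except Exception as e:
            raise StageError("vpc", e) from e

    bundle["tables"] = _fit_tables(bundle["fit"])
    return bundle


def _percent_change_pairs(ds: StudyDataset,
                          window: tuple[float, float] = (3.5, 4.5)):
    """(predose, 4 h) ratio pairs for subjects with both available."""
    pairs = []
    for s in ds.subjects:
        if not s.doses:
            continue
        t0 = s.doses[0].time
        pre = [ob.value for ob in s.observations
               if ob.analyte == "RATIO" and not ob.excluded
               and ob.time <= t0]
        post = [ob.value for ob in s.observations
                if ob.analyte == "RATIO" and not ob.excluded
                and window[0] <= ob.time - t0 <= window[1]
                and len([d for d in s.doses if d.time < ob.time]) == 1]
        if pre and post:
            pairs.append((pre[0], post[0]))
    return pairs


def run_paediatric_workflow(config: Mapping) -> dict:
    """Paediatric analysis; returns an artefact bundle.

    Exclusion rules -> direct Imax fit (IIV on IC50, proportional
    error) -> RSE -> GoF/VPC -> percent change at 4 h -> optional
    overlay against a supplied adult fit
    (``config["adult_overlay"] = {"fit": FitResult, "dataset": ...}``).
    """
    manifest = RunManifest("paediatric", {k: v for k, v in config.items()
                                          if k != "adult_overlay"})
    bundle: dict = {"manifest": manifest}
    stages = dict(config.get("stages", {}))
    try:
        ds_raw, gen_seed = _load_or_generate(config, "paediatric")
        ds, audit = apply_paediatric_exclusion_rules(ds_raw)
        manifest.add("data", gen_seed, audit=audit,
                     fingerprint=dataset_fingerprint(ds))
        bundle["dataset"] = ds
        bundle["audit"] = audit
    except Exception as e:
        raise StageError("data", e) from e

    if "init" in config:
        init, _, _ = load_population_spec(config["init"])
    else:
        init = DEFAULT_PAED_INIT
    settings = _settings_from(config)
    try:
        fit = fit_population(ds, "paed_direct", init, settings)
        manifest.add("fit_pd", settings.seed,
                     estimates=dict(fit.spec.fixed), ofv=fit.ofv)
        bundle["fit"] = fit
    except Exception as e:
        raise StageError("fit_pd", e) from e

    if stages.get("rse", True):
        try:
            bundle["rse"] = estimate_rse(fit, ds, method="fim",
                                         seed=settings.seed)
            manifest.add("rse", settings.seed)
        except Exception as e:
            raise StageError("rse", e) from e

    if stages.get("gof", True):
        bundle["gof"] = gof(ds, fit)
        manifest.add("gof", None)
    if stages.get("vpc", True):
        nsim = int(config.get("vpc_nsim", 500))
        bundle["vpc"] = vpc(ds, fit, nsim=nsim, seed=settings.seed + 2)
        manifest.add("vpc", settings.seed + 2, nsim=nsim)

    pairs = _percent_change_pairs(ds)
    bundle["percent_change_4h"] = percent_change_4h(pairs)
    manifest.add("percent_change_4h", None, n_pairs=len(pairs))

    if "adult_overlay" in config:
        ov = config["adult_overlay"]
        try:
            bundle["overlay"] = comparison_overlay(
                ov["fit"], ov["dataset"], ds,
                nsim=int(config.get("vpc_nsim", 500)),
                seed=settings.seed + 3)
            manifest.add("overlay", settings.seed + 3)
        except Exception as e:
            raise StageError("overlay", e) from e

    bundle["tables"] = _fit_tables(bundle["fit"])
    return bundle


def compare_models(fits: Sequence[FitResult],
                   ds: StudyDataset | None = None,
                   nmc: int = 400, seed: int = 0,
                   labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Side-by-side model comparison table.

    Reports OFV (recomputed by importance sampling on the shared
    dataset when not already present), residual-error coefficients, IIV
    CV% and the largest RSE if available.  All fits must concern the
    same dataset.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    fps = {f.metadata.get("dataset_fingerprint") for f in fits
           if "dataset_fingerprint" in f.metadata}
    if len(fps) > 1:
        raise ValueError("fits were obtained on different datasets")
    rows = []
    for k, f in enumerate(fits):
        ofv, se = (f.ofv, f.ofv_se or 0.0)
        if ofv is None:
            if ds is None:
                raise ValueError("dataset required to recompute OFV")
            adapter = build_adapter(f.adapter_kind, ds)
            ofv, se = compute_ofv(adapter, None, f.spec, nmc=nmc,
                                  seed=seed)
        row = {"model": labels[k] if labels else f"fit_{k}",
               "method": f.method, "ofv": ofv, "ofv_mc_se": se,
               "n_fixed": len(f.spec.fixed),
               "n_iiv": len(f.spec.iiv)}
        for stream, err in f.spec.errors.items():
            row[f"{stream}_prop_err"] = err.b
            if err.kind == "combined":
                row[f"{stream}_add_err"] = err.a
        for p, om in f.spec.iiv.items():
            row[f"iiv_{p}_cv"] = omega_to_cv(om)
        if f.rse:
            row["max_rse"] = max(f.rse.values())
        rows.append(row)
    return pd.DataFrame(rows)
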