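"""Structured-config serialisation of population specs and model choices.

The packaged ``adult_final`` and ``paediatric_final`` configs carry the
published final-model parameter sets and double as the default truths of
the synthetic-study generators.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .population import CovariateLink, ErrorModel, PopulationSpec, cv_to_omega, omega_to_cv
from .structural import ModelConfig

__all__ = ["load_population_spec", "dump_population_spec",
           "adult_final_spec", "paediatric_final_spec"]


def _spec_from_dict(doc: dict) -> tuple[PopulationSpec, ModelConfig, str]:
    errors = {k: ErrorModel(**v) for k, v in doc.get("errors", {}).items()}
    links = tuple(CovariateLink(**d) for d in doc.get("covariate_links", []))
    iiv = {p: cv_to_omega(cv)
           for p, cv in doc.get("iiv_cv_percent", {}).items()}
    iiv.update(doc.get("iiv_omega", {}))
    spec = PopulationSpec(
        fixed=doc["fixed"], iiv=iiv,
        correlations=tuple(tuple(c) for c in doc.get("correlations", [])),
        covariate_links=links, errors=errors)
    model = ModelConfig(**doc.get("model", {}))
    return spec, model, doc.get("population", "adult")


def load_population_spec(source) -> tuple[PopulationSpec, ModelConfig, str]:
    """Load (spec, model config, population) from a YAML file or name.

    ``source`` may be a path or one of the packaged names
    ``"adult_final"`` / ``"paediatric_final"``.
    """
    if source in ("adult_final", "paediatric_final"):
        text = resources.files("ratiopkpd.configs") \
            .joinpath(f"{source}.yaml").read_text()
    else:
        text = Path(source).read_text()
    return _spec_from_dict(yaml.safe_load(text))


def dump_population_spec(spec: PopulationSpec, population: str,
                         model: ModelConfig | None = None,
                         path=None) -> str:
    """Serialise a spec back to the YAML config dialect."""
    doc = {
        "population": population,
        "fixed": {k: float(v) for k, v in spec.fixed.items()},
        "iiv_cv_percent": {p: float(omega_to_cv(om))
                           for p, om in spec.iiv.items()},
        "correlations": [[a, b, float(r)]
                         for a, b, r in spec.correlations],
        "errors": {k: ({"kind": e.kind, "b": float(e.b)}
                       | ({"a": float(e.a)} if e.kind == "combined" else {}))
                   for k, e in spec.errors.items()},
    }
    if spec.covariate_links:
        doc["covariate_links"] = [
            {"parameter": l.parameter, "covariate": l.covariate,
             "form": l.form, "coefficient": float(l.coefficient),
             "reference": float(l.reference)}
            for l in spec.covariate_links]
    if model is not None:
        doc["model"] = {
            "absorption": model.absorption,
            "disposition": model.disposition,
            "pd_link": model.pd_link,
            "inhibition": model.inhibition,
            "hill": model.hill,
        }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def adult_final_spec() -> tuple[PopulationSpec, ModelConfig]:
    spec, model, _ = load_population_spec("adult_final")
    return spec, model


def paediatric_final_spec() -> tuple[PopulationSpec, ModelConfig]:
    spec, model, _ = load_population_spec("paediatric_final")
    return spec, model
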