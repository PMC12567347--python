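"""Hierarchical statistical layer of the population model.

Inter-individual variability (IIV) is lognormal: each subject's parameter
is ``theta_pop * exp(eta)`` with ``eta ~ N(0, Omega)``.  IIV magnitudes
are reported on the CV% scale, related to the log-scale SD ``omega`` by
the exact lognormal transform ``omega = sqrt(ln(1 + (cv/100)^2))``.
Selected pairs of random effects may be correlated (off-diagonal Omega).

Covariate effects enter multiplicatively: a power model
``(cov/ref)^beta`` for continuous covariates (centred at a weighted mean)
and ``exp(beta * I[category])`` for categorical ones.

Residual errors are proportional (sd = b*f) or combined additive +
proportional (sd = a + b*f, the Monolix ``combined1`` convention; the
quadrature form sqrt(a^2 + b^2 f^2) is selectable for sensitivity
checks).  Observations below the lower limit of quantification enter the
likelihood as interval-censored on [0, LLOQ] — the probability mass the
Gaussian residual model puts on that interval (M4-style handling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import log_ndtr

__all__ = [
    "ErrorModel",
    "CovariateLink",
    "PopulationSpec",
    "cv_to_omega",
    "omega_to_cv",
    "realise_individual",
    "observation_loglik",
]


def cv_to_omega(cv_percent):
    """Log-scale SD of a lognormal random effect with the given CV%."""
    cv = np.asarray(cv_percent, dtype=float)
    if np.any(cv < 0):
        raise ValueError("CV% must be non-negative")
    out = np.sqrt(np.log1p((cv / 100.0) ** 2))
    return float(out) if out.ndim == 0 else out


def omega_to_cv(omega):
    """CV% of a lognormal random effect with log-scale SD ``omega``."""
    om = np.asarray(omega, dtype=float)
    if np.any(om < 0):
        raise ValueError("omega must be non-negative")
    out = 100.0 * np.sqrt(np.expm1(om ** 2))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ErrorModel:
    """Residual-error model for one observation stream.

    ``kind`` is "proportional" (sd = b*f) or "combined" (sd = a + b*f by
    default; ``variant="quadrature"`` switches to sqrt(a^2 + b^2 f^2)).
    """

    kind: str
    b: float
    a: float = 0.0
    variant: str = "linear"

    def __post_init__(self) -> None:
        if self.kind not in ("proportional", "combined"):
            raise ValueError("kind must be 'proportional' or 'combined'")
        if self.variant not in ("linear", "quadrature"):
            raise ValueError("variant must be 'linear' or 'quadrature'")
        if self.b < 0 or self.a < 0:
            raise ValueError("error coefficients must be non-negative")
        if self.kind == "proportional" and self.a != 0:
            raise ValueError("proportional error has no additive term")

    def sd(self, f):
        f = np.asarray(f, dtype=float)
        if self.kind == "proportional":
            return self.b * np.abs(f)
        if self.variant == "linear":
            return self.a + self.b * np.abs(f)
        return np.sqrt(self.a ** 2 + (self.b * f) ** 2)


@dataclass(frozen=True)
class CovariateLink:
    """Multiplicative covariate effect on one structural parameter."""

    parameter: str
    covariate: str
    form: str  # power_scaled | exponential_categorical
    coefficient: float
    reference: float = 1.0

    def __post_init__(self) -> None:
        if self.form not in ("power_scaled", "exponential_categorical"):
            raise ValueError(f"unknown covariate form {self.form!r}")
        if self.form == "power_scaled" and self.reference <= 0:
            raise ValueError("power link requires a positive reference")

    def factor(self, value):
        if self.form == "power_scaled":
            return (np.asarray(value, dtype=float) / self.reference) ** \
                self.coefficient
        return np.exp(self.coefficient * np.asarray(value, dtype=float))


@dataclass(frozen=True)
class PopulationSpec:
    """Fixed effects + IIV + correlations + covariate links + errors."""

    fixed: Mapping[str, float]
    iiv: Mapping[str, float] = field(default_factory=dict)  # param -> omega
    correlations: Sequence[tuple[str, str, float]] = ()
    covariate_links: Sequence[CovariateLink] = ()
    errors: Mapping[str, ErrorModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed", dict(self.fixed))
        object.__setattr__(self, "iiv", dict(self.iiv))
        object.__setattr__(self, "correlations",
                           tuple(tuple(c) for c in self.correlations))
        object.__setattr__(self, "covariate_links",
                           tuple(self.covariate_links))
        object.__setattr__(self, "errors", dict(self.errors))
        for p, om in self.iiv.items():
            if p not in self.fixed:
                raise ValueError(f"IIV on unknown parameter {p!r}")
            if om < 0:
                raise ValueError(f"omega for {p!r} must be non-negative")
        for p1, p2, r in self.correlations:
            if p1 not in self.iiv or p2 not in self.iiv:
                raise ValueError(
                    f"correlation ({p1}, {p2}) requires IIV on both")
            if not abs(r) < 1:
                raise ValueError("|correlation| must be < 1")
        # loud positive-definiteness check at construction time
        self.omega_matrix()

    @property
    def random_parameters(self) -> tuple[str, ...]:
        """Parameters carrying IIV, in fixed-effect declaration order."""
        return tuple(p for p in self.fixed if p in self.iiv)

    def omega_matrix(self) -> np.ndarray:
        """Covariance matrix of the log-scale random effects."""
        names = self.random_parameters
        om = np.array([self.iiv[p] for p in names])
        O = np.diag(om ** 2)
        idx = {p: i for i, p in enumerate(names)}
        for p1, p2, r in self.correlations:
            O[idx[p1], idx[p2]] = O[idx[p2], idx[p1]] = r * om[idx[p1]] * \
                om[idx[p2]]
        active = om > 0
        if active.any():
            sub = O[np.ix_(active, active)]
            eig = np.linalg.eigvalsh(sub)
            if eig.min() <= -1e-12 * max(eig.max(), 1.0):
                raise ValueError(
                    "implied Omega matrix is not positive semi-definite "
                    f"(min eigenvalue {eig.min():.3e})")
        return O

    def iiv_cv_percent(self) -> dict[str, float]:
        return {p: omega_to_cv(om) for p, om in self.iiv.items()}


def realise_individual(spec: PopulationSpec,
                       eta: Mapping[str, float] | Sequence[float],
                       covariates: Mapping[str, float] | None = None,
                       ) -> dict[str, float]:
    """Subject-level parameters from population values, eta, covariates.

    ``theta_i = theta_pop * exp(eta_i) * prod(covariate factors)``;
    parameters without IIV take eta = 0.  ``eta`` may be a mapping or a
    vector aligned with ``spec.random_parameters``.
    """
    names = spec.random_parameters
    if not isinstance(eta, Mapping):
        eta = np.asarray(eta, dtype=float)
        if eta.shape[-1] != len(names):
            raise ValueError(
                f"eta has dimension {eta.shape[-1]}, expected {len(names)}")
        eta = dict(zip(names, eta))
    out = {}
    for p, val in spec.fixed.items():
        out[p] = val * math.exp(eta.get(p, 0.0))
    for link in spec.covariate_links:
        if covariates is None or link.covariate not in covariates:
            raise ValueError(
                f"covariate {link.covariate!r} required by a link on "
                f"{link.parameter!r} is missing")
        out[link.parameter] *= float(link.factor(covariates[link.covariate]))
    return out


def _log_interval_prob(lower, upper, f, sd):
    """log P(lower < Y < upper) for Y ~ N(f, sd), computed in log space."""
    hi = log_ndtr((upper - f) / sd)
    lo = log_ndtr((lower - f) / sd)
    with np.errstate(divide="ignore"):
        return hi + np.log1p(-np.exp(np.minimum(lo - hi, 0.0)))


def observation_loglik(y, f, error: ErrorModel, censored=False,
                       lloq=None, lower=0.0):
    """Log-likelihood contribution of one observation (vectorised).

    Uncensored: Gaussian log-density of ``y`` with mean ``f`` and the
    error model's sd.  Censored: log-probability that the Gaussian falls
    in [``lower``, LLOQ] (unconditional interval treatment of a
    below-quantification value with a stated lower bound of zero).
    """
    f = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("model prediction must be finite")
    sd = error.sd(f)
    if np.any(sd <= 0):
        raise ValueError("residual sd must be positive at the prediction")
    censored = np.asarray(censored, dtype=bool)
    if censored.any():
        if lloq is None:
            raise ValueError("censored observation requires an LLOQ")
        lloq_arr = np.broadcast_to(np.asarray(lloq, dtype=float), f.shape) \
            if f.ndim else np.asarray(lloq, dtype=float)
        if np.any(np.where(censored, lloq_arr, 1.0) <= lower):
            raise ValueError("censoring bound must exceed the lower limit")
    y = np.asarray(y, dtype=float)
    dens = -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((y - f) / sd) ** 2
    if not censored.any():
        out = dens
    else:
        cens = _log_interval_prob(lower, np.asarray(lloq, dtype=float), f, sd)
        out = np.where(censored, cens, dens)
    return float(out) if out.ndim == 0 else out
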