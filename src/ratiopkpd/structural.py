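"""Deterministic structural PK/PD models.

Forward models for enalaprilat disposition and its effect on the
angiotensin II/angiotensin I ratio:

* absorption: a continuous transit-compartment chain (gamma-flow input
  parameterised by the transit rate constant ``k_tr`` and the mean transit
  time ``Mtt``) feeding a first-order absorption compartment; a lag-time
  and a plain first-order variant are selectable for model comparison;
* disposition: one- or two-compartment linear kinetics with apparent
  clearance/volume parameters (oral bioavailability is not identifiable,
  so all clearances and volumes are apparent, i.e. scaled by 1/F);
* effect link: either a hypothetical effect compartment with first-order
  transfer rate ``k_e0`` (delayed effect, explains clockwise hysteresis)
  or a direct link;
* pharmacodynamics: an inhibitory sigmoid Imax model on the
  ANG II/ANG I ratio, ``E0 * (1 - Imax * Ce^g / (Ce^g + IC50^g))``.

The linear system is solved semi-analytically: the compartment matrix is
eigendecomposed once per parameter set, so the impulse response is an
explicit sum of exponentials, and the transit (gamma-density) input is
convolved with it by fixed-order Gauss-Legendre quadrature restricted to
the support of the input.  This is deterministic, stiff-solver free, and
vectorises across subjects, which the stochastic estimation loop relies
on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import special, stats

__all__ = [
    "AdultStructuralParams",
    "PaedPDParams",
    "Regimen",
    "ModelConfig",
    "transit_input_rate",
    "transit_chain_profile",
    "concentration_profile",
    "effect_site_profile",
    "imax_ratio",
    "predict_profiles",
]

_GL_NODES, _GL_WEIGHTS = leggauss(40)


class ParameterisationError(ValueError):
    """Raised when structural parameters fall outside their valid domain."""


@dataclass(frozen=True)
class AdultStructuralParams:
    """Structural parameters of the adult PK/PD model.

    Units: rate constants 1/h, ``mtt`` h, clearances L/h, volumes L,
    ``ic50`` µg/L; ``gamma``, ``e0``, ``imax`` dimensionless.  ``tlag``
    (h) is only used by the lag-time absorption variant.
    """

    k_tr: float
    mtt: float
    k_a: float
    cl_f: float
    v1_f: float
    q_f: float
    v2_f: float
    k_e0: float
    gamma: float
    e0: float
    ic50: float
    imax: float = 1.0
    tlag: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_tr", "mtt", "k_a", "cl_f", "v1_f", "q_f", "v2_f",
                     "k_e0", "gamma", "e0", "ic50"):
            if not getattr(self, name) > 0:
                raise ParameterisationError(f"{name} must be positive")
        if not 0 < self.imax <= 1:
            raise ParameterisationError("imax must lie in (0, 1]")


@dataclass(frozen=True)
class PaedPDParams:
    """Parameters of the paediatric direct full-inhibition Imax model."""

    e0: float
    ic50: float
    imax: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not self.e0 > 0:
            raise ParameterisationError("e0 must be positive")
        if not self.ic50 > 0:
            raise ParameterisationError("ic50 must be positive")


@dataclass(frozen=True)
class Regimen:
    """Ordered oral dose events; amounts in µg of enalapril maleate."""

    times: tuple[float, ...]
    amounts: tuple[float, ...]
    horizon: float = np.inf

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size != len(self.amounts):
            raise ValueError("times and amounts must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("dose times must be strictly increasing")
        if np.any(np.asarray(self.amounts) <= 0):
            raise ValueError("dose amounts must be positive")

    @classmethod
    def single(cls, amount: float, time: float = 0.0,
               horizon: float = np.inf) -> "Regimen":
        return cls(times=(time,), amounts=(amount,), horizon=horizon)


@dataclass(frozen=True)
class ModelConfig:
    """Structural model selection switches."""

    absorption: str = "transit"        # transit | lag | first_order
    disposition: str = "2cmt"          # 1cmt | 2cmt
    pd_link: str = "effect_compartment"  # direct | effect_compartment
    inhibition: str = "full"           # full | partial
    hill: str = "estimated"            # fixed1 | estimated
    # +1 transit-stage convention: n = k_tr*Mtt instead of k_tr*Mtt - 1
    transit_convention: str = "n_minus_1"  # n_minus_1 | n

    def __post_init__(self) -> None:
        checks = {
            "absorption": ("transit", "lag", "first_order"),
            "disposition": ("1cmt", "2cmt"),
            "pd_link": ("direct", "effect_compartment"),
            "inhibition": ("full", "partial"),
            "hill": ("fixed1", "estimated"),
            "transit_convention": ("n_minus_1", "n"),
        }
        for name, allowed in checks.items():
            if getattr(self, name) not in allowed:
                raise ValueError(f"{name} must be one of {allowed}")


def _transit_shape(k_tr, mtt, convention: str = "n_minus_1"):
    """Number of transit stages n implied by (k_tr, Mtt)."""
    k_tr = np.asarray(k_tr, dtype=float)
    mtt = np.asarray(mtt, dtype=float)
    n = k_tr * mtt - (1.0 if convention == "n_minus_1" else 0.0)
    if np.any(n <= 0):
        raise ParameterisationError(
            "k_tr * Mtt must exceed 1 for the transit-chain input "
            "(implied stage count would be non-positive)")
    return n


def transit_input_rate(t, dose: float, k_tr: float, mtt: float,
                       convention: str = "n_minus_1"):
    """Drug delivery rate (µg/h) of the continuous transit chain.

    rate(t) = dose * k_tr * (k_tr t)^n * exp(-k_tr t) / Gamma(n+1)
    with n = k_tr*Mtt - 1, i.e. the dose flows in as a gamma density with
    shape n+1 and rate k_tr (mean transit time (n+1)/k_tr = Mtt).
    """
    n = _transit_shape(k_tr, mtt, convention)
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    # gamma pdf with shape n+1, scale 1/k_tr; stable via log form
    logr = (np.log(k_tr) + n * np.log(k_tr * t[pos]) - k_tr * t[pos]
            - special.gammaln(n + 1.0))
    out[pos] = dose * np.exp(logr)
    return out if out.ndim else float(out)


def imax_ratio(ce, e0, ic50, imax=1.0, gamma=1.0):
    """Predicted ANG II/ANG I ratio at effect-site concentration ``ce``.

    ratio = E0 * (1 - Imax * Ce^g / (Ce^g + IC50^g)); monotonically
    non-increasing in Ce, approaching E0*(1-Imax) at high exposure.
    """
    ce = np.asarray(ce, dtype=float)
    if np.any(ce < 0):
        raise ValueError("effect-site concentration must be non-negative")
    ce_g = np.power(ce, gamma, where=ce > 0, out=np.zeros(np.shape(ce)))
    frac = np.divide(ce_g, ce_g + np.power(ic50, gamma))
    out = e0 * (1.0 - imax * frac)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# semi-analytic linear-system machinery


def _system_matrix(theta: Mapping[str, np.ndarray], config: ModelConfig):
    """Batched compartment matrix; states (Aa, Ac[, Ap][, Ce])."""
    k_a = np.asarray(theta["k_a"], dtype=float)
    v1 = np.asarray(theta["v1_f"], dtype=float)
    cl = np.asarray(theta["cl_f"], dtype=float)
    B = np.broadcast(k_a, v1, cl).shape or (1,)
    two_cmt = config.disposition == "2cmt"
    eff = config.pd_link == "effect_compartment"
    m = 2 + (1 if two_cmt else 0) + (1 if eff else 0)
    A = np.zeros(B + (m, m))
    A[..., 0, 0] = -k_a
    A[..., 1, 0] = k_a
    k_el = cl / v1
    A[..., 1, 1] = -k_el
    idx = 2
    if two_cmt:
        q = np.asarray(theta["q_f"], dtype=float)
        v2 = np.asarray(theta["v2_f"], dtype=float)
        A[..., 1, 1] -= q / v1
        A[..., 1, idx] = q / v2
        A[..., idx, 1] = q / v1
        A[..., idx, idx] = -q / v2
        idx += 1
    if eff:
        ke0 = np.asarray(theta["k_e0"], dtype=float)
        A[..., idx, 1] = ke0 / v1
        A[..., idx, idx] = -ke0
    return A, m, idx if eff else None


def _impulse_coefficients(A: np.ndarray):
    """Eigen-expansion of exp(A t) @ e1: rows r -> sum_j c[r, j] e^{w_j t}."""
    try:
        w, V = np.linalg.eig(A)
        e1 = np.zeros(A.shape[-1])
        e1[0] = 1.0
        b = np.broadcast_to(e1[:, None], A.shape[:-2] + (A.shape[-1], 1))
        alpha = np.linalg.solve(V, b.astype(V.dtype))[..., 0]
        c = V * alpha[..., None, :]
    except np.linalg.LinAlgError:
        # defective or near-defective system (coinciding rates): nudge the
        # diagonal deterministically and retry
        jitter = 1.0 + 1e-9 * np.arange(1, A.shape[-1] + 1)
        A = A * 1.0
        diag = np.einsum("...ii->...i", A)
        diag *= jitter
        return _impulse_coefficients(A)
    if not (np.all(np.isfinite(w)) and np.all(np.isfinite(c))):
        raise FloatingPointError(
            "non-finite eigen-expansion of the compartment matrix; "
            "check parameter magnitudes")
    return w, c


def _gamma_support(n, k_tr):
    """Upper truncation point containing all but 1e-13 of the input mass."""
    return stats.gamma.ppf(1.0 - 1e-13, np.asarray(n) + 1.0,
                           scale=1.0 / np.asarray(k_tr))


def _convolved_states(w, c, n, k_tr, dt):
    """States at times-since-dose ``dt`` for a unit gamma-flow input.

    w, c: (..., m) eigenvalues / (..., m, m) coefficients, n, k_tr: (...,),
    dt: (..., T).  Returns (..., T, m) real state amounts.
    """
    upper = np.minimum(dt, _gamma_support(n, k_tr)[..., None])  # (...,T)
    upper = np.clip(upper, 0.0, None)
    # Gauss-Legendre nodes on [0, upper]
    s = 0.5 * upper[..., None] * (_GL_NODES + 1.0)          # (...,T,K)
    wq = 0.5 * upper[..., None] * _GL_WEIGHTS               # (...,T,K)
    n_ = np.asarray(n)[..., None, None]
    ktr_ = np.asarray(k_tr)[..., None, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        logg = (np.log(ktr_) + n_ * np.log(ktr_ * s) - ktr_ * s
                - special.gammaln(n_ + 1.0))
    g = np.where(s > 0, np.exp(logg), 0.0)                  # (...,T,K)
    # e^{w (dt - s)}: (...,T,K,m)
    expo = np.exp(w[..., None, None, :] * (dt[..., None] - s)[..., None])
    integ = np.einsum("...tk,...tk,...tkm->...tm", wq, g, expo)
    # states_r = sum_j c[r,j] * integ_j
    states = np.einsum("...rj,...tj->...tr", c, integ)
    return states.real


def _bolus_states(w, c, dt):
    """States at times-since-dose ``dt`` for a unit bolus into Aa."""
    pre = dt < 0
    expo = np.exp(w[..., None, :] * np.clip(dt, 0.0, None)[..., None])
    states = np.einsum("...rj,...tj->...tr", c, expo)
    return np.where(pre[..., None], 0.0, states.real)


def predict_profiles(theta: Mapping[str, np.ndarray], regimen: Regimen,
                     times: Sequence[float],
                     config: ModelConfig = ModelConfig()) -> dict:
    """Central and effect-site concentration profiles, batched.

    ``theta`` maps parameter names to scalars or (B,) arrays; all subjects
    share the dose ``regimen`` and output ``times`` (hours since first
    dose).  Returns ``{"conc": (B, T), "ce": (B, T)}`` in µg/L; ``ce`` is
    the central concentration itself under a direct link.  Repeated doses
    superpose linearly.
    """
    times = np.asarray(times, dtype=float)
    A, m, ce_row = _system_matrix(theta, config)
    w, c = _impulse_coefficients(A)
    B = A.shape[:-2]
    v1 = np.broadcast_to(np.asarray(theta["v1_f"], dtype=float), B)
    total = np.zeros(B + (times.size, m))
    if config.absorption == "transit":
        n = np.broadcast_to(
            _transit_shape(theta["k_tr"], theta["mtt"],
                           config.transit_convention), B)
        k_tr = np.broadcast_to(np.asarray(theta["k_tr"], dtype=float), B)
    tlag = np.broadcast_to(
        np.asarray(theta.get("tlag", 0.0), dtype=float), B)
    for td, amt in zip(regimen.times, regimen.amounts):
        if config.absorption == "transit":
            dt = np.clip(times - td, 0.0, None)
            dt = np.broadcast_to(dt, B + (times.size,))
            total += amt * _convolved_states(w, c, n, k_tr, dt)
        else:
            shift = td + (tlag if config.absorption == "lag"
                          else np.zeros_like(tlag))
            dt = times - shift[..., None]
            total += amt * _bolus_states(w, c, dt)
    conc = total[..., 1] / v1[..., None]
    if not np.all(np.isfinite(conc)):
        raise FloatingPointError("non-finite concentration profile")
    ce = total[..., ce_row] if ce_row is not None else conc
    return {"conc": conc, "ce": ce}


def concentration_profile(params: AdultStructuralParams, regimen: Regimen,
                          times: Sequence[float],
                          config: ModelConfig = ModelConfig()) -> np.ndarray:
    """Central enalaprilat concentration (µg/L) at ``times`` (h)."""
    times = np.asarray(times, dtype=float)
    if np.any(times > regimen.horizon):
        raise ValueError("requested times exceed the regimen horizon")
    theta = {k: np.asarray([getattr(params, k)]) for k in
             ("k_tr", "mtt", "k_a", "cl_f", "v1_f", "q_f", "v2_f",
              "k_e0", "tlag")}
    return predict_profiles(theta, regimen, times, config)["conc"][0]


def effect_site_profile(times: Sequence[float], central: Sequence[float],
                        k_e0: float) -> np.ndarray:
    """First-order effect-compartment filter of a sampled profile.

    Solves dCe/dt = k_e0 (C - Ce), Ce(0) = 0, treating the central
    concentration as piecewise linear between samples (exact update per
    interval, no step-size error beyond the interpolation).
    """
    if k_e0 < 0:
        raise ValueError("k_e0 must be non-negative")
    t = np.asarray(times, dtype=float)
    C = np.asarray(central, dtype=float)
    if t.shape != C.shape:
        raise ValueError("times and central must have equal shape")
    ce = np.zeros_like(C)
    for i in range(1, t.size):
        h = t[i] - t[i - 1]
        if h <= 0:
            raise ValueError("times must be strictly increasing")
        e = np.exp(-k_e0 * h)
        slope = (C[i] - C[i - 1]) / h
        # exact response to linear input C(t) = C0 + slope*(t - t0)
        ce[i] = (ce[i - 1] * e + C[i - 1] * (1 - e)
                 + slope * (h - (1 - e) / k_e0 if k_e0 > 0 else 0.0))
    return ce


def transit_chain_profile(params: AdultStructuralParams, regimen: Regimen,
                          times: Sequence[float], n_stages: int,
                          config: ModelConfig = ModelConfig()) -> np.ndarray:
    """Cross-validation fallback: explicit integer transit chain by ODE.

    Integrates ``n_stages`` discrete transit compartments (rate k_tr each,
    so Mtt = n_stages / k_tr ought to hold for comparability) feeding the
    same absorption/disposition system with an adaptive Runge-Kutta
    solver.  Slow; used to cross-check the continuous gamma-flow input.
    """
    from scipy.integrate import solve_ivp

    p = params
    two = config.disposition == "2cmt"

    def rhs(t, y):
        tr = y[:n_stages]
        aa, ac = y[n_stages], y[n_stages + 1]
        ap = y[n_stages + 2] if two else 0.0
        d = np.empty_like(y)
        d[0] = -p.k_tr * tr[0]
        for i in range(1, n_stages):
            d[i] = p.k_tr * (tr[i - 1] - tr[i])
        d[n_stages] = p.k_tr * tr[-1] - p.k_a * aa
        dac = p.k_a * aa - (p.cl_f / p.v1_f) * ac
        if two:
            dac += -(p.q_f / p.v1_f) * ac + (p.q_f / p.v2_f) * ap
            d[n_stages + 2] = (p.q_f / p.v1_f) * ac - (p.q_f / p.v2_f) * ap
        d[n_stages + 1] = dac
        return d

    times = np.asarray(times, dtype=float)
    m = n_stages + (3 if two else 2)
    out = np.zeros(times.size)
    for td, amt in zip(regimen.times, regimen.amounts):
        y0 = np.zeros(m)
        y0[0] = amt
        mask = times > td
        if not mask.any():
            continue
        sol = solve_ivp(rhs, (td, times[mask].max()), y0,
                        t_eval=times[mask], rtol=1e-10, atol=1e-12,
                        method="DOP853")
        out[mask] += sol.y[n_stages + 1] / p.v1_f
    return out
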