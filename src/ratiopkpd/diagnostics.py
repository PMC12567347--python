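"""Model evaluation: VPC, goodness of fit, hysteresis, effect summaries.

The visual predictive check simulates replicate studies on the original
design (same subjects, dose histories and sampling times), computes the
10th/50th/90th percentiles of observed and simulated data per time bin,
and reports the 90% prediction interval of each simulated percentile
together with flags for bins where an observed percentile leaves its
interval.  Rich designs are binned on the scheduled nominal times;
sparse designs on quantiles of time since last dose.

The goodness-of-fit table carries population and individual predictions
and individual weighted residuals (IWRES); censored observations are
reported separately (no residual is defined for an interval).

``hysteresis_metric`` classifies the time-ordered loop in the
concentration-effect plane by its shoelace signed area: a clockwise
loop (negative area) is the signature of an effect that lags
concentration, motivating the effect-compartment link.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import StudyDataset
from .estimation import (AdultPKPDLikelihood, FitResult,
                         PaediatricDirectLikelihood, build_adapter)
from .population import PopulationSpec
from .structural import ModelConfig

__all__ = [
    "VPCResult",
    "GofTable",
    "simulate_replicates",
    "vpc",
    "gof",
    "hysteresis_metric",
    "percent_change_4h",
    "comparison_overlay",
]


@dataclass
class VPCResult:
    """Observed percentiles per bin + prediction intervals of simulated
    percentiles; one instance per observation stream."""

    stream: str
    bin_mid: np.ndarray
    bin_n: np.ndarray
    percentiles: tuple[float, ...]
    observed: dict[float, np.ndarray]
    pi_low: dict[float, np.ndarray]
    pi_high: dict[float, np.ndarray]
    nsim: int
    pi: float
    flags: pd.DataFrame = None
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, t in enumerate(self.bin_mid):
            for p in self.percentiles:
                rows.append({
                    "stream": self.stream, "bin_mid": t,
                    "n_obs": int(self.bin_n[j]), "percentile": p,
                    "observed": self.observed[p][j],
                    "pi_low": self.pi_low[p][j],
                    "pi_high": self.pi_high[p][j],
                    "outside": bool(self.observed[p][j] < self.pi_low[p][j]
                                    or self.observed[p][j] >
                                    self.pi_high[p][j])})
        return pd.DataFrame(rows)


def _sample_phi(spec: PopulationSpec, adapter, n: int,
                rng: np.random.Generator) -> dict[str, np.ndarray]:
    names = [p for p in adapter.param_names if spec.iiv.get(p, 0.0) > 0]
    om = np.array([spec.iiv[p] for p in names])
    omega = np.diag(om ** 2)
    idx = {p: i for i, p in enumerate(names)}
    for a, b, r in spec.correlations:
        if a in idx and b in idx:
            omega[idx[a], idx[b]] = omega[idx[b], idx[a]] = \
                r * om[idx[a]] * om[idx[b]]
    vals = {}
    if names:
        eta = rng.multivariate_normal(np.zeros(len(names)), omega, size=n,
                                      method="cholesky")
        for j, p in enumerate(names):
            vals[p] = spec.fixed[p] * np.exp(eta[:, j])
    for p in adapter.param_names:
        if p not in vals:
            vals[p] = np.full(n, spec.fixed[p])
    # a valid transit chain needs k_tr*Mtt > 1: redraw the far tail
    if "k_tr" in vals and "mtt" in vals:
        bad = vals["k_tr"] * vals["mtt"] <= 1.05
        while bad.any():
            eta_b = rng.multivariate_normal(np.zeros(len(names)), omega,
                                            size=int(bad.sum()),
                                            method="cholesky")
            for j, p in enumerate(names):
                vals[p][bad] = spec.fixed[p] * np.exp(eta_b[:, j])
            bad = vals["k_tr"] * vals["mtt"] <= 1.05
    return vals


def simulate_replicates(ds: StudyDataset, spec: PopulationSpec,
                        model_config: ModelConfig | None,
                        adapter_kind: str, nsim: int, seed: int,
                        chunk: int = 50) -> dict[str, np.ndarray]:
    """Simulate ``nsim`` replicate studies on the dataset's own design.

    Returns, per stream, an array (nsim, n_subjects, n_obs_max) of
    simulated observations aligned with the adapter's padded layout.
    """
    adapter = build_adapter(adapter_kind, ds)
    rng = np.random.default_rng(seed)
    n = adapter.n_subjects
    out = {s: [] for s in adapter.stream_names}
    done = 0
    while done < nsim:
        k = min(chunk, nsim - done)
        vals = _sample_phi(spec, _TiledAdapter(adapter, k), k * n, rng)
        preds = _TiledAdapter(adapter, k).predict(vals)
        for sname in adapter.stream_names:
            f = preds[sname].reshape(k, n, -1)
            err = spec.errors[sname]
            if sname == "pk":
                y = f + err.sd(f) * rng.standard_normal(f.shape)
            else:
                y = f * (1.0 + err.b * rng.standard_normal(f.shape))
                neg = y <= 0
                while neg.any():
                    y[neg] = f[neg] * (1.0 + err.b *
                                       rng.standard_normal(neg.sum()))
                    neg = y <= 0
            out[sname].append(y)
        done += k
    return {s: np.concatenate(v, axis=0) for s, v in out.items()}


class _TiledAdapter:
    """View of an adapter replicated k times along the subject axis."""

    def __init__(self, adapter, k: int):
        self._a = adapter
        self._k = k
        self.param_names = adapter.param_names
        self.stream_names = adapter.stream_names

    @property
    def n_subjects(self) -> int:
        return self._k * self._a.n_subjects

    def predict(self, values):
        a, k = self._a, self._k
        if isinstance(a, PaediatricDirectLikelihood):
            conc = np.tile(a.conc, (k, 1))
            e0 = np.asarray(values["e0"])[:, None]
            ic50 = np.asarray(values["ic50"])[:, None]
            return {"pd": e0 * (1.0 - conc / (conc + ic50))}
        return a.predict(values)


def _nominal_bins(times: np.ndarray) -> np.ndarray:
    return np.unique(times)


def _quantile_bin_edges(times: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.linspace(0, 100, n_bins + 1)
    edges = np.percentile(times, qs)
    return np.unique(edges)


def _bin_indices(times, mode: str, n_bins: int, min_per_bin: int,
                 log: list[str]):
    """Assign observations to bins; merge bins thinner than the floor."""
    if mode == "nominal":
        centers = _nominal_bins(times)
        idx = np.searchsorted(centers, times)
        mids = centers
    else:
        edges = _quantile_bin_edges(times, n_bins)
        idx = np.clip(np.searchsorted(edges, times, side="right") - 1,
                      0, len(edges) - 2)
        mids = 0.5 * (edges[:-1] + edges[1:])
    # merge undersized bins into their left neighbour
    changed = True
    while changed:
        changed = False
        counts = np.bincount(idx, minlength=len(mids))
        for j in np.where((counts > 0) & (counts < min_per_bin))[0]:
            tgt = j - 1 if j > 0 else j + 1
            if tgt < 0 or tgt >= len(mids) or counts[tgt] == 0:
                continue
            log.append(f"bin at {mids[j]:.3g} ({counts[j]} obs) merged "
                       f"into neighbour at {mids[tgt]:.3g}")
            idx[idx == j] = tgt
            changed = True
            break
    keep = np.unique(idx)
    remap = {b: i for i, b in enumerate(keep)}
    new_idx = np.array([remap[b] for b in idx])
    new_mids = np.array([np.mean(times[new_idx == i])
                         for i in range(len(keep))])
    return new_idx, new_mids


def vpc(ds: StudyDataset, fit: FitResult, nsim: int = 500,
        percentiles: Sequence[float] = (10, 50, 90), pi: float = 90.0,
        seed: int = 0, binning: str = "auto", n_bins: int = 8,
        min_per_bin: int = 3) -> dict[str, VPCResult]:
    """Visual predictive check on the dataset's own design structure.

    The rich adult design is binned on the scheduled nominal times; the
    sparse paediatric direct model is binned on quantiles of the
    measured concentration (its natural regressor axis).
    """
    if nsim < 100:
        raise ValueError("VPC requires nsim >= 100")
    adapter = build_adapter(fit.adapter_kind, ds)
    if binning == "auto":
        binning = "nominal" if isinstance(adapter, AdultPKPDLikelihood) \
            else "quantile"
    sims = simulate_replicates(ds, fit.spec, fit.model_config,
                               fit.adapter_kind, nsim, seed)
    alpha = (100.0 - pi) / 2.0
    results = {}
    for sname in adapter.stream_names:
        data = adapter.streams[sname]
        mask = data.mask
        if isinstance(adapter, AdultPKPDLikelihood):
            times = adapter.times[adapter._idx[sname]][mask]
            axis = "time_h"
        else:
            times = adapter.conc[mask]
            axis = "concentration_ugl"
        y = data.y[mask]
        log: list[str] = []
        idx, mids = _bin_indices(times, binning, n_bins, min_per_bin, log)
        nb = len(mids)
        obs_pct = {p: np.array([np.percentile(y[idx == j], p)
                                for j in range(nb)]) for p in percentiles}
        sim = sims[sname][:, mask]  # (nsim, n_obs)
        lo, hi, counts = {}, {}, np.zeros(nb)
        sim_pct = {p: np.empty((nsim, nb)) for p in percentiles}
        for j in range(nb):
            cols = idx == j
            counts[j] = cols.sum()
            block = sim[:, cols]
            for p in percentiles:
                sim_pct[p][:, j] = np.percentile(block, p, axis=1)
        for p in percentiles:
            lo[p] = np.percentile(sim_pct[p], alpha, axis=0)
            hi[p] = np.percentile(sim_pct[p], 100 - alpha, axis=0)
        res = VPCResult(stream=sname, bin_mid=mids, bin_n=counts,
                        percentiles=tuple(percentiles), observed=obs_pct,
                        pi_low=lo, pi_high=hi, nsim=nsim, pi=pi,
                        metadata={"binning": binning, "axis": axis,
                                  "percentile_definition":
                                      "linear interpolation (type 7)",
                                  "merge_log": log, "seed": seed})
        res.flags = res.to_frame()[["stream", "bin_mid", "percentile",
                                    "outside"]]
        results[sname] = res
    return results


@dataclass
class GofTable:
    """Goodness-of-fit surfaces as plot-ready tables."""

    table: pd.DataFrame            # uncensored observations
    censored: pd.DataFrame         # censored records with predictions
    n_large_iwres: int             # count of |IWRES| > 2
    frac_large_iwres: float

    def surfaces(self) -> dict[str, pd.DataFrame]:
        t = self.table
        return {
            "obs_vs_ipred": t[["ipred", "observed", "stream"]],
            "obs_vs_pred": t[["pred", "observed", "stream"]],
            "iwres_vs_ipred": t[["ipred", "iwres", "stream"]],
            "iwres_vs_time": t[["time", "iwres", "stream"]],
        }


def gof(ds: StudyDataset, fit: FitResult) -> GofTable:
    """Population/individual predictions and IWRES for every record."""
    if fit.ebes is None:
        raise ValueError("fit carries no empirical Bayes estimates; "
                         "run fit_population first")
    adapter = build_adapter(fit.adapter_kind, ds)
    spec = fit.spec
    n = adapter.n_subjects
    pop_vals = {p: np.full(n, spec.fixed[p]) for p in adapter.param_names}
    ind_vals = {p: v.copy() for p, v in pop_vals.items()}
    for j, sid in enumerate(adapter.subject_ids):
        for p, eta in fit.ebes[sid].items():
            ind_vals[p][j] = spec.fixed[p] * math.exp(eta)
    pred = adapter.predict(pop_vals)
    ipred = adapter.predict(ind_vals)
    rows, crows = [], []
    for sname in adapter.stream_names:
        data = adapter.streams[sname]
        err = spec.errors[sname]
        if isinstance(adapter, AdultPKPDLikelihood):
            tmat = adapter.times[adapter._idx[sname]]
        else:
            tmat = np.zeros_like(data.y)
        for i, sid in enumerate(adapter.subject_ids):
            for k in np.where(data.mask[i])[0]:
                f_i = float(ipred[sname][i, k])
                row = {"subject_id": sid, "stream": sname,
                       "time": float(tmat[i, k]),
                       "observed": float(data.y[i, k]),
                       "pred": float(pred[sname][i, k]), "ipred": f_i}
                if data.censored[i, k]:
                    crows.append(row | {"lloq": float(data.lloq[i, k])})
                else:
                    sd = float(err.sd(f_i))
                    row["iwres"] = (row["observed"] - f_i) / sd
                    rows.append(row)
    table = pd.DataFrame(rows)
    censored = pd.DataFrame(crows)
    n_large = int((table["iwres"].abs() > 2).sum()) if len(table) else 0
    frac = n_large / len(table) if len(table) else 0.0
    return GofTable(table, censored, n_large, frac)


def hysteresis_metric(conc: Sequence[float], effect: Sequence[float],
                      times: Sequence[float] | None = None,
                      tol_scale: float = 1e-9) -> tuple[float, str]:
    """Signed shoelace area of the time-ordered concentration-effect loop.

    Negative area (clockwise traversal with concentration on x) means
    the effect lags concentration; the loop is closed last-to-first
    point.  Returns (area, direction) with direction in
    {"clockwise", "counterclockwise", "none"}.
    """
    x = np.asarray(conc, dtype=float)
    y = np.asarray(effect, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need at least 4 time-ordered (conc, effect) "
                         "pairs")
    if times is not None:
        t = np.asarray(times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
    area = 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    tol = tol_scale * max(np.ptp(x) * np.ptp(y), 1e-300)
    if abs(area) <= tol:
        return area, "none"
    return area, "clockwise" if area < 0 else "counterclockwise"


def percent_change_4h(paired: Sequence[tuple[float, float]]
                      ) -> dict[str, float | int | list]:
    """Percent decrease of the ratio from predose to 4 h post dose.

    Each pair is (predose ratio, 4 h ratio); change is
    100*(pre - post)/pre.  Pairs with a non-positive predose value are
    rejected with a warning.
    """
    import warnings
    changes = []
    n_rejected = 0
    for pre, post in paired:
        if pre <= 0:
            warnings.warn("pair with non-positive predose ratio rejected",
                          stacklevel=2)
            n_rejected += 1
            continue
        changes.append(100.0 * (pre - post) / pre)
    if not changes:
        return {"n": 0, "n_rejected": n_rejected, "median": math.nan,
                "min": math.nan, "max": math.nan, "changes": []}
    return {"n": len(changes), "n_rejected": n_rejected,
            "median": float(np.median(changes)),
            "min": float(np.min(changes)), "max": float(np.max(changes)),
            "changes": changes}


def comparison_overlay(adult_fit: FitResult, adult_ds: StudyDataset,
                       paediatric_ds: StudyDataset, nsim: int = 500,
                       seed: int = 0) -> dict[str, pd.DataFrame]:
    """Adult ratio VPC bands with paediatric observations overlaid.

    Bands come from the adult fit simulated on the adult design (time
    axis = time since the single dose).  Paediatric ratio observations
    are re-indexed to time since last dose and tagged with their dose
    class and whether the ANG II value was LLOQ/2-substituted
    (six symbol classes).  True first-dose predose records, which have
    no prior dose, are placed at t = 0 with their own class.
    Observation values are never altered.
    """
    bands = vpc(adult_ds, adult_fit, nsim=nsim, seed=seed,
                binning="nominal")["pd"].to_frame()
    rows = []
    skipped = []
    for s in paediatric_ds.subjects:
        for ob in s.observations:
            if ob.analyte != "RATIO" or ob.excluded:
                continue
            prior = [d.time for d in s.doses if d.time < ob.time]
            if not prior:
                if s.doses and ob.time > s.doses[0].time:
                    skipped.append(ob)
                    continue
                tsld, dose_class = 0.0, "predose_first"
            else:
                tsld = ob.time - max(prior)
                dose_class = "post_first" if len(prior) == 1 else \
                    "post_repeated"
            rows.append({
                "subject_id": ob.subject_id, "time_since_last_dose": tsld,
                "ratio": ob.value, "dose_class": dose_class,
                "blq_class": "substituted" if ob.substituted
                else "quantified",
                "symbol": f"{dose_class}/"
                          f"{'substituted' if ob.substituted else 'quantified'}",
            })
    points = pd.DataFrame(rows)
    return {"bands": bands, "points": points,
            "log": pd.DataFrame(
                [{"subject_id": ob.subject_id, "time": ob.time,
                  "reason": "no dose history"} for ob in skipped])}
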