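"""Flux fitting from isotopomer data and derived flux summaries.

The net-flux space is parametrized by the nullspace of the stacked
constraint system (steady-state balances + fixed uptake and biomass
drains); free coordinates plus the exchange fluxes of the reversible
reactions are estimated by weighted least squares against the
measurement set, with seeded multistart local optimization.  Confidence
intervals come from the Jacobian at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import lstsq, null_space
from scipy.optimize import least_squares, minimize

from .measure import MeasurementModel, MeasurementSet
from .network import AtomTransitionModel, FluxDistribution

_PEN = 100.0        # weight of the irreversibility penalty residuals
_EXCH_MAX = 20.0


@dataclass
class FitResult:
    fluxes: FluxDistribution
    covariance: np.ndarray
    chi2: float
    n_data: int
    n_free: int
    start_costs: list[float] = field(default_factory=list)
    seed: int | None = None

    @property
    def reduced_chi2(self) -> float:
        dof = max(self.n_data - self.n_free, 1)
        return self.chi2 / dof


class FluxParametrization:
    """v = v0 + N z subject to S v = 0 and the fixed constraints."""

    def __init__(self, atoms: AtomTransitionModel, constraints: dict[str, float]):
        self.atoms = atoms
        self.fids = atoms.flux_ids
        mets, S = atoms.balance_matrix()
        rows = [S]
        rhs = [np.zeros(S.shape[0])]
        for rid, val in constraints.items():
            e = np.zeros(len(self.fids))
            e[self.fids.index(rid)] = 1.0
            rows.append(e[None, :])
            rhs.append(np.array([val]))
        A = np.vstack(rows)
        b = np.concatenate(rhs)
        v0, *_ = lstsq(A, b)
        if np.abs(A @ v0 - b).max() > 1e-6:
            raise ValueError("constraints are inconsistent with the balances")
        self.v0 = v0
        self.N = null_space(A)
        self.n_free = self.N.shape[1]
        self.irrev_idx = [i for i, f in enumerate(self.fids)
                          if f not in atoms.reversible]

    def fluxes(self, z: np.ndarray, exchange: dict[str, float] | None = None
               ) -> FluxDistribution:
        v = self.v0 + self.N @ z
        return FluxDistribution(net=dict(zip(self.fids, v)),
                                exchange=dict(exchange or {}))

    @property
    def _A(self):
        if not hasattr(self, "_A_cache"):
            mets, S = self.atoms.balance_matrix()
            self._A_cache = S
        return self._A_cache


def _project_feasible(par: FluxParametrization,
                      constraints: dict[str, float]) -> np.ndarray:
    """Interior nonnegative starting point via SLSQP least-norm."""
    n = len(par.fids)
    A_rows = [par._A]
    b_rows = [np.zeros(par._A.shape[0])]
    for rid, val in constraints.items():
        e = np.zeros(n)
        e[par.fids.index(rid)] = 1.0
        A_rows.append(e[None, :])
        b_rows.append(np.array([val]))
    A = np.vstack(A_rows)
    b = np.concatenate(b_rows)
    bounds = [(0.0, None) if i in set(par.irrev_idx) else (None, None)
              for i in range(n)]
    res = minimize(lambda v: float(v @ v), np.clip(par.v0, 0, None),
                   jac=lambda v: 2 * v, bounds=bounds, method="SLSQP",
                   constraints=[{"type": "eq", "fun": lambda v: A @ v - b,
                                 "jac": lambda v: A}],
                   options={"maxiter": 500, "ftol": 1e-12})
    return par.N.T @ (res.x - par.v0)


def fit_fluxes(measurements: MeasurementSet, atoms: AtomTransitionModel,
               constraints: dict[str, float], n_starts: int = 10,
               seed: int = 0, perturbation: float = 1.0,
               model: MeasurementModel | None = None) -> FitResult:
    """Weighted least-squares flux fit (chi2 = sum ((sim-obs)/sd)^2).

    ``constraints`` fixes net fluxes (methanol uptake, biomass drains).
    Free parameters: nullspace coordinates of the net-flux space plus the
    exchange fluxes of the reversible reactions.  Multi-start local
    optimization; the seed controls the starts and is recorded.
    """
    par = FluxParametrization(atoms, constraints)
    mm = model or MeasurementModel(atoms)
    obs = measurements.data
    sim_index = pd.Index(mm.ids())
    order = sim_index.get_indexer(obs["id"])
    if (order < 0).any():
        missing = obs["id"][order < 0].tolist()[:3]
        raise ValueError(f"measurements not in layout, e.g. {missing}")
    yobs = obs["value"].to_numpy()
    sd = obs["sd"].to_numpy()
    nrev = len(atoms.reversible)
    d = par.n_free

    def unpack(theta):
        z = theta[:d]
        exch = dict(zip(atoms.reversible, theta[d:]))
        return par.fluxes(z, exch)

    def residuals(theta):
        fl = unpack(theta)
        try:
            sim = mm.values(fl)[order]
        except Exception:
            return np.full(len(yobs) + len(par.irrev_idx), 1e3)
        r = (sim - yobs) / sd
        v = np.array([fl.net[par.fids[i]] for i in par.irrev_idx])
        pen = _PEN * np.minimum(v, 0.0)
        return np.concatenate([r, pen])

    z_feas = _project_feasible(par, constraints)
    rng = np.random.default_rng(seed)
    lb = np.concatenate([np.full(d, -np.inf), np.zeros(nrev)])
    ub = np.concatenate([np.full(d, np.inf), np.full(nrev, _EXCH_MAX)])

    def min_irrev(z):
        v = par.v0 + par.N @ z
        return min(v[i] for i in par.irrev_idx)

    def feasible_start(dz):
        # backtrack the perturbation until irreversible fluxes are only
        # mildly violated (the penalty handles the rest)
        a = 1.0
        for _ in range(20):
            if min_irrev(z_feas + a * dz) > -0.05:
                break
            a *= 0.5
        return z_feas + a * dz
    best = None
    costs = []
    for k in range(n_starts):
        if k == 0:
            z0 = z_feas.copy()
            x0 = np.concatenate([z0, np.full(nrev, 1.0)])
        else:
            z0 = feasible_start(rng.normal(0.0, perturbation, size=d))
            exch0 = np.exp(rng.uniform(np.log(0.1), np.log(8.0), size=nrev))
            x0 = np.concatenate([z0, exch0])
        sol = least_squares(residuals, x0, bounds=(lb, ub), method="trf",
                            xtol=1e-9, ftol=1e-9, max_nfev=80 * (d + nrev))
        costs.append(2 * sol.cost)
        if best is None or sol.cost < best.cost:
            best = sol
    theta = best.x
    fl = unpack(theta)
    ndata = len(yobs)
    chi2 = float(np.sum(residuals(theta)[:ndata] ** 2))
    J = best.jac[:ndata, :]
    JtJ = J.T @ J
    cov = np.linalg.pinv(JtJ)
    # propagate to net fluxes: v = v0 + N z
    cov_z = cov[:d, :d]
    cov_v = par.N @ cov_z @ par.N.T
    sds = np.sqrt(np.clip(np.diag(cov_v), 0.0, None))
    fl.net_sd = dict(zip(par.fids, sds))
    exch_sd = np.sqrt(np.clip(np.diag(cov)[d:], 0.0, None))
    fl.exchange_sd = dict(zip(atoms.reversible, exch_sd))
    # flag unidentifiable directions as unbounded rather than silent
    for rid, s in fl.net_sd.items():
        if s > 1e2:
            fl.net_sd[rid] = np.inf
    for rid, s in fl.exchange_sd.items():
        if s > 1e2:
            fl.exchange_sd[rid] = np.inf
    return FitResult(fl, cov, chi2, ndata, d + nrev, costs, seed)


# ---------------------------------------------------------------------------
# flux summaries
# ---------------------------------------------------------------------------

#: central CO2-consuming and CO2-releasing reactions (dissimilatory
#: formate oxidation excluded; biosynthetic CO2 handled by the drains)
CO2_CONSUMING = ("ppc", "ccr", "pcc")
CO2_RELEASING = ("pepck", "mae", "pdh", "icd", "akgdh", "gnd", "gcc")


def flux_summaries(fluxes: FluxDistribution, mu: float | None = None,
                   nadph_per_gdw: float | None = None) -> dict:
    """Headline quantities of a flux map: % methanol directly oxidized,
    net central CO2 fixation, biomass-carbon-from-CO2 fraction, the four
    substrate-cycle recycling fractions, ATP cost of cycling and the
    NADPH demand decomposition."""
    v = fluxes.net
    uptake = v.get("mxa", 0.0)
    direct = v.get("fdh", 0.0)
    methf = v.get("fhs_l", 0.0)
    fix = (sum(v.get(r, 0.0) for r in CO2_CONSUMING)
           - sum(v.get(r, 0.0) for r in CO2_RELEASING))
    out = {
        "uptake": uptake,
        "direct_oxidation": direct,
        "pct_direct_oxidation": 100.0 * direct / uptake if uptake else np.nan,
        "methf_assimilation": methf,
        "net_co2_fixation": fix,
        "biomass_carbon_from_co2": fix / (fix + methf) if fix + methf > 0
        else np.nan,
    }
    pyk, pps = v.get("pyk", 0.0), v.get("pps", 0.0)
    ppc, pepck = v.get("ppc", 0.0), v.get("pepck", 0.0)
    mae, mclt, mtk = v.get("mae", 0.0), v.get("mclt", 0.0), v.get("mtk", 0.0)
    out["cycling"] = {
        "pep_pyruvate": pps / pyk if pyk > 0 else np.nan,
        "pep_oaa": pepck / ppc if ppc > 0 else np.nan,
        "pep_malate_pyruvate": min(mae, pps) / ppc if ppc > 0 else np.nan,
        "malate_accoa_glx": mclt / mtk if mtk > 0 else np.nan,
    }
    out["atp_cost_cycling"] = pps + pepck + mclt
    nadph = {
        "formate_assimilation": methf,
        "emcp": v.get("phaB", 0.0) + v.get("ccr", 0.0),
    }
    if mu is not None and nadph_per_gdw is not None:
        nadph["biosynthesis"] = mu * nadph_per_gdw
        nadph["total"] = sum(nadph.values())
    out["nadph_demand"] = nadph
    return out
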