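"""Linear-programming analyses: growth, cofactor/precursor yields, FVA,
NADPH-production scans.

All problems are ``max c.v  s.t.  S.v = 0, lb <= v <= ub`` solved with
HiGHS through :func:`scipy.optimize.linprog`.  Route restrictions are
imposed as bounds, never by deleting reactions, so model variants stay
structurally comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import PRECURSOR_CARBONS, PRECURSOR_DRAINS, StoichiometricModel

STEADY_STATE_TOL = 1e-9

#: dissimilation route -> reactions bounded to zero
ROUTES = {
    "cytoplasmic_FDH": ["fald_p", "fdh_p", "cs"],
    "periplasmic_FDH": ["fae", "fdh_c", "cs"],
    "TCA_of_acetylCoA": ["fdh_c", "fdh_p", "fald_p"],
    "unrestricted": [],
}

COFACTOR_DRAINS = {"ATP": "ngam", "NADH": "dm_nadh", "NADPH": "dm_nadph"}


@dataclass
class FluxBounds:
    """Per-reaction bounds (mmol.gDW^-1.h^-1; biomass flux in h^-1)."""
    lower: dict[str, float] = field(default_factory=dict)
    upper: dict[str, float] = field(default_factory=dict)

    def set(self, rid: str, lb: float | None, ub: float | None):
        if lb is not None and ub is not None and lb > ub:
            raise ValueError(f"lb > ub for {rid}")
        if lb is not None:
            self.lower[rid] = lb
        if ub is not None:
            self.upper[rid] = ub
        return self

    def fix(self, rid: str, value: float):
        return self.set(rid, value, value)

    def block(self, rids):
        for rid in rids:
            self.fix(rid, 0.0)
        return self


def default_bounds(model: StoichiometricModel, uptake: float = 15.0,
                   ngam: bool = True) -> FluxBounds:
    """Standard growth-simulation bounds: methanol uptake capped, CO2/O2
    free, maintenance drain fixed at the non-growth-associated ATP
    requirement when on, cofactor drains closed, and the 13 precursor
    overflow drains closed (biomass is the only biosynthetic sink, as in
    the living cell; yield analyses open their target drain explicitly)."""
    b = FluxBounds()
    b.set("EX_meoh", 0.0, uptake)
    comp = model.biomass_composition
    b.fix("ngam", (comp.ngam if comp else 9.5) if ngam else 0.0)
    b.block(["dm_nadh", "dm_nadph"])
    b.block(d for d in PRECURSOR_DRAINS if d in model.reactions)
    b.block(model.blocked)
    return b


@dataclass
class FBAResult:
    status: str                    # optimal | infeasible | unbounded
    objective: float | None
    fluxes: dict[str, float] | None

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]


def _bounds_arrays(model: StoichiometricModel, bounds: FluxBounds | None):
    bounds = bounds or FluxBounds()
    rids = model.reaction_ids
    lo, hi = [], []
    for rid in rids:
        rxn = model.reactions[rid]
        lb = bounds.lower.get(rid, -np.inf if rxn.reversible else 0.0)
        ub = bounds.upper.get(rid, np.inf)
        if rid in model.blocked:
            lb = ub = 0.0
        if not rxn.reversible:
            lb = max(lb, 0.0)
        lo.append(lb)
        hi.append(ub)
    return rids, lo, hi


def fba(model: StoichiometricModel, objective_id: str | None = None,
        bounds: FluxBounds | None = None, sense: int = 1,
        norm_min: bool = False) -> FBAResult:
    """Optimize a single reaction flux.  ``sense=1`` maximizes.

    With ``norm_min`` the reported flux vector is additionally the
    minimizer of ||v||_1 among alternate optima (degeneracy tie-break).
    """
    objective_id = objective_id or model.objective_id
    if objective_id not in model.reactions:
        raise KeyError(f"unknown objective {objective_id!r}")
    rids, lo, hi = _bounds_arrays(model, bounds)
    S = model.stoichiometric_matrix(rids)
    c = np.zeros(len(rids))
    c[rids.index(objective_id)] = -float(sense)
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(lo, hi)), method="highs")
    if res.status == 2:
        return FBAResult("infeasible", None, None)
    if res.status == 3:
        return FBAResult("unbounded", None, None)
    if not res.success:
        return FBAResult("infeasible", None, None)
    obj = -res.fun * float(sense) * sense  # = c.v with sign restored
    obj = float(np.dot(-c, res.x))
    v = res.x
    if norm_min:
        n = len(rids)
        # min sum(t) s.t. t >= v, t >= -v, S v = 0, objective fixed
        A_eq = np.hstack([S, np.zeros_like(S)])
        row = np.zeros((1, 2 * n))
        row[0, rids.index(objective_id)] = 1.0
        A_eq = np.vstack([A_eq, row])
        b_eq = np.zeros(A_eq.shape[0])
        b_eq[-1] = v[rids.index(objective_id)]
        A_ub = np.block([[np.eye(n), -np.eye(n)], [-np.eye(n), -np.eye(n)]])
        b_ub = np.zeros(2 * n)
        c2 = np.concatenate([np.zeros(n), np.ones(n)])
        big = [(l if np.isfinite(l) else None, u if np.isfinite(u) else None)
               for l, u in zip(lo, hi)] + [(0, None)] * n
        res2 = linprog(c2, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                       bounds=big, method="highs")
        if res2.success:
            v = res2.x[:n]
    fluxes = dict(zip(rids, v))
    return FBAResult("optimal", obj, fluxes)


def max_cofactor_yield(model: StoichiometricModel, substrate: str = "meoh",
                       cofactor: str = "ATP",
                       route: str = "cytoplasmic_FDH") -> float:
    """Maximal cofactor yield (mol per mol substrate) for a dissimilation
    route, with biomass and maintenance fixed to zero."""
    if cofactor not in COFACTOR_DRAINS:
        raise KeyError(f"cofactor must be one of {sorted(COFACTOR_DRAINS)}")
    if route not in ROUTES:
        raise KeyError(f"unknown route {route!r}; choose from {sorted(ROUTES)}")
    drain = COFACTOR_DRAINS[cofactor]
    b = FluxBounds()
    b.fix(f"EX_{substrate}", 1.0)
    b.fix("biomass", 0.0)
    b.block(model.blocked)
    b.block(ROUTES[route])
    b.block(PRECURSOR_DRAINS)  # pure dissimilation
    for d in COFACTOR_DRAINS.values():
        if d != drain:
            b.fix(d, 0.0)
    b.set(drain, 0.0, None)
    res = fba(model, drain, b)
    if res.status != "optimal":
        raise RuntimeError(f"cofactor yield LP {res.status}")
    return res.objective


def max_precursor_yield(model: StoichiometricModel, substrate: str = "meoh",
                        precursor: str = "oaa") -> tuple[float, float]:
    """(molar yield, carbon yield) for one of the 13 precursor drains,
    maintenance off, CO2 co-uptake allowed (carbon yields may exceed 1)."""
    drain = f"drain_{precursor}"
    if drain not in PRECURSOR_DRAINS:
        raise KeyError(f"{precursor!r} is not one of the precursor drains")
    b = FluxBounds()
    b.fix(f"EX_{substrate}", 1.0)
    b.fix("biomass", 0.0)
    b.fix("ngam", 0.0)
    b.block(["dm_nadh", "dm_nadph"])
    b.block(model.blocked)
    b.block(d for d in PRECURSOR_DRAINS if d != drain)
    res = fba(model, drain, b)
    if res.status != "optimal":
        raise RuntimeError(f"precursor yield LP {res.status}")
    molar = res.objective
    subs_c = model.metabolites[substrate].carbon_count
    carbon = molar * PRECURSOR_CARBONS[drain] / subs_c
    return molar, carbon


def fva(model: StoichiometricModel, bounds: FluxBounds | None = None,
        reactions: list[str] | None = None) -> dict[str, tuple[float, float]]:
    """Flux variability: [min, max] for each reaction under the constraints."""
    rids, lo, hi = _bounds_arrays(model, bounds)
    S = model.stoichiometric_matrix(rids)
    out: dict[str, tuple[float, float]] = {}
    targets = reactions or rids
    for rid in targets:
        j = rids.index(rid)
        c = np.zeros(len(rids))
        lohi = []
        for sense in (1, -1):
            c[j] = -sense
            res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                          bounds=list(zip(lo, hi)), method="highs")
            lohi.append(sense * -res.fun if res.success else np.nan)
        out[rid] = (min(lohi), max(lohi))
    return out


def nadph_scan(model: StoichiometricModel, grid=None, uptake: float = 15.0,
               ngam: bool = True):
    """Scan growth versus NADPH production fixed at the NADP-linked
    methylene-H4MPT dehydrogenase; returns (grid, growth, argmax_flux)."""
    grid = np.arange(0.0, 15.0 + 1e-9, 0.25) if grid is None else np.asarray(grid)
    growth = []
    for q in grid:
        b = default_bounds(model, uptake=uptake, ngam=ngam)
        b.fix("mtdh_nadph", float(q))
        res = fba(model, "EX_biomass", b)
        growth.append(res.objective if res.status == "optimal" else np.nan)
    growth = np.array(growth, dtype=float)
    argmax = float(grid[int(np.nanargmax(growth))])
    return grid, growth, argmax
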