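"""Elementary flux mode enumeration and mode-level analyses.

Modes are enumerated by the double-description method on the flux cone
``{v : S v = 0, v_irrev >= 0}`` after splitting reversible reactions,
entirely in exact integer/rational arithmetic.  The network is first
compressed (structurally blocked reactions removed, unbranched metabolite
nodes merged), which preserves the elementary modes one-to-one while
keeping intermediate ray counts small.  Enumeration is deterministic:
modes are returned sorted lexicographically by support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd

from .model import (EMCP_EXCLUSIVE, PRECURSOR_CARBONS, PRECURSOR_DRAINS,
                    StoichiometricModel)


class EnumerationCapExceeded(RuntimeError):
    """Intermediate ray count blew past the configured cap; restrict the
    enumeration with ``target_drain`` or raise ``max_modes``."""


@dataclass(frozen=True)
class ElementaryMode:
    """A support-minimal steady-state flux vector (exact rationals).

    Fluxes are normalized so that methanol uptake equals 1 whenever the
    mode consumes methanol; otherwise the lexicographically first active
    reaction is scaled to 1.
    """
    fluxes: tuple[tuple[str, Fraction], ...]

    @property
    def flux_dict(self) -> dict[str, Fraction]:
        return dict(self.fluxes)

    @property
    def support(self) -> frozenset[str]:
        return frozenset(r for r, _ in self.fluxes)

    @property
    def length(self) -> int:
        return len(self.fluxes)

    def __getitem__(self, rid: str) -> Fraction:
        return self.flux_dict.get(rid, Fraction(0))


@dataclass
class EfmSet:
    modes: list[ElementaryMode]
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.modes)

    def __iter__(self):
        return iter(self.modes)

    def __getitem__(self, i):
        return self.modes[i]


@dataclass
class YieldNormalizationParams:
    """Parameters of the maintenance-corrected biomass-yield normalization.

    mu_max: maximal growth rate of the network (h^-1); mu_i: reference
    growth rate at which every mode is scaled (h^-1); ngam_s: substrate
    uptake equivalent of the non-growth maintenance (mmol.g^-1.h^-1);
    mw_s: substrate molecular weight (g/mol).
    """
    mu_max: float = 0.201
    mu_i: float = 0.1
    ngam_s: float = 1.9
    mw_s: float = 32.04

    def __post_init__(self):
        if min(self.mu_max, self.mu_i, self.ngam_s, self.mw_s) <= 0:
            raise ValueError("yield-normalization parameters must be positive")


def ngam_substrate_equivalent(ngam_atp: float = 9.5,
                              atp_per_substrate: float = 5.0) -> float:
    """Substrate uptake needed to cover the NGAM ATP drain, given the
    maximal ATP yield of dissimilation (9.5 / 5 = 1.9 for methanol)."""
    return ngam_atp / atp_per_substrate


# ---------------------------------------------------------------------------
# compression
# ---------------------------------------------------------------------------

class _CompressedReaction:
    __slots__ = ("stoich", "reversible", "members")

    def __init__(self, stoich, reversible, members):
        self.stoich = stoich          # met -> Fraction
        self.reversible = reversible
        self.members = members        # list of (original rid, Fraction mult)


def _compress(model: StoichiometricModel, active: list[str]):
    """Iteratively drop structurally blocked reactions and merge
    2-degree metabolite nodes.  Returns compressed reaction list."""
    rxns: list[_CompressedReaction] = []
    exchanged: set[str] = set()
    for rid in active:
        r = model.reactions[rid]
        rxns.append(_CompressedReaction(dict(r.stoichiometry), r.reversible,
                                        [(rid, Fraction(1))]))
        if r.is_exchange:
            exchanged.update(r.stoichiometry)

    def balanced_mets(rlist):
        mets: dict[str, list[int]] = {}
        for i, r in enumerate(rlist):
            for m in r.stoich:
                mets.setdefault(m, []).append(i)
        return mets

    changed = True
    while changed:
        changed = False
        mets = balanced_mets(rxns)
        # blocked: a metabolite with no producer or no consumer, or one
        # touched by a single reaction (which then cannot carry flux,
        # reversible or not)
        dead: set[int] = set()
        for m, idxs in mets.items():
            if len(idxs) == 1:
                dead.update(idxs)
                continue
            prod = any(rxns[i].reversible or rxns[i].stoich[m] > 0 for i in idxs)
            cons = any(rxns[i].reversible or rxns[i].stoich[m] < 0 for i in idxs)
            if not (prod and cons):
                dead.update(idxs)
        if dead:
            rxns = [r for i, r in enumerate(rxns) if i not in dead]
            changed = True
            continue
        # merge a metabolite appearing in exactly two reactions
        for m, idxs in mets.items():
            if len(idxs) != 2:
                continue
            i, j = idxs
            ri, rj = rxns[i], rxns[j]
            ci, cj = ri.stoich[m], rj.stoich[m]
            if not ri.reversible and not rj.reversible and ci * cj > 0:
                continue  # both produce or both consume: handled as dead next
            # orient so ri produces m, rj consumes it
            flip_i = ci < 0 and cj < 0
            # combined flux: vj = -ci/cj * vi ; require positive ratio for
            # irreversible partners
            ratio = -ci / cj
            if ratio < 0:
                if rj.reversible:
                    # flip rj
                    rj = _CompressedReaction(
                        {k: -v for k, v in rj.stoich.items()}, True,
                        [(rid, -mu) for rid, mu in rj.members])
                    cj, ratio = -cj, -ratio
                elif ri.reversible:
                    ri = _CompressedReaction(
                        {k: -v for k, v in ri.stoich.items()}, True,
                        [(rid, -mu) for rid, mu in ri.members])
                    ci, ratio = -ci, -ratio
                else:
                    continue
            del flip_i
            stoich: dict[str, Fraction] = dict(ri.stoich)
            for k, v in rj.stoich.items():
                stoich[k] = stoich.get(k, Fraction(0)) + ratio * v
            stoich = {k: v for k, v in stoich.items() if v != 0}
            members = list(ri.members) + [(rid, mu * ratio)
                                          for rid, mu in rj.members]
            # an empty merged stoichiometry is a fully balanced pathway:
            # keep it as a zero column so it surfaces as a standalone mode
            rev = ri.reversible and rj.reversible
            rxns = [r for k, r in enumerate(rxns) if k not in (i, j)]
            rxns.append(_CompressedReaction(stoich, rev, members))
            changed = True
            break
    return rxns


# ---------------------------------------------------------------------------
# double description on the compressed, split network
# ---------------------------------------------------------------------------

def _ray_normalize(vec: list[int]) -> tuple[int, ...]:
    g = 0
    for x in vec:
        g = gcd(g, abs(x))
    g = g or 1
    return tuple(x // g for x in vec)


def _extreme_rays(S_rows: list[list[Fraction]], n: int, cap: int):
    """Extreme rays of {v >= 0, S v = 0} by double description."""
    # integerize rows
    rows = []
    for row in S_rows:
        den = 1
        for c in row:
            den = den * c.denominator // gcd(den, c.denominator)
        rows.append([int(c * den) for c in row])
    # heuristic: process sparse rows first
    rows.sort(key=lambda r: sum(1 for x in r if x))
    rays: list[tuple[int, ...]] = [tuple(1 if j == i else 0 for j in range(n))
                                   for i in range(n)]
    zeros = [sum(1 << j for j in range(n) if r[j] == 0) for r in rays]
    for row in rows:
        if not any(row):
            continue
        vals = [sum(c * r[j] for j, c in enumerate(row) if c) for r in rays]
        keep = [k for k, v in enumerate(vals) if v == 0]
        pos = [k for k, v in enumerate(vals) if v > 0]
        neg = [k for k, v in enumerate(vals) if v < 0]
        new_rays = [rays[k] for k in keep]
        new_zeros = [zeros[k] for k in keep]
        all_zeros = zeros
        for p in pos:
            zp = all_zeros[p]
            for q in neg:
                z = zp & all_zeros[q]
                # adjacency: no third ray's zero set contains z
                adjacent = True
                for t, zt in enumerate(all_zeros):
                    if t != p and t != q and (z & zt) == z:
                        adjacent = False
                        break
                if not adjacent:
                    continue
                a, b = vals[p], -vals[q]
                vec = [b * rays[p][j] + a * rays[q][j] for j in range(n)]
                new_rays.append(_ray_normalize(vec))
                new_zeros.append(sum(1 << j for j in range(n)
                                     if new_rays[-1][j] == 0))
        if len(new_rays) > cap:
            raise EnumerationCapExceeded(
                f"{len(new_rays)} intermediate rays exceed the cap {cap}; "
                "restrict enumeration with target_drain or raise max_modes")
        rays, zeros = new_rays, new_zeros
    return rays


def enumerate_efms(model: StoichiometricModel, max_modes: int = 10**6,
                   target_drain: str | None = None,
                   closed: set[str] | frozenset[str] = frozenset()) -> EfmSet:
    """Enumerate all elementary flux modes.

    ``target_drain`` focuses enumeration on one sink: 'biomass' closes the
    13 precursor drains; a drain id closes biomass and the other drains.
    ``closed`` bounds additional reactions to zero.
    """
    closed = set(closed) | set(model.blocked) | {"dm_nadh", "dm_nadph"}
    if target_drain is not None:
        if target_drain == "biomass":
            closed |= set(PRECURSOR_DRAINS)
        else:
            if target_drain not in PRECURSOR_DRAINS:
                raise KeyError(f"unknown target drain {target_drain!r}")
            closed |= {"biomass", "EX_biomass"}
            closed |= set(PRECURSOR_DRAINS) - {target_drain}
    active = [rid for rid in model.reaction_ids if rid not in closed]
    comp = _compress(model, active)
    # split reversibles
    cols: list[tuple[int, int]] = []   # (comp index, direction)
    for i, r in enumerate(comp):
        cols.append((i, +1))
        if r.reversible:
            cols.append((i, -1))
    mets = sorted({m for r in comp for m in r.stoich})
    midx = {m: i for i, m in enumerate(mets)}
    S_rows = [[Fraction(0)] * len(cols) for _ in mets]
    for j, (i, d) in enumerate(cols):
        for m, c in comp[i].stoich.items():
            S_rows[midx[m]][j] = d * c
    rays = _extreme_rays(S_rows, len(cols), max_modes)
    # recombine split columns; drop rays using both directions of a reaction
    modes: dict[frozenset, dict[str, Fraction]] = {}
    order = {rid: k for k, rid in enumerate(model.reaction_ids)}
    for ray in rays:
        net: dict[int, int] = {}
        ok = True
        for j, (i, d) in enumerate(cols):
            if ray[j]:
                if i in net:
                    ok = False
                    break
                net[i] = d * ray[j]
        if not ok or not net:
            continue
        flux: dict[str, Fraction] = {}
        for i, v in net.items():
            for rid, mult in comp[i].members:
                flux[rid] = flux.get(rid, Fraction(0)) + v * mult
        flux = {r: c for r, c in flux.items() if c != 0}
        if not flux:
            continue
        supp = frozenset(flux)
        if supp not in modes:
            modes[supp] = flux
    # support minimality filter (compression can in principle leave
    # non-elementary combinations after recombination)
    supports = list(modes)
    minimal = []
    for s in supports:
        if not any(t < s for t in supports):
            minimal.append(s)
    out: list[ElementaryMode] = []
    for s in minimal:
        flux = modes[s]
        scale = flux.get("EX_meoh")
        if not scale or scale <= 0:
            first = min(flux, key=lambda r: order[r])
            scale = abs(flux[first])
        flux = {r: c / scale for r, c in flux.items()}
        out.append(ElementaryMode(tuple(sorted(flux.items()))))
    out.sort(key=lambda m: sorted(order[r] for r in m.support))
    return EfmSet(out, provenance={
        "n_reactions": len(active), "target_drain": target_drain,
        "closed": sorted(closed), "max_modes": max_modes,
    })


# ---------------------------------------------------------------------------
# mode-level analyses
# ---------------------------------------------------------------------------

def normalized_yield(efm: ElementaryMode,
                     params: YieldNormalizationParams | None = None) -> float:
    """Maintenance-corrected biomass yield of a mode (g biomass / g substrate).

    The mode is scaled to the reference growth rate mu_i, giving a
    substrate uptake q_si; the yield then reads
    ``Y = mu_max / (q_si * mu_max / mu_i + NGAM_s) * 1000 / MW_s``,
    i.e. the maintenance uptake NGAM_s is added to the growth-scaled
    uptake before forming biomass-per-substrate.
    """
    params = params or YieldNormalizationParams()
    vb = float(efm["EX_biomass"] or efm["biomass"])
    if vb <= 0:
        raise ValueError("mode does not produce biomass; yield undefined")
    vm = float(efm["EX_meoh"])
    if vm <= 0:
        raise ValueError("mode does not take up substrate; yield undefined")
    qsi = vm * params.mu_i / vb
    return params.mu_max / (qsi * params.mu_max / params.mu_i + params.ngam_s) \
        * 1000.0 / params.mw_s


def classify_dissimilation(efm: ElementaryMode) -> dict[str, float]:
    """Relative flux (per mol methanol taken up) through the dissimilation
    routes: cytoplasmic FDH, periplasmic FDH, TCA oxidation of acetyl-CoA,
    and other decarboxylations."""
    vm = float(efm["EX_meoh"])
    if vm <= 0:
        return {"fdh_cytoplasmic": 0.0, "fdh_periplasmic": 0.0,
                "TCA_oxidation": 0.0, "other": 0.0}
    fdh_c = float(efm["fdh_c"]) / vm
    fdh_p = float(efm["fdh_p"]) / vm
    # gross decarboxylation can exceed uptake when substrate cycles
    # re-fix CO2; attribute at most the net CO2 release
    tca = min(float(efm["icd"] + efm["akgdh"]) / vm, 1.0)
    co2_out = max(0.0, float(efm["EX_co2"])) / vm
    other = min(max(0.0, co2_out - fdh_c - fdh_p - tca), 1.0)
    return {
        "fdh_cytoplasmic": fdh_c,
        "fdh_periplasmic": fdh_p,
        "TCA_oxidation": tca,
        "other": other,
    }


def precursor_efm_stats(model: StoichiometricModel, precursor: str,
                        max_modes: int = 10**6) -> dict:
    """Assimilatory-mode statistics for one of the 13 precursor drains."""
    drain = f"drain_{precursor}"
    if drain not in PRECURSOR_DRAINS:
        raise KeyError(f"{precursor!r} is not a precursor drain target")
    efms = enumerate_efms(model, max_modes=max_modes, target_drain=drain)
    assim = [m for m in efms if m[drain] > 0 and m["EX_meoh"] > 0]
    if not assim:
        return {"n_modes": 0, "max_molar_yield": 0.0, "max_carbon_yield": 0.0,
                "min_length": None, "emcp_usage_fraction": 0.0}
    ncarb = PRECURSOR_CARBONS[drain]
    ylds = [float(m[drain] / m["EX_meoh"]) for m in assim]
    exch = {rid for rid in model.reaction_ids
            if model.reactions[rid].is_exchange}
    lengths = [len(m.support - exch) for m in assim]
    emcp = sum(1 for m in assim
               if any(m[r] != 0 for r in EMCP_EXCLUSIVE)) / len(assim)
    return {
        "n_modes": len(assim),
        "max_molar_yield": max(ylds),
        "max_carbon_yield": max(ylds) * ncarb,
        "min_length": min(lengths),
        "emcp_usage_fraction": emcp,
    }


def co2_only_modes(efms: EfmSet,
                   params: YieldNormalizationParams | None = None):
    """Biomass modes in which no reduced C1 enters assimilation (the
    formate -> THF flux is zero, so all methanol carbon leaves the C1
    pathways as CO2 and biomass carbon derives entirely from CO2).

    Returns (subset, max normalized yield or None)."""
    subset = [m for m in efms
              if m["EX_biomass"] > 0 and m["fhs"] == 0 and m["EX_meoh"] > 0]
    if not subset:
        return [], None
    best = max(normalized_yield(m, params) for m in subset)
    return subset, best
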