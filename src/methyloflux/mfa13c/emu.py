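"""Steady-state isotopomer simulation via the EMU decomposition.

An EMU (elementary metabolite unit) is a subset of a metabolite's carbon
atoms; its mass-isotopomer distribution (MID) obeys linear balances once
the MIDs of smaller EMUs are known, so the network is solved as a cascade
of linear systems ordered by EMU size.  Production of a symmetric
metabolite (succinate, fumarate) is split over its two carbon
orientations at half flux each.

The decomposition is purely structural and is cached on the atom model;
per-evaluation work is assembling and solving small dense systems, which
keeps repeated simulation (fitting) cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import INPUT_POOLS, AtomTransitionModel, FluxDistribution

EMU = tuple[str, tuple[int, ...]]  # (metabolite, sorted 0-based atom indexes)


class SingularLabelingSystem(RuntimeError):
    pass


def _directed_reactions(atoms: AtomTransitionModel):
    """Expand the atom maps into directed variants with orientation
    handling for symmetric products.

    Returns list of (flux_key, direction, weight, substrates, products)
    where flux_key indexes into the directed-flux dict and substrates /
    products are lists of (met, atom_letters)."""
    out = []
    for rid, (subs, prods, rev) in atoms.parsed.items():
        variants = [(subs, prods)]
        # orientation scrambling: for every symmetric product, add the
        # reversed-atom variant; weights are renormalized below
        for met in atoms.symmetric:
            new = []
            for s, p in variants:
                flips = [i for i, (m, _) in enumerate(p) if m == met]
                if not flips:
                    new.append((s, p))
                    continue
                for orient in (False, True):
                    if not orient:
                        new.append((s, p))
                    else:
                        p2 = [(m, a[::-1]) if m == met else (m, a)
                              for m, a in p]
                        new.append((s, p2))
            variants = new
        w = 1.0 / len(variants)
        for s, p in variants:
            out.append((rid, +1, w, s, p))
        if rev:
            # backward direction: products become substrates; symmetric
            # *substrates* of the forward direction are now products and
            # scramble likewise
            bvariants = [(prods, subs)]
            for met in atoms.symmetric:
                new = []
                for s, p in bvariants:
                    flips = [i for i, (m, _) in enumerate(p) if m == met]
                    if not flips:
                        new.append((s, p))
                        continue
                    for orient in (False, True):
                        if not orient:
                            new.append((s, p))
                        else:
                            p2 = [(m, a[::-1]) if m == met else (m, a)
                                  for m, a in p]
                            new.append((s, p2))
                bvariants = new
            wb = 1.0 / len(bvariants)
            for s, p in bvariants:
                out.append((rid, -1, wb, s, p))
    return out


@dataclass
class _Term:
    flux_key: tuple[str, int]      # (reaction, direction)
    weight: float
    sources: tuple[EMU, ...]       # >1 entries = convolution


class EmuSystem:
    """Structural EMU decomposition for a set of requested EMUs."""

    def __init__(self, atoms: AtomTransitionModel, targets: list[EMU]):
        self.atoms = atoms
        self.targets = [(m, tuple(sorted(a))) for m, a in targets]
        self.directed = _directed_reactions(atoms)
        self.producers: dict[str, list] = {}
        for entry in self.directed:
            for met, letters in entry[4]:
                if met == "co2":
                    continue
                self.producers.setdefault(met, []).append(entry)
        self.consumption: dict[str, list[tuple[str, int, float]]] = {}
        for rid, d, w, subs, prods in self.directed:
            for met, letters in subs:
                self.consumption.setdefault(met, []).append((rid, d, w))
        for drain, met in atoms.drains.items():
            self.consumption.setdefault(met, []).append((drain, +1, 1.0))
        self.equations: dict[EMU, list[_Term]] = {}
        stack = [t for t in self.targets if t[0] not in INPUT_POOLS]
        while stack:
            emu = stack.pop()
            if emu in self.equations:
                continue
            met, atom_idx = emu
            terms: list[_Term] = []
            for rid, d, w, subs, prods in self.producers.get(met, []):
                for pmet, pletters in prods:
                    if pmet != met:
                        continue
                    wanted = [pletters[i] for i in atom_idx]
                    by_source: dict[int, list[tuple[str, int]]] = {}
                    for letter in wanted:
                        for si, (smet, sletters) in enumerate(subs):
                            j = sletters.find(letter)
                            if j >= 0:
                                by_source.setdefault(si, []).append((smet, j))
                                break
                        else:
                            raise AssertionError(
                                f"{rid}: atom {letter} has no source")
                    sources = []
                    for si in sorted(by_source):
                        smet = by_source[si][0][0]
                        idxs = tuple(sorted(j for _, j in by_source[si]))
                        sources.append((smet, idxs))
                    terms.append(_Term((rid, d), w, tuple(sources)))
                    for s in sources:
                        if s[0] not in INPUT_POOLS and s not in self.equations:
                            stack.append(s)
            self.equations[emu] = terms
        self.by_size: dict[int, list[EMU]] = {}
        for emu in self.equations:
            self.by_size.setdefault(len(emu[1]), []).append(emu)
        for k in self.by_size:
            self.by_size[k].sort()

    # -- numeric solve ----------------------------------------------
    def solve(self, fluxes: FluxDistribution, tol: float = 1e-12
              ) -> dict[EMU, np.ndarray]:
        directed = fluxes.directed(self.atoms)

        def flux_of(key):
            rid, d = key
            f, b = directed.get(rid, (0.0, 0.0))
            return f if d > 0 else b

        mids: dict[EMU, np.ndarray] = {}
        parked: set[str] = set()

        def mid_of(emu):
            met, idx = emu
            if met in INPUT_POOLS:
                base = self.atoms.input_mid(met)
                out = base
                for _ in range(len(idx) - 1):
                    out = np.convolve(out, base)
                return out
            return mids[emu]

        for size in sorted(self.by_size):
            emus = self.by_size[size]
            index = {e: i for i, e in enumerate(emus)}
            n = len(emus)
            A = np.zeros((n, n))
            B = np.zeros((n, size + 1))
            for e in emus:
                i = index[e]
                met = e[0]
                out_flux = 0.0
                for rid, d, w in self.consumption.get(met, []):
                    if rid in self.atoms.drains:
                        out_flux += self.fluxval(fluxes, rid)
                    else:
                        f, b = directed.get(rid, (0.0, 0.0))
                        out_flux += w * (f if d > 0 else b)
                if out_flux <= tol:
                    # pool carries no flux at these fluxes: its MID is
                    # never used (all consumers are at zero); park it at
                    # unlabeled rather than making the system singular
                    parked.add(met)
                    A[i, i] = -1.0
                    B[i, 0] = -1.0
                    continue
                A[i, i] -= out_flux
                for term in self.equations[e]:
                    f = flux_of(term.flux_key) * term.weight
                    if f == 0.0:
                        continue
                    if (len(term.sources) == 1
                            and term.sources[0][0] not in INPUT_POOLS
                            and len(term.sources[0][1]) == size):
                        A[i, index[term.sources[0]]] += f
                    else:
                        y = mid_of(term.sources[0])
                        for s in term.sources[1:]:
                            y = np.convolve(y, mid_of(s))
                        B[i, :] -= f * y
            if n:
                try:
                    X = np.linalg.solve(A, B)
                except np.linalg.LinAlgError:
                    bad = [emus[i][0] for i in range(n) if abs(A[i, i]) < tol]
                    raise SingularLabelingSystem(
                        "singular isotopomer balance; disconnected pool(s) "
                        f"at zero flux: {sorted(set(bad)) or emus}")
                for e, i in index.items():
                    mids[e] = np.clip(X[i], 0.0, None)
                    s = mids[e].sum()
                    if s <= 0:
                        raise SingularLabelingSystem(
                            f"degenerate MID for pool {e[0]}")
                    mids[e] /= s
        dead_targets = sorted({t[0] for t in self.targets} & parked)
        if dead_targets:
            raise SingularLabelingSystem(
                "requested pool(s) disconnected at zero flux: "
                f"{dead_targets}")
        return {t: mid_of(t) for t in self.targets}

    @staticmethod
    def fluxval(fluxes: FluxDistribution, rid: str) -> float:
        return fluxes.net.get(rid, 0.0)


def simulate_labeling(atoms: AtomTransitionModel, fluxes: FluxDistribution,
                      fragments: list[EMU]) -> dict[EMU, np.ndarray]:
    """MIDs for the requested metabolite fragments at isotopic steady state.

    ``fragments`` are (metabolite, 0-based atom index tuple) pairs.
    Raises :class:`SingularLabelingSystem` when a requested pool is
    disconnected at the given fluxes.
    """
    system = EmuSystem(atoms, fragments)
    return system.solve(fluxes)
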