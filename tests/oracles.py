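"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own algorithms: EFMs by
support-subset nullspace search (sympy exact arithmetic), minimal cut
sets by exhaustive subset enumeration, isotopomer distributions by
fixed-point iteration over the full 2^n isotopomer state space.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np
import sympy

from methyloflux.model import StoichiometricModel


def brute_force_efms(model: StoichiometricModel) -> set[frozenset[str]]:
    """All EFM supports by checking every sign-feasible nullspace support.

    A support S is an EFM support iff the nullspace of the S-restricted
    stoichiometric matrix is one-dimensional, its sign pattern is
    feasible (irreversible reactions nonnegative after a global sign
    flip), its support is exactly S, and no feasible proper subset
    support exists (support minimality).
    """
    rids = model.reaction_ids
    S = sympy.Matrix([[sympy.Rational(model.reactions[r].stoichiometry.get(m, 0))
                       for r in rids] for m in model.metabolite_ids])
    feasible: set[frozenset[str]] = set()
    n = len(rids)
    for size in range(1, n + 1):
        for combo in itertools.combinations(range(n), size):
            sub = S[:, list(combo)]
            ns = sub.nullspace()
            if len(ns) != 1:
                continue
            v = ns[0]
            if any(x == 0 for x in v):
                continue  # support would be smaller
            for flip in (1, -1):
                w = [flip * x for x in v]
                ok = all(w[k] > 0 or model.reactions[rids[j]].reversible
                         for k, j in enumerate(combo))
                if ok:
                    feasible.add(frozenset(rids[j] for j in combo))
                    break
    minimal = {s for s in feasible
               if not any(t < s for t in feasible)}
    return minimal


def brute_force_mcs(supports: list[frozenset[str]], universe: set[str],
                    max_cardinality: int) -> set[frozenset[str]]:
    """All minimal hitting sets up to a cardinality by subset enumeration."""
    hits: list[frozenset[str]] = []
    elems = sorted(universe)
    for k in range(1, max_cardinality + 1):
        for combo in itertools.combinations(elems, k):
            cs = frozenset(combo)
            if any(h <= cs for h in hits):
                continue
            if all(cs & s for s in supports):
                hits.append(cs)
    return set(hits)


def isotopomer_oracle(pools: dict[str, int], inputs: dict[str, np.ndarray],
                      reactions: list[tuple[float, list, list]],
                      drains: dict[str, float], n_iter: int = 2000):
    """Full isotopomer-space steady state by fixed-point iteration.

    pools: metabolite -> carbon count (non-input pools).
    inputs: metabolite -> per-carbon labeling probability MID ([p0, p1]).
    reactions: (flux, substrates, products) with substrates/products as
      (met, atom_letters); every product atom letter must appear in one
      substrate.  Symmetric variants must be passed pre-expanded.
    drains: metabolite -> outflux.

    Returns metabolite -> isotopomer distribution array of length 2^n
    (bit i of the index = labeling state of carbon i).
    """
    state = {m: np.ones(2 ** n) / 2 ** n for m, n in pools.items()}

    def distr(met):
        if met in inputs:
            p = inputs[met][1]
            n = 1
            d = np.array([1 - p, p])
            return d
        return state[met]

    outflux = {m: drains.get(m, 0.0) for m in pools}
    for flux, subs, prods in reactions:
        for met, atoms in subs:
            if met in pools:
                outflux[met] += flux
    for _ in range(n_iter):
        prod_acc = {m: np.zeros(2 ** n) for m, n in pools.items()}
        for flux, subs, prods in reactions:
            if flux == 0:
                continue
            # joint distribution over all substrate atoms
            letters: list[tuple[str, int, str]] = []
            dists = []
            for met, atoms in subs:
                d = distr(met)
                dists.append(d)
                for i, a in enumerate(atoms):
                    letters.append((met, i, a))
            for met, atoms in prods:
                if met not in pools:
                    continue
                n = pools[met]
                acc = np.zeros(2 ** n)
                # enumerate joint substrate isotopomers
                sizes = [len(a) for _, a in subs]
                for states in itertools.product(
                        *[range(2 ** s) for s in sizes]):
                    p = 1.0
                    lab = {}
                    for (met_s, atoms_s), st, d in zip(subs, states, dists):
                        p *= d[st]
                        for i, a in enumerate(atoms_s):
                            lab[a] = (st >> i) & 1
                    if p == 0:
                        continue
                    idx = 0
                    for i, a in enumerate(atoms):
                        idx |= lab[a] << i
                    acc[idx] += p
                prod_acc[met] += flux * acc
        new = {}
        for m in pools:
            if outflux[m] > 0:
                new[m] = prod_acc[m] / outflux[m]
            else:
                new[m] = state[m]
        state = new
    return state


def iso_to_mid(distr: np.ndarray, atoms: tuple[int, ...]) -> np.ndarray:
    """Marginal MID of an atom subset from a full isotopomer distribution."""
    n = int(np.log2(len(distr)))
    mid = np.zeros(len(atoms) + 1)
    for idx, p in enumerate(distr):
        w = sum((idx >> a) & 1 for a in atoms)
        mid[w] += p
    return mid
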