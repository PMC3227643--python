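"""Minimal cut sets over target elementary modes, fragility coefficients
and essentiality predictions.

A cut set is a set of reactions intersecting the support of every target
mode; a *minimal* cut set (MCS) has no proper subset with that property.
MCSs are the minimal transversals of the support hypergraph and are
computed by Berge-style incremental dualization with a cardinality cap.

The fragility coefficient of a reaction is 1 over the mean cardinality of
the MCSs containing it (0 if it appears in none); FC = 1 is equivalent to
the singleton {reaction} being an MCS, i.e. the reaction is essential for
the target function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .efm import EfmSet


@dataclass(frozen=True)
class CutSet:
    reactions: frozenset[str]

    @property
    def cardinality(self) -> int:
        return len(self.reactions)


@dataclass
class FragilityReport:
    fc: dict[str, float]
    essential: list[str]
    phenotypes: dict[str, str] = field(default_factory=dict)

    def is_essential(self, rid: str) -> bool:
        return self.fc.get(rid, 0.0) >= 1.0 - 1e-12


def _target_supports(target_efms, restrict_to: set[str] | None):
    supports = []
    for m in target_efms:
        supp = set(m.support)
        if restrict_to is not None:
            supp &= restrict_to
        if supp:
            supports.append(frozenset(supp))
    # drop supersets: they are hit whenever a minimal support is hit
    supports = sorted(set(supports), key=len)
    minimal = []
    for s in supports:
        if not any(t <= s for t in minimal):
            minimal.append(s)
    return minimal


def compute_mcs(target_efms: EfmSet | Sequence, max_cardinality: int = 4,
                restrict_to: Iterable[str] | None = None) -> list[CutSet]:
    """All minimal hitting sets (up to max_cardinality) of the supports of
    the target modes.  ``restrict_to`` limits candidate reactions (e.g. to
    non-exchange reactions); a mode whose restricted support is empty is
    uncuttable and removed from the hypergraph by definition of the
    restriction.  Deterministic ordering: by cardinality, then reaction ids.
    """
    modes = list(target_efms)
    if not modes:
        raise ValueError("empty target mode set: nothing to cut")
    restrict = set(restrict_to) if restrict_to is not None else None
    supports = _target_supports(modes, restrict)
    if not supports:
        raise ValueError("no cuttable reactions in any target mode")
    cuts: list[frozenset[str]] = [frozenset()]
    for supp in supports:
        hit = [c for c in cuts if c & supp]
        miss = [c for c in cuts if not (c & supp)]
        new: list[frozenset[str]] = list(hit)
        for c in miss:
            if len(c) >= max_cardinality:
                continue
            for r in sorted(supp):
                cand = c | {r}
                # minimality: no existing hitting set may be a subset
                if any(h <= cand for h in hit):
                    continue
                new.append(cand)
        # prune non-minimal candidates among the new ones
        new = sorted(set(new), key=len)
        pruned: list[frozenset[str]] = []
        for c in new:
            if not any(p < c for p in pruned):
                pruned.append(c)
        cuts = pruned
    cuts = [c for c in cuts if c]
    cuts.sort(key=lambda c: (len(c), tuple(sorted(c))))
    return [CutSet(c) for c in cuts]


def fragility_coefficients(mcs_list: Sequence[CutSet],
                           reactions: Iterable[str],
                           phenotypes: dict[str, str] | None = None
                           ) -> FragilityReport:
    """FC_i = 1 / mean cardinality of the MCSs containing reaction i."""
    sizes: dict[str, list[int]] = {}
    for cs in mcs_list:
        for r in cs.reactions:
            sizes.setdefault(r, []).append(cs.cardinality)
    fc = {}
    for r in reactions:
        ks = sizes.get(r)
        fc[r] = (len(ks) / sum(ks)) if ks else 0.0
    essential = sorted(r for r, v in fc.items() if v >= 1.0 - 1e-12)
    return FragilityReport(fc=fc, essential=essential,
                           phenotypes=dict(phenotypes or {}))


def essential_reactions(report: FragilityReport, model=None,
                        subsystem_filter: str | None = None) -> dict:
    """Summarize essentiality; optionally per subsystem and against an
    observed mutant-phenotype table (lethal / non-lethal / unknown)."""
    rids = list(report.fc)
    if subsystem_filter is not None:
        if model is None:
            raise ValueError("subsystem filtering needs the model")
        rids = [r for r in rids
                if model.reactions[r].subsystem == subsystem_filter]
    ess = [r for r in rids if report.is_essential(r)]
    out = {
        "n_reactions": len(rids),
        "n_essential": len(ess),
        "essential_fraction": len(ess) / len(rids) if rids else 0.0,
        "essential": sorted(ess),
    }
    if report.phenotypes:
        tp = fp = tn = fn = 0
        for r in rids:
            obs = report.phenotypes.get(r, "unknown")
            if obs == "unknown":
                continue
            pred_lethal = report.is_essential(r)
            if obs == "lethal":
                tp += pred_lethal
                fn += not pred_lethal
            else:
                fp += pred_lethal
                tn += not pred_lethal
        out["confusion"] = {"tp": tp, "fp": fp, "tn": tn, "fn": fn}
        n = tp + fp + tn + fn
        out["accuracy"] = (tp + tn) / n if n else None
    return out
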