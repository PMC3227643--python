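"""Evidence-based reduction of the model to the methanol-active subnetwork.

The reduction mirrors the multi-criterion procedure used to carve the
methylotrophic subnetwork out of a genome-scale reconstruction: remove
reactions tied to absent medium components / undetected end products and
degradation pathways, keep reactions with genetic essentiality evidence,
keep reactions whose omics signal on methanol is at least twice the
non-methanol level (or simply present), and refuse any removal set that
destroys biomass feasibility (checked by LP), re-adding blocking
reactions deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .fba import FluxBounds, default_bounds, fba
from .model import StoichiometricModel

EVIDENCE_COLUMNS = [
    "reaction", "physiology", "genetic", "biochemical",
    "transcript_fold", "protein_fold", "protein_present", "metabolomic",
    "medium_excluded", "degradation",
]


@dataclass
class ReductionRules:
    fold_threshold: float = 2.0     # "at least twice higher" omics rule
    require_feasible: bool = True
    growth_tol: float = 1e-6


def evidence_table(model: StoichiometricModel,
                   overrides: dict[str, dict] | None = None) -> pd.DataFrame:
    """All-supported evidence template for a model; per-reaction fields
    can be overridden (e.g. to mark a reaction unsupported)."""
    rows = []
    for rid in model.reaction_ids:
        rows.append({
            "reaction": rid, "physiology": 1.0, "genetic": "unknown",
            "biochemical": 0.0, "transcript_fold": 2.0,
            "protein_fold": float("nan"), "protein_present": True,
            "metabolomic": False, "medium_excluded": False,
            "degradation": False,
        })
    df = pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)
    df = df.set_index("reaction", drop=False)
    for rid, fields in (overrides or {}).items():
        for k, v in fields.items():
            df.loc[rid, k] = v
    bad = df["transcript_fold"].dropna() <= 0
    if bad.any():
        raise ValueError("fold-changes must be positive")
    return df


def _supported(row, rules: ReductionRules) -> tuple[bool, list[str]]:
    reasons = []
    if row["genetic"] == "essential":
        reasons.append("genetic essentiality")
    if row["biochemical"] and row["biochemical"] > 0:
        reasons.append("biochemical assay")
    tf = row["transcript_fold"]
    if pd.notna(tf) and tf >= rules.fold_threshold:
        reasons.append(f"transcript fold {tf:g} >= {rules.fold_threshold:g}")
    pf = row["protein_fold"]
    if pd.notna(pf) and pf >= rules.fold_threshold:
        reasons.append(f"protein fold {pf:g} >= {rules.fold_threshold:g}")
    if row["protein_present"]:
        reasons.append("protein detected")
    if row["metabolomic"]:
        reasons.append("metabolite detected")
    if row["physiology"] and row["physiology"] > 0:
        reasons.append("physiological evidence")
    return bool(reasons), reasons


def reduce_network(model: StoichiometricModel, evidence: pd.DataFrame,
                   rules: ReductionRules | None = None
                   ) -> tuple[StoichiometricModel, dict[str, dict]]:
    """Apply the multi-criterion reduction; returns (reduced model, trail).

    The trail maps reaction id -> {decision, reasons}.  Removals that
    would destroy biomass production are refused (the reaction is kept
    and flagged ``kept_for_feasibility``).
    """
    rules = rules or ReductionRules()
    evidence = evidence.set_index("reaction", drop=False) \
        if evidence.index.name != "reaction" else evidence
    protected = {rid for rid in model.reaction_ids
                 if model.reactions[rid].is_exchange
                 or model.reactions[rid].subsystem == "biosynthesis_drain"}
    trail: dict[str, dict] = {}
    removable: list[str] = []
    for rid in model.reaction_ids:
        if rid in protected:
            trail[rid] = {"decision": "kept", "reasons": ["pseudo-reaction"]}
            continue
        if rid not in evidence.index:
            trail[rid] = {"decision": "kept", "reasons": ["no evidence row"]}
            continue
        row = evidence.loc[rid]
        if row["genetic"] == "essential":
            trail[rid] = {"decision": "kept",
                          "reasons": ["genetic essentiality"]}
            continue
        if row["medium_excluded"] or row["degradation"]:
            why = ("absent medium component / end product"
                   if row["medium_excluded"] else "degradation pathway")
            removable.append(rid)
            trail[rid] = {"decision": "removed", "reasons": [why]}
            continue
        ok, reasons = _supported(row, rules)
        if ok:
            trail[rid] = {"decision": "kept", "reasons": reasons}
        else:
            removable.append(rid)
            trail[rid] = {"decision": "removed",
                          "reasons": ["no methanol-condition support"]}
    reduced = model.copy()
    reduced.remove_reactions(removable)
    if rules.require_feasible:
        def grows(m):
            res = fba(m, "EX_biomass", default_bounds(m, 15.0, True))
            return (res.status == "optimal"
                    and res.objective > rules.growth_tol)
        if not grows(reduced):
            # deterministic greedy re-add until growth is restored
            blocking = []
            for rid in sorted(removable):
                r = model.reactions[rid]
                reduced.add_reaction(r)
                blocking.append(rid)
                trail[rid] = {"decision": "kept_for_feasibility",
                              "reasons": ["removal blocks biomass"]}
                if grows(reduced):
                    # try to drop earlier re-adds that are not needed
                    for other in list(blocking):
                        reduced.remove_reactions([other])
                        if grows(reduced):
                            blocking.remove(other)
                            trail[other] = {
                                "decision": "removed",
                                "reasons": ["no methanol-condition support"]}
                        else:
                            reduced.add_reaction(model.reactions[other])
                    break
            else:
                raise RuntimeError(
                    "reduction destroys biomass feasibility; minimal "
                    f"blocking removals: {blocking}")
    return reduced, trail
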