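"""Core stoichiometric model of methylotrophic central metabolism.

The model covers the central carbon metabolism of *Methylobacterium
extorquens* AM1 growing on methanol: periplasmic methanol oxidation, the
tetrahydromethanopterin (H4MPT) dissimilatory branch, the
tetrahydrofolate (THF) assimilatory branch, the serine cycle, the
ethylmalonyl-CoA pathway (EMCP), an anabolic TCA branch, the seven C3/C4
interconversion reactions, gluconeogenesis with the pentose-phosphate and
Entner-Doudoroff routes, lumped oxidative phosphorylation, thirteen
biomass-precursor drains and a biomass equation derived from the measured
macromolecular composition.

Only carbon and cofactor stoichiometry is balanced (no proton/charge
balance): the analyses built on top of the model depend on carbon routing
and on ATP/NAD(P)H accounting only.  Carrier moieties (CoA, THF, H4MPT,
nicotinamides, cytochrome c) are treated as carbon-free.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np

SUBSYSTEMS = (
    "C1_pathways",
    "serine_cycle",
    "EMCP",
    "TCA",
    "anaplerotic",
    "gluconeogenesis_glycolysis",
    "PPP_ED",
    "PHB",
    "biosynthesis_drain",
    "transport",
    "exchange",
    "respiration",
)

COMPARTMENTS = ("cytoplasm", "periplasm", "extracellular")


class ModelError(ValueError):
    """Raised for malformed models or invalid model operations."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str
    compartment: str = "cytoplasm"
    carbon_count: int = 0
    formula: str | None = None

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ModelError(f"unknown compartment {self.compartment!r} for {self.id}")
        if self.carbon_count < 0:
            raise ModelError(f"negative carbon count for {self.id}")
        if self.formula is not None:
            m = re.search(r"C(\d*)(?![a-z])", self.formula)
            n = int(m.group(1) or 1) if m else 0
            if n != self.carbon_count:
                raise ModelError(
                    f"{self.id}: formula {self.formula} has {n} C, "
                    f"carbon_count says {self.carbon_count}"
                )


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, Fraction]
    reversible: bool = False
    subsystem: str = "transport"
    genes: list[str] = field(default_factory=list)
    confidence: int = 2
    name: str = ""

    def __post_init__(self):
        if self.subsystem not in SUBSYSTEMS:
            raise ModelError(f"unknown subsystem {self.subsystem!r} in {self.id}")
        if not 0 <= self.confidence <= 4:
            raise ModelError(f"confidence out of [0,4] in {self.id}")
        clean = {m: Fraction(c) for m, c in self.stoichiometry.items() if c != 0}
        if not clean:
            raise ModelError(f"reaction {self.id} has no nonzero coefficient")
        if len(clean) != len(self.stoichiometry):
            raise ModelError(f"reaction {self.id} has zero-coefficient species")
        self.stoichiometry = clean

    @property
    def is_exchange(self) -> bool:
        return self.subsystem == "exchange"

    def equation(self, arrow: str | None = None) -> str:
        arrow = arrow or ("<->" if self.reversible else "->")
        def side(items):
            parts = []
            for m, c in items:
                c = abs(c)
                parts.append(m if c == 1 else f"{c} {m}")
            return " + ".join(parts)
        subs = sorted((m, c) for m, c in self.stoichiometry.items() if c < 0)
        prods = sorted((m, c) for m, c in self.stoichiometry.items() if c > 0)
        return f"{side(subs)} {arrow} {side(prods)}"


def parse_equation(eq: str) -> tuple[dict[str, Fraction], bool]:
    """Parse ``a A + b B -> c C`` (or ``<->``) into a coefficient map."""
    if "<->" in eq:
        lhs, rhs = eq.split("<->")
        rev = True
    elif "->" in eq:
        lhs, rhs = eq.split("->")
        rev = False
    else:
        raise ModelError(f"no arrow in equation {eq!r}")
    stoich: dict[str, Fraction] = {}

    def add(side: str, sign: int):
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise ModelError(f"empty term in {eq!r}")
            bits = term.split()
            if len(bits) == 1:
                coeff, met = Fraction(1), bits[0]
            elif len(bits) == 2:
                coeff, met = Fraction(bits[0]), bits[1]
            else:
                raise ModelError(f"cannot parse term {term!r} in {eq!r}")
            if coeff == 0:
                raise ModelError(f"zero coefficient for {met} in {eq!r}")
            stoich[met] = stoich.get(met, Fraction(0)) + sign * coeff
    add(lhs, -1)
    add(rhs, +1)
    return {m: c for m, c in stoich.items() if c != 0}, rev


@dataclass
class BiomassComposition:
    """Macromolecular composition (% cell dry weight) and maintenance.

    Defaults are the measured composition of methanol-grown cells; the
    listed mass fractions sum to 98.36 %CDW.  GAM is the growth-associated
    ATP maintenance (mmol ATP per gDW, polymerization included), NGAM the
    non-growth-associated drain (mmol ATP per gDW per h).
    """

    protein: float = 59.13
    carbohydrate: float = 16.43
    rna: float = 8.20
    fatty_acid: float = 4.95
    dna: float = 3.00
    phb: float = 2.36
    polyamine: float = 0.40
    carotenoid: float = 0.023
    metabolites: float = 2.64
    ions: float = 1.01
    cofactors: float = 0.22
    gam: float = 59.81
    ngam: float = 9.5
    nadph_per_gdw: float = 10.71  # biosynthetic NADPH, mmol/gDW

    MACROMOLECULES = (
        "protein", "carbohydrate", "rna", "fatty_acid", "dna", "phb",
        "polyamine", "carotenoid", "metabolites", "ions", "cofactors",
    )

    def fractions(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.MACROMOLECULES}

    def total(self) -> float:
        return sum(self.fractions().values())


#: mmol of precursor consumed per gram of each macromolecule class.
#: Protein demands follow a standard bacterial amino-acid composition
#: grouped by biosynthetic family; nucleic acids count ribose-5-P plus the
#: glycine, C1 and aspartate (OAA) ring atoms; fatty acids are lumped as
#: C18 acyl chains (9 acetyl-CoA) plus a glyceraldehyde-3-P head
#: contribution; PHB monomers draw (R)-3-hydroxybutyryl-CoA directly.
PRECURSOR_PER_GRAM: dict[str, dict[str, float]] = {
    "protein": {
        "pyr": 5.000, "accoa": 0.778, "oaa": 2.631, "akg": 1.802,
        "ser": 0.629, "gly": 1.058, "pep": 1.215, "e4p": 0.656,
        "r5p": 0.262, "methf": 0.265,
    },
    "carbohydrate": {"g6p": 6.173},
    "rna": {"r5p": 3.086, "gly": 1.543, "methf": 3.086, "oaa": 1.543,
            "co2": 1.543},
    "dna": {"r5p": 3.236, "gly": 1.618, "methf": 3.236, "oaa": 1.618,
            "co2": 1.618},
    "fatty_acid": {"accoa": 31.91, "ga3p": 1.18},
    "phb": {"hbcoa": 11.61},
    "polyamine": {"akg": 11.34},
    "carotenoid": {"pyr": 14.9, "ga3p": 14.9},
    "metabolites": {"pyr": 2.0, "akg": 1.0, "g6p": 1.0, "r5p": 0.5,
                    "oaa": 1.0, "accoa": 1.0},
    "ions": {},
    "cofactors": {"r5p": 2.0},
}

#: precursor id -> (pool metabolite, carriers released per mmol)
PRECURSOR_POOLS: dict[str, tuple[str, dict[str, int]]] = {
    "methf": ("ch2_thf", {"thf": 1}),
    "accoa": ("accoa", {"coa": 1}),
    "gly": ("gly", {}),
    "ser": ("ser", {}),
    "pyr": ("pyr", {}),
    "pep": ("pep", {}),
    "ga3p": ("ga3p", {}),
    "oaa": ("oaa", {}),
    "e4p": ("e4p", {}),
    "hbcoa": ("hbcoa", {"coa": 1}),
    "akg": ("akg", {}),
    "r5p": ("r5p", {}),
    "g6p": ("g6p", {}),
    "co2": ("co2", {}),
}


def precursor_demand(comp: BiomassComposition) -> dict[str, float]:
    """Biomass precursor demand vector (mmol per gDW) from mass fractions."""
    demand: dict[str, float] = {}
    for macro, frac in comp.fractions().items():
        table = PRECURSOR_PER_GRAM[macro]
        for prec, per_g in table.items():
            demand[prec] = demand.get(prec, 0.0) + per_g * frac / 100.0
    return demand


def biomass_reaction(comp: BiomassComposition,
                     precursor_map: Mapping[str, tuple[str, dict[str, int]]]
                     = PRECURSOR_POOLS) -> Reaction:
    """Build the biomass drain from a macromolecular composition.

    One unit of flux corresponds to 1 gDW h^-1; precursor coefficients are
    in mmol/gDW so the reaction couples directly to fluxes in
    mmol.gDW^-1.h^-1.  GAM ATP hydrolysis is included.
    """
    demand = precursor_demand(comp)
    if not any(v > 0 for v in demand.values()):
        raise ModelError("all-zero biomass composition")
    stoich: dict[str, Fraction] = {}

    def add(met: str, coeff: float):
        f = Fraction(coeff).limit_denominator(10**6)
        if f:
            stoich[met] = stoich.get(met, Fraction(0)) + f

    for prec, mmol in demand.items():
        if prec not in precursor_map:
            raise ModelError(f"no pool mapping for biomass precursor class {prec!r}")
        pool, carriers = precursor_map[prec]
        add(pool, -mmol)
        for carrier, n in carriers.items():
            add(carrier, n * mmol)
    add("atp", -comp.gam)
    add("adp", comp.gam)
    add("nadph", -comp.nadph_per_gdw)
    add("nadp", comp.nadph_per_gdw)
    add("biomass", 1)
    return Reaction("biomass", stoich, reversible=False,
                    subsystem="biosynthesis_drain", confidence=4,
                    name="biomass equation (1 gDW per flux unit)")


class StoichiometricModel:
    """Metabolites + reactions + biomass; exposes the S matrix."""

    def __init__(self, metabolites: Iterable[Metabolite],
                 reactions: Iterable[Reaction],
                 objective_id: str = "EX_biomass"):
        self.metabolites: dict[str, Metabolite] = {}
        for m in metabolites:
            if m.id in self.metabolites:
                raise ModelError(f"duplicate metabolite id {m.id}")
            self.metabolites[m.id] = m
        self.reactions: dict[str, Reaction] = {}
        for r in reactions:
            self.add_reaction(r)
        self.objective_id = objective_id
        #: reactions permanently bounded to zero (variant definition);
        #: kept in the network so models stay structurally comparable
        self.blocked: set[str] = set()
        self.biomass_composition: BiomassComposition | None = None

    # -- construction ------------------------------------------------
    def add_reaction(self, rxn: Reaction):
        if rxn.id in self.reactions:
            raise ModelError(f"duplicate reaction id {rxn.id}")
        for m in rxn.stoichiometry:
            if m not in self.metabolites:
                raise ModelError(f"reaction {rxn.id} references unknown metabolite {m}")
        self.reactions[rxn.id] = rxn

    def remove_reactions(self, ids: Iterable[str]):
        for i in ids:
            self.reactions.pop(i, None)

    def copy(self) -> "StoichiometricModel":
        mdl = StoichiometricModel(self.metabolites.values(), [], self.objective_id)
        for r in self.reactions.values():
            mdl.reactions[r.id] = replace(
                r, stoichiometry=dict(r.stoichiometry), genes=list(r.genes))
        mdl.blocked = set(self.blocked)
        mdl.biomass_composition = self.biomass_composition
        return mdl

    # -- views -------------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.metabolites)

    def subsystem(self, name: str) -> list[str]:
        return [r.id for r in self.reactions.values() if r.subsystem == name]

    def stoichiometric_matrix(self, reaction_ids: list[str] | None = None,
                              dtype=float) -> np.ndarray:
        rids = reaction_ids or self.reaction_ids
        mids = self.metabolite_ids
        midx = {m: i for i, m in enumerate(mids)}
        S = np.zeros((len(mids), len(rids)),
                     dtype=object if dtype is Fraction else dtype)
        if dtype is Fraction:
            S[:, :] = Fraction(0)
        for j, rid in enumerate(rids):
            for m, c in self.reactions[rid].stoichiometry.items():
                S[midx[m], j] = c if dtype is Fraction else float(c)
        return S

    # -- checks ------------------------------------------------------
    def carbon_imbalance(self, rxn: Reaction) -> Fraction:
        return sum((c * self.metabolites[m].carbon_count
                    for m, c in rxn.stoichiometry.items()), Fraction(0))

    def validate(self) -> dict[str, list[str]]:
        """Report carbon-imbalanced reactions, orphan and dead-end metabolites."""
        report: dict[str, list[str]] = {
            "carbon_imbalanced": [], "orphan_metabolites": [],
            "dead_end_metabolites": [],
        }
        for r in self.reactions.values():
            if r.is_exchange or r.id == "biomass":
                continue
            if self.carbon_imbalance(r) != 0:
                report["carbon_imbalanced"].append(r.id)
        produced: dict[str, int] = {m: 0 for m in self.metabolites}
        consumed: dict[str, int] = {m: 0 for m in self.metabolites}
        used: set[str] = set()
        for r in self.reactions.values():
            for m, c in r.stoichiometry.items():
                used.add(m)
                if c > 0 or r.reversible:
                    produced[m] += 1
                if c < 0 or r.reversible:
                    consumed[m] += 1
        for m in self.metabolites:
            if m not in used:
                report["orphan_metabolites"].append(m)
            elif produced[m] == 0 or consumed[m] == 0:
                report["dead_end_metabolites"].append(m)
        return report


def validate_model(model: StoichiometricModel) -> dict[str, list[str]]:
    return model.validate()


# ---------------------------------------------------------------------------
# Core model definition
# ---------------------------------------------------------------------------

_MET_TABLE = [
    # id, name, compartment, carbons
    ("meoh", "methanol", "extracellular", 1),
    ("fald", "formaldehyde", "cytoplasm", 1),
    ("for", "formate", "cytoplasm", 1),
    ("co2", "carbon dioxide", "extracellular", 1),
    ("o2", "oxygen", "extracellular", 0),
    ("h4mpt", "tetrahydromethanopterin", "cytoplasm", 0),
    ("ch2_h4mpt", "methylene-H4MPT", "cytoplasm", 1),
    ("ch_h4mpt", "methenyl-H4MPT", "cytoplasm", 1),
    ("fo_h4mpt", "formyl-H4MPT", "cytoplasm", 1),
    ("thf", "tetrahydrofolate", "cytoplasm", 0),
    ("fo_thf", "10-formyl-THF", "cytoplasm", 1),
    ("ch_thf", "methenyl-THF", "cytoplasm", 1),
    ("ch2_thf", "5,10-methylene-THF", "cytoplasm", 1),
    ("gly", "glycine", "cytoplasm", 2),
    ("ser", "L-serine", "cytoplasm", 3),
    ("hpyr", "hydroxypyruvate", "cytoplasm", 3),
    ("glyc", "D-glycerate", "cytoplasm", 3),
    ("pg2", "2-phosphoglycerate", "cytoplasm", 3),
    ("pg3", "3-phosphoglycerate", "cytoplasm", 3),
    ("pep", "phosphoenolpyruvate", "cytoplasm", 3),
    ("pyr", "pyruvate", "cytoplasm", 3),
    ("oaa", "oxaloacetate", "cytoplasm", 4),
    ("mal", "L-malate", "cytoplasm", 4),
    ("fum", "fumarate", "cytoplasm", 4),
    ("succ", "succinate", "cytoplasm", 4),
    ("succoa", "succinyl-CoA", "cytoplasm", 4),
    ("cit", "citrate", "cytoplasm", 6),
    ("icit", "isocitrate", "cytoplasm", 6),
    ("akg", "alpha-ketoglutarate", "cytoplasm", 5),
    ("glx", "glyoxylate", "cytoplasm", 2),
    ("mlcoa", "L-malyl-CoA", "cytoplasm", 4),
    ("accoa", "acetyl-CoA", "cytoplasm", 2),
    ("aacoa", "acetoacetyl-CoA", "cytoplasm", 4),
    ("hbcoa", "(R)-3-hydroxybutyryl-CoA", "cytoplasm", 4),
    ("crcoa", "crotonyl-CoA", "cytoplasm", 4),
    ("emcoa_s", "(2S)-ethylmalonyl-CoA", "cytoplasm", 5),
    ("emcoa_r", "(2R)-ethylmalonyl-CoA", "cytoplasm", 5),
    ("mscoa", "(2S)-methylsuccinyl-CoA", "cytoplasm", 5),
    ("mescoa", "mesaconyl-CoA", "cytoplasm", 5),
    ("mmlcoa", "beta-methylmalyl-CoA", "cytoplasm", 5),
    ("prcoa", "propionyl-CoA", "cytoplasm", 3),
    ("mmcoa_s", "(2S)-methylmalonyl-CoA", "cytoplasm", 4),
    ("mmcoa_r", "(2R)-methylmalonyl-CoA", "cytoplasm", 4),
    ("ga3p", "glyceraldehyde-3-phosphate", "cytoplasm", 3),
    ("dhap", "dihydroxyacetone phosphate", "cytoplasm", 3),
    ("fbp", "fructose-1,6-bisphosphate", "cytoplasm", 6),
    ("f6p", "fructose-6-phosphate", "cytoplasm", 6),
    ("g6p", "glucose-6-phosphate", "cytoplasm", 6),
    ("pg6", "6-phosphogluconate", "cytoplasm", 6),
    ("ru5p", "ribulose-5-phosphate", "cytoplasm", 5),
    ("r5p", "ribose-5-phosphate", "cytoplasm", 5),
    ("x5p", "xylulose-5-phosphate", "cytoplasm", 5),
    ("s7p", "sedoheptulose-7-phosphate", "cytoplasm", 7),
    ("e4p", "erythrose-4-phosphate", "cytoplasm", 4),
    ("nad", "NAD+", "cytoplasm", 0),
    ("nadh", "NADH", "cytoplasm", 0),
    ("nadp", "NADP+", "cytoplasm", 0),
    ("nadph", "NADPH", "cytoplasm", 0),
    ("fad", "FAD (membrane ET quinone level)", "cytoplasm", 0),
    ("fadh2", "FADH2 (membrane ET quinone level)", "cytoplasm", 0),
    ("cytc_ox", "cytochrome c (oxidized)", "periplasm", 0),
    ("cytc_red", "cytochrome c (reduced)", "periplasm", 0),
    ("coa", "coenzyme A", "cytoplasm", 0),
    ("atp", "ATP", "cytoplasm", 0),
    ("adp", "ADP", "cytoplasm", 0),
    ("dc", "drained biomass-precursor carbon", "extracellular", 1),
    ("biomass", "biomass", "extracellular", 0),
]

# id, equation, subsystem, genes, confidence, name
_RXN_TABLE = [
    # --- C1 pathways (10): methanol oxidation, H4MPT branch, THF branch
    ("mxa", "meoh + cytc_ox -> fald + cytc_red", "C1_pathways",
     "mxaF mxaI", 4, "methanol dehydrogenase (PQQ, periplasmic)"),
    ("fae", "fald + h4mpt -> ch2_h4mpt", "C1_pathways",
     "fae", 4, "formaldehyde activating enzyme"),
    ("mtdh_nadh", "ch2_h4mpt + nad -> ch_h4mpt + nadh", "C1_pathways",
     "mtdB", 4, "methylene-H4MPT dehydrogenase (NAD, MtdB)"),
    ("mtdh_nadph", "ch2_h4mpt + nadp -> ch_h4mpt + nadph", "C1_pathways",
     "mtdA mtdB", 4, "methylene-H4MPT dehydrogenase (NADP, MtdA/MtdB)"),
    ("mch", "ch_h4mpt -> fo_h4mpt", "C1_pathways",
     "mch", 4, "methenyl-H4MPT cyclohydrolase"),
    ("fhc", "fo_h4mpt -> for + h4mpt", "C1_pathways",
     "fhcA fhcB fhcC fhcD", 4, "formyl-H4MPT hydrolase complex (lumped)"),
    ("fdh_c", "for + nad -> co2 + nadh", "C1_pathways",
     "fdh1A fdh1B", 4, "formate dehydrogenase (cytoplasmic, NAD)"),
    ("fhs", "for + thf + atp -> fo_thf + adp", "C1_pathways",
     "ftfL", 4, "formate-THF ligase"),
    ("fch", "fo_thf -> ch_thf", "C1_pathways",
     "fch", 4, "methenyl-THF cyclohydrolase"),
    ("mtda", "ch_thf + nadph -> ch2_thf + nadp", "C1_pathways",
     "mtdA", 4, "methylene-THF dehydrogenase (NADP, MtdA)"),
    # --- serine cycle (9)
    ("shmt", "gly + ch2_thf -> ser + thf", "serine_cycle",
     "glyA", 4, "serine hydroxymethyltransferase"),
    ("sga", "ser + glx -> hpyr + gly", "serine_cycle",
     "sgaA", 4, "serine-glyoxylate aminotransferase"),
    ("hpr", "hpyr + nadh -> glyc + nad", "serine_cycle",
     "hprA", 4, "hydroxypyruvate reductase"),
    ("gck", "glyc + atp -> pg2 + adp", "serine_cycle",
     "gckA", 4, "glycerate 2-kinase"),
    ("eno", "pg2 <-> pep", "serine_cycle",
     "eno", 4, "enolase"),
    ("ppc", "pep + co2 -> oaa", "serine_cycle",
     "ppc", 4, "PEP carboxylase"),
    ("mdh", "oaa + nadh <-> mal + nad", "serine_cycle",
     "mdh", 4, "malate dehydrogenase"),
    ("mtk", "mal + coa + atp -> mlcoa + adp", "serine_cycle",
     "mtkA mtkB", 4, "malate-CoA ligase (malate thiokinase)"),
    ("mcl", "mlcoa <-> accoa + glx", "serine_cycle",
     "mclA1", 4, "malyl-CoA lyase (reversible)"),
    # --- ethylmalonyl-CoA pathway (12)
    ("phaA", "2 accoa -> aacoa + coa", "EMCP",
     "phaA", 4, "acetyl-CoA C-acetyltransferase (beta-ketothiolase)"),
    ("phaB", "aacoa + nadph -> hbcoa + nadp", "EMCP",
     "phaB", 4, "acetoacetyl-CoA reductase"),
    ("croR", "hbcoa -> crcoa", "EMCP",
     "croR", 4, "(R)-3-hydroxybutyryl-CoA dehydratase (crotonase)"),
    ("ccr", "crcoa + co2 + nadph -> emcoa_s + nadp", "EMCP",
     "ccr", 4, "crotonyl-CoA carboxylase/reductase"),
    ("epi", "emcoa_s -> emcoa_r", "EMCP",
     "epi", 4, "ethylmalonyl-CoA epimerase"),
    ("ecm", "emcoa_r -> mscoa", "EMCP",
     "ecm", 4, "ethylmalonyl-CoA mutase"),
    ("mcd", "mscoa + fad -> mescoa + fadh2", "EMCP",
     "msd", 4, "methylsuccinyl-CoA dehydrogenase"),
    ("mct", "mescoa -> mmlcoa", "EMCP",
     "mcd", 4, "mesaconyl-CoA hydratase"),
    ("mcl2", "mmlcoa -> prcoa + glx", "EMCP",
     "mclA2", 4, "beta-methylmalyl-CoA lyase"),
    ("pcc", "prcoa + co2 + atp -> mmcoa_s + adp", "EMCP",
     "pccA pccB", 4, "propionyl-CoA carboxylase"),
    ("epm", "mmcoa_s -> mmcoa_r", "EMCP",
     "epm", 4, "methylmalonyl-CoA epimerase"),
    ("mcm", "mmcoa_r -> succoa", "EMCP",
     "mcmA mcmB", 4, "methylmalonyl-CoA mutase"),
    # --- TCA branch + pyruvate dehydrogenase (8)
    ("pdh", "pyr + coa + nad -> accoa + co2 + nadh", "TCA",
     "pdhA pdhB", 3, "pyruvate dehydrogenase"),
    ("cs", "accoa + oaa -> cit + coa", "TCA",
     "gltA", 3, "citrate synthase"),
    ("acn", "cit <-> icit", "TCA", "acnA", 3, "aconitase"),
    ("icd", "icit + nadp -> akg + co2 + nadph", "TCA",
     "icd", 3, "isocitrate dehydrogenase (NADP)"),
    ("akgdh", "akg + coa + nad -> succoa + co2 + nadh", "TCA",
     "sucA sucB", 3, "2-oxoglutarate dehydrogenase"),
    ("scs", "succoa + adp <-> succ + atp + coa", "TCA",
     "sucC sucD", 3, "succinyl-CoA synthetase"),
    ("sdh", "succ + fad -> fum + fadh2", "TCA",
     "sdhA sdhB", 4, "succinate dehydrogenase"),
    ("fum", "fum <-> mal", "TCA", "fumA", 4, "fumarase"),
    # --- anaplerotic / C3-C4 interconversions / misc (6)
    ("pyk", "pep + adp -> pyr + atp", "anaplerotic",
     "pyk", 4, "pyruvate kinase"),
    ("pps", "pyr + 2 atp -> pep + 2 adp", "anaplerotic",
     "ppsA", 4, "PEP synthase (AMP recycling lumped)"),
    ("pepck", "oaa + atp -> pep + co2 + adp", "anaplerotic",
     "pckA", 4, "PEP carboxykinase"),
    ("mae", "mal + nadp -> pyr + co2 + nadph", "anaplerotic",
     "mez", 4, "malic enzyme (NADP)"),
    ("gcc", "gly + thf + nad -> ch2_thf + co2 + nadh", "anaplerotic",
     "gcvP gcvT gcvH", 3, "glycine cleavage complex"),
    ("mclt", "mlcoa -> mal + coa", "anaplerotic",
     "mclA2", 3, "malyl-CoA thioesterase"),
    ("ggt", "glx + nadph -> gly + nadp", "anaplerotic",
     "", 3, "glyoxylate aminotransferase (GDH/GOGAT ammonium assimilation lumped)"),
    # --- gluconeogenesis (6)
    ("pgm", "pg2 <-> pg3", "gluconeogenesis_glycolysis",
     "gpmA", 3, "phosphoglycerate mutase"),
    ("gapdh", "pg3 + atp + nadh -> ga3p + adp + nad",
     "gluconeogenesis_glycolysis", "pgk gap", 3,
     "PGK + GAPDH lumped (gluconeogenic direction)"),
    ("tpi", "ga3p <-> dhap", "gluconeogenesis_glycolysis",
     "tpiA", 3, "triose-phosphate isomerase"),
    ("fba", "ga3p + dhap <-> fbp", "gluconeogenesis_glycolysis",
     "fbaA", 3, "fructose-bisphosphate aldolase"),
    ("fbp", "fbp -> f6p", "gluconeogenesis_glycolysis",
     "glpX", 3, "fructose-1,6-bisphosphatase"),
    ("pgi", "f6p <-> g6p", "gluconeogenesis_glycolysis",
     "pgi", 3, "glucose-6-phosphate isomerase"),
    # --- PPP / Entner-Doudoroff (8)
    ("zwf", "g6p + nadp -> pg6 + nadph", "PPP_ED",
     "zwf", 3, "glucose-6-P dehydrogenase (+lactonase, lumped)"),
    ("gnd", "pg6 + nadp -> ru5p + co2 + nadph", "PPP_ED",
     "gnd", 3, "6-phosphogluconate dehydrogenase"),
    ("edd_eda", "pg6 -> pyr + ga3p", "PPP_ED",
     "edd eda", 3, "Entner-Doudoroff dehydratase + aldolase (lumped)"),
    ("rpi", "ru5p <-> r5p", "PPP_ED", "rpiA", 3, "ribose-5-P isomerase"),
    ("rpe", "ru5p <-> x5p", "PPP_ED", "rpe", 3, "ribulose-5-P epimerase"),
    ("tkt1", "x5p + r5p <-> s7p + ga3p", "PPP_ED",
     "tktA", 3, "transketolase I"),
    ("tal", "s7p + ga3p <-> e4p + f6p", "PPP_ED",
     "talB", 3, "transaldolase"),
    ("tkt2", "x5p + e4p <-> f6p + ga3p", "PPP_ED",
     "tktA", 3, "transketolase II"),
    # --- respiration (5): lumped oxidative phosphorylation; the periplasmic
    #     (cytochrome-linked) formaldehyde/formate oxidations live here too.
    ("resp_nadh", "nadh + 1/2 o2 + 2 adp -> nad + 2 atp", "respiration",
     "", 2, "NADH dehydrogenase + chain, effective P/O 2"),
    ("resp_cytc", "cytc_red + 1/4 o2 + adp -> cytc_ox + atp", "respiration",
     "", 2, "cytochrome c oxidase, effective P/O 1"),
    ("resp_fadh2", "fadh2 + 1/2 o2 + adp -> fad + atp", "respiration",
     "", 2, "quinol oxidation branch, effective P/O 1"),
    ("fald_p", "fald + cytc_ox -> for + cytc_red", "respiration",
     "xoxF", 2, "formaldehyde oxidation (periplasmic, cytochrome-linked)"),
    ("fdh_p", "for + cytc_ox -> co2 + cytc_red", "respiration",
     "", 2, "formate dehydrogenase (periplasmic, cytochrome-linked)"),
]

_DRAIN_TABLE = [
    # drain id, precursor pool, carbons, carriers released
    ("drain_methf", "ch2_thf", 1, {"thf": 1}),
    ("drain_accoa", "accoa", 2, {"coa": 1}),
    ("drain_gly", "gly", 2, {}),
    ("drain_ser", "ser", 3, {}),
    ("drain_pyr", "pyr", 3, {}),
    ("drain_pep", "pep", 3, {}),
    ("drain_ga3p", "ga3p", 3, {}),
    ("drain_oaa", "oaa", 4, {}),
    ("drain_e4p", "e4p", 4, {}),
    ("drain_hbcoa", "hbcoa", 4, {"coa": 1}),
    ("drain_akg", "akg", 5, {}),
    ("drain_r5p", "r5p", 5, {}),
    ("drain_g6p", "g6p", 6, {}),
]

#: the 13 assimilation target precursors, keyed by drain reaction
PRECURSOR_DRAINS = {d[0]: d[1] for d in _DRAIN_TABLE}
PRECURSOR_CARBONS = {d[0]: d[2] for d in _DRAIN_TABLE}

#: EMCP reactions that are not shared with PHB synthesis
EMCP_EXCLUSIVE = ["croR", "ccr", "epi", "ecm", "mcd", "mct", "mcl2",
                  "pcc", "epm", "mcm"]


def build_core_model(biomass: BiomassComposition | None = None) -> StoichiometricModel:
    """Construct the curated central-metabolism model (~86 reactions)."""
    comp = biomass or BiomassComposition()
    mets = [Metabolite(i, n, c, cc) for i, n, c, cc in _MET_TABLE]
    rxns: list[Reaction] = []
    for rid, eq, sub, genes, conf, name in _RXN_TABLE:
        stoich, rev = parse_equation(eq)
        rxns.append(Reaction(rid, stoich, rev, sub,
                             genes.split() if genes else [], conf, name))
    for rid, pool, ncarb, carriers in _DRAIN_TABLE:
        stoich = {pool: Fraction(-1), "dc": Fraction(ncarb)}
        for carrier, n in carriers.items():
            stoich[carrier] = Fraction(n)
        rxns.append(Reaction(rid, stoich, False, "biosynthesis_drain",
                             [], 4, f"{pool} biosynthetic drain"))
    rxns.append(biomass_reaction(comp))
    for rid, eq, name in [
        ("EX_meoh", "-> meoh", "methanol uptake"),
        ("EX_co2", "co2 <->", "CO2 exchange (free)"),
        ("EX_o2", "-> o2", "O2 uptake"),
        ("EX_biomass", "biomass ->", "biomass sink"),
        ("EX_drained", "dc ->", "precursor drain sink"),
        ("ngam", "atp -> adp", "non-growth-associated ATP maintenance"),
        ("dm_nadh", "nadh -> nad", "NADH drain (yield analyses only)"),
        ("dm_nadph", "nadph -> nadp", "NADPH drain (yield analyses only)"),
    ]:
        stoich, rev = parse_equation(eq)
        rxns.append(Reaction(rid, stoich, rev, "exchange", [], 4, name))
    model = StoichiometricModel(mets, rxns, objective_id="EX_biomass")
    model.biomass_composition = comp
    bad = model.validate()["carbon_imbalanced"]
    if bad:  # construction invariant
        raise ModelError(f"carbon-imbalanced core reactions: {bad}")
    return model


def make_icl_variant(model: StoichiometricModel) -> StoichiometricModel:
    """Glyoxylate-cycle variant: block the EMCP downstream of crotonyl-CoA
    and add isocitrate lyase.  Malate synthase is deliberately not added
    (malyl-CoA ligase + lyase achieve the same net conversion)."""
    if "ccr" not in model.reactions:
        raise ModelError("model lacks the crotonyl-CoA -> propionyl-CoA entry "
                         "step (ccr); cannot build the ICL variant")
    variant = model.copy()
    if "icl" not in variant.reactions:
        stoich, _ = parse_equation("icit -> succ + glx")
        variant.add_reaction(Reaction("icl", stoich, False, "TCA",
                                      ["aceA"], 1, "isocitrate lyase"))
    variant.blocked = set(getattr(model, "blocked", set())) | {"ccr"}
    variant.biomass_composition = getattr(model, "biomass_composition", None)
    return variant
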