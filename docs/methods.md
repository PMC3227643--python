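# Methods

## The core model

`build_core_model()` encodes the central carbon metabolism of
methanol-grown *M. extorquens* AM1 as 87 reactions over 67 metabolites:
10 C1-pathway reactions (periplasmic methanol dehydrogenase, the
H₄MPT-dependent oxidation branch with both NAD- and NADP-linked
methylene dehydrogenases, the NAD-dependent formate dehydrogenase, and
the THF-dependent assimilation branch), the 9-reaction serine cycle, the
12-reaction ethylmalonyl-CoA pathway (EMCP, both epimerases explicit),
an anabolic TCA branch, the seven C3/C4 interconversions (enolase, PEP
synthase, pyruvate kinase, malate dehydrogenase, PEP carboxylase, PEP
carboxykinase, malic enzyme), malyl-CoA ligase/lyase/thioesterase,
gluconeogenesis, the non-oxidative/oxidative pentose-phosphate and
Entner-Doudoroff routes, glycine cleavage, a lumped glyoxylate
aminotransferase, lumped respiration, 13 biomass-precursor drains, the
biomass equation and exchanges.

Modeling conventions:

- **Balancing.** Only carbon and cofactor stoichiometry is enforced; no
  proton/charge balance. Carrier moieties (CoA, THF, H₄MPT,
  nicotinamides, cytochrome c, ATP/ADP) count zero carbons; acyl-CoA
  esters carry the acyl carbons only. Every non-exchange, non-biomass
  reaction carbon-balances exactly (rational arithmetic); this is a
  construction-time invariant.
- **Respiration.** Electron transport is lumped into three effective
  reactions: NADH + ½O₂ + 2 ADP → NAD⁺ + 2 ATP; cyt c(red) + ¼O₂ + ADP →
  cyt c(ox) + ATP; quinol-level FADH₂ + ½O₂ + ADP → FAD + ATP. The
  (2, 1) effective P/O pair is the unique small-integer choice that
  reproduces the 5 (cytoplasmic) and 3 (periplasmic) ATP-per-methanol
  dissimilation yields. NADPH is not respirable, and no transhydrogenase
  is included.
- **Nitrogen.** Untracked. Its reducing cost enters in one place where
  it matters structurally: the lumped glyoxylate aminotransferase
  (glyoxylate + NADPH → glycine) carries the two electrons that ammonium
  assimilation provides in vivo. Without that term the
  EMCP + serine-cycle + glycine-cleavage loop would fix CO₂ to
  methylene-THF at no net redox cost, which is unphysical. All other
  amino-group costs sit inside the biomass NADPH demand.
- **Reversibility.** Reactions are reversible only where the physiology
  requires it (enolase, phosphoglycerate mutase, malate dehydrogenase,
  fumarase, succinyl-CoA synthetase, malyl-CoA lyase, aconitase,
  triose-phosphate and pentose-phosphate isomerase/transfer reactions,
  CO₂ exchange). Methanol uptake, O₂ uptake and secretion steps are
  one-way.
- **Biomass.** The macromolecular composition (protein 59.13, carbo-
  hydrate 16.43, RNA 8.20, fatty acid 4.95, DNA 3.00, PHB 2.36 %CDW,
  plus minor classes; listed fractions sum to 98.36) is converted to a
  precursor-demand vector via per-macromolecule precursor tables
  (`PRECURSOR_PER_GRAM`): a standard bacterial amino-acid composition
  for protein, ribose + ring-atom accounting for nucleic acids, C18
  acyl chains for fatty acids, direct (R)-3-hydroxybutyryl-CoA for PHB.
  The resulting vector carries 43 mmol C/gDW (0.52 gC/g). GAM is
  59.81 mmol ATP/gDW (polymerization included), NGAM
  9.5 mmol ATP/gDW/h, biosynthetic NADPH 10.71 mmol/gDW (the
  flux-derived biosynthetic requirement divided by the measured growth
  rate). The table is deliberately editable: it is the single place
  where composition uncertainty enters.
- **Precursor drains** produce a generic one-carbon `drained` species so
  they carbon-balance; they are open only in yield/mode analyses, never
  during growth simulation (the living cell cannot overflow
  erythrose-4-phosphate).

Against the published full-network values, the core model is slightly
"too efficient": maximal growth 0.2215 vs 0.20 h⁻¹, maintenance-free
yield 0.53 vs ≈0.48 g/g, CO₂-only yield 0.337 vs 0.283 g/g. An ~87-
reaction core omits minor costs a 717-reaction network carries
(transport, full biosynthetic routes, proton handling); the deviations
stay within the scaled-down tolerance used by the acceptance tests
(20%). Maximal NADPH yield per methanol is 1.8 rather than 2 because the
formate dehydrogenase is modeled strictly NAD-dependent.

## Elementary flux modes

`enumerate_efms` works on the cone {v : S·v = 0, v_irrev ≥ 0}: the
network is first compressed (structurally blocked reactions removed —
including any reaction that is the sole toucher of a metabolite — and
2-degree metabolite nodes merged, with exact rational bookkeeping), then
reversible reactions are split and the double-description method is run
with integer arithmetic and a combinatorial adjacency test. Rays using
both directions of a split reaction are discarded, supports are
deduplicated, a pairwise support-minimality filter guards the
compression mapping, and modes are returned sorted lexicographically by
support with methanol uptake normalized to 1. Enumeration is
deterministic; an intermediate-ray cap (default 10⁶) guards runtime, and
`target_drain` focuses the enumeration on one sink (biomass target:
1968 modes on the core model, 1414 of them biomass-forming, ~8 s).

The maintenance-corrected yield of a biomass mode scales the mode to a
reference growth rate μ_i and adds the substrate equivalent of NGAM:
Y = μ_max/(q_si·μ_max/μ_i + NGAM_s)·1000/MW_s with defaults
μ_max = 0.201 h⁻¹, μ_i = 0.1 h⁻¹, NGAM_s = 1.9 mmol·g⁻¹·h⁻¹
(= 9.5 ATP / 5 ATP per methanol), MW = 32.04 g/mol. This is the only
dimensionally consistent reading of the published normalization and
reproduces the ≈0.42 g/g optimum at the maintenance-free LP solution.

CO₂-only modes are biomass modes whose formate→THF flux is zero: all
methanol leaves the C1 pathways as CO₂ and biomass carbon derives from
CO₂ via the EMCP + serine-cycle + glycine-cleavage loop (net
2 CO₂ → 1 glyoxylate). The glyoxylate-cycle variant
(`make_icl_variant`: crotonyl-CoA carboxylase bounded to zero —
reactions are never deleted — plus isocitrate lyase; no malate synthase)
has no such modes.

## Minimal cut sets and fragility

Cut sets are minimal transversals of the support hypergraph of the
biomass modes, computed by Berge-style incremental dualization with
subsumption pruning and a cardinality cap (default 4; the core-model
analyses use 2 — singleton membership, hence essentiality, is
independent of the cap). FC_i = 1/(mean cardinality of cut sets
containing i); whether the original fragility coefficient weighted cut
sets by multiplicity is not documented, so the unweighted mean is used
and stated. On the core model all 12 EMCP reactions and 6/9 serine-cycle
reactions (67%) are essential; C3/C4 interconversions and the drains
have FC = 0.

## ¹³C metabolic flux analysis

The MFA network is the carbon skeleton of the core model: 49 atom-mapped
reactions plus 13 drains, with linear C1 segments and the
hexose-phosphate isomerases lumped (label-equivalent). Methanol (99 atom%
¹³C) and CO₂ are fixed-label input pools; the CO₂ label defaults to
natural abundance (1.1%) with a 4.6% option reflecting the measured
methanol-derived share under the aerated cultivation. Succinate and
fumarate scramble their orientations at production (half-flux variants).
Seven reactions carry exchange fluxes (enolase, phosphoglycerate mutase,
triose-phosphate isomerase, malate dehydrogenase, fumarase, succinyl-CoA
synthetase, malyl-CoA lyase). The interior atom maps of the C5-CoA-ester
mutase steps use a documented identity convention; generation and
fitting share them, so synthetic-data studies are internally consistent,
but fitting *real* positional data would require validated maps.

Labeling is simulated with the EMU decomposition: the measurement
targets are traced back through the atom maps, unknowns are grouped by
EMU size, and one dense linear system per size is solved (condensations
enter as convolutions of smaller-EMU MIDs). The decomposition is built
once and cached; a full 193-datum simulation takes ~5 ms. Pools carrying
zero flux are parked at natural (unlabeled) composition unless they are
explicitly requested, in which case an error names them. The simulator
is verified against a full 2ⁿ-isotopomer fixed-point oracle.

Measurements emulate a combined LC-MS / 2D-NMR dataset on proteinogenic
amino acids: 56 MS data (fragment mass-isotopomer fractions) and 137
NMR data (positional enrichments, adjacent-pair and centre-triplet joint
labeling fractions approximating HSQC/TOCSY fine structure), mapped
carbon-by-carbon onto their precursors (pyruvate, serine, glycine,
oxaloacetate, 2-oxoglutarate (+CO₂ for arginine), PEP,
ribose-5-phosphate, acetyl-CoA). Default noise: 0.004 mol-fraction (MS),
0.01 (NMR); MIDs are renormalized after noise.

Fitting parametrizes net fluxes by the nullspace of the balance matrix
stacked with the fixed constraints (methanol uptake and the biomass
drains — 9 free net coordinates) plus the 7 exchange fluxes, and
minimizes χ² = Σ((sim−obs)/sd)² by trust-region least squares with a
soft irreversibility penalty and seeded multistarts (default 10 in the
API; the packaged recovery studies use 2-3, the first start being the
feasibility-projected interior point, which suffices because each
synthetic fit is well-posed: each start takes a few seconds at the
sizes used here).
Confidence intervals come from (JᵀJ)⁻¹ at the optimum, propagated
through the nullspace; directions without labeling information (pure
substrate cycles such as PEP-synthase/pyruvate-kinase or the malyl-CoA
thioesterase loop, and the triose-phosphate exchange) are reported with
effectively unbounded intervals rather than silently pinned.

## The reference flux distribution

`reference_flux_distribution()` packages the measured methylotrophic
steady state: uptake 15.10, direct formate oxidation 12.7, Me-THF
assimilation 2.4, malyl-CoA lyase 1.80, EMCP recycling 1.4 (thiolase
0.7), glyoxylate replenishment 0.70, malic enzyme 0.36, PEP
carboxykinase 0.26, PEP synthase 0.13, ED flux 0.08, thioesterase 0.80,
glycine cleavage 0 (all mmol·gDW⁻¹·h⁻¹). These are hard constraints
(except the malyl-CoA lyase and thiolase fluxes, which adjacent drains
shift to 1.73 and 0.73, within ~1.5 reported sd); the biomass drains
keep the composition-derived proportions but are scaled so total drain
carbon equals the assimilated carbon the measured fluxes provide
(2.4 Me-THF + 2.4 net CO₂ fixation = 4.8 mmol C·g⁻¹·h⁻¹, an effective
demand rate of 0.112 h⁻¹). The measured fluxes do not close the carbon
balance at full Table-composition demand × the measured growth rate;
the flux scale of the labeling fit wins because the distribution's
purpose is to carry the measured values. Remaining freedom is resolved
by a ridge-regularized equality-constrained least squares with a
deterministic active-set loop for irreversibility. The completed map
reproduces 84% direct oxidation, net central CO₂ fixation 2.4, 50%
biomass carbon from CO₂, PEP/OAA cycling 13%, malate-cycle recycling
32%, cycling ATP cost 1.2 and the NADPH decomposition 2.4/1.4/1.8
(total 5.6). One published ratio does not survive the reconciliation:
the completed map needs a 0.13 pyruvate-dehydrogenase flux, raising
PEP-synthase/pyruvate-kinase recycling to 0.84 vs the published 0.68.

## What the synthetic data do and do not show

The synthetic datasets are generated by the same atom maps and
measurement model used in fitting, so parameter-recovery results
demonstrate the correctness and conditioning of the estimation
machinery — identifiability of the dissimilation/assimilation split,
honest non-identifiability of label-invisible cycles — but not the
adequacy of the atom maps to real spectra, nor robustness to
natural-abundance effects, fragment mis-assignment or model
misspecification, none of which are emulated.

## Known limitations

- Full-network quantities (reaction/mode counts, the 391 essential
  reactions, Table-scale minimal mode lengths) are out of reach of an
  87-reaction core by construction and are not asserted.
- Proton/charge balance and nitrogen stoichiometry are not modeled;
  effective P/O ratios are fixed constants.
- The EFM enumerator is a desk-scale double-description implementation;
  genome-scale networks need compression beyond what it performs.
- MS natural-abundance correction and raw-spectrum processing are out of
  scope; measurement emulation is a documented stand-in, not a claim
  about the original dataset's exact composition.
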