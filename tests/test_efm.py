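"""Elementary flux mode enumeration and mode-level statistics.

Enumeration is validated against a brute-force oracle that tests the
support minimality of every sign-feasible nullspace support (exact
arithmetic, sympy).
"""

from fractions import Fraction

import pytest

from methyloflux import (classify_dissimilation, co2_only_modes,
                         enumerate_efms, ngam_substrate_equivalent,
                         normalized_yield)
from methyloflux.efm import YieldNormalizationParams
from methyloflux.model import (Metabolite, Reaction, StoichiometricModel,
                               parse_equation)
from methyloflux.synthetic import ToyNetworkSpec, random_toy_network

from oracles import brute_force_efms


def toy(rxns, mets):
    ms = [Metabolite(m, m, "cytoplasm", 1) for m in mets]
    rs = []
    for rid, eq in rxns:
        st, rev = parse_equation(eq)
        sub = "exchange" if rid.startswith("EX") else "transport"
        rs.append(Reaction(rid, st, rev, sub))
    return StoichiometricModel(ms, rs, rxns[0][0])


class TestEnumeration:
    def test_linear_chain_has_one_mode(self):
        m = toy([("EX_in", "-> A"), ("r1", "A -> B"), ("r2", "B -> C"),
                 ("EX_out", "C ->")], "ABC")
        modes = enumerate_efms(m)
        assert len(modes) == 1
        assert modes[0].support == {"EX_in", "r1", "r2", "EX_out"}

    def test_parallel_routes_give_two_modes(self):
        m = toy([("EX_in", "-> A"), ("r1", "A -> B"), ("r2", "A -> C"),
                 ("r3", "C -> B"), ("EX_out", "B ->")], "ABC")
        modes = enumerate_efms(m)
        assert {frozenset(x.support) for x in modes} == {
            frozenset({"EX_in", "r1", "EX_out"}),
            frozenset({"EX_in", "r2", "r3", "EX_out"})}

    def test_pure_cycle_is_a_mode(self):
        m = toy([("EX_in", "-> A"), ("r1", "A -> B"), ("r2", "B -> A"),
                 ("EX_out", "B ->")], "AB")
        supports = {frozenset(x.support) for x in enumerate_efms(m)}
        assert frozenset({"r1", "r2"}) in supports

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle_on_random_networks(self, seed):
        spec = ToyNetworkSpec(n_metabolites=5, n_reactions=9,
                              reversibility=0.3, seed=seed)
        m = random_toy_network(spec)
        ours = {frozenset(x.support) for x in enumerate_efms(m)}
        oracle = brute_force_efms(m)
        assert ours == oracle

    def test_deterministic(self, core):
        a = enumerate_efms(core, target_drain="drain_methf")
        b = enumerate_efms(core, target_drain="drain_methf")
        assert [x.fluxes for x in a] == [y.fluxes for y in b]


class TestCoreModes:
    def test_steady_state_exact_and_sign_feasible(self, core, biomass_efms):
        """S.v = 0 holds in exact rational arithmetic for every mode and
        irreversible reactions never run backwards."""
        for mode in list(biomass_efms)[::97] + [biomass_efms[0]]:
            balance: dict[str, Fraction] = {}
            for rid, v in mode.fluxes:
                assert core.reactions[rid].reversible or v > 0, rid
                for met, c in core.reactions[rid].stoichiometry.items():
                    balance[met] = balance.get(met, Fraction(0)) + c * v
            bm = core.reactions["biomass"].stoichiometry
            for met, tot in balance.items():
                ext = core.metabolites[met].compartment == "extracellular"
                if not ext:
                    assert tot == 0, (met, tot)

    def test_support_minimality_pairwise(self, biomass_efms):
        sups = [m.support for m in biomass_efms]
        sample = sups[::37]
        for s in sample:
            assert not any(t < s for t in sups)

    def test_methanol_normalization(self, biomass_efms):
        for m in list(biomass_efms)[::51]:
            if "EX_meoh" in m.support:
                assert m["EX_meoh"] == 1

    def test_efm_and_fba_optimal_yields_agree(self, core, biomass_efms):
        """Duality: the best biomass-per-methanol over all modes equals
        the LP optimum (maintenance off)."""
        from methyloflux import default_bounds, fba
        best = max(float(m["EX_biomass"] / m["EX_meoh"])
                   for m in biomass_efms
                   if m["EX_biomass"] > 0 and m["EX_meoh"] > 0)
        lp = fba(core, "EX_biomass", default_bounds(core, 1.0, ngam=False))
        assert best == pytest.approx(lp.objective, abs=1e-9)


class TestNormalizedYield:
    def test_hand_checked_arithmetic(self):
        """Independent arithmetic: mu_max 0.201, mu_i 0.1, NGAM_s 1.9,
        MW 32.04, q_si 10.4 -> Y = 0.201/(10.4*2.01+1.9)*1000/32.04."""
        p = YieldNormalizationParams(0.201, 0.1, 1.9, 32.04)
        expected = 0.201 / (10.4 * (0.201 / 0.1) + 1.9) * 1000 / 32.04
        from methyloflux.efm import ElementaryMode
        mode = ElementaryMode((("EX_biomass", Fraction(1, 10)),
                               ("EX_meoh", Fraction(104, 10)),
                               ("biomass", Fraction(1, 10))))
        # q_si at mu_i = 0.1: uptake when the mode runs at growth 0.1
        assert normalized_yield(mode, p) == pytest.approx(expected, rel=1e-12)

    def test_reduces_to_maintenance_free_yield_when_ngam_vanishes(self):
        from methyloflux.efm import ElementaryMode
        p = YieldNormalizationParams(0.201, 0.1, 1e-12, 32.04)
        mode = ElementaryMode((("EX_biomass", Fraction(1, 10)),
                               ("EX_meoh", Fraction(2)),
                               ("biomass", Fraction(1, 10))))
        q = 2.0 * 0.1 / 0.1
        assert normalized_yield(mode, p) == pytest.approx(
            0.1 * 1000 / (q * 32.04), rel=1e-6)

    def test_non_biomass_mode_rejected(self):
        from methyloflux.efm import ElementaryMode
        mode = ElementaryMode((("EX_meoh", Fraction(1)),
                               ("fdh_c", Fraction(1))))
        with pytest.raises(ValueError):
            normalized_yield(mode)

    def test_ngam_substrate_equivalent(self):
        """9.5 mmol ATP/gDW/h at 5 ATP per methanol = 1.9 mmol methanol."""
        assert ngam_substrate_equivalent(9.5, 5.0) == pytest.approx(1.9)


class TestPrecursorStats:
    def test_emcp_required_by_all_serine_and_downstream_precursors(self, core):
        """Every assimilatory mode to serine, OAA or hexose needs the
        EMCP; the C1/C2 precursors (Me-THF, acetyl-CoA) have a minority
        of EMCP-free routes."""
        from methyloflux import precursor_efm_stats
        for prec in ("ser", "oaa", "g6p"):
            st = precursor_efm_stats(core, prec)
            assert st["emcp_usage_fraction"] == pytest.approx(1.0), prec
        st = precursor_efm_stats(core, "methf")
        assert 0.5 < st["emcp_usage_fraction"] < 1.0

    def test_methf_minimal_mode_length(self, core):
        """The shortest methanol -> methylene-THF route: methanol
        dehydrogenase, H4MPT activation/oxidation to formate (4 steps),
        THF assimilation (3 steps), cytochrome respiration for the
        ligase ATP, and the drain — 10 reactions."""
        from methyloflux import precursor_efm_stats
        st = precursor_efm_stats(core, "methf")
        assert st["min_length"] == 10

    def test_min_length_is_the_smallest_support(self, core):
        from methyloflux import precursor_efm_stats
        st = precursor_efm_stats(core, "accoa")
        efms = enumerate_efms(core, target_drain="drain_accoa")
        exch = {r.id for r in core.reactions.values() if r.is_exchange}
        lengths = [len(m.support - exch) for m in efms
                   if m["drain_accoa"] > 0 and m["EX_meoh"] > 0]
        assert st["min_length"] == min(lengths)

    def test_molar_yield_matches_lp_bound(self, core):
        """The best mode yield equals the LP maximum for the same drain
        (mode/LP duality on the assimilation problem)."""
        from methyloflux import max_precursor_yield, precursor_efm_stats
        st = precursor_efm_stats(core, "oaa")
        molar, _ = max_precursor_yield(core, "meoh", "oaa")
        assert st["max_molar_yield"] == pytest.approx(molar, abs=1e-9)


class TestClassificationAndCo2Modes:
    def test_fractions_bounded(self, biomass_efms):
        for m in list(biomass_efms)[::29]:
            cl = classify_dissimilation(m)
            assert all(-1e-12 <= v <= 1 + 1e-9 for v in cl.values()), cl

    def test_pure_cytoplasmic_mode_classification(self, biomass_efms):
        full = [m for m in biomass_efms
                if m["EX_biomass"] == 0 and m["EX_meoh"] > 0
                and m["fdh_c"] == m["EX_meoh"]]
        assert full, "a pure dissimilation mode exists"
        cl = classify_dissimilation(full[0])
        assert cl["fdh_cytoplasmic"] == pytest.approx(1.0)
        assert cl["fdh_periplasmic"] == 0.0

    def test_optimal_mode_oxidizes_most_methanol_directly(self, biomass_efms):
        """In the maximum-yield biomass mode, roughly 70% of methanol is
        oxidized directly in the C1 pathways."""
        best = max((m for m in biomass_efms if m["EX_biomass"] > 0),
                   key=normalized_yield)
        frac = classify_dissimilation(best)["fdh_cytoplasmic"]
        assert 0.55 <= frac <= 0.8

    def test_co2_only_modes_exist_and_icl_variant_has_none(
            self, core, icl, biomass_efms):
        subset, ybest = co2_only_modes(biomass_efms)
        assert subset and ybest > 0
        icl_modes = enumerate_efms(icl, target_drain="biomass")
        icl_subset, _ = co2_only_modes(icl_modes)
        assert icl_subset == []

    def test_co2_only_block_balance(self, biomass_efms):
        """In CO2-only modes all methanol carbon leaves as CO2 through
        the C1 pathways and the glycine cleavage complex runs."""
        subset, _ = co2_only_modes(biomass_efms)
        for m in subset[:20]:
            assert m["fhs"] == 0
            assert m["gcc"] > 0
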