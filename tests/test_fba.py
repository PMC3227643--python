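"""LP analyses: growth, cofactor/precursor yields, FVA, NADPH scan.

The maximal-growth solution is cross-checked against an independent FBA
implementation (cobrapy / GLPK) built from the same stoichiometry.
"""

import numpy as np
import pytest

from methyloflux import (FluxBounds, default_bounds, fba, fva,
                         max_cofactor_yield, max_precursor_yield, nadph_scan)
from methyloflux.fba import ROUTES


class TestFba:
    def test_zero_uptake_means_zero_growth(self, core):
        res = fba(core, "EX_biomass", default_bounds(core, 0.0, ngam=False))
        assert res.status == "optimal"
        assert res.objective == pytest.approx(0.0, abs=1e-9)

    def test_steady_state_and_bounds_hold_at_optimum(self, core):
        res = fba(core, "EX_biomass", default_bounds(core, 15.0, True))
        S = core.stoichiometric_matrix()
        v = np.array([res.fluxes[r] for r in core.reaction_ids])
        assert np.abs(S @ v).max() <= 1e-9 * max(1.0, np.abs(v).max())
        for rid in core.reaction_ids:
            if not core.reactions[rid].reversible:
                assert res.fluxes[rid] >= -1e-9, rid
        assert res.fluxes["EX_meoh"] <= 15.0 + 1e-9

    def test_lp_homogeneity_without_maintenance(self, core):
        g1 = fba(core, "EX_biomass", default_bounds(core, 10.0, False)).objective
        g2 = fba(core, "EX_biomass", default_bounds(core, 20.0, False)).objective
        assert g2 == pytest.approx(2 * g1, rel=1e-6)

    def test_carbon_conservation_at_optimum(self, core):
        """Methanol + net CO2 uptake equals biomass + drained carbon."""
        res = fba(core, "EX_biomass", default_bounds(core, 15.0, True))
        bm = core.reactions["biomass"].stoichiometry
        biomass_c = -sum(float(c) * core.metabolites[m].carbon_count
                         for m, c in bm.items() if c < 0)
        c_in = res.fluxes["EX_meoh"] - res.fluxes["EX_co2"]
        c_out = res.fluxes["EX_drained"] + res.fluxes["EX_biomass"] * biomass_c
        # biomass co2 coefficient is a consumption on the substrate side
        assert c_in == pytest.approx(c_out, abs=1e-6)

    def test_agrees_with_independent_fba_implementation(self, core):
        import cobra
        m = cobra.Model("core")
        mets = {mid: cobra.Metabolite(mid) for mid in core.metabolite_ids}
        comp = core.biomass_composition
        for r in core.reactions.values():
            rx = cobra.Reaction(r.id)
            rx.lower_bound = -1000.0 if r.reversible else 0.0
            rx.upper_bound = 1000.0
            m.add_reactions([rx])
            rx.add_metabolites({mets[k]: float(v)
                                for k, v in r.stoichiometry.items()})
        m.reactions.EX_meoh.upper_bound = 15.0
        m.reactions.ngam.bounds = (comp.ngam, comp.ngam)
        m.reactions.dm_nadh.bounds = (0, 0)
        m.reactions.dm_nadph.bounds = (0, 0)
        m.objective = "EX_biomass"
        ours = fba(core, "EX_biomass", default_bounds(core, 15.0, True))
        assert m.optimize().objective_value == pytest.approx(
            ours.objective, rel=1e-6)

    def test_infeasible_reported_as_status(self, core):
        b = default_bounds(core, 0.0, ngam=True)   # NGAM with no substrate
        res = fba(core, "EX_biomass", b)
        assert res.status == "infeasible"

    def test_unknown_objective_raises(self, core):
        with pytest.raises(KeyError):
            fba(core, "no_such_reaction")


class TestCofactorYields:
    @pytest.mark.parametrize("cofactor,route,expected", [
        ("ATP", "cytoplasmic_FDH", 5.0),
        ("ATP", "periplasmic_FDH", 3.0),
        ("NADH", "cytoplasmic_FDH", 2.0),
        ("NADH", "periplasmic_FDH", 0.0),
    ])
    def test_route_yields(self, core, cofactor, route, expected):
        """Complete methanol oxidation: 5 ATP via the cytoplasmic NAD-FDH
        route (1 cyt c + 2 NADH at effective P/O 1 and 2), 3 ATP via the
        purely periplasmic route (3 cyt c, no NADH)."""
        y = max_cofactor_yield(core, "meoh", cofactor, route)
        assert y == pytest.approx(expected, abs=1e-6)

    def test_unknown_route_rejected(self, core):
        with pytest.raises(KeyError):
            max_cofactor_yield(core, "meoh", "ATP", "sideways")

    def test_indirect_routes_are_energetically_inferior(self, core):
        y = max_cofactor_yield(core, "meoh", "ATP", "TCA_of_acetylCoA")
        assert y < max_cofactor_yield(core, "meoh", "ATP", "cytoplasmic_FDH")


class TestPrecursorYields:
    def test_carbon_yields_can_exceed_one(self, core):
        """Net CO2 fixation makes C4 carbon yields exceed 1."""
        molar, carbon = max_precursor_yield(core, "meoh", "oaa")
        assert carbon > 1.0
        assert carbon == pytest.approx(4 * molar)

    def test_methf_is_stoichiometric(self, core):
        molar, carbon = max_precursor_yield(core, "meoh", "methf")
        assert molar == pytest.approx(1.0, abs=1e-9)
        assert carbon == pytest.approx(1.0, abs=1e-9)

    def test_unknown_precursor_rejected(self, core):
        with pytest.raises(KeyError):
            max_precursor_yield(core, "meoh", "ethanol")


class TestFva:
    def test_fully_determined_toy_has_zero_width(self, core):
        b = default_bounds(core, 15.0, True)
        b.fix("EX_meoh", 15.0)
        b.fix("EX_biomass", 0.1)
        b.fix("fhs", 2.4)
        iv = fva(core, b, reactions=["mxa", "fdh_c"])
        assert iv["mxa"][1] - iv["mxa"][0] == pytest.approx(0.0, abs=1e-6)

    def test_relaxing_a_constraint_never_shrinks_intervals(self, core):
        tight = default_bounds(core, 15.0, True)
        tight.fix("mtdh_nadph", 5.0)
        loose = default_bounds(core, 15.0, True)
        loose.set("mtdh_nadph", 0.0, 10.0)
        rxns = ["fdh_c", "ppc", "mae", "EX_biomass"]
        iv_t = fva(core, tight, reactions=rxns)
        iv_l = fva(core, loose, reactions=rxns)
        for r in rxns:
            assert iv_l[r][0] <= iv_t[r][0] + 1e-7
            assert iv_l[r][1] >= iv_t[r][1] - 1e-7

    def test_atp_excess_under_reference_constraints(self, core, reference):
        """Constrained with the measured fluxes and maximal-efficiency
        dissimilation, total ATP production far exceeds the maintenance +
        growth requirement (~29.3): the network is energetically
        overdetermined."""
        b = default_bounds(core, 15.1, True)
        b.fix("fdh_c", reference.net["fdh"])     # cytoplasmic NAD route
        b.block(["fald_p", "fdh_p"])
        b.fix("fhs", reference.net["fhs_l"])
        res = fba(core, "EX_biomass", b)
        assert res.status == "optimal"
        atp_prod = (2 * res.fluxes["resp_nadh"] + res.fluxes["resp_cytc"]
                    + res.fluxes["resp_fadh2"] + res.fluxes["pyk"]
                    + res.fluxes["scs"])
        assert atp_prod > 29.3


class TestNadphScan:
    def test_growth_peaks_inside_the_grid(self, core):
        grid, growth, argmax = nadph_scan(core, np.arange(0, 15.1, 1.0))
        assert growth[np.where(grid == argmax)][0] >= growth[0]
        assert growth[np.where(grid == argmax)][0] >= growth[-1]

    def test_emcp_network_prefers_higher_nadph_than_icl_variant(self, core, icl):
        grid = np.arange(0.0, 15.01, 0.5)
        _, g_emcp, a_emcp = nadph_scan(core, grid)
        _, g_icl, a_icl = nadph_scan(icl, grid)
        assert a_emcp > a_icl
        hi = grid >= max(a_emcp, a_icl)
        assert (g_emcp[hi] >= g_icl[hi] - 1e-9).all()
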