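"""13C-MFA: EMU simulation against a full-isotopomer oracle, measurement
emulation, synthetic datasets and flux fitting."""

import numpy as np
import pytest

from methyloflux.mfa13c import (AtomTransitionModel, FluxDistribution,
                                MeasurementModel, NoiseModel,
                                SingularLabelingSystem,
                                generate_synthetic_dataset, fit_fluxes,
                                measurement_model, simulate_labeling)
from methyloflux.mfa13c.fit import FluxParametrization, flux_summaries
from methyloflux.synthetic import reference_constraints

from oracles import iso_to_mid, isotopomer_oracle


def toy_atoms(**kw):
    defaults = dict(
        reactions={
            "v1": "meoh:a -> fald:a",
            "v2": "fald:a + co2:b -> ox:ab",
            "v3": "ox:ab -> glx:ab",
            "v4": "glx:ab -> fald:a + co2:b",
        },
        drains={"d1": "glx"},
        reversible=(), symmetric=(),
        methanol_purity=0.99, co2_labeled_fraction=0.2)
    defaults.update(kw)
    return AtomTransitionModel(**defaults)


class TestEmuSimulation:
    def test_unlabeled_substrate_gives_all_m0(self):
        atoms = toy_atoms(methanol_purity=0.0, co2_labeled_fraction=0.0)
        fl = FluxDistribution(net={"v1": 1.0, "v2": 1.0, "v3": 1.0,
                                   "v4": 0.0, "d1": 1.0})
        mids = simulate_labeling(atoms, fl, [("glx", (0, 1))])
        assert mids[("glx", (0, 1))] == pytest.approx([1.0, 0.0, 0.0])

    def test_two_pool_passthrough(self):
        atoms = AtomTransitionModel(
            reactions={"v1": "meoh:a -> fald:a", "v2": "fald:a -> for:a"},
            drains={"d": "for"}, reversible=(), symmetric=(),
            methanol_purity=0.75)
        fl = FluxDistribution(net={"v1": 2.0, "v2": 2.0, "d": 2.0})
        mids = simulate_labeling(atoms, fl, [("for", (0,)), ("fald", (0,))])
        assert mids[("for", (0,))] == pytest.approx([0.25, 0.75])
        assert mids[("for", (0,))] == pytest.approx(mids[("fald", (0,))])

    def test_converging_junction_matches_isotopomer_oracle(self):
        """A condensation + cleavage cycle: EMU MIDs equal a full 2^n
        isotopomer-space fixed-point oracle."""
        atoms = toy_atoms()
        fl = FluxDistribution(net={"v1": 1.0, "v2": 1.5, "v3": 1.5,
                                   "v4": 0.5, "d1": 1.0})
        mids = simulate_labeling(atoms, fl, [("glx", (0, 1)), ("ox", (0,))])
        state = isotopomer_oracle(
            pools={"fald": 1, "ox": 2, "glx": 2},
            inputs={"meoh": np.array([0.01, 0.99]),
                    "co2": np.array([0.8, 0.2])},
            reactions=[
                (1.0, [("meoh", "a")], [("fald", "a")]),
                (1.5, [("fald", "a"), ("co2", "b")], [("ox", "ab")]),
                (1.5, [("ox", "ab")], [("glx", "ab")]),
                (0.5, [("glx", "ab")], [("fald", "a"), ("co2", "b")]),
            ],
            drains={"glx": 1.0})
        assert mids[("glx", (0, 1))] == pytest.approx(
            iso_to_mid(state["glx"], (0, 1)), abs=1e-9)
        assert mids[("ox", (0,))] == pytest.approx(
            iso_to_mid(state["ox"], (0,)), abs=1e-9)

    def test_symmetric_metabolite_scrambles_orientations(self):
        """Succinate-style symmetry: an asymmetric precursor pattern is
        averaged over both orientations."""
        atoms = AtomTransitionModel(
            reactions={"v1": "meoh:a -> fald:a",
                       "v2": "fald:a + co2:b -> succ:ab",
                       "v3": "succ:ab -> glx:ab"},
            drains={"d": "glx"}, reversible=(), symmetric=("succ",),
            methanol_purity=1.0, co2_labeled_fraction=0.0)
        fl = FluxDistribution(net={"v1": 1.0, "v2": 1.0, "v3": 1.0, "d": 1.0})
        mids = simulate_labeling(atoms, fl, [("glx", (0,)), ("glx", (1,))])
        # without scrambling C1 would be fully labeled and C2 unlabeled
        assert mids[("glx", (0,))] == pytest.approx([0.5, 0.5])
        assert mids[("glx", (1,))] == pytest.approx([0.5, 0.5])

    def test_disconnected_pool_reported(self):
        atoms = toy_atoms()
        fl = FluxDistribution(net={"v1": 1.0, "v2": 0.0, "v3": 0.0,
                                   "v4": 0.0, "d1": 0.0})
        with pytest.raises(SingularLabelingSystem):
            simulate_labeling(atoms, fl, [("fald", (0,))])

    def test_reference_mids_normalized(self, atoms, reference):
        mm = MeasurementModel(atoms)
        df = mm.simulate(reference)
        ms = df[df["type"] == "MS"]
        sums = ms.groupby(["aa", "detail"])["value"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert (df["value"] >= -1e-12).all()


class TestMeasurementLayout:
    def test_layout_carries_193_data(self, atoms, reference):
        ds = measurement_model(atoms, reference)
        assert len(ds) == 193
        assert ds.n_nmr == 137
        assert ds.n_ms == 56

    def test_serine_fragments_pass_through_serine_pool(self, atoms, reference):
        """The serine MS fragment MID equals the serine-pool EMU MID."""
        ds = measurement_model(atoms, reference)
        mid = ds.mid("ser", (1, 3))
        emu = simulate_labeling(atoms, reference, [("ser", (0, 1, 2))])
        assert mid == pytest.approx(emu[("ser", (0, 1, 2))], abs=1e-12)

    def test_fully_labeled_pool_concentrates_at_mn(self, atoms):
        toy = AtomTransitionModel(
            reactions={"v1": "meoh:a -> ser1:a"},
            drains={"d": "ser1"}, reversible=(), symmetric=(),
            methanol_purity=1.0)
        fl = FluxDistribution(net={"v1": 1.0, "d": 1.0})
        mids = simulate_labeling(toy, fl, [("ser1", (0,))])
        assert mids[("ser1", (0,))] == pytest.approx([0.0, 1.0])

    def test_pyruvate_family_reflects_mixed_origin(self, atoms, reference):
        """Alanine (pyruvate) carbons mix three converging routes
        (pyruvate kinase, ED pathway, malic enzyme): its C1 enrichment
        sits strictly between the CO2 and methanol labels."""
        ds = measurement_model(atoms, reference)
        row = ds.data[ds.data["id"] == "NMR:ala:C1:0"]["value"].iloc[0]
        assert atoms.co2_labeled_fraction < row < atoms.methanol_purity


class TestSyntheticDatasets:
    def test_vanishing_noise_recovers_the_simulation(self, atoms, reference):
        clean = measurement_model(atoms, reference)
        tiny = generate_synthetic_dataset(
            atoms, reference, NoiseModel(ms_sd=1e-12, nmr_sd=1e-12, seed=5))
        assert np.allclose(clean.data["value"], tiny.data["value"],
                           atol=1e-9)

    def test_same_seed_reproduces_identically(self, atoms, reference):
        a = generate_synthetic_dataset(atoms, reference, NoiseModel(seed=11))
        b = generate_synthetic_dataset(atoms, reference, NoiseModel(seed=11))
        assert (a.data["value"] == b.data["value"]).all()

    def test_default_layout_has_193_data(self, atoms, reference):
        ds = generate_synthetic_dataset(atoms, reference, NoiseModel(seed=0))
        assert len(ds) == 193 and ds.n_nmr == 137 and ds.n_ms == 56


class TestFitting:
    def test_noiseless_fit_recovers_direct_oxidation(self, atoms, reference,
                                                     ref_constraints):
        """Self-consistency: fitting noise-free synthetic data recovers
        the generating direct-oxidation flux to 1e-3 relative."""
        ds = measurement_model(atoms, reference)
        res = fit_fluxes(ds, atoms, ref_constraints, n_starts=3, seed=0)
        assert res.fluxes.net["fdh"] == pytest.approx(
            reference.net["fdh"], rel=1e-3)
        assert res.fluxes.net["fhs_l"] == pytest.approx(
            reference.net["fhs_l"], rel=5e-3)

    def test_chi2_at_truth_is_of_order_n(self, atoms, reference,
                                         ref_constraints):
        """Evaluating the weighted residuals at the generating fluxes on
        a noisy dataset gives chi2 ~ number of data (the noise model and
        the weights agree)."""
        mm = MeasurementModel(atoms)
        ids = mm.ids()
        chis = []
        for seed in range(5):
            ds = generate_synthetic_dataset(atoms, reference,
                                            NoiseModel(seed=seed))
            obs = ds.data.set_index("id").loc[ids]
            sim = mm.values(reference)
            chis.append(float(np.sum(((sim - obs["value"].to_numpy())
                                      / obs["sd"].to_numpy()) ** 2)))
        mean = np.mean(chis)
        # renormalization of noisy MIDs removes a little variance
        assert 100 < mean < 260

    def test_label_invisible_exchange_leaves_chi2_unchanged(
            self, atoms, reference, ref_constraints):
        """The triose-phosphate isomerase exchange shuttles a pure
        pass-through pool (DHAP has no other source); changing it cannot
        move any measurement — non-identifiability by construction."""
        mm = MeasurementModel(atoms)
        base = mm.values(reference)
        bumped = FluxDistribution(net=dict(reference.net),
                                  exchange=dict(reference.exchange))
        bumped.exchange["tpi"] = reference.exchange["tpi"] + 7.5
        assert np.allclose(base, mm.values(bumped), atol=1e-12)

    def test_parametrization_rejects_inconsistent_constraints(self, atoms):
        cons = {"mxa": 15.1, "fdh": 100.0, "fhs_l": 100.0}  # > uptake
        with pytest.raises(ValueError):
            FluxParametrization(atoms, cons)

    def test_summaries_of_the_reference_state(self, reference):
        s = flux_summaries(reference, mu=0.168, nadph_per_gdw=10.71)
        assert s["pct_direct_oxidation"] == pytest.approx(84.1, abs=0.2)
        assert s["net_co2_fixation"] == pytest.approx(2.4, abs=0.05)
        assert s["biomass_carbon_from_co2"] == pytest.approx(0.50, abs=0.02)
        assert s["nadph_demand"]["total"] == pytest.approx(5.6, abs=0.15)
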