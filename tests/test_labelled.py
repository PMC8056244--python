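"""Isotopomer expansion: naming, atom transitions, totals and fractions."""

import numpy as np
import pytest

from kinmod import LabelMapping, Model, Simulator, expand_label_model, label_variants
from kinmod.errors import LabelMappingError, UnknownSymbolError
from kinmod.labelled import (
    apply_transition,
    expand_initial_state,
    label_fraction,
    total_concentration,
)
from kinmod.ratelaws import Constant, MassAction, MichaelisMenten


class TestLabelVariants:
    def test_two_atoms_enumerate_lexicographically(self):
        assert label_variants("A", 2) == ["A__00", "A__01", "A__10", "A__11"]

    def test_single_atom(self):
        assert label_variants("A", 1) == ["A__0", "A__1"]

    def test_zero_atoms_rejected(self):
        with pytest.raises(ValueError):
            label_variants("A", 0)

    def test_count_is_two_to_the_n(self):
        for n in (1, 2, 3, 4):
            assert len(label_variants("A", n)) == 2**n


class TestApplyTransition:
    def test_permutation(self):
        out = apply_transition("10", {0: ("B", 1), 1: ("B", 0)}, {"B": 2})
        assert out == {"B": "01"}

    def test_identity(self):
        out = apply_transition("10", {0: ("B", 0), 1: ("B", 1)}, {"B": 2})
        assert out == {"B": "10"}

    def test_unsourced_positions_default_unlabelled(self):
        out = apply_transition("1", {0: ("B", 0)}, {"B": 2})
        assert out == {"B": "10"}

    def test_out_of_range_index_rejected(self):
        with pytest.raises(LabelMappingError):
            apply_transition("1", {3: ("B", 0)}, {"B": 1})

    def test_split_to_two_products(self):
        out = apply_transition("11", {0: ("B", 0), 1: ("C", 0)}, {"B": 1, "C": 1})
        assert out == {"B": "1", "C": "1"}


def _one_atom_chain():
    """influx -> A -> B -> efflux, mass action conversion."""
    m = Model(parameters={"v0": 1.0, "k": 2.0, "k_out": 1.0},
              compounds=["A", "B"])
    m.add_reaction("influx", Constant("v0"), {"A": 1})
    m.add_reaction("conv", MassAction("k", ("A",)), {"A": -1, "B": 1})
    m.add_reaction("efflux", MassAction("k_out", ("B",)), {"B": -1})
    mapping = LabelMapping(
        labelled_compounds={"A": 1, "B": 1},
        transitions={"conv": [("A", {0: ("B", 0)})], "efflux": [("B", {})]},
        influx_patterns={"influx": ("A", "1")},
    )
    return m, mapping


class TestExpansion:
    def test_one_atom_identity_gives_two_variants(self):
        m, mapping = _one_atom_chain()
        ex = expand_label_model(m, mapping)
        conv = [r for r in ex.reactions if r.startswith("conv")]
        assert sorted(conv) == ["conv__0", "conv__1"]
        assert ex.reactions["conv__1"].stoichiometry == {"A__1": -1, "B__1": 1}

    def test_two_atom_substrate_gives_four_variants(self):
        m = Model(parameters={"k": 1.0}, compounds=["A", "B"])
        m.add_reaction("v", MassAction("k", ("A",)), {"A": -1, "B": 1})
        mapping = LabelMapping(
            labelled_compounds={"A": 2, "B": 2},
            transitions={"v": [("A", {0: ("B", 0), 1: ("B", 1)})]},
        )
        ex = expand_label_model(m, mapping)
        assert len(ex.reactions) == 4
        assert len(ex.compounds) == 8

    def test_mass_action_variant_rate_scaling(self):
        """Variant rate = base rate at totals x isotopomer fraction."""
        m = Model(parameters={"k": 3.0}, compounds=["A"])
        m.add_reaction("v", MassAction("k", ("A",)), {"A": -1})
        mapping = LabelMapping(
            labelled_compounds={"A": 1}, transitions={"v": [("A", {})]}
        )
        ex = expand_label_model(m, mapping)
        state = {"A__0": 0.75, "A__1": 0.25}
        fluxes = ex.get_fluxes(state)
        assert fluxes["v__1"] == pytest.approx(3.0 * 1.0 * 0.25)
        assert fluxes["v__0"] == pytest.approx(3.0 * 1.0 * 0.75)

    def test_variant_rates_sum_to_base_rate_for_any_kinetics(self):
        m = Model(parameters={"vmax": 2.0, "km": 0.5}, compounds=["A", "B"])
        m.add_reaction("v", MichaelisMenten("vmax", "km", "A"),
                       {"A": -1, "B": 1})
        mapping = LabelMapping(
            labelled_compounds={"A": 2, "B": 2},
            transitions={"v": [("A", {0: ("B", 0), 1: ("B", 1)})]},
        )
        ex = expand_label_model(m, mapping)
        rng = np.random.default_rng(3)
        for _ in range(10):
            parts = rng.uniform(0, 2, 4)
            state = dict(zip(label_variants("A", 2), parts))
            state.update(dict.fromkeys(label_variants("B", 2), 0.1))
            total = parts.sum()
            base = m.get_fluxes({"A": total, "B": 0.4})["v"]
            assert sum(ex.get_fluxes(state).values()) == pytest.approx(base)

    def test_zero_total_gives_zero_variant_rate(self):
        m, mapping = _one_atom_chain()
        ex = expand_label_model(m, mapping)
        state = dict.fromkeys(ex.compounds, 0.0)
        fluxes = ex.get_fluxes(state)
        assert fluxes["conv__0"] == 0.0 and fluxes["conv__1"] == 0.0

    def test_reversible_mapped_reaction_rejected(self):
        m = Model(parameters={"kf": 1.0, "kr": 1.0}, compounds=["A", "B"])
        from kinmod.ratelaws import ReversibleMassAction

        m.add_reaction("v", ReversibleMassAction("kf", "kr", ("A",), ("B",)),
                       {"A": -1, "B": 1})
        mapping = LabelMapping(
            labelled_compounds={"A": 1, "B": 1},
            transitions={"v": [("A", {0: ("B", 0)})]},
        )
        with pytest.raises(LabelMappingError, match="split"):
            expand_label_model(m, mapping)

    def test_unmapped_reaction_touching_labelled_compound_rejected(self):
        m, mapping = _one_atom_chain()
        mapping.transitions.pop("efflux")
        with pytest.raises(LabelMappingError, match="efflux"):
            expand_label_model(m, mapping)

    def test_compound_on_both_sides_rejected(self):
        m = Model(parameters={"k": 1.0}, compounds=["A", "B"])
        m.add_reaction("v", MassAction("k", ("A",)), {"A": -1, "B": 1})
        mapping = LabelMapping(
            labelled_compounds={"A": 1},
            transitions={"v": [("A", {0: ("A", 0)})]},
        )
        with pytest.raises(LabelMappingError, match="both sides"):
            expand_label_model(m, mapping)


class TestReadback:
    def test_total_and_fraction_by_hand(self):
        mapping = LabelMapping(labelled_compounds={"A": 2})
        state = {"A__00": 1.0, "A__01": 1.0, "A__10": 0.0, "A__11": 2.0}
        assert total_concentration(state, "A", mapping) == 4.0
        assert label_fraction(state, "A", 0, mapping) == pytest.approx(0.5)
        assert label_fraction(state, "A", 1, mapping) == pytest.approx(0.75)

    def test_empty_pool_uses_zero_convention(self):
        mapping = LabelMapping(labelled_compounds={"A": 1})
        state = {"A__0": 0.0, "A__1": 0.0}
        assert total_concentration(state, "A", mapping) == 0.0
        assert label_fraction(state, "A", 0, mapping) == 0.0

    def test_fully_labelled_pool(self):
        mapping = LabelMapping(labelled_compounds={"A": 2})
        state = {"A__00": 0.0, "A__01": 0.0, "A__10": 0.0, "A__11": 3.0}
        for atom in (0, 1):
            assert label_fraction(state, "A", atom, mapping) == 1.0

    def test_unlabelled_compound_rejected(self):
        mapping = LabelMapping(labelled_compounds={"A": 1})
        with pytest.raises(UnknownSymbolError):
            total_concentration({}, "Z", mapping)


class TestDynamics:
    def test_totals_track_base_model(self):
        m, mapping = _one_atom_chain()
        ex = expand_label_model(m, mapping)
        base_y0 = {"A": 1.0, "B": 0.5}
        tc_base = Simulator(m, base_y0).simulate(5.0, n_points=40)
        tc_ex = Simulator(ex, expand_initial_state(base_y0, mapping)).simulate(
            5.0, n_points=40
        )
        for i in range(len(tc_base.times)):
            state = dict(zip(ex.compounds, tc_ex.states[i]))
            for j, compound in enumerate(("A", "B")):
                assert total_concentration(state, compound, mapping) == \
                    pytest.approx(tc_base.states[i][j], abs=1e-6)

    def test_no_label_influx_keeps_fractions_zero(self):
        m, mapping = _one_atom_chain()
        mapping.influx_patterns["influx"] = ("A", "0")   # unlabelled medium
        ex = expand_label_model(m, mapping)
        tc = Simulator(ex, expand_initial_state({"A": 1.0, "B": 1.0}, mapping)
                       ).simulate(10.0, n_points=20)
        final = tc.final_state()
        assert label_fraction(final, "A", 0, mapping) == pytest.approx(0.0, abs=1e-12)
        assert label_fraction(final, "B", 0, mapping) == pytest.approx(0.0, abs=1e-12)

    def test_fully_labelled_influx_saturates_all_fractions(self):
        m, mapping = _one_atom_chain()
        ex = expand_label_model(m, mapping)
        sim = Simulator(ex, expand_initial_state({"A": 1.0, "B": 1.0}, mapping))
        previous = {"A": 0.0, "B": 0.0}
        for t_end in (2.0, 5.0, 10.0, 25.0):
            state = sim.simulate(t_end).final_state()
            for compound in ("A", "B"):
                frac = label_fraction(state, compound, 0, mapping)
                assert frac >= previous[compound] - 1e-9
                assert 0.0 <= frac <= 1.0 + 1e-12
                previous[compound] = frac
        assert previous["A"] == pytest.approx(1.0, abs=1e-4)
        assert previous["B"] == pytest.approx(1.0, abs=1e-3)
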