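"""Model construction, bookkeeping and right-hand-side assembly."""

import logging

import numpy as np
import pytest

from kinmod import Model
from kinmod.errors import (
    CycleError,
    EmptyModelError,
    NameCollisionError,
    ReservedNameError,
    UnknownSymbolError,
)
from kinmod.ratelaws import MassAction


class TestParameters:
    def test_add_and_read_back(self):
        m = Model().add_parameter("k", 3)
        assert m.parameters == {"k": 3.0}

    def test_duplicate_name_rejected(self):
        m = Model().add_parameter("k", 3)
        with pytest.raises(NameCollisionError):
            m.add_parameter("k", 4)

    def test_zero_value_propagates_to_rates(self):
        m = Model(parameters={"k": 0.0}, compounds=["A"])
        m.add_reaction("v", MassAction("k", ("A",)), {"A": -1})
        assert m.get_fluxes({"A": 2.0}) == {"v": 0.0}

    def test_update_requires_existing_name(self):
        with pytest.raises(UnknownSymbolError):
            Model().update_parameter("k", 1)


class TestDerivedParameters:
    def test_arithmetic(self):
        m = Model(parameters={"kf": 2.0, "keq": 4.0})
        m.add_derived_parameter("kr", lambda kf, keq: kf / keq, ("kf", "keq"))
        assert m._resolved_parameters()["kr"] == pytest.approx(0.5)

    def test_recomputed_after_parameter_update(self):
        m = Model(parameters={"kf": 2.0, "keq": 4.0})
        m.add_derived_parameter("kr", lambda kf, keq: kf / keq, ("kf", "keq"))
        m.update_parameter("kf", 4.0)
        assert m._resolved_parameters()["kr"] == pytest.approx(1.0)

    def test_self_dependency_is_a_cycle(self):
        m = Model(parameters={"b": 1.0})
        with pytest.raises(CycleError):
            m.add_derived_parameter("a", lambda a: a, ("a",))

    def test_mutual_dependency_rejected_with_cycle_named(self):
        m = Model(parameters={"p": 1.0})
        m.add_derived_parameter("a", lambda p: p, ("p",))
        m.add_derived_parameter("b", lambda a: a, ("a",))
        with pytest.raises(CycleError, match="a.*b|b.*a"):
            m.update_derived_parameter("a", lambda b: b, ("b",))

    def test_unknown_argument_rejected(self):
        with pytest.raises(UnknownSymbolError):
            Model().add_derived_parameter("a", lambda x: x, ("nope",))

    def test_chained_derivations_resolve_in_order(self):
        m = Model(parameters={"p": 3.0})
        m.add_derived_parameter("q", lambda p: p * 2, ("p",))
        m.add_derived_parameter("r", lambda q: q + 1, ("q",))
        assert m._resolved_parameters()["r"] == pytest.approx(7.0)


class TestCompounds:
    def test_declaration_order_preserved(self):
        m = Model().add_compounds(["A", "B"])
        assert m.compounds == ["A", "B"]

    def test_time_is_reserved(self):
        with pytest.raises(ReservedNameError):
            Model().add_compound("time")

    def test_duplicate_rejected(self):
        m = Model().add_compound("A")
        with pytest.raises(NameCollisionError):
            m.add_compound("A")


class TestReactions:
    def test_registration(self):
        m = Model(parameters={"k": 3.0}, compounds=["A"])
        m.add_reaction("v", MassAction("k", ("A",)), {"A": -1})
        assert m.get_stoichiometric_matrix().shape == (1, 1)

    def test_undeclared_stoichiometry_compound_rejected(self):
        m = Model(parameters={"k": 3.0}, compounds=["A"])
        with pytest.raises(UnknownSymbolError, match="Z"):
            m.add_reaction("v", MassAction("k", ("A",)), {"Z": -1})

    def test_unresolvable_argument_named_in_error(self):
        m = Model(compounds=["A"])
        with pytest.raises(UnknownSymbolError, match="mystery"):
            m.add_reaction("v", lambda x: x, {"A": -1}, args=("mystery",))

    def test_time_dependent_rate_via_modifier(self):
        m = Model(compounds=["A"])
        m.add_reaction(
            "v", lambda t: 2.0 * t, {"A": 1}, args=("time",), modifiers=("time",)
        )
        assert m.get_fluxes({"A": 0.0}, t=3.0) == {"v": 6.0}

    def test_compound_argument_needs_stoichiometry_or_modifier(self):
        m = Model(parameters={"k": 1.0}, compounds=["A", "B"])
        with pytest.raises(UnknownSymbolError, match="B"):
            m.add_reaction("v", MassAction("k", ("B",)), {"A": -1})

    def test_modifier_overlapping_stoichiometry_rejected(self):
        m = Model(parameters={"k": 1.0}, compounds=["A"])
        with pytest.raises(ValueError, match="modifier"):
            m.add_reaction(
                "v", MassAction("k", ("A",)), {"A": -1}, modifiers=("A",)
            )


class TestStoichiometricMatrix:
    def test_linear_chain(self, chain_model):
        np.testing.assert_array_equal(
            chain_model.get_stoichiometric_matrix(), [[-1, 0], [1, -1]]
        )

    def test_two_to_one_stoichiometry(self):
        m = Model(parameters={"k": 1.0}, compounds=["A", "B"])
        m.add_reaction("v", MassAction("k", ("A",)), {"A": -2, "B": 1})
        np.testing.assert_array_equal(
            m.get_stoichiometric_matrix(), [[-2], [1]]
        )

    def test_unused_compound_gives_zero_row(self):
        m = Model(parameters={"k": 1.0}, compounds=["A", "B"])
        m.add_reaction("v", MassAction("k", ("A",)), {"A": -1})
        np.testing.assert_array_equal(m.get_stoichiometric_matrix()[1], [0])

    def test_empty_model_rejected(self):
        with pytest.raises(EmptyModelError):
            Model().get_stoichiometric_matrix()

    def test_labelled_table_matches_matrix(self, chain_model):
        df = chain_model.get_stoichiometric_df()
        assert list(df.index) == ["A", "B"]
        assert list(df.columns) == ["v1", "v2"]
        np.testing.assert_array_equal(
            df.to_numpy(), chain_model.get_stoichiometric_matrix()
        )


class TestFluxesAndRhs:
    def test_flux_arithmetic(self):
        m = Model(parameters={"k": 3.0}, compounds=["A"])
        m.add_reaction("v", MassAction("k", ("A",)), {"A": -1})
        assert m.get_fluxes({"A": 2.0}) == {"v": 6.0}
        assert m.get_fluxes({"A": 0.0}) == {"v": 0.0}

    def test_rhs_by_hand(self):
        m = Model(parameters={"k": 3.0}, compounds=["A"])
        m.add_reaction("v", MassAction("k", ("A",)), {"A": -1})
        assert m.get_right_hand_side({"A": 2.0}) == {"A": -6.0}

    def test_chain_rhs_by_hand(self, chain_model):
        rhs = chain_model.get_right_hand_side({"A": 1.0, "B": 1.0})
        assert rhs == pytest.approx({"A": -1.0, "B": -1.0})

    def test_rhs_equals_matrix_vector_product(self, chain_model):
        rng = np.random.default_rng(42)
        N = chain_model.get_stoichiometric_matrix()
        for _ in range(100):
            state = dict(zip(chain_model.compounds, rng.uniform(0, 10, 2)))
            v = np.array(list(chain_model.get_fluxes(state).values()))
            rhs = np.array(list(chain_model.get_right_hand_side(state).values()))
            np.testing.assert_allclose(rhs, N @ v, atol=1e-12)

    def test_missing_state_compound_rejected(self, chain_model):
        with pytest.raises(UnknownSymbolError):
            chain_model.get_fluxes({"A": 1.0})

    def test_negative_concentration_warns_but_evaluates(self, chain_model, caplog):
        with caplog.at_level(logging.WARNING, logger="kinmod.core"):
            rhs = chain_model.get_right_hand_side({"A": -1.0, "B": 0.0})
        assert rhs["A"] == 1.0
        assert any("negative" in rec.message for rec in caplog.records)


class TestLiveView:
    def test_parameter_update_reflected_in_next_call(self, decay_model):
        assert decay_model.get_fluxes({"x": 1.0}) == {"decay": 1.0}
        decay_model.update_parameter("k", 5.0)
        assert decay_model.get_fluxes({"x": 1.0}) == {"decay": 5.0}

    def test_reaction_removal_reflected(self, chain_model):
        chain_model.remove_reaction("v2")
        assert list(chain_model.get_fluxes({"A": 1.0, "B": 1.0})) == ["v1"]

    def test_metadata_never_changes_numerics(self, chain_model):
        state = {"A": 0.7, "B": 0.3}
        before = chain_model.get_right_hand_side(state)
        chain_model.annotate("A", common_name="substrate",
                             identifiers=["https://identifiers.org/CHEBI:1"],
                             unit="mM")
        annotated = chain_model.get_right_hand_side(state)
        chain_model.strip_metadata()
        stripped = chain_model.get_right_hand_side(state)
        assert before == annotated == stripped
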