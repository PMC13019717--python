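"""Omics processing: bound rules, chemostat fluxes, drain balancing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kincontrol.data import (
    ChemostatObservation,
    Measurement,
    balance_with_drains,
    chemostat_exchange_flux,
    metabolite_bounds,
    proton_concentration,
)
from kincontrol.model import Compartment, MetabolicModel, Metabolite, Reaction


def compartmental_model():
    return MetabolicModel(
        [
            Compartment("c", pH=7.2, volume_fraction=0.85),
            Compartment("m", pH=7.5, volume_fraction=0.01),
        ],
        [
            Metabolite("glc_c", "c"),
            Metabolite("cit_m", "m"),
            Metabolite("pi_c", "c"),
            Metabolite("pi_m", "m"),
            Metabolite("nad_c", "c"),
            Metabolite("h_c", "c", is_fixed=True),
        ],
        [Reaction("R1", {"glc_c": -1.0, "pi_c": +1.0})],
    )


class TestBoundRules:
    def test_cytosolic_fifty_one_fifty(self):
        model = compartmental_model()
        b = metabolite_bounds([Measurement("glc_c", 2e-3)], model)
        assert b.lower["glc_c"] == pytest.approx(1e-3)
        assert b.upper["glc_c"] == pytest.approx(3e-3)
        assert b.reference["glc_c"] == pytest.approx(2e-3)

    def test_mitochondrial_hundredfold_upper(self):
        model = compartmental_model()
        b = metabolite_bounds([Measurement("cit_m", 2e-3)], model)
        assert b.upper["cit_m"] == pytest.approx(0.3)  # 100 x 1.5 x 2 mM
        assert b.lower["cit_m"] == pytest.approx(1e-15)

    def test_dual_compartment_species_gets_floor_lower(self):
        model = compartmental_model()
        b = metabolite_bounds(
            [Measurement("pi_c", 1e-3), Measurement("pi_m", 1e-3)], model
        )
        assert b.lower["pi_c"] == pytest.approx(1e-15)
        assert b.lower["pi_m"] == pytest.approx(1e-15)
        assert b.upper["pi_c"] == pytest.approx(1.5e-3)
        assert b.upper["pi_m"] == pytest.approx(0.15)

    def test_unmeasured_default_box(self):
        model = compartmental_model()
        b = metabolite_bounds([], model)
        assert b.lower["nad_c"] == pytest.approx(1e-15)
        assert b.upper["nad_c"] == pytest.approx(10.0)
        assert b.reference["nad_c"] == pytest.approx(np.sqrt(1e-14))

    def test_proton_pinned_by_pH(self):
        model = compartmental_model()
        b = metabolite_bounds([], model)
        assert b.lower["h_c"] == b.upper["h_c"] == pytest.approx(10 ** -7.2)

    def test_unknown_metabolite_warns_and_skips(self):
        model = compartmental_model()
        with pytest.warns(UserWarning, match="unknown"):
            b = metabolite_bounds([Measurement("ghost_c", 1e-3)], model)
        assert "ghost_c" not in b

    def test_non_positive_measurement_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            Measurement("glc_c", 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        conc=st.floats(min_value=1e-9, max_value=1.0),
        alpha=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_bounds_ordered_and_scale_with_measurements(self, conc, alpha):
        """lower <= reference <= upper always; measured bounds scale
        linearly with the measured concentrations (mitochondrial uppers
        included)."""
        model = compartmental_model()
        b1 = metabolite_bounds(
            [Measurement("glc_c", conc), Measurement("cit_m", conc)], model
        )
        b2 = metabolite_bounds(
            [Measurement("glc_c", conc * alpha), Measurement("cit_m", conc * alpha)],
            model,
        )
        for met in b1.lower:
            assert b1.lower[met] <= b1.reference[met] <= b1.upper[met]
        assert b2.upper["glc_c"] == pytest.approx(alpha * b1.upper["glc_c"])
        assert b2.lower["glc_c"] == pytest.approx(alpha * b1.lower["glc_c"])
        assert b2.upper["cit_m"] == pytest.approx(alpha * b1.upper["cit_m"])


class TestProtonConcentration:
    @pytest.mark.parametrize(
        "pH,expected",
        [(7.2, 10**-7.2), (7.5, 10**-7.5), (7.0, 1e-7)],
    )
    def test_definition(self, pH, expected):
        assert proton_concentration(Compartment("x", pH=pH)) == pytest.approx(
            expected, rel=1e-12
        )


class TestChemostatExchange:
    def test_uptake_negative(self):
        obs = ChemostatObservation("glc", influent_conc=100.0, effluent_conc=0.0,
                                   dilution_rate=0.1, biomass_density=2.0)
        assert chemostat_exchange_flux(obs) == pytest.approx(-5.0)

    def test_equal_concentrations_zero(self):
        obs = ChemostatObservation("glc", 10.0, 10.0, 0.2, 1.5)
        assert chemostat_exchange_flux(obs) == 0.0

    def test_secretion_positive(self):
        obs = ChemostatObservation("etoh", 0.0, 10.0, 0.2, 1.0)
        assert chemostat_exchange_flux(obs) == pytest.approx(2.0)

    def test_zero_biomass_rejected(self):
        with pytest.raises(ValueError, match="biomass"):
            ChemostatObservation("glc", 0.0, 1.0, 0.1, 0.0)


class TestBalanceWithDrains:
    def chain(self):
        return MetabolicModel(
            [Compartment("c")],
            [Metabolite("a_c", "c"), Metabolite("b_c", "c"), Metabolite("c_c", "c")],
            [
                Reaction("UPT", {"a_c": +1.0}, is_drain=True),
                Reaction("R1", {"a_c": -1.0, "b_c": +1.0}),
                Reaction("R2", {"b_c": -1.0, "c_c": +1.0}),
            ],
        )

    def test_missing_outlet_gets_drain(self):
        model, v = balance_with_drains(
            self.chain(), {"R1": 1.0, "R2": 1.0, "UPT": 1.0}
        )
        assert "DRAIN_c_c" in model.reactions
        assert v["DRAIN_c_c"] == pytest.approx(1.0)

    def test_already_balanced_unchanged(self):
        base = self.chain()
        model = MetabolicModel(
            base.compartments.values(),
            base.metabolites.values(),
            list(base.reactions.values())
            + [Reaction("SEC", {"c_c": -1.0}, is_drain=True)],
        )
        out, v = balance_with_drains(model, {"R1": 1.0, "R2": 1.0, "UPT": 1.0, "SEC": 1.0})
        assert out is model
        assert v["SEC"] == pytest.approx(1.0)

    def test_partial_residual_assigned_to_drain(self):
        model, v = balance_with_drains(
            self.chain(), {"R1": 1.0, "R2": 0.5, "UPT": 1.0}
        )
        assert v["DRAIN_b_c"] == pytest.approx(0.5)
        assert v["DRAIN_c_c"] == pytest.approx(0.5)

    def test_disabled_drain_addition_reports_residuals(self):
        with pytest.raises(ValueError, match="imbalanced"):
            balance_with_drains(
                self.chain(), {"R1": 1.0, "R2": 1.0, "UPT": 1.0}, add_missing=False
            )

    def test_missing_flux_rejected(self):
        with pytest.raises(ValueError, match="R2"):
            balance_with_drains(self.chain(), {"R1": 1.0, "UPT": 1.0})

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        v1=st.floats(min_value=-5, max_value=5),
        v2=st.floats(min_value=-5, max_value=5),
        upt=st.floats(min_value=-5, max_value=5),
    )
    def test_balance_closes_for_arbitrary_fluxes(self, v1, v2, upt):
        model, v = balance_with_drains(self.chain(), {"R1": v1, "R2": v2, "UPT": upt})
        S = model.stoichiometric_matrix(internal_only=True)
        vec = np.array([v[r] for r in model.reaction_ids])
        scale = max(np.max(np.abs(vec)), 1.0)
        assert np.max(np.abs(S @ vec)) <= 1e-9 * scale


def test_synthetic_datasets_balance_and_validate(branched_model, branched_datasets):
    """Every generated condition satisfies S_internal v = 0 and the bound
    ordering, with no warnings at generation time."""
    S = branched_model.stoichiometric_matrix(internal_only=True)
    for ds in branched_datasets:
        v = np.array([ds.reference_fluxes[r] for r in branched_model.reaction_ids])
        scale = np.max(np.abs(v))
        assert np.max(np.abs(S @ v)) < 1e-9 * scale
        ds.bounds.validate()


def test_condition_dataset_json_round_trip(branched_datasets, tmp_path):
    ds = branched_datasets[0]
    ds.to_json(tmp_path / "c.json")
    back = type(ds).from_json(tmp_path / "c.json")
    assert back.label == ds.label
    assert back.reference_fluxes == pytest.approx(ds.reference_fluxes)
    assert back.bounds.lower == pytest.approx(ds.bounds.lower)
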