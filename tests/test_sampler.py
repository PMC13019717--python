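"""GRASP-style kinetic sampling: priors, rate-constant solve, rate laws."""

import numpy as np
import pytest

from kincontrol.mechanisms import build_mechanism
from kincontrol.model import Compartment, MetabolicModel, Metabolite, Reaction, Regulation
from kincontrol.sampler import (
    compute_elementary_rate_constants,
    sample_allosteric_parameters,
    sample_enzyme_states,
    sample_instance,
    sample_reversibilities,
)
from kincontrol.thermo import ThermoConfig


def uni_pattern():
    rxn = Reaction("R", {"a_c": -1.0, "b_c": +1.0})
    model = MetabolicModel(
        [Compartment("c")],
        [Metabolite("a_c", "c"), Metabolite("b_c", "c")],
        [rxn],
    )
    return rxn, model, build_mechanism(rxn, model)


class TestReversibilities:
    def test_partition_sums_and_signs(self):
        _, _, pat = uni_pattern()
        rng = np.random.default_rng(0)
        s = sample_reversibilities(pat, -9.0, rng)
        assert s.dG_steps.sum() == pytest.approx(-9.0)
        assert np.all(s.dG_steps < 0)

    def test_single_step_deterministic(self):
        rxn = Reaction("D", {"a_c": +1.0})
        model = MetabolicModel(
            [Compartment("c")], [Metabolite("a_c", "c")], [rxn]
        )
        pat = build_mechanism(rxn, model)
        # zero-substrate reaction: catalytic + release = 2 steps minimum
        s = sample_reversibilities(pat, -2.0, np.random.default_rng(0))
        assert s.dG_steps.sum() == pytest.approx(-2.0)

    def test_flat_dirichlet_moments(self):
        """Mean weight of a flat Dirichlet over k steps is 1/k; checked
        against the analytic moments within 3 standard errors."""
        rxn = Reaction("R", {"a_c": -1.0, "b_c": -1.0, "p_c": +1.0, "q_c": +1.0})
        model = MetabolicModel(
            [Compartment("c")],
            [Metabolite(m, "c") for m in ("a_c", "b_c", "p_c", "q_c")],
            [rxn],
        )
        pat = build_mechanism(rxn, model)
        k = len(pat.cycle_steps)
        rng = np.random.default_rng(7)
        n = 10_000
        w = np.array([sample_reversibilities(pat, -1.0, rng).weights for _ in range(n)])
        mean, var = 1.0 / k, (k - 1) / (k**2 * (k + 1))
        se = np.sqrt(var / n)
        assert np.all(np.abs(w.mean(axis=0) - mean) < 3 * se)


class TestEnzymeStates:
    def test_simplex_membership(self):
        _, _, pat = uni_pattern()
        s = sample_enzyme_states(pat, np.random.default_rng(0))
        assert s.fractions.sum() == pytest.approx(1.0)
        assert np.all(s.fractions > 0)

    def test_flat_dirichlet_moments(self):
        _, _, pat = uni_pattern()
        k = len(pat.forms)
        rng = np.random.default_rng(3)
        n = 10_000
        f = np.array([sample_enzyme_states(pat, rng).fractions for _ in range(n)])
        se = np.sqrt(((k - 1) / (k**2 * (k + 1))) / n)
        assert np.all(np.abs(f.mean(axis=0) - 1.0 / k) < 3 * se)


class TestRateConstantSolve:
    def test_net_step_flux_equals_reference(self):
        _, _, pat = uni_pattern()
        cfg = ThermoConfig()
        rng = np.random.default_rng(1)
        rev = sample_reversibilities(pat, -6.0, rng)
        states = sample_enzyme_states(pat, rng)
        kp, km = compute_elementary_rate_constants(pat, rev, states, 1.0, cfg)
        form = {f: i for i, f in enumerate(pat.forms)}
        for i, step in enumerate(pat.steps):
            f = kp[i] * states.fractions[form[step.source]]
            b = km[i] * states.fractions[form[step.target]]
            assert f - b == pytest.approx(1.0, abs=1e-12)
            # reverse/forward ratio matches the step energy
            assert b / f == pytest.approx(float(np.exp(rev.dG_steps[i] / cfg.RT)))

    def test_haldane_product_matches_overall_energy(self):
        """Product of k+/k- around the cycle equals exp(-dG/RT); oracle =
        multiplying the sampled per-step ratios."""
        _, _, pat = uni_pattern()
        cfg = ThermoConfig()
        rng = np.random.default_rng(2)
        for dG in (-12.0, -3.0, +4.0):
            v = 1.0 if dG < 0 else -1.0
            rev = sample_reversibilities(pat, dG, rng)
            states = sample_enzyme_states(pat, rng)
            kp, km = compute_elementary_rate_constants(pat, rev, states, v, cfg)
            ratio = np.prod(kp / km)
            assert ratio == pytest.approx(float(np.exp(-dG / cfg.RT)), rel=1e-9)

    def test_negative_flux_direction(self):
        _, _, pat = uni_pattern()
        cfg = ThermoConfig()
        rng = np.random.default_rng(4)
        rev = sample_reversibilities(pat, +5.0, rng)
        states = sample_enzyme_states(pat, rng)
        kp, km = compute_elementary_rate_constants(pat, rev, states, -2.0, cfg)
        assert np.all(kp > 0) and np.all(km > 0)

    def test_near_equilibrium_guard_keeps_finite(self):
        _, _, pat = uni_pattern()
        cfg = ThermoConfig()
        rng = np.random.default_rng(5)
        rev = sample_reversibilities(pat, -1e-12, rng)
        states = sample_enzyme_states(pat, rng)
        kp, km = compute_elementary_rate_constants(pat, rev, states, 1.0, cfg)
        assert np.all(np.isfinite(kp)) and np.all(np.isfinite(km))


class TestAllostericParameters:
    def allosteric_reaction(self):
        return Reaction(
            "R", {"a_c": -1.0, "b_c": +1.0},
            regulations=(
                Regulation("R", "i_c", "allosteric_inhibitor"),
                Regulation("R", "x_c", "allosteric_activator"),
            ),
        )

    def test_parameters_for_each_effector(self):
        p = sample_allosteric_parameters(self.allosteric_reaction(), np.random.default_rng(0))
        assert set(p.half_saturation) == {"i_c", "x_c"}
        assert p.kinds["i_c"] == "allosteric_inhibitor"
        assert p.L0 > 0 and p.n_subunits == 4

    def test_non_allosteric_rejected(self):
        rxn = Reaction("R", {"a_c": -1.0, "b_c": +1.0})
        with pytest.raises(ValueError, match="not allosteric"):
            sample_allosteric_parameters(rxn, np.random.default_rng(0))

    def test_same_seed_identical(self):
        rxn = self.allosteric_reaction()
        p1 = sample_allosteric_parameters(rxn, np.random.default_rng(11))
        p2 = sample_allosteric_parameters(rxn, np.random.default_rng(11))
        assert p1 == p2


class TestInstances:
    def test_reference_state_reproduced(self, small_ensemble):
        for inst in small_ensemble.instances:
            assert inst.max_steady_state_error() <= 1e-9

    def test_enzyme_level_linearity(self, small_ensemble):
        inst = small_ensemble.instances[0]
        u = np.ones(len(inst.met_index))
        j = inst.rxn_index["HEX"]
        assert inst.evaluate_reaction(j, u, 2.0) == pytest.approx(
            2.0 * inst.evaluate_reaction(j, u, 1.0)
        )

    def test_zero_net_rate_at_equilibrium(self, small_ensemble):
        """Scaling the product concentration to the root of dG(x) = 0 drives
        the net rate to zero: the equilibrium point from the thermodynamic
        layer is also the kinetic one."""
        inst = small_ensemble.instances[0]
        cfg = inst.thermo.config
        rxn = inst.model.reactions["GLCt"]  # uni-uni: glc_e -> glci_c
        j = inst.rxn_index["GLCt"]
        i_prod = inst.met_index["glci_c"]
        # dG(u) = dG_ref + RT ln(u_prod) for a uni-uni with fixed substrate
        u_eq = float(np.exp(-inst.thermo.dG["GLCt"] / cfg.RT))
        u = np.ones(len(inst.met_index))
        u[i_prod] = u_eq
        scale = abs(inst.thermo.v["GLCt"])
        assert abs(inst.evaluate_reaction(j, u)) <= 1e-9 * scale

    def test_product_increase_never_raises_uni_uni_rate(self, small_ensemble):
        """Thermodynamic monotonicity of the transporter rate law."""
        inst = small_ensemble.instances[1]
        j = inst.rxn_index["GLCt"]
        i_prod = inst.met_index["glci_c"]
        u = np.ones(len(inst.met_index))
        rates = []
        for scale in (0.5, 1.0, 2.0, 5.0, 20.0):
            u2 = u.copy()
            u2[i_prod] = scale
            rates.append(inst.evaluate_reaction(j, u2))
        assert np.all(np.diff(rates) < 0)

    def test_same_seed_bit_identical(
        self, branched_model, branched_datasets, branched_std
    ):
        def draw():
            rng = np.random.default_rng(123)
            return sample_instance(
                branched_model, branched_datasets[0], branched_std, rng
            )

        a, b = draw(), draw()
        assert a.thermo.ln_x == b.thermo.ln_x
        assert a.thermo.dG == b.thermo.dG
        for r in a.kinetics:
            np.testing.assert_array_equal(a.kinetics[r].k_plus, b.kinetics[r].k_plus)
            np.testing.assert_array_equal(a.kinetics[r].k_minus, b.kinetics[r].k_minus)

    def test_instance_serialises(self, small_ensemble, tmp_path):
        small_ensemble.instances[0].save(tmp_path / "inst.json")
        assert (tmp_path / "inst.json").stat().st_size > 0
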