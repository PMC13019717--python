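"""Sampling of thermodynamically consistent elementary kinetic models.

One :class:`KineticInstance` is a complete kinetic parameterisation of the
model that reproduces a reference steady state *exactly*.  Construction
follows the ensemble-sampling recipe:

1. a thermodynamic layer (fluxes v, Gibbs energies dG, reference
   log-concentrations) is drawn (:mod:`kincontrol.thermo`);
2. per reaction, the Gibbs energy is partitioned onto the elementary steps
   by a flat Dirichlet draw (step *reversibilities*), fixing each step's
   reverse/forward unidirectional rate ratio exp(dG_step / RT);
3. enzyme-form abundances are drawn from a flat Dirichlet on the simplex;
4. elementary rate constants are then *solved* so every cycle step carries
   the reference net flux: f_i - b_i = v_ref with b_i / f_i = exp(dG_i/RT),
   giving k+ = f_i / e_source and k- = b_i / e_target in normalised
   concentration units (x / x_ref = 1 at reference).

The construction guarantees the Haldane relation per reaction: the product
of k+/k- around the cycle times the reference mass-action ratio equals
exp(-dG0 / RT).

Rates at arbitrary concentrations come from a quasi-steady-state solve of
the enzyme-form distribution (linear King-Altman system).  Allosteric
reactions are modulated by a concerted MWC active fraction
rho = 1 / (1 + L_eff(x)) with
L_eff = L0 * prod_inh (1 + x/K)^n / prod_act (1 + x/K)^n; the catalytic
cycle is calibrated against v_ref / rho_ref so the reference state is still
reproduced exactly.  Drains follow first-order mass action calibrated to
their reference flux.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data import ConditionDataset
from .mechanisms import MechanismPattern, build_mechanism
from .model import ALLOSTERIC_KINDS, MetabolicModel, Reaction
from .thermo import (
    StandardGibbs,
    ThermoConfig,
    ThermoInfeasible,
    ThermoSample,
    sample_fluxes_and_gibbs,
)

__all__ = [
    "ReversibilitySample",
    "EnzymeStateSample",
    "AllostericParameters",
    "ReactionKinetics",
    "KineticInstance",
    "KineticSolveError",
    "sample_reversibilities",
    "sample_enzyme_states",
    "sample_allosteric_parameters",
    "compute_elementary_rate_constants",
    "sample_instance",
]

#: Magnitude floor for a step Gibbs energy during rate-constant solving
#: (kJ/mol); keeps f = v / (1 - exp(dG/RT)) finite near equilibrium.
DG_STEP_FLOOR = 1e-9

#: Below this |flux| a reaction is treated as at equilibrium.
ZERO_FLUX_TOL = 1e-12


class KineticSolveError(RuntimeError):
    """Rate-constant solving or steady-state reproduction failed."""

    stage = "kinetics"

    def __init__(self, reaction: str, message: str):
        self.reaction = reaction
        super().__init__(message)


# make the thermodynamic rejection carry its stage label too
ThermoInfeasible.stage = "thermodynamics"


@dataclass(frozen=True)
class ReversibilitySample:
    """Partition of a reaction's Gibbs energy onto its elementary steps."""

    weights: np.ndarray
    dG_steps: np.ndarray

    def __post_init__(self) -> None:
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("reversibility weights must sum to 1")


@dataclass(frozen=True)
class EnzymeStateSample:
    """Enzyme-form abundance fractions on the simplex (order = pattern.forms)."""

    fractions: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.fractions <= 0) or not np.isclose(self.fractions.sum(), 1.0):
            raise ValueError("enzyme-form fractions must be positive and sum to 1")


@dataclass(frozen=True)
class AllostericParameters:
    """Concerted (MWC) allosteric parameters of one reaction.

    ``half_saturation`` maps effector id -> molar K; ``kinds`` records
    whether each effector stabilises the inactive (inhibitor) or active
    (activator) conformation.
    """

    n_subunits: int
    L0: float
    half_saturation: dict[str, float]
    kinds: dict[str, str]

    def __post_init__(self) -> None:
        if self.n_subunits < 1 or self.L0 <= 0:
            raise ValueError("allosteric parameters must be positive")
        if any(k <= 0 for k in self.half_saturation.values()):
            raise ValueError("half-saturations must be positive")


def sample_reversibilities(
    mech: MechanismPattern, dG_reaction: float, rng: np.random.Generator
) -> ReversibilitySample:
    """Flat-Dirichlet partition of dG_reaction over the cycle steps.

    Every step energy inherits the sign of the reaction Gibbs energy, so a
    thermodynamically downhill reaction is downhill in every elementary
    step.  A single-step mechanism gets weight 1 deterministically.
    """
    n = len(mech.cycle_steps)
    w = np.ones(1) if n == 1 else rng.dirichlet(np.ones(n))
    return ReversibilitySample(weights=w, dG_steps=w * dG_reaction)


def sample_enzyme_states(
    mech: MechanismPattern, rng: np.random.Generator
) -> EnzymeStateSample:
    """Flat-Dirichlet enzyme-form fractions over all forms (incl. dead ends)."""
    n = len(mech.forms)
    e = np.ones(1) if n == 1 else rng.dirichlet(np.ones(n))
    return EnzymeStateSample(fractions=e)


def sample_allosteric_parameters(
    reaction: Reaction,
    rng: np.random.Generator,
    bounds=None,
    L0_span: tuple[float, float] = (1e-2, 1e2),
    default_K_span: tuple[float, float] = (1e-6, 1e-2),
) -> AllostericParameters:
    """Draw MWC parameters for an allosteric reaction.

    L0 is log-uniform over ``L0_span``; each effector half-saturation is
    log-uniform within the effector's concentration bounds when *bounds*
    (a :class:`~kincontrol.data.ConcentrationBounds`) is given, else over
    ``default_K_span`` (molar).
    """
    if not reaction.is_allosteric:
        raise ValueError(f"reaction {reaction.id!r} is not allosteric")
    L0 = float(np.exp(rng.uniform(np.log(L0_span[0]), np.log(L0_span[1]))))
    half: dict[str, float] = {}
    kinds: dict[str, str] = {}
    for reg in reaction.regulations:
        if reg.kind not in ALLOSTERIC_KINDS:
            continue
        if bounds is not None and reg.effector in bounds:
            lo = max(bounds.lower[reg.effector], 1e-12)
            hi = max(bounds.upper[reg.effector], lo)
        else:
            lo, hi = default_K_span
        half[reg.effector] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        kinds[reg.effector] = reg.kind
    return AllostericParameters(
        n_subunits=reaction.n_subunits, L0=L0, half_saturation=half, kinds=kinds
    )


def compute_elementary_rate_constants(
    mech: MechanismPattern,
    rev: ReversibilitySample,
    states: EnzymeStateSample,
    v_ref: float,
    cfg: ThermoConfig,
    rng: np.random.Generator | None = None,
    exchange_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve per-step forward/reverse rate constants (normalised units).

    Cycle steps: with r_i = exp(dG_i/RT), the unidirectional rates at the
    reference state are f_i = v_ref / (1 - r_i) and b_i = r_i f_i, so each
    step's net flux is v_ref and its rate ratio matches its Gibbs energy.
    Zero net flux is handled as equilibrium (f = b = exchange rate).
    Dead-end inhibitor branches carry zero net flux with a log-uniformly
    sampled exchange rate.  Returns (k_plus, k_minus) over ``mech.steps``.
    """
    form_index = {f: i for i, f in enumerate(mech.forms)}
    e = states.fractions
    k_plus = np.zeros(len(mech.steps))
    k_minus = np.zeros(len(mech.steps))
    scale = max(abs(v_ref), exchange_scale)
    cyc = 0
    for i, step in enumerate(mech.steps):
        es, et = e[form_index[step.source]], e[form_index[step.target]]
        if step.dead_end:
            q = scale * 10.0 ** (rng.uniform(-1.0, 1.0) if rng is not None else 0.0)
            f = b = q
        else:
            dG = float(rev.dG_steps[cyc])
            cyc += 1
            if abs(v_ref) < ZERO_FLUX_TOL:
                f = b = scale
            else:
                if abs(dG) < DG_STEP_FLOOR:
                    dG = -np.sign(v_ref) * DG_STEP_FLOOR
                r = np.exp(dG / cfg.RT)
                f = v_ref / (1.0 - r)
                b = r * f
        if f <= 0 or b < 0:
            raise KineticSolveError(
                mech.reaction,
                f"non-positive unidirectional rate in step {step.source}->{step.target} "
                f"(f={f:g}, b={b:g}); thermodynamic layer inconsistent",
            )
        k_plus[i] = f / es
        k_minus[i] = b / et
    return k_plus, k_minus


@dataclass
class ReactionKinetics:
    """Sampled elementary kinetics of one reaction (normalised units)."""

    reaction: str
    pattern: MechanismPattern
    k_plus: np.ndarray
    k_minus: np.ndarray
    v_ref: float
    allosteric: AllostericParameters | None = None
    # derived at assembly time
    _form_index: dict[str, int] = field(default_factory=dict, repr=False)
    _step_bound: list[np.ndarray] = field(default_factory=list, repr=False)
    _step_released: list[np.ndarray] = field(default_factory=list, repr=False)
    _effector_idx: dict[str, int] = field(default_factory=dict, repr=False)

    def finalise(self, met_index: Mapping[str, int]) -> None:
        self._form_index = {f: i for i, f in enumerate(self.pattern.forms)}
        self._step_bound = [
            np.array([met_index[m] for m in s.bound], dtype=int) for s in self.pattern.steps
        ]
        self._step_released = [
            np.array([met_index[m] for m in s.released], dtype=int)
            for s in self.pattern.steps
        ]
        if self.allosteric:
            self._effector_idx = {
                m: met_index[m] for m in self.allosteric.half_saturation
            }

    def active_fraction(self, u: np.ndarray, x_ref: np.ndarray) -> float:
        """MWC active fraction rho(x) in [0, 1]; 1 for non-allosteric."""
        if self.allosteric is None:
            return 1.0
        a = self.allosteric
        L_eff = a.L0
        for met, K in a.half_saturation.items():
            idx = self._effector_idx[met]
            x = u[idx] * x_ref[idx]
            factor = (1.0 + x / K) ** a.n_subunits
            if a.kinds[met] == "allosteric_inhibitor":
                L_eff *= factor
            else:
                L_eff /= factor
        return 1.0 / (1.0 + L_eff)

    def rate(self, u: np.ndarray, x_ref: np.ndarray, E: float = 1.0) -> float:
        """Net rate at normalised concentrations *u* and enzyme level *E*.

        Solves the quasi-steady-state enzyme-form distribution from the
        pseudo-first-order transition matrix, then evaluates the net flux
        through the catalytic step scaled by the enzyme level and the MWC
        active fraction.
        """
        n = len(self.pattern.forms)
        if n == 1:
            e = np.ones(1)
        else:
            A = np.zeros((n, n))
            for i, step in enumerate(self.pattern.steps):
                s = self._form_index[step.source]
                t = self._form_index[step.target]
                lam_f = self.k_plus[i] * float(np.prod(u[self._step_bound[i]]))
                lam_b = self.k_minus[i] * float(np.prod(u[self._step_released[i]]))
                A[t, s] += lam_f
                A[s, s] -= lam_f
                A[s, t] += lam_b
                A[t, t] -= lam_b
            A[-1, :] = 1.0
            rhs = np.zeros(n)
            rhs[-1] = 1.0
            try:
                e = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError as exc:
                raise KineticSolveError(
                    self.reaction, f"singular enzyme-form system: {exc}"
                ) from exc
        i = self.pattern.catalytic_index
        step = self.pattern.steps[i]
        f = self.k_plus[i] * e[self._form_index[step.source]] * float(
            np.prod(u[self._step_bound[i]])
        )
        b = self.k_minus[i] * e[self._form_index[step.target]] * float(
            np.prod(u[self._step_released[i]])
        )
        return E * self.active_fraction(u, x_ref) * (f - b)


class KineticInstance:
    """One sampled kinetic model reproducing the reference steady state.

    Evaluation interface: concentrations are passed normalised to the
    reference (u = x / x_ref, so u = 1 at reference), enzyme levels are
    dimensionless with 1 at reference.
    """

    def __init__(
        self,
        model: MetabolicModel,
        thermo: ThermoSample,
        kinetics: dict[str, ReactionKinetics],
        seed: int | None = None,
    ) -> None:
        self.model = model
        self.thermo = thermo
        self.kinetics = kinetics
        self.seed = seed
        self.met_index = {m: i for i, m in enumerate(model.metabolite_ids)}
        self.rxn_index = {r: i for i, r in enumerate(model.reaction_ids)}
        self.x_ref = np.array(
            [np.exp(thermo.ln_x[m]) for m in model.metabolite_ids]
        )
        self.v_ref = np.array([thermo.v[r] for r in model.reaction_ids])
        for kin in kinetics.values():
            kin.finalise(self.met_index)
        # drains: first-order in the species consumed by the flux direction
        self._drain_consumed: dict[str, np.ndarray] = {}
        for rxn in model.reactions.values():
            if not rxn.is_drain:
                continue
            v = thermo.v[rxn.id]
            if v >= 0:
                mets = [m for m, c in rxn.stoichiometry.items() if c < 0]
            else:
                mets = [m for m, c in rxn.stoichiometry.items() if c > 0]
            idx = [
                self.met_index[m]
                for m in mets
                if not model.metabolites[m].is_fixed
            ]
            self._drain_consumed[rxn.id] = np.array(idx, dtype=int)
        # metabolites each reaction's rate law can depend on (fixed species
        # are pinned, so they are never perturbed)
        fixed_idx = {
            self.met_index[m.id] for m in model.metabolites.values() if m.is_fixed
        }
        self._involved: list[np.ndarray] = []
        for rxn in model.reactions.values():
            if rxn.is_drain:
                self._involved.append(self._drain_consumed[rxn.id])
            else:
                kin = kinetics[rxn.id]
                ids: set[int] = set()
                for b in kin._step_bound:
                    ids.update(int(i) for i in b)
                for r in kin._step_released:
                    ids.update(int(i) for i in r)
                ids.update(kin._effector_idx.values())
                self._involved.append(np.array(sorted(ids - fixed_idx), dtype=int))

    # -- evaluation ----------------------------------------------------

    def evaluate_reaction(self, j: int, u: np.ndarray, E_j: float = 1.0) -> float:
        rxn_id = self.model.reaction_ids[j]
        rxn = self.model.reactions[rxn_id]
        if rxn.is_drain:
            v0 = self.v_ref[j]
            if v0 == 0.0:
                return 0.0
            return E_j * v0 * float(np.prod(u[self._drain_consumed[rxn_id]]))
        return self.kinetics[rxn_id].rate(u, self.x_ref, E_j)

    def evaluate(self, u: np.ndarray, E: np.ndarray | None = None) -> np.ndarray:
        """Flux vector v(u, E) over the model's reaction order."""
        if E is None:
            E = np.ones(len(self.rxn_index))
        return np.array(
            [self.evaluate_reaction(j, u, E[j]) for j in range(len(self.rxn_index))]
        )

    def involved_metabolites(self, j: int) -> np.ndarray:
        return self._involved[j]

    # -- invariant helpers ---------------------------------------------

    def implied_keq(self, rxn_id: str) -> float:
        """Equilibrium constant implied by the elementary rate constants.

        Product of k+/k- around the catalytic cycle times the reference
        mass-action ratio; equals exp(-dG0/RT) by the Haldane relation.
        """
        kin = self.kinetics[rxn_id]
        ratio = 1.0
        for i, step in enumerate(kin.pattern.steps):
            if not step.dead_end:
                ratio *= kin.k_plus[i] / kin.k_minus[i]
        rxn = self.model.reactions[rxn_id]
        ln_q_ref = sum(
            c * self.thermo.ln_x[m] for m, c in rxn.stoichiometry.items()
        )
        return ratio * float(np.exp(ln_q_ref))

    def max_steady_state_error(self) -> float:
        """Max relative deviation of v(u=1, E=1) from the reference fluxes."""
        v = self.evaluate(np.ones(len(self.met_index)))
        scale = np.max(np.abs(self.v_ref)) or 1.0
        return float(np.max(np.abs(v - self.v_ref)) / scale)

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "ln_x": self.thermo.ln_x,
            "v": self.thermo.v,
            "dG": self.thermo.dG,
            "dG0": self.thermo.dG0,
            "reactions": {
                r: {
                    "k_plus": kin.k_plus.tolist(),
                    "k_minus": kin.k_minus.tolist(),
                    "allosteric": None
                    if kin.allosteric is None
                    else {
                        "n_subunits": kin.allosteric.n_subunits,
                        "L0": kin.allosteric.L0,
                        "half_saturation": kin.allosteric.half_saturation,
                        "kinds": kin.allosteric.kinds,
                    },
                }
                for r, kin in self.kinetics.items()
            },
        }

    def save(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def sample_instance(
    model: MetabolicModel,
    dataset: ConditionDataset,
    std: StandardGibbs,
    rng: np.random.Generator,
    cfg: ThermoConfig | None = None,
    thermo_sample: ThermoSample | None = None,
    seed: int | None = None,
    reproduction_tol: float = 1e-9,
) -> KineticInstance:
    """One sampling attempt: thermodynamic draw + kinetic parameterisation.

    Raises :class:`~kincontrol.thermo.ThermoInfeasible` (stage
    ``"thermodynamics"``) or :class:`KineticSolveError` (stage
    ``"kinetics"``); on success the returned instance reproduces the
    reference fluxes at (u=1, E=1) to ``reproduction_tol`` relative.
    """
    cfg = cfg or ThermoConfig()
    thermo = thermo_sample or sample_fluxes_and_gibbs(dataset, std, model, rng, cfg)
    flux_scale = max((abs(x) for x in thermo.v.values()), default=1.0) or 1.0
    kinetics: dict[str, ReactionKinetics] = {}
    for rxn in model.reactions.values():
        if rxn.is_drain:
            continue
        pattern = build_mechanism(rxn, model)
        rev = sample_reversibilities(pattern, thermo.dG.get(rxn.id, 0.0), rng)
        states = sample_enzyme_states(pattern, rng)
        allo = None
        rho_ref = 1.0
        if rxn.is_allosteric:
            allo = sample_allosteric_parameters(rxn, rng, bounds=dataset.bounds)
            # active fraction at the sampled reference concentrations
            L_eff = allo.L0
            for met, K in allo.half_saturation.items():
                x = float(np.exp(thermo.ln_x[met]))
                factor = (1.0 + x / K) ** allo.n_subunits
                if allo.kinds[met] == "allosteric_inhibitor":
                    L_eff *= factor
                else:
                    L_eff /= factor
            rho_ref = 1.0 / (1.0 + L_eff)
        v_cycle = thermo.v[rxn.id] / rho_ref
        k_plus, k_minus = compute_elementary_rate_constants(
            pattern, rev, states, v_cycle, cfg, rng=rng, exchange_scale=flux_scale
        )
        kinetics[rxn.id] = ReactionKinetics(
            reaction=rxn.id,
            pattern=pattern,
            k_plus=k_plus,
            k_minus=k_minus,
            v_ref=thermo.v[rxn.id],
            allosteric=allo,
        )
    instance = KineticInstance(model, thermo, kinetics, seed=seed)
    err = instance.max_steady_state_error()
    if err > reproduction_tol:
        raise KineticSolveError(
            "<instance>", f"steady-state reproduction error {err:g} above tolerance"
        )
    return instance
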