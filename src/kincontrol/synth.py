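"""Synthetic chemostat datasets with known ground truth.

Emulates, at toy scale, everything the real chemostat study supplies: a
compartmentalised model, a generating kinetic instance (the ground truth),
steady states across growth conditions (a dilution-rate sweep of a
glucose-limited medium plus nutrient-limitation variants), noisy
concentration "measurements", and balanced flux tables — so the entire
pipeline is testable without any external download.

Templates
---------
``linear_chain(n)``
    supply -> n internal conversions -> secretion.
``branched_glycolysis_mini``
    an ATP-coupled uptake/phosphorylation step, a fermentative branch and a
    "respiratory" branch with different ATP yields, an ATP-ase drain, one
    allosterically ATP-inhibited reaction (PFK-like) and one competitive
    product inhibition — the motifs behind glucose-limited control
    patterns, with an adenylate conserved moiety.
``two_compartment_mini``
    a chain crossing two intracellular compartments with distinct pH.
``atp_competition_mini``
    the branched template extended with a storage branch (trehalose-like)
    that competes with the hexokinase-like step for internal glucose and
    ATP; built to exhibit a supply-dependent sign flip of the kinase's
    control over the storage flux.

Conditions are emulated by scaling the uptake enzyme level with the
dilution rate (reference = the highest rate); nutrient-limitation variants
additionally scale the maintenance ATP-ase. Measurements carry
multiplicative lognormal noise on concentrations only; fluxes come from
balances and are noiseless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data import (
    ConditionDataset,
    Measurement,
    balance_with_drains,
    metabolite_bounds,
    proton_concentration,
)
from .mca import ControlCoefficientMatrix, flux_control_coefficients, solve_steady_state
from .model import Compartment, MetabolicModel, Metabolite, Reaction, Regulation
from .sampler import KineticInstance, sample_instance
from .stability import jacobian_at_reference
from .thermo import StandardGibbs, ThermoConfig, ThermoSample

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "MassActionSystem",
    "generate_toy_model",
    "generate_ground_truth",
    "generate_condition_series",
    "reference_state",
    "standard_gibbs_table",
    "DEFAULT_DILUTION_RATES",
    "LIMITATION_LABELS",
]

#: Chemostat dilution-rate sweep of the glucose-limited medium (1/h).
DEFAULT_DILUTION_RATES = (0.05, 0.11, 0.16, 0.22, 0.30)

#: Nutrient-limitation variants, all run at D = 0.11 1/h, with their
#: maintenance (ATP-ase) multiplier emulating limitation-specific energy
#: demand shifts.
LIMITATION_LABELS = {
    "phosphate-limited": 1.3,
    "ammonia-limited": 1.15,
    "leucine-limited": 0.85,
    "uracil-limited": 0.7,
}


@dataclass
class SyntheticSpec:
    """Configuration of one synthetic dataset."""

    template: str = "branched_glycolysis_mini"
    chain_length: int = 3
    dilution_rates: tuple[float, ...] = DEFAULT_DILUTION_RATES
    limitations: Mapping[str, float] = field(default_factory=lambda: dict(LIMITATION_LABELS))
    noise_sigma: float = 0.2
    seed: int = 0
    measured: str | Sequence[str] = "all"
    reference_driving_force: float = -7.0  # kJ/mol per reaction at reference
    dG0_half_width: float = 3.0  # kJ/mol half-width of the published-style range

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dilution_rates):
            raise ValueError("dilution rates must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


# ---------------------------------------------------------------------
# templates


def generate_toy_model(spec: SyntheticSpec) -> MetabolicModel:
    """Instantiate the template named in *spec* as a validated model."""
    t = spec.template
    if t.startswith("linear_chain"):
        return _linear_chain(spec.chain_length)
    if t == "branched_glycolysis_mini":
        return _branched_glycolysis_mini()
    if t == "two_compartment_mini":
        return _two_compartment_mini()
    if t == "atp_competition_mini":
        return _atp_competition_mini()
    raise ValueError(f"unknown template {t!r}")


def _linear_chain(n: int) -> MetabolicModel:
    comps = [Compartment("c", pH=7.2, volume_fraction=0.9)]
    mets = [Metabolite(f"m{i}_c", "c") for i in range(1, n + 2)]
    rxns = [Reaction("UPT", {"m1_c": +1.0}, mechanism="mass_action_drain", is_drain=True)]
    for i in range(1, n + 1):
        rxns.append(Reaction(f"R{i}", {f"m{i}_c": -1.0, f"m{i+1}_c": +1.0}, mechanism="uni_uni"))
    rxns.append(
        Reaction("SEC", {f"m{n+1}_c": -1.0}, mechanism="mass_action_drain", is_drain=True)
    )
    return MetabolicModel(comps, mets, rxns)


def _branched_glycolysis_mini() -> MetabolicModel:
    comps = [
        Compartment("c", pH=7.2, volume_fraction=0.9),
        Compartment("e", pH=5.0, volume_fraction=1.0, intracellular=False),
    ]
    mets = [
        Metabolite("glc_e", "e", is_fixed=True),
        Metabolite("glci_c", "c"),
        Metabolite("hp_c", "c"),
        Metabolite("fer_c", "c"),
        Metabolite("res_c", "c"),
        Metabolite("atp_c", "c"),
        Metabolite("adp_c", "c"),
    ]
    rxns = [
        # reversible, saturable transporter: the uptake drive that the
        # dilution rate scales; being elastic to internal glucose it shares
        # control with the kinases downstream
        Reaction("GLCt", {"glc_e": -1.0, "glci_c": +1.0}, mechanism="uni_uni"),
        Reaction(
            "HEX",
            {"glci_c": -1.0, "atp_c": -1.0, "hp_c": +1.0, "adp_c": +1.0},
            mechanism="ordered_bi_bi",
            regulations=(Regulation("HEX", "hp_c", "competitive_inhibitor"),),
        ),
        Reaction(
            "FERM",
            {"hp_c": -1.0, "adp_c": -1.0, "fer_c": +1.0, "atp_c": +1.0},
            mechanism="ordered_bi_bi",
            regulations=(Regulation("FERM", "atp_c", "allosteric_inhibitor"),),
            n_subunits=4,
        ),
        Reaction(
            "RESP",
            {"hp_c": -1.0, "adp_c": -2.0, "res_c": +1.0, "atp_c": +2.0},
            mechanism="ordered",
        ),
        Reaction("ATPASE", {"atp_c": -1.0, "adp_c": +1.0}, mechanism="uni_uni"),
        Reaction("FER_sec", {"fer_c": -1.0}, mechanism="mass_action_drain", is_drain=True),
        Reaction("RES_sec", {"res_c": -1.0}, mechanism="mass_action_drain", is_drain=True),
    ]
    return MetabolicModel(comps, mets, rxns)


def _atp_competition_mini() -> MetabolicModel:
    """Branched template plus a storage branch competing with the kinase.

    The trehalose-like branch (TRE) draws on internal glucose *and* ATP, so
    the hexokinase-like enzyme and the storage flux compete for both.  At
    low uptake drive the substrate competition dominates (negative control
    of HEX on the storage flux); at high drive the ATP coupling through the
    producing branches can dominate and turn the control positive — the
    supply-dependent control sign flip this template is built to exhibit.
    """
    base = _branched_glycolysis_mini()
    mets = list(base.metabolites.values()) + [Metabolite("tre_c", "c")]
    rxns = list(base.reactions.values())
    rxns.insert(
        2,
        Reaction(
            "TRE",
            {"glci_c": -1.0, "atp_c": -1.0, "tre_c": +1.0, "adp_c": +1.0},
            mechanism="ordered_bi_bi",
        ),
    )
    rxns.insert(
        3,
        Reaction("TRE_sec", {"tre_c": -1.0}, mechanism="mass_action_drain", is_drain=True),
    )
    return MetabolicModel(base.compartments.values(), mets, rxns)


def _two_compartment_mini() -> MetabolicModel:
    comps = [
        Compartment("c", pH=7.2, volume_fraction=0.89),
        Compartment("m", pH=7.5, volume_fraction=0.01),
    ]
    mets = [
        Metabolite("a_c", "c"),
        Metabolite("a_m", "m"),
        Metabolite("b_m", "m"),
        Metabolite("b_c", "c"),
    ]
    rxns = [
        Reaction("UPT", {"a_c": +1.0}, mechanism="mass_action_drain", is_drain=True),
        Reaction("T_IN", {"a_c": -1.0, "a_m": +1.0}, mechanism="uni_uni"),
        Reaction("CONV", {"a_m": -1.0, "b_m": +1.0}, mechanism="uni_uni"),
        Reaction("T_OUT", {"b_m": -1.0, "b_c": +1.0}, mechanism="uni_uni"),
        Reaction("SEC", {"b_c": -1.0}, mechanism="mass_action_drain", is_drain=True),
    ]
    return MetabolicModel(comps, mets, rxns)


# ---------------------------------------------------------------------
# reference states (concentrations molar, fluxes mmol/gDW/h)

_BRANCHED_XREF = {
    "glc_e": 1e-2,
    "glci_c": 2e-4,
    "hp_c": 1e-3,
    "fer_c": 2e-3,
    "res_c": 1e-3,
    "atp_c": 2e-3,
    "adp_c": 5e-4,
}
_BRANCHED_VREF = {
    "GLCt": 1.0,
    "HEX": 1.0,
    "FERM": 0.6,
    "RESP": 0.4,
    "ATPASE": 0.4,
    "FER_sec": 0.6,
    "RES_sec": 0.4,
}

#: enzyme whose level is scaled with dilution rate, per template
_DRIVE_REACTION = {
    "linear_chain": "UPT",
    "branched_glycolysis_mini": "GLCt",
    "atp_competition_mini": "GLCt",
    "two_compartment_mini": "UPT",
}
_MAINTENANCE_REACTION = {
    "branched_glycolysis_mini": "ATPASE",
    "atp_competition_mini": "ATPASE",
}


def reference_state(model: MetabolicModel, spec: SyntheticSpec) -> tuple[dict, dict]:
    """(x_ref molar, v_ref mmol/gDW/h) of the template's reference condition.

    The reference is the *highest* dilution rate, so every other condition
    scales the uptake drive down and relaxes onto a reachable steady state.
    """
    if spec.template == "branched_glycolysis_mini":
        return dict(_BRANCHED_XREF), dict(_BRANCHED_VREF)
    if spec.template == "atp_competition_mini":
        x_ref = dict(_BRANCHED_XREF)
        x_ref["tre_c"] = 1e-3
        v_ref = dict(_BRANCHED_VREF)
        # 5% of uptake diverted to the ATP-consuming storage branch
        v_ref.update({"GLCt": 1.05, "TRE": 0.05, "TRE_sec": 0.05, "ATPASE": 0.35})
        return x_ref, v_ref
    x_ref = {m: 1e-3 for m in model.metabolite_ids}
    v_ref = {r: 1.0 for r in model.reaction_ids}
    return x_ref, v_ref


def true_thermo_sample(
    model: MetabolicModel, spec: SyntheticSpec, cfg: ThermoConfig | None = None
) -> ThermoSample:
    """Ground-truth thermodynamic layer consistent with the reference state.

    Every flux-carrying non-drain reaction is assigned the same driving
    force (``spec.reference_driving_force``, sign opposing the flux); the
    standard Gibbs energy follows from dG0 = dG - RT sum s ln x_ref.
    """
    cfg = cfg or ThermoConfig()
    x_ref, v_ref = reference_state(model, spec)
    ln_x = {m: float(np.log(x_ref[m])) for m in model.metabolite_ids}
    dG, dG0 = {}, {}
    for rxn in model.reactions.values():
        if rxn.is_drain:
            continue
        sign = -np.sign(v_ref[rxn.id]) if v_ref[rxn.id] != 0 else -1.0
        g = sign * abs(spec.reference_driving_force)
        q = sum(c * ln_x[m] for m, c in rxn.stoichiometry.items())
        dG[rxn.id] = g
        dG0[rxn.id] = g - cfg.RT * q
    return ThermoSample(v=dict(v_ref), dG=dG, dG0=dG0, ln_x=ln_x, config=cfg)


def standard_gibbs_table(model: MetabolicModel, spec: SyntheticSpec) -> StandardGibbs:
    """Published-style dG0 range table bracketing the ground truth."""
    thermo = true_thermo_sample(model, spec)
    std = StandardGibbs(source="synthetic ground truth")
    for rxn_id, g0 in thermo.dG0.items():
        std.lo[rxn_id] = g0 - spec.dG0_half_width
        std.hi[rxn_id] = g0 + spec.dG0_half_width
    return std


# ---------------------------------------------------------------------
# ground truth


@dataclass
class ConditionTruth:
    """True steady state and control pattern of one growth condition."""

    label: str
    dilution_rate: float
    enzyme_levels: np.ndarray
    u_star: np.ndarray
    x_star: np.ndarray
    v_star: np.ndarray
    control: ControlCoefficientMatrix


@dataclass
class GroundTruth:
    """Generating instance plus per-condition true states and control."""

    model: MetabolicModel
    spec: SyntheticSpec
    instance: KineticInstance
    conditions: list[ConditionTruth]

    def condition(self, label: str) -> ConditionTruth:
        for c in self.conditions:
            if c.label == label:
                return c
        raise KeyError(label)


def condition_plan(spec: SyntheticSpec) -> list[tuple[str, float, float]]:
    """(label, dilution rate, maintenance multiplier) per condition."""
    plan = [
        (f"glucose-limited D={d:.2f}", d, 1.0) for d in sorted(spec.dilution_rates)
    ]
    d_lim = 0.11
    for label, maint in spec.limitations.items():
        plan.append((f"{label} D={d_lim:.2f}", d_lim, maint))
    return plan


def generate_ground_truth(
    model: MetabolicModel, spec: SyntheticSpec, max_retries: int = 20
) -> GroundTruth:
    """Sample a generating instance and derive all condition truths.

    The generating instance is drawn with the same sampler the pipeline
    uses, anchored at the template's reference state; candidates are
    redrawn (bounded retries) until the instance is linearly stable and
    every condition's steady state converges.
    """
    thermo = true_thermo_sample(model, spec)
    x_ref, v_ref = reference_state(model, spec)
    # a minimal dataset just to give the sampler effector bounds
    from .data import ConcentrationBounds

    bounds = ConcentrationBounds()
    for m in model.metabolite_ids:
        bounds.lower[m] = x_ref[m] * 0.5
        bounds.upper[m] = x_ref[m] * 1.5
        bounds.reference[m] = x_ref[m]
    ref_dataset = ConditionDataset(
        label="reference", bounds=bounds, reference_fluxes=dict(v_ref),
        dilution_rate=max(spec.dilution_rates),
    )
    std = standard_gibbs_table(model, spec)
    plan = condition_plan(spec)
    d_max = max(spec.dilution_rates)
    drive = _DRIVE_REACTION.get(
        "linear_chain" if spec.template.startswith("linear_chain") else spec.template
    )
    maint_rxn = _MAINTENANCE_REACTION.get(spec.template)
    rxn_ids = model.reaction_ids

    last_error: Exception | None = None
    for retry in range(max_retries):
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, 7919, retry])
        )
        try:
            instance = sample_instance(
                model, ref_dataset, std, rng, thermo_sample=thermo, seed=spec.seed
            )
            if not jacobian_at_reference(instance).stable:
                raise RuntimeError("generating instance unstable at reference")
            conditions: list[ConditionTruth] = []
            for label, d, maint in plan:
                E = np.ones(len(rxn_ids))
                if drive is not None:
                    E[rxn_ids.index(drive)] = d / d_max
                if maint_rxn is not None:
                    E[rxn_ids.index(maint_rxn)] *= maint
                u_star = solve_steady_state(instance, E)
                v_star = instance.evaluate(u_star, E)
                C = flux_control_coefficients(instance, u=u_star, E=E)
                conditions.append(
                    ConditionTruth(
                        label=label,
                        dilution_rate=d,
                        enzyme_levels=E,
                        u_star=u_star,
                        x_star=u_star * instance.x_ref,
                        v_star=v_star,
                        control=C,
                    )
                )
            return GroundTruth(model=model, spec=spec, instance=instance, conditions=conditions)
        except Exception as exc:  # redraw on instability / non-convergence
            last_error = exc
    raise RuntimeError(
        f"no viable generating instance after {max_retries} retries: {last_error}"
    )


# ---------------------------------------------------------------------
# condition series (the emulated omics tables)


def generate_condition_series(
    truth: GroundTruth,
    spec: SyntheticSpec | None = None,
    rng: np.random.Generator | None = None,
) -> list[ConditionDataset]:
    """Noisy per-condition datasets in the pipeline's input format.

    Measured concentrations are the condition's true steady-state values
    times lognormal(0, sigma) noise; bound rules are then applied exactly
    as for real data.  Fluxes are the true non-drain fluxes, re-balanced
    through the drain rule (noiseless).
    """
    spec = spec or truth.spec
    if spec.noise_sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    rng = rng or np.random.default_rng(np.random.SeedSequence([spec.seed, 104729]))
    model = truth.model
    met_ids = model.metabolite_ids
    measured: list[str]
    if spec.measured == "all":
        measured = [m for m in met_ids if not model.metabolites[m].is_fixed]
    elif spec.measured == "none":
        measured = []
    else:
        measured = list(spec.measured)

    datasets = []
    for cond in truth.conditions:
        meas = []
        for m in measured:
            x_true = cond.x_star[met_ids.index(m)]
            noise = float(np.exp(rng.normal(0.0, spec.noise_sigma))) if spec.noise_sigma else 1.0
            meas.append(Measurement(metabolite=m, concentration=x_true * noise, condition=cond.label))
        bounds = metabolite_bounds(meas, model, mito_compartments=("m",))
        partial = {
            r: float(cond.v_star[model.reaction_ids.index(r)])
            for r in model.reaction_ids
            if not model.reactions[r].is_drain
        }
        _, v_bal = balance_with_drains(model, partial)
        protons = {
            c.id: proton_concentration(c) for c in model.compartments.values()
        }
        datasets.append(
            ConditionDataset(
                label=cond.label,
                bounds=bounds,
                reference_fluxes=v_bal,
                dilution_rate=cond.dilution_rate,
                proton_concentrations=protons,
            )
        )
    return datasets


# ---------------------------------------------------------------------
# independent hand-written fixture kinetics


class MassActionSystem:
    """Reversible mass-action kinetics — an independent fixture system.

    Rates are v_j = E_j (kf_j prod_subs x^|s| - kr_j prod_prods x^s) in raw
    molar concentrations.  Implements the same evaluation protocol as
    :class:`~kincontrol.sampler.KineticInstance` (normalised concentrations
    u = x / x_ref), so the stability and MCA machinery runs on it
    unchanged; being hand-written, it breaks the circularity of testing the
    sampler against itself.
    """

    def __init__(
        self,
        model: MetabolicModel,
        kf: Mapping[str, float],
        kr: Mapping[str, float],
        x_ref: Mapping[str, float],
    ) -> None:
        self.model = model
        self.met_index = {m: i for i, m in enumerate(model.metabolite_ids)}
        self.x_ref = np.array([x_ref[m] for m in model.metabolite_ids])
        self.kf = np.array([kf.get(r, 0.0) for r in model.reaction_ids])
        self.kr = np.array([kr.get(r, 0.0) for r in model.reaction_ids])
        self._subs = []
        self._prods = []
        for rxn in model.reactions.values():
            subs = [(self.met_index[m], -c) for m, c in rxn.stoichiometry.items() if c < 0]
            prods = [(self.met_index[m], c) for m, c in rxn.stoichiometry.items() if c > 0]
            self._subs.append(subs)
            self._prods.append(prods)
        self._involved = []
        for j, rxn in enumerate(model.reactions.values()):
            idx = sorted(
                {i for i, _ in self._subs[j]} | {i for i, _ in self._prods[j]}
                - {self.met_index[m] for m in rxn.stoichiometry
                   if model.metabolites[m].is_fixed}
            )
            # fixed species stay in the rate law but are not perturbed
            self._involved.append(np.array(
                [i for i in idx
                 if not model.metabolites[model.metabolite_ids[i]].is_fixed],
                dtype=int,
            ))
        self.v_ref = self.evaluate(np.ones(len(self.met_index)))

    def evaluate_reaction(self, j: int, u: np.ndarray, E_j: float = 1.0) -> float:
        x = u * self.x_ref
        fwd = self.kf[j]
        for i, p in self._subs[j]:
            fwd *= x[i] ** p
        rev = self.kr[j]
        for i, p in self._prods[j]:
            rev *= x[i] ** p
        return E_j * (fwd - rev)

    def evaluate(self, u: np.ndarray, E: np.ndarray | None = None) -> np.ndarray:
        n = len(self.model.reactions)
        E = np.ones(n) if E is None else E
        return np.array([self.evaluate_reaction(j, u, E[j]) for j in range(n)])

    def involved_metabolites(self, j: int) -> np.ndarray:
        return self._involved[j]
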