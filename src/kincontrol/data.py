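"""Processing of per-condition omics measurements into pipeline inputs.

Two products per growth condition:

* concentration bounds for every model metabolite — measured cytosolic
  species get [50%, 150%] of the measured value; measured mitochondrial
  species get a 100-fold relaxed upper bound (all molecules could sit in
  the ~1% mitochondrial volume); species present in both cytosol and
  mitochondria get a 1e-15 M lower bound in both; unmeasured species get
  the non-informative [1e-15 M, 10 M] box; protons are pinned at 10^-pH;
* a balanced reference flux vector — exchange rates from chemostat
  influent/effluent differences, internal fluxes consumed as a table, and
  drain reactions added/adjusted so every internal metabolite closes its
  mass balance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .model import MetabolicModel, add_drain

__all__ = [
    "Measurement",
    "ConcentrationBounds",
    "ChemostatObservation",
    "ConditionDataset",
    "metabolite_bounds",
    "proton_concentration",
    "chemostat_exchange_flux",
    "balance_with_drains",
    "UNMEASURED_LOWER",
    "UNMEASURED_UPPER",
]

#: Non-informative concentration box for unmeasured metabolites (molar).
UNMEASURED_LOWER = 1e-15
UNMEASURED_UPPER = 10.0

#: Default relative bound factors around a measured concentration.
LOWER_FACTOR = 0.5
UPPER_FACTOR = 1.5

#: Relaxation of the upper bound for mitochondrial measurements
#: (mitochondria occupy ~1% of cell volume; a whole-cell measurement could
#: in the extreme be localised entirely there).
MITO_UPPER_RELAXATION = 100.0


@dataclass(frozen=True)
class Measurement:
    """One metabolite concentration measurement (molar) in one condition."""

    metabolite: str
    concentration: float
    condition: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.concentration) or self.concentration <= 0:
            raise ValueError(
                f"measurement for {self.metabolite!r}: concentration must be > 0, "
                f"got {self.concentration}"
            )


@dataclass
class ConcentrationBounds:
    """Per-metabolite concentration box and reference value (molar)."""

    lower: dict[str, float] = field(default_factory=dict)
    upper: dict[str, float] = field(default_factory=dict)
    reference: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for met in self.lower:
            lo, hi, ref = self.lower[met], self.upper[met], self.reference[met]
            if not (0 < lo <= ref <= hi):
                raise ValueError(
                    f"bounds for {met!r} violate 0 < lower <= reference <= upper: "
                    f"({lo}, {ref}, {hi})"
                )

    def __contains__(self, met: str) -> bool:
        return met in self.lower


@dataclass(frozen=True)
class ChemostatObservation:
    """Influent/effluent concentrations of one exchanged species.

    ``dilution_rate`` D in 1/h, ``biomass_density`` X in gDW/L,
    concentrations in mmol/L.
    """

    species: str
    influent_conc: float
    effluent_conc: float
    dilution_rate: float
    biomass_density: float

    def __post_init__(self) -> None:
        if self.dilution_rate <= 0:
            raise ValueError(f"{self.species}: dilution rate must be > 0")
        if self.biomass_density <= 0:
            raise ValueError(f"{self.species}: biomass density must be > 0")
        if self.influent_conc < 0 or self.effluent_conc < 0:
            raise ValueError(f"{self.species}: negative concentration")


@dataclass
class ConditionDataset:
    """Inputs for sampling one growth condition.

    ``reference_fluxes`` are per-reaction specific rates (mmol/gDW/h)
    balanced so that S_internal . v = 0; ``bounds`` the concentration box;
    ``proton_concentrations`` the pH-pinned proton levels per compartment.
    """

    label: str
    bounds: ConcentrationBounds
    reference_fluxes: dict[str, float]
    dilution_rate: float = 0.0
    proton_concentrations: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "label": self.label,
            "dilution_rate": self.dilution_rate,
            "bounds": {
                m: [self.bounds.lower[m], self.bounds.reference[m], self.bounds.upper[m]]
                for m in self.bounds.lower
            },
            "reference_fluxes": self.reference_fluxes,
            "proton_concentrations": self.proton_concentrations,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ConditionDataset":
        doc = json.loads(Path(path).read_text())
        bounds = ConcentrationBounds()
        for m, (lo, ref, hi) in doc["bounds"].items():
            bounds.lower[m] = lo
            bounds.reference[m] = ref
            bounds.upper[m] = hi
        return cls(
            label=doc["label"],
            bounds=bounds,
            reference_fluxes=doc["reference_fluxes"],
            dilution_rate=doc.get("dilution_rate", 0.0),
            proton_concentrations=doc.get("proton_concentrations", {}),
        )


def proton_concentration(compartment) -> float:
    """Proton concentration (molar) pinned by the compartment pH: 10^-pH."""
    if compartment.pH is None:
        raise ValueError(f"compartment {compartment.id!r} has no pH")
    return 10.0 ** (-compartment.pH)


def metabolite_bounds(
    measurements: Iterable[Measurement],
    model: MetabolicModel,
    mito_compartments: tuple[str, ...] = ("m",),
    mito_relaxation: float = MITO_UPPER_RELAXATION,
) -> ConcentrationBounds:
    """Concentration box for every model metabolite from measurements.

    Rules (applied per metabolite, concentrations molar):

    * measured, cytosolic (or any non-mitochondrial compartment):
      ``[0.5 c, 1.5 c]``, reference = measured value;
    * measured, mitochondrial: ``[1e-15, 100 * 1.5 c]``;
    * species measured and present in both cytosol and mitochondria:
      lower bound 1e-15 for both instances;
    * unmeasured: ``[1e-15, 10]``, reference = geometric mean of bounds;
    * fixed species at a pH-governed proton id: pinned to ``10^-pH``.

    Measurements naming metabolites not in the model are skipped with a
    warning; non-positive concentrations raise at construction.
    """
    by_met: dict[str, float] = {}
    for meas in measurements:
        if meas.metabolite not in model.metabolites:
            warnings.warn(
                f"measurement for unknown metabolite {meas.metabolite!r} skipped",
                stacklevel=2,
            )
            continue
        by_met[meas.metabolite] = meas.concentration

    # species (compartment-free names) present in >1 intracellular compartment
    species_comps: dict[str, set[str]] = {}
    for met in model.metabolites.values():
        comp = model.compartments.get(met.compartment)
        if comp is not None and comp.intracellular:
            species_comps.setdefault(met.species, set()).add(met.compartment)
    dual = {s for s, comps in species_comps.items() if len(comps) > 1}

    bounds = ConcentrationBounds()
    for met in model.metabolites.values():
        if met.id in by_met:
            c = by_met[met.id]
            lo, hi = LOWER_FACTOR * c, UPPER_FACTOR * c
            if met.compartment in mito_compartments:
                lo, hi = UNMEASURED_LOWER, mito_relaxation * hi
            if met.species in dual:
                lo = UNMEASURED_LOWER
            ref = c
        else:
            lo, hi = UNMEASURED_LOWER, UNMEASURED_UPPER
            ref = float(np.sqrt(lo * hi))
        if met.is_fixed and met.species in ("h", "h+", "proton"):
            comp = model.compartments[met.compartment]
            lo = hi = ref = proton_concentration(comp)
        bounds.lower[met.id] = lo
        bounds.upper[met.id] = hi
        bounds.reference[met.id] = ref
    bounds.validate()
    return bounds


def chemostat_exchange_flux(obs: ChemostatObservation) -> float:
    """Specific exchange rate from a chemostat balance (mmol/gDW/h).

    q = D (c_effluent - c_influent) / X.  Positive = net secretion,
    negative = net uptake.
    """
    return (
        obs.dilution_rate
        * (obs.effluent_conc - obs.influent_conc)
        / obs.biomass_density
    )


def balance_with_drains(
    model: MetabolicModel,
    partial_fluxes: Mapping[str, float],
    add_missing: bool = True,
    tol: float = 1e-9,
) -> tuple[MetabolicModel, dict[str, float]]:
    """Close every internal mass balance by assigning/adding drain fluxes.

    ``partial_fluxes`` must cover all non-drain reactions; existing drains
    may be covered too (their values are kept as a starting point).  For
    each internal metabolite with nonzero net production the flux of its
    drain (a ``{met: -1}`` sink, added if absent and ``add_missing``) is set
    so the balance closes.  Returns the (possibly extended) model and the
    complete reference flux vector satisfying ``S_internal . v = 0``.
    """
    for rxn in model.reactions.values():
        if not rxn.is_drain and rxn.id not in partial_fluxes:
            raise ValueError(f"no flux provided for non-drain reaction {rxn.id!r}")

    v = {r: float(partial_fluxes.get(r, 0.0)) for r in model.reactions}
    internal = model.internal_metabolite_ids

    # drains touching exactly one internal metabolite, by metabolite
    drain_of: dict[str, str] = {}
    for rxn in model.reactions.values():
        if rxn.is_drain:
            touched = [m for m in rxn.stoichiometry if m in model.metabolites
                       and not model.metabolites[m].is_fixed]
            if len(touched) == 1:
                drain_of.setdefault(touched[0], rxn.id)

    def residuals(mdl: MetabolicModel, flux: Mapping[str, float]) -> dict[str, float]:
        res = {m: 0.0 for m in mdl.internal_metabolite_ids}
        for rxn in mdl.reactions.values():
            vj = flux[rxn.id]
            for met, coeff in rxn.stoichiometry.items():
                if met in res:
                    res[met] += coeff * vj
        return res

    res = residuals(model, v)
    scale = max((abs(x) for x in v.values()), default=1.0) or 1.0
    new_model = model
    for met in internal:
        r = res[met]
        if abs(r) <= tol * scale:
            continue
        if met in drain_of:
            rxn_id = drain_of[met]
            coeff = new_model.reactions[rxn_id].stoichiometry[met]
            # balance: r + coeff * delta_v = 0
            v[rxn_id] += -r / coeff
        elif add_missing:
            new_model = add_drain(new_model, met)
            v[f"DRAIN_{met}"] = r  # stoichiometry {met: -1}
        else:
            bad = {m: x for m, x in res.items() if abs(x) > tol * scale}
            raise ValueError(
                f"imbalanced metabolites with drain addition disabled: {bad}"
            )

    res = residuals(new_model, v)
    worst = max(abs(x) for x in res.values()) if res else 0.0
    if worst > tol * scale:
        raise AssertionError(f"balancing failed, residual {worst:g}")
    return new_model, v
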