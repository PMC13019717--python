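"""Compartmentalised kinetic model structure and stoichiometry.

A :class:`MetabolicModel` owns compartments, metabolites and reactions
(with kinetic mechanism labels and regulator annotations) and derives the
stoichiometric matrix ``S`` (metabolites x reactions).  Species flagged as
*fixed* (protons held at the compartment pH, extracellular pools) appear in
rate laws and thermodynamic terms but are excluded from mass balancing and
from the dynamic state.

Models round-trip losslessly through a JSON document (canonical format) and
can also be read from a two-table TSV layout (reactions table + metabolites
table) mirroring spreadsheet-style model supplements.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Compartment",
    "Metabolite",
    "Regulation",
    "Reaction",
    "MetabolicModel",
    "ModelStructureError",
    "load_model",
    "load_model_tables",
    "load_model_sbml",
    "parse_reaction_string",
    "format_reaction_string",
    "remove_regulation",
    "add_drain",
    "REGULATION_KINDS",
    "ALLOSTERIC_KINDS",
]

REGULATION_KINDS = frozenset(
    {"competitive_inhibitor", "activator", "allosteric_inhibitor", "allosteric_activator"}
)
ALLOSTERIC_KINDS = frozenset({"allosteric_inhibitor", "allosteric_activator"})


class ModelStructureError(ValueError):
    """A structural inconsistency in a model definition."""


@dataclass(frozen=True)
class Compartment:
    """A cellular compartment.

    ``volume_fraction`` is the fraction of total cell volume occupied by the
    compartment; intracellular fractions must sum to <= 1.  ``pH`` fixes the
    proton concentration of species held at the compartment pH.
    """

    id: str
    pH: float = 7.0
    volume_fraction: float = 1.0
    intracellular: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.pH <= 14.0):
            raise ModelStructureError(f"compartment {self.id!r}: pH {self.pH} outside [0, 14]")
        if not (0.0 < self.volume_fraction <= 1.0):
            raise ModelStructureError(
                f"compartment {self.id!r}: volume fraction {self.volume_fraction} outside (0, 1]"
            )


@dataclass(frozen=True)
class Metabolite:
    """A chemical species located in one compartment.

    ``is_fixed`` marks boundary species (protons, extracellular pools) whose
    concentration is held constant: they contribute to rate laws and Gibbs
    energies but are excluded from mass balance and the dynamic state.
    """

    id: str
    compartment: str
    is_measured: bool = False
    is_fixed: bool = False
    name: str | None = None

    @property
    def species(self) -> str:
        """Compartment-free species name (``pi_c`` -> ``pi``)."""
        if self.name:
            return self.name
        suffix = "_" + self.compartment
        return self.id[: -len(suffix)] if self.id.endswith(suffix) else self.id


@dataclass(frozen=True)
class Regulation:
    """One regulatory interaction of a metabolite on a reaction."""

    reaction: str
    effector: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in REGULATION_KINDS:
            raise ModelStructureError(
                f"regulation {self.reaction}/{self.effector}: unknown kind {self.kind!r} "
                f"(expected one of {sorted(REGULATION_KINDS)})"
            )


@dataclass(frozen=True)
class Reaction:
    """A reaction with signed stoichiometry (negative = substrate).

    ``is_drain`` marks boundary reactions (uptake, secretion, biomass
    precursor sinks); drains are exempt from thermodynamic constraints and
    follow first-order mass-action kinetics.  ``n_subunits`` is the MWC
    subunit count used when the reaction is allosteric.
    """

    id: str
    stoichiometry: Mapping[str, float]
    mechanism: str = "ordered"
    is_drain: bool = False
    regulations: tuple[Regulation, ...] = ()
    n_subunits: int = 4

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelStructureError(f"reaction {self.id!r}: empty stoichiometry")
        if any(c == 0 for c in self.stoichiometry.values()):
            raise ModelStructureError(f"reaction {self.id!r}: zero stoichiometric coefficient")
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))
        object.__setattr__(self, "regulations", tuple(self.regulations))
        if self.n_subunits < 1:
            raise ModelStructureError(f"reaction {self.id!r}: n_subunits must be >= 1")

    @property
    def is_allosteric(self) -> bool:
        return any(r.kind in ALLOSTERIC_KINDS for r in self.regulations)

    @property
    def substrates(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c < 0]

    @property
    def products(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c > 0]


class MetabolicModel:
    """A validated compartmentalised metabolic model.

    Parameters
    ----------
    compartments, metabolites, reactions
        Model components.  Order of metabolites and reactions is preserved
        and defines row/column order of the stoichiometric matrix.
    """

    def __init__(
        self,
        compartments: Iterable[Compartment],
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
    ) -> None:
        self.compartments: dict[str, Compartment] = {}
        for comp in compartments:
            if comp.id in self.compartments:
                raise ModelStructureError(f"duplicate compartment id {comp.id!r}")
            self.compartments[comp.id] = comp
        self.metabolites: dict[str, Metabolite] = {}
        for met in metabolites:
            if met.id in self.metabolites:
                raise ModelStructureError(f"duplicate metabolite id {met.id!r}")
            self.metabolites[met.id] = met
        self.reactions: dict[str, Reaction] = {}
        for rxn in reactions:
            if rxn.id in self.reactions:
                raise ModelStructureError(f"duplicate reaction id {rxn.id!r}")
            self.reactions[rxn.id] = rxn
        self._validate()

    # -- validation ----------------------------------------------------

    def _validate(self) -> None:
        if not self.reactions:
            raise ModelStructureError("no reactions")
        vol = sum(
            c.volume_fraction for c in self.compartments.values() if c.intracellular
        )
        if vol > 1.0 + 1e-12:
            raise ModelStructureError(
                f"intracellular volume fractions sum to {vol:.3f} > 1"
            )
        for met in self.metabolites.values():
            if met.compartment not in self.compartments:
                raise ModelStructureError(
                    f"metabolite {met.id!r}: unknown compartment {met.compartment!r}"
                )
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelStructureError(
                        f"reaction {rxn.id!r}: unknown metabolite {met_id!r} in stoichiometry"
                    )
            for reg in rxn.regulations:
                if reg.reaction != rxn.id:
                    raise ModelStructureError(
                        f"reaction {rxn.id!r}: regulation labelled for {reg.reaction!r}"
                    )
                if reg.effector not in self.metabolites:
                    raise ModelStructureError(
                        f"reaction {rxn.id!r}: unknown effector {reg.effector!r}"
                    )
            if rxn.is_drain:
                internal = [
                    m for m in rxn.stoichiometry if not self.metabolites[m].is_fixed
                ]
                if len(internal) > 1:
                    raise ModelStructureError(
                        f"drain {rxn.id!r} touches {len(internal)} internal metabolites "
                        "(at most one allowed)"
                    )

    # -- derived structure ---------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.metabolites)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    @property
    def internal_metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if not m.is_fixed]

    def stoichiometric_matrix(self, internal_only: bool = False) -> np.ndarray:
        """Signed stoichiometric matrix S (metabolites x reactions).

        With ``internal_only`` the rows of fixed (boundary) species are
        dropped, giving the matrix used for mass balancing.
        """
        mets = self.internal_metabolite_ids if internal_only else self.metabolite_ids
        idx = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(self.reactions)))
        for j, rxn in enumerate(self.reactions.values()):
            for met_id, coeff in rxn.stoichiometry.items():
                if met_id in idx:
                    S[idx[met_id], j] = coeff
        return S

    def summary(self) -> dict[str, int]:
        return {
            "n_reactions": len(self.reactions),
            "n_metabolites": len(self.metabolites),
            "n_compartments": len(self.compartments),
            "n_allosteric": sum(r.is_allosteric for r in self.reactions.values()),
            "n_drains": sum(r.is_drain for r in self.reactions.values()),
            "n_fixed": sum(m.is_fixed for m in self.metabolites.values()),
        }

    # -- equality / serialisation --------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return (
            self.compartments == other.compartments
            and self.metabolites == other.metabolites
            and self.reactions == other.reactions
        )

    def __repr__(self) -> str:
        s = self.summary()
        return (
            f"<MetabolicModel {s['n_reactions']} reactions, {s['n_metabolites']} "
            f"metabolites, {s['n_compartments']} compartments>"
        )

    def to_dict(self) -> dict:
        return {
            "compartments": [
                {
                    "id": c.id,
                    "pH": c.pH,
                    "volume_fraction": c.volume_fraction,
                    "intracellular": c.intracellular,
                }
                for c in self.compartments.values()
            ],
            "metabolites": [
                {
                    "id": m.id,
                    "compartment": m.compartment,
                    "is_measured": m.is_measured,
                    "is_fixed": m.is_fixed,
                    **({"name": m.name} if m.name else {}),
                }
                for m in self.metabolites.values()
            ],
            "reactions": [
                {
                    "id": r.id,
                    "stoichiometry": dict(r.stoichiometry),
                    "mechanism": r.mechanism,
                    "is_drain": r.is_drain,
                    "n_subunits": r.n_subunits,
                    "regulations": [
                        {"effector": g.effector, "kind": g.kind} for g in r.regulations
                    ],
                }
                for r in self.reactions.values()
            ],
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "MetabolicModel":
        compartments = [Compartment(**c) for c in doc.get("compartments", [])]
        metabolites = [Metabolite(**m) for m in doc.get("metabolites", [])]
        reactions = [
            Reaction(
                id=r["id"],
                stoichiometry=r["stoichiometry"],
                mechanism=r.get("mechanism", "ordered"),
                is_drain=r.get("is_drain", False),
                n_subunits=r.get("n_subunits", 4),
                regulations=tuple(
                    Regulation(reaction=r["id"], effector=g["effector"], kind=g["kind"])
                    for g in r.get("regulations", [])
                ),
            )
            for r in doc.get("reactions", [])
        ]
        return cls(compartments, metabolites, reactions)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


# -- reaction string parsing -------------------------------------------

_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?)\s+)?(\S+)\s*$")


def parse_reaction_string(text: str) -> dict[str, float]:
    """Parse ``"glc_c + atp_c -> g6p_c + adp_c"`` into signed stoichiometry.

    Coefficients precede the metabolite id (``"2 adp_c"``).  ``->``, ``<->``
    and ``=`` all separate substrates from products.
    """
    for arrow in ("<->", "->", "<=>", "="):
        if arrow in text:
            lhs, rhs = text.split(arrow, 1)
            break
    else:
        raise ModelStructureError(f"no reaction arrow in {text!r}")
    stoich: dict[str, float] = {}

    def _add(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            m = _TERM_RE.match(term)
            if not m:
                raise ModelStructureError(f"cannot parse term {term!r} in {text!r}")
            coeff = float(m.group(1)) if m.group(1) else 1.0
            met = m.group(2)
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    _add(lhs, -1.0)
    _add(rhs, +1.0)
    return {m: c for m, c in stoich.items() if c != 0.0}


def format_reaction_string(stoich: Mapping[str, float]) -> str:
    def fmt(items: list[tuple[str, float]]) -> str:
        parts = []
        for met, coeff in items:
            c = abs(coeff)
            parts.append(met if c == 1 else f"{c:g} {met}")
        return " + ".join(parts)

    subs = [(m, c) for m, c in stoich.items() if c < 0]
    prods = [(m, c) for m, c in stoich.items() if c > 0]
    return f"{fmt(subs)} -> {fmt(prods)}"


# -- loading -----------------------------------------------------------


def load_model(path: str | Path) -> MetabolicModel:
    """Load a model from its canonical JSON document.

    Raises :class:`ModelStructureError` on unresolvable cross-references or
    duplicate ids, naming the offending reaction or metabolite.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return MetabolicModel.from_dict(json.loads(path.read_text()))


def load_model_tables(reactions_tsv: str | Path, metabolites_tsv: str | Path) -> MetabolicModel:
    """Load a model from the two-table TSV layout.

    The metabolites table has columns ``id, compartment, is_measured,
    is_fixed`` plus one row per compartment in a leading block with columns
    ``compartment_id, pH, volume_fraction, intracellular`` (separate file
    section marked by a ``#compartments`` header line).  The reactions table
    has columns ``id, equation, mechanism, is_drain, n_subunits,
    regulators`` where ``regulators`` is a comma-separated list of
    ``kind:metabolite`` entries.
    """
    import pandas as pd

    met_path = Path(metabolites_tsv)
    text = met_path.read_text().splitlines()
    comp_rows: list[str] = []
    met_rows: list[str] = []
    section = "metabolites"
    for line in text:
        if line.strip().lower() == "#compartments":
            section = "compartments"
            continue
        if line.strip().lower() == "#metabolites":
            section = "metabolites"
            continue
        (comp_rows if section == "compartments" else met_rows).append(line)

    from io import StringIO

    comp_df = pd.read_csv(StringIO("\n".join(comp_rows)), sep="\t")
    met_df = pd.read_csv(StringIO("\n".join(met_rows)), sep="\t")
    rxn_df = pd.read_csv(reactions_tsv, sep="\t").fillna("")

    compartments = [
        Compartment(
            id=str(r["compartment_id"]),
            pH=float(r.get("pH", 7.0)),
            volume_fraction=float(r.get("volume_fraction", 1.0)),
            intracellular=bool(r.get("intracellular", True)),
        )
        for _, r in comp_df.iterrows()
    ]
    metabolites = [
        Metabolite(
            id=str(r["id"]),
            compartment=str(r["compartment"]),
            is_measured=bool(r.get("is_measured", False)),
            is_fixed=bool(r.get("is_fixed", False)),
        )
        for _, r in met_df.iterrows()
    ]
    reactions = []
    for _, r in rxn_df.iterrows():
        regs = []
        if str(r.get("regulators", "")).strip():
            for entry in str(r["regulators"]).split(","):
                kind, _, effector = entry.strip().partition(":")
                regs.append(Regulation(reaction=str(r["id"]), effector=effector, kind=kind))
        reactions.append(
            Reaction(
                id=str(r["id"]),
                stoichiometry=parse_reaction_string(str(r["equation"])),
                mechanism=str(r.get("mechanism", "ordered") or "ordered"),
                is_drain=bool(r.get("is_drain", False)),
                n_subunits=int(r.get("n_subunits", 4) or 4),
                regulations=tuple(regs),
            )
        )
    return MetabolicModel(compartments, metabolites, reactions)


def load_model_sbml(path: str | Path) -> MetabolicModel:
    """Import stoichiometry and compartments from an SBML file.

    Mechanism labels and regulator annotations are not read from SBML; merge
    them from a sidecar table afterwards if needed.
    """
    import cobra.io

    cb = cobra.io.read_sbml_model(str(path))
    compartments = [Compartment(id=cid or "c") for cid in cb.compartments]
    metabolites = [
        Metabolite(id=m.id, compartment=m.compartment or "c", is_fixed=bool(m.boundary_condition) if hasattr(m, "boundary_condition") else False)
        for m in cb.metabolites
    ]
    reactions = [
        Reaction(
            id=r.id,
            stoichiometry={m.id: c for m, c in r.metabolites.items()},
            is_drain=bool(r.boundary),
        )
        for r in cb.reactions
    ]
    return MetabolicModel(compartments, metabolites, reactions)


# -- structural edits --------------------------------------------------


def remove_regulation(model: MetabolicModel, reaction: str, effector: str) -> MetabolicModel:
    """Return a copy of *model* with one (reaction, effector) regulation removed.

    Used for in-silico mechanism perturbations (e.g. removing a phosphate
    inhibition or an allosteric ATP effector).  The original model is left
    unchanged; removing an absent regulation is an error that lists the
    reaction's remaining regulations.
    """
    if reaction not in model.reactions:
        raise ModelStructureError(f"unknown reaction {reaction!r}")
    rxn = model.reactions[reaction]
    kept = tuple(g for g in rxn.regulations if g.effector != effector)
    if len(kept) == len(rxn.regulations):
        existing = [(g.effector, g.kind) for g in rxn.regulations]
        raise ModelStructureError(
            f"no regulation of {reaction!r} by {effector!r}; existing: {existing}"
        )
    new_rxn = replace(rxn, regulations=kept)
    reactions = [new_rxn if r.id == reaction else r for r in model.reactions.values()]
    return MetabolicModel(model.compartments.values(), model.metabolites.values(), reactions)


def add_drain(model: MetabolicModel, metabolite: str, drain_id: str | None = None) -> MetabolicModel:
    """Return a copy of *model* with a sink drain ``{metabolite: -1}`` appended."""
    if metabolite not in model.metabolites:
        raise ModelStructureError(f"unknown metabolite {metabolite!r}")
    drain_id = drain_id or f"DRAIN_{metabolite}"
    if drain_id in model.reactions:
        raise ModelStructureError(f"reaction id {drain_id!r} already exists")
    drain = Reaction(
        id=drain_id,
        stoichiometry={metabolite: -1.0},
        mechanism="mass_action_drain",
        is_drain=True,
    )
    return MetabolicModel(
        model.compartments.values(),
        model.metabolites.values(),
        list(model.reactions.values()) + [drain],
    )
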