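"""Reaction Gibbs-energy ranges and joint flux/Gibbs sampling.

Given standard Gibbs energy ranges (kJ/mol, e.g. eQuilibrator-derived) and
a concentration box per metabolite, each non-drain reaction gets a range of
attainable transformed Gibbs energies

    dG = dG0 + R T sum_i s_ij ln x_i

with the box extrema taken per species by stoichiometric sign.  A
:class:`ThermoSample` is one jointly consistent draw of a reference
log-concentration vector, a standard Gibbs energy per reaction and the
implied dG, restricted so that sign(dG_j) = -sign(v_j) for every flux-
carrying non-drain reaction (the second law at the reference state).
Fluxes are fixed at the condition's balanced reference vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .data import ConditionDataset
from .model import MetabolicModel

__all__ = [
    "ThermoConfig",
    "StandardGibbs",
    "GibbsRange",
    "ThermoSample",
    "ThermoInfeasible",
    "compute_gibbs_ranges",
    "sample_fluxes_and_gibbs",
]

#: Gas constant, kJ/(mol K).
R_GAS = 8.314e-3


@dataclass(frozen=True)
class ThermoConfig:
    """Thermodynamic constants; T defaults to 30 degC (303.15 K)."""

    R: float = R_GAS
    T: float = 303.15

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be > 0 K")

    @property
    def RT(self) -> float:
        return self.R * self.T


@dataclass
class StandardGibbs:
    """Standard Gibbs energy range per reaction (kJ/mol); drains exempt."""

    lo: dict[str, float] = field(default_factory=dict)
    hi: dict[str, float] = field(default_factory=dict)
    source: str = ""

    def validate(self) -> None:
        for rxn in self.lo:
            if self.lo[rxn] > self.hi[rxn]:
                raise ValueError(f"dG0 range for {rxn!r} inverted")

    @classmethod
    def from_tsv(cls, path) -> "StandardGibbs":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        out = cls(source=str(path))
        for _, row in df.iterrows():
            out.lo[str(row["reaction"])] = float(row["dG0_lo"])
            out.hi[str(row["reaction"])] = float(row["dG0_hi"])
        out.validate()
        return out

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"reaction": list(self.lo), "dG0_lo": list(self.lo.values()),
             "dG0_hi": [self.hi[r] for r in self.lo]}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class GibbsRange:
    """Attainable reaction Gibbs energy range at the concentration box.

    Drains carry the unconstrained sentinel (-inf, +inf).
    """

    lo: dict[str, float] = field(default_factory=dict)
    hi: dict[str, float] = field(default_factory=dict)


class ThermoInfeasible(Exception):
    """A reaction whose Gibbs range excludes the flux-consistent sign."""

    def __init__(self, reaction: str, message: str | None = None):
        self.reaction = reaction
        super().__init__(message or f"thermodynamically infeasible reaction {reaction!r}")


@dataclass
class ThermoSample:
    """One consistent draw: fluxes v, Gibbs energies dG, log-concentrations.

    ``dG0`` holds the sampled standard Gibbs energy per reaction so that
    dG_j = dG0_j + RT sum_i s_ij ln_x_i holds exactly.  Drain reactions have
    no entries in ``dG``/``dG0``.
    """

    v: dict[str, float]
    dG: dict[str, float]
    dG0: dict[str, float]
    ln_x: dict[str, float]
    config: ThermoConfig = field(default_factory=ThermoConfig)


def _ln_bounds(dataset: ConditionDataset, met: str) -> tuple[float, float]:
    return (np.log(dataset.bounds.lower[met]), np.log(dataset.bounds.upper[met]))


def compute_gibbs_ranges(
    std: StandardGibbs,
    dataset: ConditionDataset,
    model: MetabolicModel,
    cfg: ThermoConfig | None = None,
) -> GibbsRange:
    """Gibbs energy range per reaction over the concentration box.

    ``dG_lo = dG0_lo + RT * min_box sum_i s_ij ln x_i`` (minimum attained by
    taking the lower bound for substrates-with-positive-coefficient ... i.e.
    per-species extremum chosen by coefficient sign), ``dG_hi`` analogously.
    A missing dG0 range for a non-drain reaction is an error.
    """
    cfg = cfg or ThermoConfig()
    out = GibbsRange()
    for rxn in model.reactions.values():
        if rxn.is_drain:
            out.lo[rxn.id] = -np.inf
            out.hi[rxn.id] = np.inf
            continue
        if rxn.id not in std.lo:
            raise ValueError(f"missing standard Gibbs energy range for reaction {rxn.id!r}")
        lo_sum = 0.0
        hi_sum = 0.0
        for met, coeff in rxn.stoichiometry.items():
            ln_lo, ln_hi = _ln_bounds(dataset, met)
            if coeff > 0:
                lo_sum += coeff * ln_lo
                hi_sum += coeff * ln_hi
            else:
                lo_sum += coeff * ln_hi
                hi_sum += coeff * ln_lo
        out.lo[rxn.id] = std.lo[rxn.id] + cfg.RT * lo_sum
        out.hi[rxn.id] = std.hi[rxn.id] + cfg.RT * hi_sum
    return out


def sample_fluxes_and_gibbs(
    dataset: ConditionDataset,
    std: StandardGibbs,
    model: MetabolicModel,
    rng: np.random.Generator,
    cfg: ThermoConfig | None = None,
    zero_flux_tol: float = 1e-12,
) -> ThermoSample:
    """Draw one thermodynamically consistent (v, dG, ln_x) triple.

    Fluxes are fixed at the dataset's balanced reference vector.  The
    log-concentration vector is drawn uniformly in its box; per reaction the
    standard Gibbs energy is then drawn uniformly from the subinterval of
    its range compatible with sign(dG) = -sign(v) (truncated sampling).  An
    empty subinterval raises :class:`ThermoInfeasible` naming the reaction —
    callers count it as one failed sampling attempt.
    """
    cfg = cfg or ThermoConfig()
    ln_x: dict[str, float] = {}
    for met in model.metabolites:
        ln_lo, ln_hi = _ln_bounds(dataset, met)
        ln_x[met] = ln_lo if ln_lo == ln_hi else rng.uniform(ln_lo, ln_hi)

    v = {r: float(dataset.reference_fluxes.get(r, 0.0)) for r in model.reactions}
    dG: dict[str, float] = {}
    dG0: dict[str, float] = {}
    for rxn in model.reactions.values():
        if rxn.is_drain:
            continue
        if rxn.id not in std.lo:
            raise ValueError(f"missing standard Gibbs energy range for reaction {rxn.id!r}")
        q = sum(c * ln_x[m] for m, c in rxn.stoichiometry.items())
        lo = std.lo[rxn.id] + cfg.RT * q
        hi = std.hi[rxn.id] + cfg.RT * q
        vj = v[rxn.id]
        # strict sign: dG must oppose the flux direction (open interval at 0,
        # realised by a tiny exclusion so a degenerate draw cannot land on 0)
        if vj > zero_flux_tol:
            hi = min(hi, -1e-12)
        elif vj < -zero_flux_tol:
            lo = max(lo, 1e-12)
        if lo > hi:
            raise ThermoInfeasible(
                rxn.id,
                f"reaction {rxn.id!r}: flux {vj:g} requires dG in "
                f"[{'-inf' if vj > 0 else '0'}, {'0' if vj > 0 else '+inf'}] but "
                f"attainable range at the sampled concentrations is empty",
            )
        g = lo if lo == hi else rng.uniform(lo, hi)
        dG[rxn.id] = g
        dG0[rxn.id] = g - cfg.RT * q
    return ThermoSample(v=v, dG=dG, dG0=dG0, ln_x=ln_x, config=cfg)
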