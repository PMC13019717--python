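"""Elementary-step kinetic mechanism patterns.

Every non-drain reaction is expanded into a cycle of elementary steps over
enzyme forms (free enzyme, substrate- and product-bound complexes) in the
King-Altman tradition:

* substrates bind in declared order, one elementary step each;
* a single catalytic interconversion step;
* products release in declared order;
* essential activators wrap the cycle (bind before the first substrate,
  release after the last product);
* competitive inhibitors sit on dead-end branches off the free enzyme.

Species flagged fixed in the model (protons, boundary pools) take part in
binding steps like any other species — their concentration is simply
pinned, so their pseudo-first-order factor is constant.  Stoichiometric
multiplicities > 1 become repeated binding events and must be integral.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import MetabolicModel, Reaction

__all__ = ["ElementaryStep", "MechanismPattern", "MechanismError", "build_mechanism"]


class MechanismError(ValueError):
    pass


@dataclass(frozen=True)
class ElementaryStep:
    """One reversible elementary transition between two enzyme forms.

    ``bound`` metabolites are consumed in the forward direction, ``released``
    are produced; the reverse direction swaps the roles.
    """

    source: str
    target: str
    bound: tuple[str, ...] = ()
    released: tuple[str, ...] = ()
    catalytic: bool = False
    dead_end: bool = False


@dataclass(frozen=True)
class MechanismPattern:
    """Connected cycle of elementary steps plus dead-end inhibitor branches."""

    reaction: str
    forms: tuple[str, ...]
    steps: tuple[ElementaryStep, ...]

    @property
    def cycle_steps(self) -> tuple[ElementaryStep, ...]:
        return tuple(s for s in self.steps if not s.dead_end)

    @property
    def dead_end_steps(self) -> tuple[ElementaryStep, ...]:
        return tuple(s for s in self.steps if s.dead_end)

    @property
    def catalytic_index(self) -> int:
        for i, s in enumerate(self.steps):
            if s.catalytic:
                return i
        raise MechanismError(f"{self.reaction}: no catalytic step")

    def net_traversal(self) -> dict[str, float]:
        """Net metabolite turnover of one forward cycle traversal."""
        net: dict[str, float] = {}
        for s in self.cycle_steps:
            for m in s.bound:
                net[m] = net.get(m, 0.0) - 1.0
            for m in s.released:
                net[m] = net.get(m, 0.0) + 1.0
        return {m: c for m, c in net.items() if c != 0.0}


def _expand(ids: list[str], stoich, sign: int) -> list[str]:
    out: list[str] = []
    for met in ids:
        coeff = abs(stoich[met])
        n = int(round(coeff))
        if abs(coeff - n) > 1e-9:
            raise MechanismError(
                f"non-integer stoichiometric coefficient {coeff} for {met!r} "
                "in a mechanistic reaction"
            )
        out.extend([met] * n)
    return out


def build_mechanism(reaction: Reaction, model: MetabolicModel) -> MechanismPattern:
    """Build the ordered elementary-step pattern for one reaction.

    The builder validates that the net cycle traversal reproduces the
    reaction's stoichiometry (restricted to non-fixed species) and that the
    declared competitive inhibitors appear on exactly the dead-end branches.
    """
    if reaction.is_drain:
        raise MechanismError(f"{reaction.id}: drains have no elementary mechanism")

    subs = _expand(reaction.substrates, reaction.stoichiometry, -1)
    prods = _expand(reaction.products, reaction.stoichiometry, +1)

    activators = [g.effector for g in reaction.regulations if g.kind == "activator"]
    inhibitors = [g.effector for g in reaction.regulations if g.kind == "competitive_inhibitor"]

    # event list around the cycle: (bound, released, catalytic)
    events: list[tuple[tuple[str, ...], tuple[str, ...], bool]] = []
    for a in activators:
        events.append(((a,), (), False))
    for s in subs:
        events.append(((s,), (), False))
    events.append(((), (), True))
    for p in prods:
        events.append(((), (p,), False))
    for a in reversed(activators):
        events.append(((), (a,), False))

    n = len(events)
    forms = tuple(f"F{i}" for i in range(n))
    steps = [
        ElementaryStep(
            source=forms[i],
            target=forms[(i + 1) % n],
            bound=ev[0],
            released=ev[1],
            catalytic=ev[2],
        )
        for i, ev in enumerate(events)
    ]
    all_forms = list(forms)
    for k, inh in enumerate(inhibitors):
        dead_form = f"FI{k}"
        all_forms.append(dead_form)
        steps.append(
            ElementaryStep(source=forms[0], target=dead_form, bound=(inh,), dead_end=True)
        )

    pattern = MechanismPattern(reaction=reaction.id, forms=tuple(all_forms), steps=tuple(steps))

    expected = dict(reaction.stoichiometry)
    net = pattern.net_traversal()
    if net != expected:
        raise MechanismError(
            f"{reaction.id}: mechanism net traversal {net} does not match "
            f"stoichiometry {expected}"
        )
    return pattern
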