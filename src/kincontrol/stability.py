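"""Jacobian construction and linear-stability filtering.

The dynamic state is the vector of internal (non-fixed) metabolite
concentrations, normalised to the reference (u = x / x_ref).  Conserved
moieties are removed through the link-matrix decomposition S = L S_R before
eigenvalues are taken, so structural zero modes do not contaminate the
stability call.  An instance is *stable* when the largest real part of the
reduced Jacobian's eigenvalues is strictly below the threshold (default
1e-5, in the reciprocal time units of the flux scale); the small positive
threshold additionally tolerates numerically-zero modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "JacobianReport",
    "reduce_stoichiometry",
    "jacobian_at_reference",
    "stability_filter",
    "STABILITY_THRESHOLD",
]

STABILITY_THRESHOLD = 1e-5


def reduce_stoichiometry(S: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Link-matrix decomposition S = L @ S_R removing dependent rows.

    Returns ``(independent_row_indices, S_R, L)`` where ``S_R`` stacks a
    maximal independent subset of rows (in original order) and
    ``L[independent_rows] = I``.  Rows of S that are linear combinations of
    others correspond to conserved moieties.
    """
    if S.size == 0:
        raise ValueError("empty stoichiometric matrix")
    _, R, piv = scipy.linalg.qr(S.T, pivoting=True, mode="economic")
    diag = np.abs(np.diag(R))
    tol = max(S.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol)) if diag.size else 0
    if rank == 0:
        raise ValueError("stoichiometric matrix has rank 0")
    idx = np.sort(piv[:rank])
    S_R = S[idx, :]
    L = S @ np.linalg.pinv(S_R)
    if not np.allclose(L @ S_R, S, atol=1e-8 * max(1.0, np.abs(S).max())):
        raise np.linalg.LinAlgError("link-matrix decomposition failed")
    return idx, S_R, L


@dataclass
class JacobianReport:
    """Reduced Jacobian, its spectrum and the stability verdict."""

    J: np.ndarray
    eigenvalues: np.ndarray
    max_real: float
    stable: bool
    threshold: float = STABILITY_THRESHOLD
    instance_id: int | None = None


def jacobian_at_reference(
    system,
    u: np.ndarray | None = None,
    E: np.ndarray | None = None,
    threshold: float = STABILITY_THRESHOLD,
    instance_id: int | None = None,
) -> JacobianReport:
    """Reduced metabolite Jacobian J = S_R (dv/du) L and its eigenvalues.

    *system* is any kinetic system exposing ``model``, ``x_ref``,
    ``evaluate_reaction`` and ``involved_metabolites`` (a
    :class:`~kincontrol.sampler.KineticInstance` or a hand-written
    mass-action system).
    """
    from .mca import elasticities, internal_reduction

    model = system.model
    u = np.ones(len(model.metabolite_ids)) if u is None else u
    eps, iint, S_u, idx, S_R, L = internal_reduction(system, u, E)
    J = S_R @ eps[:, iint] @ L
    lam = np.linalg.eigvals(J)
    max_real = float(np.max(lam.real)) if lam.size else -np.inf
    return JacobianReport(
        J=J,
        eigenvalues=lam,
        max_real=max_real,
        stable=bool(max_real < threshold),
        threshold=threshold,
        instance_id=instance_id,
    )


def stability_filter(reports) -> tuple[list, list]:
    """Partition Jacobian reports into (stable, unstable) by their flag."""
    stable = [r for r in reports if r.stable]
    unstable = [r for r in reports if not r.stable]
    return stable, unstable
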