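"""Metabolic control analysis: elasticities and flux control coefficients.

The scaled flux control coefficient of enzyme E_k over steady-state flux
J_i is C^{J_i}_{E_k} = (dJ_i / J_i) / (dE_k / E_k).  The analytic route
uses the standard MCA matrix identities: with elasticities eps = dv/du at
the reference state and the moiety-reduced stoichiometry S = L S_R,

    dxi/dE_k = -(S_R eps L)^{-1} S_R  dv/dE_k
    dJ/dE_k  = dv/dE_k + eps L dxi/dE_k

with dv_j/dE_k = delta_jk v_j / E_k (rates linear in enzyme level).  The
rows of the scaled matrix obey the summation theorem (sum_k C = 1).

A finite-difference route — perturb one enzyme level, re-solve the steady
state (damped Newton with an ODE-integration fallback), difference the log
fluxes — serves as the independent oracle for the analytic path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.integrate

from .stability import STABILITY_THRESHOLD, reduce_stoichiometry

__all__ = [
    "ElasticityMatrix",
    "ControlCoefficientMatrix",
    "SteadyStateError",
    "UnstableInstanceError",
    "elasticities",
    "flux_control_coefficients",
    "finite_difference_control",
    "solve_steady_state",
]

#: Fluxes below this fraction of the flux scale are treated as zero; their
#: scaled control-coefficient rows are undefined (NaN) and excluded from
#: ensemble medians.
ZERO_FLUX_FRACTION = 1e-12


class SteadyStateError(RuntimeError):
    pass


class UnstableInstanceError(RuntimeError):
    """Finite-difference control requested on a linearly unstable instance."""


@dataclass
class ElasticityMatrix:
    """Unscaled dv/du and its (v, u)-scaled variant at an operating point."""

    unscaled: np.ndarray  # n_rxn x n_met, derivative wrt normalised u
    scaled: np.ndarray  # elasticity coefficients dln v / dln u (NaN where v=0)
    metabolite_ids: list[str]
    reaction_ids: list[str]


@dataclass
class ControlCoefficientMatrix:
    """Scaled flux control coefficients (rows = fluxes, cols = enzymes)."""

    C: np.ndarray
    flux_ids: list[str]
    enzyme_ids: list[str]
    instance_id: int | None = None

    def row_sums(self) -> np.ndarray:
        return np.nansum(self.C, axis=1)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.C, index=self.flux_ids, columns=self.enzyme_ids)


def elasticities(
    system,
    u: np.ndarray | None = None,
    E: np.ndarray | None = None,
    h: float = 1e-6,
) -> np.ndarray:
    """Unscaled elasticity matrix dv/du by central differences in ln u.

    Only metabolites a reaction's rate law can depend on are perturbed
    (binding partners, effectors, drain substrates); all other entries are
    structural zeros.
    """
    model = system.model
    n_rxn = len(model.reactions)
    n_met = len(model.metabolites)
    u = np.ones(n_met) if u is None else np.asarray(u, dtype=float)
    E = np.ones(n_rxn) if E is None else np.asarray(E, dtype=float)
    eps = np.zeros((n_rxn, n_met))
    up, dn = np.exp(h), np.exp(-h)
    for j in range(n_rxn):
        for i in system.involved_metabolites(j):
            u_p = u.copy()
            u_p[i] = u[i] * up
            u_m = u.copy()
            u_m[i] = u[i] * dn
            dv_dlnu = (
                system.evaluate_reaction(j, u_p, E[j])
                - system.evaluate_reaction(j, u_m, E[j])
            ) / (2.0 * h)
            eps[j, i] = dv_dlnu / u[i]
    return eps


def elasticity_matrix(system, u=None, E=None, h: float = 1e-6) -> ElasticityMatrix:
    """Elasticities with the (x_ref/v_ref)-scaled variant attached."""
    model = system.model
    u_arr = np.ones(len(model.metabolites)) if u is None else np.asarray(u, float)
    eps = elasticities(system, u, E, h)
    v = system.evaluate(u_arr, E)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = eps * u_arr[None, :] / v[:, None]
    scaled[np.abs(v) < ZERO_FLUX_FRACTION * (np.max(np.abs(v)) or 1.0), :] = np.nan
    return ElasticityMatrix(
        unscaled=eps,
        scaled=scaled,
        metabolite_ids=model.metabolite_ids,
        reaction_ids=model.reaction_ids,
    )


def reduction_structure(system):
    """Moiety-reduced internal stoichiometry in normalised-concentration units.

    Returns ``(internal_indices, S_u, independent_idx, S_R, L)`` where
    ``S_u`` is the internal stoichiometry scaled to normalised-concentration
    dynamics (rows divided by x_ref) and ``S_u = L @ S_R``.
    """
    iint, S_u, idx, S_R, L, _ = _full_reduction(system)
    return iint, S_u, idx, S_R, L


def _full_reduction(system):
    """As :func:`reduction_structure` plus the *unscaled* independent rows.

    Reference concentrations can legitimately span many decades (relaxed
    mitochondrial bounds reach 1e-15 M), which makes the 1/x_ref-scaled
    residual catastrophically ill-conditioned; steady-state residuals and
    the MCA linear solve therefore use the unscaled rows ``S_R_raw`` (same
    row selection — diagonal scaling preserves row independence) while the
    scaled pair (S_R, L) defines the dynamics and its conserved manifold.
    """
    model = system.model
    met_ids = model.metabolite_ids
    iint = np.array(
        [i for i, m in enumerate(met_ids) if not model.metabolites[m].is_fixed],
        dtype=int,
    )
    S_int = model.stoichiometric_matrix(internal_only=True)
    x_ref_int = np.asarray(system.x_ref, dtype=float)[iint]
    S_u = S_int / x_ref_int[:, None]
    idx, S_R, L = reduce_stoichiometry(S_u)
    S_R_raw = S_int[idx, :]
    return iint, S_u, idx, S_R, L, S_R_raw


def internal_reduction(system, u: np.ndarray, E: np.ndarray | None):
    """Elasticities plus the moiety-reduced internal stoichiometry."""
    eps = elasticities(system, u, E)
    iint, S_u, idx, S_R, L = reduction_structure(system)
    return eps, iint, S_u, idx, S_R, L


def flux_control_coefficients(
    system,
    u: np.ndarray | None = None,
    E: np.ndarray | None = None,
    instance_id: int | None = None,
) -> ControlCoefficientMatrix:
    """Scaled flux control coefficient matrix at an operating point.

    The operating point defaults to the instance's reference state (u = 1,
    E = 1), which is a steady state by construction.  Rows belonging to
    zero-flux reactions are NaN (scaled coefficients undefined).
    """
    model = system.model
    n_rxn = len(model.reactions)
    n_met = len(model.metabolites)
    u = np.ones(n_met) if u is None else np.asarray(u, dtype=float)
    E = np.ones(n_rxn) if E is None else np.asarray(E, dtype=float)

    eps = elasticities(system, u, E)
    iint, S_u, idx, S_R, L, S_R_raw = _full_reduction(system)
    eps_int = eps[:, iint]
    v = system.evaluate(u, E)
    M = S_R_raw @ eps_int @ L
    dvdE = np.diag(v / E)  # dv_j/dE_k = delta_jk v_j / E_k
    try:
        X = -np.linalg.solve(M, S_R_raw @ dvdE)
    except np.linalg.LinAlgError as exc:
        raise SteadyStateError(
            f"singular reduced Jacobian for instance {instance_id}: {exc}"
        ) from exc
    dJdE = dvdE + eps_int @ L @ X
    scale = np.max(np.abs(v)) or 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        C = dJdE * E[None, :] / v[:, None]
    C[np.abs(v) < ZERO_FLUX_FRACTION * scale, :] = np.nan
    return ControlCoefficientMatrix(
        C=C,
        flux_ids=model.reaction_ids,
        enzyme_ids=model.reaction_ids,
        instance_id=instance_id,
    )


def solve_steady_state(
    system,
    E: np.ndarray,
    u0: np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 60,
) -> np.ndarray:
    """Steady state u* with S_internal v(u*, E) = 0, moiety totals from u0.

    Damped Newton in the reduced coordinates (u = u0 + L xi), with an
    ODE-integration fallback towards the attractor before a final Newton
    polish.  Raises :class:`SteadyStateError` on non-convergence.
    """
    model = system.model
    n_met = len(model.metabolites)
    u0 = np.ones(n_met) if u0 is None else np.asarray(u0, dtype=float)
    iint, S_u, idx, S_R, L, S_R_raw = _full_reduction(system)
    # residual scale: the largest row of |S_R| |v| — what a completely
    # unbalanced flux vector of this magnitude would produce
    v0 = system.evaluate(u0, E)
    g_scale = max(float(np.max(np.abs(S_R_raw) @ np.abs(v0))), 1e-30)

    def newton(u_start: np.ndarray) -> np.ndarray | None:
        u = u_start.copy()
        g = S_R_raw @ system.evaluate(u, E)
        for _ in range(max_iter):
            if np.linalg.norm(g, np.inf) <= tol * g_scale:
                return u
            eps = elasticities(system, u, E)
            M = S_R_raw @ eps[:, iint] @ L
            try:
                step = -np.linalg.solve(M, g)
            except np.linalg.LinAlgError:
                return None
            du = L @ step
            alpha = 1.0
            improved = False
            while alpha > 1e-8:
                u_new = u.copy()
                u_new[iint] = u[iint] + alpha * du
                if np.all(u_new[iint] > 0):
                    g_new = S_R_raw @ system.evaluate(u_new, E)
                    if np.linalg.norm(g_new, np.inf) < np.linalg.norm(g, np.inf):
                        u, g = u_new, g_new
                        improved = True
                        break
                alpha *= 0.5
            at_noise_floor = np.linalg.norm(du, np.inf) < 1e-11
            if at_noise_floor and np.linalg.norm(g, np.inf) <= 1e-6 * g_scale:
                return u  # stalled at the floating-point noise floor
            if not improved:
                return None
        return None

    u_star = newton(u0)
    if u_star is not None:
        return u_star

    # fallback: relax towards the attractor by integration, then polish
    flux_scale = max(np.max(np.abs(v0)), 1e-12)

    def rhs(_t, y):
        u = u0.copy()
        u[iint] = np.maximum(y, 1e-12)
        return S_u @ system.evaluate(u, E)

    y = u0[iint].copy()
    t_end = 10.0 / flux_scale
    for _ in range(12):
        sol = scipy.integrate.solve_ivp(
            rhs, (0.0, t_end), y, method="LSODA", rtol=1e-9, atol=1e-11
        )
        if not sol.success:
            break
        y = sol.y[:, -1]
        u = u0.copy()
        u[iint] = np.maximum(y, 1e-12)
        u_star = newton(u)
        if u_star is not None:
            return u_star
        t_end *= 4.0
    raise SteadyStateError("steady-state re-solve did not converge")


def finite_difference_control(
    system,
    delta: float = 1e-6,
    u: np.ndarray | None = None,
    E: np.ndarray | None = None,
    check_stability: bool = True,
    instance_id: int | None = None,
) -> ControlCoefficientMatrix:
    """Flux control coefficients by enzyme perturbation and re-solution.

    For each enzyme k the level is scaled by (1 + delta), the steady state
    re-solved, and C estimated as Delta ln J_i / Delta ln E_k.  Requires
    ``0 < delta <= 1e-3``.  Linearly unstable instances are refused
    (:class:`UnstableInstanceError`) unless ``check_stability=False`` —
    their perturbed states are not attractors and a relaxation-based
    re-solve would not report anything meaningful.
    """
    if not (0.0 < delta <= 1e-3):
        raise ValueError(f"delta must be in (0, 1e-3], got {delta}")
    model = system.model
    n_rxn = len(model.reactions)
    n_met = len(model.metabolites)
    u = np.ones(n_met) if u is None else np.asarray(u, dtype=float)
    E = np.ones(n_rxn) if E is None else np.asarray(E, dtype=float)

    if check_stability:
        from .stability import jacobian_at_reference

        rep = jacobian_at_reference(system, u=u, E=E)
        if not rep.stable:
            raise UnstableInstanceError(
                f"instance {instance_id}: max Re(lambda) = {rep.max_real:g} "
                f">= {rep.threshold:g}"
            )

    v0 = system.evaluate(u, E)
    scale = np.max(np.abs(v0)) or 1.0
    C = np.full((n_rxn, n_rxn), np.nan)
    dlnE = np.log1p(delta)
    for k in range(n_rxn):
        E_p = E.copy()
        E_p[k] = E[k] * (1.0 + delta)
        try:
            u_star = solve_steady_state(system, E_p, u0=u)
        except SteadyStateError as exc:
            raise SteadyStateError(
                f"enzyme {model.reaction_ids[k]!r}, instance {instance_id}: {exc}"
            ) from exc
        v1 = system.evaluate(u_star, E_p)
        for i in range(n_rxn):
            if abs(v0[i]) < ZERO_FLUX_FRACTION * scale:
                continue  # scaled coefficient undefined
            if v1[i] * v0[i] <= 0:
                continue  # flux sign changed; log-difference undefined
            C[i, k] = (np.log(abs(v1[i])) - np.log(abs(v0[i]))) / dlnE
    return ControlCoefficientMatrix(
        C=C,
        flux_ids=model.reaction_ids,
        enzyme_ids=model.reaction_ids,
        instance_id=instance_id,
    )
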