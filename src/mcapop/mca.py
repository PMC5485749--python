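"""Control-coefficient computation, stability filtering, and response predictions.

Flux and concentration control coefficients are the scaled steady-state
sensitivities ``C_q^J = d ln J / d ln q`` and ``C_q^x = d ln x / d ln q`` for
parameters ``q`` (enzyme activities, one per reaction, with parameter
elasticity 1).  They are computed through the reduced-Jacobian (link-matrix)
formalism so conserved moieties are handled exactly:

    A  = N_R diag(v)                    (flux-scaled reduced stoichiometry)
    Lt = diag(1/x) L diag(x_i)          (concentration-scaled link matrix)
    C_x = -(A E Lt)^{-1} A              (independent concentration control)
    C_v = I + E Lt C_x                  (flux control)

The summation theorems (flux rows sum to 1, concentration rows to 0) hold by
construction because ``A 1 = N_R v = 0`` at steady state.  Only samples whose
reduced Jacobian has all eigenvalue real parts < 0 are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import ReducedStructure
from .thermo import FluxProfile

#: eigenvalues with real part above this are treated as unstable or marginal
STABILITY_TOL = -1e-12


class DegenerateSampleError(RuntimeError):
    """Reduced Jacobian numerically singular for this elasticity sample."""


@dataclass
class ControlSample:
    """One sampled linearization's control coefficients.

    ``C_flux`` is n x n (target flux x enzyme parameter); ``C_conc`` is
    m_indep x n over the independent internal metabolites.
    """

    reaction_ids: list[str]
    met_ids: list[str]  # independent internal metabolites
    C_flux: np.ndarray
    C_conc: np.ndarray
    stable: bool
    eigenvalues: np.ndarray
    provenance: tuple = ()

    def flux_cc(self, parameter: str, target: str) -> float:
        return float(
            self.C_flux[self.reaction_ids.index(target), self.reaction_ids.index(parameter)]
        )

    def conc_cc(self, parameter: str, target_met: str) -> float:
        return float(self.C_conc[self.met_ids.index(target_met), self.reaction_ids.index(parameter)])


def _scaled_operators(
    reduced: ReducedStructure, v: np.ndarray, E: np.ndarray, concentrations: np.ndarray | None
):
    NR = reduced.reduced_matrix
    L = reduced.link_matrix
    mi = NR.shape[0]
    if concentrations is None:
        x = np.ones(L.shape[0])
    else:
        x = np.asarray(concentrations, dtype=float)
    xi = x[reduced.independent_rows]
    A = NR * v[None, :]
    Lt = (L * (1.0 / x)[:, None]) * xi[None, :]
    return A, Lt, xi


def control_coefficients(
    reduced: ReducedStructure,
    v: FluxProfile | np.ndarray,
    E: np.ndarray,
    concentrations: np.ndarray | None = None,
    reaction_ids: list[str] | None = None,
    met_ids: list[str] | None = None,
    provenance: tuple = (),
    cond_max: float = 1e12,
) -> ControlSample:
    """Flux and concentration control coefficients for one elasticity sample.

    ``v`` is a steady-state flux vector (or profile), ``E`` the n x m scaled
    elasticity matrix over internal metabolites, ``concentrations`` the
    matching internal metabolite levels (ones when absent or when the model
    has no conserved moieties, where they cancel).
    """
    if isinstance(v, FluxProfile):
        reaction_ids = reaction_ids or v.reaction_ids
        v = v.v
    v = np.asarray(v, dtype=float)
    A, Lt, xi = _scaled_operators(reduced, v, E, concentrations)
    M = A @ E @ Lt
    if not np.all(np.isfinite(M)) or np.linalg.cond(M) > cond_max:
        raise DegenerateSampleError("singular reduced Jacobian; sample excluded")
    C_x = -np.linalg.solve(M, A)
    C_v = np.eye(len(v)) + E @ Lt @ C_x
    # Jacobian in time units: M scaled back by the independent concentrations
    J = M * (1.0 / xi)[None, :]
    eig = np.linalg.eigvals(J)
    stable = bool(np.max(eig.real) < STABILITY_TOL)
    n_ids = reaction_ids or [f"r{j}" for j in range(len(v))]
    m_ids = met_ids or [f"m{i}" for i in reduced.independent_rows]
    return ControlSample(
        reaction_ids=list(n_ids),
        met_ids=list(m_ids),
        C_flux=C_v,
        C_conc=C_x,
        stable=stable,
        eigenvalues=eig,
        provenance=provenance,
    )


def stability_check(
    reduced: ReducedStructure,
    v: np.ndarray,
    E: np.ndarray,
    concentrations: np.ndarray | None = None,
) -> tuple[bool, np.ndarray]:
    """Stability of the linearized system, built element-wise.

    Deliberately assembles the reduced Jacobian by explicit loops over the
    unscaled derivatives ``dv_j/dx_k = v_j * E_jk / x_k`` rather than through
    the matrix pipeline above, so it can serve as an independent check of the
    retain/reject decision.
    """
    NR = reduced.reduced_matrix
    L = reduced.link_matrix
    mi, n = NR.shape
    mfull = L.shape[0]
    x = np.ones(mfull) if concentrations is None else np.asarray(concentrations, float)
    dvdx = np.zeros((n, mfull))
    for j in range(n):
        for k in range(mfull):
            dvdx[j, k] = v[j] * E[j, k] / x[k]
    J = np.zeros((mi, mi))
    for i in range(mi):
        for c in range(mi):
            acc = 0.0
            for j in range(n):
                for k in range(mfull):
                    acc += NR[i, j] * dvdx[j, k] * L[k, c]
            J[i, c] = acc
    eig = np.linalg.eigvals(J)
    return bool(np.max(eig.real) < STABILITY_TOL), eig


@dataclass
class TurnoverCC:
    metabolite: str
    tMet: float
    C_turnover: dict[str, float]


def turnover_control(
    sample: ControlSample,
    flux: FluxProfile,
    metabolite: str,
    producing: list[str],
    parameters: list[str] | None = None,
) -> TurnoverCC:
    """Turnover control coefficients of a metabolite.

    The turnover ``tMet`` is the summed producing flux; its control
    coefficient under parameter q is the flux-weighted sum
    ``sum_i (v_i/tMet) * C_q^{v_i}`` over the producing reactions.
    """
    v_prod = {rid: flux.flux(rid) for rid in producing}
    if any(val < 0 for val in v_prod.values()):
        raise ValueError("producing fluxes must be oriented non-negative toward the metabolite")
    tmet = sum(v_prod.values())
    if tmet <= 0:
        raise ValueError(f"zero turnover for {metabolite}")
    params = parameters or sample.reaction_ids
    cc = {
        q: sum(v_prod[rid] / tmet * sample.flux_cc(q, rid) for rid in producing) for q in params
    }
    return TurnoverCC(metabolite=metabolite, tMet=tmet, C_turnover=cc)


def respond(C: float, activity_change_pct: float, mode: str = "linear") -> float:
    """Predicted percent change of a flux/concentration for an enzyme-activity change.

    The default is the linear interpretation of the control coefficient:
    ``predicted % = C * (% activity change)`` (a coefficient of 0.29 and a
    twofold increase, +100%, predict +29%).  ``mode='power'`` applies the
    log-linear extrapolation ``(fold^C - 1) * 100`` instead (non-default).
    """
    if mode == "linear":
        return C * activity_change_pct
    if mode == "power":
        fold = 1.0 + activity_change_pct / 100.0
        if fold <= 0:
            raise ValueError("power-law response needs a positive fold change")
        return (fold**C - 1.0) * 100.0
    raise ValueError(f"unknown response mode {mode!r}")
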