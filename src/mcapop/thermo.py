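"""Thermodynamics-based flux analysis and concentration sampling.

The first two stages of the model-population workflow:

1. **TFA** -- an FBA problem augmented with Gibbs-energy constraints.  For
   every reaction with a standard Gibbs energy the reaction energy is
   ``dG_r = dG0_r + RT * sum_i s_ir * ln(x_i)`` and a binary direction
   indicator couples ``sign(v_r)`` to ``sign(dG_r)`` through big-M
   constraints, so that net flux always runs downhill.  Encoded as a MILP and
   solved with HiGHS via :func:`scipy.optimize.milp`.

2. **Concentration sampling** -- given a TFA-feasible flux profile, the set of
   log-concentration vectors compatible with all bounds and all directional
   dG constraints is a convex polytope; a hit-and-run Markov chain walks it
   and yields displacement profiles (log-concentrations plus per-reaction
   thermodynamic displacement ``Gamma = exp(dG/RT)`` in the direction of net
   flux).

The displacement ``Gamma`` quantifies distance from equilibrium:
``Gamma = (1/K_eq) * prod(P_j) / prod(S_i)`` so ``Gamma -> 1`` at
equilibrium and ``dG = RT ln Gamma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import LinearConstraint, Bounds, linprog, milp

from .network import NetworkModel

#: ideal gas constant, kJ/mol/K
R_KJ = 8.314e-3
#: default temperature (cultivation at 30 C); kelvins
DEFAULT_T = 303.15
#: minimal driving force used to keep strict inequalities away from zero, kJ/mol
DG_EPSILON = 1e-3

#: species conventionally held at activity 1 and excluded from Gamma
DEFAULT_EXCLUDED = frozenset({"h_c", "h_m", "h_e", "h2o_c", "h2o_m", "h2o_e"})


class TfaInfeasibleError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# scalar displacement relations
# ---------------------------------------------------------------------------

def displacement(
    K_eq: float,
    substrate_concs: dict[str, float],
    product_concs: dict[str, float],
    stoich: dict[str, float] | None = None,
) -> float:
    """Thermodynamic displacement ``Gamma = (1/K_eq) * prod P^|s| / prod S^|s|``.

    ``stoich`` optionally supplies signed coefficients; absent, all exponents
    are 1.  Returns 1 exactly at equilibrium.
    """
    for name, c in {**substrate_concs, **product_concs}.items():
        if c <= 0:
            raise ValueError(f"non-positive concentration for {name!r}")
    num = 1.0
    for m, c in product_concs.items():
        num *= c ** (abs(stoich[m]) if stoich else 1.0)
    den = 1.0
    for m, c in substrate_concs.items():
        den *= c ** (abs(stoich[m]) if stoich else 1.0)
    return (1.0 / K_eq) * num / den


def gibbs_from_displacement(gamma: float, temperature_K: float = DEFAULT_T) -> float:
    """``dG = RT ln(Gamma)`` in kJ/mol; negative iff Gamma < 1."""
    if gamma <= 0:
        raise ValueError(f"Gamma must be positive, got {gamma}")
    return R_KJ * temperature_K * np.log(gamma)


def keq_from_deltaG0(deltaG0: float, temperature_K: float = DEFAULT_T) -> float:
    """``K_eq = exp(-dG0 / RT)`` (the standard relation)."""
    return float(np.exp(-deltaG0 / (R_KJ * temperature_K)))


DISPLACEMENT_BINS = (
    "far",            # 0 < Gamma <= 0.1
    "middle",         # 0.1 <= Gamma <= 0.9
    "near",           # 0.9 <= Gamma < 1
    "far+middle",     # 0 < Gamma <= 0.9
    "middle+near",    # 0.1 <= Gamma < 1
    "full",           # 0 < Gamma < 1
)


def classify_displacement(samples) -> str:
    """Classify a reaction's displacement samples into the six range bins.

    ``far`` is strictly far from equilibrium (all samples in (0, 0.1]),
    ``near`` strictly near (all in [0.9, 1)), ``middle`` in between; the three
    composite bins cover distributions spanning more than one range.
    """
    g = np.asarray(list(samples), dtype=float)
    if g.size == 0:
        raise ValueError("no displacement samples given")
    if np.any((g <= 0) | (g >= 1)):
        raise ValueError("displacement samples must lie strictly in (0, 1)")
    lo, hi = float(g.min()), float(g.max())
    if hi <= 0.1:
        return "far"
    if lo >= 0.9:
        return "near"
    if lo >= 0.1 and hi <= 0.9:
        return "middle"
    if hi <= 0.9:
        return "far+middle"
    if lo >= 0.1:
        return "middle+near"
    return "full"


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

@dataclass
class FluxProfile:
    """Steady-state net fluxes (mmol/gDW/h) with direction bookkeeping."""

    reaction_ids: list[str]
    v: np.ndarray
    objective_info: dict = field(default_factory=dict)
    ln_conc: np.ndarray | None = None  # aligned with model metabolites

    @property
    def direction(self) -> np.ndarray:
        return np.sign(self.v)

    def flux(self, rid: str) -> float:
        return float(self.v[self.reaction_ids.index(rid)])


@dataclass
class DisplacementProfile:
    """One sampled log-concentration vector with its per-reaction displacement.

    ``gamma[r]`` is the displacement of reaction ``r`` in the direction of its
    net flux (in (0,1) for any flux-carrying reaction), ``deltaG[r]`` the
    matching Gibbs energy (kJ/mol, negative), ``K_eq[r]`` the equilibrium
    constant of the flux direction.
    """

    met_ids: list[str]
    ln_conc: np.ndarray
    gamma: dict[str, float]
    deltaG: dict[str, float]
    K_eq: dict[str, float]


# ---------------------------------------------------------------------------
# shared constraint assembly
# ---------------------------------------------------------------------------

def _dg_rows(model: NetworkModel, rids, temperature_K, excluded):
    """Rows of RT * s_ir over the full metabolite index, per constrained rxn."""
    RT = R_KJ * temperature_K
    m = len(model.metabolites)
    rows = np.zeros((len(rids), m))
    for k, rid in enumerate(rids):
        r = model.reaction(rid)
        for mid, c in r.stoichiometry.items():
            if mid in excluded:
                continue
            rows[k, model.met_index[mid]] = RT * float(c)
    return rows


def _ln_bounds(model: NetworkModel, conc_bounds: dict | None):
    lb, ub = [], []
    for met in model.metabolites:
        b = (conc_bounds or {}).get(met.id, (met.conc_lb, met.conc_ub))
        lb.append(np.log(b[0]))
        ub.append(np.log(b[1]))
    return np.array(lb), np.array(ub)


# ---------------------------------------------------------------------------
# TFA MILP
# ---------------------------------------------------------------------------

def tfa_solve(
    model: NetworkModel,
    measured_rates: dict[str, tuple[float, float]] | None = None,
    conc_bounds: dict[str, tuple[float, float]] | None = None,
    deltaG0: dict[str, float] | None = None,
    objective: tuple[str, str] | None = None,
    temperature_K: float = DEFAULT_T,
    flux_cap: float = 100.0,
    excluded_species: frozenset = DEFAULT_EXCLUDED,
) -> FluxProfile:
    """Thermodynamics-based flux analysis.

    ``measured_rates`` maps reaction ids to (lb, ub) flux bounds (mmol/gDW/h).
    ``deltaG0`` overrides/extends the per-reaction standard Gibbs energies
    stored on the model.  ``objective`` is ``(reaction_id, 'max'|'min')``;
    omitted, the solve is a pure feasibility problem.  Mass balance of the
    returned profile is re-verified by matrix multiplication.
    """
    n = len(model.reactions)
    mfull = len(model.metabolites)
    dg0 = {r.id: r.deltaG0 for r in model.reactions if r.deltaG0 is not None}
    if deltaG0:
        dg0.update(deltaG0)
    dg_rids = [r.id for r in model.reactions if r.id in dg0 and not r.is_exchange]
    nb = len(dg_rids)

    # variable layout: v (n) | ln x (mfull) | z (nb binaries)
    nvar = n + mfull + nb
    v_lb = np.array([-flux_cap if r.reversible else 0.0 for r in model.reactions])
    v_ub = np.full(n, flux_cap)
    for rid, (lo, hi) in (measured_rates or {}).items():
        j = model.rxn_index[rid]
        v_lb[j] = max(v_lb[j], lo)
        v_ub[j] = min(v_ub[j], hi)
        if v_lb[j] > v_ub[j]:
            raise TfaInfeasibleError(f"inconsistent measured bounds for {rid}")
    u_lb, u_ub = _ln_bounds(model, conc_bounds)
    lb = np.concatenate([v_lb, u_lb, np.zeros(nb)])
    ub = np.concatenate([v_ub, u_ub, np.ones(nb)])
    integrality = np.concatenate([np.zeros(n + mfull), np.ones(nb)])

    cons = []
    # mass balance on internal metabolites
    Nint = model.internal_stoich
    A_mb = np.hstack([Nint, np.zeros((Nint.shape[0], mfull + nb))])
    cons.append(LinearConstraint(A_mb, 0.0, 0.0))

    # big-M direction coupling
    dgrows = _dg_rows(model, dg_rids, temperature_K, excluded_species)
    RT = R_KJ * temperature_K
    Mv = flux_cap * 1.01
    Mg = max((abs(dg0[r]) for r in dg_rids), default=0.0)
    if nb:
        umax = float(max(np.max(np.abs(u_lb)), np.max(np.abs(u_ub))))
        Mg += float(np.max(np.sum(np.abs(dgrows), axis=1))) * umax + 10.0
    else:
        Mg += 10.0
    for k, rid in enumerate(dg_rids):
        j = model.rxn_index[rid]
        # v_j <= Mv * z_k
        row = np.zeros(nvar)
        row[j] = 1.0
        row[n + mfull + k] = -Mv
        cons.append(LinearConstraint(row, -np.inf, 0.0))
        # v_j >= -Mv * (1 - z_k)
        row = np.zeros(nvar)
        row[j] = 1.0
        row[n + mfull + k] = -Mv
        cons.append(LinearConstraint(row, -Mv, np.inf))
        # dG_j <= -eps + Mg * (1 - z_k)
        row = np.zeros(nvar)
        row[n : n + mfull] = dgrows[k]
        row[n + mfull + k] = Mg
        cons.append(LinearConstraint(row, -np.inf, Mg - dg0[rid] - DG_EPSILON))
        # dG_j >= eps - Mg * z_k
        row = np.zeros(nvar)
        row[n : n + mfull] = dgrows[k]
        row[n + mfull + k] = Mg
        cons.append(LinearConstraint(row, -dg0[rid] + DG_EPSILON, np.inf))

    c = np.zeros(nvar)
    if objective is not None:
        rid, sense = objective
        c[model.rxn_index[rid]] = -1.0 if sense == "max" else 1.0

    res = milp(c=c, constraints=cons, bounds=Bounds(lb, ub), integrality=integrality)
    if not res.success:
        raise TfaInfeasibleError(
            "TFA problem infeasible or unsolved: "
            f"{res.message}; {len(measured_rates or {})} measured-rate bounds, "
            f"{nb} Gibbs-energy constraints"
        )
    v = res.x[:n]
    u = res.x[n : n + mfull]
    # independent mass-balance re-check (do not trust the solver)
    resid = float(np.max(np.abs(Nint @ v))) if Nint.size else 0.0
    if resid > 1e-6:
        raise TfaInfeasibleError(f"solver returned unbalanced fluxes (residual {resid})")
    info = {"objective": objective, "milp_status": res.status, "mass_balance_residual": resid}
    return FluxProfile(
        reaction_ids=[r.id for r in model.reactions], v=v, objective_info=info, ln_conc=u
    )


def fva(
    model: NetworkModel,
    measured_rates: dict[str, tuple[float, float]] | None = None,
    conc_bounds: dict[str, tuple[float, float]] | None = None,
    deltaG0: dict[str, float] | None = None,
    reactions: list[str] | None = None,
    **kw,
) -> dict[str, tuple[float, float]]:
    """Flux variability analysis under the full TFA constraint set.

    Per-reaction (min, max) flux via paired optimizations.  Restrict with
    ``reactions`` to save solves.
    """
    out = {}
    for rid in reactions or [r.id for r in model.reactions]:
        lo = tfa_solve(model, measured_rates, conc_bounds, deltaG0, objective=(rid, "min"), **kw)
        hi = tfa_solve(model, measured_rates, conc_bounds, deltaG0, objective=(rid, "max"), **kw)
        out[rid] = (lo.flux(rid), hi.flux(rid))
    return out


# ---------------------------------------------------------------------------
# hit-and-run sampling of the log-concentration polytope
# ---------------------------------------------------------------------------

def _polytope(model, flux: FluxProfile, dg0, temperature_K, excluded, conc_bounds, zero_tol):
    """Assemble A u <= b over the full ln-concentration vector."""
    mfull = len(model.metabolites)
    u_lb, u_ub = _ln_bounds(model, conc_bounds)
    rids = []
    for r in model.reactions:
        if r.is_exchange or r.id not in dg0:
            continue
        if abs(flux.flux(r.id)) <= zero_tol:
            continue
        rids.append(r.id)
    rows = _dg_rows(model, rids, temperature_K, excluded)
    A, b = [], []
    for k, rid in enumerate(rids):
        s = 1.0 if flux.flux(rid) > 0 else -1.0
        A.append(s * rows[k])
        b.append(-s * dg0[rid] - DG_EPSILON)
    A = np.array(A) if A else np.zeros((0, mfull))
    b = np.array(b)
    # box constraints
    eye = np.eye(mfull)
    A = np.vstack([A, eye, -eye])
    b = np.concatenate([b, u_ub, -u_lb])
    return A, b, rids


def _chebyshev_center(A, b):
    norms = np.linalg.norm(A, axis=1)
    n = A.shape[1]
    c = np.zeros(n + 1)
    c[-1] = -1.0
    Aub = np.hstack([A, norms[:, None]])
    res = linprog(c, A_ub=Aub, b_ub=b, bounds=[(None, None)] * n + [(0, None)], method="highs")
    if not res.success or res.x[-1] <= 0:
        raise TfaInfeasibleError(
            "empty log-concentration polytope for this flux profile; "
            "consider relaxing concentration bounds"
        )
    return res.x[:-1], res.x[-1]


def sample_concentrations(
    model: NetworkModel,
    flux: FluxProfile,
    deltaG0: dict[str, float] | None = None,
    conc_bounds: dict[str, tuple[float, float]] | None = None,
    n: int = 100,
    seed: int | None = None,
    burn_in: int = 1000,
    thin: int = 10,
    temperature_K: float = DEFAULT_T,
    excluded_species: frozenset = DEFAULT_EXCLUDED,
    zero_flux_tol: float = 1e-9,
) -> list[DisplacementProfile]:
    """Hit-and-run MCMC over thermodynamically feasible log-concentrations.

    Every returned profile satisfies all concentration bounds and has
    ``sign(dG_r) = -sign(v_r)`` for each flux-carrying reaction with a known
    standard Gibbs energy.  Fixed ``seed`` gives identical output.
    """
    dg0 = {r.id: r.deltaG0 for r in model.reactions if r.deltaG0 is not None}
    if deltaG0:
        dg0.update(deltaG0)
    A, b, rids = _polytope(
        model, flux, dg0, temperature_K, excluded_species, conc_bounds, zero_flux_tol
    )
    u, _ = _chebyshev_center(A, b)
    rng = np.random.default_rng(seed)
    RT = R_KJ * temperature_K
    dgrows = _dg_rows(model, rids, temperature_K, excluded_species)
    met_ids = [m.id for m in model.metabolites]
    out: list[DisplacementProfile] = []
    total = burn_in + n * thin
    slack = b - A @ u
    for step in range(total):
        d = rng.standard_normal(A.shape[1])
        d /= np.linalg.norm(d)
        Ad = A @ d
        with np.errstate(divide="ignore"):
            t = slack / Ad
        t_hi = np.min(t[Ad > 0]) if np.any(Ad > 0) else np.inf
        t_lo = np.max(t[Ad < 0]) if np.any(Ad < 0) else -np.inf
        if not np.isfinite(t_hi) or not np.isfinite(t_lo) or t_hi <= t_lo:
            continue  # numerically degenerate direction
        step_t = rng.uniform(t_lo, t_hi)
        u = u + step_t * d
        slack = slack - step_t * Ad
        if step >= burn_in and (step - burn_in) % thin == thin - 1:
            out.append(_profile_from_point(model, u, rids, dg0, dgrows, flux, RT, met_ids))
    if len(out) < n:
        raise RuntimeError(f"sampler produced {len(out)}/{n} samples")
    return out[:n]


def _profile_from_point(model, u, rids, dg0, dgrows, flux, RT, met_ids):
    gamma, dG, keq = {}, {}, {}
    for k, rid in enumerate(rids):
        dg_fwd = dg0[rid] + float(dgrows[k] @ u)
        s = 1.0 if flux.flux(rid) > 0 else -1.0
        dg_dir = s * dg_fwd
        gamma[rid] = float(np.exp(dg_dir / RT))
        dG[rid] = dg_dir
        keq[rid] = float(np.exp(-s * dg0[rid] / RT))
    return DisplacementProfile(
        met_ids=met_ids, ln_conc=u.copy(), gamma=gamma, deltaG=dG, K_eq=keq
    )


def recheck_profile(
    model: NetworkModel,
    profile: DisplacementProfile,
    flux: FluxProfile,
    deltaG0: dict[str, float] | None = None,
    conc_bounds: dict[str, tuple[float, float]] | None = None,
    temperature_K: float = DEFAULT_T,
    excluded_species: frozenset = DEFAULT_EXCLUDED,
) -> bool:
    """Independent feasibility re-check of a sampled displacement profile.

    Recomputes each reaction Gibbs energy from the raw log-concentrations and
    the standard Gibbs energies (not from the stored gamma) and verifies sign
    consistency with the flux direction plus all concentration bounds.
    """
    dg0 = {r.id: r.deltaG0 for r in model.reactions if r.deltaG0 is not None}
    if deltaG0:
        dg0.update(deltaG0)
    u = profile.ln_conc
    u_lb, u_ub = _ln_bounds(model, conc_bounds)
    if np.any(u < u_lb - 1e-9) or np.any(u > u_ub + 1e-9):
        return False
    RT = R_KJ * temperature_K
    for rid in profile.gamma:
        r = model.reaction(rid)
        dg = dg0[rid]
        for mid, c in r.stoichiometry.items():
            if mid in excluded_species:
                continue
            dg += RT * float(c) * u[model.met_index[mid]]
        vr = flux.flux(rid)
        if vr > 0 and dg >= 0:
            return False
        if vr < 0 and dg <= 0:
            return False
    return True
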