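"""Kinetic mechanisms, saturation sampling, and scaled elasticities.

A scaled elasticity ``eps = d ln v / d ln x`` splits into a thermodynamic
part, fixed by the displacement ``Gamma`` of the reaction, and a saturation
part, fixed by how occupied the enzyme's binding sites are at the operating
point.  For a reversible uni-uni Michaelis-Menten reaction running S -> P:

    eps_S = 1/(1 - Gamma) - sigma_S
    eps_P = -Gamma/(1 - Gamma) - sigma_P

where ``sigma`` in (0,1) is the degree of saturation of the site.  When the
kinetic constants are unknown the sigmas are sampled (uniform by default) and
each draw yields one elasticity matrix consistent with the sampled
thermodynamic state -- the Monte-Carlo backbone of the model population.

Every supported mechanism is written with a *separable* binding polynomial
(one factor per site), so each sampled sigma is exactly the occupancy of its
site and the sigmas can be drawn independently.  The matching closed-form
rate laws are available symbolically (:func:`rate_law_expr`) so the
closed-form elasticities can be cross-checked against direct differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import NetworkModel
from .thermo import DisplacementProfile, FluxProfile

MECHANISM_KINDS = (
    "rev_michaelis_menten_uni_uni",
    "ordered_bi_bi",
    "ordered_bi_ter",
    "ordered_ter_bi",
    "generalized_reversible_hill",
    "convenience",
    "hill_allosteric",
)

_HILL_KINDS = {"generalized_reversible_hill", "hill_allosteric"}
_ORDERED_ARITY = {
    "rev_michaelis_menten_uni_uni": (1, 1),
    "ordered_bi_bi": (2, 2),
    "ordered_bi_ter": (2, 3),
    "ordered_ter_bi": (3, 2),
}


@dataclass(frozen=True)
class Modifier:
    metabolite: str
    role: str  # "activator" | "inhibitor"
    same_site: bool = False


@dataclass(frozen=True)
class MechanismSpec:
    kind: str
    hill_h: float | None = None
    modifiers: tuple[Modifier, ...] = ()

    def __post_init__(self):
        if self.kind not in MECHANISM_KINDS:
            raise ValueError(f"unknown mechanism kind {self.kind!r}")
        if (self.kind in _HILL_KINDS) != (self.hill_h is not None):
            raise ValueError(f"hill_h must be given iff the mechanism is a Hill form ({self.kind})")

    @property
    def h(self) -> float:
        return self.hill_h if self.hill_h is not None else 1.0


#: the phosphofructokinase allosteric specification: Hill coefficient 4 with
#: AMP as activator and ATP as inhibitor competing for the same site
PFK_SPEC = MechanismSpec(
    kind="hill_allosteric",
    hill_h=4.0,
    modifiers=(
        Modifier("amp_c", "activator", same_site=True),
        Modifier("atp_c", "inhibitor", same_site=True),
    ),
)


def assign_mechanisms(
    model: NetworkModel, overrides: dict[str, MechanismSpec] | None = None
) -> dict[str, MechanismSpec]:
    """Assign a kinetic mechanism to every non-exchange reaction.

    Defaults: uni-uni reactions get reversible Michaelis-Menten, anything
    with more participants gets convenience kinetics (unknown binding order);
    ``overrides`` wins where given.  Reactions carrying a mechanism tag on the
    model (e.g. the packaged network) use that tag.
    """
    overrides = overrides or {}
    for rid in overrides:
        if rid not in model.rxn_index:
            raise KeyError(f"mechanism override names unknown reaction {rid!r}")
    out: dict[str, MechanismSpec] = {}
    for r in model.reactions:
        if r.is_exchange:
            continue
        if r.id in overrides:
            out[r.id] = overrides[r.id]
            continue
        if r.mechanism:
            out[r.id] = _spec_from_tag(r.mechanism)
            continue
        ns, np_ = len(r.substrates), len(r.products)
        if (ns, np_) == (1, 1):
            out[r.id] = MechanismSpec("rev_michaelis_menten_uni_uni")
        else:
            out[r.id] = MechanismSpec("convenience")
    return out


def _spec_from_tag(tag: str) -> MechanismSpec:
    if tag == "hill_allosteric_pfk":
        return PFK_SPEC
    if tag.startswith("generalized_reversible_hill"):
        bits = tag.split(":")
        h = float(bits[1]) if len(bits) > 1 else 2.0
        return MechanismSpec("generalized_reversible_hill", hill_h=h)
    return MechanismSpec(tag)


# ---------------------------------------------------------------------------
# saturation sampling
# ---------------------------------------------------------------------------

@dataclass
class SaturationSample:
    """One draw of site saturations: (reaction, metabolite) -> sigma in (0,1)."""

    sigma: dict[tuple[str, str], float]
    seed: int | None = None

    def of(self, rid: str, met: str) -> float:
        return self.sigma[(rid, met)]


def reaction_sites(model: NetworkModel, rid: str, spec: MechanismSpec) -> list[str]:
    """Binding sites demanded by the mechanism: every reactant plus modifiers."""
    r = model.reaction(rid)
    sites = list(r.stoichiometry.keys())
    sites += [m.metabolite for m in spec.modifiers if m.metabolite not in sites]
    return sites


def sample_saturations(
    model: NetworkModel,
    mechanisms: dict[str, MechanismSpec],
    n: int = 1,
    seed: int | None = None,
    low: float = 1e-6,
    high: float = 1.0 - 1e-6,
) -> list[SaturationSample]:
    """Draw ``n`` independent uniform saturation states for every site."""
    rng = np.random.default_rng(seed)
    keys = []
    for rid, spec in mechanisms.items():
        for met in reaction_sites(model, rid, spec):
            keys.append((rid, met))
    out = []
    for _ in range(n):
        draws = rng.uniform(low, high, size=len(keys))
        out.append(SaturationSample(sigma=dict(zip(keys, draws)), seed=seed))
    return out


# ---------------------------------------------------------------------------
# closed-form elasticities
# ---------------------------------------------------------------------------

def _convenience_occupancy(sigma: float, order: int) -> float:
    """d ln D / d ln x for a convenience binding polynomial of given order.

    D = sum_{k=0}^{order} xt^k with xt chosen so the first-order site
    occupancy xt/(1+xt) equals sigma; reduces to sigma when order == 1.
    """
    if order == 1:
        return sigma
    xt = sigma / (1.0 - sigma)
    ks = np.arange(order + 1)
    pw = xt**ks
    return float(np.sum(ks * pw) / np.sum(pw))


def _modifier_elasticities(spec: MechanismSpec, sigma_of) -> dict[str, float]:
    """Elasticity contributions of allosteric modifiers.

    Same-site activator/inhibitor pairs compete for one regulatory site
    (concerted two-state form); independent modifiers contribute the standard
    hyperbolic activation/inhibition terms.
    """
    out: dict[str, float] = {}
    h = spec.h
    same = [m for m in spec.modifiers if m.same_site]
    if same:
        act = [m for m in same if m.role == "activator"]
        inh = [m for m in same if m.role == "inhibitor"]
        sa = sigma_of(act[0].metabolite) if act else 0.0
        si = sigma_of(inh[0].metabolite) if inh else 0.0
        u = (1.0 - sa) ** (-h)
        w = (1.0 - si) ** (-h)
        f = u / (u + w)  # active fraction
        if act:
            out[act[0].metabolite] = out.get(act[0].metabolite, 0.0) + h * sa * (1.0 - f)
        if inh:
            out[inh[0].metabolite] = out.get(inh[0].metabolite, 0.0) - h * si * (1.0 - f)
    for m in spec.modifiers:
        if m.same_site:
            continue
        s = sigma_of(m.metabolite)
        if m.role == "activator":
            out[m.metabolite] = out.get(m.metabolite, 0.0) + (1.0 - s)
        else:
            out[m.metabolite] = out.get(m.metabolite, 0.0) - s
    return out


def elasticities(
    spec: MechanismSpec,
    sigma: dict[str, float],
    gamma: float,
    flux_sign: float,
    stoichiometry: dict[str, float],
) -> dict[str, float]:
    """Scaled elasticities of one reaction given its displacement and sigmas.

    ``gamma`` is the displacement in the direction of net flux; ``flux_sign``
    orients the stoichiometry (substrates of the *net* direction get the
    positive thermodynamic term).  Raises for Gamma outside (0, 1), which is
    inadmissible for a flux-carrying reaction.
    """
    if not (0.0 < gamma < 1.0):
        raise ValueError(f"Gamma must lie in (0,1) for a flux-carrying reaction, got {gamma}")
    if flux_sign == 0:
        raise ValueError("elasticities are undefined for zero net flux")
    h = spec.h
    thermo_s = 1.0 / (1.0 - gamma)
    thermo_p = -gamma / (1.0 - gamma)
    out: dict[str, float] = {}
    for met, coef in stoichiometry.items():
        c = coef * flux_sign  # net-direction signed coefficient
        a = abs(c)
        sig = sigma[met]
        if spec.kind == "convenience":
            exp_th = a
            occ = _convenience_occupancy(sig, max(int(round(a)), 1))
        else:
            exp_th = h * a
            occ = h * a * sig
        eps = (exp_th * thermo_s if c < 0 else exp_th * thermo_p) - occ
        out[met] = out.get(met, 0.0) + eps
    for met, eps in _modifier_elasticities(spec, lambda m: sigma[m]).items():
        out[met] = out.get(met, 0.0) + eps
    return out


def elasticity_matrix(
    model: NetworkModel,
    mechanisms: dict[str, MechanismSpec],
    displacement: DisplacementProfile,
    saturation: SaturationSample,
    flux: FluxProfile,
    zero_flux_tol: float = 1e-9,
) -> np.ndarray:
    """Assemble the n x m scaled elasticity matrix (reactions x internal mets).

    Exchange reactions and zero-flux reactions get all-zero rows; boundary
    metabolites are not columns (their levels are parameters, off by
    default).  A flux-carrying mechanism without a sampled displacement is an
    error.
    """
    internal = model.internal_metabolites
    col = {m.id: k for k, m in enumerate(internal)}
    E = np.zeros((len(model.reactions), len(internal)))
    for j, r in enumerate(model.reactions):
        if r.is_exchange or r.id not in mechanisms:
            continue
        vr = flux.flux(r.id)
        if abs(vr) <= zero_flux_tol:
            continue
        if r.id not in displacement.gamma:
            raise KeyError(f"flux-carrying reaction {r.id!r} lacks a displacement sample")
        spec = mechanisms[r.id]
        sig = {met: saturation.of(r.id, met) for met in reaction_sites(model, r.id, spec)}
        row = elasticities(spec, sig, displacement.gamma[r.id], np.sign(vr), r.stoichiometry)
        for met, eps in row.items():
            if met in col:
                E[j, col[met]] = eps
    return E


# ---------------------------------------------------------------------------
# symbolic rate laws (validation surface)
# ---------------------------------------------------------------------------

def rate_law_expr(spec: MechanismSpec, stoichiometry: dict[str, float], flux_sign: float = 1.0):
    """Closed-form rate law of a mechanism as a sympy expression.

    Returns ``(v_expr, conc_symbols, vmax_symbols)`` where concentrations are
    pre-scaled by their binding constants (``xt = x/K``).  Used to validate
    the closed-form elasticities by direct symbolic/numeric differentiation;
    not used in the sampling hot path.
    """
    import sympy as sp

    h = sp.Rational(spec.h) if float(spec.h).is_integer() else sp.Float(spec.h)
    Vf, Vr = sp.symbols("Vf Vr", positive=True)
    syms: dict[str, "sp.Symbol"] = {}
    num_f, num_r, den = sp.Integer(1), sp.Integer(1), sp.Integer(1)
    for met, coef in stoichiometry.items():
        c = coef * flux_sign
        a = sp.Integer(int(round(abs(c))))
        x = sp.symbols(f"x_{met}", positive=True)
        syms[met] = x
        if spec.kind == "convenience":
            num_f = num_f * x**a if c < 0 else num_f
            num_r = num_r * x**a if c > 0 else num_r
            den *= sum(x**k for k in range(int(a) + 1))
        else:
            e = h * a
            num_f = num_f * x**e if c < 0 else num_f
            num_r = num_r * x**e if c > 0 else num_r
            den *= (1 + x**e) if spec.kind in _HILL_KINDS else (1 + x) ** a
    v = (Vf * num_f - Vr * num_r) / den
    # allosteric regulation: multiply by the active fraction; regulatory sites
    # have their own binding constants, so a modifier that is also a reactant
    # (e.g. ATP on PFK) gets a distinct scaled variable keyed '<met>__reg'
    same = [m for m in spec.modifiers if m.same_site]
    if same:
        L = sp.Integer(1)
        u, w = sp.Integer(1), sp.Integer(1)
        for m in same:
            x = sp.symbols(f"x_{m.metabolite}_reg", positive=True)
            syms[f"{m.metabolite}__reg"] = x
            if m.role == "activator":
                u = (1 + x) ** h
            else:
                w = (1 + x) ** h
        v = v * u / (u + L * w)
    for m in spec.modifiers:
        if m.same_site:
            continue
        x = sp.symbols(f"x_{m.metabolite}_reg", positive=True)
        syms[f"{m.metabolite}__reg"] = x
        v = v * (x / (1 + x)) if m.role == "activator" else v / (1 + x)
    return v, syms, (Vf, Vr)


def operating_point(
    spec: MechanismSpec,
    stoichiometry: dict[str, float],
    sigma: dict[str, float],
    gamma: float,
    flux_sign: float = 1.0,
):
    """Numeric operating point of :func:`rate_law_expr` matching (sigma, Gamma).

    Scaled concentrations are chosen so each site's occupancy equals its
    sigma, and Vr/Vf is set so the reverse-to-forward rate ratio equals
    Gamma.  Returns ``(subs, v_expr, syms)`` ready for numeric evaluation.
    """
    import sympy as sp

    v, syms, (Vf, Vr) = rate_law_expr(spec, stoichiometry, flux_sign)
    subs = {Vf: 1.0}
    h = spec.h
    num_f, num_r = 1.0, 1.0
    for met, coef in stoichiometry.items():
        c = coef * flux_sign
        a = abs(c)
        s = sigma[met]
        if spec.kind in _HILL_KINDS:
            # site polynomial is 1 + x^(h*a): occupancy sigma => x^(h*a) = s/(1-s)
            xval = (s / (1 - s)) ** (1.0 / (h * a))
        else:
            xval = s / (1 - s)
        subs[syms[met]] = xval
        if spec.kind in _HILL_KINDS:
            term = xval ** (h * a)
        else:
            term = xval**a
        if c < 0:
            num_f *= term
        else:
            num_r *= term
    subs[Vr] = gamma * num_f / num_r
    for m in spec.modifiers:
        s = sigma[m.metabolite]
        subs[syms[f"{m.metabolite}__reg"]] = s / (1 - s)
    return subs, v, syms
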