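"""Generators and independent oracles for every pipeline stage.

Contents:

* a reduced anaerobic glucose-xylose *S. cerevisiae* network (upper/lower
  glycolysis, oxidative and non-oxidative pentose phosphate pathway, the
  XR/XDH/XK xylose assimilation route with xylitol export, fermentative
  branches to ethanol/glycerol/acetate, a lumped pyruvate-dehydrogenase/TCA/
  oxidative-phosphorylation mitochondrial block with an NADH-dehydrogenase
  analog (NDR), ATP maintenance, a lumped biomass reaction with molecular
  oxygen among its substrates, and transport/exchange reactions) -- carbon
  bookkeeping only, with plausible standard Gibbs energies;
* a scenario bundle tying that network to flux bounds derived from the
  fermentation fixture at the 12 h co-consumption time point (oxygen uptake
  capped at 2 mmol/gDW/h);
* a fermentation curve generator with additive Gaussian noise and stored
  ground truth for parameter-recovery tests;
* small toy kinetic ODE models (linear chain, branch, conserved-moiety
  cycle) with hand-written steady-state solvers and analytic elasticities;
* a brute-force finite-difference control-coefficient oracle that perturbs
  enzyme activities and re-solves the steady state, sharing no numerical
  kernel with the control-analysis engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import root

from . import fermentation as ferm
from .kinetics import MechanismSpec, assign_mechanisms
from .network import Metabolite, NetworkModel, Reaction
from .thermo import FluxProfile

#: grams per C-mol of biomass (CH1.8O0.5N0.2-type lumped composition)
BIOMASS_CMOL_MASS = 25.0

#: paper-like anaerobic batch starting point: 20 g/l glucose, 50 g/l xylose,
#: 0.15 g/l cell dry weight
DEFAULT_INITIAL = {"glucose": 20.0, "xylose": 50.0, "cdw": 0.15}


# ---------------------------------------------------------------------------
# fermentation fixture
# ---------------------------------------------------------------------------

def default_fermentation_params() -> ferm.FermentationParams:
    """Fixture parameters producing the qualitative batch landmarks.

    Chosen so that glucose is depleted around 15 h, xylose is still present
    at 140 h, and xylitol accumulates to roughly 22 g/l -- plausible values,
    not estimates from any particular cultivation.
    """
    return ferm.FermentationParams(
        Y={"glucose": 5.0, "xylose": 0.35},
        km={"glucose": 8.0, "xylose": 30.0},
        tau=8.0,
        mu={"glucose": 0.05, "xylose": 0.02},
        yields={
            "glucose": {"ethanol": 0.40, "glycerol": 0.08, "acetate": 0.02, "co2": 0.40},
            "xylose": {
                "ethanol": 0.12,
                "glycerol": 0.03,
                "acetate": 0.01,
                "co2": 0.12,
                "xylitol": 0.65,
            },
        },
        evap_a=0.012,
        evap_b=0.004,
        volume=1.5,
    )


def gen_fermentation(
    params: ferm.FermentationParams | None = None,
    initial: dict[str, float] | None = None,
    times: np.ndarray | None = None,
    noise_sigma_pct: float = 2.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a batch cultivation and add iid Gaussian measurement noise.

    Noise per species is ``noise_sigma_pct`` percent of the species maximum.
    Returns ``(noisy, clean)`` so recovery tests can compare against truth.
    """
    params = params or default_fermentation_params()
    initial = initial or dict(DEFAULT_INITIAL)
    if times is None:
        # frequent robot sampling (15 min) over a full 140 h batch
        times = np.arange(0.25, 140.25, 0.25)
    clean = ferm.simulate(params, initial, np.asarray(times, float))
    keep = [c for c in clean.columns if c != "ethanol_produced"]
    clean = clean[keep]
    rng = np.random.default_rng(seed)
    noisy = clean.copy()
    for col in noisy.columns:
        scale = noise_sigma_pct / 100.0 * float(np.max(np.abs(clean[col].to_numpy())))
        if scale > 0:
            noisy[col] = np.clip(noisy[col] + rng.normal(0.0, scale, len(noisy)), 0.0, None)
    return noisy, clean


# ---------------------------------------------------------------------------
# reduced glucose-xylose network
# ---------------------------------------------------------------------------

def _met(mid, comp, C=None, lb=1e-8, ub=1e-1, boundary=False, name=""):
    return Metabolite(
        id=mid,
        name=name or mid,
        compartment=comp,
        formula=None if C is None else {"C": C},
        conc_lb=lb,
        conc_ub=ub,
        boundary=boundary,
    )


def build_reduced_network() -> NetworkModel:
    """Construct the packaged reduced glucose-xylose network in code.

    Mirrors the topology of the co-utilization map: glucose and xylose
    transport are independent reactions catalyzed by separate enzymes (no
    shared capacity), malic-enzyme-level anaplerotic detail is not part of
    the reduction, and the biomass reaction consumes molecular oxygen.
    Formulas carry carbon counts only (lumped acetyl units are C2), so every
    reaction is exactly carbon balanced.
    """
    cy, mi, ex = "cytosol", "mitochondria", "extracellular"
    mets = [
        # extracellular boundary pools: measured-era concentration windows
        _met("glc_e", ex, 6, 1.2e-2, 2.2e-2, True, "glucose (extracellular)"),
        _met("xyl_e", ex, 5, 0.30, 0.36, True, "xylose (extracellular)"),
        _met("xlt_e", ex, 5, 1e-3, 5e-2, True, "xylitol (extracellular)"),
        _met("etoh_e", ex, 2, 5e-2, 2.5e-1, True, "ethanol (extracellular)"),
        _met("glyc_e", ex, 3, 5e-3, 5e-2, True, "glycerol (extracellular)"),
        _met("ac_e", ex, 2, 1e-3, 2e-2, True, "acetate (extracellular)"),
        _met("co2_e", ex, 1, 1e-4, 1e-2, True, "CO2 (extracellular)"),
        _met("o2_e", ex, 0, 1e-7, 2.5e-4, True, "O2 (extracellular)"),
        # fixed regulatory pool and biomass sink
        _met("amp_c", cy, 10, 5e-5, 5e-4, True, "AMP (fixed regulatory pool)"),
        _met("biomass_c", cy, 1, 1e-3, 1e-1, True, "biomass (C-mol units)"),
        # cytosol
        _met("glc_c", cy, 6),
        _met("g6p_c", cy, 6),
        _met("f6p_c", cy, 6),
        _met("fbp_c", cy, 6),
        _met("dhap_c", cy, 3),
        _met("g3p_c", cy, 3, name="glyceraldehyde 3-phosphate"),
        _met("pyr_c", cy, 3),
        _met("acald_c", cy, 2),
        _met("etoh_c", cy, 2),
        _met("ac_c", cy, 2),
        _met("glyc_c", cy, 3),
        _met("xyl_c", cy, 5),
        _met("xlt_c", cy, 5, name="xylitol (cytosolic)"),
        _met("xlu_c", cy, 5, name="xylulose"),
        _met("x5p_c", cy, 5),
        _met("ru5p_c", cy, 5),
        _met("r5p_c", cy, 5),
        _met("co2_c", cy, 1),
        _met("o2_c", cy, 0),
        # cofactor pools bounded to physiological windows (measured-level
        # knowledge integrated as bounds, as the workflow prescribes)
        _met("atp_c", cy, 10, 2e-3, 6e-3),
        _met("adp_c", cy, 10, 3e-4, 1.5e-3),
        _met("nad_c", cy, 21, 1e-3, 4e-3),
        _met("nadh_c", cy, 21, 5e-5, 3e-4),
        _met("nadp_c", cy, 21, 5e-5, 3e-4),
        _met("nadph_c", cy, 21, 2e-4, 1e-3),
        # mitochondria
        _met("pyr_m", mi, 3),
        _met("accoa_m", mi, 2, name="acetyl units (mitochondrial)"),
        _met("co2_m", mi, 1),
        _met("nad_m", mi, 21, 1e-3, 4e-3),
        _met("nadh_m", mi, 21, 1e-4, 8e-4),
    ]

    def rx(rid, stoich, rev, dg0, mech, transport=False, biomass=False):
        return Reaction(
            id=rid,
            stoichiometry=stoich,
            reversible=rev,
            deltaG0=dg0,
            mechanism=mech,
            is_transport=transport,
            is_biomass=biomass,
        )

    uu = "rev_michaelis_menten_uni_uni"
    bb = "ordered_bi_bi"
    cv = "convenience"
    rxns = [
        rx("HXT", {"glc_e": -1, "glc_c": 1}, False, 0.0, uu, transport=True),
        rx("HXK", {"glc_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1}, False, -17.0, bb),
        rx("PGI", {"g6p_c": -1, "f6p_c": 1}, True, 2.5, uu),
        rx(
            "PFK",
            {"f6p_c": -1, "atp_c": -1, "fbp_c": 1, "adp_c": 1},
            False,
            -14.0,
            "hill_allosteric_pfk",
        ),
        rx("FBA", {"fbp_c": -1, "dhap_c": 1, "g3p_c": 1}, True, 21.0, cv),
        rx("TPI", {"dhap_c": -1, "g3p_c": 1}, True, 5.5, uu),
        # lumped lower glycolysis (GAPDH..PYK)
        rx(
            "GLY",
            {"g3p_c": -1, "nad_c": -1, "adp_c": -2, "pyr_c": 1, "nadh_c": 1, "atp_c": 2},
            False,
            -25.0,
            cv,
        ),
        # lumped glycerol branch (GPD + GPP)
        rx("GPD1", {"dhap_c": -1, "nadh_c": -1, "glyc_c": 1, "nad_c": 1}, False, -30.0, bb),
        rx("GLYCt", {"glyc_c": -1, "glyc_e": 1}, False, 0.0, uu, transport=True),
        rx("PDC", {"pyr_c": -1, "acald_c": 1, "co2_c": 1}, False, -18.0, cv),
        rx("ADH1", {"acald_c": -1, "nadh_c": -1, "etoh_c": 1, "nad_c": 1}, True, -23.0, bb),
        rx("ETOHt", {"etoh_c": -1, "etoh_e": 1}, True, 0.0, uu, transport=True),
        rx("ALD", {"acald_c": -1, "nadp_c": -1, "ac_c": 1, "nadph_c": 1}, False, -45.0, bb),
        rx("ACt", {"ac_c": -1, "ac_e": 1}, False, 0.0, uu, transport=True),
        rx("XTR", {"xyl_e": -1, "xyl_c": 1}, False, 0.0, uu, transport=True),
        rx("XRI", {"xyl_c": -1, "nadph_c": -1, "xlt_c": 1, "nadp_c": 1}, False, -30.0, bb),
        rx("XRII", {"xyl_c": -1, "nadh_c": -1, "xlt_c": 1, "nad_c": 1}, False, -30.0, bb),
        rx("XDH", {"xlt_c": -1, "nad_c": -1, "xlu_c": 1, "nadh_c": 1}, True, 10.0, bb),
        rx("XK", {"xlu_c": -1, "atp_c": -1, "x5p_c": 1, "adp_c": 1}, False, -15.0, bb),
        rx("XLT", {"xlt_c": -1, "xlt_e": 1}, False, 0.0, uu, transport=True),
        # lumped oxidative PPP (ZWF + SOL + GND)
        rx(
            "ZWF",
            {"g6p_c": -1, "nadp_c": -2, "ru5p_c": 1, "co2_c": 1, "nadph_c": 2},
            False,
            -25.0,
            cv,
        ),
        rx("RPE", {"ru5p_c": -1, "x5p_c": 1}, True, -0.5, uu),
        rx("RKI", {"ru5p_c": -1, "r5p_c": 1}, True, 0.5, uu),
        # lumped non-oxidative PPP (transketolase/transaldolase block)
        rx("TKT", {"x5p_c": -2, "r5p_c": -1, "f6p_c": 2, "g3p_c": 1}, True, -10.0, cv),
        rx("PYRtm", {"pyr_c": -1, "pyr_m": 1}, True, 0.0, uu, transport=True),
        rx(
            "PDH",
            {"pyr_m": -1, "nad_m": -1, "accoa_m": 1, "co2_m": 1, "nadh_m": 1},
            False,
            -35.0,
            cv,
        ),
        # lumped TCA with one substrate-level phosphorylation
        rx(
            "TCA",
            {"accoa_m": -1, "nad_m": -3, "adp_c": -1, "co2_m": 2, "nadh_m": 3, "atp_c": 1},
            False,
            -40.0,
            cv,
        ),
        # NADH-dehydrogenase analog: lumped respiration, P/O = 2
        rx(
            "NDR",
            {"nadh_m": -1, "o2_c": -0.5, "adp_c": -2, "nad_m": 1, "atp_c": 2},
            False,
            -100.0,
            cv,
        ),
        rx("ATPM", {"atp_c": -1, "adp_c": 1}, False, -30.0, uu),
        rx("O2t", {"o2_e": -1, "o2_c": 1}, False, 0.0, uu, transport=True),
        rx("CO2tm", {"co2_m": -1, "co2_c": 1}, True, 0.0, uu, transport=True),
        rx("CO2t", {"co2_c": -1, "co2_e": 1}, True, 0.0, uu, transport=True),
        # lumped growth: oxygen is among the substrates; biosynthesis leaves
        # surplus cytosolic and mitochondrial NADH behind
        rx(
            "BIOMASS",
            {
                "g6p_c": -0.2,
                "atp_c": -2.0,
                "nadph_c": -0.2,
                "o2_c": -0.005,
                "nad_c": -0.1,
                "nad_m": -0.1,
                "biomass_c": 1.0,
                "co2_c": 0.2,
                "adp_c": 2.0,
                "nadp_c": 0.2,
                "nadh_c": 0.1,
                "nadh_m": 0.1,
            },
            False,
            -150.0,
            cv,
            biomass=True,
        ),
    ]
    return NetworkModel(mets, rxns, name="reduced_yeast_glc_xyl")


def packaged_network_path() -> Path:
    return Path(__file__).parent / "data" / "reduced_yeast_glc_xyl.json"


# ---------------------------------------------------------------------------
# scenario bundle
# ---------------------------------------------------------------------------

@dataclass
class ScenarioBundle:
    """Network + constraint set encoding the 12 h co-consumption state."""

    model: NetworkModel
    measured_rates: dict[str, tuple[float, float]]
    deltaG0: dict[str, float]
    conc_bounds: dict[str, tuple[float, float]]
    mechanisms: dict[str, MechanismSpec]
    rates_info: dict = field(default_factory=dict)

    def solve_flux(self, objective: tuple[str, str] | None = ("ATPM", "max")) -> FluxProfile:
        """Reference TFA solve of the bundle (maintenance-maximizing by default,
        reflecting residual oxygen activity at the analyzed time point)."""
        from .thermo import tfa_solve

        return tfa_solve(self.model, self.measured_rates, objective=objective)

    def write(self, out_dir: str | Path) -> Path:
        from .network import write_model

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_model(self.model, out / "network.json")
        pd.DataFrame(
            [{"reaction_id": r, "lb": lo, "ub": hi} for r, (lo, hi) in self.measured_rates.items()]
        ).to_csv(out / "flux_bounds.csv", index=False)
        pd.DataFrame(
            [{"reaction_id": r, "deltaG0_kj_mol": g} for r, g in self.deltaG0.items()]
        ).to_csv(out / "deltaG0.csv", index=False)
        pd.DataFrame(
            [
                {
                    "reaction_id": rid,
                    "mechanism": spec.kind,
                    "h": spec.hill_h,
                    "modifiers": ";".join(
                        f"{m.metabolite}:{m.role}:{int(m.same_site)}" for m in spec.modifiers
                    ),
                }
                for rid, spec in self.mechanisms.items()
            ]
        ).to_csv(out / "mechanisms.csv", index=False)
        return out


#: transporter/exchange reaction carrying each measured specific rate
_RATE_REACTIONS = {
    "glucose": "HXT",
    "xylose": "XTR",
    "xylitol": "XLT",
    "ethanol": "ETOHt",
    "glycerol": "GLYCt",
    "acetate": "ACt",
}


def make_scenario(
    kind: str = "reduced_yeast_glc_xyl",
    seed: int | None = None,
    at_time: float = 12.0,
    slack: float = 0.20,
    o2_cap: float = 2.0,
) -> ScenarioBundle:
    """Build the packaged analysis scenario.

    Flux bounds come from the fermentation fixture's specific rates at the
    co-consumption time point (default 12 h), converted to mmol/gDW/h, with a
    symmetric relative ``slack``; the oxygen uptake rate is capped at
    ``o2_cap`` mmol/gDW/h.  The bundle is TFA-feasible as shipped.
    """
    del seed  # deterministic; accepted for interface symmetry
    if kind != "reduced_yeast_glc_xyl":
        raise ValueError(f"unknown scenario kind {kind!r}")
    path = packaged_network_path()
    if path.exists():
        from .network import load_model

        model = load_model(path)
    else:
        model = build_reduced_network()
    params = default_fermentation_params()
    times = np.linspace(0.0, max(at_time, 1.0), 121)
    traj = ferm.simulate(params, dict(DEFAULT_INITIAL), times)
    state = {c: float(traj[c].iloc[-1]) for c in traj.columns}
    rates = ferm.specific_rates(params, state, at_time)
    measured: dict[str, tuple[float, float]] = {}
    mmol = {}
    for species, rid in _RATE_REACTIONS.items():
        q = rates.in_mmol(species)
        mmol[species] = q
        measured[rid] = (q * (1 - slack), q * (1 + slack))
    mu = rates.growth_rate * 1000.0 / BIOMASS_CMOL_MASS  # mmol C-units/gDW/h
    measured["BIOMASS"] = (mu * (1 - slack), mu * (1 + slack))
    measured["O2t"] = (0.0, o2_cap)
    # anaerobic repression of oxidative pyruvate metabolism: only a residual
    # flux through the lumped PDH/TCA block, so mitochondrial NADH turnover
    # is dominated by growth-associated production
    measured["PDH"] = (0.0, 0.3)
    # dual-cofactor xylose reductase: keep both isoform activities flux-carrying
    # (NADPH-preferring XRI carries the larger share)
    q_xyl = mmol["xylose"]
    measured["XRI"] = (0.4 * q_xyl, 100.0)
    measured["XRII"] = (0.2 * q_xyl, 100.0)
    deltaG0 = {r.id: r.deltaG0 for r in model.reactions if r.deltaG0 is not None}
    mechanisms = assign_mechanisms(model)
    return ScenarioBundle(
        model=model,
        measured_rates=measured,
        deltaG0=deltaG0,
        conc_bounds={},
        mechanisms=mechanisms,
        rates_info={"at_time": at_time, "q_mmol": mmol, "growth_rate_per_h": rates.growth_rate},
    )


# ---------------------------------------------------------------------------
# toy kinetic models with hand-written steady states
# ---------------------------------------------------------------------------

@dataclass
class ToyKineticModel:
    """Explicit ODE model: closed-form rates, analytic elasticities.

    ``rate(x, e)`` evaluates all reaction rates for a dict of internal
    concentrations and an enzyme-activity vector; ``solve_steady_state``
    is hand-written per topology (conserved moieties substituted out).
    """

    network: NetworkModel
    params: dict
    kind: str

    # -- rates ---------------------------------------------------------------
    def rate(self, x: dict[str, float], e: np.ndarray) -> np.ndarray:
        p = self.params
        if self.kind == "chain_first_order":
            concs = [p["a0"]] + [x[m] for m in p["internal"]] + [p["b0"]]
            return np.array(
                [
                    e[i] * (p["kf"][i] * concs[i] - p["kr"][i] * concs[i + 1])
                    for i in range(len(e))
                ]
            )
        if self.kind == "chain_rev_mm":
            concs = [p["a0"]] + [x[m] for m in p["internal"]] + [p["b0"]]
            out = []
            for i in range(len(e)):
                s = concs[i] / p["Ks"][i]
                q = concs[i + 1] / p["Kp"][i]
                out.append(e[i] * (p["kf"][i] * s - p["kr"][i] * q) / ((1 + s) * (1 + q)))
            return np.array(out)
        if self.kind == "branch":
            m = x["M"]
            return np.array(
                [
                    e[0] * (p["k1"] * p["a0"] - p["k1r"] * m),
                    e[1] * (p["k2"] * m - p["k2r"] * p["b0"]),
                    e[2] * (p["k3"] * m - p["k3r"] * p["c0"]),
                ]
            )
        if self.kind == "moiety_cycle":
            m, xc, yc = x["M"], x["X"], x["Y"]
            return np.array(
                [
                    e[0] * (p["k1"] * p["a0"] * xc - p["k1r"] * m * yc),
                    e[1] * (p["k2"] * m - p["k2r"] * p["b0"]),
                    e[2] * (p["k3"] * yc - p["k3r"] * xc),
                ]
            )
        raise ValueError(self.kind)

    @property
    def internal_ids(self) -> list[str]:
        return [m.id for m in self.network.internal_metabolites]

    # -- steady state ----------------------------------------------------------
    def solve_steady_state(self, e: np.ndarray | None = None):
        """Hand-written steady-state solve per topology; returns (x, v)."""
        p = self.params
        n = len(self.network.reactions)
        e = np.ones(n) if e is None else np.asarray(e, float)

        def solve(f, z0):
            sol = root(f, z0, tol=1e-12)
            resid = float(np.max(np.abs(f(sol.x))))
            if resid > 1e-10:
                raise RuntimeError(f"no steady state (residual {resid}): {sol.message}")
            return sol.x

        if self.kind in ("chain_first_order", "chain_rev_mm"):
            ids = p["internal"]

            def f(z):
                x = dict(zip(ids, np.exp(z)))
                v = self.rate(x, e)
                return np.diff(v)  # v_i+1 - v_i = 0 along the chain

            z = solve(f, np.zeros(len(ids)))
            x = dict(zip(ids, np.exp(z)))
        elif self.kind == "branch":

            def f(z):
                x = {"M": np.exp(z[0])}
                v = self.rate(x, e)
                return [v[0] - v[1] - v[2]]

            z = solve(f, [0.0])
            x = {"M": float(np.exp(z[0]))}
        elif self.kind == "moiety_cycle":
            T = p["T"]

            def f(z):
                m, xc = np.exp(z)
                if xc >= T:
                    return [1e3, 1e3]
                x = {"M": m, "X": xc, "Y": T - xc}
                v = self.rate(x, e)
                return [v[0] - v[1], v[2] - v[0]]

            z = solve(f, [np.log(p.get("m0", 1.0)), np.log(T / 2)])
            m, xc = np.exp(z)
            x = {"M": float(m), "X": float(xc), "Y": float(T - xc)}
        else:
            raise ValueError(self.kind)
        v = self.rate(x, e)
        if np.any(np.array(list(x.values())) <= 0):
            raise RuntimeError("no positive steady state for these parameters")
        return x, v

    # -- analytic scaled elasticities -----------------------------------------
    def elasticity_matrix_at(self, x: dict[str, float], e: np.ndarray | None = None) -> np.ndarray:
        ids = self.internal_ids
        n = len(self.network.reactions)
        e = np.ones(n) if e is None else np.asarray(e, float)
        v = self.rate(x, e)
        E = np.zeros((n, len(ids)))
        h = 1e-7
        # analytic forms are simple enough that a high-order central difference
        # on ln v vs ln x is exact to machine-level for these rational laws
        for k, mid in enumerate(ids):
            xp, xm = dict(x), dict(x)
            xp[mid] = x[mid] * (1 + h)
            xm[mid] = x[mid] * (1 - h)
            vp, vm = self.rate(xp, e), self.rate(xm, e)
            with np.errstate(divide="ignore", invalid="ignore"):
                E[:, k] = np.where(
                    np.abs(v) > 0, (vp - vm) / (2 * h * x[mid]) * x[mid] / v, 0.0
                )
        return E

    def flux_profile(self, e: np.ndarray | None = None) -> tuple[dict, FluxProfile]:
        x, v = self.solve_steady_state(e)
        return x, FluxProfile(reaction_ids=[r.id for r in self.network.reactions], v=v)


def _chain_network(n_steps: int) -> NetworkModel:
    mets = [Metabolite(id="A_ext", compartment="extracellular", boundary=True)]
    internal = [f"M{i}" for i in range(1, n_steps)]
    mets += [Metabolite(id=m) for m in internal]
    mets.append(Metabolite(id="B_ext", compartment="extracellular", boundary=True))
    chain = ["A_ext"] + internal + ["B_ext"]
    rxns = [
        Reaction(id=f"R{i + 1}", stoichiometry={chain[i]: -1, chain[i + 1]: 1}, reversible=True)
        for i in range(n_steps)
    ]
    return NetworkModel(mets, rxns, name=f"chain{n_steps}")


def gen_toy_chain(
    n_steps: int,
    kinetics: str = "first_order",
    params: dict | None = None,
    seed: int | None = None,
) -> ToyKineticModel:
    """Linear pathway between two fixed boundary pools."""
    if n_steps < 2:
        raise ValueError("a toy chain needs at least 2 steps")
    net = _chain_network(n_steps)
    rng = np.random.default_rng(seed)
    internal = [m.id for m in net.internal_metabolites]
    if params is None:
        params = {
            "a0": 2.0,
            "b0": 0.1,
            "kf": list(1.0 + rng.uniform(0, 1, n_steps)),
            "kr": list(0.2 + rng.uniform(0, 0.2, n_steps)),
        }
        if kinetics == "rev_mm":
            params["Ks"] = list(0.5 + rng.uniform(0, 1, n_steps))
            params["Kp"] = list(0.5 + rng.uniform(0, 1, n_steps))
    params = dict(params)
    params["internal"] = internal
    kind = "chain_first_order" if kinetics == "first_order" else "chain_rev_mm"
    toy = ToyKineticModel(network=net, params=params, kind=kind)
    x, v = toy.solve_steady_state()  # verify existence up front
    if np.any(np.abs(np.diff(v)) > 1e-8):
        raise RuntimeError("chain steady state violates flux equality")
    return toy


def gen_toy_branch(seed: int | None = None) -> ToyKineticModel:
    """One node feeding two competing sinks (first-order reversible)."""
    rng = np.random.default_rng(seed)
    mets = [
        Metabolite(id="A_ext", compartment="extracellular", boundary=True),
        Metabolite(id="M"),
        Metabolite(id="B_ext", compartment="extracellular", boundary=True),
        Metabolite(id="C_ext", compartment="extracellular", boundary=True),
    ]
    rxns = [
        Reaction(id="R1", stoichiometry={"A_ext": -1, "M": 1}, reversible=True),
        Reaction(id="R2", stoichiometry={"M": -1, "B_ext": 1}, reversible=True),
        Reaction(id="R3", stoichiometry={"M": -1, "C_ext": 1}, reversible=True),
    ]
    net = NetworkModel(mets, rxns, name="branch")
    params = {
        "a0": 2.0,
        "b0": 0.05,
        "c0": 0.05,
        "k1": 1.0 + rng.uniform(0, 1),
        "k1r": 0.2,
        "k2": 0.8 + rng.uniform(0, 0.5),
        "k2r": 0.1,
        "k3": 0.5 + rng.uniform(0, 0.5),
        "k3r": 0.1,
    }
    return ToyKineticModel(network=net, params=params, kind="branch")


def gen_toy_moiety(seed: int | None = None) -> ToyKineticModel:
    """Conserved-carrier cycle: A_ext + X -> M + Y; M -> B_ext; Y -> X."""
    rng = np.random.default_rng(seed)
    mets = [
        Metabolite(id="A_ext", compartment="extracellular", boundary=True),
        Metabolite(id="M"),
        Metabolite(id="X"),
        Metabolite(id="Y"),
        Metabolite(id="B_ext", compartment="extracellular", boundary=True),
    ]
    rxns = [
        Reaction(id="R1", stoichiometry={"A_ext": -1, "X": -1, "M": 1, "Y": 1}, reversible=True),
        Reaction(id="R2", stoichiometry={"M": -1, "B_ext": 1}, reversible=True),
        Reaction(id="R3", stoichiometry={"Y": -1, "X": 1}, reversible=True),
    ]
    net = NetworkModel(mets, rxns, name="moiety_cycle")
    params = {
        "a0": 1.5,
        "b0": 0.05,
        "T": 2.0,
        "k1": 1.0 + rng.uniform(0, 0.5),
        "k1r": 0.1,
        "k2": 0.7 + rng.uniform(0, 0.5),
        "k2r": 0.05,
        "k3": 0.9 + rng.uniform(0, 0.5),
        "k3r": 0.2,
    }
    return ToyKineticModel(network=net, params=params, kind="moiety_cycle")


# ---------------------------------------------------------------------------
# brute-force control-coefficient oracle
# ---------------------------------------------------------------------------

def finite_difference_cc(
    toy: ToyKineticModel,
    parameter: str,
    delta_pct: float = 0.1,
    richardson: bool = False,
) -> dict:
    """Central-difference scaled steady-state sensitivities to one enzyme.

    Perturbs the enzyme activity of ``parameter`` by +/- ``delta_pct`` %,
    re-solves the steady state from scratch, and differentiates ln(flux) and
    ln(concentration).  With ``richardson=True`` the step is halved and the
    fourth-order extrapolation returned.
    """

    def once(d_pct: float) -> tuple[dict, dict]:
        j = toy.network.rxn_index[parameter]
        n = len(toy.network.reactions)
        d = d_pct / 100.0
        e_hi, e_lo = np.ones(n), np.ones(n)
        e_hi[j] = 1.0 + d
        e_lo[j] = 1.0 - d
        x_hi, v_hi = toy.solve_steady_state(e_hi)
        x_lo, v_lo = toy.solve_steady_state(e_lo)
        dln_e = np.log((1.0 + d) / (1.0 - d))
        cflux = {
            rid: float(np.log(abs(v_hi[k]) / abs(v_lo[k])) / dln_e)
            for k, rid in enumerate(r.id for r in toy.network.reactions)
        }
        cconc = {
            mid: float(np.log(x_hi[mid] / x_lo[mid]) / dln_e) for mid in x_hi
        }
        return cflux, cconc

    cf1, cc1 = once(delta_pct)
    if not richardson:
        return {"flux": cf1, "conc": cc1}
    cf2, cc2 = once(delta_pct / 2.0)
    flux = {k: (4 * cf2[k] - cf1[k]) / 3.0 for k in cf1}
    conc = {k: (4 * cc2[k] - cc1[k]) / 3.0 for k in cc1}
    return {"flux": flux, "conc": conc}
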