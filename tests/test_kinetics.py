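import numpy as np
import pytest
import sympy as sp

from mcapop import synthetic as syn
from mcapop.kinetics import (
    PFK_SPEC,
    MechanismSpec,
    Modifier,
    assign_mechanisms,
    elasticities,
    elasticity_matrix,
    operating_point,
    reaction_sites,
    sample_saturations,
)

CASES = [
    (MechanismSpec("rev_michaelis_menten_uni_uni"), {"S": -1, "P": 1}),
    (MechanismSpec("ordered_bi_bi"), {"A": -1, "B": -1, "P": 1, "Q": 1}),
    (MechanismSpec("ordered_bi_ter"), {"A": -1, "B": -1, "P": 1, "Q": 1, "R": 1}),
    (MechanismSpec("ordered_ter_bi"), {"A": -1, "B": -1, "C": -1, "P": 1, "Q": 1}),
    (MechanismSpec("generalized_reversible_hill", hill_h=2.0), {"S": -1, "P": 1}),
    (MechanismSpec("convenience"), {"A": -2, "B": -1, "P": 1, "Q": 2}),
    (PFK_SPEC, {"f6p_c": -1, "atp_c": -1, "fbp_c": 1, "adp_c": 1}),
]


class TestAssignment:
    def test_defaults_and_overrides(self, scenario):
        model = scenario.model
        mechs = assign_mechanisms(model)
        assert mechs["PGI"].kind == "rev_michaelis_menten_uni_uni"
        assert mechs["PFK"].kind == "hill_allosteric"
        assert mechs["PFK"].hill_h == 4.0
        roles = {m.metabolite: m.role for m in mechs["PFK"].modifiers}
        assert roles == {"amp_c": "activator", "atp_c": "inhibitor"}
        assert all(m.same_site for m in mechs["PFK"].modifiers)
        override = {"PGI": MechanismSpec("generalized_reversible_hill", hill_h=2.0)}
        assert assign_mechanisms(model, override)["PGI"].hill_h == 2.0

    def test_multisubstrate_defaults_to_convenience(self):
        toy = syn.gen_toy_moiety(seed=0)
        mechs = assign_mechanisms(toy.network)
        assert mechs["R1"].kind == "convenience"
        assert mechs["R2"].kind == "rev_michaelis_menten_uni_uni"

    def test_unknown_reaction_override_rejected(self, scenario):
        with pytest.raises(KeyError):
            assign_mechanisms(scenario.model, {"NOPE": MechanismSpec("convenience")})

    def test_hill_spec_requires_coefficient(self):
        with pytest.raises(ValueError):
            MechanismSpec("hill_allosteric")
        with pytest.raises(ValueError):
            MechanismSpec("convenience", hill_h=2.0)


class TestSaturationSampling:
    def test_deterministic_under_seed(self, scenario):
        a = sample_saturations(scenario.model, scenario.mechanisms, n=3, seed=9)
        b = sample_saturations(scenario.model, scenario.mechanisms, n=3, seed=9)
        assert all(x.sigma == y.sigma for x, y in zip(a, b))

    def test_uniform_moments(self, scenario):
        draws = sample_saturations(scenario.model, scenario.mechanisms, n=10_000, seed=1)
        key = ("HXK", "glc_c")
        vals = np.array([d.sigma[key] for d in draws])
        assert abs(vals.mean() - 0.5) < 0.02
        assert np.all((vals > 0) & (vals < 1))

    def test_sites_cover_reactants_and_modifiers(self, scenario):
        sites = reaction_sites(scenario.model, "PFK", scenario.mechanisms["PFK"])
        assert set(sites) >= {"f6p_c", "atp_c", "fbp_c", "adp_c", "amp_c"}

    def test_missing_site_is_a_construction_error(self, scenario):
        sample = sample_saturations(scenario.model, scenario.mechanisms, n=1, seed=0)[0]
        with pytest.raises(KeyError):
            sample.of("HXK", "not_a_site")


class TestElasticities:
    def test_uni_uni_closed_form(self):
        spec = MechanismSpec("rev_michaelis_menten_uni_uni")
        eps = elasticities(spec, {"S": 0.5, "P": 0.5}, gamma=0.01, flux_sign=1, stoichiometry={"S": -1, "P": 1})
        assert eps["S"] == pytest.approx(1 / 0.99 - 0.5, abs=1e-12)
        assert eps["P"] == pytest.approx(-0.01 / 0.99 - 0.5, abs=1e-12)

    def test_far_from_equilibrium_limits(self):
        spec = MechanismSpec("rev_michaelis_menten_uni_uni")
        g = 1e-12
        sat = elasticities(spec, {"S": 1 - 1e-12, "P": 0.5}, g, 1, {"S": -1, "P": 1})
        assert sat["S"] == pytest.approx(0.0, abs=1e-9)  # fully saturated
        lin = elasticities(spec, {"S": 1e-12, "P": 0.5}, g, 1, {"S": -1, "P": 1})
        assert lin["S"] == pytest.approx(1.0, abs=1e-9)  # first-order regime

    def test_near_equilibrium_thermodynamic_dominance(self):
        spec = MechanismSpec("rev_michaelis_menten_uni_uni")
        eps = elasticities(spec, {"S": 0.99, "P": 0.99}, gamma=0.99, flux_sign=1,
                           stoichiometry={"S": -1, "P": 1})
        # the 1/(1-Gamma) term exceeds any saturation term by >= 10x
        assert abs(eps["S"]) > 10
        assert abs(eps["P"]) > 10

    def test_signs_substrates_positive_products_negative(self):
        rng = np.random.default_rng(0)
        spec = MechanismSpec("ordered_bi_bi")
        for _ in range(50):
            sig = {k: float(rng.uniform(0.01, 0.99)) for k in "ABPQ"}
            eps = elasticities(spec, sig, float(rng.uniform(0.01, 0.99)), 1,
                               {"A": -1, "B": -1, "P": 1, "Q": 1})
            assert eps["A"] > 0 and eps["B"] > 0
            assert eps["P"] < 0 and eps["Q"] < 0

    def test_inadmissible_gamma_rejected(self):
        spec = MechanismSpec("rev_michaelis_menten_uni_uni")
        for g in (0.0, 1.0, 1.5):
            with pytest.raises(ValueError):
                elasticities(spec, {"S": 0.5, "P": 0.5}, g, 1, {"S": -1, "P": 1})

    @pytest.mark.parametrize("spec,stoich", CASES, ids=[c[0].kind for c in CASES])
    def test_closed_form_matches_rate_law_differentiation(self, spec, stoich):
        """Symbolic d ln v / d ln x of the explicit law reproduces the closed form."""
        rng = np.random.default_rng(17)
        sites = list(stoich) + [m.metabolite for m in spec.modifiers if m.metabolite not in stoich]
        for _ in range(3):
            sigma = {m: float(rng.uniform(0.05, 0.95)) for m in sites}
            gamma = float(rng.uniform(0.02, 0.95))
            closed = elasticities(spec, sigma, gamma, 1.0, stoich)
            subs, v, syms = operating_point(spec, stoich, sigma, gamma)
            per_met = {}
            for key, x in syms.items():
                met = key.split("__")[0]
                per_met[met] = per_met.get(met, 0.0) + float((x * sp.diff(v, x) / v).subs(subs))
            for met, val in per_met.items():
                assert closed[met] == pytest.approx(val, rel=1e-6), (spec.kind, met)

    @pytest.mark.parametrize("spec,stoich", CASES[:6], ids=[c[0].kind for c in CASES[:6]])
    def test_closed_form_matches_finite_differences(self, spec, stoich):
        """Central differences of the numeric rate law agree to 1e-6 relative."""
        rng = np.random.default_rng(23)
        sites = list(stoich) + [m.metabolite for m in spec.modifiers if m.metabolite not in stoich]
        sigma = {m: float(rng.uniform(0.1, 0.9)) for m in sites}
        gamma = float(rng.uniform(0.05, 0.9))
        closed = elasticities(spec, sigma, gamma, 1.0, stoich)
        subs, v, syms = operating_point(spec, stoich, sigma, gamma)
        vmax_subs = {k: s for k, s in subs.items() if k not in set(syms.values())}
        f = sp.lambdify(list(syms.values()), v.subs(vmax_subs), "numpy")
        x0 = np.array([float(subs[s]) for s in syms.values()])
        h = 1e-6
        for i, key in enumerate(syms):
            met = key.split("__")[0]
            hi, lo = x0.copy(), x0.copy()
            hi[i] *= 1 + h
            lo[i] *= 1 - h
            num = (np.log(abs(f(*hi))) - np.log(abs(f(*lo)))) / (np.log(hi[i]) - np.log(lo[i]))
            assert num == pytest.approx(closed[met], rel=1e-6, abs=1e-8)


class TestElasticityMatrix:
    def test_sparsity_and_zero_rows(self, scenario, scenario_flux):
        from mcapop.thermo import sample_concentrations

        prof = sample_concentrations(scenario.model, scenario_flux, n=1, seed=2)[0]
        sat = sample_saturations(scenario.model, scenario.mechanisms, n=1, seed=2)[0]
        E = elasticity_matrix(scenario.model, scenario.mechanisms, prof, sat, scenario_flux)
        model = scenario.model
        internal = {m.id: k for k, m in enumerate(model.internal_metabolites)}
        for j, r in enumerate(model.reactions):
            if abs(scenario_flux.flux(r.id)) < 1e-9:
                assert not E[j].any()
                continue
            allowed = set(r.stoichiometry) | {
                m.metabolite for m in scenario.mechanisms[r.id].modifiers
            }
            nz = {mid for mid, k in internal.items() if E[j, k] != 0}
            assert nz <= allowed
            assert nz  # flux-carrying reactions respond to something

    def test_missing_displacement_is_an_error(self, scenario, scenario_flux):
        from mcapop.thermo import DisplacementProfile, sample_concentrations

        prof = sample_concentrations(scenario.model, scenario_flux, n=1, seed=2)[0]
        sat = sample_saturations(scenario.model, scenario.mechanisms, n=1, seed=2)[0]
        broken = DisplacementProfile(
            met_ids=prof.met_ids, ln_conc=prof.ln_conc, gamma={}, deltaG={}, K_eq={}
        )
        with pytest.raises(KeyError):
            elasticity_matrix(scenario.model, scenario.mechanisms, broken, sat, scenario_flux)
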