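import numpy as np
import pytest
from scipy import stats

import mcapop as mp
from mcapop import synthetic as syn
from mcapop.network import Metabolite, NetworkModel, Reaction
from mcapop.thermo import (
    DEFAULT_T,
    R_KJ,
    TfaInfeasibleError,
    classify_displacement,
    displacement,
    gibbs_from_displacement,
    keq_from_deltaG0,
    recheck_profile,
    sample_concentrations,
)


def chain_model(dg0=(None, None, None)):
    mets = [
        Metabolite(id="A_ext", compartment="extracellular", boundary=True,
                   conc_lb=1e-3, conc_ub=1e-2),
        Metabolite(id="A_c"),
        Metabolite(id="B_c"),
        Metabolite(id="B_ext", compartment="extracellular", boundary=True,
                   conc_lb=1e-6, conc_ub=1e-4),
    ]
    rxns = [
        Reaction(id="T1", stoichiometry={"A_ext": -1, "A_c": 1}, deltaG0=dg0[0]),
        Reaction(id="R1", stoichiometry={"A_c": -1, "B_c": 1}, deltaG0=dg0[1]),
        Reaction(id="T2", stoichiometry={"B_c": -1, "B_ext": 1}, deltaG0=dg0[2]),
    ]
    return NetworkModel(mets, rxns, name="chain")


class TestDisplacement:
    def test_equilibrium_gives_one(self):
        assert displacement(1.0, {"S": 0.3}, {"P": 0.3}) == pytest.approx(1.0)

    def test_uni_uni_arithmetic(self):
        assert displacement(10.0, {"S": 1.0}, {"P": 1.0}) == pytest.approx(0.1)

    def test_product_proportionality(self):
        g1 = displacement(5.0, {"S": 0.2}, {"P": 0.1})
        g2 = displacement(5.0, {"S": 0.2}, {"P": 0.2})
        assert g2 == pytest.approx(2 * g1)

    def test_stoichiometric_exponents(self):
        g = displacement(1.0, {"S": 0.5}, {"P": 0.5}, stoich={"S": -2, "P": 1})
        assert g == pytest.approx(0.5 / 0.25)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            displacement(1.0, {"S": 0.0}, {"P": 1.0})


class TestGibbs:
    def test_zero_at_equilibrium(self):
        assert gibbs_from_displacement(1.0) == 0.0

    def test_rt_value_at_standard_temperature(self):
        assert gibbs_from_displacement(np.exp(-1), 298.15) == pytest.approx(-2.479, abs=1e-3)

    def test_sign_convention(self):
        assert gibbs_from_displacement(0.5) < 0
        with pytest.raises(ValueError):
            gibbs_from_displacement(0.0)

    def test_keq_standard_relation(self):
        dg0 = -10.0
        k = keq_from_deltaG0(dg0)
        assert -R_KJ * DEFAULT_T * np.log(k) == pytest.approx(dg0)


class TestClassification:
    @pytest.mark.parametrize(
        "samples,expected",
        [
            ([0.01, 0.05, 0.1], "far"),
            ([0.95], "near"),
            ([0.3, 0.5, 0.8], "middle"),
            ([0.05, 0.5, 0.85], "far+middle"),
            ([0.2, 0.95], "middle+near"),
            ([0.05, 0.5, 0.95], "full"),
        ],
    )
    def test_six_bins(self, samples, expected):
        assert classify_displacement(samples) == expected

    def test_empty_and_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_displacement([])
        with pytest.raises(ValueError):
            classify_displacement([1.0])


class TestTfa:
    def test_toy_chain_conservation(self):
        model = chain_model()
        flux = mp.tfa_solve(model, {"T1": (1.0, 1.0)})
        assert flux.flux("R1") == pytest.approx(1.0, abs=1e-9)
        assert flux.flux("T2") == pytest.approx(1.0, abs=1e-9)

    def test_thermodynamic_contradiction_reported(self):
        # dG0 strongly positive and concentrations unable to compensate, while
        # the measured rate forces forward flux
        model = chain_model(dg0=(None, 150.0, None))
        with pytest.raises(TfaInfeasibleError):
            mp.tfa_solve(model, {"R1": (1.0, 1.0)})

    def test_oxygen_cap_respected_on_packaged_scenario(self, scenario, scenario_flux):
        assert scenario.measured_rates["O2t"] == (0.0, 2.0)
        assert scenario_flux.flux("O2t") <= 2.0 + 1e-9

    def test_mass_balance_reverified(self, scenario, scenario_flux):
        N = scenario.model.internal_stoich
        assert np.max(np.abs(N @ scenario_flux.v)) < 1e-6

    def test_flux_directions_thermodynamically_signed(self, scenario, scenario_flux):
        # the TFA solution's own log-concentrations certify every direction
        RT = R_KJ * DEFAULT_T
        for r in scenario.model.reactions:
            if r.deltaG0 is None or r.is_exchange or abs(scenario_flux.flux(r.id)) < 1e-9:
                continue
            dg = r.deltaG0 + RT * sum(
                float(c) * scenario_flux.ln_conc[scenario.model.met_index[m]]
                for m, c in r.stoichiometry.items()
            )
            assert np.sign(dg) == -np.sign(scenario_flux.flux(r.id))


class TestFva:
    def test_toy_chain_full_range(self):
        model = chain_model()
        res = mp.fva(model, {"T1": (0.0, 1.0)})
        for rid in ("T1", "R1", "T2"):
            assert res[rid][0] == pytest.approx(0.0, abs=1e-9)
            assert res[rid][1] == pytest.approx(1.0, abs=1e-9)

    def test_fixed_reaction_collapses_range(self):
        model = chain_model()
        res = mp.fva(model, {"T1": (0.0, 1.0), "R1": (0.0, 0.0)})
        assert res["T2"] == (pytest.approx(0.0, abs=1e-9), pytest.approx(0.0, abs=1e-9))

    def test_ranges_contain_random_feasible_points(self):
        model = chain_model()
        res = mp.fva(model, {"T1": (0.2, 0.8)})
        rng = np.random.default_rng(0)
        for _ in range(100):
            u = rng.uniform(0.2, 0.8)  # feasible uptake pins every flux
            for rid in ("T1", "R1", "T2"):
                assert res[rid][0] - 1e-9 <= u <= res[rid][1] + 1e-9


class TestConcentrationSampler:
    def test_determinism_under_fixed_seed(self):
        model = chain_model(dg0=(0.0, -5.0, 0.0))
        flux = mp.tfa_solve(model, {"T1": (1.0, 1.0)})
        a = sample_concentrations(model, flux, n=20, seed=42)
        b = sample_concentrations(model, flux, n=20, seed=42)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.ln_conc, pb.ln_conc)

    def test_gamma_strictly_inside_unit_interval(self):
        model = chain_model(dg0=(0.0, -5.0, 0.0))
        flux = mp.tfa_solve(model, {"T1": (1.0, 1.0)})
        profiles = sample_concentrations(model, flux, n=200, seed=1)
        gam = np.array([p.gamma[r] for p in profiles for r in p.gamma])
        assert np.all((gam > 0) & (gam < 1))

    def test_every_profile_passes_independent_recheck(self, scenario, scenario_flux):
        profiles = sample_concentrations(scenario.model, scenario_flux, n=100, seed=5)
        assert all(recheck_profile(scenario.model, p, scenario_flux) for p in profiles)

    def test_one_dimensional_marginal_uniform(self):
        # single free internal metabolite, no dG constraints: the feasible
        # region is a box and the sampled ln-concentration must be uniform
        mets = [
            Metabolite(id="A_ext", compartment="extracellular", boundary=True),
            Metabolite(id="M_c", conc_lb=1e-6, conc_ub=1e-2),
            Metabolite(id="B_ext", compartment="extracellular", boundary=True),
        ]
        rxns = [
            Reaction(id="R1", stoichiometry={"A_ext": -1, "M_c": 1}),
            Reaction(id="R2", stoichiometry={"M_c": -1, "B_ext": 1}),
        ]
        model = NetworkModel(mets, rxns)
        flux = mp.tfa_solve(model, {"R1": (1.0, 1.0)})
        profiles = sample_concentrations(model, flux, n=10_000, seed=3, burn_in=200, thin=2)
        j = model.met_index["M_c"]
        u = np.array([p.ln_conc[j] for p in profiles])
        scaled = (u - np.log(1e-6)) / (np.log(1e-2) - np.log(1e-6))
        ks = stats.kstest(scaled, "uniform").statistic
        assert ks < 0.05

    def test_empty_polytope_is_an_error(self):
        model = chain_model(dg0=(0.0, 150.0, 0.0))
        flux = mp.FluxProfile(reaction_ids=["T1", "R1", "T2"], v=np.ones(3))
        with pytest.raises(TfaInfeasibleError):
            sample_concentrations(model, flux, n=5, seed=0)
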