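import numpy as np
import pytest

import mcapop as mp
from mcapop import synthetic as syn
from mcapop.mca import respond, stability_check, turnover_control
from mcapop.network import Metabolite, NetworkModel, Reaction

from conftest import engine_control_sample


class TestClosedFormChain:
    def test_two_step_first_order_chain(self):
        """C_E1^J = b/(a+b), C_E2^J = a/(a+b) for elasticities (-a, +b) on M.

        Independent hand computation: at steady state e1(k1 A - k1r M) =
        e2(k2 M - k2r B); implicit differentiation of ln J with respect to
        ln e1 and ln e2 gives the textbook ratio of elasticity magnitudes.
        """
        toy = syn.gen_toy_chain(2, "first_order", seed=5)
        x, fp, cs = engine_control_sample(toy)
        E = toy.elasticity_matrix_at(x)
        a = -E[0, 0]  # product elasticity of step 1 on M (negative entry)
        b = E[1, 0]  # substrate elasticity of step 2 on M
        assert cs.flux_cc("R1", "R1") == pytest.approx(b / (a + b), rel=1e-6)
        assert cs.flux_cc("R2", "R1") == pytest.approx(a / (a + b), rel=1e-6)
        # flux control is the same for every step of a linear chain
        assert cs.flux_cc("R1", "R2") == pytest.approx(b / (a + b), rel=1e-6)

    def test_oracle_agreement_chain_to_1e6(self):
        toy = syn.gen_toy_chain(2, "first_order", seed=5)
        _, _, cs = engine_control_sample(toy)
        fd = syn.finite_difference_cc(toy, "R1", richardson=True)
        assert cs.flux_cc("R1", "R1") == pytest.approx(fd["flux"]["R1"], rel=1e-6)


class TestOracleEquivalence:
    def test_engine_matches_finite_differences_on_all_toys(self, toy_models):
        """Control coefficients agree with brute-force steady-state sensitivities."""
        for name, toy in toy_models.items():
            x, fp, cs = engine_control_sample(toy)
            assert cs.stable, name
            for rid in [r.id for r in toy.network.reactions]:
                fd = syn.finite_difference_cc(toy, rid, richardson=True)
                for tid, expected in fd["flux"].items():
                    assert cs.flux_cc(rid, tid) == pytest.approx(
                        expected, rel=1e-3, abs=1e-6
                    ), (name, rid, tid)
                for mid in cs.met_ids:
                    assert cs.conc_cc(rid, mid) == pytest.approx(
                        fd["conc"][mid], rel=1e-3, abs=1e-6
                    ), (name, rid, mid)


class TestTheorems:
    def test_summation_theorems_on_toys(self, toy_models):
        for name, toy in toy_models.items():
            _, _, cs = engine_control_sample(toy)
            np.testing.assert_allclose(cs.C_flux.sum(axis=1), 1.0, atol=1e-8, err_msg=name)
            np.testing.assert_allclose(cs.C_conc.sum(axis=1), 0.0, atol=1e-8, err_msg=name)

    def test_connectivity_theorem_on_chain(self):
        # sum_q C_q^J * eps_q,M = 0 for flux; = -delta for concentrations
        toy = syn.gen_toy_chain(3, "first_order", seed=8)
        x, fp, cs = engine_control_sample(toy)
        E = toy.elasticity_matrix_at(x)
        np.testing.assert_allclose(cs.C_flux @ E, 0.0, atol=1e-8)
        np.testing.assert_allclose(cs.C_conc @ E, -np.eye(len(cs.met_ids)), atol=1e-8)


class TestStability:
    def test_filter_matches_independent_jacobian_assembly(self, toy_models):
        from mcapop.network import reduce_structure

        for name, toy in toy_models.items():
            x, fp, cs = engine_control_sample(toy)
            red = reduce_structure(toy.network)
            xv = np.array([x[m] for m in toy.internal_ids])
            E = toy.elasticity_matrix_at(x)
            ok, eig = stability_check(red, fp.v, E, xv)
            assert ok == cs.stable
            np.testing.assert_allclose(
                np.sort(eig.real), np.sort(cs.eigenvalues.real), rtol=1e-8
            )

    def test_positive_eigenvalue_rejected(self):
        # a constructed autocatalytic-style elasticity makes the state unstable
        mets = [
            Metabolite(id="A_ext", compartment="extracellular", boundary=True),
            Metabolite(id="M"),
            Metabolite(id="B_ext", compartment="extracellular", boundary=True),
        ]
        rxns = [
            Reaction(id="R1", stoichiometry={"A_ext": -1, "M": 1}),
            Reaction(id="R2", stoichiometry={"M": -1, "B_ext": 1}),
        ]
        net = NetworkModel(mets, rxns)
        red = mp.reduce_structure(net)
        v = np.array([1.0, 1.0])
        E = np.array([[2.0], [-1.0]])  # production grows with M faster than removal
        cs = mp.control_coefficients(red, v, E)
        assert not cs.stable
        ok, _ = stability_check(red, v, E)
        assert not ok

    def test_marginal_zero_eigenvalue_rejected(self):
        mets = [
            Metabolite(id="A_ext", compartment="extracellular", boundary=True),
            Metabolite(id="M"),
            Metabolite(id="B_ext", compartment="extracellular", boundary=True),
        ]
        rxns = [
            Reaction(id="R1", stoichiometry={"A_ext": -1, "M": 1}),
            Reaction(id="R2", stoichiometry={"M": -1, "B_ext": 1}),
        ]
        net = NetworkModel(mets, rxns)
        red = mp.reduce_structure(net)
        ok, _ = stability_check(red, np.ones(2), np.array([[1.0], [1.0]]))
        assert not ok  # Jacobian exactly zero: marginal, rejected


class TestTurnover:
    def test_single_producer_degenerates_to_flux_cc(self, toy_models):
        toy = toy_models["chain_first_order"]
        _, fp, cs = engine_control_sample(toy)
        t = turnover_control(cs, fp, "M1", producing=["R1"], parameters=["R1"])
        assert t.C_turnover["R1"] == pytest.approx(cs.flux_cc("R1", "R1"))
        assert t.tMet == pytest.approx(fp.flux("R1"))

    def test_two_producer_weighted_sum(self):
        # v = (1, 1), C = (0.2, 0.4) -> 0.3, constructed directly
        cs = mp.ControlSample(
            reaction_ids=["P1", "P2"],
            met_ids=[],
            C_flux=np.array([[0.2, 0.0], [0.4, 0.0]]),
            C_conc=np.zeros((0, 2)),
            stable=True,
            eigenvalues=np.array([]),
        )
        fp = mp.FluxProfile(reaction_ids=["P1", "P2"], v=np.array([1.0, 1.0]))
        t = turnover_control(cs, fp, "met", producing=["P1", "P2"], parameters=["P1"])
        assert t.C_turnover["P1"] == pytest.approx(0.3)

    def test_zero_turnover_rejected(self):
        cs = mp.ControlSample(
            reaction_ids=["P1"], met_ids=[], C_flux=np.zeros((1, 1)),
            C_conc=np.zeros((0, 1)), stable=True, eigenvalues=np.array([]),
        )
        fp = mp.FluxProfile(reaction_ids=["P1"], v=np.array([0.0]))
        with pytest.raises(ValueError):
            turnover_control(cs, fp, "met", producing=["P1"])


class TestRespond:
    @pytest.mark.parametrize(
        "C,change,expected",
        [(0.29, 100.0, 29.0), (-0.07, 100.0, -7.0), (0.18, -50.0, -9.0),
         (0.095, -50.0, -4.75), (-0.11, 100.0, -11.0), (0.5, 0.0, 0.0)],
    )
    def test_linear_interpretation(self, C, change, expected):
        assert respond(C, change) == pytest.approx(expected)

    def test_power_law_alternative(self):
        assert respond(1.0, 100.0, mode="power") == pytest.approx(100.0)
        assert respond(0.5, 100.0, mode="power") == pytest.approx((2**0.5 - 1) * 100)
        with pytest.raises(ValueError):
            respond(0.5, -150.0, mode="power")
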