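"""Network model: schema validation, stoichiometric decomposition, rate laws."""

import numpy as np
import pytest

import stocan as sc
from stocan.errors import EvaluationError, SchemaError

BD_TEXT = """
model birth_death
species
  X = 5
parameters
  k_s = 2.0
  k_d = 0.4
reactions
  synthesis: -> X ; k_s
  degradation: X -> ; k_d * X
"""


class TestBuildNetwork:
    def test_birth_death_from_text(self):
        net = sc.build_network(BD_TEXT)
        assert len(net.species) == 1
        assert len(net.reactions) == 2
        assert len(net.parameters) == 2
        assert net.parameter_ids == ["k_s", "k_d"]  # declaration order

    def test_birth_death_from_dict(self):
        net = sc.build_network(
            {
                "species": [{"id": "X", "initial_amount": 5}],
                "parameters": [{"id": "k_s", "value": 2.0}, {"id": "k_d", "value": 0.4}],
                "reactions": [
                    {"id": "syn", "stoichiometry": {"X": 1}, "rate": "k_s"},
                    {"id": "deg", "stoichiometry": {"X": -1}, "rate": "k_d*X"},
                ],
            }
        )
        assert net.stoichiometry_matrix.tolist() == [[1, -1]]

    def test_promoter_has_four_species(self, promoter):
        assert len(promoter.species) == 4
        assert len(promoter.reactions) == 6

    @pytest.mark.parametrize(
        "mutation, match",
        [
            (dict(value=0.0), "must be > 0"),
            (dict(value=-1.0), "must be > 0"),
        ],
    )
    def test_nonpositive_parameter_rejected(self, mutation, match):
        with pytest.raises(SchemaError, match=match):
            sc.Parameter("k", **mutation)

    def test_undeclared_identifier_rejected(self):
        with pytest.raises(SchemaError, match="undeclared identifier"):
            sc.build_network(BD_TEXT.replace("k_d * X", "k_d * Y"))

    def test_unsupported_function_rejected(self):
        with pytest.raises(SchemaError, match="unsupported construct"):
            sc.build_network(BD_TEXT.replace("k_d * X", "sin(X)"))

    def test_duplicate_id_rejected(self):
        with pytest.raises(SchemaError, match="duplicate"):
            sc.ReactionNetwork(
                species=[sc.Species("X", 1.0), sc.Species("X", 2.0)],
                parameters=[sc.Parameter("k", 1.0)],
                reactions=[sc.Reaction("r", {"X": 1}, "k")],
            )

    def test_hill_is_part_of_the_grammar(self):
        net = sc.build_network(
            BD_TEXT.replace("k_d * X", "k_d * X * hill(X, 10, 2)")
        )
        v = net.rates([10.0])
        assert v[1] == pytest.approx(0.4 * 10 / 2)  # midpoint of the Hill term


class TestDecomposition:
    def test_birth_death_full_rank(self, birth_death):
        s = sc.stoichiometric_decomposition(birth_death)
        assert s.N.tolist() == [[1, -1]]
        assert np.array_equal(s.N_R, s.N)
        assert s.L.tolist() == [[1.0]]
        assert s.conservation == []

    def test_promoter_conservation(self, promoter):
        s = sc.stoichiometric_decomposition(promoter)
        assert s.N_R.shape[0] == 3
        assert len(s.conservation) == 1
        g, total = s.conservation[0]
        assert total == pytest.approx(1.0)  # one promoter copy in total
        assert np.allclose(g @ s.N, 0)

    def test_pathway_A_rank_three(self, pathway_A):
        s = sc.stoichiometric_decomposition(pathway_A)
        # E is a boundary species: no row in N; the chain has full rank
        assert s.N.shape == (3, 4)
        assert s.N_R.shape[0] == 3
        assert s.conservation == []

    @pytest.mark.parametrize(
        "maker",
        ["birth_death", "two_state_promoter", "linear_pathway", "feedback_oscillator"],
    )
    def test_factorization_exact(self, maker):
        net = sc.get_fixture(maker)
        s = sc.stoichiometric_decomposition(net)
        assert np.array_equal(s.L @ s.N_R, s.N)
        assert np.linalg.matrix_rank(s.N) == s.N_R.shape[0]
        for g, total in s.conservation:
            assert np.allclose(g @ s.N, 0)

    def test_conserved_totals_follow_the_state(self, promoter):
        s = sc.stoichiometric_decomposition(promoter)
        traj = sc.ssa_simulate(promoter, s, t_end=5.0, seed=3)
        dyn = [promoter.species_ids.index(x) for x in promoter.dynamic_species]
        for g, total in s.conservation:
            assert np.allclose(traj.states[:, dyn] @ g, total)


class TestRates:
    def test_birth_death_values(self, birth_death):
        assert np.allclose(sc.evaluate_rates(birth_death, [5.0]), [2.0, 2.0])

    def test_steady_state_annihilates_rates(self, promoter):
        s = sc.stoichiometric_decomposition(promoter)
        x_star, v_star = sc.solve_steady_state(promoter, s)
        assert np.linalg.norm(s.N_R @ v_star) < 1e-10 * max(1, np.linalg.norm(v_star))

    def test_negative_rate_raises(self):
        net = sc.build_network(BD_TEXT.replace("k_d * X", "k_d * (X - 10)"))
        with pytest.raises(EvaluationError, match="negative rate"):
            net.rates([5.0])


class TestDerivatives:
    def test_birth_death_analytic(self, birth_death):
        dvdx, dvdp = sc.rate_derivatives(birth_death, [5.0])
        assert np.allclose(dvdx, [[0.0], [0.4]])
        assert np.allclose(dvdp, [[1.0, 0.0], [0.0, 5.0]])

    def test_mass_action_product_rule(self):
        net = sc.build_network(
            {
                "species": [{"id": "A", "initial_amount": 3}, {"id": "B", "initial_amount": 4}],
                "parameters": [{"id": "k", "value": 2.0}],
                "reactions": [{"id": "bind", "stoichiometry": {"A": -1, "B": -1}, "rate": "k*A*B"}],
            }
        )
        dvdx, _ = sc.rate_derivatives(net, [3.0, 4.0])
        assert np.allclose(dvdx, [[2.0 * 4.0, 2.0 * 3.0]])

    def test_hill_midpoint_slope(self):
        # d/dX [k E hill(X,K,h)] at X=K equals -k E h / (4K)
        k, E, K, h = 1.5, 10.0, 8.0, 2.0
        net = sc.build_network(
            {
                "species": [
                    {"id": "E", "initial_amount": E, "is_boundary": True},
                    {"id": "X", "initial_amount": K},
                ],
                "parameters": [{"id": "k", "value": k}, {"id": "K", "value": K}, {"id": "h", "value": h}],
                "reactions": [{"id": "in", "stoichiometry": {"X": 1}, "rate": "k*E*hill(X,K,h)"}],
            }
        )
        dvdx, _ = sc.rate_derivatives(net, [E, K])
        assert dvdx[0, 0] == pytest.approx(-k * E * h / (4 * K))

    @pytest.mark.parametrize(
        "name, kw",
        [
            ("birth_death", {}),
            ("two_state_promoter", {}),
            ("linear_pathway", {"variant": "BC"}),
            ("feedback_oscillator", {}),
        ],
    )
    def test_symbolic_agrees_with_finite_differences(self, name, kw):
        net = sc.get_fixture(name, **kw)
        x = net.initial_state + 0.5
        sym = sc.rate_derivatives(net, x, method="symbolic")
        fd = sc.rate_derivatives(net, x, method="fd")
        for a, b in zip(sym, fd):
            assert np.allclose(a, b, rtol=1e-6, atol=1e-8)


class TestSchemaRoundTrip:
    @pytest.mark.parametrize(
        "name, kw",
        [
            ("birth_death", {}),
            ("two_state_promoter", {}),
            ("linear_pathway", {"variant": "B"}),
            ("feedback_oscillator", {}),
        ],
    )
    def test_serialize_parse_identical(self, name, kw):
        net = sc.get_fixture(name, **kw)
        back = sc.parse_model_text(sc.serialize_model(net))
        assert back.species_ids == net.species_ids
        assert back.parameter_ids == net.parameter_ids
        assert np.array_equal(back.stoichiometry_matrix, net.stoichiometry_matrix)
        assert np.allclose(back.parameter_values, net.parameter_values)
        if net.kind == "langevin":
            assert np.allclose(back.diffusion, net.diffusion)
        # same steady state to high precision
        s1 = sc.lna_analysis(net)
        s2 = sc.lna_analysis(back)
        assert np.allclose(s1.x_star, s2.x_star, rtol=1e-12, atol=1e-12)
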