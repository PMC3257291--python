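"""Control design: projections, generalized control, tolerance geometry,
pair ranking, iterative reduction, oscillation scoring."""

import numpy as np
import pytest

import stocan as sc
from stocan.design import ControlVector, _find_trough_peak
from stocan.errors import DesignError


def cv(comps, var="v", pids=None):
    comps = np.asarray(comps, float)
    pids = pids or [f"p{i}" for i in range(len(comps))]
    return ControlVector(variable=var, parameter_ids=pids, components=comps)


class TestControlVector:
    def test_birth_death_vectors(self, birth_death):
        ccs = sc.compute_control_coefficients(birth_death)
        assert np.allclose(sc.control_vector(ccs, "mean:X").components, [1, -1])
        assert np.allclose(sc.control_vector(ccs, "noise:X").components, [-1, 1])

    def test_single_parameter_subspace(self, birth_death):
        ccs = sc.compute_control_coefficients(birth_death)
        g = sc.control_vector(ccs, "mean:X", ["k_d"])
        assert g.components.shape == (1,)
        assert g.components[0] == pytest.approx(-1.0)

    def test_unknown_variable_raises(self, birth_death):
        ccs = sc.compute_control_coefficients(birth_death)
        with pytest.raises(DesignError):
            sc.control_vector(ccs, "mean:nosuch")
        with pytest.raises(DesignError):
            sc.control_vector(ccs, "mean:X", ["nosuch"])


class TestOrthogonalDesign:
    def test_anti_parallel_impossible(self, birth_death):
        ccs = sc.compute_control_coefficients(birth_death)
        d = sc.orthogonal_design(
            sc.control_vector(ccs, "mean:X"), sc.control_vector(ccs, "noise:X")
        )
        assert d.impossible
        assert d.strength_S == 0.0
        assert d.efficiency_eps < 1e-8

    def test_perpendicular_is_maximal(self):
        d = sc.orthogonal_design(cv([1, 0]), cv([0, 1]), sense="reduce")
        assert np.allclose(d.direction, [0, -1])
        assert d.efficiency_eps == pytest.approx(1.0)
        assert d.strength_S == pytest.approx(1.0)

    def test_direction_orthogonal_to_fixed(self, rng):
        for _ in range(50):
            n = rng.integers(2, 7)
            gf, gm = cv(rng.normal(size=n)), cv(rng.normal(size=n))
            d = sc.orthogonal_design(gf, gm)
            if d.impossible:
                continue
            assert abs(d.direction @ gf.components) < 1e-10
            assert 0 <= d.efficiency_eps <= 1
            assert d.strength_S <= gm.norm + 1e-12

    def test_lagrange_projection_equivalence(self, rng):
        """Min-norm perturbation holding the fixed variable and moving the
        moved one is parallel to the projection construction."""
        for _ in range(100):
            n = rng.integers(2, 7)
            gf, gm = rng.normal(size=n), rng.normal(size=n)
            d = sc.orthogonal_design(cv(gf), cv(gm), sense="reduce")
            if d.impossible:
                continue
            G = np.vstack([gf, gm])
            delta = np.linalg.pinv(G) @ np.array([0.0, -1.0])
            cos = delta @ d.direction / np.linalg.norm(delta)
            assert cos > 1 - 1e-10


class TestGeneralizedDesign:
    def test_birth_death_orthogonal_request_overconstrained(self, birth_death):
        ccs = sc.compute_control_coefficients(birth_death)
        G = np.vstack(
            [sc.control_vector(ccs, "mean:X").components,
             sc.control_vector(ccs, "noise:X").components]
        )
        d = sc.generalized_design(G, [0.0, -3.0], parameter_ids=ccs.parameter_ids)
        assert d.status == "overconstrained"

    def test_single_target_min_norm(self):
        d = sc.generalized_design(np.array([[1.0, -1.0]]), [-10.0])
        assert d.status == "min-norm"
        assert np.allclose(d.delta_p, [-5.0, 5.0])

    def test_square_nonsingular_exact(self):
        G = np.array([[1.0, 0.5], [0.0, 2.0]])
        t = np.array([1.0, -2.0])
        d = sc.generalized_design(G, t)
        assert d.status == "exact"
        assert d.residual == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(G @ d.delta_p, t)


class TestToleranceGeometry:
    def test_zero_tolerance_reduces_to_orthogonal(self, rng):
        for _ in range(20):
            gf, gm = cv(rng.normal(size=4)), cv(rng.normal(size=4))
            base = sc.orthogonal_design(gf, gm)
            tolled = sc.tolerance_adjusted_metrics(gf, gm, 0.0)
            assert tolled.efficiency_eps == pytest.approx(base.efficiency_eps)
            assert tolled.strength_S == pytest.approx(base.strength_S)
            if not base.impossible:
                assert np.allclose(tolled.direction, base.direction)

    def test_small_fixed_vector_gives_full_efficiency(self):
        gf, gm = cv([0.1, 0.0]), cv([3.0, 4.0])
        d = sc.tolerance_adjusted_metrics(gf, gm, tol=0.5)
        assert d.efficiency_eps == pytest.approx(1.0)
        assert d.strength_S == pytest.approx(5.0)

    def test_anti_parallel_half_norm_tolerance(self):
        # cone half-angle arcsin(1/2) = 30 degrees; residual angle 60 degrees
        gf, gm = cv([1.0, -1.0]), cv([-1.0, 1.0])
        d = sc.tolerance_adjusted_metrics(gf, gm, tol=gf.norm / 2)
        assert d.efficiency_eps == pytest.approx(0.5)

    def test_efficiency_monotone_in_tolerance(self, rng):
        for _ in range(10):
            gf, gm = cv(rng.normal(size=3)), cv(rng.normal(size=3))
            tols = np.linspace(0, 1.5 * gf.norm, 12)
            eps = [sc.tolerance_adjusted_metrics(gf, gm, t).efficiency_eps for t in tols]
            assert np.all(np.diff(eps) >= -1e-12)
            assert eps[-1] == pytest.approx(1.0)


class TestRankPairs:
    def test_birth_death_single_pair(self, birth_death):
        ccs = sc.compute_control_coefficients(birth_death)
        r = sc.rank_parameter_pairs(ccs, "mean:X", "noise:X")
        assert len(r.entries) == 1
        assert r.entries[0][1] == pytest.approx(0.0, abs=1e-8)

    def test_pathway_A_all_pairs_zero(self, pathway_A):
        ccs = sc.compute_control_coefficients(pathway_A)
        r = sc.rank_parameter_pairs(ccs, "mean:X3", "noise:X3")
        assert len(r.entries) == 6
        assert all(eps < 1e-8 for _, eps, _ in r.entries)

    def test_promoter_top_pair_includes_translation(self, promoter):
        ccs = sc.compute_control_coefficients(promoter)
        r = sc.rank_parameter_pairs(ccs, "mean:protein", "noise:protein", tol=0.05)
        assert len(r.entries) == 15
        assert "k_tl" in r.entries[0][0]
        eps_values = [e for _, e, _ in r.entries]
        assert eps_values == sorted(eps_values, reverse=True)


class TestIterateNoiseReduction:
    def test_pathway_BC_noise_strictly_decreases(self):
        net = sc.linear_pathway("BC")
        tr = sc.iterate_noise_reduction(net, "X3", ["k1", "k2", "k3", "k4"], lam=0.05, n_iter=5)
        assert tr.status == "ok"
        assert np.all(np.diff(tr.noise_levels) < 0)
        # the end-product mean is exactly invariant along this flow (k1 and
        # k4 move by the same factor); drift is at solver precision
        assert abs(tr.means[-1] - tr.means[0]) < 1e-6 * tr.means[0]

    def test_pathway_A_flagged_impossible(self, pathway_A):
        tr = sc.iterate_noise_reduction(pathway_A, "X3", ["k1", "k2", "k3", "k4"], lam=0.05)
        assert tr.impossible
        assert len(tr.steps) == 1  # halted before any parameter update

    def test_promoter_euler_drift_order(self, promoter):
        """Fixed-mean drift is second order per step: halving lam at fixed
        step count shrinks the total drift ~4x."""
        def drift(lam):
            tr = sc.iterate_noise_reduction(promoter, "protein", lam=lam, n_iter=5)
            return abs(tr.means[-1] - tr.means[0])

        ratio = drift(0.05) / drift(0.025)
        assert 3.0 < ratio < 5.0

    def test_parameters_stay_positive(self, promoter):
        tr = sc.iterate_noise_reduction(promoter, "protein", lam=0.2, n_iter=8)
        for s in tr.steps:
            assert np.all(s["parameters"] > 0)


class TestOscillationScores:
    def test_monotone_autocorrelation_rejected(self, birth_death):
        st = sc.lna_analysis(birth_death)
        lags = np.linspace(0, 10, 101)
        curve = sc.autocorrelation(st.A, st.C, st.structure, lags)
        ccs = sc.compute_control_coefficients(birth_death, lags=lags)
        with pytest.raises(DesignError, match="non-oscillatory"):
            sc.oscillation_control_scores(ccs, curve, "X")

    def test_trough_peak_detection(self):
        lags = np.linspace(0, 4 * np.pi, 200)
        curve = np.exp(-0.1 * lags) * np.cos(lags)
        t, p = _find_trough_peak(lags, curve)
        assert curve[t] < 0 < curve[p]
        # extrema of a damped cosine shift earlier by arctan(decay/frequency)
        shift = np.arctan(0.1)
        assert lags[t] == pytest.approx(np.pi - shift, abs=0.1)
        assert lags[p] == pytest.approx(2 * np.pi - shift, abs=0.1)

    def test_oscillator_amplitude_ranking(self, oscillator):
        lags = np.linspace(0, 12, 121)
        ccs = sc.compute_control_coefficients(oscillator, lags=lags)
        st = ccs.steady
        curve = sc.autocorrelation(st.A, st.C, st.structure, lags)
        amp, per, anchors = sc.oscillation_control_scores(ccs, curve, "P")
        assert amp[0][1] > 0  # a usable amplitude-control parameter exists
        top = amp[0][0]
        si = curve.species_ids.index("P")
        j = ccs.parameter_ids.index(top)
        k1 = int(np.argmin(np.abs(lags - anchors["trough"])))
        k2 = int(np.argmin(np.abs(lags - anchors["peak"])))
        assert ccs.autocorr[k1, si, j] * ccs.autocorr[k2, si, j] > 0

    def test_sign_rules(self, oscillator):
        lags = np.linspace(0, 12, 121)
        ccs = sc.compute_control_coefficients(oscillator, lags=lags)
        st = ccs.steady
        curve = sc.autocorrelation(st.A, st.C, st.structure, lags)
        amp, per, _ = sc.oscillation_control_scores(ccs, curve, "P")
        amp_d, per_d = dict(amp), dict(per)
        for pid in ccs.parameter_ids:
            # a parameter cannot score for amplitude with opposite-sign CCs
            # at trough and peak, nor for period with same-sign CCs
            assert amp_d[pid] >= 0 and per_d[pid] >= 0
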