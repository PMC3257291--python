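"""Linear noise approximation engine.

Computes the deterministic steady state of a reaction network, its
linearization (Jacobian ``A`` and diffusion matrix ``D`` over the independent
species), the stationary covariance ``C`` from the Lyapunov /
fluctuation-dissipation equation ``A C + C A' + D = 0``, noise levels
``eta_ij = C_ij / (x_i x_j)`` (squared coefficient of variation on the
diagonal), and stationary autocorrelations ``R(tau) = expm(A tau) C``.

Covariances are solved in the independent-species space and lifted with the
link matrix ``L``; conservation relations (e.g. total promoter copies) make
the full-space Lyapunov equation singular, so this reduction is essential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
from scipy.integrate import solve_ivp

from .errors import EvaluationError, SolverError, StabilityError
from .network import NetworkStructure, ReactionNetwork, stoichiometric_decomposition

__all__ = [
    "SteadyStateLNA",
    "AutocorrelationCurve",
    "solve_steady_state",
    "linearize",
    "solve_lyapunov",
    "noise_levels",
    "autocorrelation",
    "lna_analysis",
]

_SS_RTOL = 1e-10  # relative steady-state residual tolerance


@dataclass
class SteadyStateLNA:
    """Steady state plus second-moment characterization under the LNA.

    ``x_star`` spans all species (boundary species keep their fixed amounts);
    ``A`` and ``D`` live in the independent-species space; ``C`` and ``eta``
    span the dynamic species (boundary species fluctuate by definition not at
    all).  ``eta`` entries with a zero mean are NaN; :func:`noise_levels`
    raises for such species when they are explicitly requested.
    """

    net: ReactionNetwork
    structure: NetworkStructure
    x_star: np.ndarray
    v_star: np.ndarray
    A: np.ndarray
    D: np.ndarray
    C_ind: np.ndarray
    C: np.ndarray
    eta: np.ndarray

    @property
    def species_ids(self) -> list[str]:
        return self.structure.dynamic_ids

    def x_dynamic(self) -> np.ndarray:
        idx = [self.net.species_ids.index(s) for s in self.structure.dynamic_ids]
        return self.x_star[idx]

    def noise_level(self, species: str) -> float:
        return noise_levels(self.C, self.x_dynamic(), self.species_ids, [species])[0]

    def mean(self, species: str) -> float:
        return float(self.x_star[self.net.species_ids.index(species)])


@dataclass
class AutocorrelationCurve:
    """Covariance-lag matrices R(tau) with normalized same-species curves."""

    lags: np.ndarray
    R: np.ndarray  # (n_lags, n_dyn, n_dyn)
    A_norm: np.ndarray  # (n_lags, n_dyn); R_ii(tau) / C_ii
    species_ids: list[str]

    def curve(self, species: str) -> np.ndarray:
        return self.A_norm[:, self.species_ids.index(species)]


def _dyn_index(net: ReactionNetwork) -> list[int]:
    return [net.species_ids.index(s) for s in net.dynamic_species]


def _full_state(net, structure, xi, x_ref):
    """All-species state with independent coordinates ``xi``."""
    x = x_ref.copy()
    dyn = _dyn_index(net)
    xi0 = x_ref[dyn][structure.independent]
    x[dyn] = x_ref[dyn] + structure.L @ (xi - xi0)
    return x


def solve_steady_state(net, structure=None, initial_guess=None):
    """Solve ``N_R v(x) = 0`` on the conservation class of the initial state.

    Damped Newton iteration in the independent-species coordinates with an
    ODE-relaxation fallback (integrate the rate equations toward
    stationarity, then polish with Newton).  Returns ``(x_star, v_star)``.
    """
    structure = stoichiometric_decomposition(net) if structure is None else structure
    x_ref = net.initial_state.copy() if initial_guess is None else np.asarray(initial_guess, float)
    if np.any(x_ref < 0):
        raise SolverError("initial guess has negative amounts")
    dyn = _dyn_index(net)
    N_R, L = structure.N_R, structure.L

    def residual(xi):
        return N_R @ net.rates(_full_state(net, structure, xi, x_ref))

    def jac(xi):
        x = _full_state(net, structure, xi, x_ref)
        return N_R @ net.rate_jacobian_x(x) @ L

    def newton(xi, max_iter=80):
        for _ in range(max_iter):
            f = residual(xi)
            scale = max(1.0, np.linalg.norm(net.rates(_full_state(net, structure, xi, x_ref))))
            if np.linalg.norm(f) < _SS_RTOL * scale:
                return xi, True
            try:
                step = np.linalg.solve(jac(xi), -f)
            except np.linalg.LinAlgError:
                return xi, False
            lam, f0 = 1.0, np.linalg.norm(f)
            while lam > 1e-8:
                cand = xi + lam * step
                x_cand = _full_state(net, structure, cand, x_ref)
                if np.all(x_cand[dyn] >= -1e-12):
                    try:
                        if np.linalg.norm(residual(cand)) < (1 - 0.25 * lam) * f0:
                            xi = cand
                            break
                    except EvaluationError:
                        pass
                lam /= 2
            else:
                return xi, False
        return xi, np.linalg.norm(residual(xi)) < _SS_RTOL * max(1.0, np.linalg.norm(f))

    xi0 = x_ref[dyn][structure.independent].astype(float)
    xi, ok = newton(xi0)
    if not ok:
        # relax along the rate equations, then retry Newton
        def rhs(_t, xi_):
            return N_R @ net.rates(_full_state(net, structure, np.maximum(xi_, 0), x_ref))

        sol = solve_ivp(rhs, (0.0, 1e4), xi0, method="LSODA", rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise SolverError(f"steady-state relaxation failed: {sol.message}")
        xi, ok = newton(np.maximum(sol.y[:, -1], 0.0))
        if not ok:
            raise SolverError(
                f"steady state did not converge; residual {np.linalg.norm(residual(xi)):.3e}"
            )

    x_star = _full_state(net, structure, xi, x_ref)
    if np.any(x_star[dyn] < -1e-9):
        raise SolverError(f"negative steady state {x_star}")
    x_star[dyn] = np.maximum(x_star[dyn], 0.0)
    v_star = net.rates(x_star)
    return x_star, v_star


def linearize(net, structure, x_star):
    """Jacobian ``A = N_R (dv/dx) L`` and diffusion ``D`` at the steady state.

    For markov-jump networks ``D = N_R diag(v*) N_R'`` (each reaction injects
    shot noise proportional to its stationary flux); langevin networks carry
    an explicit constant diffusion matrix, which is passed through.
    """
    dvdx = net.rate_jacobian_x(x_star)
    A = structure.N_R @ dvdx @ structure.L
    if net.kind == "markov-jump":
        v_star = net.rates(x_star)
        D = structure.N_R @ np.diag(v_star) @ structure.N_R.T
    else:
        if structure.conservation:
            raise StabilityError(
                "langevin networks with conservation relations are not supported"
            )
        D = np.asarray(net.diffusion, dtype=float)
    return A, D


def _require_hurwitz(A):
    eig = np.linalg.eigvals(A)
    if np.any(eig.real >= 0):
        raise StabilityError(
            f"Jacobian is not Hurwitz (max Re eigenvalue {eig.real.max():.3e}); "
            "the stationary covariance is undefined"
        )
    return eig


def solve_lyapunov(A, D, structure: NetworkStructure) -> np.ndarray:
    """Stationary covariance over dynamic species from ``A C + C A' + D = 0``."""
    A = np.asarray(A, float)
    D = np.asarray(D, float)
    _require_hurwitz(A)
    C_ind = sla.solve_continuous_lyapunov(A, -D)
    C_ind = 0.5 * (C_ind + C_ind.T)
    resid = np.linalg.norm(A @ C_ind + C_ind @ A.T + D)
    if resid > 1e-10 * max(1.0, np.linalg.norm(D)):
        raise SolverError(f"Lyapunov residual too large: {resid:.3e}")
    w = np.linalg.eigvalsh(C_ind)
    if w.min() < -1e-9 * max(1.0, w.max()):
        raise SolverError(f"covariance not positive semidefinite (min eig {w.min():.3e})")
    return structure.lift_covariance(C_ind)


def noise_levels(C, x_dyn, species_ids=None, requested=None) -> np.ndarray:
    """Noise-level matrix ``eta_ij = C_ij / (x_i x_j)``.

    With ``requested`` species names, returns their diagonal entries and
    raises if any requested species has zero mean.
    """
    x = np.asarray(x_dyn, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        eta = C / np.outer(x, x)
    eta[~np.isfinite(eta)] = np.nan
    if requested is not None:
        out = []
        for sid in requested:
            i = species_ids.index(sid)
            if x[i] <= 0:
                raise EvaluationError(f"noise level undefined: species {sid!r} has zero mean")
            out.append(eta[i, i])
        return np.array(out)
    return eta


def autocorrelation(A, C, structure, lags, method="expm") -> AutocorrelationCurve:
    """Stationary covariance-lag curves ``R(tau) = expm(A tau) C_ind`` lifted by L.

    ``method="ode"`` integrates ``dR/dtau = A R`` from ``R(0) = C_ind``
    instead (the matrix-inversion-free route); both agree to solver accuracy.
    """
    lags = np.asarray(lags, dtype=float)
    if np.any(lags < 0) or np.any(np.diff(lags) < 0):
        raise ValueError("lags must be sorted and nonnegative")
    _require_hurwitz(A)
    L = structure.L
    # recover independent-space covariance from the lifted one
    C_ind = np.asarray(C, float)[np.ix_(structure.independent, structure.independent)]
    n = A.shape[0]
    if method == "expm":
        R_ind = np.array([sla.expm(A * t) @ C_ind for t in lags])
    elif method == "ode":
        def rhs(_t, y):
            return (A @ y.reshape(n, n)).ravel()

        sol = solve_ivp(
            rhs,
            (0.0, float(lags[-1]) if lags[-1] > 0 else 1.0,),
            C_ind.ravel(),
            t_eval=lags if lags[-1] > 0 else None,
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success:
            raise SolverError(f"autocorrelation ODE failed: {sol.message}")
        if lags[-1] > 0:
            R_ind = sol.y.T.reshape(len(lags), n, n)
        else:
            R_ind = np.array([C_ind for _ in lags])
    else:
        raise ValueError(f"unknown method {method!r}")
    R = np.einsum("ik,tkl,jl->tij", L, R_ind, L)
    C_dyn = structure.lift_covariance(C_ind)
    diag = np.diag(C_dyn).copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        A_norm = np.array([np.diag(Rt) / diag for Rt in R])
    return AutocorrelationCurve(lags=lags, R=R, A_norm=A_norm, species_ids=structure.dynamic_ids)


def lna_analysis(net: ReactionNetwork, structure=None, initial_guess=None) -> SteadyStateLNA:
    """Full steady-state LNA pipeline: steady state, (A, D), covariance, noise."""
    structure = stoichiometric_decomposition(net) if structure is None else structure
    x_star, v_star = solve_steady_state(net, structure, initial_guess)
    A, D = linearize(net, structure, x_star)
    C = solve_lyapunov(A, D, structure)
    dyn = _dyn_index(net)
    eta = noise_levels(C, x_star[dyn])
    C_ind = C[np.ix_(structure.independent, structure.independent)]
    return SteadyStateLNA(
        net=net,
        structure=structure,
        x_star=x_star,
        v_star=v_star,
        A=A,
        D=D,
        C_ind=C_ind,
        C=C,
        eta=eta,
    )
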