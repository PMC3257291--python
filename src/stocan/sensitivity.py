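"""Control coefficients (CCs) of stationary means, covariances, noise levels
and autocorrelations with respect to rate parameters.

The scaled CC of a stationary quantity ``Y`` with respect to a parameter
``p`` is the log-log derivative ``(p / Y) dY/dp``: the relative change in
``Y`` per relative change in ``p``.  Mean CCs follow the classical
(metabolic-control-analysis) formula

    dx*/dp = -L (N_R J L)^{-1} N_R (dv/dp),     J = dv/dx,

and second-moment CCs propagate that implicit steady-state shift through the
Lyapunov equation: differentiate ``A C + C A' + D = 0`` along ``p`` and solve
the resulting Sylvester-type equation

    A dC + dC A' = -(dA C + C dA' + dD)

where ``dA`` and ``dD`` combine the explicit parameter dependence with the
dependence through the shifted steady state.  Autocorrelation CCs integrate
the variational system ``d(dR)/dtau = A dR + dA R`` alongside
``dR/dtau = A R`` with a single block matrix exponential.

Because stationary means and noise levels are invariant under a uniform
rescaling of all rate constants (time-unit freedom), the scaled CCs over all
rate parameters sum to zero — the stochastic analogue of the MCA summation
theorems.  This holds here to solver accuracy and is used as a test oracle.

:func:`finite_difference_ccs` is an independent brute-force oracle: it
recomputes the full pipeline at multiplicatively perturbed parameters and
takes central differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .errors import SolverError
from .lna import SteadyStateLNA, autocorrelation, lna_analysis
from .network import NetworkStructure, ReactionNetwork, stoichiometric_decomposition

__all__ = [
    "ControlCoefficientSet",
    "mean_ccs",
    "covariance_ccs",
    "noise_ccs",
    "autocorr_ccs",
    "finite_difference_ccs",
    "compute_control_coefficients",
]


@dataclass
class ControlCoefficientSet:
    """Scaled and unscaled sensitivities of stationary properties.

    Shapes: ``mean`` is (species, parameters); ``covariance`` and ``noise``
    are (species, species, parameters); ``autocorr`` is
    (lags, species, parameters) for normalized same-species autocorrelations.
    Scaled entries are NaN wherever the underlying quantity vanishes (the
    log-derivative is undefined there); unscaled values are always kept.
    """

    parameter_ids: list[str]
    species_ids: list[str]
    mean: np.ndarray
    mean_unscaled: np.ndarray
    covariance: np.ndarray | None = None
    covariance_unscaled: np.ndarray | None = None
    noise: np.ndarray | None = None
    noise_unscaled: np.ndarray | None = None
    autocorr_lags: np.ndarray | None = None
    autocorr: np.ndarray | None = None
    autocorr_unscaled: np.ndarray | None = None
    steady: SteadyStateLNA | None = field(default=None, repr=False)

    def _sidx(self, species: str) -> int:
        return self.species_ids.index(species)

    def _pidx(self, parameters) -> list[int]:
        return [self.parameter_ids.index(p) for p in parameters]

    def mean_vector(self, species, parameters=None) -> np.ndarray:
        parameters = self.parameter_ids if parameters is None else parameters
        return self.mean[self._sidx(species), self._pidx(parameters)]

    def noise_vector(self, species, parameters=None) -> np.ndarray:
        parameters = self.parameter_ids if parameters is None else parameters
        i = self._sidx(species)
        return self.noise[i, i, self._pidx(parameters)]

    def autocorr_vector(self, species, lag, parameters=None) -> np.ndarray:
        parameters = self.parameter_ids if parameters is None else parameters
        k = int(np.argmin(np.abs(self.autocorr_lags - lag)))
        return self.autocorr[k, self._sidx(species), self._pidx(parameters)]

    def to_frame(self):
        """Long-format table (variable, species, parameter, lag, scaled, unscaled)."""
        import pandas as pd

        rows = []
        for i, s in enumerate(self.species_ids):
            for j, p in enumerate(self.parameter_ids):
                rows.append(("mean", s, p, None, self.mean[i, j], self.mean_unscaled[i, j]))
                if self.noise is not None:
                    rows.append(
                        ("noise", s, p, None, self.noise[i, i, j], self.noise_unscaled[i, i, j])
                    )
        if self.autocorr is not None:
            for k, lag in enumerate(self.autocorr_lags):
                for i, s in enumerate(self.species_ids):
                    for j, p in enumerate(self.parameter_ids):
                        rows.append(
                            (
                                "autocorr",
                                s,
                                p,
                                float(lag),
                                self.autocorr[k, i, j],
                                self.autocorr_unscaled[k, i, j],
                            )
                        )
        return pd.DataFrame(
            rows, columns=["variable", "species", "parameter", "lag", "scaled", "unscaled"]
        )


def _scale(unscaled, values, params):
    """Scaled CC (p/Y) dY/dp with NaN where Y == 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = unscaled * params / values[..., None]
    scaled = np.asarray(scaled)
    scaled[~np.isfinite(scaled)] = np.nan
    return scaled


def mean_ccs(net: ReactionNetwork, structure: NetworkStructure, steady: SteadyStateLNA):
    """Unscaled and scaled CCs of the stationary means, (species x parameters)."""
    dvdx = net.rate_jacobian_x(steady.x_star)
    dvdp = net.rate_jacobian_p(steady.x_star)
    M = structure.N_R @ dvdx @ structure.L
    if np.linalg.cond(M) > 1e12:
        raise SolverError("steady state is degenerate: N_R (dv/dx) L is ill conditioned")
    unscaled = -structure.L @ np.linalg.solve(M, structure.N_R @ dvdp)
    x_dyn = steady.x_dynamic()
    scaled = _scale(unscaled, x_dyn, net.parameter_values)
    return unscaled, scaled


def _total_derivatives(net, structure, steady, dxdp_dyn):
    """Per-parameter total derivatives (dA_j, dD_j) in the independent space.

    Combines explicit parameter dependence with the implicit dependence
    through the shifted steady state ``dx*/dp`` (all derivatives symbolic).
    """
    x, p = steady.x_star, net.parameter_values
    n_p = len(p)
    J = net.rate_jacobian_x(x)
    dvdp = net.rate_jacobian_p(x)
    Hxx, Hpx = net.rate_hessians(x)  # lists over dynamic species k
    N_R, L = structure.N_R, structure.L

    dA = []
    dD = []
    for j in range(n_p):
        dxdp_j = dxdp_dyn[:, j]
        # dJ_{rk}/dp_j = d2v_r/(dx_k dp_j) + sum_m d2v_r/(dx_k dx_m) dx_m/dp_j
        dJ = np.zeros_like(J)
        for k in range(J.shape[1]):
            dJ[:, k] = Hpx[k][:, j] + sum(
                Hxx[m][:, k] * dxdp_j[m] for m in range(J.shape[1])
            )
        dA.append(N_R @ dJ @ L)
        if net.kind == "markov-jump":
            dv_tot = dvdp[:, j] + J @ dxdp_j
            dD.append(N_R @ np.diag(dv_tot) @ N_R.T)
        else:
            dD.append(np.zeros_like(steady.D))  # explicit diffusion: parameter free
    return dA, dD


def covariance_ccs(net, structure, steady, mean_unscaled):
    """Unscaled and scaled CCs of the stationary covariance, (i, j, parameter)."""
    A, C_ind = steady.A, steady.C_ind
    dA, dD = _total_derivatives(net, structure, steady, mean_unscaled)
    n_dyn = len(structure.dynamic_ids)
    n_p = len(net.parameter_ids)
    unscaled = np.zeros((n_dyn, n_dyn, n_p))
    norm_D = max(1.0, np.linalg.norm(steady.D))
    for j in range(n_p):
        rhs = -(dA[j] @ C_ind + C_ind @ dA[j].T + dD[j])
        dC = sla.solve_continuous_lyapunov(A, rhs)
        dC = 0.5 * (dC + dC.T)
        resid = np.linalg.norm(A @ dC + dC @ A.T - rhs)
        if resid > 1e-9 * norm_D:
            raise SolverError(f"covariance-sensitivity Lyapunov residual {resid:.3e}")
        unscaled[:, :, j] = structure.lift_covariance(dC)
    scaled = _scale(unscaled, steady.C, net.parameter_values)
    return unscaled, scaled


def noise_ccs(steady: SteadyStateLNA, mean_unscaled, covariance_unscaled, parameter_values):
    """Unscaled and scaled CCs of the noise levels eta_ij = C_ij/(x_i x_j)."""
    x = steady.x_dynamic()
    C = steady.C
    inv_xx = 1.0 / np.outer(x, x)
    rel_mean = mean_unscaled / x[:, None]  # (i, p): (dx_i/dp)/x_i
    unscaled = covariance_unscaled * inv_xx[:, :, None] - (
        C * inv_xx
    )[:, :, None] * (rel_mean[:, None, :] + rel_mean[None, :, :])
    scaled = _scale(unscaled, steady.eta, parameter_values)
    return unscaled, scaled


def autocorr_ccs(net, structure, steady, covariance_unscaled, lags, mean_unscaled=None):
    """Per-lag CCs of the normalized same-species autocorrelations.

    For each parameter, ``R`` and its sensitivity ``dR`` satisfy the block
    linear system d/dtau [R; dR] = [[A, 0], [dA, A]] [R; dR] with initial
    condition [C; dC]; one matrix exponential per (lag, parameter) solves it.
    The CC of A_ii(tau) = R_ii(tau)/C_ii follows by the quotient rule.  At
    lags where |A_ii| <= 1e-6 the scaled CC is NaN (kept unscaled only).
    """
    lags = np.asarray(lags, float)
    A, C_ind = steady.A, steady.C_ind
    if mean_unscaled is None:
        mean_unscaled, _ = mean_ccs(net, structure, steady)
    dA_list, _ = _total_derivatives(net, structure, steady, mean_unscaled)
    L = structure.L
    ind = structure.independent
    n = A.shape[0]
    n_dyn = len(structure.dynamic_ids)
    n_p = len(net.parameter_ids)
    C_dyn = steady.C
    diag_C = np.diag(C_dyn)

    unscaled = np.zeros((len(lags), n_dyn, n_p))
    A_norm = np.zeros((len(lags), n_dyn))
    for j in range(n_p):
        dC_ind = covariance_unscaled[np.ix_(ind, ind)][:, :, j]
        B = np.block([[A, np.zeros((n, n))], [dA_list[j], A]])
        X0 = np.vstack([C_ind, dC_ind])
        for k, tau in enumerate(lags):
            X = sla.expm(B * tau) @ X0
            R_ind, dR_ind = X[:n], X[n:]
            R = L @ R_ind @ L.T
            dR = L @ dR_ind @ L.T
            r_ii = np.diag(R)
            dr_ii = np.diag(dR)
            dC_ii = np.diag(covariance_unscaled[:, :, j])
            with np.errstate(divide="ignore", invalid="ignore"):
                unscaled[k, :, j] = (dr_ii * diag_C - r_ii * dC_ii) / diag_C**2
                if j == 0:
                    A_norm[k] = r_ii / diag_C
    scaled = np.full_like(unscaled, np.nan)
    p = net.parameter_values
    guard = np.abs(A_norm) > 1e-6
    for j in range(n_p):
        with np.errstate(divide="ignore", invalid="ignore"):
            s = unscaled[:, :, j] * p[j] / A_norm
        scaled[:, :, j] = np.where(guard, s, np.nan)
    return unscaled, scaled


def compute_control_coefficients(
    net: ReactionNetwork,
    structure: NetworkStructure | None = None,
    steady: SteadyStateLNA | None = None,
    lags=None,
) -> ControlCoefficientSet:
    """Full analytic CC pipeline (means, covariances, noise, optional autocorr)."""
    structure = stoichiometric_decomposition(net) if structure is None else structure
    steady = lna_analysis(net, structure) if steady is None else steady
    m_un, m_sc = mean_ccs(net, structure, steady)
    c_un, c_sc = covariance_ccs(net, structure, steady, m_un)
    e_un, e_sc = noise_ccs(steady, m_un, c_un, net.parameter_values)
    out = ControlCoefficientSet(
        parameter_ids=list(net.parameter_ids),
        species_ids=list(structure.dynamic_ids),
        mean=m_sc,
        mean_unscaled=m_un,
        covariance=c_sc,
        covariance_unscaled=c_un,
        noise=e_sc,
        noise_unscaled=e_un,
        steady=steady,
    )
    if lags is not None:
        a_un, a_sc = autocorr_ccs(net, structure, steady, c_un, lags, m_un)
        out.autocorr_lags = np.asarray(lags, float)
        out.autocorr = a_sc
        out.autocorr_unscaled = a_un
    return out


def finite_difference_ccs(
    net: ReactionNetwork,
    structure: NetworkStructure | None = None,
    target: str = "noise",
    step: float = 1e-4,
    lags=None,
) -> ControlCoefficientSet:
    """Independent brute-force oracle: central differences of the recomputed
    pipeline at multiplicatively perturbed parameters ``p (1 +/- step)``.

    ``target`` selects which blocks to fill ("mean", "noise" — which also
    fills covariance — or "autocorr").
    """
    if not 0 < step <= 0.1:
        raise ValueError("step must be in (0, 0.1]")
    structure = stoichiometric_decomposition(net) if structure is None else structure
    base = lna_analysis(net, structure)
    p0 = net.parameter_values
    n_p = len(p0)
    n_dyn = len(structure.dynamic_ids)
    x_base = base.x_dynamic()

    want_autocorr = target == "autocorr"
    if want_autocorr and lags is None:
        raise ValueError("autocorr oracle needs a lag grid")

    m_un = np.zeros((n_dyn, n_p))
    c_un = np.zeros((n_dyn, n_dyn, n_p))
    e_un = np.zeros((n_dyn, n_dyn, n_p))
    a_un = np.zeros((len(lags), n_dyn, n_p)) if want_autocorr else None

    def evaluate(params):
        pert = net.with_parameters(params)
        st = lna_analysis(pert, structure, initial_guess=base.x_star)
        x = st.x_dynamic()
        eta = st.C / np.outer(x, x)
        acf = None
        if want_autocorr:
            acf = autocorrelation(st.A, st.C, structure, lags).A_norm
        return x, st.C, eta, acf

    for j in range(n_p):
        up, dn = p0.copy(), p0.copy()
        up[j] = p0[j] * (1 + step)
        dn[j] = p0[j] * (1 - step)
        try:
            xu, Cu, eu, au = evaluate(up)
            xd, Cd, ed, ad = evaluate(dn)
        except SolverError as exc:
            raise SolverError(
                f"oracle: perturbed steady state failed for {net.parameter_ids[j]}"
            ) from exc
        h = 2 * step * p0[j]
        m_un[:, j] = (xu - xd) / h
        c_un[:, :, j] = (Cu - Cd) / h
        e_un[:, :, j] = (eu - ed) / h
        if want_autocorr:
            a_un[:, :, j] = (au - ad) / h

    eta_base = base.eta
    out = ControlCoefficientSet(
        parameter_ids=list(net.parameter_ids),
        species_ids=list(structure.dynamic_ids),
        mean=_scale(m_un, x_base, p0),
        mean_unscaled=m_un,
        covariance=_scale(c_un, base.C, p0),
        covariance_unscaled=c_un,
        noise=_scale(e_un, eta_base, p0),
        noise_unscaled=e_un,
        steady=base,
    )
    if want_autocorr:
        acf_base = autocorrelation(base.A, base.C, structure, lags).A_norm
        guard = np.abs(acf_base) > 1e-6
        scaled = np.full_like(a_un, np.nan)
        for j in range(n_p):
            with np.errstate(divide="ignore", invalid="ignore"):
                s = a_un[:, :, j] * p0[j] / acf_base
            scaled[:, :, j] = np.where(guard, s, np.nan)
        out.autocorr_lags = np.asarray(lags, float)
        out.autocorr = scaled
        out.autocorr_unscaled = a_un
    return out
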