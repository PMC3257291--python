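"""Control design: turn control coefficients into parameter perturbations.

All perturbations live in relative (log) parameter space: a design direction
``u`` is applied as ``p_j -> p_j (1 + lam u_j)``, pairing naturally with the
scaled CCs and keeping parameters positive for small ``lam``.

Orthogonal control holds one stationary property fixed (typically a mean)
while moving another (typically a noise level): the design direction is the
moved variable's control vector projected onto the hyperplane perpendicular
to the fixed variable's control vector.  Efficiency ``eps = |sin theta|``
(``theta`` the angle between the two control vectors) is the fraction of the
moved vector surviving the projection; strength ``S = ||G_moved|| eps``.
When the two vectors are (anti-)parallel — as they are for any species with
a Poisson stationary law — the projection vanishes and orthogonal control is
impossible.

A constraint tolerance ``tol`` (allowed % change of the fixed variable per
unit perturbation) widens the admissible set from the perpendicular
hyperplane to a cone of half-angle ``theta_d = arcsin(min(1, tol /
||G_fixed||))`` around it, re-defining efficiency as the cosine of the
residual angle from the moved vector to that cone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .errors import DesignError
from .lna import AutocorrelationCurve, lna_analysis
from .network import ReactionNetwork, stoichiometric_decomposition
from .sensitivity import ControlCoefficientSet, compute_control_coefficients

__all__ = [
    "ControlVector",
    "OrthogonalDesign",
    "GeneralizedDesign",
    "ToleranceSettings",
    "SchemeRanking",
    "IterationTrace",
    "control_vector",
    "orthogonal_design",
    "generalized_design",
    "tolerance_adjusted_metrics",
    "rank_parameter_pairs",
    "iterate_noise_reduction",
    "oscillation_control_scores",
]

_EPS_IMPOSSIBLE = 1e-10


@dataclass
class ControlVector:
    """Scaled CCs of one variable over an ordered parameter subset."""

    variable: str
    parameter_ids: list[str]
    components: np.ndarray

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.components))


@dataclass
class OrthogonalDesign:
    fixed_variable: str
    moved_variable: str
    parameter_ids: list[str]
    direction: np.ndarray
    strength_S: float
    efficiency_eps: float
    theta: float
    impossible: bool = False
    tol: float = 0.0


@dataclass
class GeneralizedDesign:
    targets: list[tuple[str, float]]
    parameter_ids: list[str]
    delta_p: np.ndarray
    residual: float
    status: str  # exact | min-norm | overconstrained


@dataclass
class ToleranceSettings:
    tol: float
    theta_d: float


@dataclass
class SchemeRanking:
    fixed_variable: str
    moved_variable: str
    entries: list[tuple[tuple[str, ...], float, float]]  # (pair, eps, S)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [("+".join(pair), eps, S) for pair, eps, S in self.entries],
            columns=["parameters", "efficiency", "strength"],
        )


@dataclass
class IterationTrace:
    parameter_ids: list[str]
    steps: list[dict] = field(default_factory=list)
    step_size: float = 0.0
    impossible: bool = False
    status: str = "ok"

    @property
    def means(self):
        return np.array([s["mean"] for s in self.steps])

    @property
    def noise_levels(self):
        return np.array([s["noise"] for s in self.steps])


def _parse_variable(ccs: ControlCoefficientSet, variable: str, pidx: list[int]) -> np.ndarray:
    """Components of a variable's control vector: 'mean:X', 'noise:X',
    'autocorr:X:<lag>'."""
    parts = variable.split(":")
    kind = parts[0]
    if kind == "mean":
        return ccs.mean[ccs._sidx(parts[1]), pidx]
    if kind == "noise":
        if ccs.noise is None:
            raise DesignError("noise CCs not computed")
        i = ccs._sidx(parts[1])
        j = ccs._sidx(parts[2]) if len(parts) > 2 else i
        return ccs.noise[i, j, pidx]
    if kind == "autocorr":
        if ccs.autocorr is None:
            raise DesignError("autocorrelation CCs not computed")
        k = int(np.argmin(np.abs(ccs.autocorr_lags - float(parts[2]))))
        return ccs.autocorr[k, ccs._sidx(parts[1]), pidx]
    raise DesignError(f"unknown variable {variable!r}")


def control_vector(ccs: ControlCoefficientSet, variable: str, parameter_subset=None) -> ControlVector:
    """Extract the control vector of ``variable`` over a parameter subset."""
    subset = list(parameter_subset) if parameter_subset is not None else list(ccs.parameter_ids)
    if not subset:
        raise DesignError("empty parameter subset")
    try:
        pidx = ccs._pidx(subset)
    except ValueError as exc:
        raise DesignError(f"unknown parameter in subset {subset}") from exc
    try:
        comps = np.asarray(_parse_variable(ccs, variable, pidx), dtype=float)
    except ValueError as exc:
        raise DesignError(f"unknown variable {variable!r}") from exc
    return ControlVector(variable=variable, parameter_ids=subset, components=comps)


def _angle(gf: np.ndarray, gm: np.ndarray) -> float:
    cos = float(np.clip(gf @ gm / (np.linalg.norm(gf) * np.linalg.norm(gm)), -1.0, 1.0))
    return float(np.arccos(cos))


def orthogonal_design(
    G_fixed: ControlVector, G_moved: ControlVector, sense: str = "reduce"
) -> OrthogonalDesign:
    """Project ``G_moved`` out of ``G_fixed``'s direction.

    The returned unit ``direction`` satisfies ``direction @ G_fixed = 0``;
    moving parameters along it changes the moved variable at rate ``S`` per
    unit perturbation while leaving the fixed variable unchanged to first
    order.  ``sense="reduce"`` decreases the moved variable.  When the
    projection vanishes (anti-parallel control vectors) the design is
    returned with ``impossible=True`` and ``S = 0``.
    """
    if G_fixed.parameter_ids != G_moved.parameter_ids:
        raise DesignError("control vectors must share the same parameter subset")
    if sense not in ("reduce", "increase"):
        raise DesignError(f"unknown sense {sense!r}")
    gf, gm = G_fixed.components, G_moved.components
    nf, nm = np.linalg.norm(gf), np.linalg.norm(gm)
    if nf == 0:
        raise DesignError("fixed variable has zero control vector; nothing to hold")
    sign = -1.0 if sense == "reduce" else 1.0
    if nm == 0:
        return OrthogonalDesign(
            G_fixed.variable, G_moved.variable, list(G_fixed.parameter_ids),
            np.zeros_like(gf), 0.0, 0.0, np.nan, impossible=True,
        )
    theta = _angle(gf, gm)
    proj = gm - (gm @ gf / nf**2) * gf
    npj = np.linalg.norm(proj)
    # |sin theta| computed from the projection norm: exact cancellation for
    # (anti-)parallel vectors, unlike arccos -> sin round-tripping
    eps = npj / nm
    if eps < _EPS_IMPOSSIBLE or npj == 0:
        return OrthogonalDesign(
            G_fixed.variable, G_moved.variable, list(G_fixed.parameter_ids),
            np.zeros_like(gf), 0.0, float(eps), float(theta), impossible=True,
        )
    direction = sign * proj / npj
    return OrthogonalDesign(
        fixed_variable=G_fixed.variable,
        moved_variable=G_moved.variable,
        parameter_ids=list(G_fixed.parameter_ids),
        direction=direction,
        strength_S=float(nm * eps),
        efficiency_eps=float(eps),
        theta=float(theta),
    )


def generalized_design(
    cc_matrix, targets, parameter_ids=None, feasibility_tol: float = 1e-8
) -> GeneralizedDesign:
    """Minimum-norm relative parameter perturbation achieving given % changes.

    Solves ``cc_matrix @ delta_p = targets`` by pseudoinverse (equivalent to
    the Lagrange-multiplier construction).  ``status`` is ``exact`` for a
    square nonsingular system, ``overconstrained`` when the least-squares
    residual exceeds ``feasibility_tol * ||targets||``, else ``min-norm``.
    """
    G = np.atleast_2d(np.asarray(cc_matrix, dtype=float))
    if isinstance(targets, dict):
        items = list(targets.items())
        t = np.array([v for _, v in items], float)
        names = [k for k, _ in items]
    else:
        t = np.asarray(targets, dtype=float).ravel()
        names = [f"target_{i}" for i in range(len(t))]
    if G.shape[0] != len(t):
        raise DesignError("one target per control-vector row required")
    pids = list(parameter_ids) if parameter_ids is not None else [
        f"p{j}" for j in range(G.shape[1])
    ]
    delta = np.linalg.pinv(G) @ t
    residual = float(np.linalg.norm(G @ delta - t))
    if residual > feasibility_tol * max(np.linalg.norm(t), 1e-300):
        status = "overconstrained"
    elif G.shape[0] == G.shape[1] and np.linalg.matrix_rank(G) == G.shape[0]:
        status = "exact"
    else:
        status = "min-norm"
    return GeneralizedDesign(
        targets=list(zip(names, t)),
        parameter_ids=pids,
        delta_p=delta,
        residual=residual,
        status=status,
    )


def tolerance_settings(G_fixed: ControlVector, tol: float) -> ToleranceSettings:
    nf = G_fixed.norm
    theta_d = np.pi / 2 if nf <= tol else float(np.arcsin(tol / nf))
    return ToleranceSettings(tol=tol, theta_d=theta_d)


def tolerance_adjusted_metrics(
    G_fixed: ControlVector, G_moved: ControlVector, tol: float, sense: str = "reduce"
) -> OrthogonalDesign:
    """Orthogonal-control metrics with the perpendicular plane widened to a
    cone of half-angle ``theta_d = arcsin(min(1, tol/||G_fixed||))``.

    With ``alpha = |pi/2 - theta|`` the angle between the moved vector and
    the perpendicular plane: efficiency is 1 when ``alpha <= theta_d`` (the
    moved vector lies inside the widened space), else ``cos(alpha -
    theta_d)``.  ``tol = 0`` reduces exactly to :func:`orthogonal_design`.
    """
    if tol < 0:
        raise DesignError("tol must be nonnegative")
    base = orthogonal_design(G_fixed, G_moved, sense=sense)
    if tol == 0:
        base.tol = 0.0
        return base
    gf, gm = G_fixed.components, G_moved.components
    nf, nm = np.linalg.norm(gf), np.linalg.norm(gm)
    if nm == 0:
        base.tol = tol
        return base
    settings = tolerance_settings(G_fixed, tol)
    theta_d = settings.theta_d
    theta = _angle(gf, gm)
    # angle between G_moved and the perpendicular plane, via the projection
    # split (arctan2 keeps full precision near both 0 and pi/2)
    par = gm @ gf / nf
    perp = gm - (par / nf) * gf
    alpha = float(np.arctan2(abs(par), np.linalg.norm(perp)))
    eps_tol = 1.0 if alpha <= theta_d else float(np.cos(alpha - theta_d))
    sign = -1.0 if sense == "reduce" else 1.0
    target = sign * gm / nm  # unit vector we want to move along
    if alpha <= theta_d:
        direction = target
    else:
        # rotate the target toward the perpendicular plane down to angle theta_d
        proj = target - (target @ gf / nf**2) * gf
        npj = np.linalg.norm(proj)
        gf_hat = gf / nf
        axis_sign = np.sign(target @ gf_hat) or 1.0
        if npj < 1e-300:
            # collinear case: pick a deterministic in-plane companion
            e = np.zeros_like(gf)
            e[int(np.argmin(np.abs(gf_hat)))] = 1.0
            e = e - (e @ gf_hat) * gf_hat
            e /= np.linalg.norm(e)
        else:
            e = proj / npj
        direction = np.cos(theta_d) * e + np.sin(theta_d) * axis_sign * gf_hat
    out = OrthogonalDesign(
        fixed_variable=G_fixed.variable,
        moved_variable=G_moved.variable,
        parameter_ids=list(G_fixed.parameter_ids),
        direction=direction,
        strength_S=float(nm * eps_tol),
        efficiency_eps=float(eps_tol),
        theta=float(theta),
        impossible=eps_tol < _EPS_IMPOSSIBLE,
        tol=tol,
    )
    return out


def rank_parameter_pairs(
    ccs: ControlCoefficientSet,
    fixed_variable: str,
    moved_variable: str,
    tol: float = 0.0,
    sense: str = "reduce",
) -> SchemeRanking:
    """Tolerance-adjusted (efficiency, strength) for every unordered parameter
    pair, sorted descending by efficiency then strength (ties lexicographic)."""
    pids = ccs.parameter_ids
    if len(pids) < 2:
        raise DesignError("need at least two parameters to rank pairs")
    entries = []
    for pa, pb in combinations(pids, 2):
        gf = control_vector(ccs, fixed_variable, [pa, pb])
        gm = control_vector(ccs, moved_variable, [pa, pb])
        if gf.norm == 0 and gm.norm == 0:
            entries.append(((pa, pb), 0.0, 0.0))
            continue
        if gf.norm == 0:
            # whole subspace leaves the fixed variable untouched
            entries.append(((pa, pb), 1.0, gm.norm))
            continue
        if gm.norm == 0:
            entries.append(((pa, pb), 0.0, 0.0))
            continue
        d = tolerance_adjusted_metrics(gf, gm, tol, sense=sense)
        entries.append(((pa, pb), d.efficiency_eps, d.strength_S))
    entries.sort(key=lambda e: (-e[1], -e[2], e[0]))
    return SchemeRanking(fixed_variable=fixed_variable, moved_variable=moved_variable, entries=entries)


def iterate_noise_reduction(
    net: ReactionNetwork,
    target_species: str,
    parameter_subset=None,
    lam: float = 0.05,
    n_iter: int = 5,
    tol: float = 0.0,
) -> IterationTrace:
    """Iterative orthogonal noise reduction (first-order Euler protocol).

    Each step recomputes the control vectors at the current parameters,
    projects the noise-level control vector onto the plane perpendicular to
    the mean-level control vector, and updates ``p_j -> p_j (1 + lam u_j)``
    along the normalized projection.  The fixed mean drifts only at second
    order in ``lam`` per step.
    """
    if lam <= 0:
        raise DesignError("step size lam must be positive")
    if n_iter < 1:
        raise DesignError("n_iter must be >= 1")
    structure = stoichiometric_decomposition(net)
    subset = list(parameter_subset) if parameter_subset is not None else list(net.parameter_ids)
    current = net
    trace = IterationTrace(parameter_ids=subset, step_size=lam)

    for it in range(n_iter + 1):
        try:
            ccs = compute_control_coefficients(current, structure)
        except Exception as exc:
            trace.status = f"halted: {exc}"
            return trace
        steady = ccs.steady
        i = structure.dynamic_ids.index(target_species)
        record = {
            "iteration": it,
            "parameters": current.parameter_values.copy(),
            "mean": float(steady.x_dynamic()[i]),
            "noise": float(steady.eta[i, i]),
        }
        trace.steps.append(record)
        if it == n_iter:
            break
        gf = control_vector(ccs, f"mean:{target_species}", subset)
        gm = control_vector(ccs, f"noise:{target_species}", subset)
        design = (
            tolerance_adjusted_metrics(gf, gm, tol, sense="reduce")
            if tol > 0
            else orthogonal_design(gf, gm, sense="reduce")
        )
        if design.impossible:
            trace.impossible = True
            trace.status = "orthogonal control impossible"
            break
        p_new = dict(zip(current.parameter_ids, current.parameter_values))
        for pid, u in zip(subset, design.direction):
            p_new[pid] = p_new[pid] * (1 + lam * float(u))
        if any(v <= 0 for v in p_new.values()):
            trace.status = "halted: parameter became nonpositive"
            break
        current = current.with_parameters(p_new)
    return trace


def _find_trough_peak(lags, curve):
    """First interior minimum (trough) and the next maximum (peak) of curve."""
    d = np.diff(curve)
    trough = peak = None
    for k in range(1, len(curve) - 1):
        if trough is None and d[k - 1] < 0 <= d[k]:
            trough = k
        elif trough is not None and d[k - 1] > 0 >= d[k]:
            peak = k
            break
    return trough, peak


def oscillation_control_scores(
    ccs: ControlCoefficientSet, curve: AutocorrelationCurve, species: str
):
    """Amplitude and period controllability scores per single parameter.

    Anchors: the first trough lag ``tau1`` and next peak lag ``tau2`` of the
    normalized autocorrelation (amplitude), and the two steepest-slope lags
    between them (period).  A parameter scores for amplitude when its scaled
    CCs at the two anchors share a sign (raising both relative values deepens
    the trough and raises the peak together) and for period when the two
    steepest-slope CCs have opposite signs (the curve stretches along the lag
    axis).  Returns ``(amplitude_ranking, period_ranking, anchors)`` with
    rankings as (parameter, score) sorted descending.
    """
    a = curve.curve(species)
    lags = curve.lags
    trough, peak = _find_trough_peak(lags, a)
    if trough is None or peak is None:
        raise DesignError(
            f"non-oscillatory autocorrelation for {species!r}: no trough/peak found"
        )
    slopes = np.gradient(a, lags)
    inner = slice(trough, peak + 1)
    k_up = trough + int(np.argmax(slopes[inner]))
    # steepest descent before the trough (the falling flank of the oscillation)
    k_down = int(np.argmin(slopes[: trough + 1]))
    tau1, tau2 = lags[trough], lags[peak]
    tau_a, tau_b = lags[k_down], lags[k_up]

    si = curve.species_ids.index(species)
    k1 = int(np.argmin(np.abs(ccs.autocorr_lags - tau1)))
    k2 = int(np.argmin(np.abs(ccs.autocorr_lags - tau2)))
    ka = int(np.argmin(np.abs(ccs.autocorr_lags - tau_a)))
    kb = int(np.argmin(np.abs(ccs.autocorr_lags - tau_b)))

    amp, per = [], []
    for j, pid in enumerate(ccs.parameter_ids):
        c1, c2 = ccs.autocorr[k1, si, j], ccs.autocorr[k2, si, j]
        ca, cb = ccs.autocorr[ka, si, j], ccs.autocorr[kb, si, j]
        amp_score = min(abs(c1), abs(c2)) if np.isfinite(c1) and np.isfinite(c2) and c1 * c2 > 0 else 0.0
        per_score = min(abs(ca), abs(cb)) if np.isfinite(ca) and np.isfinite(cb) and ca * cb < 0 else 0.0
        amp.append((pid, float(amp_score)))
        per.append((pid, float(per_score)))
    amp.sort(key=lambda e: (-e[1], e[0]))
    per.sort(key=lambda e: (-e[1], e[0]))
    anchors = {"trough": float(tau1), "peak": float(tau2), "slope_lags": (float(tau_a), float(tau_b))}
    return amp, per, anchors
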