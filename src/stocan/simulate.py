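"""Stochastic simulation: exact jump-process (Gillespie direct method) and
Euler-Maruyama Langevin integration, with stationary-statistics estimators
for verifying LNA predictions and control designs.

The SSA is the direct method without tau-leaping: the fixture networks are
small and exactness is the point.  Stationary estimators use a uniform
resampling of the post-burn-in trajectory; standard errors come from batch
means (32 batches by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SimulationError
from .network import ReactionNetwork, stoichiometric_decomposition

__all__ = [
    "Trajectory",
    "StationaryStats",
    "ssa_simulate",
    "langevin_simulate",
    "stationary_statistics",
]


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # (n_events, n_species), all-species order
    species_ids: list[str]
    seed: int
    method: str  # ssa | langevin
    absorbed: bool = False

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=self.species_ids)
        df.insert(0, "time", self.times)
        return df


@dataclass
class StationaryStats:
    species_ids: list[str]
    mean: np.ndarray
    covariance: np.ndarray
    noise_level: np.ndarray
    mean_se: np.ndarray
    noise_se: np.ndarray
    autocorr_lags: np.ndarray | None = None
    autocorr: np.ndarray | None = None  # (n_lags, n_species)
    autocorr_se: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)

    def noise(self, species: str) -> tuple[float, float]:
        i = self.species_ids.index(species)
        return float(self.noise_level[i, i]), float(self.noise_se[i])


def ssa_simulate(net: ReactionNetwork, structure=None, t_end: float = 1e3, seed: int = 0,
                 initial_state=None, max_events: int = 20_000_000) -> Trajectory:
    """Exact direct-method jump trajectory, reproducible given ``seed``.

    States are integer molecule counts; propensities are the rate expressions
    evaluated at the current state.  Stops early with ``absorbed=True`` when
    the total propensity vanishes.
    """
    if net.kind != "markov-jump":
        raise SimulationError("ssa_simulate requires a markov-jump network")
    structure = stoichiometric_decomposition(net) if structure is None else structure
    x0 = net.initial_state.copy() if initial_state is None else np.asarray(initial_state, float)
    if np.any(x0 != np.round(x0)):
        raise SimulationError("SSA requires integer initial amounts")
    rng = np.random.default_rng(seed)
    dyn = [net.species_ids.index(s) for s in net.dynamic_species]
    N = structure.N  # dynamic x reactions
    rate_fn = net._rate_fn
    params = [float(p) for p in net.parameter_values]

    x = x0.astype(float)
    t = 0.0
    times = [0.0]
    states = [x.copy()]
    absorbed = False
    for _ in range(max_events):
        v = np.asarray(rate_fn(*x, *params), dtype=float).ravel()
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise SimulationError(f"invalid propensity {v} at state {x}")
        total = v.sum()
        if total <= 0:
            absorbed = True
            break
        t += rng.exponential(1.0 / total)
        if t >= t_end:
            break
        j = int(np.searchsorted(np.cumsum(v), rng.random() * total, side="right"))
        j = min(j, len(v) - 1)
        x[dyn] += N[:, j]
        times.append(t)
        states.append(x.copy())
    else:
        raise SimulationError(f"exceeded max_events={max_events} before t_end")
    times.append(min(t, t_end))
    states.append(states[-1].copy())
    return Trajectory(
        times=np.array(times),
        states=np.array(states),
        species_ids=list(net.species_ids),
        seed=seed,
        method="ssa",
        absorbed=absorbed,
    )


def langevin_simulate(net: ReactionNetwork, t_end: float, dt: float, seed: int = 0,
                      initial_state=None) -> Trajectory:
    """Euler-Maruyama path of ``dx = N v(x) dt + B dW`` with ``B B' = D``.

    ``D`` is the network's explicit diffusion matrix over dynamic species
    (``D = 0`` degenerates to the forward-Euler ODE path).
    """
    if dt <= 0:
        raise SimulationError("dt must be positive")
    if net.kind != "langevin":
        raise SimulationError("langevin_simulate requires a langevin network")
    structure = stoichiometric_decomposition(net)
    rng = np.random.default_rng(seed)
    dyn = [net.species_ids.index(s) for s in net.dynamic_species]
    N = structure.N.astype(float)
    D = np.asarray(net.diffusion, float)
    if np.allclose(D, 0):
        B = np.zeros_like(D)
    else:
        # PSD square root via eigendecomposition (D may be singular)
        w, V = np.linalg.eigh(D)
        if w.min() < -1e-10 * max(1.0, w.max()):
            raise SimulationError("diffusion matrix is not positive semidefinite")
        B = V @ np.diag(np.sqrt(np.clip(w, 0, None))) @ V.T
    rate_fn = net._rate_fn
    params = [float(p) for p in net.parameter_values]

    n_steps = int(np.ceil(t_end / dt))
    x = (net.initial_state.copy() if initial_state is None
         else np.asarray(initial_state, float))
    times = np.empty(n_steps + 1)
    states = np.empty((n_steps + 1, len(x)))
    times[0], states[0] = 0.0, x
    sqdt = np.sqrt(dt)
    for k in range(n_steps):
        v = np.asarray(rate_fn(*x, *params), dtype=float).ravel()
        drift = N @ v
        x = x.copy()
        x[dyn] += drift * dt + sqdt * (B @ rng.standard_normal(len(dyn)))
        if not np.all(np.isfinite(x)):
            raise SimulationError(f"state blow-up at t={times[k] + dt:.4g}")
        times[k + 1] = (k + 1) * dt
        states[k + 1] = x
    return Trajectory(
        times=times,
        states=states,
        species_ids=list(net.species_ids),
        seed=seed,
        method="langevin",
    )


def _resample_uniform(traj: Trajectory, burn_in_fraction: float, n_samples: int):
    t0 = burn_in_fraction * traj.times[-1]
    if traj.method == "ssa":
        # sample-and-hold resampling of the jump path
        grid = np.linspace(t0, traj.times[-1], n_samples)
        idx = np.searchsorted(traj.times, grid, side="right") - 1
        samples = traj.states[idx]
    else:
        # langevin paths are uniformly sampled already: keep native samples
        # (interpolating between steps would deflate the variance), at most
        # decimated to roughly n_samples points
        i0 = int(np.searchsorted(traj.times, t0))
        stride = max(1, (len(traj.times) - i0) // n_samples)
        grid = traj.times[i0::stride]
        samples = traj.states[i0::stride]
    return grid, samples


def stationary_statistics(
    traj: Trajectory,
    burn_in_fraction: float = 0.2,
    lag_grid=None,
    n_batches: int = 32,
    n_samples: int = 1 << 16,
) -> StationaryStats:
    """Stationary mean/covariance/noise-level (and autocorrelation) estimates
    with batch-means standard errors.

    The post-burn-in segment is resampled onto a uniform time grid (sample-
    and-hold for jump paths), split into ``n_batches`` contiguous batches;
    the spread of per-batch statistics gives the standard errors.  With fewer
    than 20 batches the SEs are reported missing with a warning.
    """
    if traj.times[-1] * (1 - burn_in_fraction) <= 0:
        raise SimulationError("trajectory shorter than burn-in")
    grid, samples = _resample_uniform(traj, burn_in_fraction, n_samples)
    dt = grid[1] - grid[0]
    n_sp = samples.shape[1]
    mean = samples.mean(axis=0)
    dev = samples - mean
    cov = dev.T @ dev / len(grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        noise = cov / np.outer(mean, mean)
    noise[~np.isfinite(noise)] = np.nan

    warnings = []
    batch_size = len(grid) // n_batches
    have_se = n_batches >= 20 and batch_size > 1
    if not have_se:
        warnings.append("fewer than 20 batches: standard errors missing")

    lags = None if lag_grid is None else np.asarray(lag_grid, float)
    lag_idx = None if lags is None else np.round(lags / dt).astype(int)
    if lags is not None:
        # report the lags actually evaluated on the resampled grid
        lags = lag_idx * dt
    if lag_idx is not None and np.any(lag_idx >= batch_size):
        warnings.append("some lags exceed batch length; their SEs are unreliable")

    b_mean = np.full((n_batches, n_sp), np.nan)
    b_noise = np.full((n_batches, n_sp), np.nan)
    b_acf = None if lags is None else np.full((n_batches, len(lags), n_sp), np.nan)
    for b in range(n_batches):
        seg = samples[b * batch_size : (b + 1) * batch_size]
        mu = seg.mean(axis=0)
        var = seg.var(axis=0)
        b_mean[b] = mu
        with np.errstate(divide="ignore", invalid="ignore"):
            b_noise[b] = var / mu**2
        if lags is not None:
            d = seg - mu
            for li, l in enumerate(lag_idx):
                if l >= len(seg):
                    continue
                num = (d[: len(seg) - l] * d[l:]).mean(axis=0) if l > 0 else var
                with np.errstate(divide="ignore", invalid="ignore"):
                    b_acf[b, li] = num / var

    def batch_se(arr):
        return np.nanstd(arr, axis=0, ddof=1) / np.sqrt(n_batches)

    mean_se = batch_se(b_mean) if have_se else np.full(n_sp, np.nan)
    noise_se = batch_se(b_noise) if have_se else np.full(n_sp, np.nan)

    acf = acf_se = None
    if lags is not None:
        var_all = np.diag(cov)
        acf = np.full((len(lags), n_sp), np.nan)
        dev_all = samples - mean
        for li, l in enumerate(lag_idx):
            if l >= len(samples):
                continue
            num = (dev_all[: len(samples) - l] * dev_all[l:]).mean(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                acf[li] = num / var_all
        acf_se = batch_se(b_acf) if have_se else np.full((len(lags), n_sp), np.nan)

    # flag degenerate (constant) components
    if np.any(np.diag(cov) == 0):
        warnings.append("constant trajectory component: autocorrelation undefined")

    return StationaryStats(
        species_ids=list(traj.species_ids),
        mean=mean,
        covariance=cov,
        noise_level=noise,
        mean_se=mean_se,
        noise_se=noise_se,
        autocorr_lags=lags,
        autocorr=acf,
        autocorr_se=acf_se,
        warnings=warnings,
    )
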