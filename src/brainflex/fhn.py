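"""Coupled FitzHugh-Nagumo network driven by a block-task square wave.

Each brain region k is a two-variable FitzHugh-Nagumo (FHN) neural mass
with activator u_k and inhibitor w_k:

    eps * du_k/dt = u_k - u_k^3/3 - w_k + I0 - sigma * sum_l g_kl u_l + I_k(t)
    dw_k/dt      = u_k + a - b * w_k

where g_kl are structural-connectome weights and sigma is the overall
coupling constant. The external drive I_k(t) is a square wave
``-c (2*floor(f t) - floor(2 f t))`` with f = 1/T, alternating T/2 seconds
of 0 (baseline block) and T/2 seconds of amplitude c (task block),
delivered only to the selected target nodes. One FHN time unit is
identified with one second so that the 60 s task period and the
hemodynamic time constants share a clock.

Integration is fixed-step classical 4th-order Runge-Kutta. The grid is
required to align with the square-wave edges (T/(2 dt) integer) so that no
RK4 substep straddles an input discontinuity and the observed convergence
order stays ~4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .connectome import NodeSelection, StructuralConnectome

__all__ = [
    "FHNParams",
    "StimulusProtocol",
    "NeuralTrajectory",
    "EnsembleSpec",
    "square_wave_input",
    "input_vector",
    "fhn_rhs",
    "random_initial_conditions",
    "integrate",
    "run_ensemble",
]


@dataclass(frozen=True)
class FHNParams:
    """FHN and coupling parameters (defaults: the study's working point)."""

    a: float = 0.45
    b: float = 0.9
    epsilon: float = 0.1
    sigma: float = 1.8
    I0: float = 0.8

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass(frozen=True)
class StimulusProtocol:
    """Square-wave task input: amplitude c, period T, target nodes."""

    amplitude_c: float = 3.0
    period_T: float = 60.0
    targets: Optional[NodeSelection] = None
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.period_T <= 0:
            raise ValueError("period_T must be positive")


@dataclass(frozen=True)
class NeuralTrajectory:
    """Uniform-grid time courses of activator u and inhibitor w.

    ``u`` and ``w`` are ``(N, n_steps)`` arrays; ``times`` the shared grid.
    """

    times: np.ndarray
    u: np.ndarray
    w: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.u.shape[0]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class EnsembleSpec:
    """Ensemble of repeated runs; run r uses seed ``base_seed + r``."""

    n_runs: int = 300
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


def square_wave_input(t: float, protocol: StimulusProtocol, node_index: int) -> float:
    """Drive I_k(t) for node ``node_index`` (1-based) at time t.

    Equals ``-c (2*floor(f t) - floor(2 f t))`` with f = 1/T on target
    nodes — 0 on [0, T/2), c on [T/2, T), periodically — and 0 for
    non-target nodes or when the protocol is disabled.
    """
    if not protocol.enabled or protocol.targets is None:
        return 0.0
    if node_index not in protocol.targets.indices:
        return 0.0
    f = 1.0 / protocol.period_T
    return -protocol.amplitude_c * (2.0 * np.floor(f * t) - np.floor(2.0 * f * t))


def input_vector(t: float, protocol: StimulusProtocol, n_nodes: int) -> np.ndarray:
    """Vector of I_k(t) over all nodes (vectorised square_wave_input)."""
    out = np.zeros(n_nodes)
    if not protocol.enabled or protocol.targets is None:
        return out
    f = 1.0 / protocol.period_T
    val = -protocol.amplitude_c * (2.0 * np.floor(f * t) - np.floor(2.0 * f * t))
    out[protocol.targets.zero_based()] = val
    return out


def fhn_rhs(
    u: np.ndarray,
    w: np.ndarray,
    t: float,
    G: StructuralConnectome,
    params: FHNParams,
    protocol: StimulusProtocol,
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives (du, dw) of the coupled network at state (u, w).

    ``u``/``w`` may be ``(N,)`` or batched ``(R, N)``; coupling and the
    external input act on the activator component only.
    """
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    drive = input_vector(t, protocol, G.n_nodes)
    coupling = u @ G.weights.T
    du = (u - u**3 / 3.0 - w + params.I0 - params.sigma * coupling + drive) / params.epsilon
    dw = u + params.a - params.b * w
    return du, dw


def random_initial_conditions(
    N: int, seed: int, lo: float = -2.0, hi: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Node-wise i.i.d. uniform initial state on [lo, hi] for u and w."""
    if not lo < hi:
        raise ValueError("need lo < hi")
    rng = np.random.default_rng(seed)
    u0 = rng.uniform(lo, hi, size=N)
    w0 = rng.uniform(lo, hi, size=N)
    return u0, w0


def _check_grid(protocol: StimulusProtocol, dt: float) -> None:
    if not protocol.enabled:
        return
    half = protocol.period_T / 2.0
    ratio = half / dt
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"input half-period {half} s is not an integer multiple of dt={dt}; "
            "align the grid so block edges fall on grid points"
        )


def _integrate_raw(
    G: StructuralConnectome,
    params: FHNParams,
    protocol: StimulusProtocol,
    duration: float,
    dt: float,
    U0: np.ndarray,
    W0: np.ndarray,
    store_w: bool = True,
    guard: float = 1e6,
) -> tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    """RK4 core; state arrays of shape (..., N), trajectories (..., N, S)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < dt:
        raise ValueError("duration must be at least one step")
    _check_grid(protocol, dt)
    n_steps = int(round(duration / dt)) + 1
    times = np.arange(n_steps) * dt
    u = np.array(U0, dtype=float)
    w = np.array(W0, dtype=float)
    U = np.empty(u.shape + (n_steps,))
    W = np.empty(u.shape + (n_steps,)) if store_w else None
    U[..., 0] = u
    if W is not None:
        W[..., 0] = w
    for i in range(1, n_steps):
        t = times[i - 1]
        k1u, k1w = fhn_rhs(u, w, t, G, params, protocol)
        k2u, k2w = fhn_rhs(u + 0.5 * dt * k1u, w + 0.5 * dt * k1w, t + 0.5 * dt, G, params, protocol)
        k3u, k3w = fhn_rhs(u + 0.5 * dt * k2u, w + 0.5 * dt * k2w, t + 0.5 * dt, G, params, protocol)
        k4u, k4w = fhn_rhs(u + dt * k3u, w + dt * k3w, t + dt, G, params, protocol)
        u = u + (dt / 6.0) * (k1u + 2.0 * k2u + 2.0 * k3u + k4u)
        w = w + (dt / 6.0) * (k1w + 2.0 * k2w + 2.0 * k3w + k4w)
        m = max(np.max(np.abs(u)), np.max(np.abs(w)))
        if not np.isfinite(m) or m > guard:
            mag = np.nan_to_num(np.abs(u) + np.abs(w), nan=np.inf)
            node = int(np.argmax(mag.reshape(-1, u.shape[-1]).max(axis=0)))
            raise FloatingPointError(
                f"trajectory diverged at t={times[i]:.4f} s (node {node + 1}: "
                f"|state| exceeded guard {guard:g})"
            )
        U[..., i] = u
        if W is not None:
            W[..., i] = w
    return times, U, W


def integrate(
    G: StructuralConnectome,
    params: FHNParams,
    protocol: StimulusProtocol,
    duration: float,
    dt: float,
    u0: np.ndarray,
    w0: np.ndarray,
    guard: float = 1e6,
) -> NeuralTrajectory:
    """Integrate the coupled FHN network with fixed-step RK4.

    The returned grid includes t=0 and has ``round(duration/dt)+1`` points.
    Raises ``FloatingPointError`` naming the first offending time if any
    state magnitude exceeds ``guard``.
    """
    u0 = np.asarray(u0, dtype=float)
    w0 = np.asarray(w0, dtype=float)
    if u0.shape != (G.n_nodes,) or w0.shape != (G.n_nodes,):
        raise ValueError(f"initial conditions must have shape ({G.n_nodes},)")
    times, U, W = _integrate_raw(G, params, protocol, duration, dt, u0, w0, guard=guard)
    return NeuralTrajectory(
        times, U, W, meta={"dt": dt, "params": params, "protocol": protocol}
    )


def run_ensemble(
    G: StructuralConnectome,
    params: FHNParams,
    protocol: StimulusProtocol,
    duration: float,
    dt: float,
    spec: EnsembleSpec,
) -> Iterator[NeuralTrajectory]:
    """Yield one trajectory per run; run r starts from seed base_seed + r."""
    for r in range(spec.n_runs):
        seed = spec.base_seed + r
        u0, w0 = random_initial_conditions(G.n_nodes, seed)
        traj = integrate(G, params, protocol, duration, dt, u0, w0)
        traj.meta["seed"] = seed
        traj.meta["run"] = r
        yield traj
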