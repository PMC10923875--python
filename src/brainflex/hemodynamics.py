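"""Balloon-Windkessel hemodynamic forward model.

Maps normalized neural activity u_hat to a BOLD-like observable through
four per-node state variables: vasodilatory signal s, normalized blood
inflow f_in, normalized venous volume v and normalized deoxyhemoglobin
content q:

    ds/dt    = eps_B * u_hat - s/tau_s - (f_in - 1)/tau_f
    df_in/dt = s
    dv/dt    = (f_in - v^phi) / tau0
    dq/dt    = (E(f_in)/E0 - v^phi * q / v) / tau0,  E(f) = 1 - (1-E0)^(1/f)

with outflow f_out(v) = v^phi. The BOLD observable is

    y = V0 * [k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v)],
    k1 = 7 E0, k2 = 2, k3 = 2 E0 - 0.2.

The resting point (s, f_in, v, q) = (0, 1, 1, 1) is an exact equilibrium
under zero drive, where y = 0.

The flow-volume exponent is taken literally from the study's parameter
table as phi = 0.32; ``grubb_convention=True`` switches to the common
Balloon-literature reading phi = 1/0.32.

Hemodynamic states are integrated with RK4 at the neural grid step (the
drive is interpolated linearly at half-step substeps) and the BOLD signal
is point-sampled at the repetition time TR, with volumes at k*TR for
k*TR < duration (so 256 s at TR=2 s gives 128 volumes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .fhn import NeuralTrajectory

__all__ = [
    "BalloonParams",
    "BOLDTimeSeries",
    "normalize_activity",
    "bold_signal",
    "hemo_rhs",
    "integrate_hemodynamics",
    "transform",
]


@dataclass(frozen=True)
class BalloonParams:
    """Balloon-Windkessel constants (time constants in seconds)."""

    tau0: float = 0.98          # mean venous transit time
    E0: float = 0.34            # resting oxygen extraction fraction
    V0: float = 0.02            # resting blood volume fraction
    inv_alpha: float = 0.32     # flow-volume exponent as printed: f_out = v^0.32
    tau_s: float = 0.65         # signal decay
    tau_f: float = 0.41         # autoregulatory feedback
    epsilon_B: float = 0.5      # neural efficacy (not in the study's table)
    grubb_convention: bool = False

    def __post_init__(self) -> None:
        if min(self.tau0, self.tau_s, self.tau_f) <= 0:
            raise ValueError("time constants must be positive")
        if not 0 < self.E0 < 1:
            raise ValueError("E0 must lie in (0, 1)")
        if self.V0 <= 0 or self.inv_alpha <= 0:
            raise ValueError("V0 and inv_alpha must be positive")

    @property
    def k1(self) -> float:
        return 7.0 * self.E0

    @property
    def k2(self) -> float:
        return 2.0

    @property
    def k3(self) -> float:
        return 2.0 * self.E0 - 0.2

    @property
    def flow_volume_exponent(self) -> float:
        return 1.0 / self.inv_alpha if self.grubb_convention else self.inv_alpha


@dataclass(frozen=True)
class BOLDTimeSeries:
    """BOLD-like signal y, ``(N, n_vol)``, sampled every TR seconds."""

    times: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.y.shape[0]

    @property
    def n_vol(self) -> int:
        return self.y.shape[1]

    @property
    def TR(self) -> float:
        return float(self.times[1] - self.times[0]) if self.n_vol > 1 else float(self.meta.get("TR", 0))


def normalize_activity(u_series: np.ndarray, axis: int = -1) -> np.ndarray:
    """Z-score a neural time series over its whole span.

    Uses the population standard deviation (divide by n). Raises on a
    constant series, identifying the offending node for 2-D input.
    """
    u = np.asarray(u_series, dtype=float)
    if u.shape[axis] < 2:
        raise ValueError("need at least 2 samples to normalize")
    mu = u.mean(axis=axis, keepdims=True)
    sd = u.std(axis=axis, keepdims=True)  # ddof=0
    if np.any(sd == 0):
        bad = np.argwhere(sd == 0)
        raise ValueError(f"constant series (zero SD) at index {tuple(bad[0][:-1])}")
    return (u - mu) / sd


def bold_signal(v: np.ndarray, q: np.ndarray, params: BalloonParams) -> np.ndarray:
    """BOLD observable y(v, q); zero at the resting point v = q = 1."""
    v = np.asarray(v, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(v <= 0):
        raise ValueError("venous volume v must be positive")
    return params.V0 * (
        params.k1 * (1.0 - q) + params.k2 * (1.0 - q / v) + params.k3 * (1.0 - v)
    )


def hemo_rhs(
    state: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    u_hat: np.ndarray,
    params: BalloonParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Derivatives (ds, df_in, dv, dq) for the hemodynamic state.

    The extraction ratio E(f_in)/E0 is evaluated as exactly 1 at f_in = 1
    (the analytic identity E(1) = E0), which keeps the resting point
    (0, 1, 1, 1) exactly stationary in floating point.
    """
    s, f_in, v, q = state
    phi = params.flow_volume_exponent
    f_out = v**phi
    f_in_arr = np.asarray(f_in, dtype=float)
    E_ratio = np.where(
        f_in_arr == 1.0,
        1.0,
        (1.0 - (1.0 - params.E0) ** (1.0 / f_in_arr)) / params.E0,
    )
    ds = params.epsilon_B * u_hat - s / params.tau_s - (f_in - 1.0) / params.tau_f
    df = s
    dv = (f_in - f_out) / params.tau0
    dq = (E_ratio - f_out * q / v) / params.tau0
    return ds, df, dv, dq


def integrate_hemodynamics(
    u_hat: np.ndarray,
    dt: float,
    params: BalloonParams,
    sample_stride: Optional[int] = None,
    n_samples: Optional[int] = None,
) -> np.ndarray:
    """Drive the Balloon-Windkessel ODEs with ``u_hat`` and return y.

    ``u_hat`` has shape ``(..., S)`` with S time points at step ``dt``;
    the drive is interpolated linearly at RK4 half-steps. Integration
    starts from the resting point (0, 1, 1, 1). With ``sample_stride``
    given, y is returned only at sample indices ``0, stride, 2*stride, ...``
    (``n_samples`` of them); otherwise y is returned on the full grid.
    Positivity of f_in, v and q is enforced at every step.
    """
    u_hat = np.asarray(u_hat, dtype=float)
    S = u_hat.shape[-1]
    base = u_hat.shape[:-1]
    s = np.zeros(base)
    f = np.ones(base)
    v = np.ones(base)
    q = np.ones(base)
    if sample_stride is None:
        out = np.empty(base + (S,))
        out_idx = np.arange(S)
    else:
        n_out = n_samples if n_samples is not None else (S - 1) // sample_stride + 1
        out = np.empty(base + (n_out,))
        out_idx = np.arange(n_out) * sample_stride
    next_out = 0
    for i in range(S):
        if next_out < out.shape[-1] and out_idx[next_out] == i:
            out[..., next_out] = bold_signal(v, q, params)
            next_out += 1
        if i == S - 1:
            break
        d0 = u_hat[..., i]
        d1 = u_hat[..., i + 1]
        dm = 0.5 * (d0 + d1)
        k1 = hemo_rhs((s, f, v, q), d0, params)
        k2 = hemo_rhs(
            (s + 0.5 * dt * k1[0], f + 0.5 * dt * k1[1], v + 0.5 * dt * k1[2], q + 0.5 * dt * k1[3]),
            dm, params,
        )
        k3 = hemo_rhs(
            (s + 0.5 * dt * k2[0], f + 0.5 * dt * k2[1], v + 0.5 * dt * k2[2], q + 0.5 * dt * k2[3]),
            dm, params,
        )
        k4 = hemo_rhs(
            (s + dt * k3[0], f + dt * k3[1], v + dt * k3[2], q + dt * k3[3]),
            d1, params,
        )
        s = s + (dt / 6.0) * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        f = f + (dt / 6.0) * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        v = v + (dt / 6.0) * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        q = q + (dt / 6.0) * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        low = min(np.min(f), np.min(v), np.min(q))
        if not np.isfinite(low) or low <= 0:
            which = np.nan_to_num(np.minimum(np.minimum(f, v), q), nan=-np.inf)
            node = int(np.argmin(which.reshape(-1, base[-1]).min(axis=0))) if base else 0
            raise FloatingPointError(
                f"hemodynamic state lost positivity at t={(i + 1) * dt:.4f} s "
                f"(node {node + 1}); try a smaller dt"
            )
    return out


def transform(
    traj: NeuralTrajectory, params: BalloonParams = BalloonParams(), TR: float = 2.0
) -> BOLDTimeSeries:
    """Turn a neural trajectory into a TR-sampled BOLD-like time series.

    Per node the activator u is z-scored over the whole span, fed to the
    Balloon-Windkessel ODEs at the neural step dt, converted to y, and
    point-sampled at volumes k*TR, k*TR < duration (no anti-alias filter).
    Requires TR to be an integer multiple of dt.
    """
    dt = traj.dt
    stride_f = TR / dt
    stride = int(round(stride_f))
    if abs(stride_f - stride) > 1e-9 or stride < 1:
        raise ValueError(f"TR={TR} must be an integer multiple of dt={dt}")
    duration = float(traj.times[-1])
    n_vol = int(np.floor(duration / TR - 1e-9)) + 1
    u_hat = normalize_activity(traj.u, axis=-1)
    y = integrate_hemodynamics(u_hat, dt, params, sample_stride=stride, n_samples=n_vol)
    times = np.arange(n_vol) * TR
    return BOLDTimeSeries(times, y, meta={"TR": TR, "source": traj.meta})
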