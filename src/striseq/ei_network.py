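"""Excitatory network with shared inhibition and depressing excitatory synapses.

    tau   dx_i/dt = -x_i + phi( sum_j J_ij x_j y_j - J_EI x_I + x_i^in )
    tau_I dx_I/dt = -x_I + phi_I( J_IE sum_j x_j y_j )

with J_ij >= 0 (self-excitation plus feedforward excitation), a single
shared inhibitory unit x_I, and the same per-unit depression dynamics for y
as the inhibitory rate model (the substitution x_j -> x_j*y_j makes the
excitatory synapses depressing).  phi_I defaults to the rectified tanh
Theta(v)*tanh(v).

When inhibition is fast (tau_I -> 0) and phi_I is linear, the inhibitory
drive reduces to J_I * sum_j x_j y_j with J_I = J_EI*J_IE, so the model
collapses onto the purely inhibitory network with effective weights
W = J - J_I (valid when J_I >= max J).  With the relaxed defaults
(tau_I = tau, rectified-tanh phi_I) the behaviour is qualitatively the same
but the finite inhibitory timescale limits how fast switching can get,
restricting the achievable dynamic range of sequence speeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from . import analysis
from .core_rate import InputProtocol, _parse_init, RateNetworkParams, tonic_protocol

__all__ = [
    "EINetworkParams",
    "EIState",
    "EITrace",
    "build_ei_weights",
    "simulate_ei_network",
    "effective_inhibitory_weights",
    "scan_ei_periods",
]


def build_ei_weights(n_units: int, j_self: float = 0.6, j_ff: float = 0.2, cyclic: bool = True) -> np.ndarray:
    """Excitatory matrix J = j_self on the diagonal, j_ff on the subdiagonal."""
    if j_self < 0 or j_ff < 0:
        raise ValueError("excitatory weights must be non-negative")
    J = j_self * np.eye(n_units)
    idx = np.arange(n_units - 1)
    J[idx + 1, idx] = j_ff
    if cyclic:
        J[0, n_units - 1] = j_ff
    return J


@dataclass
class EINetworkParams:
    """Parameters of the excitatory network with shared inhibition."""

    J: np.ndarray
    J_EI: float = 1.0
    J_IE: float = 1.0
    tau: float = 1.0
    tau_I: float = 1.0
    beta: float = 0.2
    tau_y: float = 20.0
    lam: float = 20.0
    phi_I: str = "rectified_tanh"

    def __post_init__(self):
        self.J = np.asarray(self.J, dtype=float)
        if self.J.ndim != 2 or self.J.shape[0] != self.J.shape[1]:
            raise ValueError("J must be square")
        if np.any(self.J < 0):
            raise ValueError("excitatory weights J must be non-negative")
        if self.J_EI < 0 or self.J_IE < 0:
            raise ValueError("J_EI and J_IE must be non-negative")
        if self.phi_I not in ("rectified_tanh", "linear"):
            raise ValueError(f"phi_I must be 'rectified_tanh' or 'linear', got {self.phi_I!r}")
        if self.J_EI * self.J_IE < self.J.max():
            warnings.warn(
                "J_EI*J_IE < max(J): the mapping onto the effective inhibitory model is invalid",
                stacklevel=2,
            )

    @property
    def n_units(self) -> int:
        return self.J.shape[0]

    @property
    def J_I(self) -> float:
        return self.J_EI * self.J_IE


@dataclass
class EIState:
    x: np.ndarray
    x_I: float
    y: np.ndarray
    t: float = 0.0


@dataclass(frozen=True)
class EITrace:
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    x_I: np.ndarray


def _phi_I(v: float, kind: str) -> float:
    if kind == "linear":
        return v
    return np.tanh(v) if v > 0 else 0.0


def simulate_ei_network(
    params: EINetworkParams,
    protocol: InputProtocol,
    duration: float,
    dt: float = 0.02,
    init="one_hot(0)",
    sample_every: int = 1,
    threshold: float = 0.5,
) -> tuple[EITrace, analysis.SequenceTrace]:
    """Integrate the E/I system by explicit Euler and extract the sequence.

    dt must not exceed a tenth of the fastest time constant (tau or tau_I).
    Initial x_I is phi_I(J_IE * sum x*y) evaluated at the initial state.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if dt <= 0 or dt > 0.1 * min(params.tau, params.tau_I):
        raise ValueError(f"dt must satisfy 0 < dt <= 0.1*min(tau, tau_I), got {dt}")
    n = params.n_units
    if protocol.n_units != n:
        raise ValueError("protocol size does not match network size")
    # reuse the one-hot preset parser from the rate model
    rp = RateNetworkParams(n_units=n, tau=params.tau, tau_y=params.tau_y, beta=params.beta, lam=params.lam)
    state = _parse_init(init, rp)
    x, y = state.x, state.y
    x_I = _phi_I(params.J_IE * float(np.sum(x * y)), params.phi_I)
    n_steps = int(round(duration / dt))
    n_samples = n_steps // sample_every + 1
    ts = np.empty(n_samples)
    xs = np.empty((n_samples, n))
    ys = np.empty((n_samples, n))
    xIs = np.empty(n_samples)
    J, J_EI, J_IE = params.J, params.J_EI, params.J_IE
    k = 0
    for step in range(n_steps + 1):
        t = step * dt
        if step % sample_every == 0 and k < n_samples:
            ts[k], xs[k], ys[k], xIs[k] = t, x, y, x_I
            k += 1
        if step == n_steps:
            break
        s = x * y
        drive = J @ s - J_EI * x_I + protocol(t)
        x_new = x + (dt / params.tau) * (-x + expit(params.lam * drive))
        x_I_new = x_I + (dt / params.tau_I) * (-x_I + _phi_I(J_IE * float(np.sum(s)), params.phi_I))
        y_new = y + (dt / params.tau_y) * (-(y - 1.0) * (1.0 - x) - (y - params.beta) * x)
        x, y, x_I = x_new, y_new, x_I_new
    trace = EITrace(t=ts[:k], x=xs[:k], y=ys[:k], x_I=xIs[:k])
    seq = analysis.active_unit_trace(trace.t, trace.x, threshold=threshold)
    return trace, seq


def effective_inhibitory_weights(params: EINetworkParams) -> np.ndarray:
    """Map onto the purely inhibitory model: W = J - J_I (entry-wise).

    Valid in the fast, linear-inhibition limit provided J_I >= max(J);
    the result is a non-positive matrix usable by the rate-model simulator.
    """
    if params.J_I < params.J.max() - 1e-12:
        raise ValueError("mapping requires J_EI*J_IE >= max(J)")
    return params.J - params.J_I


def scan_ei_periods(
    params: EINetworkParams,
    levels,
    dt: float = 0.02,
    n_switches: int = 8,
    init="one_hot(0)",
):
    """Measure sequence periods (per-unit mean switch time) over tonic levels.

    Returns a DataFrame with columns level, mean_switch_time, n_events,
    order_ok (realized cycle equals the feedforward order 0..N-1).  Levels
    at which the sequence stalls or breaks order are flagged invalid; the
    stable bracket is whatever subset of levels remains valid.
    """
    import pandas as pd

    n = params.n_units
    wired = list(range(n))
    rows = []
    for level in levels:
        protocol = tonic_protocol(n, float(level))
        # generous duration: slowest sequences take ~ tau_y * ln(1/(eps)) per switch
        duration = (n_switches + 2) * 3.0 * params.tau_y
        _, seq = simulate_ei_network(params, protocol, duration, dt=dt, init=init)
        try:
            mean_T, _ = analysis.measure_switch_times(seq)
        except ValueError:
            mean_T = np.nan
        cyc = seq.cycle_order()
        start = cyc.index(0) if 0 in cyc else 0
        order_ok = len(cyc) == n and cyc[start:] + cyc[:start] == wired and len(seq) >= n
        rows.append(
            dict(level=float(level), mean_switch_time=mean_T, n_events=len(seq), order_ok=bool(order_ok))
        )
    return pd.DataFrame(rows)
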