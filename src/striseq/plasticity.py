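"""Anti-Hebbian plasticity: tutoring the inhibitory network with patterned input.

The recurrent inhibitory weights evolve as

    dW_ij/dt = -alpha1 * W_ij * x_i * xbar_j  -  alpha2 * (W_ij + 1) * (1 - x_i) * xbar_j

where xbar_j is the presynaptic activity low-pass filtered over tau_w.  The
first term drives W_ij toward 0 when postsynaptic unit i fires together with
or immediately after presynaptic unit j (depotentiation of inhibition); the
second drives W_ij toward -1 when j fires but i does not (potentiation).
Both terms vanish when j has not been recently active.  The flow leaves the
interval [-1, 0] invariant.

Driving the network with a strongly time-dependent "tutoring" input enslaves
the activity to the input order; the rule then carves a depotentiated path
through the inhibition along that order, after which tonic drive alone
replays the sequence at a speed set by the drive level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import analysis
from .core_rate import (
    InputProtocol,
    RateNetworkParams,
    _check_dt,
    _euler_step,
    _parse_init,
    simulate_rate_network,
    tonic_protocol,
    validate_weights,
)

__all__ = [
    "PlasticityParams",
    "TraceState",
    "TrainingRun",
    "lowpass_update",
    "weight_update",
    "make_training_protocol",
    "train_network",
    "tonic_probe",
    "perturb_weights",
    "random_weights",
    "learned_link_weights",
]


@dataclass(frozen=True)
class PlasticityParams:
    """Learning rates (per tau) and presynaptic trace time constant (in tau)."""

    alpha1: float = 0.05
    alpha2: float = 0.02
    tau_w: float = 3.0

    def __post_init__(self):
        if self.alpha1 <= 0 or self.alpha2 <= 0 or self.tau_w <= 0:
            raise ValueError("alpha1, alpha2 and tau_w must all be positive")


@dataclass
class TraceState:
    """Low-pass filtered presynaptic activities xbar, bounded by the range of x."""

    x_bar: np.ndarray


def lowpass_update(x_bar: np.ndarray, x: np.ndarray, dt: float, tau_w: float) -> np.ndarray:
    """First-order exponential filter step: x_bar += dt/tau_w * (x - x_bar)."""
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    return x_bar + (dt / tau_w) * (np.asarray(x, float) - x_bar)


def weight_update(
    W: np.ndarray, x: np.ndarray, x_bar: np.ndarray, dt: float, params: PlasticityParams
) -> np.ndarray:
    """One Euler step of the anti-Hebbian rule; entries remain in [-1, 0]."""
    W = np.asarray(W, dtype=float)
    x = np.asarray(x, dtype=float)
    x_bar = np.asarray(x_bar, dtype=float)
    dW = -params.alpha1 * W * x[:, None] * x_bar[None, :] - params.alpha2 * (W + 1.0) * (
        1.0 - x
    )[:, None] * x_bar[None, :]
    return np.clip(W + dt * dW, -1.0, 0.0)


def random_weights(n_units: int, seed: int = 0, low: float = -1.0, high: float = -0.5) -> np.ndarray:
    """Unstructured initial matrix: off-diagonal uniform in [low, high], diagonal 0."""
    rng = np.random.default_rng(seed)
    W = rng.uniform(low, high, size=(n_units, n_units))
    np.fill_diagonal(W, 0.0)
    return W


def make_training_protocol(
    kind: str,
    n_units: int,
    cycle_length: float,
    cycles: int,
    probe_config: dict | None = None,
    seed: int = 0,
    order: np.ndarray | None = None,
    pulse_width: float | None = None,
    amplitude: float = 1.2,
) -> InputProtocol:
    """Build a tutoring protocol spanning ``cycles`` repetitions.

    ``kind='pulses'``: one rectangular pulse per unit per cycle in ``order``
    (default 0..N-1), width ``pulse_width`` (default cycle_length/n_units).
    ``kind='sinusoids'``: each unit receives a seeded random superposition of
    the first four harmonics of the cycle frequency (amplitudes uniform in
    [0, 0.5], phases uniform in [0, 2*pi)) on a tonic floor; a fresh seed
    yields a different emergent activity order.

    ``probe_config`` (optional) is a dict with key ``level``: the first half
    of the first cycle and the last half of the last cycle are replaced by
    constant input at that level to all units, providing before/after probes
    of autonomous expression within the same run.
    """
    if cycle_length <= 0 or cycles < 1:
        raise ValueError("cycle_length must be positive and cycles >= 1")
    schedule: dict = {"cycle_length": cycle_length, "cycles": cycles}
    if probe_config is not None:
        level = float(probe_config["level"])
        if level < 0:
            raise ValueError("probe level must be non-negative")
        windows = [(0.0, cycle_length / 2), ((cycles - 0.5) * cycle_length, cycles * cycle_length)]
        for t0, t1 in windows:
            if t1 <= t0 or t1 > cycles * cycle_length + 1e-9:
                raise ValueError(f"invalid probe segment ({t0}, {t1})")
        schedule["probe"] = {"level": level, "windows": windows}
    if kind == "pulses":
        if order is not None:
            schedule["order"] = np.asarray(order, dtype=int)
        if pulse_width is not None:
            schedule["pulse_width"] = float(pulse_width)
        schedule["amplitude"] = amplitude
    elif kind != "sinusoids":
        raise ValueError(f"training protocol kind must be 'pulses' or 'sinusoids', got {kind!r}")
    return InputProtocol(kind=kind, n_units=n_units, schedule=schedule, seed=seed)


@dataclass
class TrainingRun:
    """Result of co-integrating the network, the presynaptic trace, and the rule."""

    protocol: InputProtocol
    cycles: int
    cycle_length: float
    weight_snapshots: list  # [(time, W copy)] taken at cycle boundaries
    trace_t: np.ndarray  # sparsely sampled trajectory of the training phase
    trace_x: np.ndarray
    probe_before: analysis.SequenceTrace | None = None
    probe_after: analysis.SequenceTrace | None = None

    @property
    def W_final(self) -> np.ndarray:
        return self.weight_snapshots[-1][1]

    def taught_order(self) -> list[int]:
        """Realized activity order over the penultimate training cycle.

        Extracted from the recorded trajectory away from probe windows, where
        the dynamics are fully enslaved to the tutoring input.
        """
        t1 = (self.cycles - 0.5) * self.cycle_length
        t0 = t1 - self.cycle_length
        sel = (self.trace_t >= t0) & (self.trace_t < t1)
        seq = analysis.active_unit_trace(self.trace_t[sel], self.trace_x[sel])
        units = seq.order
        # rotate so the cycle starts after the wrap point, then deduplicate
        out: list[int] = []
        for u in units:
            if u in out:
                break
            out.append(u)
        return out


def train_network(
    W0: np.ndarray,
    protocol: InputProtocol,
    params: PlasticityParams,
    net_params: RateNetworkParams,
    dt: float = 0.02,
    init="one_hot(0)",
    sample_every: int | None = None,
) -> TrainingRun:
    """Run a tutoring protocol with plasticity on, returning weight snapshots.

    Co-integrates the rate dynamics, the low-pass presynaptic trace, and the
    anti-Hebbian weight update with a shared Euler step.  Plasticity is
    frozen inside the protocol's probe windows (probes measure expression,
    not learning).  Weight snapshots are taken at every cycle boundary.
    Sequential calls on the result's final weights overwrite previously
    stored sequences.
    """
    _check_dt(dt, net_params.tau)
    W = validate_weights(W0, net_params.n_units).copy()
    if protocol.n_units != net_params.n_units:
        raise ValueError("protocol size does not match network size")
    sch = protocol.schedule
    if "cycle_length" not in sch or "cycles" not in sch:
        raise ValueError("training protocol must carry cycle_length and cycles in its schedule")
    cycle_length = float(sch["cycle_length"])
    cycles = int(sch["cycles"])
    if params.tau_w > net_params.tau_y:
        warnings.warn(
            "tau_w exceeds tau_y; the presynaptic trace may outlast unit dwell times, "
            "depotentiating links between non-consecutive units",
            stacklevel=2,
        )
    duration = cycles * cycle_length
    n_steps = int(round(duration / dt))
    if sample_every is None:
        sample_every = max(1, int(round(0.5 / dt)))
    state = _parse_init(init, net_params)
    x, y = state.x, state.y
    x_bar = np.zeros(net_params.n_units)
    snap_stride = int(round(cycle_length / dt))
    snapshots = [(0.0, W.copy())]
    ts, xs = [], []
    a1, a2, tau_w = params.alpha1, params.alpha2, params.tau_w
    for step in range(n_steps + 1):
        t = step * dt
        if step % sample_every == 0:
            ts.append(t)
            xs.append(x.copy())
        if step > 0 and step % snap_stride == 0:
            snapshots.append((t, W.copy()))
        if step == n_steps:
            break
        inp = protocol(t)
        if not protocol.in_probe(t):
            pre = x_bar[None, :]
            dW = -a1 * W * x[:, None] * pre - a2 * (W + 1.0) * (1.0 - x)[:, None] * pre
            W += dt * dW
            np.clip(W, -1.0, 0.0, out=W)
        x_bar += (dt / tau_w) * (x - x_bar)
        x, y = _euler_step(x, y, W, inp, dt, net_params)
    trace_t = np.array(ts)
    trace_x = np.array(xs)
    run = TrainingRun(
        protocol=protocol,
        cycles=cycles,
        cycle_length=cycle_length,
        weight_snapshots=snapshots,
        trace_t=trace_t,
        trace_x=trace_x,
    )
    for name, (t0, t1) in zip(("probe_before", "probe_after"), protocol.probe_windows[:2]):
        sel = (trace_t >= t0 + 5 * net_params.tau) & (trace_t < t1)
        if sel.any():
            setattr(run, name, analysis.active_unit_trace(trace_t[sel], trace_x[sel]))
    return run


def tonic_probe(
    W: np.ndarray,
    net_params: RateNetworkParams,
    level: float,
    duration: float,
    dt: float = 0.02,
    init="one_hot(0)",
):
    """Express a stored sequence under constant drive with plasticity frozen."""
    protocol = tonic_protocol(net_params.n_units, level)
    return simulate_rate_network(net_params, W, protocol, duration, dt=dt, init=init)


def perturb_weights(W: np.ndarray, p: float, seed: int = 0) -> np.ndarray:
    """Perturb every weight by p * xi_ij * <W>, xi_ij standard normal.

    <W> is the mean over off-diagonal entries; the perturbed matrix is
    clipped back to [-1, 0].
    """
    if p < 0:
        raise ValueError(f"perturbation fraction must be >= 0, got {p}")
    W = np.asarray(W, dtype=float)
    if p == 0:
        return W.copy()
    n = W.shape[0]
    mean_w = W[~np.eye(n, dtype=bool)].mean()
    rng = np.random.default_rng(seed)
    return np.clip(W + p * rng.standard_normal(W.shape) * mean_w, -1.0, 0.0)


def learned_link_weights(W: np.ndarray, order: list[int], cyclic: bool = True) -> dict[int, float]:
    """Weight of the sequence link out of each unit in a taught order.

    Returns {j: W[successor(j), j]}; the link's effective depotentiation is
    eta_j = 1 + W[successor(j), j].
    """
    pairs = list(zip(order[:-1], order[1:]))
    if cyclic and len(order) > 1:
        pairs.append((order[-1], order[0]))
    return {j: float(W[k, j]) for j, k in pairs}
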