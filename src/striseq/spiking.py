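"""Clustered exponential integrate-and-fire network with depressing synapses.

Membrane dynamics per neuron (explicit Euler, V in mV, t in ms):

    C dV/dt = g_L (E_L - V) + g_L * Delta_T * exp[(V - V_T)/Delta_T] + I(t)

A spike is recorded when V crosses V_peak (numerical stand-in for the
divergence of the exponential term) and V is reset to E_L.  Each synapse
carries a depression variable x in (0, 1] — the fraction of available
neurotransmitter — which recovers toward 1 with time constant tau_x and is
scaled by (1 - u) at every presynaptic spike.  A presynaptic spike of
neuron j delivers charge u*Q*x_ij*W_ij to neuron i (an instantaneous voltage
jump u*Q*x_ij*W_ij/C), with W_ij in [-1, 0] inhibitory.

Because the depression dynamics depend only on presynaptic spikes and all
synapses start fully recovered, every synapse sharing presynaptic neuron j
follows the identical trajectory; the per-synapse variables are therefore
stored as one value per presynaptic neuron (an exact reduction, not an
approximation).

The anti-Hebbian STDP rule is trace-based and presynaptically gated: no
weight changes without a presynaptic spike nearby.  Each presynaptic spike
contributes -a (potentiation of inhibition toward -1) plus A times the
postsynaptic trace (depotentiation toward 0 for post-before-pre pairings,
window tau_post); each postsynaptic spike contributes A times the
presynaptic trace (depotentiation for post-after-pre pairings, window
tau_pre).  Weights are clipped to [-1, 0].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SpikingParams",
    "STDPParams",
    "Sin8InputParams",
    "SpikingNetwork",
    "SpikingResult",
    "eif_rheobase",
    "build_clustered_network",
    "make_sin8_input",
    "tonic_current",
    "simulate_spiking",
    "stdp_update",
    "depression_fixed_point",
    "scaled_charge",
]


@dataclass(frozen=True)
class SpikingParams:
    """EIF membrane and synapse constants (pF, nS, mV, ms, pC)."""

    C: float = 300.0
    g_L: float = 30.0
    E_L: float = -70.0
    V_T: float = -50.0
    Delta_T: float = 2.0
    tau_x: float = 200.0
    u: float = 0.5
    Q: float = 1.5
    V_peak: float = 0.0
    dt: float = 0.05

    def __post_init__(self):
        if min(self.C, self.g_L, self.tau_x, self.Q, self.Delta_T) <= 0:
            raise ValueError("C, g_L, tau_x, Q and Delta_T must be positive")
        if not 0 <= self.u <= 1:
            raise ValueError(f"release fraction u must be in [0, 1], got {self.u}")
        if self.V_peak <= self.V_T:
            raise ValueError("V_peak must exceed V_T")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C/g_L in ms."""
        return self.C / self.g_L


def eif_rheobase(params: SpikingParams) -> float:
    """Minimum constant current (nA) for repetitive EIF firing: g_L*(V_T - E_L - Delta_T)."""
    return params.g_L * (params.V_T - params.E_L - params.Delta_T) / 1000.0


def scaled_charge(cluster_size: int, Q_ref: float = 1.5, size_ref: int = 100) -> float:
    """Synaptic charge rescaled to preserve total per-cluster inhibition.

    With fixed connection probability the number of synapses a neuron
    receives from a cluster scales with cluster size, so scaled-down
    networks use Q * size_ref / cluster_size to keep the aggregate charge
    delivered by an active cluster unchanged.
    """
    if cluster_size < 1:
        raise ValueError("cluster_size must be >= 1")
    return Q_ref * size_ref / cluster_size


@dataclass(frozen=True)
class STDPParams:
    """Anti-Hebbian STDP amplitudes and trace time constants (ms)."""

    A: float = 0.05
    a: float = 0.002
    tau_pre: float = 20.0
    tau_post: float = 5.0

    def __post_init__(self):
        if min(self.A, self.a, self.tau_pre, self.tau_post) <= 0:
            raise ValueError("all STDP parameters must be positive")
        if self.A <= self.a:
            raise ValueError("depotentiation amplitude A must exceed potentiation amplitude a")


@dataclass(frozen=True)
class Sin8InputParams:
    """Tutoring current I_i(t) = x0 + x1 * sin^8(pi*t/period + theta_i), in nA.

    theta_i = pi * n_i / 8 for cluster index n_i = 1..n_clusters by default.
    Gaussian noise (sigma_* fields) is redrawn independently per input cycle
    for x0, x1 and theta, and higher-frequency terms ~ sin(8*pi*t/T) and
    sin(12*pi*t/T) with |N(0, sigma_harmonic)| amplitudes and uniform random
    phases are added per cycle.  Currents are clipped at 0.  Set the sigmas
    to 0 for the noise-free waveform.
    """

    x0: float = 0.2
    x1: float = 0.5
    period: float = 800.0
    sigma_x0: float = 0.02
    sigma_x1: float = 0.05
    sigma_theta: float = 0.05
    sigma_harmonic: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError(f"period must be positive, got {self.period}")


@dataclass
class SpikingNetwork:
    """Clustered network state: connectivity, weights, depression, voltages.

    ``x_syn`` holds one depression variable per presynaptic neuron (all
    synapses from a given neuron share the same trajectory; see module
    docstring).
    """

    n_clusters: int
    cluster_size: int
    membership: np.ndarray
    connectivity: np.ndarray
    W: np.ndarray
    x_syn: np.ndarray
    V: np.ndarray

    @property
    def n_neurons(self) -> int:
        return len(self.membership)

    def with_weights(self, W: np.ndarray, reset: bool = True) -> "SpikingNetwork":
        """Copy of the network carrying new weights, optionally with depression reset."""
        n = self.n_neurons
        return replace(
            self,
            W=np.array(W, dtype=float),
            x_syn=np.ones(n) if reset else self.x_syn.copy(),
            V=self.V.copy(),
        )


def build_clustered_network(
    n_clusters: int = 8,
    cluster_size: int = 100,
    p_connect: float = 0.2,
    w_init_range: tuple[float, float] = (-1.0, -0.5),
    seed: int = 0,
    E_L: float = -70.0,
) -> SpikingNetwork:
    """Seeded random network: Bernoulli(p) connectivity without autapses.

    Initial weights are uniform in ``w_init_range`` (a sub-interval of
    [-1, 0]) on existing synapses and 0 elsewhere; depression variables
    start fully recovered (x = 1) and membranes at rest (E_L).
    """
    if not 0 < p_connect <= 1:
        raise ValueError(f"p_connect must be in (0, 1], got {p_connect}")
    if n_clusters < 1 or cluster_size < 1:
        raise ValueError("n_clusters and cluster_size must be >= 1")
    lo, hi = w_init_range
    if not (-1.0 <= lo <= hi <= 0.0):
        raise ValueError(f"w_init_range must lie within [-1, 0], got {w_init_range}")
    n = n_clusters * cluster_size
    rng = np.random.default_rng(seed)
    conn = rng.random((n, n)) < p_connect
    np.fill_diagonal(conn, False)
    W = np.where(conn, rng.uniform(lo, hi, size=(n, n)), 0.0)
    membership = np.repeat(np.arange(n_clusters), cluster_size)
    return SpikingNetwork(
        n_clusters=n_clusters,
        cluster_size=cluster_size,
        membership=membership,
        connectivity=conn,
        W=W,
        x_syn=np.ones(n),
        V=np.full(n, E_L),
    )


def make_sin8_input(
    params: Sin8InputParams, n_clusters: int, membership: np.ndarray | None = None
) -> Callable[[float], np.ndarray]:
    """Per-neuron tutoring current function (nA) with per-cycle noise.

    Noise for cycle k is drawn from a child stream of ``params.seed`` keyed
    by k, so evaluating the function at any time is deterministic and
    independent of evaluation order.  If ``membership`` is omitted the
    function returns one current per cluster.
    """
    theta0 = np.pi * (np.arange(n_clusters) + 1) / 8.0
    cache: dict[int, tuple] = {}

    def cycle_draws(k: int):
        if k not in cache:
            if max(params.sigma_x0, params.sigma_x1, params.sigma_theta, params.sigma_harmonic) == 0:
                cache[k] = (
                    np.full(n_clusters, params.x0),
                    np.full(n_clusters, params.x1),
                    theta0,
                    np.zeros(n_clusters), np.zeros(n_clusters),
                    np.zeros(n_clusters), np.zeros(n_clusters),
                )
            else:
                rng = np.random.default_rng([params.seed, k])
                cache[k] = (
                    params.x0 + params.sigma_x0 * rng.standard_normal(n_clusters),
                    params.x1 + params.sigma_x1 * rng.standard_normal(n_clusters),
                    theta0 + params.sigma_theta * rng.standard_normal(n_clusters),
                    np.abs(params.sigma_harmonic * rng.standard_normal(n_clusters)),
                    rng.uniform(0, 2 * np.pi, n_clusters),
                    np.abs(params.sigma_harmonic * rng.standard_normal(n_clusters)),
                    rng.uniform(0, 2 * np.pi, n_clusters),
                )
        return cache[k]

    def current(t: float) -> np.ndarray:
        k = int(np.floor(t / params.period))
        x0, x1, theta, a8, p8, a12, p12 = cycle_draws(k)
        w = np.pi * t / params.period
        I = (
            x0
            + x1 * np.sin(w + theta) ** 8
            + a8 * np.sin(8 * w + p8)
            + a12 * np.sin(12 * w + p12)
        )
        I = np.maximum(I, 0.0)
        return I if membership is None else I[membership]

    return current


def tonic_current(n_neurons: int, amplitude: float) -> Callable[[float], np.ndarray]:
    """Constant current (nA) of the same amplitude to every neuron."""
    vec = np.full(n_neurons, float(amplitude))
    return lambda t: vec


@dataclass
class SpikingResult:
    """Spike raster plus final state and optional weight history."""

    spike_times: np.ndarray
    spike_neurons: np.ndarray
    W: np.ndarray
    x_syn: np.ndarray
    V: np.ndarray
    weight_snapshots: list
    duration: float


def simulate_spiking(
    network: SpikingNetwork,
    input_fn: Callable[[float], np.ndarray],
    duration: float,
    params: SpikingParams = SpikingParams(),
    stdp: STDPParams | None = None,
    seed: int = 0,
    record_weights_every: float | None = None,
) -> SpikingResult:
    """Euler-integrate the EIF network; STDP applied only if ``stdp`` given.

    ``input_fn`` maps time (ms) to per-neuron external current in nA.  The
    passed network is not mutated; final weights, depression variables and
    voltages are returned in the result.  Raises on dt > 0.05 ms and on
    non-finite voltages.
    """
    dt = params.dt
    if dt <= 0 or dt > 0.05:
        raise ValueError(f"dt must satisfy 0 < dt <= 0.05 ms, got {dt}")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    n = network.n_neurons
    V = network.V.astype(float).copy()
    x_syn = network.x_syn.astype(float).copy()
    W = network.W.astype(float).copy()
    conn = network.connectivity
    decay_x = np.exp(-dt / params.tau_x)
    jump_scale = 1000.0 * params.u * params.Q / params.C  # pC/pF -> mV per unit x*W
    gl, EL, VT, DT, C = params.g_L, params.E_L, params.V_T, params.Delta_T, params.C
    if stdp is not None:
        r = np.zeros(n)  # presynaptic trace, tau_pre
        o = np.zeros(n)  # postsynaptic trace, tau_post
        decay_pre = np.exp(-dt / stdp.tau_pre)
        decay_post = np.exp(-dt / stdp.tau_post)
    n_steps = int(round(duration / dt))
    times_out: list[np.ndarray] = []
    ids_out: list[np.ndarray] = []
    snapshots: list = []
    next_snap = 0.0
    for step in range(n_steps):
        t = step * dt
        if record_weights_every is not None and t >= next_snap - 1e-9:
            snapshots.append((t, W.copy()))
            next_snap += record_weights_every
        I_pA = 1000.0 * np.asarray(input_fn(t), dtype=float)
        exp_term = gl * DT * np.exp(np.minimum((V - VT) / DT, 20.0))
        V += dt * (gl * (EL - V) + exp_term + I_pA) / C
        spiked = np.nonzero(V >= params.V_peak)[0]
        if spiked.size:
            times_out.append(np.full(spiked.size, t + dt))
            ids_out.append(spiked)
            V[spiked] = EL
            V += jump_scale * (W[:, spiked] @ x_syn[spiked])
            if stdp is not None:
                # pre-locked terms use the post trace before this step's spikes
                cols = W[:, spiked] + conn[:, spiked] * (stdp.A * o - stdp.a)[:, None]
                W[:, spiked] = np.clip(cols, -1.0, 0.0)
                rows = W[spiked, :] + conn[spiked, :] * (stdp.A * r)[None, :]
                W[spiked, :] = np.clip(rows, -1.0, 0.0)
                r[spiked] += 1.0
                o[spiked] += 1.0
            x_syn[spiked] *= 1.0 - params.u
        x_syn = 1.0 - (1.0 - x_syn) * decay_x
        if stdp is not None:
            r *= decay_pre
            o *= decay_post
        if step % 500 == 0 and not np.all(np.isfinite(V)):
            bad = np.nonzero(~np.isfinite(V))[0]
            raise FloatingPointError(f"non-finite membrane potential at t={t:.2f} ms, neurons {bad[:5]}")
    spike_times = np.concatenate(times_out) if times_out else np.empty(0)
    spike_neurons = np.concatenate(ids_out) if ids_out else np.empty(0, dtype=int)
    return SpikingResult(
        spike_times=spike_times,
        spike_neurons=spike_neurons,
        W=W,
        x_syn=x_syn,
        V=V,
        weight_snapshots=snapshots,
        duration=duration,
    )


def stdp_update(
    w: float,
    pre_times: Sequence[float],
    post_times: Sequence[float],
    stdp: STDPParams,
) -> float:
    """Event-driven evaluation of the STDP rule for a single synapse.

    Processes the merged spike train exactly (exponential trace decay
    between events); simultaneous pre and post spikes are applied using the
    traces as they stood before either spike.  Returns the updated weight,
    clipped to [-1, 0].
    """
    events = sorted(
        [(float(t), "pre") for t in pre_times] + [(float(t), "post") for t in post_times]
    )
    r = o = 0.0
    t_last = events[0][0] if events else 0.0
    i = 0
    while i < len(events):
        t = events[i][0]
        r *= np.exp(-(t - t_last) / stdp.tau_pre)
        o *= np.exp(-(t - t_last) / stdp.tau_post)
        t_last = t
        group = []
        while i < len(events) and events[i][0] == t:
            group.append(events[i][1])
            i += 1
        dw = 0.0
        for kind in group:
            if kind == "pre":
                dw += -stdp.a + stdp.A * o
            else:
                dw += stdp.A * r
        w = float(np.clip(w + dw, -1.0, 0.0))
        for kind in group:
            if kind == "pre":
                r += 1.0
            else:
                o += 1.0
    return w


def depression_fixed_point(rate_hz: float, params: SpikingParams) -> float:
    """Steady-state depression just before each spike of a periodic train.

    For presynaptic spiking at rate r the recursion x -> (1 - (1 - (1-u)x) e)
    with e = exp(-1/(r*tau_x)) has fixed point x* = (1 - e)/(1 - (1-u) e).
    """
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    e = np.exp(-1000.0 / (rate_hz * params.tau_x))
    return float((1.0 - e) / (1.0 - (1.0 - params.u) * e))
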