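"""Winner-take-all inhibitory rate network with short-term synaptic depression.

Each unit represents a cluster of striatal medium spiny neurons.  Units are
coupled by inhibitory weights ``W`` (entries <= 0) whose efficacy is scaled
by a per-unit depression factor ``y``:

    tau   dx_i/dt = -x_i + phi( sum_j W_ij x_j y_j + x_i^in )
    tau_y dy_j/dt = -(y_j - 1)(1 - x_j) - (y_j - beta) x_j

with sigmoidal transfer phi(v) = 1 / (1 + exp(-lam * v)).  Mutual inhibition
makes the network winner-take-all; depression of the winner's outgoing
synapses (y decaying toward beta while the unit is active) lets the
least-inhibited successor take over, producing a sparse activity sequence.
The tonic drive level sets how early the successor's net input turns
positive, hence the sequence speed — faster for stronger drive, diverging as
the effective drive approaches beta.

Times are in units of the membrane time constant tau (tau = 1 throughout).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

from . import analysis

__all__ = [
    "RateNetworkParams",
    "RateState",
    "RateTrace",
    "InputProtocol",
    "SwitchTheory",
    "sigmoid_transfer",
    "build_sequence_weights",
    "build_multi_path_weights",
    "validate_weights",
    "step_rate_network",
    "simulate_rate_network",
    "effective_input",
    "switch_time_theory",
    "temporal_scaling_factor",
    "scan_switch_times",
]

ACTIVE_THRESHOLD = 0.5


@dataclass(frozen=True)
class RateNetworkParams:
    """Parameters of the depressing inhibitory rate network.

    Attributes
    ----------
    n_units : number of units (MSN clusters), >= 2.
    tau : membrane-like time constant; the reference time unit (1).
    tau_y : depression recovery time constant, in units of tau.
    beta : floor of the depression factor, in [0, 1).
    lam : sigmoid gain.
    """

    n_units: int
    tau: float = 1.0
    tau_y: float = 20.0
    beta: float = 0.2
    lam: float = 20.0

    def __post_init__(self):
        if self.n_units < 2:
            raise ValueError(f"n_units must be >= 2, got {self.n_units}")
        if not 0 <= self.beta < 1:
            raise ValueError(f"beta must be in [0, 1), got {self.beta}")
        if self.lam <= 0:
            raise ValueError(f"lam must be > 0, got {self.lam}")
        if self.tau_y <= 0 or self.tau <= 0:
            raise ValueError("tau and tau_y must be positive")


@dataclass
class RateState:
    """Instantaneous network state: activities x, depression factors y, time t."""

    x: np.ndarray
    y: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same length")


@dataclass(frozen=True)
class RateTrace:
    """Sampled trajectory of a rate simulation."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray


def sigmoid_transfer(v, lam: float):
    """Sigmoidal transfer phi(v) = 1/(1 + exp(-lam*v)), strictly increasing."""
    if lam <= 0:
        raise ValueError(f"lam must be > 0, got {lam}")
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite input to sigmoid_transfer")
    out = expit(lam * v)
    return float(out) if out.ndim == 0 else out


def validate_weights(W: np.ndarray, n_units: int | None = None) -> np.ndarray:
    """Check a recurrent weight matrix: square, inhibitory, entries in [-1, 0]."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if n_units is not None and W.shape[0] != n_units:
        raise ValueError(f"W side {W.shape[0]} does not match n_units {n_units}")
    if np.any(W > 1e-12):
        raise ValueError("inhibitory network requires W <= 0")
    if np.any(W < -1 - 1e-9):
        raise ValueError("weights must lie in [-1, 0]")
    return W


def build_sequence_weights(n_units: int, eta: float, cyclic: bool = True) -> np.ndarray:
    """Handcrafted weight matrix encoding the sequence 0 -> 1 -> ... -> N-1.

    All off-diagonal entries are -1 except those from unit j onto unit j+1,
    which are depotentiated by eta to -(1 - eta); the diagonal is 0.  If
    ``cyclic`` the wrap-around link (N-1 -> 0) is also depotentiated, making
    the sequence repeat.
    """
    if n_units < 2:
        raise ValueError(f"n_units must be >= 2, got {n_units}")
    if not 0 <= eta < 1:
        raise ValueError(f"eta must be in [0, 1), got {eta}")
    W = -np.ones((n_units, n_units))
    np.fill_diagonal(W, 0.0)
    idx = np.arange(n_units - 1)
    W[idx + 1, idx] = -(1.0 - eta)
    if cyclic:
        W[0, n_units - 1] = -(1.0 - eta)
    return W


def build_multi_path_weights(
    n_units: int, paths: Sequence[Sequence[int]], eta: float
) -> np.ndarray:
    """Weight matrix encoding several (possibly overlapping) sequences.

    Starts from the uniform inhibitory baseline (-1 off-diagonal, 0 diagonal)
    and depotentiates the link j -> k for every consecutive pair along every
    path.  Depotentiation is idempotent: links shared between paths are
    depotentiated once.
    """
    if not 0 <= eta < 1:
        raise ValueError(f"eta must be in [0, 1), got {eta}")
    W = -np.ones((n_units, n_units))
    np.fill_diagonal(W, 0.0)
    for path in paths:
        for j, k in zip(path[:-1], path[1:]):
            if not (0 <= j < n_units and 0 <= k < n_units):
                raise ValueError(f"path index ({j}, {k}) out of range for {n_units} units")
            if j == k:
                raise ValueError("paths must not contain self-links")
            W[k, j] = -(1.0 - eta)
    return W


def effective_input(xin: float, eta: float) -> float:
    """Effective drive x_hat = xin / (1 - eta), the quantity governing switching."""
    if not 0 <= eta < 1:
        raise ValueError(f"eta must be in [0, 1), got {eta}")
    return xin / (1.0 - eta)


def switch_time_theory(x_hat_in, beta: float, tau_y: float):
    """Closed-form switch time T = tau_y * ln[(1 - beta) / (x_hat_in - beta)].

    While a unit is active its outgoing depression decays as
    y(t) = beta + (1 - beta) exp(-t / tau_y); activity switches when the
    depressed inhibition on the successor falls to its effective drive,
    y(T) = x_hat_in.  Diverges as x_hat_in approaches beta (no switching at
    or below beta).
    """
    x_hat_in = np.asarray(x_hat_in, dtype=float)
    if np.any(x_hat_in <= beta):
        raise ValueError("switching requires x_hat_in > beta (T diverges otherwise)")
    if np.any(x_hat_in > 1 + 1e-12):
        raise ValueError("x_hat_in must be <= 1")
    T = tau_y * np.log((1.0 - beta) / (x_hat_in - beta))
    return float(T) if T.ndim == 0 else T


def temporal_scaling_factor(beta: float, delta: float) -> float:
    """Ratio Tmax/Tmin of switch times at the probe drives beta+delta and 1-delta.

    With drive restricted to [beta + delta, 1 - delta], the slowest and
    fastest achievable switch times give the scaling factor
    ln[(1-beta)/delta] / ln[(1-beta)/(1-beta-delta)], strictly decreasing in
    delta and equal to 1 at delta = (1-beta)/2.
    """
    if not 0 < delta <= (1.0 - beta) / 2:
        raise ValueError(f"delta must be in (0, (1-beta)/2], got {delta}")
    return float(
        switch_time_theory(beta + delta, beta, 1.0) / switch_time_theory(1.0 - delta, beta, 1.0)
    )


@dataclass(frozen=True)
class SwitchTheory:
    """Switch-time bounds for drive restricted to [beta+delta, 1-delta]."""

    beta: float
    tau_y: float
    delta: float

    def __post_init__(self):
        if not 0 < self.delta <= (1.0 - self.beta) / 2:
            raise ValueError(f"delta must be in (0, (1-beta)/2], got {self.delta}")

    @property
    def Tmax(self) -> float:
        return switch_time_theory(self.beta + self.delta, self.beta, self.tau_y)

    @property
    def Tmin(self) -> float:
        return switch_time_theory(1.0 - self.delta, self.beta, self.tau_y)

    @property
    def scaling_factor(self) -> float:
        return temporal_scaling_factor(self.beta, self.delta)


# ---------------------------------------------------------------------------
# External drive protocols


@dataclass
class InputProtocol:
    """Declarative external drive, evaluated as a non-negative vector per time.

    kind:
      - ``tonic``: constant ``level`` to every unit selected by ``mask``.
      - ``pulses``: one rectangular pulse per unit per cycle, in the order
        given by ``schedule['order']``; schedule keys: ``cycle_length``,
        ``pulse_width`` (default cycle_length/n_units), ``amplitude``
        (default 1.2, strong enough to override any stored inhibition),
        ``baseline`` (default 0).
      - ``sinusoids``: each unit receives one smooth sinusoidal lobe per
        cycle, A_i * sin^(2p)(pi*t/cycle + phi_i), with random amplitude
        A_i in ``amp_range`` (default (0.78, 0.92), below the baseline
        inhibitory weight so a fading lobe can be quenched by fresh
        inhibition), and phases assigned by a seeded random permutation of
        equally spaced slots (plus jitter) so lobes tile the cycle in a
        random order — the rate-model analogue of the sin^8 tutoring
        currents used for the spiking network.  ``exponent`` is p (default
        16, i.e. sin^32 lobes whose width roughly matches the slot
        spacing at 10 units).  Drawn once from ``seed``.
      - ``sin8_current``: x0 + x1 * sin^8(pi*t/period + phase_i) per unit
        (noise-free form; the spiking module adds per-cycle noise).
      - ``explicit``: schedule['fn'] is a callable t -> vector.

    ``schedule['probe']`` may define windows during which the drive reverts
    to a constant level applied to all units: a dict with keys ``level`` and
    ``windows`` (list of (t0, t1) pairs).  Output is clipped at 0.
    Identical (kind, level, mask, schedule, seed) reproduce the identical
    input function.
    """

    kind: str
    n_units: int
    level: float = 0.0
    mask: np.ndarray | None = None
    schedule: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        kinds = {"tonic", "pulses", "sinusoids", "sin8_current", "explicit"}
        if self.kind not in kinds:
            raise ValueError(f"unknown protocol kind {self.kind!r}; expected one of {sorted(kinds)}")
        if self.level < 0:
            raise ValueError(f"tonic level must be >= 0, got {self.level}")
        if self.mask is None:
            self._maskvec = np.ones(self.n_units)
        else:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != (self.n_units,):
                raise ValueError("mask must be a boolean vector of length n_units")
            self._maskvec = m.astype(float)
        probe = self.schedule.get("probe")
        if probe is not None:
            for t0, t1 in probe["windows"]:
                if t1 <= t0:
                    raise ValueError(f"invalid probe window ({t0}, {t1})")
        if self.kind == "pulses":
            sch = self.schedule
            self._order = np.asarray(sch.get("order", np.arange(self.n_units)), dtype=int)
            self._cycle = float(sch["cycle_length"])
            self._width = float(sch.get("pulse_width", self._cycle / len(self._order)))
            self._amp = float(sch.get("amplitude", 1.2))
            self._base = float(sch.get("baseline", 0.0))
            if self._cycle <= 0 or self._width <= 0:
                raise ValueError("cycle_length and pulse_width must be positive")
        elif self.kind == "sinusoids":
            sch = self.schedule
            self._cycle = float(sch["cycle_length"])
            if self._cycle <= 0:
                raise ValueError("cycle_length must be positive")
            self._exponent = int(sch.get("exponent", 16))
            amp_lo, amp_hi = sch.get("amp_range", (0.78, 0.92))
            self._floor = float(sch.get("floor", 0.0))
            jitter = float(sch.get("jitter", 0.1))
            n = self.n_units
            rng = np.random.default_rng(self.seed)
            perm = rng.permutation(n)
            slots = np.empty(n)
            slots[perm] = np.arange(n)
            # lobe of slot s peaks at t = (s + 0.5) * cycle / n: all peaks
            # lie strictly inside the cycle, troughs at the boundaries
            self._phases = (
                np.pi / 2
                - np.pi * (slots + 0.5) / n
                + jitter * (np.pi / n) * rng.uniform(-1.0, 1.0, n)
            )
            self._amps = rng.uniform(amp_lo, amp_hi, n)
            self.slot_order = [int(u) for u in perm]
        elif self.kind == "sin8_current":
            sch = self.schedule
            self._x0 = float(sch.get("x0", 0.2))
            self._x1 = float(sch.get("x1", 0.5))
            self._period = float(sch.get("period", 800.0))
            phases = sch.get("phases")
            if phases is None:
                phases = np.pi * (np.arange(self.n_units) + 1) / self.n_units
            self._sin8_phases = np.asarray(phases, dtype=float)
            if self._period <= 0:
                raise ValueError("period must be positive")
        elif self.kind == "explicit":
            if not callable(self.schedule.get("fn")):
                raise ValueError("explicit protocol requires a callable schedule['fn']")

    @property
    def probe_windows(self) -> list[tuple[float, float]]:
        probe = self.schedule.get("probe")
        return [] if probe is None else [tuple(w) for w in probe["windows"]]

    def in_probe(self, t: float) -> bool:
        return any(t0 <= t < t1 for t0, t1 in self.probe_windows)

    def __call__(self, t: float) -> np.ndarray:
        probe = self.schedule.get("probe")
        if probe is not None and self.in_probe(t):
            return np.full(self.n_units, float(probe["level"]))
        if self.kind == "tonic":
            v = self.level * self._maskvec
        elif self.kind == "pulses":
            phase = t % self._cycle
            slot = int(phase // (self._cycle / len(self._order)))
            v = np.full(self.n_units, self._base)
            slot_start = slot * self._cycle / len(self._order)
            if slot < len(self._order) and phase - slot_start < self._width:
                v[self._order[slot]] = self._amp
            v = v * self._maskvec
        elif self.kind == "sinusoids":
            v = self._floor + self._amps * np.sin(np.pi * t / self._cycle + self._phases) ** (
                2 * self._exponent
            )
            v = v * self._maskvec
        elif self.kind == "sin8_current":
            v = self._x0 + self._x1 * np.sin(np.pi * t / self._period + self._sin8_phases) ** 8
            v = v * self._maskvec
        else:  # explicit
            v = np.asarray(self.schedule["fn"](t), dtype=float) * self._maskvec
        return np.maximum(v, 0.0)


def tonic_protocol(n_units: int, level: float, mask: np.ndarray | None = None) -> InputProtocol:
    """Convenience constructor for a constant drive protocol."""
    return InputProtocol(kind="tonic", n_units=n_units, level=level, mask=mask)


# ---------------------------------------------------------------------------
# Integration


def _check_dt(dt: float, tau: float):
    if dt <= 0 or dt > 0.1 * tau:
        raise ValueError(f"dt must satisfy 0 < dt <= 0.1*tau, got dt={dt}, tau={tau}")


def _euler_step(x, y, W, inp, dt, params):
    drive = W @ (x * y) + inp
    x_new = x + (dt / params.tau) * (-x + expit(params.lam * drive))
    y_new = y + (dt / params.tau_y) * (-(y - 1.0) * (1.0 - x) - (y - params.beta) * x)
    return x_new, y_new


def step_rate_network(
    state: RateState, W: np.ndarray, input_vec: np.ndarray, dt: float, params: RateNetworkParams
) -> RateState:
    """One explicit Euler step of the activity and depression equations."""
    _check_dt(dt, params.tau)
    input_vec = np.asarray(input_vec, dtype=float)
    if np.any(input_vec < 0):
        raise ValueError("external input must be non-negative")
    x, y = _euler_step(state.x, state.y, np.asarray(W, float), input_vec, dt, params)
    return RateState(x=x, y=y, t=state.t + dt)


def _parse_init(init, params: RateNetworkParams) -> RateState:
    if isinstance(init, RateState):
        return RateState(x=init.x.copy(), y=init.y.copy(), t=init.t)
    m = re.fullmatch(r"one_hot\((\d+)\)", str(init))
    if not m:
        raise ValueError(f"unknown init preset {init!r}; expected 'one_hot(k)' or a RateState")
    k = int(m.group(1))
    if not 0 <= k < params.n_units:
        raise ValueError(f"one_hot index {k} out of range")
    x = np.full(params.n_units, 0.01)
    x[k] = 1.0
    return RateState(x=x, y=np.ones(params.n_units), t=0.0)


def simulate_rate_network(
    params: RateNetworkParams,
    W: np.ndarray,
    protocol: InputProtocol,
    duration: float,
    dt: float = 0.02,
    init="one_hot(0)",
    sample_every: int = 1,
    threshold: float = ACTIVE_THRESHOLD,
) -> tuple[RateTrace, analysis.SequenceTrace]:
    """Integrate the network and extract the realized activity sequence.

    Explicit Euler with step ``dt`` (must be <= 0.1*tau).  The trajectory is
    sampled every ``sample_every`` steps.  Deterministic given the protocol
    (whose randomness is fixed by its seed) and the initial condition.

    Returns the sampled (t, x, y) trajectory and the SequenceTrace of active
    units (argmax of x where it exceeds ``threshold``).
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    _check_dt(dt, params.tau)
    W = validate_weights(W, params.n_units)
    if protocol.n_units != params.n_units:
        raise ValueError("protocol size does not match network size")
    state = _parse_init(init, params)
    n_steps = int(round(duration / dt))
    n_samples = n_steps // sample_every + 1
    ts = np.empty(n_samples)
    xs = np.empty((n_samples, params.n_units))
    ys = np.empty((n_samples, params.n_units))
    x, y, t = state.x, state.y, state.t
    k = 0
    for step in range(n_steps + 1):
        if step % sample_every == 0 and k < n_samples:
            ts[k], xs[k], ys[k] = t, x, y
            k += 1
        if step == n_steps:
            break
        x, y = _euler_step(x, y, W, protocol(t), dt, params)
        t = state.t + (step + 1) * dt
    trace = RateTrace(t=ts[:k], x=xs[:k], y=ys[:k])
    seq = analysis.active_unit_trace(trace.t, trace.x, threshold=threshold)
    return trace, seq


def scan_switch_times(
    params: RateNetworkParams,
    W: np.ndarray,
    levels: Sequence[float],
    eta: float = 0.0,
    dt: float = 0.02,
    n_switches: int = 8,
    init="one_hot(0)",
):
    """Measure mean switch times over a scan of effective tonic drive levels.

    ``levels`` are effective drives x_hat; the raw tonic input applied is
    x_hat * (1 - eta).  Each level is simulated long enough for about
    ``n_switches`` activity switches (predicted from the closed-form switch
    time).  Returns a pandas DataFrame with columns x_hat, xin,
    mean_switch_time, theory_switch_time, n_events, order_ok (whether the
    realized cycle is the wired order 0..N-1).
    """
    import pandas as pd

    rows = []
    wired = list(range(params.n_units))
    for x_hat in levels:
        T_th = switch_time_theory(x_hat, params.beta, params.tau_y)
        duration = max(20 * params.tau_y, (n_switches + 2) * T_th)
        protocol = tonic_protocol(params.n_units, x_hat * (1.0 - eta))
        _, seq = simulate_rate_network(params, W, protocol, duration, dt=dt, init=init)
        try:
            mean_T, _ = analysis.measure_switch_times(seq)
        except ValueError:
            mean_T = np.nan
        cyc = seq.cycle_order()
        start = cyc.index(0) if 0 in cyc else 0
        order_ok = len(cyc) == params.n_units and cyc[start:] + cyc[:start] == wired
        rows.append(
            dict(
                x_hat=float(x_hat),
                xin=float(x_hat * (1 - eta)),
                mean_switch_time=mean_T,
                theory_switch_time=T_th,
                n_events=len(seq),
                order_ok=bool(order_ok),
            )
        )
    return pd.DataFrame(rows)
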