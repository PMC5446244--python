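# Methods

## Models

### Depressing inhibitory rate network (`core_rate`)

Unit activities x_i ∈ (0,1) and per-unit depression factors y_j ∈ [β,1]
follow

    τ  dx_i/dt = −x_i + φ( Σ_j W_ij x_j y_j + x_i^in ),   φ(v) = 1/(1+e^(−λv))
    τ_y dy_j/dt = −(y_j − 1)(1 − x_j) − (y_j − β) x_j

with W_ij ≤ 0 (row = postsynaptic) and non-negative external drive. The
model assumes (i) units stand for whole cell assemblies, so smooth rate
dynamics are meaningful; (ii) depression acts multiplicatively on all
outgoing synapses of a unit with a single recovery time τ_y ≫ τ; (iii) the
transfer function is sharp (λ ≫ 1) so winner-take-all competition is crisp.

Defaults follow the reference regime used throughout the tests: τ = 1
(the time unit), τ_y = 20, β = 0.2, λ = 20. Handcrafted sequence matrices
set all off-diagonals to −1 except the sequence links j→j+1 at −(1−η)
(η = 0.1 by default, wrap-around link included for repeating sequences),
and zero diagonal — the learning rule drives self-weights of active units
to zero, and the switch-time algebra assumes no residual self-inhibition.

**Switch-time theory.** While unit j is active its outgoing depression
decays as y(t) = β + (1−β)e^(−t/τ_y). The successor's net input turns
positive when y falls to the effective drive x̂ = x_in/(1−η), giving
T = τ_y ln[(1−β)/(x̂−β)]. The formula is validated in the test suite
against direct numerical integration of the depression ODE to the crossing.

**Validity range.** The closed form assumes instantaneous takeover
(λ → ∞, τ/τ_y → 0). At the finite defaults, full-network simulations agree
with it to within 10% for x̂ ≲ 0.65. Beyond that two finite-gain effects
dominate: the successor must climb to x·y > x_in before it can shut the old
winner off, which costs an extra depression of ≈ φ⁻¹(x_in)/λ and imposes a
floor of ~5–8 τ on the achievable switch time; and for x̂ ≳ 0.85 the old
unit re-activates mid-handoff (its drive x_in exceeds the depressed
inhibition y), producing stable two-unit co-activation patterns instead of
a faster sequence. At the slow end, x̂ ≲ 0.28, all quiescent units sit at a
small but non-zero φ(λ(x_in − y)) and this collective partial activity can
self-sustain and quench the sequence. The practical speed range at the
default gain is therefore about 5–6-fold (x̂ ≈ 0.3 … 0.8), not the
arbitrarily large range of the idealized limit; reaching theory-level
speeds at x̂ = 0.9 would need λ of order 200. The tests assert the 10%
agreement on the validated range and monotone speed-up over x̂ ∈ [0.3, 0.8].

**Integration.** Explicit Euler, default dt = 0.02 τ, hard contract
dt ≤ 0.1 τ. The dynamics are non-stiff at these gains; halving dt changes
realized orders not at all and switch times by <2% (tested). The Euler
update keeps x strictly inside (0,1) (convex combination with φ) and y
inside [β,1]. Ties in the active-unit readout (argmax of x, reported when
it exceeds 0.5) break toward the lowest index; the initial condition
preset `one_hot(k)` starts unit k at 1, all others at 0.01, all y at 1.

### Drive protocols

`InputProtocol` generates all external drives deterministically from its
seed: tonic levels (optionally masked to a "spotlight" subset of units),
rectangular pulse trains (one pulse per unit per cycle in a given order,
amplitude 1.2 — above the maximal recurrent inhibition, so the drive
overrides any stored pattern), smooth sinusoidal lobes, the sin⁸ waveform
family, explicit callables, and probe windows during which the drive
reverts to a tonic level for all units.

The "sinusoids" tutor gives each unit one smooth lobe
A_i sin³²(πt/C + φ_i) per cycle, with amplitudes drawn uniformly from
[0.78, 0.92] (just below the baseline inhibitory weight, so a fading lobe
can always be quenched by fresh inhibition), and phases assigned by a
seeded random permutation of equally spaced slots jittered by ±10% and
aligned so every peak falls strictly inside the cycle. This is the
rate-model analogue of the sin⁸ tutoring currents used for the spiking
network. Independent random superpositions of low harmonics were examined
and rejected: their broad, slowly-crossing peaks let units win twice per
cycle with different successors, so no consistent successor structure can
form (see Limitations).

### Anti-Hebbian plasticity (`plasticity`)

    dW_ij/dt = −α₁ W_ij x_i x̄_j − α₂ (W_ij + 1)(1 − x_i) x̄_j

with x̄_j a first-order low-pass of x_j over τ_w. Defaults α₁ = 0.05/τ,
α₂ = 0.02/τ, τ_w = 3 τ. The flow leaves [−1, 0] invariant (vector field
points inward at both boundaries); the Euler update additionally clips.
The rule is applied to all entries including the diagonal (active units
depotentiate their own self-weight toward 0, consistent with the
zero-diagonal convention of the handcrafted matrices). Plasticity is
frozen inside probe windows: probes measure expression, not learning.

**Learned link strength.** For pulse tutoring with dwell time T_d, a
sequence link alternates between depotentiation during the ≈τ_w handoff
co-activation and re-potentiation during the rest of the predecessor's
dwell. The per-cycle balance puts the learned successor weight near

    |W*| ≈ (1 − e^(−α₂(T_d−τ_w))) / (1 − e^(−α₂(T_d−τ_w) − α₁τ_w))

≈ 0.73 at T_d = 33 τ — i.e. an effective depotentiation η_eff ≈ 0.27.
The taught link is the least-negative entry of its column (which is what
`weight_structure_score` reads out) but is far from zero; consequently the
probe speed range of a tutored network inherits the same finite-gain limits
as a handcrafted η ≈ 0.27 network, and the re-activation failure narrows
its valid slow end further (measured dynamic range ≈ 2.5–4 across seeds).

**Training runs.** `train_network` co-integrates the rate equations, the
presynaptic trace and the weight update with a shared Euler step, snapshots
the matrix at every cycle boundary, and records a sparsely sampled activity
trace from which the realized taught order is extracted. Initial random
matrices draw off-diagonals uniformly from [−1, −0.5] (diagonal 0).
Training a second pattern on a trained matrix overwrites it; links from
units inactive in the second pattern keep x̄_j ≈ 0 and do not change.

**Perturbation experiment.** `perturb_weights` adds p·ξ_ij·⟨W⟩ with ξ_ij
standard normal and ⟨W⟩ the off-diagonal mean, clipping back to [−1, 0].
Replayed switch *times* are robust (sub-percent shift at p = 0.02), but
strict order preservation degrades with p: the taught link's margin over
its competitors (≈ 0.27) is only about two standard deviations of the
pairwise perturbation noise at p = 0.1, so column argmax flips somewhere in
the matrix are then near-certain.

### Excitatory network with shared inhibition (`ei_network`)

    τ  dx_i/dt = −x_i + φ( Σ_j J_ij x_j y_j − J_EI x_I + x_i^in )
    τ_I dx_I/dt = −x_I + φ_I( J_IE Σ_j x_j y_j )

with J_ij = 0.6 δ_ij + 0.2 δ_{j+1,j} (cyclic), J_EI = J_IE = 1, τ_I = τ and
φ_I(v) = Θ(v) tanh(v) by default; the substitution x→x·y makes the
excitatory synapses depressing. One depression variable per excitatory unit
scales both the E→E and E→I drive. In the fast linear-inhibition limit
(τ_I → 0, φ_I(v) = v) the system reduces exactly to the inhibitory model
with W = J − J_EI·J_IE (valid when J_EI·J_IE ≥ max J); the tests verify
trajectory agreement to max-abs 0.05 at τ_I = 0.01 τ. Because no specific
probe levels are fixed a priori for this variant, the stable-sequence
bracket is found by scanning tonic levels and keeping those
whose realized cycle is complete and correctly ordered (here 0.30–0.70);
the period ratio inside the bracket is ≈ 4.9, the expected roughly
four-fold range — shared inhibition's own time constant limits how fast
switching can get relative to direct lateral inhibition.

### Clustered spiking network (`spiking`)

Exponential integrate-and-fire neurons, C dV/dt = g_L(E_L − V) +
g_L Δ_T e^((V−V_T)/Δ_T) + I(t), with C = 300 pF, g_L = 30 nS, E_L = −70 mV,
V_T = −50 mV, Δ_T = 2 mV (rheobase g_L(V_T−E_L−Δ_T) = 0.54 nA, membrane
time constant 10 ms). Spikes are detected at V = 0 mV — passage from there
to divergence is sub-step at dt = 0.05 ms — and reset to E_L; no refractory
period. A presynaptic spike of neuron j delivers an instantaneous jump
u·Q·x_j·W_ij/C to each target (u = 0.5, Q = 1.5 pC), after which the
release variable is scaled by (1−u); it recovers toward 1 with
τ_x = 200 ms. Since depression depends only on presynaptic spiking and all
synapses start recovered, all synapses sharing a presynaptic neuron follow
one trajectory and are stored as a single per-neuron variable (exact).

8 clusters of 100 neurons, connection probability 0.2, no autapses.
Initial weights are uniform in [−1.0, −0.5]: deep enough that the
*trained* background inhibition (≈ −0.8 after the small constant
potentiation accumulated over tutoring) can still enforce winner-take-all
during tonic replay. Tutoring currents are
I_i(t) = x0 + x1 sin⁸(πt/T + θ_i) with x0 = 0.2 nA, x1 = 0.5 nA,
T = 800 ms and θ_i = π n_i/8 — the phase layout makes the lobes peak in
descending cluster order, which is therefore the taught cycle. Per-cycle
Gaussian noise (σ = 0.02 nA on x0, 0.05 nA on x1, 0.05 rad on θ) plus
8π/T and 12π/T harmonics with |N(0, 0.05 nA)| amplitudes and random phases
are redrawn each cycle from a seeded child stream.

The STDP rule is trace-based and presynaptically gated: each presynaptic
spike changes the synapse by −a + A·o_i (o_i the postsynaptic trace,
τ_post = 5 ms) and each postsynaptic spike by A·r_j (r_j the presynaptic
trace, τ_pre = 20 ms), with A = 0.05, a = 0.002 and clipping to [−1, 0].
Coincident or post-after-pre pairings therefore depotentiate (net ≈ A − a
toward zero) while isolated presynaptic firing slowly potentiates toward
−1. Only the amplitude/time-constant quadruple is fixed by the reference
constants; the functional form is the minimal one consistent with the
qualitative rule and is pluggable.

After ~20 noisy tutoring cycles the cluster-averaged matrix shows its
diagonal and taught-successor blocks strictly less negative than all other
blocks (gap ≈ 0.1–0.3), and tonic drive to all neurons replays the taught
cycle with the period decreasing monotonically with amplitude over
≈ 0.6–0.8 nA (≈ 3-fold range at the probe amplitudes used).

## Problem sizes and runtimes

The test suite and the reproduction script run the 10-unit handcrafted
scans, 15-unit tutoring (20 cycles of 25 τ_y), the 10-unit E/I bracket
scan, and the full 8×100 spiking pipeline (20 cycles of 800 ms, then three
5 s probes); the whole suite completes in well under ten minutes on one
CPU. Cluster sizes below ~50 neurons are not used for replay experiments:
rescaling the synaptic charge to preserve mean inhibition (see
`scaled_charge`) multiplies IPSP shot noise and lets rival clusters escape
suppression, an artifact of the scale rather than the mechanism.

## What the generators do and do not emulate

All inputs are synthetic and fully seeded; there is no external data. The
tutoring protocols emulate idealized cortical drive: disjoint rectangular
pulses (reference tutor) or smooth single-lobe waveforms in a random slot
order. They do not emulate irregular naturalistic input statistics,
correlated noise across units, or reward-modulated structure. Passing
tests therefore demonstrate the internal consistency of the mechanism —
sequence internalization, autonomous replay, tonic speed control — under
clean driving conditions, not robustness to realistic cortical
variability.

## Known limitations

- The closed-form switch time and the large claimed speed ranges hold in
  the idealized sharp-gain, separated-timescale limit; at the finite
  reference parameters the realized dynamic range of the rate models is
  ≈ 4–6-fold (quantified above), and the fast end of the theory curve is
  not reachable.
- Smooth tutoring inputs whose lobes overlap by more than ~τ_w trigger a
  two-active traveling-wave attractor under the anti-Hebbian rule (both
  link directions depotentiate), after which tonic replay ping-pongs
  between unit pairs. Sequence internalization is reliable with pulse-like
  tutors; with the smooth sinusoid tutor structure accuracy varies between
  0.7 and 1.0 across seeds.
- Strict replay-order invariance under weight perturbation holds only for
  small p (≲ 0.02 at 15 units); at p = 0.1 the mean switch time is still
  accurate for sequences that survive but order flips are common.
- Each spiking neuron belongs to exactly one cluster; overlapping
  assemblies, conductance-based synapses, transmission delays and
  interneuron populations are out of scope.
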