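# Methods

## Model

### Ideal network

A scalar signal x(t) obeys τ ẋ = −x + c(t).  N leaky integrate-and-fire
neurons receive the command c(t) and emit spike trains o_i(t); a leaky
readout x̂ integrates them with weights w_i and time constant τ (the readout
and membrane time constants are identified, which is what makes the leak
term emerge from the derivation).  A neuron spikes exactly when doing so
lowers the instantaneous loss

    E = (x − x̂)² + α Σ_i r_i + β Σ_i r_i²,

where r_i is the neuron's own leaky rate trace (τ ṙ_i = −r_i + o_i).  The
spike/no-spike comparison reduces to a fixed-threshold rule V_i > T_i with

    V_i = w_i (x − x̂) − β r_i,     T_i = ½ (w_i² + α + β),

and differentiating V_i yields LIF dynamics: leak −V_i, feed-forward drive
w_i c, recurrent inhibition −w_i w_k per spike of neuron k (self term
included), an extra reset −β for the firing cell, and a membrane noise term.

**Spike-impulse convention.**  One spike increments r_i by 1, x̂ by w_i, and
decrements voltages by the coefficient of the corresponding spike-train
term (w_i w_k cross-neuron, plus β for the firing cell).  This is the only
convention under which the threshold T = ½(w² + α + β) is exactly half the
firing neuron's total self-decrement, and it fixes the steady-state rates:
a constant target x is encoded without bias when the population fires at
x/(w τ) spikes/s (≈ 40 Hz for the 3-neuron toy at x = 4, ≈ 8.3 Hz per
neuron for the 50-neuron network at x = 50).

### Excitatory/inhibitory network with delayed synapses

Dale's law is respected by two populations with positive readout weights.
Excitatory cells encode x̂E from the feed-forward drive and are inhibited by
I spikes (their voltage is V^E_i = w_i(x − x̂I) − β_E r_i); inhibitory cells
are driven by E spikes and inhibited by I spikes, minimizing
(x̂I − x̂E)² + costs.  The connectivity therefore has exactly three
pathways — E→I, I→E, I→I — each the outer product of the postsynaptic and
presynaptic readout weights; there is no E→E pathway.

Cross-neuron spike effects are delivered through the synaptic current

    h(t) = [exp(−(t−τ_tr)/τ_d) − exp(−(t−τ_tr)/τ_r)] / (τ_d − τ_r)

for t > τ_tr and zero otherwise (defaults τ_r = 1 ms, τ_d = 3 ms,
τ_tr = 1 ms; unit integral).  The own-spike reset −β stays instantaneous:
it models intracellular dynamics, not a synapse.  Unlike the ideal network
(at most one spike per bin, highest voltage wins, ties to the lowest
index), any number of delayed-network neurons may fire in one bin — the
synchrony this permits is the phenomenon under study.

The simulator realizes the convolution with exact two-state exponential
filters per pathway plus a circular delay buffer (transmission delay
rounded to the grid).  The recursive filter's discrete impulse response
equals the sampled kernel; its geometric-sum mass is normalized so one
spike of weight m delivers integrated drive exactly m.  A
direct-convolution oracle in the test suite pins this equivalence to the
kernel's truncation error (< 10⁻³ relative).

**Synaptic failures.**  Each (spike, postsynaptic target) delivery fails
independently with probability p; surviving recurrent weights are divided
by the success probability 1 − p, keeping the expected delivered mass per
spike equal to the nominal weight.  (Dividing by the *failure* probability
would diverge as p → 0; the success-probability reading is the one
consistent with an unchanged mean input.)

**Poisson substitution.**  A fraction of cells can be replaced by Poisson
emitters whose rates equal the corresponding cells' mean rates measured
from a reference run of the intact network at the same parameters; their
spikes still enter the recurrence and the readout, while their own
recurrent input is discarded.

## Numerics

* Forward Euler, dt = 0.5 ms; initial voltages, rates and readouts zero.
  The ideal simulator also accepts a "consistent" initial state
  (V_i = w_i x(0)), under which the integrated voltage equals the closed
  form w(x − x̂) − β r at every sample to machine precision; from a zero
  start the difference decays as e^{−t/τ}.
* **Membrane noise.**  Per Euler step each voltage receives σ √(dt/τ)·ξ
  with ξ ~ N(0,1), i.e. the white-noise term enters the τ-scaled voltage
  equation, giving a stationary voltage SD of σ/√(2τ) (≈ 12 mV at σ = 17,
  τ = 0.1 s).  This reading was chosen empirically: it is the one under
  which the published operating point is self-consistent — at σ = 17 the
  bias-nulled L2 cost lands near its published value, the population spectrum
  peaks in the gamma band, per-cell CV is near unity, and both the
  reconstruction error and the E/I mismatch are minimized at σ = 17 on a
  coarse {2, 17, 60} grid.  The alternative per-step scaling σ√dt (SD
  σ√(τ/2)) shifts the whole u-shape to σ ≈ 60 and leaves the network fully
  synchronized at ~10 Hz at σ = 17.
* Onset transients are excluded from all metrics via a configurable
  burn-in (default 0.5 s).
* Blow-up guard: non-finite or > 10⁹ mV voltages abort with a diagnostic.
* Command traces are recovered from targets by forward differences
  (c = τ Δx/Δt + x, last sample copied), which makes forward-Euler
  integration of the target equation reproduce x exactly on the grid.
  Note that differentiating sampled filtered noise re-injects a white
  component at high frequencies; quantitative sweeps therefore use
  constant targets, as do the published quantitative figures.
* Filtered-noise targets use a causal (forward-only) first-order
  Butterworth filter — an online stimulus has no access to the future —
  and are affinely standardized so the realized sample mean and SD equal
  the requested values exactly.

## Calibration

Changing the noise level (or failure rate, or Poisson fraction) changes
firing rates and hence introduces an estimation bias.  Before measuring,
each sweep point nulls the biases by stochastic gradient descent on the two
L2 costs: after each 2 s chunk (0.5 s burn-in), β_E ← β_E + η·⟨x̂E − x⟩ and
β_I ← β_I + η·⟨x̂I − x̂E⟩ (over-estimation means firing too much, so the
cost rises), with η = 0.5, tolerance 0.5 (1 % of the x = 50 target), at
most 50 chunks, chunk i seeded with seed + i.  The spike threshold co-varies
with β through T = ½(w² + α + β), which is what holds rates constant across
noise levels (verified to within 10 % between σ = 8 and σ = 17).  The
inhibitory bias is measured against x̂E because that is the inhibitory
population's own target.  Convergence is declared from a chunk measured
under the current costs; non-convergence is reported via a flag, and
calibrated (point, β_E, β_I) triples can be cached to CSV so sweeps resume.

## Analysis choices

* **Spectra.**  Multitaper PSD on scipy DPSS tapers, time-bandwidth product
  4 (2NW−1 tapers, eigenvalue-weighted), mean-subtracted input, Parseval
  checked to 10 %.  Peak frequency is the argmax above 5 Hz, excluding DC
  and slow drift.  The published bandwidths were chosen empirically and are
  unrecoverable, so conclusions are asserted as band membership (30–50 Hz),
  not peak shape.
* **Spectrogram.**  Hamming-window STFT (60 ms window, 75 % overlap); each
  frequency row is smoothed along time with a first-order 3 Hz Butterworth
  filter.
* **Population rate.**  Per-bin spike counts / (N·dt), optionally low-pass
  filtered (first-order Butterworth; 5.5 Hz for a smooth envelope, 66 Hz
  for a fast view).  Spectra use the raw binned rate.
* **Currents.**  Per-cell depolarizing and hyperpolarizing input traces
  divided by a nominal 5 MΩ membrane resistance (the value only rescales
  the axis).  The inhibitory population is analysed by default: only its
  cells receive an oscillating excitatory input (the E→I drive), the
  excitatory cells' depolarizing input being the constant feed-forward
  drive.
* **Cycle peaks.**  Local maxima of the current magnitudes, retained only
  when separated by a trough at least 80 % below the smaller neighbouring
  peak; E and I peaks are paired within a 15 ms window in order of
  increasing gap (each peak used once), making the pairing symmetric under
  E ↔ I relabeling with a lag sign flip.  The cycle-frequency effect is
  quantified as the Pearson correlation between an E-peak's amplitude and
  the interval to the next E-peak.
* **Voltage pair statistics.**  Zero-lag Pearson correlation averaged over
  distinct pairs (the scalar summary of the cross-correlogram) and
  magnitude-squared coherence averaged over (subsampled) pairs.
* **Discrimination.**  Estimates are time-averaged readouts over 0.1 s
  segments; performance is d′ = (μ₂ − μ₁)/√(½(σ₁² + σ₂²)) mapped to
  p = Φ(d′/√2) = ½ erfc(−d′/2).  This is the standard two-alternative
  form — it equals ½ at d′ = 0 and increases with d′ (a literal reading of
  the published formula would decrease below chance for d′ > 0).

## Biophysical mapping

Anchoring the model threshold at a spike threshold of −55 mV and carrying
the costs in mV (L1 = 0, L2 = 8.5, γ0 = 1.2 mV^1/2) implies
V_rest = V_thresh − ½(L1 + L2 + γ0²) = −59.97 ≈ −60 mV,
V_reset = V_thresh − L2 − γ0² = −64.94 ≈ −65 mV, and unitary PSPs of
γ0² = 1.44 mV.  No unit conversion is performed inside the simulator.

## Study conditions and problem sizes

Default conditions follow the standard parameter set: 50+50 neurons,
γ0 = 1.2, β = 8.5 mV, τ = 0.1 s, σ = 17, dt = 0.5 ms, kernel 1/3/1 ms,
constant targets from the amplitude catalogue {4 (toy), 35/50/65, 48
(discrimination centre)}; filtered-noise targets use first-order
Butterworth cutoffs of 4 Hz (mean 3, SD 1) and 2 Hz (mean 50, SD 10).
Where the sources state no value the package picks once: sweep measurement
runs of 6–10 s simulated time with 2–3 seeds per grid point; coarse
bracketing grids (σ ∈ {2, 17, 60}, kernel scale ∈ {0.5, 1, 2}, N ∈
{25, 50, 100}); the synchrony toy uses 10 neurons at 10 spikes/s each for
20 s with k ∈ {1, 2, 3, 5} (at k = N the schedule degenerates into
population-wide bursts, a different regime from the one illustrated);
discrimination uses 0.1 s segments and ≥ 20 trials per condition.

## What the synthetic conditions do and do not show

All inputs are generated internally (constant or filtered-noise targets);
there is no sensory front end, no heterogeneity of time constants, no
conductance-based synapses, and a single encoded dimension.  Passing tests
show that the derived network, integrated faithfully, produces the claimed
dynamical regime and orderings (u-shape, gamma band, balance, rate
scaling); they do not show that cortical circuits implement this
computation, and the 100 ms readout/membrane time constant the performance
relies on is slower than measured cortical membranes — both limitations of
the model class, not of the implementation.

## Known limitations

* The E/I readout mismatch at the constant-input gamma point is dominated
  by the few-millisecond inhibitory lag and spike discreteness; x̂I tracking
  of x̂E is therefore asserted as positive correlation plus a mismatch below
  the uncoupled-readout level, not as a vanishing difference.
* Quantities tied to unpublished protocol details (exact sweep grids,
  durations, multitaper bandwidths) are reproduced as orderings and band
  memberships rather than curve values.
* With zero noise and symmetric initial conditions the ideal network's
  spike rotation is deterministic; single-cell irregularity requires the
  published nonzero noise.
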