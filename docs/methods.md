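# Methods

`cxcompass` models the heading-direction circuit of the *Drosophila*
central complex as a spiking ring attractor that fuses angular-velocity
input with learned visual-landmark input, and asks how well the circuit
estimates orientation — and, by dead reckoning, position — along synthetic
trajectories. This note records the model, its assumptions, every
calibrated constant, and what the synthetic conditions do and do not show.

## Circuit model

Five populations, 141 leaky integrate-and-fire neurons in total: 81
visually tuned ring neurons, 18 E-PG ("compass") neurons whose activity
bump encodes heading, 16 P-EN neurons carrying angular velocity, 16 P-EG
neurons closing the recurrent loop that sustains the bump, and 10
inhibitory PIntr (Δ7) neurons. Membrane dynamics are τ dV/dt = −V + I
with τ = 20 ms, threshold 1, reset 0, absolute refractory period 2 ms,
integrated by exponential Euler at dt = 1 ms. Zero-mean Gaussian current
noise (σ = 0.1) enters P-EG and PIntr each step; angular-velocity
measurements carry Gaussian noise with σ = 0.1 rad/s.

Fixed connection weights take three block values — +20 for every
excitatory pathway (E-PG→P-EN, E-PG→P-EG, E-PG→PIntr, P-EN→E-PG,
P-EG→E-PG), −15 for PIntr onto P-EN/P-EG, −20 for PIntr onto PIntr — and
PIntr never contact E-PG directly. Synaptic transmission is rate-coded:
each connection contributes (global gain) × weight × (presynaptic
low-pass spike trace, Hz). The trace time constant is 10 ms except for
P-EN outputs (50 ms), which filters spiking shot noise out of the
velocity pathway at a lag that is negligible against the trial
timescales.

### Ring topology

The protocerebral bridge has nine glomeruli per hemisphere for E-PG but
only eight P-EN/P-EG per hemisphere. We close the ring the way the
ellipsoid body does anatomically: the first and last wedges overlap, so
the ninth E-PG glomerulus is a functional duplicate of the first. The
ring therefore has 8 distinct heading positions at 45° spacing,
symmetric in both rotation directions; the duplicate pair is split
across hemispheres as the recurrent source for position 0 so no position
receives doubled drive, and the population-vector decoder down-weights
duplicated neurons by their multiplicity. The alternative — nine distinct
positions at 40° — leaves one glomerulus without a shift neuron in one
direction, and the bump provably cannot rotate through that seam.

### PIntr wiring

Uniform all-to-all PIntr inhibition is structurally inconsistent with the
block weights: ten −15 inputs onto each P-EG would dominate its single
+20 E-PG input at any global gain and the recurrent loop could never
fire. We instead let each PIntr pool excitation from **all** E-PG and
send inhibition to the P-EN/P-EG at the four ring positions matching its
index parity (echoing the alternating-glomerulus axonal fields of real
Δ7 neurons). Every position then receives exactly five PIntr inputs:
inhibition is spatially even, tracks total bump activity (a rate
homeostat and single-bump enforcer), and still never touches E-PG.

### Calibrated constants

The published weights are dimensionless ratios, and spiking-network
libraries typically assign per-neuron gain and bias internally, so the
absolute current scale of every pathway is implementation-defined. We fix
one global synaptic gain and three pathway factors, chosen once so the
attractor functions (stable single bump at 100–250 Hz, monotone and
symmetric velocity response) and then left alone:

| constant | value | role |
|---|---|---|
| syn_gain | 2×10⁻³ | global (weight × Hz) → current |
| pen_epg_gain | 2.0 | shift-pathway strength |
| peg_epg_gain | 0.4 | keeps the bump core below the refractory ceiling |
| pintr_out_gain | 0.2 | inhibition at the loop-viability boundary |
| epg_bias | 0.3 | constant E-PG excitation; ring weights disinhibit against it |
| P-EN baseline | 0.9 | both hemispheres active so slow turns act differentially |

Angular velocity maps linearly to P-EN current on the hemisphere
matching its sign, anchored so a P-EN driven at 10 rad/s fires at a
steady-state 250 Hz (using the discrete-time LIF rate: inter-spike
intervals quantize to whole timesteps, so the continuous closed form
1/(t_ref + τ ln(I/(I−θ))) is corrected for step quantization). A zero
baseline was tried first and rejected: without background P-EN activity
the bump is pinned at low turn rates.

## Plasticity

The 18×81 ring→E-PG matrix W is the only plastic structure; ring neurons
are inhibitory so W ≤ 0 elementwise (clipped after every update), and
visual input steers the compass by disinhibition. Two presynaptically
gated rules are implemented: the Hebbian rule
Δw = η r (a c + b − w) with a = 1.7×10⁻⁶, b = 1.7×10⁻⁴, η = 0.29, and
the error-minimizing rule Δw = η r (c − β I) with I = Σ r w and
β = 0.0025. Both are exact gradient descent on their objectives
(verified by central finite differences in the test suite).

Units: the postsynaptic trace c is in Hz (so a·c is commensurate with b
and the rule is heading-selective); the presynaptic gate r is the
normalized activation in [0, 1]; η is per second, applied as η·dt per
step times a learning-gain of 0.5 that converts activity units. The gain
is set so a 60-s trial ends mid-transient: because every pre-clip fixed
point a·c + b is positive, full convergence clips all visited weights to
zero and erases the learned association — the informative regime is the
transient.

The offline optimum solves, per compass neuron, the positive lasso

    min_{w̃ ≥ 0, α}  Σ_t ( c̃(t) + Σ_m r_m(t) w̃_m + α )²  +  λ Σ_m w̃_m

(compass activity = baseline − ring-driven inhibition) against a target
c̃ following a circular Gaussian of width 40° around each neuron's
preferred angle, then scales and sign-flips: W = −β w̃, β = 0.0025. The
target amplitude (10⁴ activation units) sets the visual current scale
against the unit firing threshold and was calibrated for estimation
accuracy of the resulting weights — beyond ~2× more, the bump snaps to
the 45° grid and quantization error grows again. λ defaults to blocked
5-fold cross-validation over per-sample penalties.

## Readout and metrics

Heading is decoded every step as the population vector of the 50
ms-filtered E-PG spike traces (duplicate-corrected); position is
dead-reckoned from decoded heading and the known ground-truth linear
speed. Orientation error is the RMSE of the wrapped difference (an
unwrapped cumulative variant is also available); position error is the
time-mean distance to ground truth as a percentage of total path length.
Experiments run 50 seeds per configuration as one vectorized batch,
aggregate with percentile bootstrap (1000 resamples) and compare
configurations with Mann–Whitney rank-sum tests.

## Synthetic study conditions

*Rotation trial*: agent fixed at the origin among three landmarks 120°
apart at 10 m; sinusoidal angular velocity, ±2 rad/s peak, 20 s period,
60 s duration. *Translation trial*: a ~1 m figure-eight traversed three
times in 60 s (turn rates to ±1 rad/s, the scale a small wheeled platform
actually turns at), two distal landmarks at 30 m and one proximal at
~2 m. Landmark bearings are exact geometric angles clipped to a 270°
field of view centred on the heading; there is no rendering, occlusion,
or visual clutter, so these trials probe the circuit and learning rules,
not a perception stack. A recorded-sensor pathway accepts per-frame
bearing tables with blank entries (frame dropout) in place of the
geometric bearings.

Note one denominator effect: the translation path (≈18 m) is long
relative to the ~2 m arena, so position errors expressed as % of path
length are smaller than the same absolute errors would be on a shorter
path.

## Known limitations

The central one: with the published weight ratios and an 8-position
discrete ring, open-loop angular-velocity integration is stick–slip. The
bump does not move below ≈0.5–0.75 rad/s of drive and, once depinned,
travels at the relaxation-limited wave speed (several rad/s) rather than
proportionally. We explored pathway gains, synaptic time constants
(5–50 ms), encoder nonlinearities consistent with the 250 Hz anchor,
neuron heterogeneity, and noise dithering without finding a proportional
regime; we believe the small neuron count per glomerulus (one shift
neuron per hemisphere per position) makes the velocity signal
shot-noise-limited and the attractor wells deep. Consequences, measured
honestly under the stated conditions:

- the **optimal** (vision-anchored) configuration tracks well:
  orientation RMSE ≈ 0.11–0.17 rad, position error ≈ 3.5% of path
  length;
- the **angular-velocity-only** configuration is near chance on both
  trials (RMSE ≈ 1.4–1.9 rad, where π/√3 ≈ 1.81 is the wrapped-uniform
  ceiling);
- **online learning** therefore trains against a near-chance teaching
  signal: its weights correlate only weakly (≈ 0–0.1) with the offline
  optimum and it performs at the av-only level rather than between the
  two extremes.

The configuration *ordering* optimal ≪ {online, av_only} is robust with
non-overlapping bootstrap intervals; the graded separation between
online and av-only reported for the reference system requires an
integrator quality this reconstruction does not reach. All trial
conditions, noise levels and printed constants were fixed before
evaluation and never adjusted toward reported values.

Smaller simplifications: no conductance synapses, delays, or
multi-compartment neurons; path integration uses ground-truth linear
speed; the decoder and learning share one 50 ms trace; the power model
counts only neuron updates, synaptic spike operations (1.7 pJ × fanout,
structural mask including all 1458 plastic edges), and plastic-synapse
updates every 63 steps — no static power, sensors, or host I/O.
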