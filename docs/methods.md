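# Methods

This note documents the models implemented in `cxring`, the choices made
where the underlying biology or published descriptions leave the design
open, and what the packaged simulations do and do not establish.

## The circuits

Two insect heading-direction circuits are modelled: the fruit-fly
(*Drosophila melanogaster*) and desert-locust (*Schistocerca gregaria*)
central-complex circuits formed by the E-PG, P-EN and P-EG columnar
neurons and the Delta7 (TB1) inhibitory neurons. The protocerebral
bridge (PB) is represented as two hemispheres of `n` glomeruli each
(fly 9, locust 8), numbered 1..n left-to-right in both hemispheres; the
ellipsoid body (EB) as eight tiles. One neuron per class per glomerulus
is modelled; anatomical copy numbers enter only when interpreting
per-neuron firing rates. Functionally both circuits fold onto eight
octants (45° sectors): glomerulus *g* maps to octant *(g−1) mod 8*, so
the fly's ninth glomerulus shares octant 0 with the first.

Projection rules (realised in `cxring.circuit`):

* **E-PG → P-EN, P-EG** within the same glomerulus and hemisphere.
  In the locust, the two medial E-PGs cross-innervate both medial
  glomeruli, which closes the ring at the open end of the
  crescent-shaped EB.
* **P-EN → E-PG** shifted by one whole tile (fly) or one half tile
  (locust). The half-tile shift produces both the onward neighbour
  connection and a reciprocal same-octant connection; the fly has only
  the onward connection. The fly has no P-EN in the innermost
  glomeruli (left G9, right G1), and tile T1 is innervated by both
  E-PG_1 and E-PG_9, giving the fly ring its seam.
* **P-EG → E-PG** reciprocally through the same tile.
* **E-PG → Delta7**: uniform weight across glomeruli in the fly;
  weighted by the Delta7 dendritic profile in the locust.
* **Delta7 → P-EN/P-EG** at the Delta7's output glomeruli (presynaptic
  terminals separated by seven glomeruli); **Delta7 → Delta7**
  all-to-all in the fly, profile-weighted in the locust.

The locust Delta7 dendritic profile over one hemisphere's glomeruli is
the Gaussian

    w(i) = W / (σ √(2π)) · exp(−((i−1)·2π/n − π)² / (2σ²)),  i = 1..n,

circularly rotated per Delta7 identity so its minimum falls on that
neuron's output glomeruli (dendrites avoid the output branches) and its
peak on the opposite side of the ring. σ = 0.8 (glomerulus-coordinate
units) approximates the dendritic-domain width visible in dye fills and
is the locust default; `W` is carried by the optimised class weight.
The **hybrid** model is the fly circuit with its two Delta7-related
rules replaced by these profiles over nine glomeruli — it isolates the
effect of the inhibition pattern from every other species difference.

Open assignments resolved here: the output glomeruli of Delta7 identity
*d* are all glomeruli of octant *d* in both hemispheres (the seam
identity also claims the wrap glomerulus in the fly); E-PG→Delta7
shares the class weight w1, keeping the five-parameter structure below.

The builder is generalised over the octant count; a 4-octant analogue
built by the same rules serves as a fast structural fixture in the test
suite (it satisfies the sign and ring-closure invariants but is not
tuned to be a functional attractor).

## Neuron model

Leaky integrate-and-fire with template action potentials, after the
spiking central-complex models this work extends:

    dV_i/dt = ((V_0 − V_i)/R_m + I_i + Σ_j M_ji I_j) / C_m

with C_m = 2 nF, R_m = 10 MΩ (τ_m = 20 ms), V_0 = −52 mV,
V_thr = −45 mV, V_max = 20 mV, V_min = −72 mV, integrated by Euler's
method at dt = 10⁻⁴ s. When V crosses threshold, a 2 ms AP template
(Gaussian-shaped rise normalised to [V_thr, V_max], sinusoidal fall to
V_min) overwrites the voltage — playback acts as the refractory
period, with threshold detection disabled and synaptic input to the
spiking neuron discarded for those 2 ms. Each spike adds a PSC template
to the neuron's output current: a 2 ms sinusoidal rise to I_PSC = 5 nA
followed by exponential decay with half-life t_PSC = 5 ms, truncated
after seven half-lives (37 ms total). Overlapping PSCs sum linearly.
Synaptic weights are dimensionless multiples of the PSC template per
action potential; inhibition is the same waveform with negative sign
carried by the weight. All internal state is SI; mV/nA appear only at
interfaces. The integration kernel is JIT-compiled (numba) and is
bit-reproducible for a given seed.

Stimulus spikes (Poisson) inject the same PSC template with weight 1.
A constant- or time-varying current-clamp input is also supported and is
used by the electrophysiology oracle tests (rheobase 0.7 nA, membrane
time constant, closed-form inter-spike interval).

## Stimuli

The heading stimulus emulates ring-neuron (TL) visual input: a von
Mises intensity profile over the eight tiles,
f(μ, x) = e^{κ cos(a(x)−μ)} / (2π I₀(κ)) with a(x) = π/4·(x−1) and
κ = 3π/4 (FWHM ≈ 90°), mapped linearly so the minimum equals the 5
imp/s background rate and the maximum the stimulus peak rate, then
sampled as independent Poisson trains onto the E-PG neurons of each
tile (both wedges of a tile share one rate). Azimuth 0° maps to the
centre of tile 1 and increases with tile index.

The peak rate is defined self-referentially (it equals the steady-state
peak of the bump it evokes), so it is calibrated deterministically:
simulate at an initial 200 imp/s, measure the steady-state E-PG bump
peak, re-simulate once at the measured rate, and use the final
measurement. Calibrated rates are stored with the fitted weight sets.

"Darkness" removes all input: the 5 imp/s background is the floor of
the *stimulus* mapping, not a tonic drive, so after stimulus removal
the network evolves deterministically from its state at removal.
Stochasticity across trials — including the stochastic choice between
two neighbouring attractor states when stimulated midway between them —
enters entirely through the Poisson spike history of the stimulus
period. The angular-velocity stimulus is an identical-rate Poisson drive to all
P-EN neurons of one hemisphere; left-hemisphere drive moves the bump
toward increasing tile index by convention.

## Free parameters and fitting

The five synaptic-class strengths are the only free parameters:
w1 (E-PG→P-EN/P-EG/Delta7), w2 (P-EN→E-PG), w3 (P-EG→E-PG) in
[0, 100]; w4 (Delta7→P-EN/P-EG), w5 (Delta7→Delta7) in [−100, 0].
A candidate is scored by a 3 s heading stimulus followed by 3 s of
darkness:

    J(w) = 4(εH1 + εH2) + εW1 + εW2 + N·p0,

where εH = |H_d − H_a|/360° (shortest angular distance; a lost bump
counts 180°), εW = |90° − W_a|/360° measured at the end of the stimulus
(t1) and 3 s into darkness (t2), and p0 = (1/N)Σ e^{−2|w_i|} penalises
weights collapsing to zero. H_d is the stimulus azimuth; the width
target is 90° for every species (the narrower locust bump is an
outcome, not a target). The objective is averaged over three fixed
stimulus realisations per candidate — deterministic per candidate, but
not overfit to a single noise draw.

Search: particle-swarm (20 particles, inertia 0.72, cognitive/social
1.49, positions clipped to the bounds) or simulated annealing
(`scipy.optimize.dual_annealing`). All particles start from the
sign-matched ±0.01 initialisation (with a small |N(0, 0.5)| jitter for
swarm diversity): from there the p0 term provides the gradient that
grows the weights until a bump forms, anchoring the search in the first
functional basin rather than in saturated large-weight regimes whose
firing rates are pinned at the 1/t_AP ceiling.

The search is constrained: penalty terms are added to J for a bump
width outside 90° ± 30° at either measurement time and for
steady-state unit peak rates outside physiological ranges (columnar
classes 64–270 imp/s, Delta7 96–540 imp/s — each modelled unit stands
for at least two columnar neurons, three to four for Delta7, firing
roughly 40–90 imp/s per cell, with a 50 % margin). Without these constraints
the unconstrained minimiser is a saturated half-ring plateau whose
firing is pinned at the 1/t_AP ceiling — formally a low objective, but
neither a ~90° bump nor a physiological operating point.

An accepted solution must additionally pass a functional screen at
stimulus seeds never used by the objective: a single bump within
90° ± 30° at t1, a heading held within 45° through 3 s of darkness,
peak rates inside the same physiological ranges, and a bump that
survives 10 s of darkness. Each circuit variant (fly, locust, hybrid,
and the two P-EG-ablated circuits) is fitted separately; optimisation
is repeated from new swarm seeds until the screen passes, and repeated
runs can be summarised with k-means clustering of the solutions. The
accepted weight sets, with their provenance (method, seed, budget,
objective value, calibrated peak rates), are committed under
`src/cxring/refweights/` and loaded by
`RingAttractorModel.reference_results`.

## Decoding and metrics

Spike trains are binned at dt and filtered along time with a Gaussian
kernel (window 120 ms, σ = 24 ms, unit mass, edge-renormalised) to give
rates in impulses/s. Every neuron carries the azimuth of its EB
synaptic domain: E-PG neurons occupy single wedges (the two hemisphere
members of a fly unit flank their tile centre by ±11.25°; a locust unit
straddles two neighbouring tiles), P-EN domains are whole tiles, and
Delta7 azimuths are their output octant centres. Rates are averaged
per domain-azimuth bin — wedge resolution (22.5°) for E-PG — and the
bump heading is the population vector (circular mean of bin azimuths
weighted by rate), with a winner-take-all decoder as cross-check. An
exactly flat or empty profile has no defined heading and is reported as
such, never as 0°. Width is the full width at half maximum (half level
= min + (max−min)/2) of the circularly linearly-interpolated profile on
that grid; wedge resolution is what lets a bump measure, say, 70°
rather than a multiple of 45°. Octant-level profiles are retained for
the jump/gradual path criterion.

Criteria: a transition counts as *settled* at the first sample from
which the decoded heading stays within 22.5° (half an octant) of the
state it finally reaches — attractor states need not coincide with the
commanded azimuth, so settling is judged against the realised state
(and a trial ending more than 45° from the command counts as
unsettled) — for ≥ 500 ms. A transition is a
*jump* unless every octant on the shortest path reaches ≥ 90 % of the
transition-period peak rate (adjacent moves are gradual by convention;
at 180° the better-travelled path is used). A trial is *stable* when
the heading reaches the target within ±45° and holds it continuously
for ≥ 3 s; a bump whose E-PG peak falls below 50 imp/s (amplitude
below 25 imp/s) is treated as lost, these floors being well above what
the 5 imp/s background produces and well below any maintained bump.

## Experiment protocols

Each protocol is a pure function of (configuration, seed); trial *i*
draws its sub-seed from a counter scheme, so extending a run never
changes earlier trials. Default segment durations are 3 s stimulus,
2 s darkness, 3 s second stimulus (configurable); bump-maintenance
measures 10 s after stimulus removal, attractor-state settling 3 s
after removal. Summaries report medians with standard deviations. In
the σ-sweep the circuit is rebuilt per σ (the fly uses the
Gaussian-profile construction, which approaches its uniform inhibition
at large σ) and the two profile blocks are rescaled to conserve the
total inhibitory input of the base circuit; full re-optimisation per σ
is available but not the default. Bump angular velocity under
uni-hemispheric drive is the slope of the unwrapped decoded heading
over the final half of the drive period, and velocity-vs-strength
curves are fitted with y = a·e^{bx} by nonlinear least squares seeded
from the log-linear fit.

## Problem sizes

Full protocols (40 maintenance trials, 40 trials per azimuth, 100-trial
noise curves) run in minutes on one core thanks to the compiled
integration kernel; `scripts/acceptance.py` uses the full 40-trial
maintenance and tuning protocols. The test suite uses scaled-down
trial counts chosen to keep the whole suite fast while leaving the
assertions' tolerances unchanged: 20 maintenance trials, 10 tuning
trials per azimuth, 8 transition trials per condition, 25–30 trials per
noise level, a 2×2 σ-grid plus the σ = 0.8 locust row, and 2 rotation
trials per strength.

## Known limitations

* One neuron per class per glomerulus; rates for real neurons follow
  only after dividing by copy numbers.
* Synaptic interaction is template superposition — no conductance
  synapses, reversal potentials, delays or plasticity; input during the
  2 ms AP playback is discarded.
* The heading stimulus abstracts the entire visual pathway as Poisson
  rates on E-PG neurons; ring-neuron dynamics are not modelled, so
  conclusions about cue-conflict or visual gain are out of reach.
* The 8-point octant profile bounds the width resolution; FWHM values
  carry an interpolation error of a few degrees, largest for bumps
  centred between octants.
* Synaptic strengths are this package's own optimiser outputs; no
  published weight values exist to copy. The fits reproduce the core
  comparative dynamics — both species hold a heading through 10 s of
  darkness, the fly snaps to a new heading while the locust flows
  gradually and far more slowly, and the locust/hybrid circuits
  tolerate much more synaptic and membrane noise than the fly — but
  not every quantitative pattern. In particular, in this
  reconstruction the locust bump is *wider* than the fly's, not
  narrower: with no direct inhibition onto E-PG and one neuron per
  class per glomerulus, no stable locust state narrower than ~95° was
  found anywhere in the admissible weight space, which points at
  per-glomerulus Delta7 output-weight structure that the available
  anatomical descriptions do not pin down.
* The accepted locust fit sits in a strong-inhibition cluster (large
  |w4|) whose bump cannot be displaced by uni-hemispheric P-EN drive,
  so the rotation protocol moves only the fly; and the only hybrid fit
  passing the screen has w5 = 0 and jumps rather than transitioning
  gradually. Both behaviours are visible in the experiment outputs and
  are flagged by the corresponding tests.
* The fly-without-P-EG circuit never passed the screen: at every
  optimiser solution its darkness bump rotates spontaneously. Its
  committed weight set is marked ``accepted: false`` and exists so the
  asymmetry-tolerance comparison can quantify exactly this
  instability.
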