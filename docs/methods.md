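# Methods

`taskbrain` simulates a visual delayed match-to-sample (DMS) experiment in a
hybrid network: a task circuit of ten 81-unit neuronal-population modules
embedded into a whole-cortex connectome of Wilson-Cowan neural masses, with a
Balloon-Windkessel forward model producing BOLD fMRI and a functional-
connectivity analysis on top. This note records the model, its assumptions,
the calibrated operating point, and what the synthetic substrate does and
does not capture.

## Dynamical layers

**Connectome nodes.** Every node of the structural connectome is a
Wilson-Cowan excitatory/inhibitory pair

    tau_E dE_i/dt = -E_i + (k_E - r_E E_i) S_E[alpha_E (c_EE E_i - c_IE I_i - theta_E + Gamma_i)]
    tau_I dI_i/dt = -I_i + (k_I - r_I I_i) S_I[alpha_I (c_EI E_i - c_II I_i - theta_I + Gamma_i)]

with sigmoid S_a(f) = c / (1 + exp(-a (f - b))) and long-range coupling
Gamma_i = G * sum_k u_ik E_k(t - d_ik), where u is the structural weight
matrix and d_ik = tract_length / conduction_speed (3 mm/ms default),
discretized to the nearest integration step with a floor of one step.
Defaults are the classical constants (tau = 10 ms, c_EE = 12, c_EI = 4,
c_IE = 13, c_II = 11, sigmoid (1.2, 2.8, 1) / (1.0, 4.0, 1)); at these values
an uncoupled node has a single stable fixed point near E ~ 0.05 and the
noise-driven network fluctuates around it without global oscillation.
Integration is stochastic explicit Euler at dt = 5 ms with additive zero-mean
Gaussian noise (sd 0.01 per step) on both populations. The same local
dynamics with zero local-neighbourhood coupling is used everywhere; no
surface-based neighbourhood term is modelled.

**Task units.** Task modules are 9x9 grids of modified Wilson-Cowan
microcircuits in rate-of-change/decay form,

    dE = Delta L(K_E [w_EE E + w_IE I + in_E - phi_E + N]) - delta E
    dI = Delta L(K_I [w_EI E + in_I - phi_I + N]) - delta I

with L the unit logistic, no inhibitory self-connection, activities clamped
to [0, 1], and rates Delta, delta expressed per 5-ms reference step (running
at another dt rescales them). N(t) is zero-mean Gaussian, drawn
independently per element and step; its amplitude is the main noise knob
(below). Task-internal connections are undelayed; connectome-sourced inputs
are read from the same delay buffer as node-node coupling, at the host
node's lags.

## Embedding

Each module has a hypothesized Talairach coordinate (V1/V2, V4, IT and D1
from the visual-experiment literature; the remaining prefrontal populations
and secondary orientation channels at illustrative nearby locations). The
embedding (i) finds the connectome node nearest the coordinate (the *host*),
(ii) connects every in-neighbour of the host to all 81 units, drawing each
coupling c_ji from N(G/81, (0.1 G/81)^2) clipped at zero — the global
coupling constant divided by the number of units, so the module aggregate
matches what the host node would have received — and (iii) adds reciprocal
feedback edges to exactly those neighbours with per-unit weight G z / 81
(z the structural weight), so the 81-unit aggregate carries G z. The host
stays an ordinary active node; no original edge is modified. Ten modules
must resolve to ten distinct hosts; when targets are only a few mm apart on
a coarse synthetic connectome the pipeline assigns the next-nearest unused
node (`on_collision="next-nearest"`), while the library default raises.

Imaging ROIs are one module plus its host and the k = 5 nearest other
connectome nodes (other modules' hosts are excluded so task activity never
leaks into a neighbour's ROI). Orientation channels are merged per cortical
area for reporting (V1 = V1h+V1v, V4 = V4h+V4c+V4v). The contralateral-IT
control region is the node nearest the x-mirrored IT coordinate plus its
five neighbours; it carries no task units.

## The task circuit

Stimuli are 9x9 oriented-stroke shapes split into horizontal/vertical
channels driving V1h/V1v. V4 applies receptive-field convergence (1x3 along
rows for V4h, 3x1 along columns for V4v, two-channel 3x3 patches for V4c).
IT reads a fixed pseudo-random fan-in of 6 V4 units per IT unit (seeded
structural anatomy, identical across subjects); with a steep gain
(K_E = 24) an IT unit fires only when at least two of its inputs are
active, producing a sparse, near-binary distributed object code (typically
5-16 of 81 units per shape).

The prefrontal working-memory loop is the part of the design space that was
genuinely open, and several mechanisms were tried before the shipped one:

* **D2** (stimulus-and-delay population) is a *monostable attention-gated
  relay*: one-to-one input from IT, one-to-one input from D1, a uniform
  attention drive to all units, weak self-excitation (w_EE = 0.2) and a
  high threshold (phi_E = 0.68). It follows IT + attention during stimuli
  and D1 + attention during the delay, and collapses within a few hundred
  ms when attention drops; its slow rates (Delta = delta = 0.15) bridge the
  stimulus-offset gap until D1 takes over.
* **D1** (delay population) carries the memory: strong one-to-one drive
  from D2 (0.7), self-excitation (w_EE = 0.45) giving per-unit hysteresis,
  and an inhibitory element driven purely by pool activity (w_EI = 0).
* **Pool inhibition** D1 -> D1 and D1 -> D2 (uniform weights onto the
  inhibitory elements, saturating through a low-threshold logistic) makes
  the formed trace suppress recruitment of *new* delay units. During S1 no
  trace exists and ignition proceeds; during S2 the S1 trace blocks
  overwriting, so the delay loop holds S1's IT pattern through the second
  stimulus. A stimulus-gated FS -> D1 suppression was tried first and
  abandoned: its release at stimulus offset races the decay of the D2
  trace, and for every workable gate strength either the delay handoff or
  the overwrite protection failed.
* **FR** (response population) is a pure coincidence detector (no
  self-excitation, K_E = 24, phi_E = 0.55) reading 0.38 D1 + 0.36 IT
  one-to-one: only units where the remembered trace and the current
  stimulus coincide cross the 0.7 response threshold, so matches respond
  and mismatches mostly do not (shape pairs with overlapping IT codes
  produce realistic false alarms).
* **Attention** (task control) reaches only D2, scaled by gain 1.3; DMS
  blocks use 0.24-0.34, passive viewing and inter-trial intervals 0.05.
  Because D2 needs roughly IT + attention (or D1 + attention) to exceed
  threshold, the low-attention condition never ignites the loop: passive
  viewing shows stimulus-locked V1/V4/IT/FS activity but no delay activity
  and no responses.

A trial is S1 (1 s), delay (1.5 s), S2 (1 s), inter-trial interval (2 s);
blocks are three trials (16.5 s); the default experiment alternates six DMS
and six control blocks (198 s, 36 trials). DMS attention is spaced evenly
across DMS blocks; match/mismatch/match within each block; control blocks
use degraded shapes (each active cell kept with probability 0.5).

## Subjects, noise, and the operating point

Simulated subjects multiply every feed-forward template by an independent
uniform draw in [0.95, 1] (feedback and lateral templates untouched) and use
an independent noise stream. The unit-noise amplitude defaults to
sd = 0.13: at this level task accuracy is noise-limited (roughly 65-90%
across subjects, errors split between missed matches at low attention and
false alarms on confusable shape pairs), which is the regime the
subject-generation procedure presupposes — at sd <= 0.08 every subject
scores 100% and the inclusion loop (retain subjects above 60% accuracy)
never rejects anyone. The amplitude was chosen so the retained-subject
accuracy distribution matches published within-subject DMS performance
(mean ~74%, range ~61-83%). Performance is the fraction of correct responses
over the 18 DMS trials; a response requires at least 2 FR units strictly
above 0.7 during the S2 window.

## Observables

Integrated synaptic activity (ISA) sums, over all ROI members and 50-ms
windows, each member's absolute input magnitude IN_i: for task units
|w_EE E| + |w_EI E| + |w_IE I| plus the absolute long-range and external
drives into either element; for connectome nodes the analogous within-unit
terms (|c_EE E| + |c_EI E| + |c_IE I| + |c_II I|) plus delayed coupling and
task feedback. External stimulus/attention drives count as synaptic input.

Each ROI's ISA is normalized to zero mean and unit range and drives the
Balloon-Windkessel system (vasodilatory signal, inflow, venous volume,
deoxyhemoglobin) from rest (0, 1, 1, 1); the read-out is
y = V0 (k1(1-q) + k2(1-q/v) + k3(1-v)) with k1 = 4.3 theta0 E0 TE,
k2 = eps r0 E0 TE, k3 = 1 - eps. Constants are the standard 1.5 T set with
the slower published time constants (tau_s = 2.0 s, tau_f = 3.5 s,
tau0 = 2.0 s, alpha = 0.32, E0 = 0.32, V0 = 0.04, TE = 40 ms,
theta0 = 40.3 s^-1, r0 = 25 s^-1, eps = 1.43), giving an impulse-response
peak ~4.1 s after the impulse, inside the physiological 4-6 s. The ODEs are
integrated with explicit Euler at the 50-ms bin width by default; sub-
stepping is configurable and used where integration accuracy itself is
under test. BOLD is decimated to TR = 2 s (every 40th bin, end-of-frame,
no anti-alias filter, matching plain downsampling).

Block signal change is the mean of the 4th-6th TR after each block onset,
expressed as percent about the series mean (y is already a fractional
signal change, so percent = 100 (y - mean y)). Functional connectivity is
the Pearson correlation over the timepoints of one condition (no
hemodynamic lag shift by default; a lag in samples is configurable);
group averages pass through Fisher's Z; condition differences use paired
two-sided t-tests, uncorrected.

## Numerical choices

* Common 5-ms Euler cadence for both subsystems; both exchange activities
  every step. The delay buffer holds past node activities; zero tract
  length still implies a one-step lag (explicit-Euler causality), and an
  infinite conduction speed reproduces the delay-free variant exactly.
* The noise stream consumes draws in a fixed order (node E, node I, unit E,
  unit I), so one seed determines the full trajectory bit-for-bit.
* Unit activities are clamped to [0, 1]; node activities are not clamped
  (noise can push them slightly negative, and IN_i uses absolute values).
* Nearest-node ties break to the lowest index; ROI neighbour lists use a
  stable sort.
* ISA normalization guards the constant series (zero range -> zero drive),
  which also makes the resting fixed point exact.

## The synthetic connectome

Tests and the acceptance study run on a seeded synthetic connectome: nodes
sampled on a two-hemisphere ellipsoidal shell in Talairach-like mm
coordinates (optionally pinning nodes at the module target coordinates so
stereotaxic lookups resolve cleanly at small n), symmetric nonnegative
weights whose probability and magnitude decay exponentially with distance
(lognormal magnitude spread), and tract lengths equal to chord distances.
It reproduces the statistical shape a DSI-derived substrate presents to the
simulator — sparsity, distance dependence, hemispheric separation,
nonnegative symmetric weights — but none of its real anatomy: no
community/lobe structure beyond distance, no curved fibre lengths, no
subject-specific variation. Passing tests therefore certify the machinery
and the qualitative task/rest contrasts, not quantitative agreement with
any empirical connectome; published group tables that depend on the real
998-node substrate are treated as direction/bound anchors only.

Default problem sizes: the shipped configuration uses a 998-node substrate;
the test and acceptance studies run the same 198-s, 36-trial experiment on
a ~100-node substrate with 5 retained subjects, sizes chosen so the whole
study remains a desk-scale computation.

## Known limitations

* The inter-module weight templates are this package's own calibration;
  the original circuit's exact tables are not published in the source
  text, so quantitative unit activities (and anything downstream of their
  magnitudes) are comparable only in repertoire, not value.
* D1 shows some activity during S1 ignition transients; its
  delay-selectivity is sharpest after the first ~300 ms of the delay.
* BOLD condition differences at 198 s contain only six blocks per
  condition; with 5-10 subjects the paired tests are powered for the large
  task effects the circuit produces, not for subtle ones.
* No EEG/MEG forward model, no spiking, no plasticity, no per-subject
  connectomes.

## Noise-performance relationship

Accuracy declines with the unit-noise amplitude through the noise-limited
regime (100% at sd <= 0.08 on the ideal subject down to ~65-85% at the
default 0.13) and then *saturates* rather than falling to chance: at high
noise the response module fires on essentially every trial, pinning
accuracy at the response-bias floor (all matches correct, all mismatches
false-alarmed — 2/3 with the default match/mismatch mix). Monotonicity
tests therefore probe the declining regime; the floor is a structural
property of the scoring rule, not of the noise.
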