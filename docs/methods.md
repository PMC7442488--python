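# Methods

## Model

`pecircuit` simulates a rate-based microcircuit of mouse V1 layer 2/3 in
which negative prediction-error (nPE) neurons — pyramidal cells that fire
above baseline only when a predicted visual stimulus is absent — emerge from
inhibitory synaptic plasticity that balances excitation and inhibition
across parvalbumin- (PV), somatostatin- (SOM) and VIP-expressing interneuron
pathways.

Pyramidal cells (PCs) are two-compartment units. The somatic rate obeys

    tau_E dr_E/dt = -r_E + [ I - Theta ]_+ ,
    I = lambda_D [ I_D^syn + c ]_+ + (1 - lambda_E) I_E^syn ,

with rheobase Theta = 14 s^-1 and time constant tau_E = 60 ms. The somatic
synaptic input `I_E^syn = x_E - w_EP r_P` combines external drive with PV
inhibition; the dendritic input `I_D^syn = x_D - w_DS r_S + w_DE r_E`
combines the motor prediction, SOM inhibition and PC recurrence. The
dendritic bracket is rectified so an excess of dendritic inhibition cannot
hyperpolarize the soma (a configuration switch disables this for the
no-nonlinearity variant). A calcium event adds c = 7 s^-1 of current when
the total dendritic input `I_D^0 = lambda_E I_E^syn + (1 - lambda_D)
I_D^syn` strictly exceeds Theta_c = 28 s^-1 (Heaviside with H(0) = 0;
configurable). Leak fractions are lambda_D = 0.27, lambda_E = 0.31.
Interneurons are rectified linear units with tau_I = 2 ms. All quantities
are kept in rate units; the gain g = 0.07 (pA s)^-1 converts to pA only in
the current-decomposition readout.

Integration uses Heun's method (2nd-order Runge-Kutta) with rates clamped
nonnegative after every stage and derivative zeroing at the r = 0 boundary.
dt = 0.1 ms is the default for test simulations and dt = 1 ms for long
plasticity runs; both sit inside the scheme's supported 0.05-2 ms window,
and halving dt changes steady states by < 1e-6 relative. A numba-jitted
kernel implements the identical arithmetic as the numpy reference path; a
regression test asserts agreement to float rounding.

## Connectivity

Populations default to 70 PCs and 10 each of PV, SOM, VIP. Every neuron of
a type receives exactly `k = round(N_pre * p)` synapses per pathway
(round-half-away-from-zero; self-connections excluded within a population),
with partners drawn uniformly without replacement and each weight set to
`mean / k`, so the summed afferent weight equals the configured mean and
results are independent of population size (verified to < 2% on doubling).
Inhibitory weights are stored as nonnegative magnitudes that enter the rate
equations with minus signs; Dale's principle is re-enforced by clipping
after every plasticity update. Non-plastic networks use the fixed means
(w_EP = 2.8, w_DS = 3.5, w_PE = 1.5, w_DE = 0.42, w_SE = 1, w_SV = 0.61,
w_VS = 0.5, w_PP = 0.1 or 1.5 depending on whether PCs receive visual
input) with (w_PS, w_PV) from the balance constraints below. The printed
weight matrix leaves one entry ambiguous; w_VE = 1 is adopted by symmetry
with w_SE and exposed as a parameter. Plastic networks draw every initial
connection from `U(0.5 w, 1.5 w)/k` around initial means chosen so the
constraint solution is Dale-compliant (w_EP = 1.75, w_DS = 0.35, w_PS =
0.3, w_PV = 0.6, and w_PE/w_PP by input configuration).

## Analytic balance constraints

For a linearized homogeneous network whose dendrites are sufficiently
inhibited in feedback and playback, PCs are nPE neurons iff

    w_PS = V_P + w_VS M_P - (1 + w_PP)/w_EP * V_E
    w_PV = M_P + w_SV V_P - w_SV (1 + w_PP)/w_EP * V_E
         = w_SV w_PS + (1 - w_SV w_VS) M_P ,

where V_X, M_X in {0,1} flag visual/motor input to population X. The solver
evaluates both forms (they agree to 1e-12 by construction) and raises when
a configuration would need negative inhibitory magnitudes. Background
drives realizing a target operating point — (1, 2, 2, 4) s^-1 for (PC, PV,
SOM, VIP) in non-plastic networks — are obtained by inverting the linear
fixed point at v = m = 0 with x_D = 0, verifying post hoc that the dendrite
is rectified-silent and below the calcium threshold. A general linear
steady-state solver assigns each unit a rectification branch, solves the
resulting linear system and checks self-consistency; branch search proceeds
by fixed-point iteration on the assignment. It serves as the independent
oracle for the nonlinear simulation (agreement to 1e-6 relative on random
stable networks).

## Stimulus protocols

A scalar visual drive v and motor prediction m are organized into 1-s
phases interleaved with 1-s baselines: feedback (v = m = s), mismatch
(m > v), playback (v > m). Training paradigms: quasi-natural (QT,
alternating feedback and playback), random gain (RT, v and m independent
U[0, s_max]) and coupled (CT, feedback only), with s ~ U[0, 7] s^-1. Test
stimuli are 7 s^-1 (plastic) or 3.5 s^-1 (non-plastic). Training playback
carries no motor drive (m = 0); the strength of a partial mismatch is
configurable for response sweeps. Routing: PC somata and PV neurons receive
v per their flags, dendrites receive m, a fraction f of SOM neurons
receives v (the rest m) and by default a fraction 1 - f of VIP neurons
receives v; the VIP fraction can also be set independently (the 90%/50%
experiment requires it). Simulated optogenetics adds -8 s^-1 (inactivation)
or +5 s^-1 (activation) to the target population's external drive, before
rate rectification, so partial inactivation is possible.

## Plasticity

All rules have the form dw ∝ ±(post − baseline)·pre, act only on existing
connections, and are clipped at zero. PV→PC soma: Δw ∝ (r_E − ρ_E0)·r_P.
SOM→dendrite: Δw ∝ (A − ε)·r_S with A = [I_D^syn + c]_+ and ε = 0.1 s^-1
easing onset transients. SOM/VIP→PV follow one of three variants: the
backprop-like rule (driven by the mean baseline deviation of each PV's
postsynaptic PCs), the local recurrent-drive approximation (error proxy
Σ_k w_PE,ik (ρ_E0,k − r_E,k)), or, when PCs receive no visual input, a
homeostatic PV-rate rule paired with an anti-Hebbian PC→PV rule.

Two choices the source material leaves open were resolved as follows.

*Baseline targets.* ρ_E0 (and ρ_P0) start from the measured pre-training
baseline (5-s settling run) and, by default, are re-measured in every
interleaved baseline phase. A frozen target over-determines the system:
as (w_PS, w_PV) approach the constraint solution the PV baseline rate
rises, the PV→PC rule then drags w_EP below the feasibility boundary
w_EP ≥ 1 + w_PP, and the network degenerates — numerically the interior
fixed point with frozen targets is infeasible at the stated parameters.
With running targets the learned weights converge onto the analytic
constraint solution. The frozen variant remains available
(`baseline_mode="fixed"`).

*Learning rates.* Not stated in the source material; defaults are
1e-6 per ms for all four rates, sized so the weight change per 1-s
stimulus (~1e-2) is far below the weight scale. The local-recurrent variant uses
a two-timescale setting (eta_EP = 4e-6, eta_DS = 2e-6, eta_PX = 2e-7 over
~9000 stimuli): its error proxy averages each PV neuron's presynaptic
rather than postsynaptic PC sample, and this feedback misalignment injects
per-PV bias noise that only stays bounded when the per-PC homeostatic
rules are much faster than the SOM/VIP->PV alignment (with equal rates a
few PCs retain 10-20% feedback responses indefinitely). Updates are
accumulated every integration step and applied every 1 ms. Training stops
when, over the last 200 stimuli, the running mean of the PC-population
|ΔR/R| during stimulus phases drops below 1% and the worst single PC's
windowed mean |ΔR/R| is also below 1% (the method's target is every PC at
baseline, and a population average can mask a few stragglers), or at the
stimulus cap; a divergence guard aborts if any population mean rate
exceeds 500 s^-1. The default network converges in 1200-1800 stimuli.

## Classification and analysis

ΔR/R = (r − r_BL)/r_BL, with r averaged over the last 500 ms of each 1-s
phase (excluding onset/offset transients; window configurable) and r_BL
from the baseline phases. nPE: ΔR/R > 20% in mismatch and within ±10% in
feedback and playback; pPE mirrored on playback; plus baseline,
suppressed-mismatch and other. Under optogenetic manipulation, ΔR/R is
referenced to the unmanipulated baseline rates so that silenced neurons
remain classifiable; the fingerprint reports increase/decrease/none per
(population × mode × phase) with a 10% dead-band matching the
classification band. Current decompositions divide rate-unit currents by g.

## What the synthetic protocols do and do not emulate

The stimulus generator reproduces the structure of closed-loop
visuomotor-coupling experiments — piecewise-constant coupled, uncoupled and
absent visual flow — not their statistics: real visual flow is
time-varying, noisy and feature-selective, and real interneurons receive
mixed rather than binary visual/motor input. Passing tests therefore show
that the plasticity mechanism produces and explains nPE responses under
idealized sensorimotor statistics, not that it quantitatively reproduces
V1 firing.

## Problem sizes used in the shipped checks

The test suite and acceptance script use the default 70/10/10/10 network
for the training-based checks (1200-1800 stimuli to convergence; caps of
3000-9000) and a 35/8/8/8 network for auxiliary qualitative checks; the
oracle-equivalence battery uses twenty 8/4/4/4 networks.

## Known limitations

- The local-recurrent rule variant requires the two-timescale learning-rate
  setting described above and ~10x more training stimuli than the backprop
  variant; with equal rates it plateaus short of all-nPE (see the
  rule-equivalence test for the dense-connectivity limit where the two
  rules coincide).
- With all SOM neurons assigned to motor input (f = 0), SOM rates rectify
  to zero during playback; the remaining dendritic excess is constant and
  is absorbed during training, so playback-selective (pPE) cells do not
  emerge under quasi-natural training in this implementation — the f-sweep
  instead transitions from all-nPE through baseline/suppressed categories
  into weak mismatch responders.
- Positive prediction-error circuits are supported only through symmetric
  protocol presets; no simultaneous nPE+pPE learning, no spiking dynamics,
  no feature selectivity, no NDNF neurons.
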