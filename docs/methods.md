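# Methods

## Model

Each brain region is a cortical column built from two Jansen-Rit
subpopulations, one tuned to the EEG alpha band and one to the gamma
band. A subpopulation consists of pyramidal cells plus excitatory and
inhibitory interneuron pools. Firing rates are obtained from mean
postsynaptic potentials (PSPs) through the sigmoid

    S(v) = zeta_max / (1 + exp(r (v_th - v))),

with zeta_max = 5 Hz, r = 0.56 /mV, v_th = 6 mV, and rates are turned
back into PSPs by alpha-function kernels h(t) = A a t e^{-a t} (gain A,
inverse time constant a; analogously B, b for inhibition). Per
subpopulation s of region i the state is three PSP blocks
(x0: excitatory feedback, x1: pyramidal input, x2: inhibitory feedback)
with velocities y0..y2:

    x0' = y0   y0' = A_s a_s S(x1 - x2)                         - 2 a_s y0 - a_s^2 x0
    x1' = y1   y1' = A_s a_s (p(t) + C2 S(C1 x0) + net_i(t))    - 2 a_s y1 - a_s^2 x1
    x2' = y2   y2' = B_s b_s C4_s S(C3 x0)                      - 2 b_s y2 - b_s^2 x2

Local gains are C1 = C, C2 = 0.8 C, C3 = 0.25 C with C = 135; C4 is the
inhibitory-to-pyramidal feedback gain, initialised at 0.25 C and made
dynamic by the plasticity rule below. (Some parameter tables label C3
"inhibitory-to-pyramidal" and C4 "pyramidal-to-inhibitory"; the ODEs
place C4 unambiguously as the gain of the inhibitory PSP onto pyramidal
cells, and this package follows the ODEs.) The alpha subpopulation uses
A = 3.9 mV, B = 26.4 mV, a = 120 /s, b = 60 /s; the gamma subpopulation
uses a = 660 /s, b = 330 /s with gains tied to the kinetics,
A_gamma = 32.5 a_gamma / 1000 and B_gamma = 440 b_gamma / 1000 (these
formulas recover the alpha gains when evaluated at the alpha kinetics).

The region's EEG-like output is the r_alpha-weighted combination of the
two pyramidal PSPs, v_i = r_alpha (x1_a - x2_a) + (1 - r_alpha)(x1_g - x2_g),
and the combined pyramidal rate is the same mixture of S-values. The
un-superscripted sigmoid arguments in the subpopulation equations are
read per subpopulation (each column is a closed circuit with its own
interneurons); the alternative reading — all sigmoids driven by the
combined potentials — was implemented and rejected empirically: it
breaks both the firing-rate clamping and the r_alpha frequency map.

Regions are coupled through pyramidal outputs only:
net_i = K C sum_{j != i} M_ij S(v_j), with M the structural
connectivity (symmetric, zero diagonal, weights in [0, 1]) and K the
global coupling. A per-subpopulation coupling source is not offered;
the combined PSP is the region's single long-range output.

## Homeostatic inhibitory plasticity (ISP)

C4 of each subpopulation follows

    tau dC4/dt = zbar_inh (zbar_pyr - rho) ((C4 - C4_min)/C)^beta,

a soft-bound rule (beta = 1, C4_min = 0) with target pyramidal rate rho
(default 2.5 Hz) and inverse learning rate tau (default 2 s). zbar_pyr
and zbar_inh are slow first-order estimates of the subpopulation's
pyramidal rate S(x1 - x2) and interneuron rate S(C3 x0), with sensor
time constant t_avg = 0.5 s. The slow sensor is a deliberate design
choice: with instantaneous rates the equilibrium condition on a limit
cycle is the inhibition-weighted average <z_inh (z_pyr - rho)> = 0, and
because z_inh tracks z_pyr with only a ~8 ms synaptic lag, the plain
time-averaged rate settles ~30% below rho (we verified this bias is
dt-independent, and that the deterministic fixed point is unstable
precisely where its rate falls in (0.2, 3.6) Hz, so exact fixed-point
clamping is impossible for the usual rho range). With t_avg much longer
than the oscillation period, the equilibrium factorises and the
time-averaged rate itself is clamped: the measured error is below 2.5%
for rho in [2, 3] and insensitive to t_avg anywhere in 0.1-2 s. Each
subpopulation carries its own C4 and sensor pair; rho, tau, beta are
shared.

## Stochastic drive and integration

Each region receives background input p(t) with mean 220 Hz and SD
31 Hz. The default noise mode ("sampled") draws an i.i.d.
p ~ N(220, 31) per 1 ms step, shared by the two subpopulations of a
region. An alternative "diffusion" mode injects
A_s a_s sigma_p sqrt(dt) N(0,1) into each y1 update (per region and per
subpopulation); its statistics are dt-invariant, but its effective
per-step input fluctuation sigma_p / sqrt(dt) is ~30x larger at 1 ms
and buries the alpha rhythm under low-frequency power, which
contradicts the model's own single-node phenomenology — hence the
sampled default.

Integration is Euler-Maruyama at dt = 1 ms (the model is specified at
this step; note the gamma kernel 1/a = 1.5 ms is marginally resolved,
see Limitations). Default protocol: 180 s simulated, first 60 s
discarded, outputs decimated to 200 Hz. The EEG-like PSP and the
bifurcation variable x0 are decimated with a zero-phase polyphase FIR
anti-aliasing filter (line-padded, avoiding end-of-array edge
artifacts); firing rates and C4 are decimated by bin averaging, which
preserves the [0, zeta_max] rate bounds. Initial conditions are the
origin with C4 = 0.25 C and the rate sensors at S(0); the discard
window absorbs the transient. Non-finite states (blow-up) abort with a
diagnostic rather than returning garbage.

A compiled (numba) kernel advances the full network; a pure-NumPy
reference step (`node_derivatives` / `em_step`) defines the semantics,
and the test suite asserts the kernel reproduces repeated reference
steps on noise-free trajectories, plus an exact regression against an
independently coded classical Jansen-Rit integrator at r_alpha = 1.

## Hemodynamics

Combined pyramidal rates drive a generalized Balloon-Windkessel model
per region: vasodilatory signal s, inflow f, venous volume v,
deoxyhemoglobin q, with tau_s = 0.65 s, tau_f = 0.41 s,
tau_v = tau_q = 0.98 s, stiffness kappa = 0.32, resting extraction
E0 = 0.4, and BOLD readout V0 (k1 (1-q) + k2 (1-q/v) + k3 (1-v)) with
V0 = 0.04, k1 = 2.77, k2 = 0.2, k3 = 0.5. The rate series is
bin-averaged onto the 10 ms Euler grid (rates enter in Hz, gain 1;
an optional gain parameter exists because the formulation assumes O(1)
inputs and no scaling is prescribed), integrated explicitly, and
strided to the scanner TR (default 2.08 s; the BOLD band is far below
the 10 ms grid's Nyquist). (0, 1, 1, 1) is the exact resting fixed
point, so zero input gives identically zero BOLD.

## Observables

EEG functional connectivity is amplitude-envelope correlation: 3rd-order
Bessel band-pass in the canonical bands (delta 0.5-4, theta 4-8,
alpha 8-13, beta 13-30 Hz), Hilbert envelope, 3rd-order Butterworth
high-pass at 0.5 Hz, Pearson correlation over region pairs. BOLD FC
band-passes 0.01-0.08 Hz (Bessel) before correlating. All filters are
applied forward-backward (zero phase) because the FC estimators are
phase-sensitive; 1 s is trimmed from each end of the envelopes to
suppress Hilbert edge artifacts. Spectra use Welch's method (2 s Hann
windows, 50% overlap, 0.5 Hz resolution); relative band power divides
per-band trapezoid integrals by the 0.5-30 Hz total; the dominant
frequency is the global spectral maximum in 0.5-60 Hz, ties broken to
the lower bin.

## Fitting

FC matrices are compared with the windowed SSIM (Gaussian weights,
sigma 1.5, data range pinned to the joint span of both matrices — the
range must be explicit for correlation-valued input; diagonals are kept
at 1 in both matrices so local windows stay dense). Spectral vectors
(relative theta/alpha/beta power) are compared with the Clarkson
distance, lambda = ||x/|x| - y/|y||/2, reported as goodness 1 - lambda.
Grid fitting sweeps two parameters exhaustively; per cell, BOLD FCs are
averaged across seeds before SSIM while EEG metrics are averaged after
(per-seed), and blown-up cells become NaN. The dual EEG+fMRI procedure
masks cells with spectral goodness >= 0.85 and maximises BOLD-FC SSIM
inside the mask, ties broken toward the lowest value of the first axis.
Effect sizes between simulation conditions are reported as Cohen's D
with the conventional qualitative bins (very small < 0.2 ... very
large < 2 <= huge).

## Synthetic data

The synthetic connectome generator draws one hemisphere of n/2 regions
with contiguous modules (within-module edge probability 0.8, between
0.2, uniform weights), mirrors it so region i and region n-1-i are
homologs (putting homotopic edges on the anti-diagonal, matching the
convention under which inter-hemispheric augmentation operates), and
adds sparse weak cross-hemisphere links. It emulates the modular,
bilaterally symmetric structure of DTI connectomes but not their weight
distributions, distance dependence, or subject-level variability — so
passing network tests demonstrates internal consistency of the
dynamics and fitting machinery, not fidelity to any empirical
connectome. Dual-fit targets are likewise synthetic: the model itself
is simulated at a known (K*, rho*) with held-out seeds, which makes
parameter recovery testable without any empirical data.

Desk-scale protocol sizes are the package defaults: 8-region networks,
3 seeds, 5x5 fitting grids over K in [0, 3] and rho in [2, 3], and
180-660 s simulations; the published-scale 41-point grids with 50 seeds
and 90-region connectomes are one configuration change away.

## Known limitations and open behaviour

- At dt = 1 ms the gamma subpopulation's kinetics (synaptic e-folding
  1.5 ms) are marginally resolved: the gamma-only limit cycle runs at
  ~35 Hz, whereas accurate integration (dt = 0.1 ms) gives ~68 Hz. The
  model is defined at dt = 1 ms and we keep that step; users probing
  gamma-band questions should check dt-sensitivity explicitly.
- The alpha subpopulation at the default constants oscillates at
  11.5-13 Hz (upper alpha), ~1.5-2.5 Hz above the nominal 10 Hz of the
  classical parameter set it derives from.
- At r_alpha = 0.5 and moderate coupling the model is bistable between
  a slow (theta) and a fast (beta/gamma) attractor; with the weak
  sampled noise the attractor reached depends on the transient
  (including the ISP time constant), while the rate and C4 equilibria
  do not. Under the diffusion noise mode the attractors mix within a
  run and the spectrum becomes path-independent.
- Excitability is homogeneous across regions; no delays, no
  thalamo-cortical loop, no leadfield to sensor space (sensor-level
  spectra are approximated by region averages).
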