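# Methods

`psapet` quantifies GABA_A/central-benzodiazepine receptor density (Bmax) and
apparent affinity (1/KdVr) from flumazenil PET time-activity curves in the
rat. It implements three layers: a saturable compartmental forward model, a
full multi-injection identification, and the non-invasive partial-saturation
(Scatchard-equilibrium) estimator, together with a synthetic-study generator
used to validate the estimator exactly as a simulation study would.

## The compartmental model

The target region follows a two-tissue-compartment model with a free
compartment F and a saturable specifically-bound compartment B. Labelled
("hot", starred) and unlabelled ("cold") flumazenil are chemically identical,
share all rate constants, and compete for the same receptor pool:

    dF*/dt = K1·Cp*(t) − k2·F* − (kon/Vr)·F*·(Bmax − B* − B) + koff·B*
    dB*/dt = (kon/Vr)·F*·(Bmax − B* − B) − koff·B*

with the identical pair for the cold species driven by Cp(t). Parameters and
units: Bmax (pmol/ml tissue), K1 (/min), k2 (/min), kon/Vr (ml·pmol⁻¹·min⁻¹),
koff (/min). Derived constants: KdVr = koff/(kon/Vr) (pmol/ml), apparent
affinity 1/KdVr (ml/pmol), free-compartment distribution volume DV1 = K1/k2,
and binding potential BP = Bmax/KdVr. A reference region without specific
binding is a one-tissue model dC/dt = k1r·Cp* − k2r·C.

Modelling choices:

- No fractional blood-volume term: the measured signal is free + bound. The
  model is the five-parameter structure, nothing more.
- All quantities are decay-corrected and expressed in pmol/ml (activity is
  converted through specific activity), so no radioactive-decay term appears.
- Integration uses a stiff-capable adaptive solver (LSODA) with relative
  tolerance 1e−8 and absolute tolerance 1e−10 pmol/ml, restarted at every
  input-function kink (injection, end of delay, end of upslope) so the
  stepper never straddles a discontinuity. States are floored at zero inside
  the bimolecular term to avoid sign flips at the noise floor.
- PET frames report interval averages, so simulated curves are averaged over
  each frame by composite Simpson quadrature on the dense ODE interpolant
  (33 samples per frame), not sampled at midpoints.

The four identified parameter sets of the multi-injection animals (A–D) are
shipped as constants; rat A (Bmax 27.26, K1 0.23, k2 0.77, kon/Vr 1.24,
koff 4) is the canonical simulation case, giving KdVr 3.23 pmol/ml,
1/KdVr 0.31 ml/pmol, DV1 0.30, BP 8.44 (at the tabled two-decimal KdVr).

## Synthetic plasma input function

Real input functions are measured from arterial samples; the generator uses
a parametric stand-in: per injection, a delay (0.25 min), a linear upslope
(0.5 min) to the peak, then a tri-exponential washout. Superposition across
injections is exact and the curve scales linearly with injected mass.

The default shape — washout fractions (0.93, 0.02, 0.05) at rates
(6, 0.6, 0.015) /min — and its dose-to-concentration scale
(44.676 (pmol/ml)/nmol at the peak) were calibrated once, by bisection, and
frozen, so that the generator reproduces the study conditions the
partial-saturation design requires under rat-A kinetics:

- a 4.5 nmol injection reaches 54% peak receptor occupancy (inside the
  50–70% design band);
- a 0.6 nmol tracer dose stays below 10% occupancy (the tracer-limit
  condition of the multi-injection protocol's first phase);
- the analysis window sits in a quasi-stationary regime: after the fast
  first-pass phase has cleared (~1 min) and the intermediate phase has
  decayed (~5 min), tissue kinetics are slaved to the slow 0.015 /min tail.

The last point is what makes the reference-region estimator behave the way
the validation experiment reports. In the tail-driven regime both the target
free compartment and a DV-matched reference track plasma with small lags;
the lag of the receptor-buffered free compartment is larger by roughly
λ3·(dB/dF)/k2, a near-constant fractional offset in F. A constant fractional
error in F leaves the fitted Bmax almost untouched and loads the bias onto
KdVr — the estimator's documented bias structure (Bmax error well under 1%,
KdVr error of a few to ~8%). A sharply peaked bolus with a weak tail breaks
this regime and the reference mode degrades badly; the calibrated default
deliberately avoids that.

## Partial-saturation estimator

After an injection sized for 50–70% occupancy, the tissue passes through a
dynamic Scatchard-like equilibrium in which instantaneous bound and free
concentrations obey B = Bmax·F/(F + KdVr). The estimator takes a target TAC
and a free-concentration TAC (either the simulator's true free trajectory or
a reference-region curve), forms per-frame pairs F = reference,
B = target − reference inside an equilibrium window, drops frames with
B < 0 or F ≤ 0 (dropping, not clamping: clamping biases the fit near the
origin; the count is reported), and fits (Bmax, KdVr) by nonlinear least
squares. Frame midpoints time-stamp the pairs. Default windows: 4.3–60 min
with the true free curve, 5.8–60 min in reference mode; when the scan is
shorter the window end clamps to the last frame with a note on the result.
Degenerate inputs — no specific binding (a ventricle-like target), no spread
in F (constant input) — are returned flagged rather than raised, since they
are legitimate data the pipeline must classify.

`equilibrium_check` verifies the Scatchard-equilibrium assumption directly:
the continuous (F, B) pairs in a window must lie on one saturation curve
(RMS residual below 1% of peak bound) and the fitted constants must move
less than 1% when the window start shifts by ±2 min. A window covering the
injection peak fails it; the default windows pass; a constant-input steady
state passes trivially (stationarity is checked instead, since a single
equilibrium point has no curvature).

## Full identification

The five-parameter fit minimises weighted least squares between the
frame-averaged hot-ligand prediction and a multi-injection TAC, with weights
proportional to frame duration (longer frames have lower variance under
counting statistics; the weighting rule is configurable). Optimisation runs
in log-parameter space with bound constraints (default [0.01×, 100×] a
physiologic prior set at the across-animal means), optional seeded
log-uniform multi-start, and a finite-difference step of 1e−4 in log space —
large enough that numerical ODE-solver noise (relative tolerance 1e−6 during
fitting) does not corrupt the Jacobian. koff is fixed at 4 /min by default,
mirroring its constancy across the identified animals; any subset of
parameters can be fixed. On noise-free data from the three-injection
protocol, all four free parameters are recovered to well under 0.01%;
approximate confidence intervals come from the Gauss–Newton covariance in
log space, exponentiated back.

## Synthetic cohorts and group statistics

The cohort generator emulates the two-group epilepsy study: control (n=7)
vs post-SE epileptic (n=8) animals with hippocampal receptor density
19.23 vs 14.17 pmol/ml and apparent affinity 0.12 vs 0.15 ml/pmol. The
printed ± values (1.18, 2.84, 0.01) are used directly as between-animal SDs:
that reading reproduces the study's reported significance levels (p<0.01 for
density, p<0.05 for affinity at these group sizes) under an unpaired t-test,
whereas interpreting them as SEMs and scaling by √n yields dispersions so
large that both comparisons would be underpowered (p≈0.14) — inconsistent
with the reported results. Draws use left-truncated normals whose parent
parameters are solved so the truncated mean and SD equal the stated values
(the correction is negligible at these dispersions but exact by
construction). Cortical generative means are set equal across groups at a
level near the control hippocampus, since no cortical difference is the
study's finding and absolute cortical values are not printed. K1 and k2 are
per-animal nuisance draws (uniform on 0.15–0.35 and 0.45–0.80 /min) shared
across ROIs; the reference region is DV-matched with k2r jittered ±10%
around k2; injected mass is uniform on 3.6–4.6 nmol; koff is 4 /min and
kon/Vr follows from koff·(1/KdVr). All draws are seeded and bit-reproducible.

A consequence the package reports rather than hides: at the cohort's
apparent affinities (KdVr ≈ 7–8 pmol/ml) the calibrated exposure from a
~4 nmol injection reaches only ~15–35% occupancy — below the design band.
The true-free fit remains stable there (a few percent bias from imperfect
equilibrium over the 33-min scan), but the reference-mode fit becomes
ill-conditioned: the weak saturation curvature is overwhelmed by the
reference's kinetic-lag error and per-animal estimates can diverge along the
Bmax–KdVr valley. The cohort pipeline therefore computes both modes per
animal, flags unstable fits, and runs the group statistics on the true-free
estimates (an observable only a simulation provides). This is a genuine
limitation of reference-based partial saturation at low occupancy, not an
implementation artifact.

Group comparisons are two-sided unpaired t-tests (pooled variance by
default, Welch by flag), labelled significant at p<0.05 and as a trend for
0.05≤p<0.10. Rank correlations are Spearman with mid-rank ties; for n ≤ 8
the two-sided p-value is exact by enumeration of rank permutations,
asymptotic otherwise, and ρ² is reported alongside ρ because rank
correlations in this literature are reported as r². The hippocampal
cell-loss score sums four subregion scores (CA1, CA3, CA3c, hilus; each 0–4,
4 = no loss) into a 0–16 total.

## Blood processing

Arterial samples (nominal 50 µl into 50 µl NaF) are background-subtracted
and decay-corrected to the start of their injection phase,
(counts − background)·2^(t/T½) with T½ = 109.77 min for ¹⁸F; negative net
counts are flagged and excluded downstream rather than clamped.
Mass-spectrometry concentrations are renormalised from the actual drawn
volume V to the nominal 1:1 mix: conc ÷ [V/(V+0.05)] × [0.05/0.1], exactly
the identity at V = 0.05 ml and linear in concentration. Corrected per-phase
series concatenate on the global clock into a sampled input function,
linearly interpolated and held at the last value — whole-blood counts are
used as-is (metabolism is blocked in the sampling tubes; parent fraction is
taken as 1), with a single user-supplied counts→concentration calibration.

## Noise model

Frame noise is zero-mean Gaussian with variance proportional to
concentration/duration (counting statistics), scale 0.3 by default (≈4%
at 20 pmol/ml in a 3-min frame, ≈20% in the low-count early frames), seeded,
with negative frames floored at zero and the floor count recorded. It
emulates reconstructed-ROI noise magnitude only: no partial-volume effects,
no inter-frame correlation from reconstruction, no scanner dead-time — so
noisy-data tests exercise estimator robustness to counting noise, not to
systematic image artifacts.

## Problem sizes used in the shipped checks

The validation experiment simulates one 60-min scan (23 frames) per mode;
the identification round-trip covers all four parameter sets on a 51-frame
three-injection scan; the Monte-Carlo robustness check runs 6 noisy
replicates of the identification; the Scatchard/grid-search oracle runs 100
seeded noisy datasets against a 2000×2000 log grid; the cohort regression
uses the default 15-animal cohort. The cohort-recovery property uses a
60-min scan with an 8-min window start — the period the equilibrium check
identifies as equilibrated at low occupancy, where residual bias falls
within 2%.

## Known limitations

- Plasma parent fraction is assumed 1 (metabolite kinetics out of scope).
- ROI-level only; no voxelwise maps, no partial-volume or spillover model.
- The reference region is an idealised 1TC tissue; a real olive nucleus has
  a small specific-binding component that partially buffers it like the
  target, which the generator does not emulate.
- The reference-mode KdVr bias depends jointly on the input-function tail,
  the reference efflux rate and the window; the validation report exposes
  all three rather than asserting a single cause.
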