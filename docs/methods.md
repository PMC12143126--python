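# Methods

This note describes the models and procedures `thetaflow` implements, the
defaults it ships with and why, what the synthetic-data generator does and
does not emulate, and the numerical choices that affect results.

## Scientific setting

The package targets a within-subject, two-condition (placebo vs. an
active, catecholaminergic condition modeled purely as a labeled coupling
change) EEG study of action–effect binding. In each trial a fixation
period (2000 ms) is followed by a colored cue (2000 ms); a correct
keypress within a 1000 ms response window triggers a 2000 ms audiovisual
action effect whose visual component flickers at 4.5 or 8 Hz (150 trials
each of 300). The flicker frequency-tags the processing of the action
effect: neural activity tracking the (anticipated or perceived) effect
appears as spectral power at the tagged frequency, strongest over
posterior electrodes. Analysis divides the trial into an action-planning
phase (0–1000 ms cue-locked), a standby phase (1000–2000 ms cue-locked)
and a perception phase (0–1000 ms effect-locked), and asks how directed
theta-band communication between the anterior temporal lobe (ATL),
insular cortex (IC) and inferior frontal cortex (IFC) differs between
directions, phases and conditions.

## Synthetic data generator

All inputs are generated; nothing is downloaded. The generator's defaults
define the study conditions under which the test suite's claims hold.

**Trial timeline.** `simulate_trial_events` draws per-trial correctness
(Bernoulli, accuracy 0.97 by default) and a response latency
(normal, 290 ± 60 ms, clipped to the response window); a correct response
places the action-effect onset at the response sample; incorrect trials
carry none.

**Source dynamics.** `simulate_source_dynamics` iterates the ground-truth
nonlinear MVAR recursion

    x_i(t) = Σ_k Σ_j A[k,i,j] x_j(t−k) + Σ nl-terms→i + drive_i(t) + ε_i(t)

with Gaussian innovations (SD 1), an optional deterministic 4.5 Hz theta
drive, and a 500-sample burn-in. Matrices use the target-row convention
(`[i, j]` means j→i) throughout the package. Stationarity of the linear
part is enforced by the companion-matrix spectral radius (< 1); the
nonlinear coupling library is {quadratic, pairwise product,
tanh-saturating}. The canonical validation network (`default_network`,
order 3) has self-regressions (0.45, −0.25, 0.1), linear edges ATL→IFC
(0.45, lag 1) and IC→ATL (0.35, lag 2), a quadratic IC→IFC edge
(gain 0.4, lag 1) and an ATL×IC product edge into IFC (gain 0.35, lag 2).
Its directed graph is deliberately acyclic: an unbounded quadratic inside
a feedback loop diverges for rare large excursions, so unbounded
nonlinearities only feed sink nodes, while the bounded tanh form is used
wherever bidirectional nonlinear coupling is wanted (the study
generator).

**Head model.** `make_toy_leadfield` places sensors on the upper
hemisphere of a 100 mm shell (Fibonacci layout, 0.5 mm seeded jitter) over
a cubic grid spanning ±60 mm. Gains fall off as `1/(1 + (d/60 mm)²)`; the
60 mm scale keeps the gain dynamic range moderate so the unit-gain
beamformer's depth bias (noise power ∝ 1/‖l‖²) stays bounded. Voxels are
labeled deterministically: a central sphere (r < 25 mm) is SUBCORTICAL
(excluded from ROI construction), the left hemisphere is OTHER, and the
right hemisphere splits into IFC (anterior), ATL (inferior posterior) and
IC (superior posterior) stand-ins. This is a toy geometry: no
boundary-element modeling, no realistic conductivities, no atlas.

**Tagged sensor EEG.** `simulate_tagged_eeg` sums four components:
(i) network source dynamics projected through the leadfield at each
region's seed voxel, scaled to 1.5 µV RMS; (ii) the steady-state response:
a sinusoid at the trial's flicker frequency plus its first harmonic 6 dB
down on the 6 most posterior sensors — at full amplitude (default 3 µV)
during the action effect, where the flicker is physically present, and at
0.6× amplitude with a linear 150–650 ms ramp during the cue period,
modeling endogenous anticipatory reactivation that builds up after the
cue (an instantaneous onset would be both physiologically wrong and would
smear tagged power backwards, by the wavelet half-length, into the
pre-cue normalization window); (iii) 1/f-shaped Gaussian noise with SD
`ssvep_amp / snr`; (iv) an ongoing narrowband alpha background (8–12 Hz,
2× the broadband noise SD). The alpha floor matters: without it, the
harmonic of the 4.5 Hz flicker (9 Hz) dominates *relative* power change
at the measured 8 Hz control frequency, a regime occipital EEG — with its
substantial resting alpha — is never in. Components are independent, so
sensor variance decomposes additively (tested to 5 %).

**Study generator.** `StudyConfig` defines 12 subjects × 2 conditions ×
3 phases, 2000 samples per cell at 256 Hz. Each subject carries one
multiplicative coupling jitter (SD 0.08) that persists across all their
cells (a within-subject design); innovations differ per cell. All
background coupling is bidirectionally symmetric in expectation,
including a symmetric tanh pair on IC<>IFC, so the *only* systematic
directional asymmetry in the study is the configured ATL<>IFC gain pair:
(0.25, 0.25) everywhere except the active condition's perception phase,
where it is (0.45, 0.08). This gives the inference layer a single known
cell to find. `simulate_behavior` generates per-subject reaction times
(16.55 ms condition effect, 50 ms between-subject SD, 31 ms paired-
difference SD) and accuracies (0.97 vs 0.98, paired SD 0.042); the
difference SDs are matched to the paired statistics such a study reports
at n = 54.

## Preprocessing

BrainVision reading goes through MNE-Python and returns µV with stimulus
markers mapped to `(sample, code)`; the writer (multiplexed
IEEE_FLOAT_32 or INT_16) exists in-package because MNE only reads the
format. Resampling is polyphase (`scipy.signal.resample_poly`) with
event samples rescaled and rounded half-to-even; upsampling is refused.
The band-pass is a Butterworth run forward–backward (`sosfiltfilt`,
zero phase). The default order is 5: with the squared magnitude response
of filtfilt this attenuates 60 Hz line activity below 1 % RMS for the
0.5–40 Hz band, which a 4th-order design narrowly misses (1.36 %).
Epochs use half-open sample windows `[start, end)`; events whose window
leaves the record are dropped and counted. Data are assumed
already referenced and artifact-free — ICA, bad-channel repair and robust
re-referencing are out of scope because the synthetic inputs are clean.

## Time–frequency analysis

The Morlet kernel is `exp(i2πft)·exp(−t²/2σ_t²)` with
`σ_t = n_cycles/(2πf)` (default 5 cycles), truncated at ±3σ_t, and
amplitude-calibrated so a unit sinusoid at f yields power 1 (units µV²).
Relative power change divides by the mean power in the −350…−150 ms
pre-cue baseline (endpoints inclusive at sample resolution); a truncated
real-signal wavelet leaves ~0.2 % ripple, which bounds attainable
flatness in noiseless tests. The pointwise contrast runs a two-sided
paired t per electrode × time point with BH-FDR applied jointly across
the tested family; zero-variance points (possible in degenerate
fixtures) are reported as undefined and excluded from the family rather
than assigned p = 0. Analyses that need both a signal window and an
all-null control window test them as *separate* families: FDR control
deliberately admits ~α false discoveries in a mostly-significant family,
and those would otherwise concentrate in the null stretch and turn the
control check into a test of BH mechanics. Phase windows are half-open
and gap-free per lock (planning/standby cue-locked, perception
effect-locked).

## Beamforming

The CSD at the tagging frequency is the trial average of outer products
of Hann-tapered, amplitude-calibrated Fourier coefficients (Hermitian
PSD by construction). Both beamformers use the fixed-orientation
unit-gain filter `w = C_reg⁻¹ l / (lᵀ C_reg⁻¹ l)` with diagonal loading
`C_reg = Re(C) + λ·mean(diag)·I`; λ defaults to 5 % and is the main free
parameter (a singular covariance at λ = 0 raises an error advising
λ > 0). DICS power is `Re(wᴴ C w)`; the top-3 % rule selects
`ceil(0.03·V)` voxels with ties at the cutoff all included. Selected
voxel coordinates are clustered with DBSCAN (defaults eps = 1.5 × grid
spacing, min_samples = 3; on coarse grids where regions touch, a tighter
eps of about one grid step avoids chaining adjacent regions into one
cluster). Each cluster takes the majority anatomical label of its voxels
(lexicographic tie-break, logged in provenance); clusters sharing a
label merge; noise voxels and subcortical labels are dropped; a required
ROI ending empty is an error naming it. This deterministic rule replaces
a manual grouping step and is a documented interpretation, not a claim
about the original procedure. LCMV uses the time-domain covariance of
the analysis window; within an ROI, voxel series are sign-aligned to the
first voxel (beamformer polarity is arbitrary) before averaging. ROI
theta power is Morlet power at 4.5 Hz averaged over trials and interior
time (edge samples within half the wavelet support excluded).

## Directed connectivity estimator

One network is fitted per subject × condition × phase. Channels are
z-scored with training-split statistics; trials are demeaned individually
and lag-embedding never straddles trial boundaries; the train/test split
(default 0.8) is contiguous in time to respect temporal dependence.
The network is a single hidden layer of tanh units (default 10) over the
`K·p` lag coordinates (default p = 3, capturing directed delays up to
~12 ms at 256 Hz), trained full-batch with L-BFGS (analytic gradients,
max 600 iterations) from a seeded Gaussian initialization — identical
data and seed give bit-identical weights. Training minimizes mean squared
one-step error plus an L2 weight penalty, default 3e−3. The weight decay
doubles as the estimator's linearity prior: on data generated by a purely
linear process it keeps the fit inside the tanh's linear range, so the
nonlinear statistic stays below ~0.1 of the linear one on true edges,
while leaving genuine quadratic/product couplings fully detectable (edge-
ranking AUC 1.0 at the generator's default gains and n = 5000). With
weaker decay (1e−5) spurious curvature reaches 0.3 of the linear
statistic. Models carry train/test MSE and per-channel R²; a test R²
below the configured floor flags the model (`quality_ok = False`) rather
than silently discarding it.

The Taylor split is exact by construction: `A` is the first-order term at
z = 0 (retaining `sech²(b_h)` so the expansion is exact at that point),
and the nonlinear part is defined as the residual `f(z) − A z − f(0)`,
so the identity holds at every point to machine precision. The edge
statistics — time-averaged first-order contribution magnitude for L,
time-averaged Jacobian deviation `mean |J(z_t) − A|` for NL — are this
package's operationalization of the linear/nonlinear split; their
absolute scale is not comparable to other implementations, only the
comparative structure across edges, directions, phases and conditions is
interpreted.

## Surrogates and group inference

Circular time-shift surrogates divide each series into consecutive
windows of half a cycle of 4.5 Hz (`round(fs/9)` samples ≈ 110 ms at
256 Hz) and roll each window of each channel by an independent uniform
shift — per-window sample multisets (hence means and variances) are
preserved exactly while consistent cross-channel lag structure is
destroyed. Shifts are drawn independently per channel (a documented
choice). Each surrogate is refitted with identical hyperparameters and
initialization seed; an edge is significant when the observed value
exceeds the linear-interpolation 95th percentile of its surrogate null.
A divergent surrogate fit is redrawn once, then errors.

Group comparisons of the two directions of an edge use the paired t
(`t = mean(diff)/(sd/√n)`, two-sided), BH-FDR within one linearity ×
condition family (9 tests — the granularity at which corrected p-values
are reported), the paired effect size d = |t|/√n, and the two-sided JZS
Bayes factor with Cauchy(0, √2/2) effect-size prior evaluated by adaptive
quadrature of the inverse-gamma mixture (relative error < 1e−6,
cross-checked in tests against an independent implementation). Evidence
labels follow Jeffreys bands on max(BF10, 1/BF10) — anecdotal to 3,
moderate to 10, strong to 30, very strong to 100, extreme beyond —
with direction H1 iff BF10 > 1 (BF10 = 1 counts as anecdotal H0). Zero-
variance difference vectors split into two cases: identical directions
report t = 0, p = 1 (no evidence of a difference); a constant nonzero
shift has no defined t and is excluded from the FDR family.

## Problem sizes used by the test suite

The validation suite runs the estimator at n = 5000 samples (20 seeds)
for edge-ranking recovery; the surrogate calibration at 20 surrogates ×
20 seeds on 1200-sample series with a reduced network (8 hidden units,
200 iterations); the tagging contrast with 16 synthetic subjects × 24
trials (20 seeds); and the end-to-end study at the full 12 subjects ×
2 conditions × 3 phases × 2000 samples (20 seeds). These sizes keep each
claim testable at useful statistical resolution; all pass/fail
thresholds are stated in the tests themselves.

## Known limitations

- The head model and labeling are synthetic stand-ins; nothing here
  validates source localization against real anatomy, volume conduction
  or atlas labeling.
- The generator's SSVEP amplitude, SNR, alpha level and anticipatory
  ramp are stated defaults, not quantities matched to any recording;
  passing tests demonstrate method correctness under these conditions,
  not performance on real data, which adds artifacts, nonstationarity
  and reference effects the generator omits.
- DICS with a single CSD cannot split sources that are strongly
  correlated across the analysis window; the toy fixtures use phase
  randomization across trials to keep sources separable.
- The majority-label ROI rule cannot split a single spatial cluster that
  spans two anatomical regions; on coarse grids the clustering eps must
  stay near one grid step.
- With few subjects the map-wide paired-t/FDR cascade is nearly
  all-or-nothing (the first discovery faces an almost Bonferroni-level
  threshold); group-level tagging claims need cohorts of roughly 16+
  even with strong per-subject effects.
- The interpretation of the wavelet parameter pair (5 cycles, "length 3")
  as truncation at ±3σ_t is a documented reading; power values at other
  truncations differ at the sub-percent level.
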