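# thetaflow

Directed theta-band network communication from frequency-tagged EEG.

`thetaflow` re-implements, as a tested and reusable Python library, an
analysis chain for studying how actions and their sensory effects are
bound together in a cortical theta (4–8 Hz) network spanning the anterior
temporal lobe (ATL), insular cortex (IC) and inferior frontal cortex
(IFC). The chain runs end to end on synthetic data with known ground
truth, so every stage is falsifiable without access to raw recordings:

1. **Synthetic data** (`thetaflow.synthio`) — trial timelines of a
   forced-choice task whose visual action effect flickers at 4.5 or 8 Hz
   (frequency tagging / SSVEP), coupled source dynamics from a
   ground-truth nonlinear multivariate autoregressive (MVAR) network, a
   toy spherical head model with labeled voxel regions, continuous
   tagged sensor EEG written as BrainVision files, and a two-condition
   within-subject study generator with a configurable condition-by-phase
   coupling asymmetry.
2. **Preprocessing & I/O** (`thetaflow.preprocess`) — BrainVision
   read/write (EDF read), polyphase resampling (500 → 256 Hz), zero-phase
   0.5–40 Hz Butterworth band-pass, and epoching with half-open sample
   windows.
3. **Time–frequency tagging** (`thetaflow.tf`) — Morlet wavelet power
   (5 cycles, kernel truncated at ±3σ), relative change against the
   −350…−150 ms pre-cue baseline, pointwise paired t contrasts between
   the measured 4.5 and 8 Hz with Benjamini–Hochberg FDR, and the
   planning / standby / perception phase windows.
4. **Beamforming** (`thetaflow.beamforming`) — DICS source power from the
   sensor cross-spectral density, top-3 % voxel selection, DBSCAN
   clustering with a deterministic majority-label ROI rule, LCMV
   virtual-sensor extraction, and per-ROI theta power.
5. **Directed connectivity** (`thetaflow.ncreann`) — a single-hidden-layer
   tanh network fitted as a nonlinear MVAR one-step predictor, split
   *exactly* into constant + linear + nonlinear parts by a Taylor
   expansion of the hidden activation; directed linear and nonlinear
   edge statistics per region pair.
6. **Inference** (`thetaflow.stats`, `thetaflow.pipeline`) — circular
   time-shift surrogate significance (95th percentile of 100 surrogates),
   paired bidirectional t-tests with FDR, the paired effect size
   d = |t|/√n, default JZS Bayes factors, Jeffreys evidence labels, and
   the full 36-row bidirectional-connectivity report.

## The model at the core

For K ROI time series z-scored to `z`, a network
`f(z) = W_out tanh(W_in z + b_h) + b_o` is fitted to predict `x(t)` from
the lags `x(t−1) … x(t−p)` (default p = 3 at 256 Hz). Writing
`u_h(z) = W_in[h]·z + b_h`, the first-order expansion around the data
mean gives the exact split

```
f(z) = f(0) + A z + nl(z),    A[i,m] = Σ_h W_out[i,h] sech²(b_h) W_in[h,m]
```

Directed **linear** connectivity j→i is the time-averaged magnitude of
j's first-order contribution `mean_t |Σ_k A[i,(j,k)] z_j(t−k)|`; directed
**nonlinear** connectivity is the time-averaged deviation of the
network's instantaneous Jacobian from `A` on j's lag coordinates. Edge
significance compares each observed value with the 95th percentile of
values refitted on segment-wise circularly shifted surrogates; group
inference compares the two directions of each pair across subjects with
paired t-tests, FDR, d = |t|/√n and the JZS Bayes factor
(Cauchy(0, √2/2) effect-size prior).

## Worked example

```
$ python examples/04_directed_connectivity.py
fit: train MSE 0.647, test R2 0.34
linear connectivity L[target, source]:
[[  nan 0.296 0.025]
 [0.032   nan 0.013]
 [0.287 0.012   nan]]
nonlinear connectivity NL[target, source]:
[[  nan 0.025 0.015]
 [0.016   nan 0.02 ]
 [0.074 0.205   nan]]
true linear edges:
 [[1 1 0]
 [0 1 0]
 [1 0 1]]
true nonlinear edges:
 [[0 0 0]
 [0 0 0]
 [1 1 0]]
```

The ground-truth network has linear edges IC→ATL and ATL→IFC and
nonlinear (quadratic and product) edges into IFC. The two largest linear
entries, `L[0,1] = 0.296` (IC→ATL) and `L[2,0] = 0.287` (ATL→IFC), are
exactly the true linear edges; the two largest nonlinear entries,
`NL[2,1] = 0.205` and `NL[2,0] = 0.074`, are exactly the true nonlinear
edges, while absent connections stay several-fold smaller. The script
then flags edges against a 20-surrogate circular-shift null.
The other examples cover session simulation and BrainVision round-trip
(`01`), the 4.5-vs-8 Hz tagging contrast (`02`), DICS/LCMV source
analysis (`03`), and the full two-condition study report with behavioral
statistics (`05`).

## Limits

The head model is a toy geometry (no boundary-element modeling, no
template MRI, no atlas); artifact correction (ICA, bad channels, robust
reference) is out of scope because the synthetic inputs are generated
clean; and the connectivity edge statistic's absolute scale is a property
of this operationalization — comparative structure across edges,
directions, phases and conditions is the quantity of interest. See
`docs/methods.md` for the full model description, parameter defaults and
known limitations.
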