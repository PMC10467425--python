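# Methods

## Scope and model

`tacsnet` models the in-silico arm of an IAF-tACS (individual-alpha-frequency
transcranial alternating current stimulation) study.  The pipeline has three
stages:

1. **Field geometry.**  A weak extracellular field polarizes a pyramidal cell
   according to the field component along its somato-dendritic axis, which is
   perpendicular to the cortical surface.  Given a triangulated white/gray
   boundary sheet with unit normals `n̂_t` oriented toward white matter and a
   field vector `E⃗_t` sampled at each triangle centroid, the signed normal
   component is the scalar product `E⊥_t = E⃗_t · n̂_t = |E_t| cos θ_t`;
   positive values mean orthodromic (tuft-to-axon, soma-depolarizing)
   alignment.  Components are pooled per parcel into distributions whose
   summaries (mean, squared mean, skewness, excess kurtosis, mode count)
   both characterize the parcel's folding geometry and later serve as
   regression predictors.

2. **Spiking network.**  Each region is a fully connected population of 80
   excitatory (regular-spiking) and 20 inhibitory (fast-spiking) adaptive
   exponential integrate-and-fire neurons:

       C dv/dt = −g_L (v − E_L) + g_L Δ_T exp((v − v_th)/Δ_T) − w
                 + I + I_noise − I_syn + I_ext
       τ_w dw/dt = a (v − E_L) − w

   with spike detection at v_peak = 0 mV, reset to v_reset, w → w + b, and a
   2 ms refractory clamp.  Synapses are conductance-based alpha kernels
   (AMPA τ = 3.0 ms, E_rev = 0 mV; GABA_A τ = 3.2 ms, E_rev = −85 mV) that
   peak at exactly the maximum conductance one time constant after the
   presynaptic spike.  Within a region wiring is all-to-all without
   self-connections at 1 ms delay; between regions only excitatory neurons
   project, with per-pair maximum conductance `ω · w_kk'/max(w) · ḡ_AMPA`
   (connectome weight normalized by its maximum, times the global coupling
   factor) and delay `length_kk' / conduction speed` (default 3.9 m/s, so
   15–180 mm tracts give ≈4–46 ms).  Every neuron receives an independent
   2.4 kHz Poisson background train onto AMPA-type synapses.  The local
   field potential of a region is the signed sum of its neurons' synaptic
   currents (background excluded).

3. **Stimulation.**  tACS enters as a per-neuron sinusoidal current
   `I_ext,i = A_i · V · sin(2πft)`: amplitudes `A_i` are drawn i.i.d. from a
   region's normal-component distribution (empirical inverse-CDF), so a
   region under a bimodal zero-mean distribution receives two anti-phase
   subpopulations of drive, and `V` (pA per field unit) is the global
   intensity scaling that calibration fits.

## Numerical choices

- Fixed-step forward Euler at dt = 0.1 ms (numba-compiled kernel).  The
  membrane potential is clamped at v_peak inside the exponential argument,
  the standard aeif overflow guard; with it, arbitrarily strong inputs
  cannot overflow the state (tested).
- Alpha conductances are advanced by the exact two-state linear update of
  the kernel (impulse `ḡ·e/τ` on the auxiliary state per delivered spike),
  not by event summation; delays are quantized to the integration grid.
- The background Poisson stream comes from the kernel RNG seeded once per
  run, making a run a pure function of (model, stimulus, duration, dt,
  seed); a stimulus with V = 0 consumes the same stream and is bit-identical
  to an unstimulated run.
- Halving dt moves the unstimulated alpha-peak frequency by <2% (tested).

## The free parameters and how they were fixed

The membrane and synaptic constants are standard regular-spiking /
fast-spiking values and are fixed.  Four quantities are model-level degrees
of freedom: the bias currents I (per class) and the maximum conductances
ḡ_AMPA, ḡ_GABA, ḡ_noise.  They were frozen once by a grid search selecting
an unstimulated single-region LFP peak inside 8–12 Hz with firing rates in
1–20 Hz: **I_exc = 60 pA, I_inh = 10 pA, ḡ_AMPA = 0.01 nS, ḡ_GABA = 0.4 nS,
ḡ_noise = 0.03 nS**, which yields a 10.0 Hz peak with E-cells at ~10 Hz (one
spike per cycle).  Two qualitatively different alpha regimes exist in this
parameter space: a strongly coupled, hypersynchronous rhythm (every E cell
doublet-fires per cycle) and an adaptation-paced, weakly coupled regime in
which each cell's spike-triggered adaptation (b = 65 pA, τ_w = 88 ms) sets
the ~100 ms cycle.  The strongly coupled regime turns out to be fragile
under sinusoidal drive — moderate currents make it period-skip to ~5 Hz —
whereas the weak-coupling regime reproduces the full entrainment
phenomenology (1:1 and 2:1 tongues, intermediate faster/slower states), so
the defaults sit there.

## Entrainment read-outs

Spectra are Welch estimates (2 s Hann segments, 50% overlap, zero-padded to
a 0.125 Hz grid, 0–45 Hz).  Two scales are kept: the density normalized to
unit 2–45 Hz power (for comparing spectral shape and locating peaks) and the
unnormalized density (for absolute band-power changes of one model; under
stimulation total broadband power grows, so the normalized alpha *share* can
fall while absolute alpha power rises — the stimulation effect is measured
on the absolute scale).  The peak-to-stimulation frequency ratio of a sweep
cell is the *median* over repetitions: the dominant frequency is a discrete
state label, and one run whose PSD argmax lands on a harmonic would corrupt
a mean.  Sync states are classified from the ratio r with tolerance
tol = 0.05: 1:1 if |r−1| ≤ tol, 2:1 if |r−2| ≤ 2·tol, "faster" in between,
"slower" below 1−tol.

In single-node sweeps the amplitude samples are dimensionless and V is set
per assignment so that the *maximum injected amplitude* max|A_i·V| equals
the sweep-cell intensity, mapping every distribution onto the same 0–200 pA
axis.

Phase locking (PLV) uses a zero-phase 4th-order Butterworth band-pass
(8–12 Hz default), Hilbert phases, a 1 s edge trim, and pools time samples;
the FC fit is the Pearson correlation of strictly-upper-triangular PLV
matrices; working-point selection maximizes that fit subject to a mean-PLV
ceiling (default 0.8; "unrealistically high" synchrony excluded) and a
median node peak frequency inside the alpha band.

## Calibration and statistics

The cohort experiment stimulates each synthetic subject's network at its
trial-specific IAF — the alpha-band argmax of the cluster-averaged raw
baseline spectrum, one value per trial (reading the IAF off an averaged
spectrum keeps the band where the cluster actually carries power; a median
of per-region peaks can fall between two detuned peaks and make the
baseline denominator vanish).  The baseline run is longer than the
stimulated runs (28 s vs 12 s in the shipped protocol): the baseline band
power sits in every rise denominator and the IAF anchors every band, so
sharpening them once per subject buys more variance reduction per unit of
compute than extra stimulated repetitions.  The alpha rise of a trial is
`100·(P_stim − P_base)/P_base`, with P the cluster-mean absolute band power
at IAF ± 0.5 Hz.  Strongly bimodal zero-mean parcels respond to IAF drive
by frequency doubling, which moves power out of the IAF band entirely and
makes their "rise" a bifurcation indicator rather than a dose measure.  The
shipped cohort therefore folds its subjects moderately
(1.5-3 mm, giving clear responders and mild non-responders like an
empirical sample) and measures the rise over all regions; the strongly
folded regime stays available through the mesh generator and is what the
bimodal-distribution single-node experiments probe.  V* is the grid value
whose group-mean rise is closest to the target; the V grid is spaced
densely around the response knee and sparsely on the upper flank, where
slowly responding cohorts cross the target.

Efficacy statistics: per-subject one-sided Wilcoxon signed-rank tests
(stimulated > baseline) with W reported as the rank sum of unfavorable
differences (W = 0 when stimulation wins every pair), rank-biserial
correlation, common-language effect size, and Holm step-down correction
across subjects.  The per-region regression is iteratively reweighted least
squares with Huber's T (t = 1.345, tol 1e-8, ≤50 iterations) on seven
standardized predictors — squared mean, skewness, excess kurtosis and mode
count of E⊥, log₂ node strength, baseline mean PLV, and
stimulation-minus-baseline frequency mismatch — with optional backward
elimination at p > 0.05, plus the same model restricted to
negative-response rows.  Mode counting uses a Gaussian KDE (Silverman
bandwidth, 512-point grid spanning the range ± 3 bandwidths) and counts
local maxima above 5% of the global maximum.

## Synthetic data: what it emulates, what it does not

The fixtures module stands in for every empirical input: sinusoidal
gyrified sheets (the folding knob controls how bimodal the wall parcels'
projections are; parcels are contiguous strips along the folding axis so
crowns and walls land in different parcels), uniform fields (idealizing the
roughly antero-posterior Oz–Cz current flow), log-normal-weight connectomes
with fiber lengths uniform in 15–180 mm, distance-decaying target PLV
matrices, and the three prototypical amplitude distributions — bimodal
symmetric (equal Gaussians at mean ± 0.1, sd 0.03), bimodal asymmetric
(weights 0.65/0.35 at offsets +0.07/−0.13, same mean, same total
separation), Gaussian (sd 0.05) — each at mean 0 and mean 0.05.  The
component geometry of the bimodal prototypes is a declared default (only
the means are externally fixed).

What passing tests therefore show is that the *mechanisms* — projection
geometry, entrainment regimes, calibration logic, statistics — behave as
specified.  They do not show anything about real cortical folding (real
surfaces are not sinusoids), real field inhomogeneity (a uniform field has
no focality), tractography biases, or subject-level empirical numbers;
regression coefficients fitted on synthetic cohorts are not comparable to
coefficients fitted on human data.

## Problem sizes

Library defaults follow the long protocol (50 s runs, first 4 s discarded,
3 repetitions for sweeps; 30 repetitions per intensity for calibration).
The shipped experiment protocols and the test suite run a reduced version —
12 s runs (4 s transient cut), 3 seeds for single-cell read-outs, 2-seed
coarse sweeps, and a 4-subject × 6-region cohort (coupling ω = 0.5) with an 8-point V grid
and two repetitions per grid point — sizes chosen so the full pipeline executes on a single CPU
in minutes while leaving the qualitative regimes intact.

## Known limitations

- Normal estimation on the synthetic sheet is second-order (slope-space
  averaging); very steep folds need proportionally finer grids (the error
  at 45–60° walls is ~1–2.5° at 64² vertices and shrinks ~4× per resolution
  doubling, tested).
- The 2:1/1:1 tongue boundaries depend on the frozen working point; other
  alpha-generating parameter sets (hypersynchronous ones in particular) do
  not entrain.
- PLV pools time samples of one run rather than trial segments; for short
  runs its null bias is non-negligible (quantified against circular-shift
  surrogates in the tests).
- Calibration near regime boundaries is genuinely non-monotone per subject;
  the group-mean response curve is only piecewise smooth, which is why the
  calibration grid is dense at low V.
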