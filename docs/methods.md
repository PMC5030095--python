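# Methods

This note documents the models and procedures implemented in `locomod`,
the parameters that matter, and the choices made where the design was
genuinely open.

## Signal model and ΔF/F₀

Raw fluorescence of one ROI is modelled (and, in the simulator,
generated) as

F(t) = offset · (1 + A · (s ∗ k)(t)) + α · n(t) + ε(t)

with s the spike-count series, k a causal single-exponential kernel
(instantaneous rise, 1/e decay τ = 0.7 s, GCaMP6f-like; amplitude
A = 0.2 ΔF/F per spike), n(t) a slow shared neuropil signal, α the
per-ROI contamination weight, and ε white Gaussian noise. Defaults:
offset 100 a.u., noise sd 2 a.u. (2 % of baseline), α ∈ [0.05, 0.15]
per neuron, neuropil level 0.5·offset with 0.3 Hz-low-passed
fluctuations. No indicator nonlinearity, bleaching, or movement
artifacts are modelled; the kernel parameters are config-exposed.

The baseline F₀ is the 5th percentile (linear interpolation between
order statistics) of the 1 Hz low-pass smoothed trace, taken per 60 s
trial and averaged over all trials of the session, dark and stimulation
pooled — one scalar per neuron, used for both the subtraction and the
division in ΔF/F₀ = (F − F₀)/F₀. The per-trial-varying alternative
reading of the baseline definition was rejected because a single shared
baseline is what guarantees that dark and stimulation values are on the
same scale. All low-pass steps use one mechanism: a Hamming
windowed-sinc FIR of even order (default 60) applied forward–backward
(zero phase, unity DC gain) with mirror padding of 3×order samples.

**Percentile-baseline bias.** The 5th percentile lands on the true
offset only if the trace is quiet somewhere within each trial. Additive
slow contaminants shift it: with neuropil at α = 0.1 the baseline sits
below the true offset by the trough depth of the slow fluctuation,
which adds a constant to ΔF/F₀ and biases LMI toward 0 (measured with
the simulator: ≈ −0.03 at gain 3). This is precisely the artifact NMF
demixing targets, and why demixing belongs before the baseline step.
Demixing is config-optional (`process.demix`); the
parameter-recovery test suites run on contamination-free traces to
isolate the estimator itself, and demixing quality is validated
separately.

## Neuropil demixing

NMF with Lee–Seung multiplicative updates on the nonnegative
(ROI, neuropil) trace matrix, rank 2 by default, seeded random
initialization, squared-Frobenius objective recorded per iteration
(non-increasing by construction; asserted in tests). The component most
correlated with the ROI trace is returned as the somatic signal — the
mapping from components back to "the" corrected trace is not prescribed
anywhere, so max-correlation is this package's rule. NMF separability
requires each source to vanish somewhere (calcium transients do;
min-subtraction helps the rest); with both sources riding a large
common offset the factorization is not identifiable, which the toy
tests illustrate by construction.

## Behavioral-state segmentation

Speed is linearly interpolated from the encoder onto the 40 Hz frame
grid (positions are differentiated first; output clipped at 0). The
three locomotion criteria — instantaneous, 0.25 Hz-filtered, and 2 s
centered-window mean speed all ≥ 0.1 cm/s — are evaluated at 40 Hz (the
criteria are defined on the resampled series; evaluating them at the
raw encoder rate is not meaningfully different for the statistics and
was not adopted). Rule order is: criteria → merge inter-locomotion gaps
strictly shorter than 500 ms → exclusion windows (3 s after / 0.2 s
before locomotion), because the windows refer to the final merged
periods. Frames above the instantaneous threshold that fail the other
criteria fit neither state definition and are EXCLUDED. The 2 s window
is truncated at the trace edges rather than discarding 1 s at each end.
A frame-by-frame brute-force restatement of these rules (independent
filter code, explicit loops) reproduces the vectorized labels exactly
on randomized traces.

## Sampling, bootstrap, responsiveness

ΔF/F₀ is cut into 1 s samples, each fully inside a maximal period with
one behavioral state and one stimulus (direction × static/drifting for
gratings), bins anchored at the period onset with starts 2 s apart;
trailing partial bins are discarded. Consecutive samples of one
condition are correlated (R = 0.35 is adopted as a fixed property of
the calcium signal, not re-estimated per dataset), so each bootstrap
iteration draws round(0.65 · n) samples with replacement — separately
for the locomotion and stationary pools. Stratification is this
package's choice: it guarantees every iteration has both states (the
LMI is defined in every resample) and preserves the state ratio; the
resulting intervals are slightly conservative, which the type-I suite
confirms. 10000 iterations give an equal-tailed 95 % percentile CI.
Responsive: CI excludes 0 and |LMI| > 0.2; the negative (inhibited)
rule is the mirror image. Neuron-contexts with under 5 s of either
state, fewer than 5 samples per state, or R_L + R_S ≤ 0 (the index is
unbounded there) are flagged invalid and excluded from population
summaries rather than clipped.

## Context-dependence classification

Per context, locomotion and stationary epochs are numbered in time
order (independently; their interleaving is immaterial) and separate
LMIs computed from the odd and the even epochs; a neuron's variability
is |LMI_odd − LMI_even|. The 5 % most variable neurons of a population
cannot be labelled CD. Two scopes are implemented: the default flags
5 % of *neurons* (largest variability across contexts — one joint
exclusion set, as "the 5 % most variable neurons ... for either
context" reads); the alternative (`classify.variability_scope:
"context"`) takes a 95th percentile per context separately, which
excludes up to ~10 % of neurons because the two 5 % tails are nearly
independent. High variability blocks only the CD label; a reliable-
looking CI call is not forbidden for a flagged neuron.

Significance of the context difference is a bootstrap CI of
LMI_stim − LMI_dark from iteration-wise differences of the two
contexts' independent bootstrap streams. Labels: CD = significant
difference ∧ reliable; CI = not CD ∧ |ΔLMI| < 0.2 ∧ responsive in at
least one context (both, with `ci_requires_both`); otherwise OTHER.
Every analyzed neuron receives exactly one label.

## Population statistics

Animals are the statistical unit: all tests consume per-animal
summaries (median LMI; mean ΔF/F₀ per state; responsive fractions) and
neuron-level tests are deliberately not offered. Wilcoxon signed-rank
for paired state/context comparisons, Kruskal–Wallis for dark-vs-stim
LMI, Mann-Whitney U for layer comparisons; two-tailed; p to 3
significant figures; no multiple-testing correction. Groups under 3
animals are skipped with a warning.

## Synthetic behavior and spiking

Running is an alternating renewal process: exponential bouts (mean
10 s) and exponential gaps whose context-specific means are derived
from the target run fractions (0.26 dark, 0.41 stimulation sessions),
realized as per-frame geometric hazards so context switches take effect
immediately. Within-bout speed is a 1 Hz-smoothed Gaussian around
5 ± 1.5 cm/s clipped at 0.5 cm/s (robustly above all three 0.1 cm/s
criteria); zero outside bouts. The 10 s bout mean keeps bouts long
relative to the indicator decay: the first ~τ of each bout sits below
the new fluorescence steady state, so short bouts depress measured R_L
by ~τ/mean-bout of the locomotion increment (the matching decay tail
into stationary periods is already removed by the 3 s exclusion
window). Magnitudes and bout statistics are free parameters of the
model — only the run fractions are constrained.

Spiking is inhomogeneous Poisson at rate
baseline × (1 + visual_gain · bump(direction)) × G(t), with bump a
cosine-power tuning curve (exponent 0 = untuned) during grating frames
and G(t) the context-specific locomotion gain while the animal runs —
applied only during visual drive for gated (SST-like) neurons.
Multiplicative gain makes the ground-truth LMI analytic,
(g − 1)/(g + 1), under the rate-linear readout. Archetype defaults:
VIP-like g = 4 both contexts; PV-like 2/2; SST-like 1 dark / 3
stimulation, gated; excitatory 1.2/1.8 with tuned visual drive; NULL
g = 1. Baseline rates are lognormal across neurons (σ = 0.3), a
standard description of cortical rate distributions. Recovery
populations use a 0.5 Hz baseline so quiet periods exist within every
trial and the percentile baseline is unbiased — the same sparse-firing
regime the 5th-percentile convention assumes on real data.

## What the simulator does and does not establish

Passing recovery tests shows the pipeline correctly inverts its own
forward model: rate-linear readout, Poisson noise, stationary bout
statistics, no indicator nonlinearity or saturation, no slow drift, no
motion artifacts, no correlated population noise. Real recordings
violate several of these (the fluorescence–spike relationship is
nonlinear and cell-type dependent), so ground-truth recovery here
validates the statistics, not the biology. The published in-vivo
percentages and ΔF/F₀ values depend on unreleased data and are not
reproduction targets.

## Problem sizes and determinism

Validation suites are sized to run comfortably on one CPU: recovery
uses 100 neurons across 4 dark-trial sessions with 2000 bootstrap
iterations; type-I control 1000 NULL neurons across 20 sessions;
CD/CI recovery 100 + 100 neurons across 4 full sessions; the demo
pipeline 2 animals × 20 neurons with reduced trial counts and 300
iterations. All randomness flows from one root seed through
`numpy.random.SeedSequence` spawning, so every stage — and the full
pipeline, including written tables — is bit-reproducible; degenerate
inputs (empty sample sets, all-zero responses, single epochs,
non-positive denominators) return flagged-invalid results rather than
raising mid-pipeline.
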