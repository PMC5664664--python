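# Methods

This note documents the models, conventions and numerical choices
behind `xrfdwt`, and what the synthetic-data tests do and do not
establish about real instrument data.

## Transform conventions

The Mallat pyramid is implemented in the orthonormal convention: the
low-pass taps satisfy Σh = √2 and Σh² = 1, the high-pass taps follow
the quadrature-mirror rule g_n = (−1)ⁿ h_{L−1−n}, and reconstruction
uses the time-reversed taps. Under this convention the per-level 1/√2
prefactors of the textbook recursions are absorbed into the taps, the
periodic-boundary transform is an orthogonal map (energy conservation
and perfect reconstruction hold to round-off), and coefficients agree
with PyWavelets up to the sign of the detail blocks (PyWavelets uses
the opposite high-pass sign; the magnitude and every reconstruction are
identical). The oracle tests compare detail blocks with normalized
sign for this reason.

Boundary handling defaults to half-sample symmetric extension, which
avoids the edge ramps a periodic wrap would create on spectra whose
low-channel counts are far from their high-channel counts; block
lengths then follow ceil((N+L−1)/2) per level and stored per-level
lengths drive exact-length inversion. Periodic mode is available and
is what the orthogonality tests use. Supported families: Haar,
Daubechies 1–10, Symlets 2–8, Coiflets 1–5, embedded as standard
constant tap tables and validated at import by the filter-bank
invariants (DC sum, unit norm, QMF relation, double-shift
orthogonality), which would catch any transcription error.

Level indexing: `details[0]` is the finest scale; `level` may not
exceed ⌊log₂ N⌋ (a 4096-channel spectrum supports the level-9 baseline
with margin).

## Denoising

Three steps: decompose, shrink details, reconstruct. The approximation
block is never modified. The threshold rule is the universal threshold
with a MAD noise estimate taken from the finest detail block and
applied globally to all levels, in soft mode — a standard, assumption-
light default for counting noise that is approximately white at the
finest scale. A fixed threshold and hard mode are available for
diagnostics; t = 0 reduces to the identity (perfect reconstruction).

### Selection metrics

SNR, MSE and entropy compare the processed spectrum x against the
original y (not against an unknown truth): SNR = 10·log₁₀(Σy²/Σ(x−y)²)
(log base 10, dB convention), MSE = (1/N)Σ(y−x)², and
H = −Σp·log₂p with p the processed counts clipped at zero and
normalized to sum 1 (0·log 0 ≡ 0). When a clean truth exists
(simulation), truth-referenced variants are computed explicitly against
that truth instead; the two uses are never mixed.

Two conventions for the composite coefficient α circulate for this
recipe and they are exact reciprocals; the package defaults to
α = MSE/(SNR·H), **minimized** — the form consistent with the published
comparison tables this selection procedure reproduces — and exposes
α = SNR·H/MSE (maximized) behind the `eq10` flag. Ranking ties are
broken by candidate order (stable sort). Degenerate cases: identical
inputs give the SNR = +∞ sentinel with MSE = 0 and α = 0; zero entropy
with nonzero MSE gives α = +∞ (ranked last).

H and SNR magnitudes depend on the spectrum itself; they are internal
ranking scores here, not reproduction targets — only the α arithmetic
and the induced ranking are testable without the original instrument
spectra.

## Baseline estimation

The peeling loop replaces f⁰ with min(f⁰, a_J(f⁰)) pointwise, where a_J
is the level-J approximation (J = 9 default). The same level drives
both the clipping passes and the final extraction — the simplest
reading of "clip against a deep approximation, then take the deep
approximation of the gentle curve". Stopping: maximum relative change
≤ 1e−3 (relative to the input maximum) or 10 iterations, whichever
comes first; the min rule makes the iteration pointwise monotone
non-increasing, so the cap is a safeguard, not a tuning knob. Negative
residuals after subtraction are clamped at zero by default (counts are
physical); the clamp can be disabled for diagnostics. When a denoise
configuration is supplied the baseline is estimated on the denoised
spectrum (denoise at level 3, then baseline at level 9 — the standard
operating order).

Two known systematic effects, both visible in the tests:

* a single level-9 approximation cannot follow curvature sharper than
  its ~2⁹-channel scale, so very steep continuum edges (the low-channel
  rise) are tracked imperfectly;
* on convex peak-free stretches the min rule nibbles ~0.2 % of the
  curve per iteration, biasing the baseline slightly low.

Consequently the "smooth baseline in, zero out" test uses a fixture
that is genuinely smooth at the level-9 scale (decay constant 3000
channels, hump σ 800; residual ≈ 1 %), while recovery on the default,
steeper generator continuum is asserted at the 10 % known-truth level
(measured ≈ 5 % off-peak). Peak positions are preserved to ≤ 1 channel
through the full chain.

## Quantification

Net intensity is the plain sum of processed counts over the line's
inclusive channel band (floor/ceil of the keV band edges under the
energy calibration — conservative coverage), averaged over replicates;
no peak fitting. Calibration is classical (intensity on concentration,
OLS via `scipy.stats.linregress`), inverted for prediction; R² is
direction-invariant, which is what matters for comparing raw and
processed arms. Blank predictions are deliberately not clamped at
zero: detection limits are 3× and 10× the n−1 standard deviation of 11
predicted blank concentrations, in mg/kg, so QNDL/QDL = 10/3 exactly by
construction. Reported limits are rounded to two decimals only at the
reporting layer.

The energy–channel calibration is fitted channel-on-energy (channels
are the measured axis) over reference (energy, channel) pairs and
inverted; the five-line reference fit gives ≈ 154.48 channels/keV
(6.47 eV/channel) with sub-channel intercept, and leave-one-out
predictions land on the printed channels of the held-out lines.

## Synthetic data model

`synthdata` emulates the study conditions, with every default fixed a
priori at values a practitioner would call realistic for a portable
SDD instrument, and not revisited:

* 4096 channels, gain 6.476 eV/channel (placing Cr Kα at channel 836),
  offset 0;
* continuum 400·exp(−ch/1500) + 150·exp(−(ch−2900)²/(2·500²)) counts —
  a smooth decaying scatter background with one broad hump, the
  qualitative shape of real tube-scatter backgrounds and smooth enough
  at the level-9 scale for the baseline method to be applicable (the
  method's own stated operating regime);
* Gaussian peaks at the calibrated line channels with
  FWHM(E) = 0.06 + 0.04·√E keV (silicon-drift-detector scale), area =
  sensitivity · concentration · live-time scale, sensitivity 20
  counts/(mg/kg) for all five elements;
* channel-wise Poisson noise; a master seed spawns per-spectrum
  generators through `SeedSequence(entropy=seed, spawn_key=(level,
  replicate))`, so calibration sets are bit-reproducible and single
  members can be re-drawn.

Calibration sets default to 12 equally spaced levels across the
standard soil ranges (Cr 32–749, Cu 11.4–577, Zn 31–680, As 4.4–806,
Pb 13.4–644 mg/kg) with 3 replicates per level; blanks default to 11
replicates.

What passing tests show: the chain is numerically correct (exact
transform properties, oracle agreement), it preserves the linear
response it is supposed to protect (R² ≥ 0.99 per element through the
full pipeline), and preprocessing reduces blank-derived detection
limits relative to the raw arm in the large majority of seeds (the
per-seed criterion counts a seed as a success when a majority of the
five elements improve, since the five share one blank set). What they
do not show: absolute detection-limit or SNR magnitudes of any real
instrument — those depend on matrix effects, detector artifacts
(escape/sum peaks, pile-up) and acquisition details that the generator
deliberately omits.

## Problem sizes

The test suite runs full-size (4096-channel) spectra throughout; the
synthetic recovery study uses 10 seeds × 5 elements × 12 levels × 3
replicates plus paired blank arms, and the transform property sweep
covers all 23 filters × levels 1–6 × 100 random signals of lengths
64–128. The whole suite completes in well under a minute on one core.

## Limitations

* No matrix-effect correction (Compton normalization, fundamental
  parameters) — intensities are assumed matrix-free, as in the
  synthetic model.
* No spectral deconvolution: overlapping lines (Cu/Zn Kα are only ~90
  channels apart at this gain) are handled solely by the narrow
  quantification bands.
* Cd, Ni and Hg are out of scope (not quantifiable with this class of
  instrument).
* The peeling baseline is biased low by design (min rule); the bias is
  small and stable under the default iteration budget but grows with
  `max_iter` on peak-free convex regions.
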