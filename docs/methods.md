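# Methods

This note records the models implemented in `aggrescope`, the assumptions
behind them, the parameters that matter, and the numerical choices made
where the underlying workflow left the design open.  Problem sizes quoted
here are the package's test defaults.

## Synthetic data and what passing tests show

Raw micrographs of the original experiments are not programmatically
available, so every stage is exercised on synthetic inputs from
`aggrescope.syndata` with recorded ground truth.  The generators reproduce
the *statistical structure* each estimator assumes, not the optics of a
microscope:

- **Detector noise** is Poisson shot noise with a gain plus additive
  Gaussian read noise (`NoiseModel`, defaults gain 1, read σ = 2 counts) —
  the standard fluorescence-camera model.  There is no PSF blur, no spectral
  bleed-through, and no realistic EM texture; those are deliberately out of
  scope.
- **Colocalization cells** are ellipses (semi-axes 45 × 35 px in a 128-px
  frame) containing Gaussian puncta (σ = 2.5 px, 12 per cell, amplitude 200
  over background 20).  A planted fraction ρ of channel-2 puncta is
  co-placed on channel-1 positions; the rest are kept ≥ 4σ away.  The
  segmented-line ROI is a seeded self-avoiding walk of 5–10 segments inside
  the cell, mimicking a hand-drawn line that covers as much of the spore as
  possible.
- **Bleach pairs** follow the quenching closed form: donor emits
  D₀(1 − E) before and D₀(1 − E(1 − b)) after a bleach of efficiency *b*;
  the acceptor drops to (1 − b) of its pre level.  Noise is applied last.
- **FRAP traces** follow I(t) = I_b + m(I_pre − I_b)(1 − e^(−kt)) with an
  optional acquisition-bleaching factor e^(−βt) applied to both halves
  (β is a generator parameter, default 0, because the magnitude of
  acquisition bleaching in the original series is not stated).  Defaults:
  180 frames at 1 s, bleach floor 0.3, noise σ = 0.02 of the pre level.
- **Nuclei** are isotropic 2-D Gaussians (amplitude 300, offset 30).
- **EM sections** are anisotropic-voxel balls rasterized into 60 nm serial
  sections at 10 nm pixels (z-scale dz/dxy = 6), non-overlapping, with
  Poisson counts per cell and class.
- **DAmFRET events** draw expression (donor + acceptor) log-uniformly over
  10² – 10⁵ with a photoconverted fraction of 0.30 ± 0.03.  Monomeric events
  scatter AmFRET around 0 (σ = 0.02, like the fluorophore-only control);
  assembled events sit at 0.30 ± 0.05.  Three regimes: `monomer_only`,
  `always_assembled`, and `assembly_above_threshold` with a planted
  expression cutpoint.
- **Screen tables** score growth 0–4; healthy scores are 3–4, failures 0–1.
  Planted hits fail only with toxin plasmids under induction;
  galactose-sick strains fail under induction with empty vectors too.
  Hit phenotypes are planted in the proportions 81:5:20 over categories
  dispersed-both / antidote-normal-poison-dispersed / low-signal.

Passing tests therefore demonstrate that the estimators are correct and
well-calibrated under their own model assumptions; they do not certify
performance on real micrographs with structured background, bleed-through,
or focus drift.

## Colocalization

Profiles are sampled at 1-px arc-length spacing with bilinear
interpolation, averaging the `width_px` perpendicular offsets centered on
the line (width 2 → offsets ±0.5 px; pixel-center convention, 0-based
coordinates, x rightward, y downward).  The shift unit is one profile
sample (= 1 px of arc length); shifts are applied in samples, range ±10 by
default, because the physical unit and range of the original analysis are
not stated.  Pearson r uses the sample definition on the overlapping
segment only — padding would bias r toward zero.  Per-cell curves are
averaged with the standard error of the mean; at least 6 cells by default.
Shifts whose overlap falls below 3 samples, or with zero variance, are
flagged and reduce n at that shift rather than contributing a silent 0.

## Acceptor-photobleaching FRET

The estimator is E = (D_post − D_pre)/D_post, the standard
acceptor-photobleaching form (it reports 40% when the donor rises from 60
to 100).  Cells are accepted only if the bleach depth 1 − A_post/A_pre
reaches 0.8; donor_post ≤ 0 excludes the cell.  Negative apparent E is
reported and flagged, not clipped — clipping would bias group means upward.
Reported range is clamped to (−0.5, 1).  Background is the mean intensity
outside the cell polygon, subtracted per channel and timepoint.

## DAmFRET gating

Expression is binned into 16 log-spaced bins; the gate in each bin is the
0.99 quantile of the control AmFRET distribution, with sparse bins (< 20
control events) widened symmetrically until populated.  Verdicts:

- *continuous-assembly* — fraction below the gate < 0.01 in every populated
  bin (no detectable monomeric population at any expression level, hence no
  rate-limiting nucleation step);
- *monomer-only* — overall fraction below the gate ≥ 0.95.  The gate is
  itself a 0.99 quantile, so a genuinely monomeric sample fluctuates around
  0.99 from both sides; requiring literally > 0.99 would misclassify about
  half of true monomer samples, and 0.95 is far above anything a partially
  assembling sample produces;
- *two-state* — otherwise; the changepoint is the expression at which the
  per-bin assembled fraction crosses ½, interpolated in log-expression.

## FRAP

Double normalization, F(t) = (bleached/reference)/(pre/reference_pre),
uses the unbleached half as reference so acquisition bleaching cancels; a
180-frame series accrues enough of it to matter.  The recovery model is a
single exponential with F₀ fixed to the first post-bleach value; m is
clamped to [0, 1]; solid-like iff m < 0.2 (configurable — the underlying
claim is qualitative).  Diffusion-equation FRAP models are out of scope:
half-punctum geometry defeats the simple closed forms anyway.

Numerical identifiability: when the fitted recovery has not plateaued
inside the series (k·T < 2), amplitude and rate are only jointly
determined — a flat noisy trace can be fit equally well by m → 1 with
k → 0.  In that regime the fitter falls back to the model-free endpoint
estimate (F_end − F₀)/(1 − F₀), which is unbiased for immobile material
and conservative for genuinely slow recoveries.

## Morphometrics

FWHM = 2√(2 ln 2)σ.  The 1-D estimator takes the background as the profile
minimum and interpolates the two half-maximum crossings flanking the global
peak (after a 3-sample smoothing pass for peak finding); both the 1-D and
the 2-D Gaussian-fit estimators are provided because the original
quantifications used each in different places.  The 2-D fit is plain least
squares with moment initialization; non-convergent or degenerate fits are
flagged and excluded from group statistics.  Group comparisons use Welch's
(unequal-variance) two-sample t-test: group sizes are unequal (e.g. 203 vs
133 cells) and no variance homogeneity is claimed.  Connectivity is 8 in
2-D and 26 in 3-D, matching the ImageJ defaults the original workflow would
have inherited.  Nuclear fragmentation calling is a threshold rule
(≥ 2 above-half-max components → fragmented; FWHM below a control quantile
→ condensed); the original scoring was by eye.

## Tile segmentation

Targets: the mask channel is true inside any ROI polygon (fill semantics —
boundary pixels belong to the object), the outline channel true on the 1-px
polygon boundary.  Tiling reflect-pads the frame so stride-multiple offsets
cover it exactly (512-px window, 50% overlap at full scale; tests use 64-px
windows).  Augmentation applies seeded uniform rotations plus translations
of at most half a stride, identically to image/mask/outline.  Normalization
is (I − MEAN)/STDEV + 0.5 over nonzero pixels, with the population (n)
standard deviation, estimated once at training time and stored with the
model.

The network is an encoder–decoder with skip concatenation: 3×3
convolutions and 2×2 max-pools double channels while halving resolution,
leaky ReLU (slope 0.1) after each convolution, nearest-neighbor ×2
upsampling followed by convolution on the way back, a 1×1 head, and a tanh
squashed to probabilities via (tanh + 1)/2, trained with MSE.  The
full-scale geometry (512-px tiles, a 32×32×512 bottleneck ⇒ depth 4, base
64) exists as a configuration; the desk default is depth 3, base 8.

Training numerics (the underlying recipe specifies "a learning rate
adjusting over time" and nothing else, so these are this implementation's
choices, made for optimization robustness):

- Adam, base rate 3·10⁻⁴, linear warmup over the first 50 iterations,
  0.999 multiplicative decay per iteration, batch 4.
- β₂ = 0.99: with the conventional 0.999 the second moment remembers the
  large warm-up gradients for ~1000 iterations and suppresses steps for
  most of a short (600–2200 iteration) budget.
- Binary targets are softened to {0.05, 0.95} before the MSE: exact {0, 1}
  targets put the optimum at tanh = ±1 (infinite pre-activation), and early
  steps then saturate units irrecoverably.
- Init selection: tanh saturation is an absorbing state (the network
  predicts background everywhere and its gradients vanish), and whether a
  run is captured depends on the initial weights.  Up to 6 candidate
  initializations are probed for 150 iterations each; the first whose probe
  loss clearly beats the best constant predictor is re-instantiated fresh
  and trained for the full budget.  Deterministic given the training seed,
  in the spirit of `n_init` in k-means.

Training halts at exactly `max_iterations` (default 2200); validation loss
over the full validation set is logged at every iteration divisible by
`validate_every` (default 100).  Retraining warm-starts from a checkpoint
and keeps its stored normalization.  Inference stitches per-tile
predictions by center priority — each pixel takes its value from the tile
in which it lies farthest from a tile border — with overlap averaging
available behind a flag, and the outer `border` pixels blanked.
Post-processing thresholds mask − outline·[subtract] at 0.5 and labels
8-connected components; outline subtraction separates touching objects at
the cost of eroding the shared boundary.

The scaled-down benchmark (depth 3/base 8, 64-px tiles, 600 iterations,
~30 training tiles from 8 annotated 96-px frames, 20 held-out frames)
reaches object F1 ≥ 0.9 and pixel IoU ≥ 0.7 on the blob fixture; the
training-schedule contract is checked at full 2200-iteration length on a
minimal (depth 1, base 2, 16-px) configuration.

## Screen triage

Growth is an ordinal 0–4 score (the original screen was scored manually;
the scale is this package's encoding) with fail threshold 1, i.e. at most
faint growth at the undiluted spot.  Stage 1 flags strains failing with
toxin plasmids under induction but growing without induction; stage 2
confirms only those that grow with empty vectors under induction, removing
strains that are galactose-sick for unrelated reasons.  Phenotype
categorization resolves overlaps in a fixed order — low-signal first
(dispersal is unscorable without signal), then antidote-normal /
poison-dispersed, then dispersed-both, else wildtype-like — so the scored
categories always partition the confirmed hits.  Enrichment is a generic
two-sided Fisher's exact test per category against the screened background
with Benjamini–Hochberg correction (significance q < 0.05); mapping genes
to curated ontology terms is out of scope, so categories are caller-supplied
labels.

## Protein-architecture bookkeeping

The antidote's N-terminal extension (45 residues of a 337-residue protein)
leaves 337 − 45 = 292 residues shared with the poison.  The C-terminal
7-residue motif (IGNAFRG) occurs as ~1.5 tandem units in the wild-type
allele; inserting 18 codons yields ⌊(1.5·7 + 18)/7⌋ = 4 complete units.
Counts are floors of total residues over the unit length.

## Known limitations

- No optical PSF, bleed-through, or compensation modeling; DAmFRET
  compensation is assumed done upstream (on-instrument).
- The FRAP model is a single exponential; reaction–diffusion kinetics and
  photofatigue beyond the reference ratio are not modeled.
- Section-to-section registration is out of scope; 3-D volumetry assumes
  pre-aligned label stacks.
- The segmentation benchmark uses well-separated soft-edged blobs; dense,
  touching, or textured objects will need the full-scale model preset and
  more annotation.
- ImageJ binary `.roi` files are not parsed; ROIs travel in a documented
  JSON schema, and cytometry events travel as CSV rather than FCS.
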