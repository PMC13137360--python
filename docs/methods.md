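# Methods

## The model

The detector treats a 2-D slice as a bag of rectangular sections and makes
the tumor/no-tumor call per section before aggregating to the image level.
The underlying assumption is that a bright lesion, however small, dominates
the upper tail of the intensity distribution of *some* section, so
range-normalized views of each section are a sufficient input
representation: the minimum-referenced view `P = (I − PD_min)/range` places
the lesion near 1, the maximum-referenced view `Q = 1 − P` near 0, and the
pair tells the classifier both where the section's extremes sit spatially
and how everything else distributes between them. The complementary pair is
deliberately redundant — the two views weight the dark and bright tails
oppositely after bilinear resizing, and the disagreement of single-view
predictions is itself an output (ρ_E, below).

This design trades boundary precision for sensitivity and speed: the
smallest decision unit is a section, but the *size* estimate ω is pixel-level
(bright pixels within flagged sections), so small lesions are both
detectable and sizeable without any dense labelling.

## Pipeline stages and their parameters

**Pre-processing.** Median filter, window 3 (radius 1), as the default
denoiser — it removes impulse noise without moving edges, which matters
because the section statistics are extrema and a single hot pixel would
saturate `PD_max`. All derived maps (Sobel edge magnitude, forward-difference
contrast maps C_H/C_V, central-difference gradient magnitude) use replicate
border padding so image borders do not create spurious responses in border
sections. Intensities are floats internally and re-quantized only on export.

**Fragmentation.** Default grid 2×5 = 10 sections; division remainders go to
the last row/column. Ten sections on a 128×128 slice gives 64×25-px
sections — large enough to carry a textured intensity distribution, small
enough that one flagged section pins the lesion to a tenth of the image.
The uncertainty score `UN_c = range / (2^bit_depth − 1)` is the gate that
makes degenerate sections undecidable: constant sections (`UN_c = 0`,
equivalently `Q ≡ 0`) are discarded outright, and the decision rule refuses
to flag any section with `UN_c < u_floor = 0.02` (5 gray levels at 8 bit) no
matter how confident the classifier is. The x/y representation maps mark
pixels within a tail fraction t = 0.05 of the section extrema; t is a
reporting convention, not a decision input.

**Classifier.** Input 32×32×2 (P, Q resized bilinearly); conv 3×3 (8
filters) → ReLU → maxpool 2 → conv 3×3 (16 filters) → ReLU → maxpool 2 →
dense 32 → sigmoid; 34,153 parameters. Adam (lr 1e-3), binary cross-entropy,
batch 32, at most 800 mini-batch iterations with early stopping on
validation loss (20% stratified split, patience 50 iterations, min-delta
1e-4). He-initialized, fully seeded. The budget of 800 iterations is
generous for this architecture: on the phantom training set it converges in
roughly 150–300 iterations.

The network is implemented directly on NumPy (im2col convolution,
hand-written backward passes, deterministic tie-breaking in max-pool).
Besides keeping the dependency surface to the scientific stack, this makes
training bit-reproducible for a fixed (data, config, seed) triple, which the
pipeline's determinism contract — identical reports on rerun — requires.

**Channel dropout and ρ_E.** During training, 15% of batch samples have
their P channel zeroed and another 15% their Q channel zeroed. This exists
for one reason: ρ_E is defined as the disagreement rate between a
P-only and a Q-only prediction pass (the other channel masked to zero), and
a network trained exclusively on joint views treats a single-view input as
out-of-distribution, saturating ρ_E at 1.0 regardless of data. With the
augmentation, single-view passes are in-distribution and ρ_E becomes a
meaningful instability measure (0.01–0.09 on phantom suites). The small
accuracy cost is absorbed by the iteration budget.

**Decision thresholds.** τ_seg = 0.5 (the natural BCE operating point);
θ_img = 0.1, i.e. a single flagged section among ten declares the image
positive — chosen for small-lesion sensitivity, since a small tumor
occupies exactly one section. Ties at either threshold flag (≥), documented
rather than configurable.

**Size estimate ω.** Bright pixels inside flagged sections, where "bright"
means above a *two-stage* Otsu threshold: the first Otsu pass on the whole
slice separates the dark air background from the head; the second pass,
restricted to supra-threshold pixels, separates tissue from the bright tail.
A single-stage Otsu on a brain-like slice lands between background and head
and would count the entire head as lesion. Connected bright components are
labelled on the whole slice and any component touching a flagged section is
counted in full, so a lesion straddling a grid line is counted exactly once
even if only one of its sections is flagged. When a pixel spacing is known,
ω is also reported in physical units (spacing² per pixel).

**Reform/cure tracking.** With a prior visit, per-section transitions are
labelled stable / new (0→1) / resolved (1→0); "reform" is any new section.
A single-image run reports presence only and marks the baseline as absent.

## Reported metrics

Accuracy, precision, recall and F1 use the standard confusion closed forms;
zero-denominator ratios are returned as flagged `None`, never NaN. Two
metrics have no universal formula and are defined canonically here:
**training rate** is the final training-set accuracy (with
iterations-to-0.9-accuracy as a secondary speed figure), and the
**analysis ratio** is the fraction of retained sections whose probability is
decisive, `|prob − 0.5| ≥ margin` with margin 0.2 — a measure of how rarely
the classifier sits on the fence. Wall-clock analysis time is recorded per
stage and reported, never asserted.

## The phantom generator

Each phantom is an elliptical head (axis fractions 0.84/0.88 of the image
half-size) of tissue at mean 110 with two noise components scaled by
`tissue_noise_sd = 6`: a smooth field (Gaussian-filtered white noise,
σ = 6 px) emulating slow anatomical intensity variation, and per-pixel
Gaussian noise. Tumors are filled rotated ellipses (axis ratio 0.6–1,
radius 4–12 px by default) with contrast 60–120 above tissue and a 1-px
Gaussian-softened intensity boundary; the *hard* ellipse rasterization is
the ground-truth mask, so masks are exact by construction. Tumors are placed
fully inside the head, never overlapping, with bounded retries (failures are
logged and skipped). Default images are 128×128 at 8 bit — large enough for
10 sections of 1,600 px, small enough that a full train-and-evaluate cycle
runs in well under a minute on one CPU. Dataset generation balances classes
exactly (`round(n · tumor_fraction)` tumor-bearing images, chosen by a
seeded shuffle).

What the phantoms do **not** emulate: MR acquisition physics (bias fields,
Rician noise), skull/CSF anatomy, multi-modal contrasts, partial-volume
boundaries, non-bright (e.g. necrotic) lesions, and 3-D continuity. Passing
the phantom suites therefore demonstrates that the pipeline's machinery —
statistics, replication, training, decision and sizing rules — is correct
and sensitive under its stated intensity model, not that the detector is
clinically validated; on real MRI the contrast distribution and tissue
heterogeneity would require retraining and plausibly a denser grid.

## Numerical choices and degenerate inputs

- Histograms use 64 fixed-width bins over the full bit-depth range, so bins
  are comparable across sections and images.
- Population (not sample) standard deviation throughout: a section is the
  complete population of its pixels.
- Constant sections define `x`/`y` maps as empty, entropy 0, skewness 0,
  centroid (0.5, 0.5); a fully constant image discards all sections and
  yields δ = 0, ω = 0, ρ_FD = ρ_E = 0 with no NaN anywhere.
- Max-pool ties resolve to the first index; batch sampling, the
  train/validation split and parameter initialization all derive from the
  configured seeds, making every training run exactly repeatable.
- The evaluation problem sizes used by `scripts/acceptance.py` — 60 training
  phantoms (600 sections), 200 evaluation phantoms over five generator
  seeds, 40 small-tumor phantoms — are the package's standing desk-scale
  study conditions; they keep a full from-scratch run under a minute while
  the pooled evaluation still has ~100 positives.

## Known limitations

- The section grid is axial and fixed; lesions much larger than a section
  are detected but their ρ_FD saturates, and radial or overlapping section
  geometries are not implemented.
- ω counts *bright* pixels, so a hypo-intense lesion would be sized at ~0
  even if flagged.
- The two-stage Otsu assumes a dark background and a brighter head; slices
  without background (tight crops) degrade to a one-stage split, which can
  overestimate ω.
- Training rate and analysis ratio are package-canonical definitions; when
  comparing against other toolkits, compare the definitions first.
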