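# Methods

## The problem being modeled

Identifying circulating tumor cells (CTCs) on a fluorescence
antibody-capture chip is a two-class image classification problem with an
extreme label budget: tumor-cell training images number in the hundreds at
best, and clinically identified CTCs in the low hundreds for an entire
patient cohort. The standard remedy is to pre-train a CNN on cultured
cancer cell lines — morphologically similar, available in bulk — and
fine-tune on the few clinical images. Whether that transfer helps, harms,
or does nothing must be established statistically, because single
train/test splits at n ≤ 20 are dominated by split noise.

This package implements the full pipeline and evaluates it entirely on
synthetic scenes with known ground truth. Synthetic data make every claim
checkable (segmentation recall against true centroids, leakage audits via
provenance ids, known domain-shift magnitude) at the price of realism;
see *What the generator does not emulate* below.

## Scene generator

Each scene is a triple of registered 8-bit rasters: blue (Hoechst,
nuclei), red (cytokeratin, tumor cytoplasm), green (CD45, leukocytes).
Cells are ellipses placed by rejection sampling (≤ 100 retries per cell;
center distance ≥ 0.8·(r₁+r₂); unplaceable cells are reported as omitted,
never dropped silently). Tumor cells paint blue nucleus + red over the
cell footprint (nucleus dilated by the cytoplasm ring width); leukocytes
paint blue nucleus + green footprint. Gaussian noise (clipped to [0,255])
is added last; an optional linear illumination gradient attenuates signal
left to right.

Defaults were chosen once, on biology and typical chip imaging:

| parameter | default | rationale |
|---|---|---|
| nucleus radius (tumor) | 7 ± 1 px | CTCs 12–25 µm at the synthetic scale |
| leukocyte radius factor | 0.7 | leukocytes 7–12 µm, smaller than CTCs |
| blue intensity | 200 ± 20 | bright nuclear stain, SNR ≈ 38 over background |
| red intensity | 200 ± 15 | cytokeratin bright in tumor cytoplasm ("pink" phenotype) |
| green intensity | 120 ± 15 | CD45 clearly positive but dimmer than CK |
| background / noise sd | 10 / 5 | clean chip background |

The cell-line and clinical populations share one renderer; `ShiftSpec`
multiplies radii and intensities, bounds ellipse eccentricity, and adds
noise when the domain is clinical. The identity shift renders the two
domains bit-identically — a tested invariant. One master seed spawns
independent substreams for placement, intensity and noise, so changing
one knob perturbs only its own stream.

## Segmentation

Cell localization uses only the nuclear channel: Otsu's threshold
(vectorized 256-bin scan; foreground = pixel > t; ties broken toward the
lower threshold; constant images yield an empty mask with a degenerate
flag), 8-connected components gated to [20, 2000] px² of area, sorted by
centroid. Fixed 32 px windows centered on each component centroid are cut
identically from all three channels (zero-padded at borders), so the red
and green content of a cell travels with its nucleus. The classifier
input is a single brightness composite, clip(Σ wᵢ·channelᵢ, 0, 255)
min-max normalized to [0,1], equal weights by default (weights are
config-exposed and recorded in run metadata); a raw tri-channel input
mode exists behind a config flag for ablation. No rule-based CD45
exclusion is applied before classification — all segmented cells go to
the CNN, which learns the distinction.

The Otsu implementation is hand-written rather than delegated to
scikit-image because the mask convention, tie-break direction and
degenerate handling are part of the module contract; scikit-image serves
as an independent cross-check in the tests, and an exhaustive-scan oracle
enforces exact agreement.

## Augmentation

Rotation (uniform in [0, 360°]; exact right angles use pure pixel
permutation), horizontal/vertical flips at probability 0.5 each, scaling,
additive brightness (uniform ±δ), multiplicative contrast about the patch
mean, and integer translations (≤ 3 px default). Transforms are applied
in that fixed order with bilinear interpolation and zero fill. Applied to
training splits only — never to test data — and each augmented crop keeps
its ancestor's provenance id, which the evaluation protocol audits.
Augmentation is available in both training phases (pre-training and
fine-tuning), switchable in config.

## Model and training

Default architecture (fully config-driven; any alternate is a YAML edit):
input 32×32×1 → conv(16, 3×3, ReLU) → maxpool 2 → conv(32, 3×3, ReLU) →
maxpool 2 → dense(64, ReLU) → dropout 0.25 → dense(2, softmax); ~79k
parameters, float32 throughout. Training is SGD with momentum 0.9 at
learning rate 0.001 on cross-entropy — fixed hyperparameters of the
recipe — with the epoch count and sampling mode as the enumerable axes
(epoch grid {2, 6, 12, 25, 50, 100, 300}; an optional grid-search runner
accepts user-supplied grids for learning rate, batch size and dropout).
The forward/backward passes are implemented in numpy (im2col convolution,
argmax-routed pooling gradients, inverted dropout), verified against
finite differences in the tests; two identical seeded runs produce
identical parameter trajectories.

The balanced-minibatch sampler builds every batch exactly half-and-half:
the majority class is swept once per epoch, the minority reshuffled and
reused with replacement, giving ceil(2·majority/batch) batches and an
epoch-level class ratio of exactly 0.5. It is the pre-training device
against the ~1:3.4 tumor:healthy imbalance; fine-tuning defaults to plain
full-pool minibatches because transfer sets may be a single image (a
single class), where balancing is undefined — the sampler falls back
automatically in that case.

Fine-tuning copies the pre-trained model and continues training **all**
layers (a freeze-feature-layers option exists, off by default). Zero
epochs or zero examples return the initialization unchanged; non-finite
loss aborts with a diagnostic.

## Evaluation protocol

The clinical pool is first class-matched: all positives plus an
equal-size seeded random subsample of negatives (mirroring the
201-CTC-vs-201-random-non-CTC design that prevents accuracy inflation).
Each replicate then draws a stratified train split of n images
(ceil(n/2) positives — the scarce class gets the extra odd image — and
floor(n/2) negatives), trains under its condition, and scores accuracy on
the entire held-out remainder. Conditions: *transfer* (fine-tune the
pre-trained model), *scratch* (same split, random initialization),
*pretrain_only* (no clinical training). 100 replicates per (condition, n)
by default, scalable in config. Replicate seeds derive from
(master seed, condition, n, replicate), so any cell reproduces in
isolation. Train/test disjointness is asserted on every replicate over
provenance ids *including augmentation ancestors*.

Welch's unequal-variance t-test compares condition pairs per n:
t = (x̄−ȳ)/√(s²ₓ/nₓ + s²ᵧ/nᵧ), Welch–Satterthwaite degrees of freedom,
two-sided p, α = 0.05. The two samples entering each test are the
per-replicate accuracy lists of the two arms. Both-variances-zero edge
cases: equal means give t = 0, p = 1; unequal means are flagged as a
degenerate infinite-t result with p = 0 and df = nₓ+nᵧ−2 by convention.
No multiple-comparison correction is applied across the n grid by
default (an optional Holm adjustment is provided and logged when used).
`min_n_significant` scans n ascending and returns the first cell whose
comparison arm has both the higher mean and p < α.

## The fixed benchmark

`ctcvision.benchmark.run_transfer_benchmark`: pre-train on 800/800
cell-line crops (25 epochs, balanced minibatches), fine-tune 50 epochs
with 2× flip/rotation augmentation on n ∈ {2, 5, 10, 20} clinical-like
images, 20 replicates per cell, test on the ~200/200 held-out remainder
of a clinical pool rendered with shift radius_scale = 1.3,
intensity_scale = 0.7, extra_noise = 10. The shift moves absolute cell
size and contrast — exactly the cues a cell-line-only model keys on
(clinical leukocytes at 1.3× approach the size of cell-line tumor
cells) — while leaving the class structure intact, so pre-training
transfers but is measurably miscalibrated until fine-tuned. These sizes
keep a full run around three minutes on one CPU while leaving the three
qualitative findings (transfer beats scratch, most at small n; fine-tuning
beats pretrain-only; no harm at large n) clearly resolvable at 20
replicates.

## What passing tests do and do not show

The generator produces hard-edged ellipses with stationary Gaussian
noise, perfectly registered channels and exactly two cell classes. It
omits point-spread blur, autofluorescence, debris and staining artifacts,
cell clusters and touching-nucleus splitting, focus drift, and the
patient-to-patient heterogeneity of real CTCs; the domain shift is a
four-parameter caricature of that heterogeneity. Results here validate
the *machinery* — segmentation correctness, sampler balance, transfer
benefit under a controlled shift, statistical protocol — not clinical
accuracy figures, which depend on data this package deliberately does not
claim to model.

## Numerical and design notes

- 8-bit channels, top-left origin, x right / y down, 0-based indices.
- Otsu ties toward the lower threshold; mask is strictly greater-than.
- Pooling drops a trailing odd row/column (32 → 30 → 15 → 13 → 6).
- Prediction ties resolve to class 0 (non-tumor).
- Dataset generation trims the overrepresented class (from the end,
  deterministically) to hit the requested imbalance ratio, because small
  leukocytes merge into neighboring components slightly more often than
  tumor cells.
- The epoch grid is exposed as data, not hard-coded; the training
  ``iteration`` count (default 20 repetitions for pre-trained model
  selection) is likewise a config field.
- CSV I/O uses round-trip float parsing; scene TIFF/PNG round-trips are
  bit-exact and tested.
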