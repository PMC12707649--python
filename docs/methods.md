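# Methods

## The task and the model

A constellation stimulus hides an object outline as dots: contour dots are
sampled at a fixed arc spacing along the outline, and distractor dots are
scattered uniformly with a minimum separation. The solver never sees the
outline — only a 160×160 single-channel raster and the dot coordinates.
Identification is treated as analysis-by-synthesis: candidate images are
generated top-down from a latent code, scored bottom-up by how well their
edge contours fit the dots, and the latent code is refined by search.

Two search variants share the generator and the scoring:

* **Evolutionary search.** A population of latent vectors is drawn from
  the standard-normal prior. Each generation, candidates are decoded,
  scored, and ranked; the top K become parents; offspring are built by
  copying a uniformly chosen parent, applying uniform crossover with a
  second parent with small probability, then perturbing each gene
  independently with probability `mutation_rate` by an additive uniform
  [−1, 1] kick. Parents carry over unchanged (elitism), so the best
  fitness is non-decreasing and the stopping rule — no improvement for
  `patience` consecutive generations — is well defined. The final label
  comes from a classifier applied to the best generated greyscale image,
  never to its edge map.
* **Gradient descent (ablation).** A single latent is optimised on a
  differentiable surrogate: the dots become a Gaussian heatmap
  H(x,y) = Σᵢ exp(−((x−xᵢ)²+(y−yᵢ)²)/(2σ²)) with σ = 3 px; the candidate
  becomes a Sobel edge-magnitude map E; the loss is ℒ = −Σ H·E over the
  pixels where H exceeds a small cutoff. The learning rate follows a
  triangular schedule (linear warm-up to the peak at mid-run, linear decay
  back). The final image is always re-scored with the non-differentiable
  structural fitness so both variants are compared on the same metric.

## Structural fitness

1. The candidate (greyscale, upscaled bilinearly from the generator's
   64×64 to the stimulus resolution) is edge-detected with Canny
   (hysteresis thresholds 100/200 on a 0–255 intensity scale, Gaussian
   σ = 1). The binary edge map is thinned to one-pixel width before
   tracing: non-maximum suppression leaves doubled pixels on staircase
   diagonals which would otherwise inflate arc lengths by ~20 %.
2. Edge pixels are ordered into 8-connected chains. Chains start at
   endpoints when one exists and at the lowest scan-order pixel for
   loops; junctions split the edge set into several chains, each pixel
   used once; the walk prefers 4-neighbours over diagonals in a fixed
   order, so tracing is deterministic.
3. A dot matches when its Euclidean distance to the nearest contour point
   is strictly below `edge_threshold` (default 3 px); ties go to the
   lowest contour index.
4. On each contour, matched dots are sorted by arc position; a dot
   contributes to the score when its arc-length gap to an adjacent
   matched dot on the same contour is strictly below `link_threshold`
   (default 40 px). Closed contours wrap the gap around; a contour's sole
   matched dot never contributes. The score is the number of contributing
   dots. Measuring the 40-px link along the contour (rather than as
   straight-line distance between dots) reflects the rule's purpose —
   penalising overly long drawings, a path-length property — and a
   `link_metric="euclidean"` switch provides the other reading.

## Parameter defaults

| Parameter | Default | Meaning |
|---|---|---|
| stimulus size | 160×160 px | raster resolution |
| spacing (difficulty) | 11 px | inter-dot arc distance; 10 in the toy benchmark |
| noise ratio | 0.5 | distractors = round(ratio × contour dots) |
| min separation | spacing/2 | closest allowed dot pair |
| dot radius | 1.5 px | rendered disc radius |
| edge_threshold | 3 px | dot-to-edge match tolerance (strict <) |
| link_threshold | 40 px | max arc gap between adjacent matched dots |
| population / parents | 1000 / 200 | evolutionary search (200/40 in the desk-scale benchmark) |
| mutation / crossover rate | 0.5 / 0.01 | per-gene / per-offspring |
| max generations / patience | 30 / 5 | generation cap and stall limit |
| batch size | 100 | fitness-evaluation chunk (no effect on results) |
| heatmap σ | 3 px | gradient-variant target width |
| iterations / base_lr / max_lr | 300 / 0.01 / 0.1 | gradient-variant schedule |
| mask ε | 1e−4 | heatmap support cutoff |
| coverage margin | 3 px | dots-covered metric |

The gradient step is divided by the stimulus's total masked heatmap mass,
which makes the learning-rate schedule scale-free (a given rate moves
genes by comparable amounts regardless of how many dots a stimulus has);
the reported loss is the raw masked dot product.

## The toy generator and what the tests show

The parametric toy family maps 8 genes through `tanh(z/3)` to a filled
superellipse: centre (±12 px), two log-radii around 14 px, rotation,
squareness exponent, and two boundary harmonics (3-fold and 4-fold,
amplitude ≤ 0.35). The boundary is rendered as a sigmoid of the signed
radial distance (steepness 1.5/px), so the mapping is smooth and
differentiable everywhere the search goes. The gene scale 3 is chosen so
a one-unit gene change moves boundary pixels by roughly the 3-px match
tolerance: unit-sized mutation kicks then straddle the scale at which the
fitness responds, and search moves remain informative from coarse
exploration to final refinement.

Five canonical latents define categories (circle, square, ellipse,
trefoil, clover), classified by a nearest-template classifier (softmax
over negative squared pixel distances; an exact template match scores 1).
Planted stimuli jitter the canonical genes (σ = 0.75 gene units) for
within-category variability; because a large jitter can carry a latent
across a category boundary — a heavily deformed circle genuinely is a
weak trefoil — jittered draws are re-sampled until the rendered shape
still classifies as its nominal category, so the stimulus depicts the
label it is scored against.

What the toy family emulates: a smooth, low-dimensional generative space
over closed object-like shapes, with category structure and a planted
optimum whose drawing exactly fits the contour dots. What it does not:
the high-dimensional, learned, imperfect manifold of a trained GAN —
multi-part objects, interior texture edges, mode gaps. Passing the
planted-recovery tests therefore shows the search machinery works when a
fitting solution exists in the space; it does not bound performance on
natural image families, where the paper-scale pipeline (the trainable
convolutional generator with latent dimension 256) applies.

## Convolutional generator

The trainable generator is the standard four-deconvolution stack
(dense 4×4×8f, then stride-2 transposed convolutions to 64×64, batch
normalisation and ReLU between layers, tanh output rescaled to [0, 1]),
against a four-convolution discriminator with leaky ReLU and batch
normalisation, trained with Adam (2e−4, β₁ = 0.5) and one-sided label
smoothing (real target 0.9). Training, like the rest of the package, runs
on the in-repo autodiff core, is deterministic under a seed (bit-identical
checkpoints), and is intended for desk-scale experiments; matching
full-dataset GAN sample quality is a non-goal.

## Numerical choices and edge cases

* Coordinates are (x, y) = (column, row), 0-based, floats; rendering
  rounds to the nearest pixel. Dot extraction returns connected-component
  centroids, recovering rendered coordinates within 0.5 px per axis.
* Contour arc positions are naive polyline sums, as contracted. Where a
  test needs an unbiased length of a digitised smooth curve it uses the
  corrected chain-code estimator (0.948 per straight step, 1.343 per
  diagonal), which removes the ~6–12 % staircase bias.
* IOU of two empty coverage sets is 1.0 (perfect agreement on "nothing");
  IOU(mistakes) with no mistakes on either side is undefined and excluded
  from averages rather than imputed.
* Confusion-matrix correlation drops cells that are zero in both
  matrices; fewer than two retained cells, or zero variance after
  filtering, raises an undefined-correlation error instead of returning a
  number.
* Distractor placement uses bounded rejection sampling and raises a
  capacity error when the separation constraint cannot be met.
* Raster drawings are skeletonized to 1-px strokes before the coverage
  metric so stroke width does not inflate coverage (configurable).
* Sobel magnitude √(Gx²+Gy²) defines its gradient as 0 where the
  magnitude is 0 (constant regions), keeping backpropagation finite.
* Fitness evaluation is chunked (default 100 candidates); scoring is
  deterministic, so chunking cannot change results. Parent fitness is
  cached across generations for the same reason.
* With elitism disabled (`elitism=False`, the literal
  offspring-only reading of population replacement), the best fitness may
  drop and the stall rule then measures "no new best", still terminating.

## Desk-scale problem sizes

The bundled benchmark and the acceptance script run the toy problem at
population 200 / 40 parents over at most 30 generations, 10 stimuli, one
CPU — the package's reduced problem size for self-contained runs; all
method constants (tolerances, rates, schedules) keep their full-scale
values. The comparison report they emit (per-method accuracy, mean dots
covered, mean IOU against ground truth) is a qualitative mirror of the
full study's genetic-vs-gradient contrast, not a reproduction of its
numbers, which require externally trained generators and human data.

## Known limitations

* The toy categories are far more separable than MNIST digits; toy
  accuracy is therefore optimistic relative to paper-scale accuracy.
* The contour tracer splits at junctions rather than resolving crossings,
  so a single stroke crossing itself scores as several contours.
* The gradient variant optimises one trajectory per restart; on the
  narrow toy manifold it is noticeably weaker than the evolutionary
  search on both accuracy and dots covered, whereas at paper scale the
  published contrast is low accuracy but high dot coverage. The benchmark
  reports whatever direction it measures.
* Canny thresholds follow an 8-bit OpenCV-style convention mapped onto
  scikit-image's gradient-magnitude semantics; other edge-detector
  dialects will shift absolute fitness values slightly.
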