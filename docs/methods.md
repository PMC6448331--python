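# Methods

This note records the model, the conventions the implementation fixes
where the method description leaves room, and what the synthetic
generator does and does not emulate.

## Pipeline model and assumptions

The pipeline assumes whole images are photographed from lesion tissue,
so (i) every parent patch of an image shares the image's label during
training (no patch-level annotation exists), and (ii) most patches of
an image are class-typical — the assumption behind distance-matrix
weighting (DMW), which up-weights patches close to the image's feature
consensus. Both assumptions fail for images containing large normal
regions; a lesion-masking step would be needed there and is out of
scope.

Classes are ordered alphabetically (CLL, FL, MCL) in every score
vector, table and report. The train/test split is stratified at the
image level: all patches of an image stay on one side, preventing
patch-level leakage. Images of the same patient case can still fall on
both sides; with case identifiers available, splitting by case would
be stricter.

## Colorimetry

The RGB→XYZ step uses the classic BT.709-primaries/D65 matrix; its row
sums equal the white point (0.950456, 1.0, 1.088754), so pure white
maps to L = 100, a = b = 0 exactly. sRGB gamma linearization is
applied by default (standard colorimetry; `gamma=False` / `--no-gamma`
gives the naive linear reading). The piecewise cube-root uses the
canonical threshold (6/29)³ with the linear branch
(1/3)(29/6)²·t + 4/29. Conversions agree with scikit-image's
`rgb2lab` to well under 0.5 units per channel; the Lab histograms clip
a/b to [−128, 127] before binning, matching the nominal channel
ranges (sRGB inputs never actually exceed them).

The blue-ratio image is unbounded above (pure blue maps to 25500), and
downstream texture/statistics operators expect 8-bit gray, so each BR
image is min–max rescaled to [0, 255] per image with
round-half-to-even; a constant image maps to zeros. Per-image
rescaling makes the texture features invariant to global stain
intensity but ties the scale to the image's own extremes — an
alternative (fixed clipping) would preserve absolute intensity
information at the cost of saturation.

## ULBP conventions

The uniform-LBP histogram is implemented here (vectorized over the
patch) because several conventions must be pinned for reproducibility
and are checked bin-exactly against a brute-force per-pixel oracle in
the tests:

* neighbors are sampled counter-clockwise starting at angle 0,
  position (−r·sin θ, r·cos θ), bilinear interpolation at non-lattice
  positions, near-integer coordinates snapped;
* a neighbor scores 1 when ≥ the center (with a 1e−6 tolerance
  absorbing interpolation round-off; `strict_gt=True` switches to the
  literal "greater than" reading — under ≥ a constant patch lands in
  the all-ones uniform pattern, under > in the all-zeros one);
* bit k carries weight 2^k; uniform codes (≤ 2 circular transitions)
  occupy bins in ascending code order, one trailing bin pools all
  non-uniform codes, giving p(p−1)+3 = 59 bins for p = 8;
* histograms are normalized to sum 1 over valid interior pixels, so
  features are patch-size invariant.

Inside the pipeline the code image is computed once per parent patch
and sliced per subpatch; this is exact because a subpatch-interior
pixel's neighborhood lies entirely inside the subpatch.

## Statistics and aggregation conventions

Gray statistics use the population standard deviation and
linear-interpolation percentiles (so do the parent-level p10/p90
blocks). Parent vectors concatenate (mean, std, p10, p90) blocks in
subfeature order. The Lab "color histogram" is read as the 85 raw bin
values per channel — the only reading consistent with 170 dims per
subpatch.

DMW degenerate cases: m = 1 returns weight [1.0] (the defining sum
divides by m−1); identical patches return uniform weights; a zero mean
distance is clamped to 1e−12 times the largest pairwise distance,
which preserves the symmetry-forced uniform limit. The diagonal
d_kk = 0 term is included in the mean-distance sum with the m−1
divisor, as defined. Majority-voting ties break to the lowest class
index (deterministic beats random).

Inside the pipeline, DMW features are the same set fed to that path's
classifier (F1 features for the F1 path, F2 for the fused C3 path,
embeddings for the deep path), z-scored per dimension over the image's
patches before distances so heterogeneous scales don't dominate;
`dmw_standardize=False` / `--dmw-no-standardize` restores raw
Euclidean distances. Standardization does not change the pure-op
worked examples (uniform scaling cancels in the weight ratios).

## Deep path

The deep path's contract is a fixed-width embedding per RGB patch plus
a softmax head trained by seeded minibatch SGD (constant learning
rate 0.001, batch 100 by default) on standardized embeddings — i.e.
only the new head is fit, the backbone stays frozen. The default
`mock` backend is a deterministic stand-in: patches are mean-pooled to
16×16×3 and projected by a fixed seeded Gaussian matrix to 2048 dims.
It preserves coarse color/density information (enough for the
synthetic classes) but learns nothing; the `pretrained` backend slot
(Inception v3 pre-logit 2048-d pooled activations, the only 2048-wide
layer) requires torchvision weights and is optional.

## Synthetic generator

Each image is an eosin-pink background (shared across classes,
RGB (240, 185, 205)) with Gaussian pixel noise (sd 8) and elliptical
nuclei placed by a Poisson process. Class parameters (blobs per 10⁴
px, semi-axis range, nucleus RGB):

| class | density | radius | nucleus color | extra |
|-------|---------|--------|---------------|-------|
| CLL   | 16.0    | 3–4    | (60, 40, 150) | —     |
| FL    | 6.0     | 4–6    | (90, 50, 140) | 80% of nuclei cluster into follicle-like disks (radius ≈ 70 px) |
| MCL   | 1.5     | 6–9    | (110, 60, 120)| —     |

Densities and radii are set so nuclear coverage × nuclear blue-ratio
decreases strictly CLL > FL > MCL; the mean blue-ratio therefore ranks
the classes in density order, and each feature family is individually
informative: blob density/size drive r_LBP and r_sta, nucleus hue
drives r_Lab, spatial clustering adds an FL-specific texture cue. All
randomness flows through one `numpy` generator seeded per
(image seed, class index); no global state.

What the generator does **not** emulate: real nuclear morphology and
chromatin texture, stain variability between laboratories, overlapping
cell architecture, compression artifacts. Passing the end-to-end tests
therefore demonstrates that the pipeline machinery is correct and that
the feature families respond to their intended axes — not that the
reported synthetic accuracies transfer to real slides.

## Problem sizes and defaults

Unit tests run on 150–200 px images with s1 = 100. The end-to-end
standard uses 10 training + 5 test images per class at 600×600 with
all reference defaults (s1 = 200, s2 = 50, r_o = 0.5, 200 trees,
w_P = 0.7) over three seeds — large enough that each image contributes
9 parent patches and aggregation is non-trivial, small enough to keep
a full run near a minute. With the default well-separated class
parameters both patch- and image-level accuracy typically saturate at
1.0; shrinking the inter-class parameter gaps in `SynthConfig`
degrades accuracy and exposes the patch→image improvement that
aggregation provides.

## Known limitations

* The stride rule `round(s2·(1−r_o))` raises for configurations that
  round to zero rather than flooring to 1; the reference settings
  never hit this.
* Precision for a never-predicted class is reported as 0 with a
  warning (common convention); per-class values for a class absent
  from the ground truth are reported as missing, not 0.
* The overall AUC is the unweighted macro average of the three
  one-vs-rest AUCs; micro-averaging is available behind a flag.
* The CLI `predict` verb covers the handcrafted modes C1–C3; the deep
  modes C4/C5 are available through `run-all` and the Python API,
  which can recompute embeddings in memory.
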