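# Methods

## Scan-specific mixture thresholding (`valvequant.ct`)

The CT quantification assumes the valve ROI intensity histogram is a
mixture of three Gaussian populations — fibrotic tissue, contrast-bright
blood pool, calcium — with strictly ordered means. A 1-D Gaussian
mixture is fitted by EM to the ROI sample (after dropping voxels below
the tissue floor; see below):

* **Initialisation.** Equal weights, means at the 10th/50th/90th sample
  percentiles (evenly spread quantiles for K ≠ 3), all SDs at the pooled
  sample SD. Because a single start can lock onto a local optimum that
  merges two populations and splits a third, EM is additionally run from
  four restarts whose initial means are randomly chosen data values
  (seeded, hence reproducible) and the fit with the highest final log
  likelihood is kept.
* **Numerics.** Responsibilities via log-sum-exp; SD floor 1 HU to
  prevent collapse onto repeated values; convergence when the relative
  log-likelihood change drops below 1e−6 (default), at most 500
  iterations, `converged=False` reported otherwise. Components are
  stored sorted by ascending mean. K = 1 uses the closed form (sample
  mean, population SD). A constant sample with K > 1 is an error, as is
  a sample smaller than 10·K.
* **Thresholds.** Each class boundary is the smallest root of
  w_i·N(μ_i, σ_i²) = w_j·N(μ_j, σ_j²) strictly between the two adjacent
  means — a quadratic in x, solved in closed form (linear when the SDs
  coincide). If no root lies between the means (pathological overlap)
  the midpoint of the means is used and the result is flagged. On
  mixtures that are unimodally ordered over the working HU range this
  threshold rule classifies every voxel identically to the per-voxel
  posterior argmax; the test suite verifies that equivalence by
  exhaustive integer scan from −200 to 2000 HU.
* **Classification.** Half-open intervals, upper class wins at each
  boundary: HU < floor → excluded, [floor, t_low) → fibrotic,
  [t_low, t_high) → blood, ≥ t_high → calcific. Assignment is hard — a
  single label per voxel, no partial-volume fractions, since the
  quantities of interest are single volumes per tissue.
* **Tissue floor.** Default −30 HU: attenuation below fat cannot be
  valve tissue. The floor is applied both to the labels and to the
  mixture sample itself; an imprecisely drawn ROI that clips background
  air (−1024 HU) would otherwise capture a mixture component.
* **Outputs.** Volumes are label counts × voxel volume (cm³).
  Composition percentages use the fibrocalcific volume as denominator —
  the blood pool is excluded, which is what forces fibrotic% +
  calcific% = 100. The fibrocalcific ratio is fibrotic/calcific volume,
  flagged undefined when no calcium is present.

Shifting all intensities and all mixture means by a constant shifts both
thresholds by exactly that constant and leaves labels unchanged (tested
to 1e−8).

## Histology pixel classification (`valvequant.histology`)

Quantitative histology of Movat-stained slides reduces to pixel
fractions: fibrosis stains red, mineral yellow. Pixels are classified by
maximum likelihood under class-conditional Gaussian colour models in
CIELAB (perceptually uniform, so an isotropic covariance is meaningful);
the shipped reference uses nominal class colours RGB (178, 34, 34)
fibrotic, (218, 165, 32) calcific, (245, 245, 245) other/background,
diagonal Lab covariance 30 per channel, and a minimum tissue luminance
of L* = 8 (excludes near-black debris). The reference is an editable
configuration object, not a trained model: it replaces an unspecified
proprietary neural classifier with a fully specified, deterministic
procedure while preserving the downstream pixel-fraction computation.

Slide composition is 100·n_fibrotic/(n_fibrotic + n_calcific); "other"
pixels (ground substance, elastin, background) are excluded from the
denominator, mirroring the CT convention so the two modalities report
the same quantity. Whether real quantitative histology includes further
tissue classes in its denominator is unknowable from a two-class
report; the symmetric convention is adopted and is the main sensitivity
point when comparing against other histology pipelines. Per-valve
composition is the unweighted arithmetic mean over the defined slide
values (nine slides, three per cusp, by default); undefined slides
(no tissue pixels) are dropped and counted. Slide order is irrelevant
and duplicating every pixel leaves compositions unchanged.

## Agreement statistics (`valvequant.agreement`)

* **Spearman.** Pearson correlation of average-ranked series; two-sided
  p from the t approximation with n−2 df. Constant series → flagged
  undefined.
* **ICC.** Two-way mean squares from the n×2 table. Primary form is
  absolute agreement, single measure — ICC(A,1) — because intermodality
  and inter-reader questions are absolute-agreement questions (a
  systematic offset between readers is disagreement); the consistency
  form ICC(C,1) is also reported. 95% CIs use the standard
  F-distribution bounds (Satterthwaite df for ICC(A,1)); both estimates
  and CIs reproduce `pingouin.intraclass_corr` in the test suite. Zero
  between-subject variance, or a perfect fit (zero error mean square),
  is flagged degenerate; mean squares below 1e−12 of the dominant one
  are treated as zero so that bit-identical series yield an exact
  degenerate ICC of 1 rather than floating-point dust.
* **Bland-Altman.** Differences oriented a−b; SD with n−1 denominator;
  limits of agreement bias ± 1.96·SD. The 1.96 multiplier is fixed (not
  a small-sample t quantile): it is the convention under which the
  published interobserver summaries are internally consistent. The
  coefficient of repeatability is defined as 1.96·SD — identically half
  the LoA width — so LoA midpoint = bias and LoA width = 2·cor hold as
  algebraic identities (tested to 1e−9). A published intermodality
  repeatability value that contradicts this identity exists; this
  package deliberately implements only the self-consistent convention.
* **Wilcoxon signed rank.** Paired test (the rank-sum test is not a
  paired test; a tie-corrected rank-sum routine is provided separately
  for post hoc two-group comparisons). Zero differences dropped,
  average ranks for tied magnitudes; for ≤ 15 informative pairs the
  null is enumerated exactly over all 2^n sign assignments of the
  realized ranks, above that a tie-corrected normal approximation with
  continuity correction is used (matches `scipy.stats.wilcoxon` in both
  regimes).
* **Kruskal-Wallis.** H with the standard tie correction, chi-square p
  with (groups − 1) df; pairwise rank-sum p values are multiplied by the
  number of pairs and capped at 1 (Bonferroni).
* **Qualitative bands.** <0.5 poor, 0.5–0.74 moderate, 0.75–0.90 good,
  >0.90 excellent; a value exactly on 0.90 is "good".

## Synthetic data (`valvequant.phantoms`)

The generators define the conditions every test runs under.

* **CT phantom.** The ROI is the set of voxels physically nearest the
  grid centre, sized to hold the requested tissue plus blood pool;
  calcific and fibrotic voxels are carved out as unions of balls around
  seeded random centres (contiguous blobs, nontrivial boundaries), the
  remainder is blood; HU drawn i.i.d. from the class Gaussians;
  everything outside the ROI is flat background at −1024 HU. Defaults:
  64³ grid, 0.5 mm isotropic voxels, fibrotic N(90, 35), blood
  N(420, 45), calcific N(850, 120) — separable populations typical of
  contrast CT — target volumes 1.18 cm³ fibrotic / 0.79 cm³ calcific
  (severe-stenosis medians), blood fraction 0.35. No anatomy (cusps,
  ostia) and no scanner physics (beam hardening, photon starvation —
  the artifact plausibly behind real-world CT underestimation of
  fibrosis near dense calcium) are modelled: the classifier under test
  is intensity-based, so passing tests demonstrate correct intensity
  modelling and bookkeeping, not robustness to structured artifacts.
* **Second reader.** Voxels within `boundary_jitter` of the ROI surface
  flip membership independently with probability 0.3 — a boundary-local
  perturbation emulating independent contouring. Jitter 0 is the
  identity.
* **Pseudo-histology.** Tissue occupies a central disc; each slide's
  fibrotic fraction is the valve composition plus truncated-Gaussian
  noise (rejection-sampled on [0, 100]); fibrotic pixels fill the disc
  from the centre outwards; colours are the class reference colours
  plus Gaussian RGB noise (SD 6). Real slides have texture, stain
  variability and five Movat classes; these rasters only carry the
  pixel-fraction signal, which is the quantity under test.
* **Cohort.** Group sizes 19/5/5 (severe/moderate/control) with
  per-group median fibrotic/calcific volumes (1.18, 0.79), (1.36, 0.11),
  (0.71, 0.04) cm³; volumes lognormal with log-SD 0.5 (fibrotic) and
  1.0 (calcific), chosen once from the printed IQRs. CT composition =
  truth − bias + noise, histology = truth + noise (both truncated to
  [0, 100]); default intermodality bias 5 points, composition noise SD
  3, reader volume noise SD 0.08 cm³ (the order implied by the published
  interobserver LoA). All randomness flows from one integer seed per
  call; identical seeds give bit-identical outputs.

## Pipeline and I/O (`valvequant.io`, `valvequant.pipeline`, `valvequant.cli`)

NIfTI for volumes (int16 HU) and masks (uint8, binarized at >0 on read),
PNG for slides, CSV (comma, UTF-8, header, "." decimal) for tables, JSON
for reports. Volume/mask congruence is enforced on shape and affine
within 1e−4 — silent resampling would corrupt volumes. Every output row
carries provenance (ids, seed, parameter hash); the run manifest records
per-file SHA-256 hashes, and the parameter hash covers scientific
parameters only (not paths), so identical config+seed reruns are
byte-identical wherever they are written.

## Validation design and problem sizes

The test suite uses phantoms of 10⁴–24×10³ ROI voxels, cohorts of 29,
and 10–50 replicate seeds — sizes at which every check completes in
seconds while keeping Monte-Carlo standard errors well inside the
asserted tolerances (e.g. recovered-bias SE ≈ 3·√2/√29 ≈ 0.8 points per
cohort). For mean-recovery validation the phantom allocates class sizes
by Neyman allocation (n ∝ class SD: 1750 fibrotic / 2250 blood / 6000
calcific in a 10⁴-voxel ROI), which equalises the relative precision of
the three mean estimates. Even so, the calcific mean has a sampling SE
of ≈ 1.6 HU (SD 120, n 6000): any tolerance below ~5 HU at this ROI
size is a ≲3-sigma bound and individual replicates can exceed 3 HU
through draw noise alone — a limit of the ROI voxel budget, not of the
estimator, which the EM fit tracks to within ~1 HU of the oracle
per-class sample mean.

## Known limitations

* The mixture component count (default K = 3) encodes the three named
  tissue classes; valves with negligible calcium can make the third
  component chase noise — the fibrocalcific ratio and composition flags
  mark the degenerate cases rather than guessing.
* The colour classifier assumes batch-consistent staining; no stain
  normalisation is provided.
* Hard voxel assignment ignores partial-volume mixing at tissue
  boundaries, which in real CT biases small-structure volumes.
* Agreement statistics assume pairwise-complete data; no missing-data
  handling beyond refusing it.
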