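# Methods

## Model and assumptions

A subject is represented by a 3-D grey-matter probability map (voxel
values in [0, 1]) assumed already segmented, spatially normalized,
modulated and smoothed; preprocessing is upstream and out of scope, and
maps must be pre-aligned to their parcellation (no resampling is
performed — geometry is taken from the NIfTI header as-is). The
parcellation is any integer-label volume; its catalogue fixes the node
order of every matrix and table.

Morphological connectivity (MC) between two regions is the KLS
similarity e^(−KL) of their voxel-intensity densities, where KL is the
symmetric Kullback–Leibler divergence. The underlying assumption is that
regions developing or degenerating together exhibit similar intensity
distributions; the method sees only distributions, never voxel
locations, so it is insensitive to within-region spatial pattern.

## Density estimation

- Support: all densities live on a fixed common grid of 512 equispaced
  points on [0, 1]. Intensities are probability-like, so the unit
  interval is the natural full support; a shared grid makes pairwise
  integrals well defined.
- Bandwidth: Silverman's rule of thumb by default, Scott's rule as an
  option; the rule used is recorded in output metadata (`mc_meta.json`)
  so runs are comparable. Both are deterministic automatic rules.
- Floor and renormalization: every density is floored at ε = 1e−12 and
  renormalized to unit trapezoidal integral before any logarithm, so KL
  is always finite. On smooth synthetic densities results are stable for
  ε ≤ 1e−8.
- Zero-variance samples (possible for degenerate synthetic regions) fall
  back to a single Gaussian kernel of bandwidth max(1e−3, grid spacing),
  with a logged warning.
- Integration: trapezoidal rule, chosen over Simpson for robustness to
  the floor's kinks. On the 512-point grid the equal-variance Gaussian
  closed form (μ₁−μ₂)²/σ² is reproduced within 1% for σ ≥ 0.03 whenever
  both means sit a few σ inside the support; nearer the boundary the
  truncation of the Gaussian tails, not the quadrature, dominates the
  discrepancy.
- The diagonal (self-similarity) is fixed at exactly 1 and excluded from
  thresholding and statistics.

## Network analysis

- Binarization keeps the k = round(s·N(N−1)/2) strongest edges at
  sparsity s (round half away from zero). Ties at the cutoff break by
  ascending (i, j) index — deterministic, and it makes edge sets nested
  along the sweep, so nodal degree is monotone in s.
- Sweep: arithmetic sequence from 0.05 to 0.40 in steps of 0.02,
  endpoint included only when hit exactly — i.e. 0.05, 0.07, …, 0.39
  (18 thresholds). Both endpoints and step are configurable.
- Characteristic path length averages shortest paths over *connected*
  pairs only (the convention of the common neuroimaging toolboxes); an
  edgeless graph reports L = ∞. Efficiency needs no convention:
  disconnected pairs contribute 1/∞ = 0.
- Small-worldness σ = (C/C_rand)/(L/L_rand), with null means over
  degree-preserving Maslov–Sneppen double-edge-swap rewirings: 10·|E|
  swaps per null, 100 nulls by default, null seeds derived
  deterministically from one seed. A degree sequence that cannot be
  rewired (complete graph, < 2 edges, or exhausted swap attempts) keeps
  C_rand = C and L_rand = L, so σ = 1 with a metadata note. When C and
  C_rand are both 0 the ratio is taken as 1; if only the nulls lose all
  triangles σ is reported as ∞ and the group test uses the finite
  thresholds only.

## Group statistics

- Two-sample tests default to Student's pooled-variance t; Welch is
  available behind a flag, and the variant is recorded in outputs.
- FDR is Benjamini–Hochberg step-up; rejection is `adjusted ≤ q`.
  Edgewise tests correct jointly across all N(N−1)/2 edges; nodewise
  degree tests correct across nodes within each sparsity (per-threshold
  reporting); global metrics correct across the sweep's thresholds per
  metric.
- Edge clusters are connected components of same-sign significant edges
  on the ROI graph; only components with more than 4 edges (≥ 5) are
  reported, mirroring the cluster-size convention for MC differences.
  The pipeline clusters on the uncorrected p < α mask, the reading under
  which multi-edge clusters are observable at realistic sample sizes;
  `cluster_significant_edges` also accepts the FDR mask.
- GMV comparisons fit per-ROI OLS `gmv ~ group + TIV`. TIV is computed
  as Σ(intensity × voxel volume) over the whole map — a grey-matter-only
  proxy for a three-compartment intracranial volume, overridden by a
  `tiv_mm3` column in the subject table when provided. A constant TIV
  column is dropped (with a warning), which reduces the model exactly to
  the pooled t-test.
- The GMV-on-pain GLM (`gmv ~ pain + TIV`, one group at a time) applies
  a primary uncorrected threshold p < 0.005 — the conventional
  cluster-forming level — then BH across the surviving ROIs. This is an
  ROI-level stand-in for voxel-cluster inference, which would require
  smoothed voxel maps and random-field or permutation cluster statistics.
- Correlations with pain scores are computed within each group for the
  features showing significant group differences, BH-corrected within
  each feature family (MC edges; degrees). Zero-variance features (a
  degree saturated by the sweep) report r = NaN and are excluded from
  the correction.

## Synthetic cohorts

The generator emulates the study design the statistics target: two
cohorts of preprocessed grey-matter maps with controllable differences.

- Intensity model: each ROI's voxels are i.i.d. clipped normal on [0, 1].
  This is deliberately the simplest model giving unimodal KDE-friendly
  densities; the connectivity method consumes only distributions, so
  nothing finer is needed. Parameter validation rejects configurations
  that would clip more than 1% of draws, so clipping is a negligible
  perturbation.
- Default geometry: 90 ROIs tiled as contiguous raster blocks on a
  30×30×30 grid of 1 mm³ voxels (≥ 50 voxels per ROI enforced); default
  group sizes 38 and 16, mirroring the unbalanced two-cohort design the
  statistics must cope with. Tests use smaller, balanced cohorts sized
  for power and runtime (stated per test).
- Effects: `mc_effect_rois` shifts group B's intensity mean (and/or
  scales its sd) in chosen ROIs — every edge touching a shifted ROI is
  "affected" by convention, since its similarity to all partners
  changes. `gmv_effect_rois` shifts the intensity mean to change
  regional volume; note such a shift also moves that ROI's density, as
  it must for any intensity-derived volume.
- Pain scores: intercept + slope · z + noise, where z is the measured
  mean intensity of a named ROI standardized by its theoretical mean and
  standard error. The population correlation between pain and feature is
  therefore slope/√(slope² + noise_sd²) analytically — slope 0.9 with
  noise 1 gives r ≈ 0.67, the small-cohort recovery scenario used in the
  acceptance tests (n = 16).
- Determinism: all randomness flows through `SeedSequence` children of
  the config seed; identical (config, seed) reproduces every volume and
  table byte-identically, and the run manifest's SHA-256 hashes verify
  it end to end.

What the generator does not emulate: spatial smoothness and voxel
autocorrelation, anatomically shaped regions, segmentation error, bias
fields, multimodal intensity distributions, white-matter/CSF
compartments (TIV is a GM proxy), or emotion covariates. Passing tests
therefore demonstrate correctness and calibration of the estimation and
inference machinery under the stated generative model — not robustness
to real-scanner artefacts or anatomical variability.

## Problem sizes used in the test suite

Calibration and recovery suites are sized to give stable Monte-Carlo
estimates while keeping the default test run fast: FDR null calibration
uses 100 replicate cohorts of 20 ROIs × (15 + 15) subjects on a 10³
grid; effect recovery uses 20 replicates at n = 30/group with a 0.2 mean
shift (sd 0.1); correlation recovery uses 100 replicates at n = 16; the
graph-metric oracle enumerates all 1253 non-isomorphic graphs on ≤ 7
nodes. The full suite completes in well under five minutes on one CPU.

## Known limitations

- The automatic-bandwidth rule of the original morphometric-similarity
  literature is not uniquely identified; Silverman's rule is the
  recorded default, and conclusions that hinge on bandwidth choice
  should be checked against the Scott alternative.
- Whether densities should be floored/renormalized before the
  divergence is a numerical necessity here, not an identified
  convention; sensitivity to ε is negligible on smooth densities.
- Edge "clusters" have no canonical definition for MC matrices;
  connected components of same-sign significant edges are one defensible
  reading, and anatomically grouped alternatives may differ.
- ROI-level GMV inference is coarser than voxel-level cluster inference;
  effects confined to a fraction of an ROI are diluted.
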