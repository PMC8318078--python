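# Methods

`obmark` implements a complete computational workflow for identifying
mitral-cell (MC)–specific marker genes in the mouse olfactory bulb (OB)
from single-cell RNA-seq counts, together with the spatial and functional
quantifications used to validate candidate markers: laminar-depth histology
statistics and calcium-imaging odor-response statistics. Everything is
exercised against synthetic data with planted ground truth; no external
dataset is required.

## Marker discovery pipeline

### Count transform and gene selection

Counts are transformed elementwise to log2(count + 1); no library-size
normalization is applied. For each gene *x* the overdispersion statistic is
the log Fano factor

    F_x = log10( sigma^2_x / mu_x )

with mean and variance taken across cells (sample variance, n−1
denominator). Because F_x trends with expression level, genes are ordered
by mean expression and split into 20 equal-count bins; within each bin
F_x is Z-scored (again with the sample SD). The 500 genes with the largest
Z are the overdispersed set used downstream.

Choices worth knowing:

- **Fano on log values.** The statistic is computed on the log-transformed
  matrix by default, following the stated order of operations; computing on
  raw counts is available via `OverdispersedGeneSelector(on_log=False)` and
  `MarkerDiscovery(fano_on_log=False)`.
- **Equal-count bins.** The binning rule is only specified as "20 subsets
  by mean expression"; equal-count quantile bins avoid empty bins in the
  heavy right tail of mean expression. Ties in the mean are broken by input
  order (stable sort), making the partition deterministic.
- **Exclusions.** Genes with zero mean or zero variance have no defined
  Fano factor and are excluded before binning rather than carried with
  sentinel values. A bin whose Fano values are all equal gets Z = 0 (with a
  logged warning) rather than NaN.
- **Ties at the top-k cutoff** break by lexicographic gene name, so the
  selected set is invariant to input gene order.

### Embedding and clustering

The selected-gene submatrix (cells × 500) is reduced with PCA to 10
components and embedded in 2-D with tSNE (learning rate 10, perplexity 33,
PCA initialization, fixed seed). HDBSCAN with min_cluster_size = 5 and
min_samples = 13 (the neighbor rank used for core distances) clusters the
embedding; noise cells (label −1) are excluded from all role assignment and
differential expression.

tSNE requires more than 3 × perplexity points; the subclustering step lowers
its perplexity automatically when the Tbx21 population is small (the value
used is recorded in the run manifest via `get_params`). Exact tSNE geometry
is seed- and implementation-dependent; only cluster-level structure is
contracted by the tests.

### Cluster roles

MCs and tufted cells (TCs) both express *Tbx21*, while *Cck* is abundant in
TCs and largely absent from MCs; *Slc17a7* marks the glutamatergic
projection-neuron populations. The role logic is:

1. **Tbx21 population.** The cluster with the highest mean *Tbx21* is found
   (ties → larger cluster, then smaller label). By default the population
   that gets subclustered is the union of all clusters whose fraction of
   cells with *Tbx21* > 3 (log2 units) exceeds 0.5 (`tbx21_scope="rich"`).
   This covers both the case where MCs and Tbx21-positive TCs co-cluster at
   the whole-OB level and the case where the first pass already separates
   them. `tbx21_scope="top"` restricts to the single highest-mean cluster.
2. **Putative MC cluster.** The Tbx21 population is re-embedded and
   re-clustered; the subcluster with the *lowest fraction* of cells
   expressing *Cck* above threshold 3 is tagged MC (the fraction rule is
   primary; mean *Cck*, then smaller label, break ties). The remaining
   subclusters are TC1. With a single subcluster the rule is undefined and
   an error is raised.
3. **TC2.** Clusters outside the Tbx21 population whose *Cck* and
   *Slc17a7* expressing fractions both exceed 0.5 (configurable; the
   cutoffs are not prescribed anywhere, 0.5 mirrors the other fraction
   rules). May legitimately be empty.

### Marker screen

Each gene is tested MC vs the pooled TC1 ∪ TC2 cells with the two-sided
Mann–Whitney U test (exact null distribution when both groups have ≤ 8
ties-free observations, tie-corrected normal approximation otherwise), and
p values are adjusted across **all** tested genes with Benjamini–Hochberg
(the family size is not stated in the source analysis; all-genes is
standard practice). A gene is a marker when all three hold:

- adjusted p < 0.05 (`significant`);
- expressed above 3 in > 50% of MC cells (`consistent_in_mc`) — this
  fraction rule subsumes the alternative "median above 3" phrasing, which
  is available via `use_median_rule=True`;
- expressed above 3 in < 10% of cells within *every* comparison cluster
  separately (`absent_outside`) — the strictest reading; pooled evaluation
  is available via `pool_comparison`.

All inequalities are strict, exactly as printed in the screening rules.

## Histology quantification

**Normalized EPL depth.** The mitral cell layer (MCL) boundary is depth 0
and the lower glomerular layer (GL) boundary depth 1. For a point between
the boundaries, depth = d_MCL / (d_MCL + d_GL) with nearest-point distances
to each polyline — well defined for curved layers, exact for parallel ones.
Points below the MCL get negative depths, and points beyond the GL depths
above 1, both scaled by the local thickness (d_G − d_M or d_M − d_G). The
side tests use the direction from the point's boundary projection toward
the opposite boundary. Points whose projection lands on a free polyline
endpoint are outside the annotated extent and flagged invalid (closed
ring-shaped boundaries have no free endpoints). Negative-depth somata are
reported with their depths; `mcl_fraction` counts depth ≤ 0.3 and therefore
includes displaced MCs below the MCL.

**Density profiles.** For a binary mask, each depth bin holds the fraction
of that bin's pixels that carry signal (the average of the binary signal
along the axis parallel to the layers); for points, per-bin counts
normalized by the total. The dendritic preference index is
(upper − lower)/(upper + lower) of the mean densities, with the upper EPL
depth ∈ (0.5, 1] and the lower half closed at 0.5; zero total signal gives
NaN.

**Particle detection.** Connected components (8-connectivity, configurable
to 4) filtered by pixel area 70–600 and circularity 4π·area/perimeter² in
0.1–1.0, clipped at 1 for rasterization artifacts. The perimeter is the
Crofton estimate of the outline length: the alternative contour-following
metric collapses the boundary of 1-px-wide shapes to a single traversal and
lets thin lines pass the 0.1 circularity floor they are meant to fail.

**Polar standardization.** The OB center is the centroid of the MCL
polyline resampled at uniform arc length (the duplicate seam point of a
closed ring is dropped); each soma is projected to its nearest MCL point
and its angle measured counter-clockwise from the +x axis in [0, 2π).
Linear density is counts per mm of MCL arc, per angular quadrant and
overall; region density is point-in-polygon counts per mm², with on-edge
points counted inside.

## Functional imaging

ΔF/F uses F0 = mean fluorescence over a 2 s baseline window ending at
inhalation onset (the baseline window is not stated in the source;
configurable). Trials of the same odor are averaged on ΔF/F first, then
Z = (mean ΔF/F in the 1 s window from inhalation onset − baseline mean) /
baseline SD of the averaged trace; a per-trial Z mode is available. A
cell-odor pair is responsive when Z > 2. Zero baseline SD yields NaN
(flagged, not an exception). Cumulative response-amplitude distributions
across cell classes are compared with the standard two-sample KS test.

## Synthetic data: what it emulates and what it does not

**Counts.** Negative binomial with dispersion (size) 2 and per-gene
baseline means scattered lognormally (σ = 0.5) around 2 — the conventional
overdispersed scRNA-seq noise model, giving the mean-binned Fano screen a
realistic mean–dispersion spread. Planted genes are zero-inflated: a
Bernoulli expression gate (fraction 0.9 inside the enriched roles, 0.02
outside for MC markers) over NB at a 2^4-fold elevated mean, so the
fraction-based screening rules have exact planted truth. The default
fixture is 600 cells (150 per role: MC, TC1, TC2, background) × 2,000
genes with three planted MC markers, the three role-identity genes
(*Tbx21* in MC+TC1, *Cck* in TC1+TC2, *Slc17a7* in MC+TC1+TC2) and eight
signature genes for each non-MC role so each planted population has a
transcriptional identity; none of the extra genes satisfies the MC-marker
definition. Not emulated: ambient RNA, doublets, batch effects, realistic
gene–gene correlation — a green pipeline test establishes that the method
recovers planted structure under NB noise, not performance on real tissue.

**Laminar scenes.** Straight parallel boundaries with somata placed at
planted normalized depths (MC depths truncated-normal around 0.12, TC
uniform on [0.35, 0.95] by default) — exact round-trips by construction;
curvature is exercised separately by the geometry tests.

**Traces.** `noise_sd` parameterizes the baseline frame noise SD of the
*trial-averaged* ΔF/F trace: per-trial frame noise is scaled by
√n_trials, and each trial's odor window carries an additional gain noise of
the same magnitude (trial-to-trial response variability). Responsive pairs
get a deterministic mean shift of effect_z × noise_sd in the window. Under
this model the null Z statistic is ≈ N(0, 1) — so the Z > 2 cut has the
one-sided normal false-positive rate (≈ 2.3%) — and a planted pair has
Z ≈ N(effect_z, 1). This is the simplest noise model consistent with the
summary statistics the Z-score analysis reports; real indicator kinetics,
bleaching and movement are not modeled.

All generators are deterministic given their seed.

## Numerical conventions

- Sample SD (n−1) everywhere a SD is estimated from data.
- Strict inequalities at every screening threshold.
- Angle seam: values within 1e-9 of 2π snap to 0.
- Degenerate inputs raise `ValueError` with the violated constraint named;
  undefined statistics (DPI with zero signal, Z with zero baseline SD)
  return NaN rather than raising.

## Known limitations

- The screen's statistical behaviour on the real reference dataset (27,998
  genes × 10,745 OB cells) is not reproduced here; published p values
  depend on that external dataset.
- tSNE coordinates are only reproducible for a fixed seed, library version
  and BLAS; tests therefore assert cluster-level agreement, not geometry.
- The histology module consumes already-binarized masks; raster
  pre-filters (background subtraction, unsharp masking) are upstream tools'
  responsibility.
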