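# Methods

`ecspat` quantifies the spatial organisation and transcriptional output
of extrachromosomal DNA (ecDNA) in cancer nuclei from three kinds of
evidence: 3D coordinates of FISH/immunofluorescence foci, single-slice
nuclear images, and bulk sequencing count tables.  This note records
the models, the parameters that matter, and the design choices made
where the design was genuinely open.

## 1. Point patterns and the clustering test

### Containers and distances

Foci are point centroids in µm (`FociSet`); distances are always
centre-to-centre 3D Euclidean.  Spot diameters are metadata only — no
surface-to-surface distances, and no 2D maximum-intensity-projection
mode, since projecting a 3 µm section onto a plane inflates apparent
clustering.  Cross-channel shortest-distance summaries are directional:
(A→B) asks, for each A focus, how far the nearest B focus is, and is
not the same question as (B→A) when the channels differ in abundance.

Close-contact fractions use a strict inequality (`d < threshold`), and
large protein foci (polymerase-II hubs) are defined by an inclusive
diameter threshold (`d ≥ 0.5 µm`).  Displayed percentages follow two
conventions: rare-contact fractions are *truncated* at two decimals
(4/1011 → 0.39%), so a handful of contacts is never overstated by
rounding up, while cohort bookkeeping percentages are rounded to one
decimal (4/24 → 16.7%).

### Ripley's K estimator

For n foci in a nucleus of volume V the statistic is the literal form

    K(r) = V · Σ_{i≠j} 1{d(i,j) ≤ r} / n²

with ordered pairs (each unordered pair counts twice), inclusive
`d ≤ r`, and **no edge correction**.  This is not the textbook
`V·Σ/(n(n−1))` estimator (available via `estimator="textbook"`); the
choice is inconsequential for inference because the Monte-Carlo null
below uses the identical estimator on the identical geometry, so both
the n²-vs-n(n−1) factor and the boundary bias cancel.  Under complete
spatial randomness (CSR) in a ball of radius R, E[K(r)] ≈
(4/3)πr³·(n−1)/n for r ≪ R, which the tests verify against the
sampled null.

The fast path sorts pairwise distances once and counts by binary
search; it is checked for exact (integer pair count) agreement against
an independent O(n²) counter.

### Null model and test

Each tested nucleus is compared against `n_null` (default 10,000;
simulations in the test-suite use 1,000) CSR samples of the *same*
number of points drawn uniformly in a ball of radius `bounding_radius`
(default 5 µm) — one fixed null geometry for all nuclei, the
convention being that nucleus shape and size do not materially change
the verdict at these radii.  An option to pass a per-nucleus volume
exists but is off by default.  Radii default to 0.1–1.0 µm in 0.1 µm
steps.  Nuclei with ≤ `min_foci` (default 20, an exclusive bound: a
nucleus needs *more than* 20 foci) are excluded with a recorded
reason, not silently dropped.

The p-value at each radius is the one-sided upper-tail empirical rank
of the observed K in the null sample.  K values are integer pair
counts times a constant, so exact ties between the observation and
null values are routine and need an explicit policy:

* `p_hi = #{null ≥ obs}/N` counts ties against significance,
  `p_lo = #{null > obs}/N` counts them in favour.
* When no tie touches the decision, `p = p_hi`.
* When the tied block **straddles the alpha cut** (`p_lo ≤ α < p_hi`)
  — exactly the situation where the observed K coincides with the null
  K at the significance cut-off — the configured policy resolves it:
  `optimistic` takes `p_lo` (biasing in favour of calling clustering),
  `conservative` takes `p_hi`, and `randomized` declares significance
  with probability equal to the fraction of tied rank positions below
  the cut (a dedicated, recorded tie seed makes this reproducible).
* The tie-break is entertained **only when the observed K exceeds the
  null median**.  Without this guard the huge tied-at-zero block at
  small radii (often 99% of the null *and* the observation are zero)
  would let the optimistic rank manufacture p ≈ 0.01 for patterns with
  no excess over the null at all, and those spurious small p-values
  would distort the within-nucleus FDR step.  With the guard the
  family-wise type-I rate of the whole procedure sits at the nominal
  level in simulation.

When `p_lo = 0` the stored p is 0 and the resolution bound `1/n_null`
is stored alongside, so "0" is always read as "< 1/N".

Benjamini-Hochberg FDR control (level 0.05) is applied across the ten
radii *within* each nucleus — each nucleus is one family, which is
what per-nucleus significance calls require; a `global` scope across
nuclei × radii is available in `cluster_cohort`.  The final call at a
radius requires both `q ≤ fdr` and observed K above the null median,
so dispersion (low K) is never labelled clustering.  Note that the
optimistic policy is, by construction, anti-conservative at the
boundary: a single focus pair that exactly ties the null's 95th
percentile value resolves in favour of clustering, which adds a few
percent of single-pair calls at small radii.  This is the documented
bias of the procedure, not an accident; the `randomized` or
`conservative` policies remove it.

## 2. Synthetic point patterns

The generators produce the regimes the test must distinguish:

* **CSR** — uniform in the ball via isotropic directions and inverse-CDF
  radii (`r = R·u^{1/3}`), so the radial CDF is (r/R)³.
* **Thomas process** — uniform parents, Poisson(`mean_children`)
  offspring, isotropic Gaussian scatter (`sigma` per axis).  Parents
  are *not* emitted (standard Thomas); true parent labels travel in a
  `parent_id` column for diagnostics.  Children falling outside the
  ball are **resampled, not clipped**, preserving pairwise-distance
  structure.  Defaults (5 parents, 8 children, σ = 50 nm) emulate a
  "hub" regime of ~40 foci in tight clusters.
* **Doublets** — anchor uniform, partner at exactly `separation` in a
  random direction (resampled to stay inside), emulating double
  minutes; `separation = 0` gives coincident pairs, which downstream
  code accepts.
* **Dual channel** — `coloc_fraction·min(n_a, n_b)` cross-channel pairs
  at a fixed separation plus independent CSR remainders, emulating a
  minority subpopulation of ecDNA carrying both oncogenes.

Geometry is a ball (no ellipsoid by default), lengths are µm
throughout, and there is no z-anisotropy: spot coordinates, not image
stacks, are the unit of 3D simulation.  Optical sectioning (foci
outside the imaged 3 µm slab) is deliberately not modelled.  Cohorts
split one master seed into per-nucleus `SeedSequence` streams, so any
single nucleus can be regenerated alone, and identical configurations
are byte-identical.

## 3. Erosion-shell radial profiling

`equal_area_shells` partitions a single connected nucleus mask into
`n_shells` (default 5) concentric bins of equal area, shell 1 at the
periphery.  Pixels are ordered by their exact Euclidean distance to
the mask boundary (`scipy.ndimage.distance_transform_edt`) —
equivalent to peeling the mask with a growing disc — and split at
exact area quantiles, so shell areas differ by at most one pixel and
the partition is rotation-invariant.  Iterative erosion with a small
discrete structuring element (e.g. a 3×3 cross) was considered and
rejected: it shrinks a disc anisotropically (up to a factor 1/√2
between axis and diagonal directions), so shells on a circular nucleus
would not be circular; the distance-transform formulation keeps the
"erosion" semantics without the metric artefact.  For a disc of radius
R the shell k/k+1 boundary lands at R·√(1−k/n) to sub-pixel accuracy.

`shell_profile` sums each channel per shell and normalises by the
DAPI sum in the same shell (zero DAPI in a shell is an error naming
the shell).  Because shell areas are equal, the sum ratio equals the
ratio of per-pixel means; a genuinely different `pixelwise` option
(mean of the per-pixel channel/DAPI ratio) exists for comparison.
`ratio_profile` divides two DAPI-normalised channels (e.g. gene probe
over whole-chromosome paint) to expose radial preference beyond the
chromosome's own. `shell_trend_test` runs Kruskal-Wallis across shells
on per-nucleus normalised intensities, returning H = 0, p = 1 for
perfectly flat input.  The image simulator produces a circular mask
with flat DAPI and probe ∝ (r/R)^bias plus optional Gaussian noise;
for bias = 2 the expected shell means are (a²+b²)/2R² over each
annulus, i.e. 0.9, 0.7, 0.5, 0.3, 0.1 — used as an analytic fixture.
Nuclei touching the image border should be excluded upstream; the
simulator never produces them.

## 4. Dosage model and statistics

The generative model ties everything to copy number.  A nucleus has
`chr7_copies` chromosomal gene copies (default 3, a typical modal
count for these tumours) and a negative-binomial number of ecDNA
copies (mean 30, shape 3 → SD ≈ 18), reflecting the strong per-cell
copy-number heterogeneity characteristic of ecDNA.  Each copy
transcribes (produces a nascent-RNA focus) independently with
probability `p_transcribe_chr` / `p_transcribe_ec` (default 0.5 per
copy); equal probabilities are the copy-number-only null, and e.g.
`p_ec = 2·p_chr` models a per-copy efficiency boost on ecDNA.

Derived statistics:

* **RNA:DNA ratio** = RNA foci / DNA foci per nucleus (undefined and
  excluded when DNA foci = 0); **ecDNA proportion** = (DNA − CEN7)/DNA,
  using the centromere-7 count as the chromosomal copy number.  A
  negative proportion (CEN7 miscount) is kept and flagged `anomalous`,
  never clamped.  Spearman rho between the two across nuclei is ≈ 0
  under the null and positive under a boost (power ≥ 0.8 at 40 nuclei
  with a 2× boost, verified by simulation).
* **Exon groups** — per-exon RNA count / WGS count, Mann-Whitney
  between exons carried only on the chromosome (exons 2–7, deleted
  from the ecDNA species) and exons predominantly on ecDNA (1, 8–28;
  the grouping ships as `E26_EXON_GROUPS` and is an *input*, not
  computed).  Bulk copy numbers in the generator are cohort means;
  read counts are Poisson at `depth_scale` × copy number (WGS) or ×
  summed per-copy rate (RNA), so under the null both groups share the
  same normalised expectation.
* **Allele-frequency ratios** — SNPs heterozygous in the control
  sample (control AF in [0.40, 0.60], bounds inclusive) and covered by
  ≥ 20 RNA-seq reads.  In the generator the amplified allele sits on
  every ecDNA copy plus one chromosomal copy (amplification derived
  from one parental allele), fixing true WGS AF = (ec+1)/(ec+chr) and
  RNA AF = (ec·p_ec + p_chr)/(ec·p_ec + chr·p_chr); observed AFs are
  binomial draws at Poisson depths.  The per-gene median of RNA-AF /
  WGS-AF is exactly 1 under equal per-copy rates (simulation: within
  [0.95, 1.05] at depth scale 100) and rises monotonically with the
  boost factor.  Medians are unweighted across SNPs.

## 5. What the simulations do and do not show

The generators reproduce the *statistical structure* the analyses
assume — uniform/clustered/doublet point geometry, radially biased
intensity, copy-number-driven counts — not microscopy physics: no
point-spread function, photon noise, spot-detection errors, optical
sectioning, or segmentation errors, and no alignment/calling artefacts
on the sequencing side.  Passing tests therefore validate the
*inference machinery* (estimators, nulls, tie handling, FDR,
partitioning, ratio algebra) at the stated sample sizes, not the
upstream measurement pipeline.

## 6. Problem sizes and numerical choices

The verification suite and `scripts/acceptance.py` use scaled-down but
statistically meaningful sizes chosen for desk-scale reproducibility:
1,000-sample nulls (the resolution floor 1/N is carried with every
p-value), 200-nucleus CSR cohorts for type-I calibration, 50-nucleus
Thomas cohorts for power, 100 random nuclei up to n = 300 for oracle
equivalence, 200-SNP tables at depth scale 100 for dosage calibration.
Determinism everywhere: one master seed, `SeedSequence` splitting, and
a recorded tie seed for the randomized policy.  Degenerate inputs have
defined behaviour rather than crashes wherever a measurement could
plausibly produce them (coincident foci, zero separations, empty
summaries, all-identical Kruskal-Wallis input, CEN7 > DNA counts);
hard errors are reserved for structurally invalid input (missing
columns, non-numeric coordinates, disconnected masks, empty nulls).

## Known limitations

* The bounding-ball null ignores true nucleus shape; strongly
  aspherical nuclei shift absolute K values, though rank-based
  inference is less affected.
* The optimistic tie policy is intentionally anti-conservative at the
  significance boundary (see §1); cohort-level small-radius rates
  should be read with that bias in mind.
* Erosion shells are 2D single-slice only; no 3D shell analysis.
* The dosage generator models one gene and one ecDNA species per
  cohort and treats bulk sequencing as the cohort mean, ignoring
  subclonal structure.
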