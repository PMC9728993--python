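# ecspat

Spatial point-pattern and gene-dosage statistics for extrachromosomal
DNA (ecDNA) in cancer nuclei.

Amplified oncogenes in tumours such as glioblastoma often reside on
ecDNA — centromere-free circles present at high, heterogeneous copy
number.  Two competing explanations for their outsized transcriptional
output are (a) spatial organisation: ecDNA clustering with each other
or with large RNA-polymerase-II hubs, and (b) plain gene dosage:
more copies, more transcript.  `ecspat` implements the quantitative
analyses needed to arbitrate between the two from microscopy
coordinates, nuclear images, and sequencing count tables:

* **Nearest-neighbour distance analysis** of FISH foci — per-focus
  shortest distances within and between channels, close-contact
  fractions at a threshold (e.g. < 200 nm), pooled cumulative
  distributions, and distances to large (≥ 500 nm) polymerase hubs.
* **Per-nucleus 3D Ripley's K clustering test** — the estimator
  `K(r) = V·Σ_{i≠j} 1{d(i,j) ≤ r}/n²` over r = 0.1–1.0 µm, ranked
  against a Monte-Carlo null of the same number of foci uniform in a
  5 µm bounding ball, with explicit tie policies for the discrete K
  values, Benjamini-Hochberg FDR across radii within each nucleus, and
  a clustering-only significance call (observed K must exceed the null
  median).
* **Equal-area erosion-shell profiling** — nucleus masks partitioned
  into five concentric equal-area bins from periphery to centre,
  per-shell probe intensity normalised to DAPI, probe-to-probe ratios,
  and a Kruskal-Wallis radial-trend test.
* **Copy-number-normalised transcription statistics** — RNA:DNA focus
  ratios vs ecDNA proportion (Spearman), per-exon RNA/WGS-normalised
  expression compared between chromosomal-only and ecDNA exons
  (Mann-Whitney), and RNA/WGS allele-frequency ratios at heterozygous
  amplicon SNPs (≈ 1 when per-copy transcription is equal).
* **Synthetic data generators** for every input kind — CSR, Thomas
  clusters, double-minute doublets, dual-channel colocalization,
  radially biased nuclear images, and an explicit copy-number model of
  transcription with an optional per-copy ecDNA boost — so the entire
  pipeline is testable without microscope or sequencer.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Clustered vs uniform foci (`examples/simulate_and_cluster.py`):

```python
from ecspat import (RipleyConfig, SimulationConfig, cluster_cohort,
                    cohort_summary, simulate_cohort)

cfg = RipleyConfig(n_null=1000, seed=1)
csr = simulate_cohort(SimulationConfig(seed=2, n_nuclei=10, foci_per_nucleus=40))
hubs = simulate_cohort(SimulationConfig(seed=3, n_nuclei=10, process="thomas"))
for label, cohort in [("CSR", csr), ("Thomas", hubs)]:
    results = cluster_cohort(cohort, "EGFR", cfg)
    n = sum(r.any_significant() for r in results if not r.excluded)
    print(label, n, "of", len(results), "nuclei significant")
```

prints

```
CSR 0 of 10 nuclei significant
Thomas 10 of 10 nuclei significant
```

— uniform nuclei are never called clustered, while nuclei whose ~40
foci sit in five 50 nm-wide Thomas clusters are flagged at small radii
in every case.  Dosage analysis (`examples/dosage_analysis.py`) prints,
for the copy-number-only model vs a doubled per-copy ecDNA rate:

```
copy-number-only null:
  Spearman rho(RNA:DNA, ecDNA proportion) = -0.192 (p = 0.0556, n = 100 nuclei)
  exon-group Mann-Whitney p = 0.935 (chromosomal vs ecDNA normalised counts)
  median SNP allele-frequency ratio (RNA/WGS) = 0.998

2x per-copy ecDNA boost:
  Spearman rho(RNA:DNA, ecDNA proportion) = +0.554 (p = 2.25e-09, n = 100 nuclei)
  exon-group Mann-Whitney p = 5.31e-06 (chromosomal vs ecDNA normalised counts)
  median SNP allele-frequency ratio (RNA/WGS) = 1.031
```

— under pure dosage all three statistics sit at their null values
(rho ≈ 0, flat exon groups, AF ratio ≈ 1); a genuine per-copy boost
moves all three.

Each script in `examples/` demonstrates one capability end to end:
`distance_analysis.py`, `radial_profile.py`, `hub_distances.py` cover
doublet detection, erosion profiling, and hub distances.

A thin CLI mirrors the stages:

```
ecspat simulate --process thomas --n-nuclei 10 --seed 3 --out foci.csv
ecspat cluster-test --foci foci.csv --channel EGFR --n-null 1000 --seed 1 --out ripley.csv
ecspat distances --foci foci.csv --source EGFR --threshold 0.2 --out dist.csv
ecspat run --config pipeline.yaml --out results/
```

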