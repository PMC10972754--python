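# Methods

## Scoring model

Each gene *g* receives three sub-scores in [0, 1] and a composite
`S(g) = c_pcc + c_tpm + c_bgc`, maximum 3.0.

**Coexpression.** `c_pcc = ramp(r_g; 0.8, 0.9)` where `r_g` is the Pearson
correlation of *g*'s TPM vector with the bait gene's across all samples and
`ramp(x; lo, hi)` is 0 at or below `lo`, 1 at or above `hi`, linear between.
The value exactly at the lower knot is 0 (the published rule is explicit
only at the upper knot — "0.9 or greater" scores 1 — so the lower knot was
fixed for continuity of the ramp). Genes with zero variance have no defined
correlation; they score 0, with a logged warning.

**Abundance.** `c_tpm = ramp(TPM_prim; 1000, 3000)` on the arithmetic mean
TPM over the replicates of the abundance tissue ("primordia" by default; the
aggregation rule across replicates is this package's choice).

**Cluster membership.** `c_bgc = 1` if *g* belongs to at least one putative
BGC containing a characterized pathway gene, 0.5 if it belongs to any other
putative BGC, 0 otherwise. A gene in several clusters takes the maximum
bonus — the only monotone choice.

Ranking sorts by descending composite, breaking ties by PCC, then primordium
TPM, then gene id (full determinism). An optional enzyme-class whitelist is
applied before the top-N cut by default (both orders are supported via
`whitelist_before_topn`, since either narrowing order is defensible). The
composite is kept at full precision internally; rounding to two decimals
happens only in the report table.

## Coexpression conventions

PCC is computed on raw TPM across all individual samples. Log1p transform
and tissue-mean aggregation are available as switches (`--log1p`,
`--tissue-means`) because the literature uses all three conventions and the
best choice is data-dependent; raw-TPM/all-samples is the default as the
simplest reproducible convention. Missing values are disallowed (count
matrices are dense); pairwise-complete correlation is deliberately not
implemented.

## Cluster calling

The built-in caller is a transparent proximity heuristic, not a
reimplementation of pHMM-based cluster-mining tools: per scaffold,
signature-class genes sorted by start are chained while the intergenic gap
(`next.start − prev.end − 1`, overlaps count as 0) stays within
`max_gap_bp` (default 20,000 bp); chains with ≥ 2 signature genes covering
≥ `min_classes` (default 2) distinct enzyme classes become clusters, and
every gene inside the chain's span is a member. The signature-class
catalogue (oxidosqualene-cyclase, CYP, glycosyltransferase, PKSIII,
BAHD-acyltransferase, SDR-reductase, CCL) is configuration, shared with the
simulator. Real cluster-mining output can be ingested instead
(`--clusters`, TSV with `cluster_id`/`member_id`); spans and flags are then
recomputed from the annotation. Because the heuristic is deliberately
simplified, cluster calls on real genomes will differ from pHMM-based
tools'; the scoring layer is agnostic to the source.

## Synthetic data generator

The generator emulates the statistical structure the prioritization relies
on, at desk scale. Defaults (the study conditions used throughout the test
suite): 2,000 genes on 10 scaffolds; 8 tissues × 3 replicates; a 12-gene
pathway module (bait included) planted in two 6-gene genomic blocks, each
seeded with characterized genes (4 total); 4 coexpression decoys (shared
expression profile, isolated in the genome) and 4 clustered decoys (inside
planted blocks, background expression).

* **Layout.** Genes are placed left-to-right with intergenic gaps uniform in
  25–80 kb, except inside planted blocks (0.2–5 kb, i.e. within
  `cluster_gap_bp`). Background gaps exceed the default calling gap, so the
  planted blocks are the only true clusters; ~20% of background genes carry
  signature classes to exercise the class filters. Ground truth is written
  to a JSON sidecar and never encoded in gene identifiers.
* **Expression.** The module shares one latent tissue profile: primordia at
  `primordium_mean_tpm` (6,000), other tissues at 1–10% of it, each gene
  scaled by a lognormal factor (log-sd 0.3, mean 1). Background genes draw
  independent lognormal tissue means (log-mean 5.0, log-sd 1.5 — chosen so
  the 2,000-gene transcriptome sums near 1e6 TPM, so the per-tissue
  renormalization to exactly 1e6 barely moves the planted targets).
* **Counts.** `counts[g,s] ~ NB(mean = TPM_target × length / Σ(TPM×length)
  × library_size, variance = m + φ·m²)` with equal library sizes (5e6), so
  recomputing TPM from counts recovers the targets in expectation — the
  scoring thresholds act on TPM, so targets are specified on that scale.
* **Dispersion.** Default φ = 0.03. This is a designed value: for two genes
  sharing a latent profile, the expected sample correlation is approximately
  `1 / (1 + φ(1 + M²/V))` with `M`, `V` the mean and variance of the profile
  across samples; a one-tissue spike over 8 tissues × 3 replicates caps
  `V/M²` near 7, so φ = 0.1 would cap the expected module PCC near 0.87–0.90
  and the module would straddle the 0.9 scoring knot. φ = 0.03 (biological
  CV ≈ 17%, typical of clean bulk RNA-seq replicates for well-expressed
  genes) puts the expected module PCC near 0.96, so the planted module sits
  clearly above the knot while decoys and background do not.
* **Randomness.** One root seed; per-stage child streams (layout, counts)
  are spawned deterministically, so identical seeds give byte-identical
  outputs and growing one stage does not reshuffle another.

**What the generator does not emulate:** read-level effects (mapping,
multi-mapping, positional bias), isoforms, library-size variation, batch
effects, correlated background modules, and realistic plant gene content.
Passing recovery tests therefore demonstrates that the pipeline's
computations are correct and that the score separates the planted structure
under clean assumptions — not that the thresholds are optimal for any real
transcriptome. One emergent realistic behavior is retained: a background
gene whose random tissue profile happens to spike in primordia can correlate
highly with the bait by chance, exactly as in real bait searches.

## Numerical choices and degenerate inputs

* TPM columns of all-zero samples are emitted as zeros with a warning, never
  an error; non-degenerate columns sum to 1e6 within 1e-6 relative.
* Correlations are clipped to [−1, 1] to absorb last-ulp excursions;
  zero-variance genes (or bait) yield undefined PCC rather than 0.
* The composite is the exact floating-point sum of the sub-scores — no
  internal rounding.
* Tie-breaking is total (ends at the gene id), so ranking is reproducible.
* Cluster calling treats overlapping genes as gap 0; coordinates are 1-based
  inclusive throughout.

## Problem sizes used in the test suite

Unit and property tests use small instances (≤ 25-gene scaffolds for the
1,000-instance cluster-caller oracle comparison; 10-sample vectors for the
correlation oracle at 1e-12 agreement). Recovery and determinism tests run
the full default conditions above (2,000 genes × 24 samples), which complete
in seconds; these sizes were chosen as the smallest at which every planted
feature (two clusters, both decoy kinds, background class noise) is
simultaneously present with margin.

## Known limitations

* The proximity cluster caller is a stand-in: no pHMM scanning, no gene-family
  kernels; fidelity of cluster calls to sophisticated miners is not claimed.
* Equal-weight summation is the only scoring scheme offered; no calibration
  of the thresholds against data is performed (they are configuration).
* Single bait only; no network inference beyond per-gene correlation with
  the bait.
* Ranks from real data inherit every upstream artifact (quantification,
  annotation completeness) that the synthetic data does not model.
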