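# acetylscan

Differential histone-acetylation ChIP-seq region analysis with bootstrap
motif enrichment.

Leukaemogenic fusion proteins reprogram the transcriptional circuitry of
haematopoietic stem/progenitor cells, and the reprogramming leaves a
genome-wide footprint in active-chromatin marks such as H3K9 acetylation.
`acetylscan` implements the complete analytical chain for interrogating that
footprint across a multi-condition progression design (baseline →
pre-leukaemic initiation → frank leukaemia, for two oncogene models):

1. **Peak calling** — mapped ChIP tags (5′ end + strand) are extended
   strand-specifically to 200 bp, per-base coverage is built, and peaks are
   maximal runs of coverage ≥ *h*, where *h* is the smallest height whose
   estimated false discovery rate under a uniform-tag null (analytic Poisson
   by default, Monte-Carlo optional) is ≤ 0.05.
2. **Region atlas** — each peak contributes a 400 bp window centred on its
   summit; windows from all samples are reduced to a non-redundant atlas by
   greedy height-ranked selection, giving disjoint fixed-width candidate
   regulatory regions.
3. **Scoring** — every region is scored in every sample by counting
   overlapping 200 bp-extended reads, normalised to reads per million.
4. **Differential acetylation** — a Bayesian-regularized (Cyber-T-style)
   t-test compares a baseline sample group against a leukaemic group.
   Per-region within-group variance s² is shrunk toward a background
   variance σ₀² (mean variance of the *w* = 101 regions with the nearest
   mean signal):

       s̃² = (ν₀σ₀² + (n−1)s²)/(ν₀ + n − 1),
       t = (x̄_B − x̄_A)/√(s̃²_A/n_A + s̃²_B/n_B),

   with p-values from Student's t on n_A + n_B − 2 + 2ν₀ degrees of freedom
   (ν₀ = 0 recovers the classical two-sample t-test exactly).  Regions at
   p ≤ 0.05 are partitioned into *enriched* (higher in the leukaemic group)
   and *deprived* (lower).
5. **Motif enrichment** — IUPAC consensus motifs (e.g. the GATA consensus
   `WGATAR`) are counted on both strands of the enriched/deprived region
   sets; expected occurrences come from 1000 bootstrap resamples of
   equally-sized region sets from the full atlas, and
   Z = (observed − mean)/SD with |Z| ≥ 3 calling over/under-representation.
6. **Expression branch** — detection filtering (expressed in ≥ 1 sample),
   moderated per-transition differential expression at FDR ≤ 0.001
   (regularized t + Benjamini–Hochberg), non-redundant DE unions, and the
   direction-matched cross-model intersection that defines shared
   progression gene sets.

Because real study data are not shipped, a first-class synthetic-data module
generates genomes, ChIP tag sets and expression matrices with planted
ground truth (enriched regions, group effects, motif placements, DE probes)
so that every stage's recovery behaviour is testable.

## Worked example

Run the full synthetic pipeline at the default study conditions (1 Mb
genome, 200 planted regions of which 40 % lose acetylation at fold 0.25 in
the leukaemic group, 12 ChIP samples of 100 000 tags, 18 expression
samples):

```python
from acetylscan import PipelineConfig, run_pipeline

summary = run_pipeline(PipelineConfig(seed=1), "run1")
```

or equivalently `acetylscan pipeline run --out run1 --seed 1`.  The summary
(also written to `run1/summary.json`) reads, abridged:

```json
{
  "atlas_size": 201,
  "region_class_counts": {"deprived": 80, "enriched": 117, "stable": 4},
  "motif_enrichment": {
    "deprived": {
      "Gata2": {"observed": 313, "z": 8.03, "call": "over"},
      "Cebpa": {"observed": 99,  "z": -0.47, "call": "ns"}
    },
    "enriched": {
      "Gata2": {"observed": 226, "z": -6.27, "call": "under"},
      "Cebpa": {"observed": 152, "z": 0.53, "call": "ns"}
    }
  },
  "n_expressed_probes": 4580,
  "n_nonredundant_de": 727,
  "n_shared_up": 40,
  "n_shared_down": 87
}
```

Reading: the atlas holds 201 candidate regions (200 planted + 1 spurious);
all 80 acetylation-deprived regions are recovered as "deprived".  The GATA
consensus, planted at 3× the background rate in deprived regions, is
strongly over-represented there (Z = +8.0) and correspondingly depleted in
the enriched set, while the uniformly planted control motif stays
non-significant — the motif-level contrast that links loss of acetylation
to a downregulated transcription factor.  On the expression side 45.8 % of
probes pass the detection filter, and the cross-model intersection recovers
40/40 planted shared-up and 87/88 shared-down probes.

Stage-level CLIs (`acetylscan simulate / callpeaks / atlas / score /
difftest / motif / express`) expose the same functionality over BED/FASTA/
TSV files.

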