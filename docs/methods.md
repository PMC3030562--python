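# Methods

This note records the models, parameter choices and numerical conventions
behind `acetylscan`, and what the synthetic-data experiments do and do not
establish about real data.

## Coordinate and data conventions

All genomic intervals are 0-based half-open (BED convention).  A ChIP tag
is the 5′-end position and strand of a mapped read; read length never
enters any computation, because extension is defined from the 5′ end: a
forward tag at *p* covers [p, p+L), a reverse tag covers [p−L+1, p+1),
clipped at chromosome bounds.  The extension length L defaults to 200 bp,
the expected ChIP fragment size.  Coverage at a base is the number of
extended fragments containing it; the suite verifies exact mass
conservation (Σ heights = Σ clipped lengths) and mirror symmetry under
strand reversal plus coordinate reflection.

## Peak calling

Peaks are maximal runs of coverage ≥ h.  The threshold h is the smallest
height whose estimated FDR does not exceed `peak_fdr` (default 0.05), with

    FDR(h) = min(1, E[false peaks at h] / max(1, observed peaks at h)).

Under the default analytic null, coverage at a base behaves as
Poisson(λ = library_size·L/G) and the genome contributes ≈ G/L independent
windows, so E[false peaks at h] = (G/L)·P(Pois(λ) ≥ h).  A Monte-Carlo
null (uniform tag placement, default 200 iterations) is available and
agrees with the analytic threshold within ±1 on tested instances.  The
estimate is capped at 1, so `peak_fdr = 1` accepts everything at h = 1.
Summit ties break to the leftmost maximum; runs separated by ≥ 1 base
below h are distinct peaks (no gap merging).  This caller is a fully
specified stand-in for the original tool's unpublished null; no numerical
fidelity to that tool is claimed, only the contract "significant peaks at
FDR ≤ 0.05".

## Region atlas and scoring

Each peak yields a 400 bp window centred on its summit (clipped at
chromosome ends).  Non-redundancy across samples is implemented as greedy
height-ranked selection: windows sorted by descending source height (ties
by chromosome, start, then sample id) are accepted iff they overlap no
accepted window.  This keeps regions at fixed width — necessary for
unbiased motif counting — and favours the strongest summits; every
rejected window provably overlaps an accepted one.  Regions are scored per
sample by counting extended tags with ≥ 1 bp overlap (a containment mode
exists behind a flag; overlap is the default because containment discards
edge reads), normalised to reads per million.  RPM is a convention only:
the downstream t-statistic is scale-invariant.

## Regularized differential test

With two replicates per condition and six conditions per group, per-region
variance estimates are noisy.  The test shrinks each group's sample
variance toward a background variance σ₀², the mean variance of the w
rank-nearest regions by within-group mean (w = 101; the window is clamped
at the rank edges so it always holds w regions, and w equal to the region
count yields the grand mean).  The shrunken variance uses weights
(ν₀, n−1) with denominator ν₀+n−1, so ν₀ = 0 reduces *exactly* to the
classical two-sample t-test — a clean, testable identity; the alternative
ν₀+n−2 denominator is available via `variance_denominator="n-2"`.  Degrees
of freedom default to n_A+n_B−2+2ν₀, crediting the prior pseudo-replicates
symmetrically; `df_mode="classical"` drops the credit.  ν₀ defaults to 10.
Significant regions (p ≤ 0.05, no multiplicity correction — the analysis
thresholds raw p, though a BH mode exists in the expression branch) are
classified *enriched*/*deprived* by the sign of mean_B − mean_A, where
group B is the leukaemic side.

Replicate concordance is visualised by a hand-rolled Gaussian-kernel
density on a log₂(score+1) grid (Silverman bandwidth by default); the
density is explicitly renormalised so cell masses sum to 1, and the
single-point degenerate case is handled directly rather than through a
covariance estimate.

## Motif enrichment

IUPAC consensus patterns are scanned with overlapping matches on both
strands: forward matches of the pattern plus forward matches of its
reverse complement, with palindromic patterns counted once per position.
`N` in a scanned sequence matches nothing.  Occurrences are total match
counts (a regions-with-≥1-match mode exists behind a flag).  The null for
a target set of k regions is built by drawing B = 1000 sets of k regions
uniformly *with replacement* from the full atlas (without-replacement
subsampling is available) and totalling occurrences; Z = (obs − mean)/SD
with SD on denominator B−1, and |Z| ≥ 3 (inclusive) calls significance.
Null sets match the target only in cardinality; length matching is
automatic because the atlas is fixed-width, and GC matching is out of
scope.  A degenerate SD = 0 null yields z = 0 if observed equals the mean,
otherwise a signed-infinity sentinel with the call taken from the sign.
The shipped motif strings are editable IUPAC stand-ins for six
haematopoietic factors; only `WGATAR` (GATA) is a field-standard
consensus.

## Expression branch

Probes are "expressed" when detected in ≥ 1 sample; a cell counts as
detected when its detection score exceeds 0.01.  Chip platforms disagree
on the direction of detection p-values, so `convention="less"` inverts the
comparison.  Per-transition differential expression uses the same
regularized t (n = 3 per condition) with BH adjustment across tested
probes and calls at adjusted p ≤ 0.001.  The six default transitions are
the baseline→initiation and initiation→progression pairs for each
oncogene model.  Non-redundant DE is the union of probes called in ≥ 1
transition; the shared progression sets are the direction-matched
intersection of the MLL-ENL baseline→initiation calls with the MOZ-TIF2
initiation→progression calls.  Probe→gene collapsing requires a
user-supplied mapping table; without one, results stay at probe level.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical skeleton of the study design: six
conditions split into a baseline group (WT, FDCP, MT-I) and a leukaemic
group (ME-I, ME-L, MT-L); two ChIP replicates and three expression
replicates per condition.  Defaults (chosen once, as realistic desk-scale
conditions): a 1 Mb genome (2 × 500 kb, GC 0.45), 200 planted 400 bp
regions at 10-fold background enrichment, 40 % of them carrying a 0.25
group effect (acetylation loss in group B), ChIP depth 100 000 tags per
sample (the study does not report per-sample depths; this gives λ ≈ 20
per-base background-free signal at desk scale), fragment length 200 bp.
Enriched fragments centre on the region midpoint with SD = width/4;
forward tags sit half a fragment upstream of the midpoint and reverse tags
downstream, reproducing the strand asymmetry that extension corrects.
Tag totals are multinomial, so library size equals the requested depth
exactly.  Per-sample random streams derive from the master seed via
SHA-256(master:label), keeping streams independent and reproducible.

Motifs are written into the genome sequence at recorded positions: the
GATA consensus at an expected 3 per deprived region versus 1 elsewhere,
and a control motif at 1 everywhere.  Expression intensities are Gaussian
on the log scale (baseline mean ≈ 7, SD 1, replicate noise SD 0.5); DE
probes shift the target condition by ±log-fc (pipeline default 3.0, i.e.
6× the replicate noise — a strong planted effect).  Exactly
round(0.458·n) probes are detected, with planted DE probes filling the
quota first: a differentially expressed gene is expressed by
construction, and the detected fraction recovers the 45.8 % parameter
exactly.

Two realistic artefacts are deliberately present.  First, fixed total
depth induces a compositional shift: when deprived regions lose tags in
group B, all remaining regions gain ≈ 16 % density, so the test genuinely
classifies many non-planted regions as enriched — the same coupling that
total-count normalisation imposes on real libraries.  Second, at an FDR
bar of 0.001 across 10⁴ probes, a 4σ expression effect with n = 3 is
recovered for only ~40 % of planted probes (the BH cut sits near |t| ≈ 5
at df 24); the frozen recovery bounds in the tests reflect this measured
power, and the shared-set analysis uses the stronger 6σ planting.

Not modelled: sequencing errors, mappability, duplicate reads, GC bias,
real genome structure, probe cross-hybridisation.  Passing recovery tests
therefore demonstrates correctness of the inference machinery under the
assumed generative model, not performance on real libraries.

## Problem sizes

Default test and acceptance runs use a 1 Mb genome, 12 × 100 000 tags,
~200 atlas regions, 1000 bootstrap resamples and 8 000–20 000 probes;
the full suite plus the acceptance script completes in well under a
minute on one CPU.  All sizes scale linearly through the configuration.

## Known limitations

- The peak-FDR null assumes independent G/L windows; long-range coverage
  autocorrelation makes it mildly conservative at large L/G.
- Greedy atlas selection is order-free but not globally optimal; a dense
  summit cluster keeps only its strongest window.
- The bootstrap null does not condition on GC content; enrichment calls
  for strongly GC-biased motifs in GC-biased target sets would need a
  matched null.
- Cyber-T window and prior settings are documented defaults, not values
  recovered from the original analysis, which does not publish them.
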