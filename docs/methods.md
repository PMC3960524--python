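# Methods

## The procedure

`tftarget` scores the association between a query set of lncRNA features
and each ChIP-Seq experiment in four steps.

1. **Annotation.**  The lncRNA universe comes from a GTF.  Every feature
   line carrying a `transcript_id` contributes to its transcript; a
   transcript's span is the min-start/max-end of its features, and genes
   are groups of transcripts sharing a `gene_id` (required to agree on
   chromosome and strand; disagreement is a parse error, not a warning,
   because it invariably indicates a corrupted or mixed annotation).

2. **Regulatory windows.**  The TSS is the 5′-most transcribed base:
   `start` on the plus strand, `end` on the minus strand.  The window
   `[TSS − u, TSS + d]` is oriented by the *feature's* strand; peak strand
   is ignored throughout, since TF binding is double-stranded and ENCODE
   uniform-processing peaks carry `.`.  The window includes the TSS base,
   so an unclamped window has length `u + d + 1`; the choice is arbitrary
   at these scales (±1 bp against windows of ≥ 3 kb) but is fixed and
   tested so overlap semantics are never ambiguous.  Windows are clamped at
   position 1 on the left; there is no right clamp because GTF carries no
   chromosome lengths and overhang is harmless for overlap.

3. **Targeting.**  A feature is targeted by a dataset when some peak
   overlaps some window of the feature by ≥ 1 bp, on 0-based half-open
   intervals (`max(starts) < min(ends)`; an abutting peak does not count).
   Any positive overlap counts — no containment requirement, no distance
   weighting, no nearest-gene assignment.  At the gene level a gene is
   targeted when *any* member transcript's window is hit (the union rule).
   GENCODE genes frequently have several TSSs; the union is the permissive
   reading of gene-level input and makes the gene result a superset of each
   transcript's.  Per-transcript runs (`--level transcript`) are the
   alternative when TSS-specific resolution matters.

4. **Enrichment.**  Per dataset, the four counts (universe size `N`,
   universe targets `M`, input size `n`, input targets `m`) feed the
   upper-tail hypergeometric probability

   `P = Σ_{i=m}^{min(n,M)} C(M,i)·C(N−M,n−i) / C(N,n)`,

   computed term-by-term in log space (`gammaln` + `logsumexp`), which
   keeps relative error near 1e−13 at any realistic size and cannot
   overflow; the sum is clipped into [0, 1] against last-bit drift, and
   `m = 0` short-circuits to exactly 1.  P-values are adjusted with the
   Benjamini–Hochberg step-up (via `statsmodels.multipletests`) across
   **all datasets scored in the run** — with a web-style request this
   per-run family is the only defensible choice, and it is stated here
   because the family size changes adjusted values.  A dataset is flagged a
   common TF at adjusted P ≤ 0.05 (configurable).

### Reference sets and ID handling

A user reference set (e.g. the lncRNAs detectable on an array) replaces the
annotation as the measurable universe: `BG_S = |reference ∩ annotation|`,
targets and the input are intersected into it, and input IDs outside the
reference are dropped with a warning rather than an error.  Input IDs
resolve by exact ID first, then version-stripped ID (Ensembl-style `.N`
suffixes; disable with `--keep-versions`), then name; a name matching
several IDs is an error listing the candidates, duplicates collapse with a
logged count, and a run aborts only when nothing at all resolves.

### Degenerate statistics

`Odds_Ratio = (FG_H/(FG_S−FG_H)) / (BG_H/(BG_S−BG_H))` is reported as a
ratio of odds.  A saturated foreground (`FG_H = FG_S`) prints `Inf`; a
zero foreground against an informative background prints `0`; an
uninformative background (`BG_H = 0` or `BG_H = BG_S`) prints `NA`.  None
of these raise.  `Expected_H = FG_S·BG_H/BG_S` is reported unrounded.
Floats print with 6 significant digits; ties in the output ordering break
by raw P, then dataset ID, so identical runs are byte-identical.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| window `u/d` | 2000/1000 bp | upstream/downstream window around the TSS; presets `2k1k`, `10k1k`, `20k1k`, `30k2k`, `50k5k`, or any custom pair (`0/0` = TSS base only) |
| level | gene | count targeting per gene (union over member-transcript windows) or per transcript |
| threshold | 0.05 | BH-adjusted P cutoff for the common-TF flag |
| chrom-normalize | none | optional `chr`-prefix add/strip on peak chromosomes; off because silent renaming hides data errors |
| strip versions | on | match Ensembl IDs regardless of trailing `.N` |

Widening the window can only add targets (monotonicity is property-tested),
so `M` grows with the window and per-dataset P-values are not comparable
across windows.

## The synthetic-data generator

Real inputs would be a GENCODE lncRNA GTF and ENCODE uniform-processing
peak lists; the package instead ships a seeded generator so every claim is
testable without downloads.  It emulates the *geometry* of the problem:
genes are laid out in non-overlapping slots spaced at least twice the
window length apart (so every peak's targeting status is unambiguous and
the ground-truth table can be computed by direct arithmetic, independently
of the overlap machinery); transcripts of a gene share the gene's TSS with
varying lengths; null datasets place fixed-width (200 bp) peaks uniformly
over the genome; a planted dataset drops one peak inside the window of each
selected gene — foreground members with probability 0.8, background with
0.1 by default.  Default study conditions used by the test suite and the
acceptance script:

* planted-recovery design: 1,000 genes, foreground 50, 80% vs 10% hit
  rates, 5 null datasets of 300 peaks, 200 (tests) / 50 (script) replicates;
* null calibration: 2,000 genes on a 13 Mb chromosome, 20 datasets of 840
  uniform peaks (expected per-TF coverage M/N ≈ 0.2, the order of ENCODE
  TF promoter coverage), random 200-gene inputs, 50 replicates per seed
  batch.

These sizes are scaled-down surrogates chosen to keep full-suite runs in
minutes while preserving the counts' statistical regime.  What the
generator does **not** emulate: realistic peak-width and signal-shape
distributions, GC and mappability bias, clustered/bidirectional promoters,
overlapping genes, or correlated TF binding across datasets.  Passing tests
therefore demonstrate the correctness and calibration of the *method* —
interval semantics, counting, the statistic — not robustness to those
biological confounders.

## Calibration of the discrete test

The upper-tail p-value of a discrete statistic is *super-uniform*: its CDF
touches the diagonal only at attainable values and sags below in between,
by up to the local pmf (≈ 0.075 at the mode under the null-calibration
conditions above).  Consequences, both verified by the suite: the false
flag rate at BH ≤ 0.05 stays well below 0.05 (conservative, never
anti-conservative), and pooled null p-values match the exact hypergeometric
null (two-sample KS against p-values simulated from
`scipy.stats.hypergeom`) while a KS test against the *continuous* uniform
can reject on large pools precisely because of the one-sided discreteness
gap.  No epsilon flooring is applied anywhere; the summation always
includes at least one positive term, so a p-value of exactly 0 cannot
occur.

## Numerical and edge-case choices

* All internal intervals are 0-based half-open; GTF is converted on parse,
  peaks are native.  Conversions are tested explicitly at the boundaries.
* The bulk targeting path is a sorted-endpoint counting join
  (`#(peak_start < region_end) − #(peak_end ≤ region_start)` per region,
  by binary search); per-interval queries use an interval tree.  Both are
  verified against a naive all-pairs scan.
* Peaks on chromosomes absent from the annotation contribute nothing and
  are logged once per dataset; chromosome names match by exact string
  equality unless normalization is requested.
* Empty peak files load with a warning (an experiment with no reproducible
  peaks is data, not an error); an empty validated input set is an error.
* Identical windows from same-TSS transcripts collapse naturally in
  gene-level sets; duplicated peaks never change a target set (targeting is
  ≥ 1, not a count).

## Known limitations

* Enrichment treats datasets independently; correlated TFs (co-factors,
  repeated experiments on one TF) inflate the number of flagged rows, and
  the BH family is the run, not the TF.
* The background is the full annotation (or the user reference); there is
  no GC-, length- or expression-matched background construction.
* Gene-level `N` counts genes while targeting uses per-transcript windows;
  a gene with many TSSs has more chances to be targeted, which the
  hypergeometric background absorbs only on average.
* GTF only (no GFF3 dialect), no FASTA/sequence awareness, no peak
  calling or replicate handling — peak lists are taken as given.
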