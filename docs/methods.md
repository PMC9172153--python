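# Methods

## Coordinate conventions and inputs

All in-memory coordinates are 0-based half-open; conversions from 1-based
inclusive dialects (GTF, STAR `SJ.out.tab`) happen only at I/O boundaries,
so interval arithmetic is uniform everywhere else. Supported inputs: exon
annotation as GTF 2.2 or BED12; per-sample junctions as TopHat-style BED12
(intron = chromStart + blockSizes[0] … chromEnd − blockSizes[1], score =
supporting reads) or STAR `SJ.out.tab` (unique-mapping counts); coverage as
bedGraph or a BED of read intervals piled into depth by sweep-line; PAS
catalogs as BED6 1-bp intervals; expression, design and qPCR tables as TSV.
Strand is required for exons and PAS because every window is oriented by
transcription; junctions may carry strand "." and then match exons of
either strand on the same chromosome. Junction counts are taken from the
file as given (no re-filtering for mapping uniqueness — STAR's unique
counts are used for that dialect).

## Exon usage

Per exon and sample, skip evidence = Σ read counts of junctions whose
intron strictly contains the exon; inclusion evidence = Σ counts of
junctions whose intron ends at the exon start or begins at the exon end.
Rates are counts divided by the owning gene's TPM in the same sample; a
gene must exceed the TPM cutoff (default 0.025, strict inequality) in
**every** sample for its exons to be testable. Junction-to-gene assignment
is positional (the spanning/anchored relations above), so junction files
from any aligner work without name matching.

Both the skip-rate and inclusion-rate genotype contrasts
x = (m̄ − w̄)/(m̄ + w̄) are computed; the direction with the larger |x|
classifies the event (ties → exclusion) and its per-sample rate vectors go
into Welch's t-test. Inclusion events are reported with the negated
inclusion contrast so that exclusion is always the positive half-axis.
Exons with zero evidence in both directions in all samples are dropped
(logged). Note one consequence of the dominant-direction rule: selecting
the more extreme of two correlated statistics lifts the null rejection
rate of the selected test slightly above the raw Welch size (measured
below).

## Readthrough

Per PAS, signal is integrated over a fixed window (default 275 bp)
downstream of the cleavage site in the transcribed direction (mirrored for
minus-strand genes, clipped at position 0). Integration is depth × overlap
area; when the track was built from read intervals, the area is divided by
the mean read length to give read equivalents, so bedGraph and read-BED
inputs are interchangeable up to that documented scaling. Rates, contrast
and Welch test as in the exon stage; positive x = more downstream signal
in the mutant = readthrough. Multiple PAS per gene are tested
independently; PAS whose gene is absent from the expression table are
skipped with a warning.

## Motif bias

For each significant usage event, three windows in transcribed orientation:
`width` bp (default 250) upstream of the 5' boundary, the whole exon body,
and `width` bp downstream of the 3' boundary; minus-strand exons are
reverse-complemented with flanks swapped. The exon body is used whole
(rather than a fixed 250 bp from the boundary) because exons shorter than
the window are the common case. k-mer frequencies (k = 5, 4⁵ = 1024
motifs) are counted over overlapping windows; windows containing non-ACGT
letters are excluded from the denominator, so each frequency vector is a
probability vector whenever any valid window exists. Per motif and window
class, Spearman ρ (average ranks for ties) is computed between per-event
frequency and the signed usage contrast x of the significant events
(continuous mode; a binary ±1 event-class mode is available). Significance
flags use |ρ| > ρ*, where ρ* defaults to the one-tailed t-approximation
ρ* = t*/√(n − 2 + t*²) at α = 0.05 for the event count n; a fixed
threshold can be supplied instead (the preset 0.0655 matches a published
analysis at n = 571; the t-approximation gives 0.069 there, and the
derivation of the published figure is not stated). Because the one-tailed
threshold is applied to |ρ|, about 2α of motifs pass it on null data —
the flag marks "significant in its direction", one tail per sign.

## Censored qPCR ΔCt

ΔCt = Ct_abnormal − Ct_normal per (target, organ, mouse). If the abnormal
isoform never crosses threshold, Ct_A is set to the cycle ceiling (default
40, configurable), giving a lower-limit ΔCt = ceiling − Ct_N. If the
normal isoform is undetected the pair is missing ("ND") and excluded from
averages rather than imputed (group n varies accordingly). Group means
substitute censored values at their limits; the reported mean is therefore
a lower bound on the mean of any completion of the censored data
(property-tested against random completions). Per-organ Welch tests pool
targets within the organ with limit-substituted values — simple,
conservative and auditable; survival-style censored tests are out of
scope. ΔΔCt = WT mean − MUT mean, flagged a lower limit when the WT mean
is one. The packaged reference panel
(`src/splicedrift/data/qpcr_panel_delta_ct.tsv`) is a published
five-target, six-organ, 3 vs 3 panel whose recomputed summary row (WT
pooled mean >8.57, MUT >4.29, ΔΔCt >4.28) serves as a regression anchor.

## Statistical kernel

Welch's t statistic uses sample variances (ddof = 1) with
Welch–Satterthwaite degrees of freedom and a two-sided t-distribution
p-value. Degenerate zero-variance pairs are kept, not dropped: equal means
→ t = 0, p = 1; unequal means → p = 0 with a degeneracy flag, so
all-or-nothing events stay countable on the volcano. Spearman ρ is the
Pearson correlation of average-fractional ranks; constant vectors yield
NaN (flagged undefined). The contrast x = (m̄ − w̄)/(m̄ + w̄) is undefined
when both genotype means are zero; such events are dropped with a log
entry.

No multiplicity correction is applied to the volcano tables. At n = 3 vs 3
the Welch test's true size at nominal 0.05 is ≈0.035 on null data
(measured against an independent vectorized implementation on 200,000
draws), i.e. the raw-p design is conservative by construction.

## Synthetic data generator

One chromosome of i.i.d. ACGT sequence carries `n_genes` (default 125)
genes, alternating strands, each with 3–6 exons of 80–300 bp separated by
introns of 200–600 bp; intergenic gaps (600–1200 bp) must exceed twice the
PAS window so the post-PAS segments of adjacent opposite-strand genes can
never overlap (a smaller gap leaks planted readthrough into a neighbour's
null window and is rejected at validation).

Splicing follows a transcript-ensemble model: internal exon e has
inclusion usage u_e ∈ [0,1] (terminal exons u = 1) and the expected count
of the junction joining exons a < b is

    depth_scale · TPM · u_a · u_b · Π_{a<c<b} (1 − u_c)

This conserves junction flux at every exon boundary, so planting an effect
(changing one exon's u between genotypes) leaves every other exon's
measured skip and inclusion expectations exactly unchanged — unplanted
exons are true nulls, which is what makes the false-positive benchmarks
meaningful. Planted exclusion moves the skip fraction s = 1 − u from
base·(1 − x) in WT to base·(1 + x) in MUT (baseline skip 0.05), making the
planted skip-rate contrast exactly x; planted inclusion models a cryptic
exon with u itself moving from 0.1·(1 − x) to 0.1·(1 + x), placed only
where both neighbours are internal exons (genes with ≥5 exons). At x = 1
the WT side is exactly zero, producing the ±1 edge stacks.

Expression is log-normal (median 15 TPM, σ = 1 on the log scale — a
realistic dynamic range for a bulk liver library) shared between genotypes,
with per-sample multiplicative gamma noise (CV 0.1). Junction counts are
rounded gamma-multiplied means — the pipeline consumes counts and coverage,
and these are their sufficient statistics; no read-level simulation.
`depth_scale` = 60 junction reads per TPM at full usage keeps null skip
counts in the tens for typical genes, so rates are effectively continuous
and the Welch calibration is clean. Coverage is a uniform gene-body depth
(5 per TPM) plus a post-PAS segment whose depth fraction is the
readthrough rate (baseline 0.05, planted contrast analogous to exclusion).
Each gene gets one PAS at its 3' end plus Poisson-distributed internal PAS
(mean 1.4) at least 280 bp upstream, whose windows lie inside the gene
body and are nulls; internal PAS of one gene share the gene-body sampling
noise. G-rich (exclusion) or T-rich (inclusion) 5-mer runs — 8 disjoint
runs per 250-bp window — are written into the transcribed-downstream
window of each planted exon, reverse-complemented on the minus strand.

What the generator does **not** emulate: mappability and alignment
artifacts, sequencing error, positional coverage bias, overlapping genes,
multi-isoform structure beyond single-exon events, and biological
covariation between splicing and expression. Passing benchmarks therefore
demonstrate correctness and calibration of the statistics on data with the
assumed structure, not robustness to alignment pathology.

All randomness flows through one `numpy` PCG64 generator seeded from the
spec, making every output byte-reproducible; emitted files are plain text
(FASTA, GTF, BED, bedGraph, TSV).

## Benchmarks (tests/test_acceptance.py, scripts/acceptance.py)

* **Type-I calibration**: ten null simulations (no planted effects);
  pooled fraction of exon + PAS events with p < 0.05 is checked against
  0.05 ± 0.01. Measured ≈0.044 pooled: the PAS side shows the raw Welch
  size (≈0.035) while the exon side (≈0.049) is lifted toward nominal by
  the dominant-direction selection.
* **Recovery**: ten planted simulations (contrast 0.8, CV 0.1);
  sensitivity ≥ 0.8 per event class (measured 1.0), false-positive rate
  within two binomial SDs of 0.05, and mean |recovered x − planted x| ≤
  0.15 (measured ≈0.01). Ten replicates are pooled because a single
  ~500-null-exon run has a binomial SD near 0.01, too coarse to
  characterize a 5% rate.
* **Motif pattern**: on planted data, GGGGG shows significant positive ρ
  and TTTTT significant negative ρ in the downstream window.
* **Edge semantics**: hand-built mutant-only skip/inclusion evidence must
  give x = +1.0 and −1.0 exactly.
* **Oracle equivalence**: junction counting, window areas, k-mer
  frequencies, Welch p and Spearman ρ against independent brute-force or
  scipy implementations on ~100 random instances each.
* **qPCR panel**: the packaged published panel's pooled summary recomputed
  from its cells.

Problem sizes (125 genes ≈ 560 exons ≈ 300 PAS per replicate, ten
replicates) keep each benchmark in the seconds range on one CPU while
giving ~5000 null events per calibration estimate.

## Known limitations

* The dominant-direction rule makes the exon-stage null rejection rate a
  property of both the Welch test and the selection step; it is measured,
  not corrected.
* Censored Welch tests substitute detection limits; with heavy censoring
  this under-states group differences (by design, conservatively).
* The motif stage correlates significant events only (matching the
  published framing); an all-exons mode would need the binary/continuous
  switch re-examined.
* Orphan junctions between genes are never counted toward any exon;
  overlapping genes (absent from the simulator) would count a spanning
  junction for exons of both genes.
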