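# Methods

## Data model and coordinate conventions

All genomic intervals are 1-based closed internally; BED emission is the
only 0-based half-open surface. A cytosine record is strand-resolved:
the symmetric CpG position carries one record per strand, and the two
are counted as distinct sites by default (`collapse_cpg_strands`
switches this off). Context is defined by the two bases downstream of
the cytosine on its own strand: CG, CHG or CHH with H ∈ {A, C, T};
positions with fewer than two strand-downstream bases, or where a
needed base is N, are `unknown` and excluded from all summaries. The
reader can either trust a file's context column, cross-check it against
the genome (any disagreement is an error), or recompute it outright.

Gene models come from GFF3/GTF. One representative transcript per gene
— the longest by genomic span — defines the exon/UTR structure; introns
are the gaps between its consecutive exons; the promoter is the closed
interval of the `promoter_bp` (default 2,000) bases immediately 5′ of
the TSS on the gene's strand, truncated at contig boundaries. UTRs are
annotated sub-intervals of their terminal exons, so a UTR base is also
an exon base; site-to-component assignment therefore counts a site once
per component kind it hits, across all overlapping genes, and the
reported percentages use total site–kind assignments as denominator so
they sum to 100.

## Read QC

`summarize_fastq` counts reads, bases, Q20/Q30 bases (Phred ≥ 20/≥ 30),
GC and N bases; percentages are computed in exact decimal arithmetic
and rounded half-up to two decimals, with N bases included in every
denominator. `filter_reads` discards a read iff its N fraction exceeds
10% or its mean Phred is ≤ 20 (the removal boundary is inclusive; the
rule is read-level, matching read-removal semantics rather than
per-base trimming). Survivors are written unchanged, so filtering is
idempotent. Adapter trimming is out of scope — dedicated trimmers do it
before the data reach this package.

## Site calling and conversion rate

Incomplete bisulfite conversion leaves truly unmethylated cytosines
reading as C at rate *f* (the failure rate), estimated by pooling all
read observations at reference-C positions of an unmethylated spike-in
genome: *f* = unconverted / observed. Under non-methylation a
cytosine's methylated count is Binomial(coverage, *f*), so a site is
called methylated when coverage ≥ `min_site_coverage` (default 4) and
the one-sided binomial tail P(X ≥ m) falls below `site_call_alpha`
(default 0.05). No site-level multiple-testing correction is applied —
differential claims are made only at window level. Because the
uncorrected per-site test admits a small false-call rate (≈ 0.5% of
cytosines at 20–30× with *f* = 0.005), the group-level called set
requires a site to be called in a **majority** of the group's
replicates (union and intersection are available); this suppresses
sporadic false calls while tolerating replicate dropout, and keeps the
genome-wide called fraction at the ~0.1% scale the calling thresholds
target.

## Flanking-sequence profiles

For each called site the window of `kmer_len` (default 9, must be odd)
bases centred on the cytosine is read 5′→3′ on the methylated strand —
minus-strand windows are reverse-complemented — so the centre column is
always C and the CG/CHG/CHH downstream geometry is consistent across
strands. Sites too close to a contig edge are skipped and counted, not
padded. Per-position base probabilities are column frequencies; the
most-probable flanking runs are ranked by the product of per-position
marginals over the three positions on each side of the centre, with
lexicographic tie-breaking (a uniform profile ranks alphabetically).

## Gene-anatomy meta-profile

Each component instance (each exon, each intron, …) is rescaled to
`n_bins` = 20 equal-length bins oriented 5′→3′ of its gene. A bin's
level is the coverage-weighted pool Σmeth/Σtotal over all cytosines in
that bin across instances and the group's replicates (an unweighted
mean of per-site levels is the documented alternative; the pooled form
is stable at the low per-site coverages of sparse methylomes). Bins no
covered cytosine ever touches carry NaN and are flagged rather than
interpolated.

## DMR detection

Windows of `window_size_bp` = 1,000 tile each chromosome at
`step_bp` = 100; only full windows are scanned, except that a contig
shorter than one window yields a single clamped, flagged window. Within
a window, read counts are pooled over replicates within each group and
over the cytosine sites covered (coverage > 0) in **both** groups; the
site gate is strict — a window qualifies only with **more than**
`min_c_sites` = 10 such sites. The pooled 2×2 table (methylated vs
unmethylated reads, treatment vs control) gets a two-sided Fisher's
exact p; a table with a zero row or column margin is uninformative and
gets p = 1 by convention. Pooling reads over sites and replicates is
what makes an exact count-based test available at window granularity;
its cost is that biological replicate variability is not modelled, so
calibration holds under (near-)binomial replicate noise and degrades
with strong overdispersion — the synthetic null experiments quantify
this.

Candidate windows must pass all three gates: level ratio
> `min_fold_change` = 2 (larger level in the numerator; ratio is +∞
when only one level is zero and 1 when both are), absolute difference
> `min_abs_diff` = 0.1, and raw p < `alpha_raw` = 0.05. Benjamini–
Hochberg q-values are computed over **all** tested windows, not only
gate survivors — the conservative ordering where the protocol is
ambiguous — and candidates need q < `alpha_fdr` = 0.05. Merging is a
single pass over candidates sorted by position: windows that overlap or
are bookended (next start = current end + 1) join one DMR; no iterative
re-merging. Merged-span levels, direction (hyper iff the treatment
level exceeds control over the span), dominant context (modal context
of covered sites, ties resolved CG > CHG > CHH) and q_min are
recomputed from raw counts over the union interval. Contexts are
scanned jointly by default; per-context scans (CG/CHG/CHH separately)
are a config switch. Box-plot quartiles of DMR levels use type-7
linear interpolation; QQ expected quantiles for rank i of n are
−log10((i − 0.5)/n).

## Annotation, enrichment, DMG × DEG overlap

A DMR links to every gene whose span or component it overlaps by ≥ 1 bp
(promoter included), so one DMR can hit several genes and several DMRs
one gene; genes hit by both hyper and hypo DMRs are flagged ambiguous.
Term enrichment is the hypergeometric upper tail P(X ≥ k) with the
whole annotated gene set as background and BH across terms; no
transcript-length bias correction is applied (a deliberate
simplification relative to length-aware enrichment methods, documented
here). The DMG × DEG association draws `n_permutations` random gene
sets of DMG size uniformly without replacement from the annotated
universe and records each overlap with the DEG list; the default of 25
draws mirrors the protocol this pipeline follows, but ≥ 1,000 is
recommended for a usable empirical p, which is computed with the
add-one rule (1 + #{null ≥ obs})/(1 + n). An interval-placement control
(random DMR-sized intervals re-linked to genes) is provided as the
secondary null. Reported overlap percentages truncate (floor) at two
decimals by default — the convention the published percentage follows —
with half-up rounding available. Methylation–expression concordance
labels a linked gene negative-correlated when the methylation change
and expression log2 fold change have opposite signs.

## Synthetic-study generator

The generator emulates a two-group, three-replicate WGBS study of a
compact, sparsely methylated insect-like genome:

- **Genome**: i.i.d. uniform ACGT, default 300 kb over 2 chromosomes —
  large enough for thousands of windows, small enough for seconds-scale
  runs (sizes used by each experiment are stated with its results).
- **Annotation**: intron-heavy genes (exons 100–200 bp, introns
  0.8–2 kb, 3–6 exons), so introns hold the large majority (> 65%) of
  annotated bases and the intron-dominated site distribution emerges
  from uniform placement rather than being hard-coded.
- **Methylome**: each cytosine is independently a methylated site with
  context-specific probability (defaults CG 0.0012 / CHG 0.0011 /
  CHH 0.0010) at latent level 0.75, shared between groups. Because
  random sequence is 25% / 18.75% / 56.25% CG/CHG/CHH, near-equal
  per-context rates reproduce both the ~0.1% genome-wide called
  fraction and the observed called-set mix (CHH most abundant at
  ~55–57%, then CG, then CHG); a CG-skewed rate would misstate that
  ordering.
- **Planted DMRs**: intervals (default 1.5 kb) inside distinct gene
  bodies where the low group sits at level 0.1 and the high group at
  0.1 + delta (default delta 0.2, i.e. ratio 3), alternating
  hyper/hypo; recorded as ground truth.
- **Replicate noise**: the latent level of each methylated position is
  perturbed per replicate by a beta with mean equal to the level and
  dispersion rho = 0.05; conversion failure (default 0.005) then acts
  per read, so observed counts are Binomial(cov, level′ + (1−level′)f)
  with cov ~ Poisson(coverage_mean, default 30). Overdispersion is
  deliberately confined to methylated positions: conversion chemistry
  is a per-read process, and letting the failure rate itself vary
  between replicates would swamp the sparse methylome with false site
  calls, which real spike-in-calibrated data do not show.
- **Spike-in**: a separate 48.5-kb unmethylated contig sequenced with
  the same failure rate, for end-to-end conversion-rate estimation.
- **Expression and terms**: a DEG table whose planted overlap genes
  change expression opposite in sign to their methylation change (the
  predominant real pattern), and a small GMT whose first term
  concentrates the DMR genes.

Everything derives from one seed; the same design yields a
byte-identical on-disk bundle. What the generator does **not** emulate:
mappability and coverage structure of real genomes (repeats, GC bias),
correlated methylation along the genome outside planted regions,
context-specific level distributions, or read-level artefacts — so
passing tests demonstrate correctness and calibration of the
statistical machinery under its stated assumptions, not performance on
real libraries.

## Validation experiments and numerical choices

`dmrscan.benchmarks` packages three seeded experiments: (1) null
calibration — 20 independent null studies (~200 qualifying windows
each); the raw p < 0.05 pass fraction is compared with 0.05 using the
standard error of the 20 per-study fractions, because overlapping
windows share 90% of their data and a per-window binomial SD would
understate the Monte-Carlo error several-fold; the post-FDR DMR count
is also recorded (expected 0). (2) planted recovery — 10 studies with
4 planted DMRs each (delta 0.2 over base 0.1, 20×); detections match
planted regions at reciprocal overlap ≥ 0.5 and pooled sensitivity and
precision are reported. (3) profile flatness — 10,000 cytosines sampled
from uniform sequence; the largest off-centre deviation from 0.25 is
reported in binomial-SD units.

Degenerate inputs are handled explicitly rather than silently: empty
p-vectors return empty q-vectors; zero-margin tables return p = 1
flagged; a group with no covered cytosines, an empty usable site set
for a profile, or a zero-observation spike-in raise typed errors;
precision is NA when nothing is detected. Percentage arithmetic that
must reproduce printed tables runs in exact decimal, not binary
floating point.

## Known limitations

- Fisher on pooled counts ignores between-replicate variance; strongly
  overdispersed data need a beta-binomial or permutation window test,
  which this package does not implement.
- The site caller's uncorrected binomial test is intentionally simple;
  its false calls are controlled at the group level by majority voting,
  not at the single-sample level.
- Enrichment ignores transcript-length bias.
- The 25-draw default for the overlap null gives an empirical-p
  granularity of 1/26; use more permutations for inference.
- GFF3/GTF parsing assumes gene → transcript → exon/UTR structure with
  a meaningful longest transcript; fragmented annotations should be
  pre-filtered.
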