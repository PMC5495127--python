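# Methods

This note documents the models and procedures the package implements, the
defaults that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Annotation model

Coordinates are 0-based half-open internally; GTF's 1-based inclusive
convention is converted at the I/O boundary. Only `exon` and `CDS` features
are consulted; CDS intervals are projected into transcript space
(`cds_start`/`cds_end` as offsets into the spliced mRNA), which makes
5′UTR/CDS/3′UTR segmentation an exact partition of `[0, mRNA length)` on
both strands.

Two query regimes coexist by design. **Exon/intron classification of a
point uses the full annotation**: a position inside any exon of any isoform
is exonic; inside a transcript span but outside all exons, intronic;
otherwise intergenic. **Per-mRNA analyses (metagene, half-life joins,
region assignment) use representative isoforms only**: per gene the
longest-mRNA isoform (ties broken by lexicographically smallest transcript
id), after which every candidate whose genomic span overlaps another gene's
candidate is dropped — both members of the overlap, on either strand — so
peak-to-transcript assignment is never ambiguous. Strand-agnostic overlap
removal is the stricter choice and is deliberate; an alternative
"most-distal 3′ end" isoform policy is not implemented because the
longest-mRNA policy already determines the representative set uniquely.

## Peak calling

The IP library's per-base coverage defines candidate regions: maximal runs
with coverage ≥ `min_cov` (default 5), recursively split at the leftmost
interior coverage minimum while longer than `max_width` (default 100 nt),
discarding fragments under `min_width` (10 nt). These defaults are the
package's own — region demarcation is not a published primitive — and are
chosen to be deterministic and cheap to verify against a literal coverage
scan.

Each candidate is tested with a one-sided Fisher's exact test on
[in-region vs elsewhere] × [IP vs input] read counts; one-sided because
antibody enrichment is directional. No pseudocounts enter the table; a
table with an empty margin carries no information and returns p = 1.
Benjamini–Hochberg runs over all candidates and regions with FDR < 0.05
are retained, labelled exonic if *any* covered base is exonic, and
annotated with library-normalised enrichment (IP density / input density)
and RPKM in both libraries. Peak strand is the majority strand of
overlapping IP reads.

## Precise sites

Within each peak, two artifact channels nominate single-base candidates:
substitution+deletion pileups with frequency ≥ 5% of local coverage and
≥ 3 supporting reads (mutation evidence), and read-5′-terminus pileups with
≥ 3 reads and at least 5× the peak's mean per-base terminus rate
(truncation evidence). A candidate becomes a site only when it coincides
with, or is adjacent to (±1 nt), the A of a sense-strand RAC match; the
emitted coordinate is always that A, so every site sits on an adenosine by
construction. Mutation evidence is classed CIMS; truncation exactly at the
A is classed MITS and adjacent truncation CITS — the two truncation
channels are distinguished only by register, which is the observable that
separates them in read data. Motif context is RRACU when the surrounding
5-mer matches, else RAC. The 5%/3-read thresholds are configurable
defaults, not published values.

## Compartment and knockout comparisons

The same peak coordinates are counted in both sides; the test is Fisher's
exact (two-sided) on the raw (IP, input) pairs, with library-size
normalisation entering the *fold change* of enrichment rather than the
table — conditioning on the observed input keeps the table integer-valued
and assumption-light. A differential verdict (`A_higher`/`B_higher`, or
`lost_in_B` for the knockout direction) requires FDR ≤ 0.05, fold ≥ 2 in
that direction, and "adequate expression", operationalised as region input
RPKM ≥ 1 on both sides, extending the mRNA-level adequacy rule to the peak region. A peak
failing the expression gate or absent from one side is `untestable` and
excluded from the BH family. Swapping sides exactly swaps the directional
verdicts (tested).

## Splicing completion, junction m⁶A reads, PSI

For an intron, *spliced* evidence is a read whose alignment joins the two
flanking exons across it; *unspliced* evidence is a read contiguously
crossing its donor or acceptor boundary. A retained molecule exposes two
boundary windows where a spliced molecule exposes one junction window, so
the pooled unspliced count is halved before applying
spliced/(spliced+unspliced); without the correction the index is biased
toward retention by up to r/(1+r). Exon-level estimates aggregate the
exon's two flanking introns — the same both-flanking-junctions convention
the PSI estimator uses (inclusion = mean of the two inclusion junctions).

Junction m⁶A-read detection applies four gates in order: site within 80 nt
of a splice site (the read length); chromatin reads covering the site and
≥ 4 nt of adjacent intron through one contiguous block; strictly more than
two such chromatin reads; and zero qualifying reads in nucleoplasm or
cytoplasm ("should not exist" is read as a hard zero, not a rate
threshold). Accepted records report both the per-site and per-exon tallies,
since either can serve as the unit of counting.

Splicing changes between conditions are gated jointly: Fisher's exact test
on the inclusion/exclusion junction counts, BH across testable exons, and
*changed* only when both |ΔPSI| ≥ 0.1 and FDR < 5% hold — the effect-size
gate deliberately keeps trivially significant large-count exons out of the
changed set.

## Metagene profiles

Anchored profiles (stop codon, start codon, last-exon start) work in
transcript space with 10-nt bins over ±1 kb. Density is presence/absence
per mRNA: the fraction of bin-containing mRNAs with ≥ 1 peak overlapping
the bin, with an across-mRNA binomial standard error (replicate-level SEMs
are not defined here because profiles are computed from pooled calls).
Transcripts too short to contain a bin are excluded from that bin's
denominator, and coding anchors skip CDS-less transcripts.

Splice-site-relative profiles use internal exons ≥ 200 nt (so the two
100-nt flanks cannot overlap) and count sites per nt of distance from each
boundary, pooled over both sides, scaled by the mean per-nt density in exon
interiors (> 100 nt from both boundaries): 1.0 means parity with the
interior. The per-bin SEM is computed from the interior-implied expected
count (the natural null for an interior-scaled profile); observed-count
SEMs collapse in low-count bins and flag flat profiles spuriously. The
"center exon must carry a site" restriction is a flag (`require_m6a`),
honoured for observational profiles and switched off for calibration runs
where it would condition the null.

## Half-life model

First-order decay, A(t) = A₀·e^(−kt), fitted per transcript by ordinary
least squares of log abundance on time, pooling all replicate points
(default 5 time points × 3 replicates = 15 points, df = 13). Log-linear
rather than nonlinear least squares because it is closed-form,
scale-invariant, and exact on noise-free exponential input; a nonlinear
refinement was considered and rejected as adding an optimiser dependency
without changing any validated property. Zero abundances are replaced by a
pseudocount of 0.5 *only when zero* — leaving positive values untouched is
what makes the noise-free series (100, 70.71, 50, 25, 6.25) return
T½ = 2.0000 h exactly. Abundances are divided by per-library size factors
before fitting; with factors supplied, a global decaying background (e.g.
total-RNA decay after shutoff) leaves k unbiased (tested to 5%). The slope
p-value is a two-sided t test; reliability filtering keeps BH FDR < 0.05
with k > 0; k ≤ 0 is flagged non-decaying with undefined half-life, and
fewer than 3 positive points rejects the fit.

Downstream relations use rank statistics throughout (Wilcoxon rank-sum for
half-life by m⁶A content and by region, one-sample Wilcoxon on log ratios
and two-sample Kolmogorov–Smirnov for knockout half-life changes), because
half-life distributions are heavy-tailed and the questions are ordinal.

## Synthetic data: what it emulates, what it does not

The generator plants everything the pipeline later estimates. Genes are
multi-exon (3–7 exons of 150–400 nt, introns 200–600 nt) on one synthetic
chromosome with uniform base composition, non-overlapping spans, and a CDS
placed so that 95% of transcripts have the stop codon in the last exon.
Sites are sampled on sense-strand RAC adenosines with 93% exonic fraction,
3× last-exon enrichment and 0.5× depletion within 50 nt of splice sites.
Chromatin molecules retain each intron independently with a planted
probability (drawn from 0.2–0.8, increasing toward the 3′ end to mimic the
co-transcriptional trend); nucleoplasm and cytoplasm are fully spliced, so
intronic sites disappear there by construction. IP libraries oversample
~80-nt fragments (Normal(80, 10) truncated to [30, 120]) covering an
active site by the enrichment factor (default 8×) and stamp substitutions
(15%), deletions (5%) and 5′ truncations (15%) at the methylated A — the
artifact rates are placeholders exposed in config, as no measured values
exist to copy. The knockout removes each site with probability 0.9. Decay
truth couples turnover linearly to exonic site count, k = k₀ + δ·n_sites
(k₀ = 0.1/h, δ = 0.08/h): the real association is monotone with unknown
functional form, and linearity is the simplest testable stand-in. Time
courses are Poisson counts around A₀·e^(−kt) at 0/1/2/4/8 h in 3
replicates with lognormal size factors (σ = 0.1).

Not emulated: sequencing errors beyond the planted artifacts, GC or
positional bias, expression-level variation across transcripts within a
CLIP library (uniform sampling), co-transcriptional ordering beyond the
monotone retention trend, and antibody off-target binding. Passing the
closed-loop tests therefore demonstrates correctness of the estimators
under the stated generative model, not robustness to every artefact of
real libraries.

## Validation experiment sizes

The closed-loop experiments (in `m6aclip.validation`, reported by
`scripts/acceptance.py`) use: 100 genes / 200 planted sites / 80,000 reads
per library for peak calling, its label-shuffled null, and exon/intron
recovery (~150× mean IP coverage at sites, comfortably above the 20-read
floor the sensitivity claim assumes); 600 genes / 6,000 sites for metagene
profiles; 200 repeats × 200 reads per boundary window for splicing-
completion recovery; 500 transcripts at Poisson depth 500 for half-life
recovery; and 100 genes / 200 sites / 60,000 reads for the knockout loop.
These sizes make each experiment's sampling error small relative to the
property being asserted while keeping a full run around one minute on one
CPU.

## Known limitations

* Peak boundaries are coverage-defined, so reported peak widths reflect
  fragment length as much as methylation extent; only the precise-site
  coordinates are nucleotide-resolved.
* Fragment-level IP enrichment dilutes at region level (background reads
  share the 100-nt window), so sensitivity claims are depth-dependent;
  very shallow libraries will under-call weakly covered sites.
* The exon-level completion index assumes the exon's two flanking introns
  share a retention level; when they differ it estimates their average.
* `classify_interval` treats any exonic overlap as exonic; a peak spanning
  an entire short intron plus flanking exons is exonic by this rule.
* The decay model assumes complete transcription shutoff at t = 0 and
  first-order kinetics; biphasic decay is reported as a single averaged k.
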