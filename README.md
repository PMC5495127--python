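# m6aclip

Analysis of N6-methyladenosine (m⁶A) deposition on nascent pre-mRNA from
m⁶A-CLIP sequencing: peak and single-nucleotide site calling, exon/intron and
metagene localisation, splicing-completion and exon–intron junction-read
analysis, cross-compartment and methyltransferase-knockout differential
peaks, and actinomycin-D mRNA half-life inference — together with a
synthetic-data generator that plants a known ground truth so every stage can
be validated in a closed loop.

## Who this is for

m⁶A is an internal mRNA modification deposited at RAC / RRACU consensus
adenosines (R = purine). Antibody cross-linking immunoprecipitation (m⁶A-CLIP)
maps it at single-nucleotide resolution through diagnostic reverse-
transcription errors: cross-link-induced mutations (CIMS), cross-link-induced
truncations (CITS) and m⁶A-induced truncations (MITS). This package is for
analysts asking *when and where* m⁶A is added during the life of a transcript:
is it deposited on chromatin-associated nascent RNA (CA-RNA) before splicing
is complete, does it sit in exons or introns, does it avoid splice-site
neighbourhoods, and does it shorten the cytoplasmic half-life of the mature
mRNA.

## The statistics at the core

* **Peak calling** — candidate regions are maximal runs of IP coverage ≥ 5
  (split at coverage minima above a 100-nt width cap). Each region is tested
  with a one-sided Fisher's exact test on the 2×2 table
  [in-region vs elsewhere] × [IP vs input] and retained at Benjamini–Hochberg
  FDR < 5%. A region is *exonic* if any covered base lies in any annotated
  exon of any isoform.
* **Precise sites** — inside each peak, substitution/deletion pileups
  (frequency ≥ 5%, ≥ 3 reads) and read-5′-terminus pileups are matched to the
  A of an overlapping sense-strand RAC consensus.
* **Differential peaks** (CA vs nucleoplasm, nucleoplasm vs cytoplasm,
  WT vs Mettl3-KO) — Fisher's exact test on the (IP, input) count pairs of the
  two sides; a verdict additionally requires ≥ 2-fold enrichment change, FDR
  ≤ 0.05, and region input RPKM ≥ 1 on both sides.
* **Splicing completion** — for each intron, spliced evidence is a junction-
  spanning read, unspliced evidence a read contiguously crossing a boundary;
  the completion index is spliced / (spliced + unspliced) with pooled boundary
  evidence halved (a retained molecule exposes two boundary windows, a spliced
  one a single junction window). PSI comparisons use the mean of the two
  flanking inclusion junctions and gate changes at |ΔPSI| ≥ 0.1, FDR < 5%.
* **Junction m⁶A reads** — an m⁶A site counts as caught on an unspliced
  fragment only if it lies within 80 nt of a splice site, > 2 chromatin reads
  cover both the site and ≥ 4 nt of adjacent intron, and no such read exists
  in nucleoplasm or cytoplasm.
* **Half-life** — after transcription shutoff A(t) = A₀·e^(−kt); k is fitted
  per transcript by log-linear least squares pooling all replicates
  (t-test on the slope, df = n − 2), T½ = ln 2 / k, reliability filtered at
  BH FDR < 0.05.

## Worked example

Simulate a small study (60 genes, 150 planted sites, 93% exonic, three
compartments, a knockout, decay time courses) and run the whole pipeline:

```bash
cat > study.yaml <<'YAML'
seed: 11
outdir: study_out
simulate:
  n_genes: 30
  n_sites: 60
  reads_per_library: 8000
YAML
m6aclip run study.yaml
```

The report (also written to `study_out/report.json`) prints, among others:

```
"halflife_WT": {
  "median_halflife_h": 2.700584543825408,
  "n_reliable": 30
},
"halflife_change_median_ratio": 1.9494312781917174,
"peaks_CA_WT": {
  "exonic_fraction": 0.9347826086956522,
  "n_peaks": 46,
  "n_sites": 50
}
```

Reading it: 46 peak regions were called in the chromatin fraction at FDR < 5%
and 93.5% of them are exonic — matching the planted truth of 93% exonic
sites. 50 single-nucleotide sites were pinned to a RAC adenosine from
cross-link artifacts. All 30 transcripts got a reliable decay fit (median
T½ ≈ 2.7 h), and the knockout — which removed 90% of planted sites and their
decay contributions — roughly doubled the median half-life, exactly the
turnover coupling the simulator plants.

Per-transcript decay fits are also available directly, statsmodels-style:

```python
from m6aclip import ExponentialDecayModel
import pandas as pd

tc = pd.read_csv("study_out/sim/timecourse_WT.tsv", sep="\t")
sf = pd.read_csv("study_out/sim/size_factors_WT.tsv", sep="\t")
res = ExponentialDecayModel(tc, size_factors=sf).fit()
print(res.summary())
res.filter_reliable(0.05)  # DataFrame: k, se_k, p, fdr, halflife_h
```

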