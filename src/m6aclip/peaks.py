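"""m6A peak-region and precise-site calling from IP vs input libraries.

Peak regions are maximal runs of IP coverage tested for enrichment over
the input library with a one-sided Fisher's exact test and
Benjamini-Hochberg FDR control. Within significant regions, the
modified adenosine is pinpointed from the diagnostic reverse-
transcription artifacts of antibody cross-linking: substitution/
deletion pileups (CIMS) and read 5'-terminus pileups (CITS/MITS),
anchored to the A of an overlapping RAC consensus on the sense strand.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .alignio import ReadAlignment
from .annotation import GeneAnnotation
from .stats import bh_adjust, fisher_exact_p

logger = logging.getLogger(__name__)

_RAC_RE = re.compile(r"(?=[AG]AC)")
_RRACU_RE = re.compile(r"(?=[AG][AG]ACT)")

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class PeakRegion:
    """An m6A peak region with its enrichment statistics."""

    chrom: str
    start: int
    end: int
    strand: str
    ip_count: int = 0
    input_count: int = 0
    enrichment: float = float("nan")
    p_value: float = 1.0
    fdr: float = 1.0
    rpkm_ip: float = 0.0
    rpkm_input: float = 0.0
    label: str = ""  # exonic / intronic / intergenic
    peak_id: str = ""

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class PreciseSite:
    """A single-nucleotide m6A call (the A of the RAC consensus)."""

    chrom: str
    coordinate: int
    strand: str
    evidence_class: str  # CIMS / CITS / MITS
    support: int
    motif: str  # RRACU / RAC
    peak_id: str = ""


# ---- coverage and candidate regions --------------------------------------

def coverage_array(reads: list[ReadAlignment], chrom: str, length: int) -> np.ndarray:
    """Per-base aligned-read coverage on one chromosome."""
    diff = np.zeros(length + 1, dtype=np.int64)
    for r in reads:
        if r.chrom != chrom:
            continue
        for s, e in r.blocks:
            diff[s] += 1
            diff[min(e, length)] -= 1
    return np.cumsum(diff[:-1])


def _split_run(cov: np.ndarray, start: int, end: int, max_width: int) -> list[tuple[int, int]]:
    """Recursively split a coverage run at its interior coverage minimum."""
    if end - start <= max_width:
        return [(start, end)]
    interior = cov[start + 1:end - 1]
    cut = start + 1 + int(np.argmin(interior))  # leftmost interior minimum
    return _split_run(cov, start, cut, max_width) + _split_run(cov, cut, end, max_width)


def build_candidate_regions(ip_reads: list[ReadAlignment],
                            chrom_sizes: dict[str, int],
                            min_cov: int = 5,
                            max_width: int = 100,
                            min_width: int = 10) -> list[tuple[str, int, int]]:
    """Candidate peak intervals: maximal runs of IP coverage >= min_cov.

    Runs longer than ``max_width`` are split at interior coverage
    minima; fragments shorter than ``min_width`` are discarded.
    """
    if not ip_reads:
        logger.warning("empty IP library: no candidate regions")
        return []
    candidates: list[tuple[str, int, int]] = []
    for chrom in sorted(chrom_sizes):
        cov = coverage_array(ip_reads, chrom, chrom_sizes[chrom])
        above = cov >= min_cov
        if not above.any():
            continue
        padded = np.concatenate(([False], above, [False]))
        run_edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for s, e in zip(run_edges[::2], run_edges[1::2]):
            for rs, re_ in _split_run(cov, int(s), int(e), max_width):
                if re_ - rs >= min_width:
                    candidates.append((chrom, rs, re_))
    return candidates


# ---- region testing ------------------------------------------------------

def test_region(ip_in: int, ip_out: int, input_in: int, input_out: int) -> float:
    """One-sided Fisher's exact p for IP enrichment inside a region.

    The 2x2 table is [in-region vs elsewhere] x [IP vs input]; the
    alternative is over-representation of in-region reads in the IP
    library. Degenerate tables return p = 1.
    """
    return fisher_exact_p(ip_in, ip_out, input_in, input_out, "greater")


def rpkm(read_count: int, region_length_nt: int, library_mapped_reads: int) -> float:
    """Reads per kilobase per million mapped reads."""
    if region_length_nt <= 0 or library_mapped_reads <= 0:
        raise ValueError("region length and library size must be positive")
    return read_count / (region_length_nt / 1e3) / (library_mapped_reads / 1e6)


def _count_region_reads(reads: list[ReadAlignment],
                        regions: list[tuple[str, int, int]]) -> np.ndarray:
    """Reads overlapping each region (a read counts once per region)."""
    trees: dict[str, IntervalTree] = {}
    for i, (chrom, s, e) in enumerate(regions):
        trees.setdefault(chrom, IntervalTree()).addi(s, e, i)
    counts = np.zeros(len(regions), dtype=np.int64)
    for r in reads:
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        hit: set[int] = set()
        for s, e in r.blocks:
            for iv in tree.overlap(s, e):
                hit.add(iv.data)
        for i in hit:
            counts[i] += 1
    return counts


def _region_strand(reads: list[ReadAlignment], regions) -> list[str]:
    """Majority read strand per region (ties and empties default '+')."""
    plus = _count_region_reads([r for r in reads if r.strand == "+"], regions)
    minus = _count_region_reads([r for r in reads if r.strand == "-"], regions)
    return ["-" if m > p else "+" for p, m in zip(plus, minus)]


def call_peaks(ip_reads: list[ReadAlignment],
               input_reads: list[ReadAlignment],
               candidates: list[tuple[str, int, int]],
               annotation: GeneAnnotation | None = None,
               fdr_cutoff: float = 0.05) -> list[PeakRegion]:
    """Test candidate regions for IP enrichment and keep FDR < cutoff.

    Retained regions carry counts, library-normalised enrichment, RPKM
    in both libraries and an exonic/intronic label (exonic if any
    covered position lies in any annotated exon).
    """
    if not candidates:
        return []
    ip_total, input_total = len(ip_reads), len(input_reads)
    ip_in = _count_region_reads(ip_reads, candidates)
    input_in = _count_region_reads(input_reads, candidates)
    strands = _region_strand(ip_reads, candidates)

    pvals = np.array(
        [
            test_region(int(a), ip_total - int(a), int(b), input_total - int(b))
            for a, b in zip(ip_in, input_in)
        ]
    )
    fdrs = bh_adjust(pvals)

    peaks: list[PeakRegion] = []
    for i, (chrom, s, e) in enumerate(candidates):
        if fdrs[i] >= fdr_cutoff:
            continue
        ip_dens = ip_in[i] / ip_total if ip_total else 0.0
        in_dens = input_in[i] / input_total if input_total else 0.0
        enrichment = ip_dens / in_dens if in_dens > 0 else float("inf")
        label = (
            annotation.classify_interval(chrom, s, e) if annotation is not None else ""
        )
        peaks.append(
            PeakRegion(
                chrom=chrom, start=s, end=e, strand=strands[i],
                ip_count=int(ip_in[i]), input_count=int(input_in[i]),
                enrichment=enrichment, p_value=float(pvals[i]), fdr=float(fdrs[i]),
                rpkm_ip=rpkm(int(ip_in[i]), e - s, ip_total) if ip_total else 0.0,
                rpkm_input=rpkm(int(input_in[i]), e - s, input_total)
                if input_total else 0.0,
                label=label,
                peak_id=f"peak_{chrom}_{s}_{e}",
            )
        )
    return peaks


# ---- precise-site calling ------------------------------------------------

def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Sequence accessor working for dict-of-str and pyfaidx.Fasta alike."""
    if isinstance(genome, dict):
        return genome[chrom][start:end].upper()
    return str(genome[chrom][start:end]).upper()


def _rac_a_positions(sense_seq: str) -> list[int]:
    """Offsets of the A of each RAC match in a sense-strand sequence."""
    return [m.start() + 1 for m in _RAC_RE.finditer(sense_seq)]


def call_precise_sites(ip_reads: list[ReadAlignment],
                       genome,
                       peaks: list[PeakRegion],
                       min_frac: float = 0.05,
                       min_reads: int = 3,
                       truncation_fold: float = 5.0) -> list[PreciseSite]:
    """Pinpoint single-nucleotide m6A sites inside called peaks.

    Candidate positions are (substitution+deletion) pileups with
    frequency >= ``min_frac`` and >= ``min_reads`` supporting reads
    (CIMS evidence), or read 5'-terminus pileups exceeding
    ``truncation_fold`` times the local per-base expectation (truncation
    evidence). A site is emitted only when the candidate coincides with
    (or is adjacent to) the A of a sense-strand RAC consensus; the site
    coordinate is that A. Truncation exactly at the A is classed MITS,
    adjacent to it CITS. Motif context is RRACU when the surrounding
    5-mer matches, else RAC.
    """
    by_chrom: dict[str, list[ReadAlignment]] = {}
    for r in ip_reads:
        by_chrom.setdefault(r.chrom, []).append(r)

    sites: list[PreciseSite] = []
    for peak in peaks:
        plen = len(peak)
        cov = np.zeros(plen, dtype=np.int64)
        artifacts = np.zeros(plen, dtype=np.int64)
        termini = np.zeros(plen, dtype=np.int64)
        n_termini = 0
        for r in by_chrom.get(peak.chrom, ()):
            if not r.overlaps(peak.start, peak.end):
                continue
            for s, e in r.blocks:
                lo, hi = max(s, peak.start), min(e, peak.end)
                if lo < hi:
                    cov[lo - peak.start:hi - peak.start] += 1
            for pos in (*r.substitutions, *r.deletions):
                if peak.start <= pos < peak.end:
                    artifacts[pos - peak.start] += 1
            tp = r.five_prime_terminus
            if peak.start <= tp < peak.end:
                termini[tp - peak.start] += 1
                n_termini += 1

        with np.errstate(divide="ignore", invalid="ignore"):
            art_frac = np.where(cov > 0, artifacts / np.maximum(cov, 1), 0.0)
        cims_cand = set(
            np.flatnonzero((artifacts >= min_reads) & (art_frac >= min_frac))
        )
        expected_termini = n_termini / plen if plen else 0.0
        trunc_cand = set(
            np.flatnonzero(
                (termini >= min_reads)
                & (termini >= truncation_fold * max(expected_termini, 1e-9))
            )
        )
        if not cims_cand and not trunc_cand:
            continue

        pad = 2
        lo = max(0, peak.start - pad)
        seq = _fetch(genome, peak.chrom, lo, peak.end + pad)
        sense = seq if peak.strand == "+" else revcomp(seq)
        # map sense offsets back to genomic coordinates
        if peak.strand == "+":
            def to_genomic(off: int) -> int:
                return lo + off
        else:
            def to_genomic(off: int) -> int:
                return lo + len(seq) - 1 - off

        emitted: dict[int, PreciseSite] = {}
        for a_off in _rac_a_positions(sense):
            g_a = to_genomic(a_off)
            if not (peak.start <= g_a < peak.end):
                continue
            rel = g_a - peak.start
            near = {rel - 1, rel, rel + 1}
            cims_hits = cims_cand & near
            trunc_hits = trunc_cand & near
            if not cims_hits and not trunc_hits:
                continue
            if cims_hits:
                cls = "CIMS"
                support = int(max(artifacts[i] for i in cims_hits))
            elif rel in trunc_hits:
                cls = "MITS"
                support = int(termini[rel])
            else:
                cls = "CITS"
                support = int(max(termini[i] for i in trunc_hits))
            five = sense[a_off - 2:a_off + 3]
            motif = "RRACU" if _RRACU_RE.match(five) else "RAC"
            site = PreciseSite(
                chrom=peak.chrom, coordinate=g_a, strand=peak.strand,
                evidence_class=cls, support=support, motif=motif,
                peak_id=peak.peak_id,
            )
            prev = emitted.get(g_a)
            if prev is None or (prev.evidence_class != "CIMS" and cls == "CIMS"):
                emitted[g_a] = site
        sites.extend(emitted[k] for k in sorted(emitted))
    return sites


# ---- transcript-level filters -------------------------------------------

def count_exonic_intronic_reads(reads: list[ReadAlignment],
                                annotation: GeneAnnotation) -> dict[str, tuple[int, int]]:
    """Per representative transcript, (exonic, intronic) read counts.

    A read is assigned to a transcript when it lies within the
    transcript span; it counts as intronic if any aligned base falls in
    that transcript's introns, exonic otherwise.
    """
    out: dict[str, list[int]] = {
        t.transcript_id: [0, 0] for t in annotation.representatives()
    }
    reps = {t.transcript_id: t for t in annotation.representatives()}
    for r in reads:
        for t in annotation.transcripts_overlapping(r.chrom, r.start, r.end):
            if t.transcript_id not in reps:
                continue
            intronic = any(
                r.overlaps(s, e) for s, e in t.introns()
            )
            out[t.transcript_id][1 if intronic else 0] += 1
    return {k: (v[0], v[1]) for k, v in out.items()}


def select_partially_spliced(counts: dict[str, tuple[int, int]],
                             min_ratio: float = 2.0) -> set[str]:
    """Transcripts with intronic reads >= ``min_ratio`` x exonic reads.

    Transcripts with zero exonic but nonzero intronic reads are retained
    (infinite ratio); transcripts with no reads at all are not.
    """
    kept: set[str] = set()
    for tid, (exonic, intronic) in counts.items():
        if intronic == 0:
            continue
        if exonic == 0 or intronic >= min_ratio * exonic:
            kept.add(tid)
    return kept


def peaks_to_frame(peaks: list[PeakRegion]):
    """Peak list as a count DataFrame (peak_id, coords, ip/input counts)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "peak_id": p.peak_id, "chrom": p.chrom, "start": p.start,
                "end": p.end, "strand": p.strand, "ip_count": p.ip_count,
                "input_count": p.input_count, "enrichment": p.enrichment,
                "fdr": p.fdr, "label": p.label,
            }
            for p in peaks
        ]
    )


def count_peaks_in_libraries(peaks: list[PeakRegion],
                             ip_reads: list[ReadAlignment],
                             input_reads: list[ReadAlignment]):
    """Count another sample's IP/input reads over an existing peak set."""
    import pandas as pd

    regions = [(p.chrom, p.start, p.end) for p in peaks]
    ip_in = _count_region_reads(ip_reads, regions)
    input_in = _count_region_reads(input_reads, regions)
    return pd.DataFrame(
        {
            "peak_id": [p.peak_id for p in peaks],
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "ip_count": ip_in,
            "input_count": input_in,
        }
    )


# ---- exports -------------------------------------------------------------

def write_peaks_bed(peaks: list[PeakRegion], path) -> None:
    """BED6+ with ip_count, input_count, enrichment and label columns."""
    with open(path, "w") as fh:
        for p in peaks:
            score = -np.log10(max(p.fdr, 1e-300))
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{score:.3f}\t"
                f"{p.strand}\t{p.ip_count}\t{p.input_count}\t"
                f"{p.enrichment:.4g}\t{p.label}\n"
            )


def write_sites_bed(sites: list[PreciseSite], path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.coordinate}\t{s.coordinate + 1}\t{s.peak_id}\t"
                f"{s.support}\t{s.strand}\t{s.evidence_class}\t{s.motif}\n"
            )
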