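"""Transcript annotation model and positional queries.

Loads GTF transcript annotations, selects unambiguous representative
isoforms (longest mRNA per gene, overlap-pruned), and answers the
positional questions the rest of the pipeline relies on: is a point
exonic/intronic/intergenic, where does a transcript-space position sit
relative to CDS/UTRs and to splice sites, and which exon is first,
internal or last.

Two usage regimes coexist deliberately: exon/intron classification of a
point consults *all* annotated isoforms, while metagene and per-mRNA
analyses use only the representative set.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    """Raised for malformed GTF input; carries the offending line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"GTF line {lineno}: {message}")
        self.lineno = lineno


@dataclass
class TranscriptModel:
    """A transcript: ordered exons plus optional CDS in transcript space.

    ``exons`` are stored sorted by genomic coordinate; transcript
    orientation (5'->3') is the reverse of that order on the minus
    strand. ``cds_start``/``cds_end`` are transcript-space coordinates
    (offsets into the spliced mRNA), not genomic.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons "
                    f"({s1},{e1}) and ({s2},{e2})"
                )
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.transcript_id}: partial CDS annotation")
        if self.cds_start is not None:
            if not (0 <= self.cds_start < self.cds_end <= self.mrna_length):
                raise ValueError(
                    f"{self.transcript_id}: CDS [{self.cds_start},{self.cds_end}) "
                    f"outside mRNA of length {self.mrna_length}"
                )

    @property
    def mrna_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0][0], self.exons[-1][1], self.strand
        )

    def exons_in_transcript_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else self.exons[::-1]

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intron intervals, sorted by genomic coordinate."""
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    # ---- coordinate transforms ------------------------------------------

    def genomic_to_transcript(self, gpos: int) -> int | None:
        """Map a genomic position to transcript space; None if intronic/outside."""
        offset = 0
        for s, e in self.exons_in_transcript_order():
            if s <= gpos < e:
                if self.strand == "+":
                    return offset + (gpos - s)
                return offset + (e - 1 - gpos)
            offset += e - s
        return None

    def transcript_to_genomic(self, tpos: int) -> int:
        if not 0 <= tpos < self.mrna_length:
            raise ValueError(f"transcript position {tpos} outside mRNA")
        offset = 0
        for s, e in self.exons_in_transcript_order():
            if tpos < offset + (e - s):
                if self.strand == "+":
                    return s + (tpos - offset)
                return e - 1 - (tpos - offset)
            offset += e - s
        raise AssertionError("unreachable")

    def exon_index_of(self, tpos: int) -> int:
        """0-based exon index (transcript order) containing a transcript position."""
        offset = 0
        for i, (s, e) in enumerate(self.exons_in_transcript_order()):
            if tpos < offset + (e - s):
                return i
            offset += e - s
        raise ValueError(f"transcript position {tpos} outside mRNA")

    def exon_tspan(self, index: int) -> tuple[int, int]:
        """Transcript-space [start, end) of exon ``index`` (transcript order)."""
        lengths = [e - s for s, e in self.exons_in_transcript_order()]
        start = sum(lengths[:index])
        return start, start + lengths[index]


@dataclass
class GeneAnnotation:
    """A collection of transcripts with an optional representative subset."""

    transcripts: dict[str, TranscriptModel]
    representative_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._exon_trees: dict[str, IntervalTree] | None = None
        self._span_trees: dict[str, IntervalTree] | None = None

    # ---- index construction ---------------------------------------------

    def _build_trees(self) -> None:
        exon_trees: dict[str, IntervalTree] = {}
        span_trees: dict[str, IntervalTree] = {}
        for t in self.transcripts.values():
            et = exon_trees.setdefault(t.chrom, IntervalTree())
            for s, e in t.exons:
                et.addi(s, e, t.transcript_id)
            span_trees.setdefault(t.chrom, IntervalTree()).addi(
                t.span.start, t.span.end, t.transcript_id
            )
        self._exon_trees = exon_trees
        self._span_trees = span_trees

    @property
    def exon_trees(self) -> dict[str, IntervalTree]:
        if self._exon_trees is None:
            self._build_trees()
        return self._exon_trees

    @property
    def span_trees(self) -> dict[str, IntervalTree]:
        if self._span_trees is None:
            self._build_trees()
        return self._span_trees

    def representatives(self) -> list[TranscriptModel]:
        return [self.transcripts[i] for i in sorted(self.representative_ids)]

    # ---- positional queries ---------------------------------------------

    def classify_position(self, chrom: str, pos: int) -> str:
        """Classify a point as ``exonic``, ``intronic`` or ``intergenic``.

        Uses the *full* annotation: a point inside any annotated exon of
        any isoform is exonic, a point inside a transcript span but not
        in any exon is intronic, anything else is intergenic.
        """
        if chrom not in self.span_trees:
            logger.warning("unknown chromosome %r; classifying as intergenic", chrom)
            return "intergenic"
        if self.exon_trees[chrom].overlaps_point(pos):
            return "exonic"
        if self.span_trees[chrom].overlaps_point(pos):
            return "intronic"
        return "intergenic"

    def classify_interval(self, chrom: str, start: int, end: int) -> str:
        """Classify an interval; exonic if *any* covered position is exonic."""
        if chrom not in self.span_trees:
            return "intergenic"
        if self.exon_trees[chrom].overlap(start, end):
            return "exonic"
        if self.span_trees[chrom].overlap(start, end):
            return "intronic"
        return "intergenic"

    def transcripts_overlapping(self, chrom: str, start: int, end: int,
                                representative_only: bool = True
                                ) -> list[TranscriptModel]:
        tree = self.span_trees.get(chrom)
        if tree is None:
            return []
        hits = {iv.data for iv in tree.overlap(start, end)}
        if representative_only:
            hits &= self.representative_ids
        return [self.transcripts[i] for i in sorted(hits)]


# ---- GTF I/O -------------------------------------------------------------

def _parse_attributes(raw: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(raw))
    if "transcript_id" not in attrs or "gene_id" not in attrs:
        raise GtfParseError(lineno, "missing gene_id/transcript_id attributes")
    return attrs


def load_annotation(path) -> GeneAnnotation:
    """Load a GTF file (1-based inclusive) into a :class:`GeneAnnotation`.

    Only ``exon`` and ``CDS`` features are consulted. Coordinates are
    converted to 0-based half-open. Transcripts without exons are
    rejected and logged; malformed lines raise :class:`GtfParseError`
    with the line number.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    seen_tids: set[str] = set()

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(lineno, f"expected 9 fields, got {len(fields)}")
            chrom, _, feature, start_s, end_s, _, strand, _, attr_raw = fields
            if feature not in ("exon", "CDS", "transcript"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(lineno, "non-integer coordinates") from None
            if end1 < start1:
                raise GtfParseError(lineno, f"end {end1} < start {start1}")
            if strand not in ("+", "-"):
                raise GtfParseError(lineno, f"invalid strand {strand!r}")
            attrs = _parse_attributes(attr_raw, lineno)
            tid = attrs["transcript_id"]
            seen_tids.add(tid)
            prev = meta.setdefault(tid, (attrs["gene_id"], chrom, strand))
            if prev != (attrs["gene_id"], chrom, strand):
                raise GtfParseError(lineno, f"inconsistent records for {tid}")
            iv = (start1 - 1, end1)  # 1-based inclusive -> 0-based half-open
            if feature == "exon":
                exons.setdefault(tid, []).append(iv)
            elif feature == "CDS":
                cds.setdefault(tid, []).append(iv)

    transcripts: dict[str, TranscriptModel] = {}
    for tid in sorted(seen_tids):
        if tid not in exons:
            logger.warning("transcript %s has zero exons; record rejected", tid)
            continue
        gene_id, chrom, strand = meta[tid]
        t = TranscriptModel(tid, gene_id, chrom, strand, exons[tid])
        if tid in cds:
            tpos = sorted(
                tp
                for s, e in cds[tid]
                for g in range(s, e)
                if (tp := t.genomic_to_transcript(g)) is not None
            )
            if tpos:
                t.cds_start, t.cds_end = tpos[0], tpos[-1] + 1
                t.__post_init__()  # re-validate with CDS set
        transcripts[tid] = t
    return GeneAnnotation(transcripts)


def write_gtf(annotation: GeneAnnotation, path, source: str = "m6aclip") -> None:
    """Write exon and CDS features back out as GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for tid in sorted(annotation.transcripts):
            t = annotation.transcripts[tid]
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )
            if t.cds_start is not None:
                for s, e in _cds_genomic_segments(t):
                    fh.write(
                        f"{t.chrom}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                    )


def _cds_genomic_segments(t: TranscriptModel) -> list[tuple[int, int]]:
    """Genomic intervals covered by the transcript-space CDS."""
    segs: list[tuple[int, int]] = []
    offset = 0
    for s, e in t.exons_in_transcript_order():
        lo = max(t.cds_start, offset)
        hi = min(t.cds_end, offset + (e - s))
        if lo < hi:
            if t.strand == "+":
                segs.append((s + (lo - offset), s + (hi - offset)))
            else:
                segs.append((e - (hi - offset), e - (lo - offset)))
        offset += e - s
    return sorted(segs)


# ---- representative isoform selection ------------------------------------

def select_representative_isoforms(annotation: GeneAnnotation,
                                   policy: str = "longest_mrna"
                                   ) -> GeneAnnotation:
    """Flag one unambiguous isoform per gene.

    Per gene one isoform is kept: the longest mRNA under the default
    policy, or the one with the most distal 3' end under
    ``policy="distal_3prime"`` (ties broken by lexicographically
    smallest transcript_id either way). Afterwards every candidate
    whose genomic span overlaps another gene's candidate (on either
    strand) is removed, so the representative set is mutually
    non-overlapping in genomic space.
    """
    if policy == "longest_mrna":
        def sort_key(t: TranscriptModel):
            return (-t.mrna_length, t.transcript_id)
    elif policy == "distal_3prime":
        def sort_key(t: TranscriptModel):
            # distal 3' end: rightmost end on +, leftmost start on -
            distal = t.span.end if t.strand == "+" else -t.span.start
            return (-distal, t.transcript_id)
    else:
        raise ValueError(f"unknown isoform policy {policy!r}")

    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in annotation.transcripts.values():
        by_gene.setdefault(t.gene_id, []).append(t)

    candidates: list[TranscriptModel] = []
    for gene_id in sorted(by_gene):
        candidates.append(min(by_gene[gene_id], key=sort_key))

    # drop every member of any cross-gene overlap cluster (strand-agnostic)
    keep: set[str] = set()
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in candidates:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom_ts in by_chrom.values():
        chrom_ts.sort(key=lambda t: t.span.start)
        overlapping: set[str] = set()
        for a, b in zip(chrom_ts, chrom_ts[1:]):
            if b.span.start < a.span.end:
                overlapping.update((a.transcript_id, b.transcript_id))
        keep.update(
            t.transcript_id for t in chrom_ts if t.transcript_id not in overlapping
        )
    return GeneAnnotation(dict(annotation.transcripts), representative_ids=keep)


# ---- segmentation and splice-site queries --------------------------------

def segment_transcript(t: TranscriptModel) -> dict:
    """Partition a transcript into 5'UTR / CDS / 3'UTR and label exons.

    Returns a dict with transcript-space ``utr5``/``cds``/``utr3``
    intervals (None when no CDS), per-exon label sets drawn from
    {'first', 'internal', 'last'} (a single exon is both first and
    last), and ``stop_in_last_exon``.
    """
    labels: list[frozenset[str]] = []
    for i in range(t.n_exons):
        tags = set()
        if i == 0:
            tags.add("first")
        if i == t.n_exons - 1:
            tags.add("last")
        if not tags:
            tags.add("internal")
        labels.append(frozenset(tags))

    out = {
        "utr5": None,
        "cds": None,
        "utr3": None,
        "exon_labels": labels,
        "stop_in_last_exon": None,
    }
    if t.cds_start is not None:
        L = t.mrna_length
        out["utr5"] = (0, t.cds_start) if t.cds_start > 0 else None
        out["cds"] = (t.cds_start, t.cds_end)
        out["utr3"] = (t.cds_end, L) if t.cds_end < L else None
        last_start, _ = t.exon_tspan(t.n_exons - 1)
        out["stop_in_last_exon"] = (t.cds_end - 1) >= last_start
    return out


def feature_of_tpos(t: TranscriptModel, tpos: int) -> str:
    """'5UTR', 'CDS' or '3UTR' for a transcript-space position ('mRNA' if no CDS)."""
    if t.cds_start is None:
        return "mRNA"
    if tpos < t.cds_start:
        return "5UTR"
    if tpos < t.cds_end:
        return "CDS"
    return "3UTR"


def distance_to_splice_sites(t: TranscriptModel, tpos: int) -> dict:
    """Distances (nt) from an exonic transcript-space position to its
    exon's donor (5'SS) and acceptor (3'SS) boundaries, strand-aware.

    The acceptor side is the exon's 5' (transcript-orientation) edge, the
    donor side its 3' edge; a point on the first nt of an exon has
    ``dist_to_3ss`` 0. Raises ValueError for non-exonic positions.
    """
    if not 0 <= tpos < t.mrna_length:
        raise ValueError(f"position {tpos} is not within the mRNA")
    idx = t.exon_index_of(tpos)
    es, ee = t.exon_tspan(idx)
    return {
        "dist_to_3ss": tpos - es,
        "dist_to_5ss": ee - 1 - tpos,
        "exon_index": idx,
    }


# ---- exports -------------------------------------------------------------

def write_representatives_bed12(annotation: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        for t in annotation.representatives():
            sizes = ",".join(str(e - s) for s, e in t.exons)
            starts = ",".join(str(s - t.span.start) for s, e in t.exons)
            if t.cds_start is not None:
                gpos = sorted(
                    (t.transcript_to_genomic(t.cds_start),
                     t.transcript_to_genomic(t.cds_end - 1))
                )
                thick = (gpos[0], gpos[1] + 1)
            else:
                thick = (t.span.start, t.span.start)
            fh.write(
                "\t".join(
                    map(
                        str,
                        (
                            t.chrom, t.span.start, t.span.end, t.transcript_id,
                            0, t.strand, thick[0], thick[1], "0,0,0",
                            t.n_exons, sizes + ",", starts + ",",
                        ),
                    )
                )
                + "\n"
            )


def write_segmentation_tsv(annotation: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tfeature\tstart\tend\n")
        for t in annotation.representatives():
            seg = segment_transcript(t)
            for key, name in (("utr5", "5UTR"), ("cds", "CDS"), ("utr3", "3UTR")):
                if seg[key] is not None:
                    fh.write(f"{t.transcript_id}\t{name}\t{seg[key][0]}\t{seg[key][1]}\n")
            for i in range(t.n_exons):
                s, e = t.exon_tspan(i)
                label = "+".join(sorted(seg["exon_labels"][i]))
                fh.write(f"{t.transcript_id}\texon_{label}\t{s}\t{e}\n")
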