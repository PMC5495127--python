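"""Aligned-read records and their on-disk formats.

A :class:`ReadAlignment` is a (possibly spliced) alignment of one CLIP
or RNA-seq fragment: genomic blocks plus the read-level artifact
evidence that precise-site calling consumes (substitution/deletion
positions, 5'-truncation flag).

The primary on-disk format is a documented TSV dialect (lossless for
the artifact annotations); SAM import/export through pysam is provided
for interoperability. Fields:

    read_id chrom start end strand blocks library sample condition
    substitutions deletions truncated

``blocks`` is ``start-end`` pairs joined by ``;``; position lists are
comma-separated; empty lists are ``.``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pysam

TSV_COLUMNS = [
    "read_id", "chrom", "start", "end", "strand", "blocks",
    "library", "sample", "condition", "substitutions", "deletions", "truncated",
]


@dataclass
class ReadAlignment:
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    library: str  # "IP" or "input"
    sample: str = ""  # compartment tag: CA / nucleoplasm / cytoplasm
    condition: str = "WT"
    substitutions: tuple[int, ...] = ()
    deletions: tuple[int, ...] = ()
    truncated: bool = False
    read_id: str = ""

    def __post_init__(self) -> None:
        self.blocks = tuple(sorted(tuple(b) for b in self.blocks))
        for s, e in self.blocks:
            if s >= e:
                raise ValueError(f"empty alignment block ({s},{e})")
        for pos in (*self.substitutions, *self.deletions):
            if not any(s <= pos < e for s, e in self.blocks):
                raise ValueError(f"artifact position {pos} outside aligned blocks")

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def five_prime_terminus(self) -> int:
        """Genomic position of the read's 5' end (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    def covers(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.blocks)

    def overlaps(self, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in self.blocks)


def _fmt_list(values) -> str:
    return ",".join(map(str, values)) if values else "."


def _parse_list(text: str) -> tuple[int, ...]:
    return () if text == "." else tuple(int(x) for x in text.split(","))


def write_alignments_tsv(reads, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for r in reads:
            blocks = ";".join(f"{s}-{e}" for s, e in r.blocks)
            fh.write(
                "\t".join(
                    (
                        r.read_id, r.chrom, str(r.start), str(r.end), r.strand,
                        blocks, r.library, r.sample, r.condition,
                        _fmt_list(r.substitutions), _fmt_list(r.deletions),
                        "1" if r.truncated else "0",
                    )
                )
                + "\n"
            )


def read_alignments_tsv(path) -> list[ReadAlignment]:
    reads: list[ReadAlignment] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TSV_COLUMNS:
            raise ValueError(f"unexpected alignment TSV header in {path}")
        for line in fh:
            f = dict(zip(TSV_COLUMNS, line.rstrip("\n").split("\t")))
            blocks = tuple(
                tuple(map(int, b.split("-"))) for b in f["blocks"].split(";")
            )
            reads.append(
                ReadAlignment(
                    chrom=f["chrom"], strand=f["strand"], blocks=blocks,
                    library=f["library"], sample=f["sample"],
                    condition=f["condition"],
                    substitutions=_parse_list(f["substitutions"]),
                    deletions=_parse_list(f["deletions"]),
                    truncated=f["truncated"] == "1",
                    read_id=f["read_id"],
                )
            )
    return reads


# ---- SAM interop ---------------------------------------------------------
# Artifact evidence rides in auxiliary tags: sb/dl (B,i arrays of genomic
# substitution/deletion positions), tr (1 if 5'-truncated), lb/sm/cn for
# library, sample and condition.

def write_sam(reads, path, chrom_sizes: dict[str, int]) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": n} for c, n in sorted(chrom_sizes.items())],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        refs = {c: i for i, c in enumerate(sorted(chrom_sizes))}
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id or f"read{i}"
            a.reference_id = refs[r.chrom]
            a.reference_start = r.start
            a.is_reverse = r.strand == "-"
            a.mapping_quality = 255
            cigar = []
            prev_end = None
            for s, e in r.blocks:
                if prev_end is not None:
                    cigar.append((3, s - prev_end))  # N gap
                cigar.append((0, e - s))  # M
                prev_end = e
            a.cigartuples = cigar
            a.query_sequence = "*"
            a.set_tag("lb", r.library)
            a.set_tag("sm", r.sample)
            a.set_tag("cn", r.condition)
            if r.substitutions:
                a.set_tag("sb", list(r.substitutions))
            if r.deletions:
                a.set_tag("dl", list(r.deletions))
            a.set_tag("tr", 1 if r.truncated else 0)
            out.write(a)


def read_sam(path) -> list[ReadAlignment]:
    reads: list[ReadAlignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            reads.append(
                ReadAlignment(
                    chrom=a.reference_name,
                    strand="-" if a.is_reverse else "+",
                    blocks=tuple(a.get_blocks()),
                    library=a.get_tag("lb") if a.has_tag("lb") else "input",
                    sample=a.get_tag("sm") if a.has_tag("sm") else "",
                    condition=a.get_tag("cn") if a.has_tag("cn") else "WT",
                    substitutions=tuple(a.get_tag("sb")) if a.has_tag("sb") else (),
                    deletions=tuple(a.get_tag("dl")) if a.has_tag("dl") else (),
                    truncated=bool(a.get_tag("tr")) if a.has_tag("tr") else False,
                    read_id=a.query_name,
                )
            )
    return reads
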