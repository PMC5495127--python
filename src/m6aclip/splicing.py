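"""Splicing completion, m6A-bearing junction reads, and PSI comparisons.

Splicing completion of an intron is read out from junction-spanning
reads: spliced evidence is a read whose alignment joins the two
flanking exons across the intron; unspliced evidence is a read whose
contiguous alignment crosses an exon-intron boundary (donor or
acceptor side). The splicing completion index is spliced / (spliced +
unspliced), pooling both boundaries of the intron.

Exon-intron fragments that also carry a precisely mapped m6A site are
detected under strict filters: the site must lie within 80 nt of a
splice site, supporting chromatin (CA) reads must cover the site and at
least 4 nt of adjacent intron, more than two CA reads are required, and
no such read may exist in nucleoplasm or cytoplasm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignio import ReadAlignment
from .annotation import GeneAnnotation, TranscriptModel
from .peaks import PreciseSite
from .stats import bh_adjust, fisher_exact_p


# ---- junction counting ---------------------------------------------------

def count_junction_reads(reads: list[ReadAlignment],
                         transcript: TranscriptModel) -> pd.DataFrame:
    """Spliced / unspliced junction evidence per intron of a transcript.

    Returns one row per intron (genomic order) with columns ``spliced``
    (reads joining the two flanking exons), ``unspliced_donor`` and
    ``unspliced_acceptor`` (reads contiguously crossing the upstream /
    downstream genomic boundary of the intron).
    """
    introns = transcript.introns()
    spliced = np.zeros(len(introns), dtype=np.int64)
    u_left = np.zeros(len(introns), dtype=np.int64)
    u_right = np.zeros(len(introns), dtype=np.int64)
    index = {iv: i for i, iv in enumerate(introns)}

    for r in reads:
        if r.chrom != transcript.chrom:
            continue
        for (s1, e1), (s2, e2) in zip(r.blocks, r.blocks[1:]):
            i = index.get((e1, s2))
            if i is not None:
                spliced[i] += 1
        for bs, be in r.blocks:
            for i, (istart, iend) in enumerate(introns):
                if bs < istart and be > istart:
                    u_left[i] += 1
                if bs < iend and be > iend:
                    u_right[i] += 1

    rows = []
    for i, (istart, iend) in enumerate(introns):
        donor_is_left = transcript.strand == "+"
        rows.append(
            {
                "transcript_id": transcript.transcript_id,
                "intron_index": i,
                "intron_start": istart,
                "intron_end": iend,
                "spliced": int(spliced[i]),
                "unspliced_donor": int(u_left[i] if donor_is_left else u_right[i]),
                "unspliced_acceptor": int(u_right[i] if donor_is_left else u_left[i]),
            }
        )
    return pd.DataFrame(rows)


def splicing_completion_index(spliced: int, unspliced: int) -> float:
    """Fraction of spliced molecules among spliced + unspliced evidence."""
    total = spliced + unspliced
    if total <= 0:
        raise ValueError("no junction evidence: index undefined")
    return spliced / total


def completion_index_table(junctions: pd.DataFrame) -> pd.DataFrame:
    """Per-intron completion index from a junction-count table.

    A retained molecule exposes two boundary windows (donor and
    acceptor) while a spliced molecule exposes a single exon-exon
    junction window, so the pooled unspliced count is halved before the
    spliced/(spliced+unspliced) definition is applied; otherwise the
    index would be biased toward retention. Introns with no evidence
    are excluded.
    """
    df = junctions.copy()
    df["unspliced"] = (df["unspliced_donor"] + df["unspliced_acceptor"]) / 2.0
    df["n_evidence"] = df["spliced"] + df["unspliced"]
    df = df[df["n_evidence"] > 0].copy()
    df["completion_index"] = df["spliced"] / df["n_evidence"]
    return df


def retention_estimate(spliced: float, unspliced_pooled: float) -> float:
    """Intron retention from junction evidence pooled over boundaries.

    ``unspliced_pooled`` is the sum of donor- and acceptor-side
    boundary-spanning counts; the halved pool makes the estimate
    consistent with the molecule-level retention fraction.
    """
    u = unspliced_pooled / 2.0
    total = spliced + u
    if total <= 0:
        raise ValueError("no junction evidence: retention undefined")
    return u / total


# ---- m6A-bearing exon-intron junction reads ------------------------------

@dataclass
class JunctionM6ARead:
    """An accepted m6A site with unspliced exon-intron fragment support."""

    site: PreciseSite
    transcript_id: str
    exon_index: int
    side: str  # '5SS' or '3SS'
    distance_nt: int
    ca_count: int
    nucleoplasm_count: int
    cytoplasm_count: int
    max_intron_overlap_nt: int


def _qualifying_reads(reads: list[ReadAlignment], site: PreciseSite,
                      intron: tuple[int, int], boundary: int,
                      min_intron_nt: int) -> list[int]:
    """Intronic overlaps of reads covering the site contiguously across
    the given exon/intron boundary with >= min_intron_nt intronic nt."""
    overlaps = []
    for r in reads:
        if r.chrom != site.chrom or not r.covers(site.coordinate):
            continue
        for bs, be in r.blocks:
            if bs <= site.coordinate < be and bs < boundary < be:
                ov = min(be, intron[1]) - max(bs, intron[0])
                if ov >= min_intron_nt:
                    overlaps.append(ov)
                break
    return overlaps


def find_m6a_junction_reads(sites: list[PreciseSite],
                            reads_by_compartment: dict[str, list[ReadAlignment]],
                            annotation: GeneAnnotation,
                            max_splice_dist: int = 80,
                            min_intron_nt: int = 4,
                            min_ca_reads: int = 3,
                            forbidden: tuple[str, ...] = ("nucleoplasm", "cytoplasm"),
                            ) -> list[JunctionM6ARead]:
    """Detect m6A sites carried on unspliced exon-intron fragments.

    Acceptance requires (a) the site within ``max_splice_dist`` nt of a
    splice site, (b) CA reads covering both the site and at least
    ``min_intron_nt`` nt of the adjacent intron, (c) at least
    ``min_ca_reads`` such CA reads (default 3, i.e. strictly more than
    two), and (d) zero qualifying reads in the forbidden compartments.
    """
    accepted: list[JunctionM6ARead] = []
    ca_reads = reads_by_compartment.get("CA", [])
    for site in sites:
        for t in annotation.transcripts_overlapping(
            site.chrom, site.coordinate, site.coordinate + 1
        ):
            tpos = t.genomic_to_transcript(site.coordinate)
            if tpos is None:
                continue
            idx = t.exon_index_of(tpos)
            es, ee = t.exon_tspan(idx)
            exons_g = t.exons_in_transcript_order()
            # candidate sides: only real splice sites (not transcript ends)
            sides: list[tuple[str, int, tuple[int, int], int]] = []
            if idx > 0:  # acceptor side: upstream intron
                dist = tpos - es
                g_up = exons_g[idx - 1]
                g_this = exons_g[idx]
                intron = (
                    (g_up[1], g_this[0]) if t.strand == "+" else (g_this[1], g_up[0])
                )
                boundary = g_this[0] if t.strand == "+" else g_this[1]
                sides.append(("3SS", dist, intron, boundary))
            if idx < t.n_exons - 1:  # donor side: downstream intron
                dist = ee - 1 - tpos
                g_dn = exons_g[idx + 1]
                g_this = exons_g[idx]
                intron = (
                    (g_this[1], g_dn[0]) if t.strand == "+" else (g_dn[1], g_this[0])
                )
                boundary = g_this[1] if t.strand == "+" else g_this[0]
                sides.append(("5SS", dist, intron, boundary))
            for side, dist, intron, boundary in sides:
                if dist > max_splice_dist:
                    continue
                ca = _qualifying_reads(ca_reads, site, intron, boundary, min_intron_nt)
                if len(ca) < min_ca_reads:
                    continue
                contaminating = sum(
                    len(
                        _qualifying_reads(
                            reads_by_compartment.get(comp, []), site, intron,
                            boundary, min_intron_nt,
                        )
                    )
                    for comp in forbidden
                )
                if contaminating > 0:
                    continue
                accepted.append(
                    JunctionM6ARead(
                        site=site, transcript_id=t.transcript_id,
                        exon_index=idx, side=side, distance_nt=dist,
                        ca_count=len(ca),
                        nucleoplasm_count=len(
                            _qualifying_reads(
                                reads_by_compartment.get("nucleoplasm", []),
                                site, intron, boundary, min_intron_nt,
                            )
                        ),
                        cytoplasm_count=len(
                            _qualifying_reads(
                                reads_by_compartment.get("cytoplasm", []),
                                site, intron, boundary, min_intron_nt,
                            )
                        ),
                        max_intron_overlap_nt=max(ca),
                    )
                )
    return accepted


def junction_enrichment_test(ip_with_m6a: int, input_with_m6a: int,
                             ip_without_m6a: int, input_without_m6a: int
                             ) -> tuple[float, float]:
    """Fisher p-values for IP enrichment of m6A-bearing junction
    fragments and depletion of junction fragments lacking m6A.

    Both come from the 2x2 table [with vs without m6A] x [IP vs input]:
    the first p tests over-representation of m6A-bearing fragments in
    the IP, the second their under-representation (equivalently,
    depletion of m6A-lacking fragments).
    """
    args = (ip_with_m6a, ip_without_m6a, input_with_m6a, input_without_m6a)
    return (
        fisher_exact_p(*args, alternative="greater"),
        fisher_exact_p(*args, alternative="less"),
    )


# ---- PSI -----------------------------------------------------------------

def psi(inclusion: float, exclusion: float) -> float:
    """Percent spliced in: inclusion / (inclusion + exclusion)."""
    total = inclusion + exclusion
    if total <= 0:
        raise ValueError("exon untestable: no junction reads")
    return inclusion / total


def psi_from_junctions(inclusion_upstream: int, inclusion_downstream: int,
                       exclusion: int) -> float:
    """PSI with inclusion counted as the mean of the two flanking
    junction counts of the cassette exon."""
    return psi((inclusion_upstream + inclusion_downstream) / 2.0, exclusion)


def compare_splicing(records_a: pd.DataFrame,
                     records_b: pd.DataFrame,
                     dpsi_min: float = 0.1,
                     fdr_max: float = 0.05) -> pd.DataFrame:
    """Per-exon splicing change between two conditions.

    Inputs carry one row per exon with ``exon_id``, ``inclusion``,
    ``exclusion`` (junction read counts; inclusion may already be the
    mean of flanking junctions) and optional ``has_m6a`` / ``class``
    columns. An exon changes iff |dPSI| >= ``dpsi_min`` AND Fisher/BH
    FDR < ``fdr_max``; exons testable in only one condition are
    excluded from the multiple-testing family.
    """
    a = records_a.set_index("exon_id")
    b = records_b.set_index("exon_id")
    ids = sorted(set(a.index) & set(b.index))
    rows = []
    for eid in ids:
        ra, rb = a.loc[eid], b.loc[eid]
        tot_a = ra["inclusion"] + ra["exclusion"]
        tot_b = rb["inclusion"] + rb["exclusion"]
        if tot_a <= 0 or tot_b <= 0:
            continue
        psi_a = ra["inclusion"] / tot_a
        psi_b = rb["inclusion"] / tot_b
        p = fisher_exact_p(
            int(round(ra["inclusion"])), int(round(ra["exclusion"])),
            int(round(rb["inclusion"])), int(round(rb["exclusion"])),
            alternative="two-sided",
        )
        row = {
            "exon_id": eid, "psi_a": psi_a, "psi_b": psi_b,
            "delta_psi": psi_a - psi_b, "p_value": p,
        }
        for extra in ("has_m6a", "class"):
            if extra in a.columns:
                row[extra] = ra[extra]
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["fdr"] = bh_adjust(df["p_value"].to_numpy())
    df["changed"] = (df["delta_psi"].abs() >= dpsi_min) & (df["fdr"] < fdr_max)
    return df


def splicing_change_summary(comparison: pd.DataFrame) -> pd.DataFrame:
    """Changed/unchanged tallies stratified by m6A content and exon class."""
    group_cols = [c for c in ("has_m6a", "class") if c in comparison.columns]
    if not group_cols:
        return pd.DataFrame(
            {
                "n_exons": [len(comparison)],
                "n_changed": [int(comparison["changed"].sum())],
            }
        )
    out = (
        comparison.groupby(group_cols, dropna=False)
        .agg(n_exons=("changed", "size"), n_changed=("changed", "sum"))
        .reset_index()
    )
    out["frac_changed"] = out["n_changed"] / out["n_exons"]
    return out
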