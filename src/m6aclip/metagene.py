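"""Anchored metagene density profiles and motif enrichment statistics.

Peak density at an anchored offset is presence/absence per mRNA: for
each 10-nt bin around the anchor (stop codon, start codon or last-exon
start, in transcript space), the profile value is the fraction of
length-eligible mRNAs with at least one peak overlapping the bin, with
an across-mRNA binomial standard error.

Splice-site-relative density is computed per nt of distance from the
donor or acceptor side of long internal exons (>= 200 nt by default)
and scaled to the mean per-nt density in the exon interior (> 100 nt
from both splice sites), so a value of 1 means parity with the exon
interior.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import TranscriptModel, segment_transcript
from .stats import fisher_exact_p

MOTIF_PATTERNS = {
    "RRACU": r"[AG][AG]AC[TU]",
    "RAC": r"[AG]AC",
}

ANCHORS = ("stop_codon", "start_codon", "last_exon_start")


def _anchor_tpos(t: TranscriptModel, anchor: str) -> int | None:
    if anchor == "stop_codon":
        return None if t.cds_end is None else t.cds_end
    if anchor == "start_codon":
        return None if t.cds_start is None else t.cds_start
    if anchor == "last_exon_start":
        return t.exon_tspan(t.n_exons - 1)[0]
    raise ValueError(f"unknown anchor {anchor!r}")


def map_peak_to_transcript(peak, t: TranscriptModel) -> tuple[int, int] | None:
    """Transcript-space [start, end) of a peak's exonic overlap with t."""
    tpos = [
        tp
        for g in range(peak.start, peak.end)
        if (tp := t.genomic_to_transcript(g)) is not None
    ]
    if not tpos:
        return None
    return min(tpos), max(tpos) + 1


def anchored_density_profile(peak_tspans: dict[str, list[tuple[int, int]]],
                             transcripts: list[TranscriptModel],
                             anchor: str = "stop_codon",
                             span: int = 1000,
                             bin_size: int = 10) -> pd.DataFrame:
    """Fraction of eligible mRNAs with a peak per bin around an anchor.

    ``peak_tspans`` maps transcript_id -> transcript-space peak
    intervals. For each bin ``[anchor + offset, anchor + offset +
    bin_size)`` only mRNAs that fully contain the bin are eligible;
    transcripts lacking the anchor (no CDS for stop/start) are skipped.
    Returns offset, density, sem (binomial, across mRNAs) and n.
    """
    offsets = np.arange(-span, span, bin_size)
    hits = np.zeros(offsets.size, dtype=np.int64)
    totals = np.zeros(offsets.size, dtype=np.int64)
    for t in transcripts:
        a = _anchor_tpos(t, anchor)
        if a is None:
            continue
        spans = peak_tspans.get(t.transcript_id, [])
        for j, off in enumerate(offsets):
            lo, hi = a + off, a + off + bin_size
            if lo < 0 or hi > t.mrna_length:
                continue
            totals[j] += 1
            if any(s < hi and lo < e for s, e in spans):
                hits[j] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        density = np.where(totals > 0, hits / np.maximum(totals, 1), np.nan)
        sem = np.where(
            totals > 0,
            np.sqrt(np.maximum(density * (1 - density), 0) / np.maximum(totals, 1)),
            np.nan,
        )
    return pd.DataFrame(
        {"anchor": anchor, "offset": offsets, "density": density,
         "sem": sem, "n": totals}
    )


def split_by_stop_in_last_exon(transcripts: list[TranscriptModel]
                               ) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Partition coding transcripts by whether the stop codon lies in
    the last exon (the black/red metagene classes)."""
    yes, no = [], []
    for t in transcripts:
        seg = segment_transcript(t)
        if seg["stop_in_last_exon"] is None:
            continue
        (yes if seg["stop_in_last_exon"] else no).append(t)
    return yes, no


# ---- splice-site-relative site density -----------------------------------

def internal_exons(transcripts: list[TranscriptModel],
                   min_length: int = 200) -> list[tuple[TranscriptModel, int]]:
    """(transcript, exon_index) for internal exons >= min_length nt."""
    out = []
    for t in transcripts:
        for i in range(1, t.n_exons - 1):
            s, e = t.exon_tspan(i)
            if e - s >= min_length:
                out.append((t, i))
    return out


def relative_density_vs_splice_site(site_tpos: dict[str, list[int]],
                                    transcripts: list[TranscriptModel],
                                    min_exon_length: int = 200,
                                    near_span: int = 100,
                                    require_m6a: bool = True) -> pd.DataFrame:
    """Per-nt site density vs distance from splice sites, interior-scaled.

    ``site_tpos`` maps transcript_id -> transcript-space site positions.
    For each internal exon >= ``min_exon_length`` nt (optionally
    restricted to exons carrying at least one site), sites are binned by
    distance from the nearer boundary on each side (0..near_span-1) and
    pooled over exons and sides; the per-nt density is divided by the
    mean per-nt density in exon interiors (> ``near_span`` from both
    boundaries). Returns offset, relative_density, sem, n_exons.
    """
    exons = internal_exons(transcripts, min_exon_length)
    near_counts = np.zeros(near_span, dtype=np.int64)
    far_sites = 0
    far_nt = 0
    n_exons = 0
    for t, idx in exons:
        es, ee = t.exon_tspan(idx)
        sites = [p for p in site_tpos.get(t.transcript_id, []) if es <= p < ee]
        if require_m6a and not sites:
            continue
        n_exons += 1
        far_nt += max(0, (ee - es) - 2 * near_span)
        for p in sites:
            d3 = p - es          # distance from acceptor (3'SS) side
            d5 = ee - 1 - p      # distance from donor (5'SS) side
            counted_near = False
            if d3 < near_span:
                near_counts[d3] += 1
                counted_near = True
            if d5 < near_span:
                near_counts[d5] += 1
                counted_near = True
            if not counted_near:
                far_sites += 1
    if n_exons == 0:
        return pd.DataFrame(
            columns=["offset", "relative_density", "sem", "n_exons"]
        )
    # each near offset is observed on two sides of every exon
    near_density = near_counts / (2.0 * n_exons)
    far_density = far_sites / far_nt if far_nt > 0 else np.nan
    if far_density and far_density > 0:
        rel = near_density / far_density
        # SEM under the interior-rate null (the natural reference for an
        # interior-scaled profile); observed-count SEMs blow up in
        # low-count bins
        expected_count = far_density * 2.0 * n_exons
        sem = np.full(near_span, 1.0 / np.sqrt(expected_count))
    else:
        rel = np.zeros_like(near_density)
        sem = np.full(near_span, np.nan)
    return pd.DataFrame(
        {
            "offset": np.arange(near_span),
            "relative_density": rel,
            "sem": sem,
            "n_exons": n_exons,
        }
    )


# ---- motif scanning and proximity enrichment -----------------------------

@dataclass
class MotifHits:
    motif: str
    positions: list[int]  # match start offsets

    @property
    def a_positions(self) -> list[int]:
        """Positions of the methylatable A within each match."""
        off = 2 if self.motif == "RRACU" else 1
        return [p + off for p in self.positions]


def motif_scan(sequence: str, motif: str = "RRACU") -> MotifHits:
    """All (overlapping) match start positions of a degenerate motif."""
    if motif not in MOTIF_PATTERNS:
        raise ValueError(f"unknown motif {motif!r}")
    pat = re.compile(f"(?=({MOTIF_PATTERNS[motif]}))", re.IGNORECASE)
    return MotifHits(motif, [m.start() for m in pat.finditer(sequence)])


def proximity_enrichment_test(n_sites_near: int, n_sites_total: int,
                              n_motifs_near: int, n_motifs_total: int) -> float:
    """Fisher p comparing the near-splice-site share of methylated sites
    with the near share of all consensus motifs (two-sided)."""
    if n_sites_near > n_sites_total or n_motifs_near > n_motifs_total:
        raise ValueError("near counts cannot exceed totals")
    return fisher_exact_p(
        n_sites_near, n_sites_total - n_sites_near,
        n_motifs_near, n_motifs_total - n_motifs_near,
        alternative="two-sided",
    )


def plot_profile(profile: pd.DataFrame, path, value_col: str = "density") -> None:
    """Optional PNG rendering of a density profile (offset vs value)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(profile["offset"], profile[value_col], lw=1.2)
    if "sem" in profile:
        ax.fill_between(
            profile["offset"],
            profile[value_col] - profile["sem"],
            profile[value_col] + profile["sem"],
            alpha=0.3, lw=0,
        )
    ax.set_xlabel("offset (nt)")
    ax.set_ylabel(value_col.replace("_", " "))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def quartile_assign(values) -> np.ndarray:
    """Rank-based equal-count quartile labels Q1..Q4 (Q1 = smallest).

    Ties are broken by stable input order toward the lower quartile;
    quartile sizes differ by at most one. Requires >= 4 finite values.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4 or not np.isfinite(v).all():
        raise ValueError("need at least 4 finite values")
    order = np.argsort(v, kind="stable")
    labels = np.empty(v.size, dtype=object)
    for q, chunk in enumerate(np.array_split(order, 4), start=1):
        labels[chunk] = f"Q{q}"
    return labels
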