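"""Cross-compartment and knockout differential peak analysis.

The same peak region is counted in two sides (CA vs nucleoplasm,
nucleoplasm vs cytoplasm, or WT vs Mettl3-KO) and tested with Fisher's
exact test on the (IP, input) count pairs; library-size normalisation
enters the enrichment fold change, not the 2x2 table. A differential
verdict additionally requires the fold-change and expression-adequacy
gates (region input RPKM >= 1 on both sides by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peaks import rpkm
from .stats import bh_adjust, fisher_exact_p

VERDICTS = ("A_higher", "B_higher", "no_change", "lost_in_B", "untestable")

#: columns expected of a per-side peak count table
COUNT_COLUMNS = ["peak_id", "chrom", "start", "end", "ip_count", "input_count"]


def _enrichment(ip_in, input_in, lib_ip, lib_input):
    ip_dens = ip_in / lib_ip
    in_dens = input_in / lib_input
    return np.where(in_dens > 0, ip_dens / np.maximum(in_dens, 1e-300), np.inf)


def differential_peaks(counts_a: pd.DataFrame,
                       counts_b: pd.DataFrame,
                       libsizes: dict[str, int],
                       rpkm_min: float = 1.0,
                       fold_min: float = 2.0,
                       fdr_max: float = 0.05) -> pd.DataFrame:
    """Compare each peak's enrichment between side A and side B.

    ``libsizes`` holds mapped-read totals under keys ``ip_a``,
    ``input_a``, ``ip_b``, ``input_b``. Returns one row per peak with
    fold change (A/B), Fisher p, BH FDR and a verdict: ``A_higher`` /
    ``B_higher`` when FDR <= ``fdr_max`` and the fold in that direction
    is >= ``fold_min``; ``untestable`` when either side's region input
    RPKM is below ``rpkm_min`` or the peak is missing from one side;
    ``no_change`` otherwise.
    """
    a = counts_a.set_index("peak_id")
    b = counts_b.set_index("peak_id")
    ids = sorted(set(a.index) | set(b.index))
    rows = []
    for pid in ids:
        row = {"peak_id": pid, "verdict": "untestable",
               "fold_change": np.nan, "p_value": np.nan, "fdr": np.nan}
        if pid not in a.index or pid not in b.index:
            rows.append(row)
            continue
        ra, rb = a.loc[pid], b.loc[pid]
        length = int(ra["end"] - ra["start"])
        row.update(
            chrom=ra["chrom"], start=int(ra["start"]), end=int(ra["end"]),
            ip_a=int(ra["ip_count"]), input_a=int(ra["input_count"]),
            ip_b=int(rb["ip_count"]), input_b=int(rb["input_count"]),
        )
        rpkm_a = rpkm(int(ra["input_count"]), length, libsizes["input_a"])
        rpkm_b = rpkm(int(rb["input_count"]), length, libsizes["input_b"])
        row["rpkm_a"], row["rpkm_b"] = rpkm_a, rpkm_b
        if rpkm_a < rpkm_min or rpkm_b < rpkm_min:
            rows.append(row)
            continue
        enr_a = _enrichment(row["ip_a"], row["input_a"],
                            libsizes["ip_a"], libsizes["input_a"])
        enr_b = _enrichment(row["ip_b"], row["input_b"],
                            libsizes["ip_b"], libsizes["input_b"])
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = float(enr_a) / float(enr_b) if enr_b > 0 else np.inf
        row["fold_change"] = fold
        row["p_value"] = fisher_exact_p(
            row["ip_a"], row["input_a"], row["ip_b"], row["input_b"],
            alternative="two-sided",
        )
        row["verdict"] = "tested"
        rows.append(row)

    df = pd.DataFrame(rows)
    tested = df["verdict"] == "tested"
    if tested.any():
        df.loc[tested, "fdr"] = bh_adjust(df.loc[tested, "p_value"].to_numpy())
        for i in df.index[tested]:
            fold, fdr = df.at[i, "fold_change"], df.at[i, "fdr"]
            if fdr <= fdr_max and fold >= fold_min:
                df.at[i, "verdict"] = "A_higher"
            elif fdr <= fdr_max and fold <= 1.0 / fold_min:
                df.at[i, "verdict"] = "B_higher"
            else:
                df.at[i, "verdict"] = "no_change"
    return df


def peak_loss_ko(wt_counts: pd.DataFrame,
                 ko_counts: pd.DataFrame,
                 libsizes: dict[str, int],
                 rpkm_min: float = 1.0,
                 fold_min: float = 2.0,
                 fdr_max: float = 0.05) -> pd.DataFrame:
    """Flag WT peaks lost in the knockout.

    A peak is ``lost_in_B`` (B = knockout) when expression is adequate
    on both sides (region input RPKM >= ``rpkm_min``) and the knockout
    enrichment decreased at least ``fold_min``-fold at FDR <=
    ``fdr_max``. ``libsizes`` keys: ``ip_a``/``input_a`` for WT,
    ``ip_b``/``input_b`` for KO.
    """
    df = differential_peaks(
        wt_counts, ko_counts, libsizes,
        rpkm_min=rpkm_min, fold_min=fold_min, fdr_max=fdr_max,
    )
    df["verdict"] = df["verdict"].replace({"A_higher": "lost_in_B"})
    df["lost"] = df["verdict"] == "lost_in_B"
    return df


def assign_peak_regions(peaks, annotation) -> pd.DataFrame:
    """Map peaks to representative transcripts and mRNA regions.

    The midpoint of each peak's exonic overlap decides the feature
    (5UTR/CDS/3UTR) and whether it lies in the last exon; peaks outside
    every representative transcript are omitted.
    """
    from .annotation import feature_of_tpos

    rows = []
    for p in peaks:
        for t in annotation.transcripts_overlapping(p.chrom, p.start, p.end):
            tpos = [
                tp
                for g in range(p.start, p.end)
                if (tp := t.genomic_to_transcript(g)) is not None
            ]
            if not tpos:
                continue
            mid = sorted(tpos)[len(tpos) // 2]
            rows.append(
                {
                    "peak_id": p.peak_id,
                    "transcript_id": t.transcript_id,
                    "tpos": mid,
                    "region": feature_of_tpos(t, mid),
                    "last_exon": t.exon_index_of(mid) == t.n_exons - 1,
                }
            )
            break  # representatives are non-overlapping: at most one hit
    return pd.DataFrame(rows)


def tally_lost_by_transcript(loss_df: pd.DataFrame,
                             peak_regions: pd.DataFrame) -> pd.DataFrame:
    """Per-transcript tallies of lost peaks and the mRNA regions hit.

    ``peak_regions`` maps peak_id -> (transcript_id, region) where
    region is 5UTR/CDS/3UTR plus a last-exon flag. Returns one row per
    transcript with n_lost and a region summary in
    {none, CDS, 3UTR, both}.
    """
    merged = loss_df.merge(peak_regions, on="peak_id", how="left")
    rows = []
    for tid, grp in merged.groupby("transcript_id", dropna=True):
        lost = grp[grp["lost"]]
        regions = set(lost["region"].dropna())
        if {"CDS", "3UTR"} <= regions:
            region = "both"
        elif "CDS" in regions:
            region = "CDS"
        elif "3UTR" in regions:
            region = "3UTR"
        else:
            region = "none"
        rows.append(
            {
                "transcript_id": tid,
                "n_peaks": len(grp),
                "n_lost": int(lost.shape[0]),
                "lost_region": region,
                "n_lost_last_exon": int(lost.get("last_exon", pd.Series(dtype=bool)).sum())
                if "last_exon" in lost else 0,
            }
        )
    return pd.DataFrame(rows)
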