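"""End-to-end pipeline orchestration.

Stages run in dependency order on a validated YAML configuration:
annotate -> peak calling per compartment -> precise sites -> exon/
intron and metagene localisation -> splicing -> compartment and KO
comparisons -> half-lives. Every output TSV carries a provenance header
(config hash + seed); the report re-derives its numbers from the stage
outputs so the summary never contains report-only computation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import alignio, annotation as ann, compare, halflife as hl, metagene
from . import peaks as pk, simulate as sim, splicing as spl

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "fdr": 0.05, "fold": 2.0, "rpkm_min": 1.0, "dpsi_min": 0.1,
    "peak_min_cov": 5, "peak_max_width": 100, "peak_min_width": 10,
}

COMPARTMENTS = ("CA", "nucleoplasm", "cytoplasm")


class PipelineConfig:
    """Validated pipeline configuration (paths, thresholds, seed)."""

    def __init__(self, raw: dict, base_dir: Path | None = None):
        self.raw = raw
        self.base = Path(base_dir) if base_dir else Path(".")
        self.seed = int(raw.get("seed", 0))
        self.outdir = self.base / raw.get("outdir", "m6aclip_out")
        self.thresholds = {**DEFAULT_THRESHOLDS, **raw.get("thresholds", {})}
        for key in ("fdr", "dpsi_min"):
            v = self.thresholds[key]
            if not 0 < v <= 1:
                raise ValueError(f"threshold {key}={v} outside (0, 1]")
        if self.thresholds["fold"] < 1:
            raise ValueError("fold threshold must be >= 1")
        self.simulate = raw.get("simulate")
        self.paths = raw.get("paths", {})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            return cls(yaml.safe_load(fh), base_dir=path.parent)

    @property
    def config_hash(self) -> str:
        # the output location is not part of the analysis configuration
        hashable = {k: v for k, v in self.raw.items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(hashable, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _provenance(cfg: PipelineConfig) -> str:
    return f"# m6aclip config={cfg.config_hash} seed={cfg.seed}\n"


def write_tsv(df: pd.DataFrame, path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(cfg))
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---- stage: simulate -----------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> dict[str, Path]:
    """Generate all pipeline inputs from the simulator and write them."""
    outdir = cfg.outdir / "sim"
    outdir.mkdir(parents=True, exist_ok=True)
    overrides = dict(cfg.simulate or {})
    overrides.setdefault("seed", cfg.seed)
    simcfg = sim.SimulationConfig(**{
        k: tuple(v) if isinstance(v, list) else v for k, v in overrides.items()
    })
    genome, annot = sim.make_genome_and_annotation(simcfg)
    truth = sim.plant_sites(genome, annot, simcfg)

    sim.write_fasta(genome, outdir / "genome.fa")
    ann.write_gtf(annot, outdir / "annotation.gtf")
    truth.to_json(outdir / "truth.json")

    paths = {"genome": outdir / "genome.fa", "annotation": outdir / "annotation.gtf",
             "truth": outdir / "truth.json"}
    for compartment in COMPARTMENTS:
        ip, inp = sim.simulate_clip_reads(truth, annot, simcfg, compartment, "WT")
        path = outdir / f"{compartment}_WT.tsv"
        alignio.write_alignments_tsv(ip + inp, path)
        paths[f"reads_{compartment}_WT"] = path
    ip, inp = sim.simulate_clip_reads(truth, annot, simcfg, "cytoplasm", "KO")
    paths["reads_cytoplasm_KO"] = outdir / "cytoplasm_KO.tsv"
    alignio.write_alignments_tsv(ip + inp, paths["reads_cytoplasm_KO"])

    for condition in ("WT", "KO"):
        tc, sf = sim.simulate_timecourse(truth, simcfg, condition)
        tc.to_csv(outdir / f"timecourse_{condition}.tsv", sep="\t", index=False)
        sf.to_csv(outdir / f"size_factors_{condition}.tsv", sep="\t", index=False)
        paths[f"timecourse_{condition}"] = outdir / f"timecourse_{condition}.tsv"
        paths[f"size_factors_{condition}"] = outdir / f"size_factors_{condition}.tsv"
    return paths


# ---- individual stages ---------------------------------------------------

def _load_genome(path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def _split_libraries(reads):
    ip = [r for r in reads if r.library == "IP"]
    inp = [r for r in reads if r.library != "IP"]
    return ip, inp


def _chrom_sizes(genome: dict[str, str]) -> dict[str, int]:
    return {c: len(s) for c, s in genome.items()}


def call_sample_peaks(reads, genome, annot, thresholds):
    ip, inp = _split_libraries(reads)
    candidates = pk.build_candidate_regions(
        ip, _chrom_sizes(genome),
        min_cov=thresholds["peak_min_cov"],
        max_width=thresholds["peak_max_width"],
        min_width=thresholds["peak_min_width"],
    )
    return pk.call_peaks(ip, inp, candidates, annot,
                         fdr_cutoff=thresholds["fdr"])


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage whose inputs exist; return the report dict."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: cfg.base / v for k, v in cfg.paths.items()}
    if cfg.simulate is not None:
        paths.update(stage_simulate(cfg))

    report: dict = {"config_hash": cfg.config_hash, "seed": cfg.seed}
    if "annotation" not in paths:
        logger.warning("no annotation input: nothing to do")
        return report
    annot = ann.load_annotation(paths["annotation"])
    annot = ann.select_representative_isoforms(annot)
    ann.write_representatives_bed12(annot, cfg.outdir / "representatives.bed")
    ann.write_segmentation_tsv(annot, cfg.outdir / "segmentation.tsv")
    genome = _load_genome(paths["genome"]) if "genome" in paths else None

    th = cfg.thresholds
    reads_by_sample: dict[str, list] = {}
    peak_sets: dict[str, list] = {}
    sites_by_sample: dict[str, list] = {}
    for key, path in sorted(paths.items()):
        if not key.startswith("reads_"):
            continue
        sample = key[len("reads_"):]
        reads = alignio.read_alignments_tsv(path)
        reads_by_sample[sample] = reads
        if genome is None:
            logger.warning("stage callpeaks skipped for %s: no genome", sample)
            continue
        peaks = call_sample_peaks(reads, genome, annot, th)
        peak_sets[sample] = peaks
        pk.write_peaks_bed(peaks, cfg.outdir / f"peaks_{sample}.bed")
        ip, _ = _split_libraries(reads)
        sites = pk.call_precise_sites(ip, genome, peaks)
        sites_by_sample[sample] = sites
        pk.write_sites_bed(sites, cfg.outdir / f"sites_{sample}.bed")
        labels = [p.label for p in peaks if p.label in ("exonic", "intronic")]
        report[f"peaks_{sample}"] = {
            "n_peaks": len(peaks),
            "n_sites": len(sites),
            "exonic_fraction": (
                labels.count("exonic") / len(labels) if labels else None
            ),
        }

    # metagene profiles on the CA-WT peak set
    if "CA_WT" in peak_sets:
        reps = annot.representatives()
        tspans: dict[str, list[tuple[int, int]]] = {}
        for p in peak_sets["CA_WT"]:
            for t in annot.transcripts_overlapping(p.chrom, p.start, p.end):
                span = metagene.map_peak_to_transcript(p, t)
                if span:
                    tspans.setdefault(t.transcript_id, []).append(span)
        profile = metagene.anchored_density_profile(tspans, reps, "stop_codon")
        write_tsv(profile, cfg.outdir / "metagene_stop_codon.tsv", cfg)

    # splicing completion per intron (CA vs nucleoplasm)
    junction_tables = {}
    for sample in ("CA_WT", "nucleoplasm_WT"):
        if sample not in reads_by_sample:
            continue
        _, inp = _split_libraries(reads_by_sample[sample])
        tables = [
            spl.completion_index_table(spl.count_junction_reads(inp, t))
            for t in annot.representatives()
        ]
        tables = [t for t in tables if not t.empty]
        if tables:
            junction_tables[sample] = pd.concat(tables, ignore_index=True)
            write_tsv(junction_tables[sample],
                      cfg.outdir / f"splicing_completion_{sample}.tsv", cfg)

    # m6A-bearing exon-intron junction reads
    if "CA_WT" in sites_by_sample:
        by_comp = {
            "CA": reads_by_sample.get("CA_WT", []),
            "nucleoplasm": reads_by_sample.get("nucleoplasm_WT", []),
            "cytoplasm": reads_by_sample.get("cytoplasm_WT", []),
        }
        accepted = spl.find_m6a_junction_reads(
            sites_by_sample["CA_WT"], by_comp, annot
        )
        report["junction_m6a_reads"] = {
            "n_records": len(accepted),
            "n_sites": len({(a.site.chrom, a.site.coordinate) for a in accepted}),
            "n_exons": len({(a.transcript_id, a.exon_index) for a in accepted}),
        }
        rows = [
            {
                "chrom": a.site.chrom, "coordinate": a.site.coordinate,
                "transcript_id": a.transcript_id, "exon_index": a.exon_index,
                "side": a.side, "distance_nt": a.distance_nt,
                "ca_count": a.ca_count,
                "nucleoplasm_count": a.nucleoplasm_count,
                "cytoplasm_count": a.cytoplasm_count,
            }
            for a in accepted
        ]
        write_tsv(pd.DataFrame(rows), cfg.outdir / "junction_m6a_reads.tsv", cfg)

    # compartment comparison: CA vs nucleoplasm on the CA peak set
    if "CA_WT" in peak_sets and "nucleoplasm_WT" in reads_by_sample:
        ca_ip, ca_in = _split_libraries(reads_by_sample["CA_WT"])
        np_ip, np_in = _split_libraries(reads_by_sample["nucleoplasm_WT"])
        counts_a = pk.peaks_to_frame(peak_sets["CA_WT"])
        counts_b = pk.count_peaks_in_libraries(peak_sets["CA_WT"], np_ip, np_in)
        diff = compare.differential_peaks(
            counts_a, counts_b,
            {"ip_a": len(ca_ip), "input_a": len(ca_in),
             "ip_b": len(np_ip), "input_b": len(np_in)},
            rpkm_min=th["rpkm_min"], fold_min=th["fold"], fdr_max=th["fdr"],
        )
        write_tsv(diff, cfg.outdir / "diff_CA_vs_nucleoplasm.tsv", cfg)
        report["diff_CA_vs_nucleoplasm"] = (
            diff["verdict"].value_counts().to_dict()
        )

    # knockout loss on the WT cytoplasm peak set
    loss_tally = None
    if "cytoplasm_WT" in peak_sets and "cytoplasm_KO" in reads_by_sample:
        wt_ip, wt_in = _split_libraries(reads_by_sample["cytoplasm_WT"])
        ko_ip, ko_in = _split_libraries(reads_by_sample["cytoplasm_KO"])
        wt_counts = pk.peaks_to_frame(peak_sets["cytoplasm_WT"])
        ko_counts = pk.count_peaks_in_libraries(
            peak_sets["cytoplasm_WT"], ko_ip, ko_in
        )
        loss = compare.peak_loss_ko(
            wt_counts, ko_counts,
            {"ip_a": len(wt_ip), "input_a": len(wt_in),
             "ip_b": len(ko_ip), "input_b": len(ko_in)},
            rpkm_min=th["rpkm_min"], fold_min=th["fold"], fdr_max=th["fdr"],
        )
        write_tsv(loss, cfg.outdir / "ko_peak_loss.tsv", cfg)
        report["ko_peak_loss"] = {
            "n_peaks": int(len(loss)),
            "n_lost": int(loss["lost"].sum()),
        }
        regions = compare.assign_peak_regions(peak_sets["cytoplasm_WT"], annot)
        if not regions.empty:
            loss_tally = compare.tally_lost_by_transcript(loss, regions)
            write_tsv(loss_tally, cfg.outdir / "ko_loss_by_transcript.tsv", cfg)

    # half-lives
    fits = {}
    for condition in ("WT", "KO"):
        key = f"timecourse_{condition}"
        if key not in paths:
            continue
        tc = pd.read_csv(paths[key], sep="\t")
        sf_key = f"size_factors_{condition}"
        sf = pd.read_csv(paths[sf_key], sep="\t") if sf_key in paths else None
        results = hl.ExponentialDecayModel(tc, size_factors=sf).fit()
        results.to_tsv(cfg.outdir / f"decay_fits_{condition}.tsv")
        fits[condition] = results.filter_reliable(th["fdr"])
        report[f"halflife_{condition}"] = {
            "n_reliable": int(len(fits[condition])),
            "median_halflife_h": float(fits[condition]["halflife_h"].median())
            if len(fits[condition]) else None,
        }
    if {"WT", "KO"} <= fits.keys():
        change = hl.halflife_change(fits["WT"], fits["KO"], loss_tally)
        write_tsv(change, cfg.outdir / "halflife_change.tsv", cfg)
        report["halflife_change_median_ratio"] = float(change["ratio"].median())

    with open(cfg.outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    return report
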