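"""Synthetic genomes, planted m6A truth, CLIP reads and decay courses.

The generator emulates the study conditions end-to-end so that every
pipeline stage can be tested against a known ground truth: multi-exon
genes on a random genome; m6A sites planted on RAC-consensus adenosines
with a strong exon bias (93% exonic by default), last-exon enrichment
and splice-site-proximal depletion (0.5x within 50 nt); a chromatin
(CA) compartment with per-intron splicing completion levels;
IP libraries that oversample ~80-nt fragments covering sites and carry
cross-link artifacts (substitutions, deletions, 5' truncations) at the
methylated A; a knockout condition that removes 90% of sites; and
first-order decay time courses (0/1/2/4/8 h, 3 replicates) whose true
rate increases linearly with the transcript's exonic site count
(k = k0 + delta * n_sites).

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .alignio import ReadAlignment
from .annotation import GeneAnnotation, TranscriptModel
from .peaks import revcomp

BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """All knobs of the simulator; defaults are the study conditions."""

    n_genes: int = 60
    exons_per_gene: tuple[int, int] = (3, 7)
    exon_length: tuple[int, int] = (150, 400)
    intron_length: tuple[int, int] = (200, 600)
    intergenic_gap: tuple[int, int] = (300, 800)
    stop_in_last_frac: float = 0.95

    n_sites: int = 150
    frac_exonic: float = 0.93
    last_exon_enrichment: float = 3.0
    splice_depletion: float = 0.5
    splice_depletion_span: int = 50

    ca_retention: tuple[float, float] = (0.2, 0.8)
    retention_increases_3prime: bool = True

    ip_enrichment: float = 8.0
    substitution_rate: float = 0.15
    deletion_rate: float = 0.05
    truncation_rate: float = 0.15
    fragment_mean: float = 80.0
    fragment_sd: float = 10.0
    fragment_bounds: tuple[int, int] = (30, 120)
    reads_per_library: int = 20000

    k0: float = 0.1
    delta_k: float = 0.08
    a0_range: tuple[float, float] = (200.0, 800.0)
    timepoints: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 8.0)
    replicates: int = 3
    size_factor_sigma: float = 0.1

    ko_removal_frac: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_exonic", "splice_depletion", "stop_in_last_frac",
                     "ko_removal_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("exon_length", "intron_length", "intergenic_gap"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if not 0.0 <= self.ca_retention[0] <= self.ca_retention[1] <= 1.0:
            raise ValueError("ca_retention must be an increasing pair in [0,1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")


@dataclass
class PlantedSite:
    chrom: str
    pos: int  # genomic coordinate of the methylated A
    strand: str
    transcript_id: str
    exonic: bool
    exon_index: int | None  # transcript-order exon index (None for intronic)
    intron_index: int | None
    tpos: int | None  # transcript-space position (None for intronic)
    motif: str  # RRACU or RAC
    present_in_ko: bool


@dataclass
class GroundTruth:
    """Everything the simulator planted, serialisable to JSON."""

    sites: list[PlantedSite]
    retention: dict[str, float]  # "tid:intron_index" -> retained fraction
    k_wt: dict[str, float]
    k_ko: dict[str, float]
    a0: dict[str, float]
    size_factors: dict[str, float]  # "condition:time:replicate" -> factor

    def sites_for(self, transcript_id: str, condition: str = "WT") -> list[PlantedSite]:
        return [
            s for s in self.sites
            if s.transcript_id == transcript_id
            and (condition == "WT" or s.present_in_ko)
        ]

    def exonic_fraction(self) -> float:
        return sum(s.exonic for s in self.sites) / len(self.sites)

    def to_json(self, path) -> None:
        payload = {
            "sites": [asdict(s) for s in self.sites],
            "retention": self.retention,
            "k_wt": self.k_wt, "k_ko": self.k_ko, "a0": self.a0,
            "size_factors": self.size_factors,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            sites=[PlantedSite(**s) for s in payload["sites"]],
            retention=payload["retention"],
            k_wt=payload["k_wt"], k_ko=payload["k_ko"], a0=payload["a0"],
            size_factors=payload["size_factors"],
        )


# ---- genome and annotation ----------------------------------------------

def make_genome_and_annotation(config: SimulationConfig, seed: int | None = None
                               ) -> tuple[dict[str, str], GeneAnnotation]:
    """Random multi-exon genes with non-overlapping spans on one chromosome."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    transcripts: dict[str, TranscriptModel] = {}
    cursor = int(rng.integers(*config.intergenic_gap))
    for g in range(config.n_genes):
        n_exons = int(rng.integers(config.exons_per_gene[0],
                                   config.exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = cursor
        for i in range(n_exons):
            elen = int(rng.integers(config.exon_length[0],
                                    config.exon_length[1] + 1))
            exons.append((pos, pos + elen))
            pos += elen
            if i < n_exons - 1:
                pos += int(rng.integers(config.intron_length[0],
                                        config.intron_length[1] + 1))
        cursor = pos + int(rng.integers(*config.intergenic_gap))
        tid, gid = f"tx{g:04d}", f"gene{g:04d}"
        t = TranscriptModel(tid, gid, "chr1", strand, exons)
        _assign_cds(t, config, rng)
        transcripts[tid] = t

    length = cursor + int(rng.integers(*config.intergenic_gap))
    seq = "".join(rng.choice(BASES, size=length))
    annotation = GeneAnnotation(transcripts, representative_ids=set(transcripts))
    return {"chr1": seq}, annotation


def _assign_cds(t: TranscriptModel, config: SimulationConfig, rng) -> None:
    L = t.mrna_length
    cds_start = int(rng.integers(10, max(11, min(150, L // 4))))
    if t.n_exons >= 2 and rng.random() >= config.stop_in_last_frac:
        lo, hi = t.exon_tspan(t.n_exons - 2)  # stop in penultimate exon
    else:
        lo, hi = t.exon_tspan(t.n_exons - 1)
    lo = max(lo, cds_start + 30)
    if lo >= hi:
        cds_end = min(L, cds_start + 60)
    else:
        cds_end = int(rng.integers(lo, hi))
    t.cds_start, t.cds_end = cds_start, max(cds_end, cds_start + 3)
    t.__post_init__()


def write_fasta(genome: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def transcript_mrna_sequence(genome: dict[str, str], t: TranscriptModel) -> str:
    parts = []
    for s, e in t.exons_in_transcript_order():
        block = genome[t.chrom][s:e]
        parts.append(block if t.strand == "+" else revcomp(block))
    return "".join(parts)


# ---- site planting -------------------------------------------------------

def _sense_rac_positions(seq: str) -> list[int]:
    """Offsets of the A in each RAC match of a sense-strand sequence."""
    out = []
    for i in range(len(seq) - 2):
        if seq[i] in "AG" and seq[i + 1] == "A" and seq[i + 2] == "C":
            out.append(i + 1)
    return out


def _motif_context(seq: str, a_off: int) -> str:
    five = seq[max(0, a_off - 2):a_off + 3]
    if len(five) == 5 and five[0] in "AG" and five[1] in "AG" and \
            five[2] == "A" and five[3] == "C" and five[4] in "TU":
        return "RRACU"
    return "RAC"


def plant_sites(genome: dict[str, str], annotation: GeneAnnotation,
                config: SimulationConfig, seed: int | None = None) -> GroundTruth:
    """Sample m6A sites on RAC adenosines and derive the decay truth."""
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 1 & 0x7FFFFFFF
    )
    exonic_cands: list[PlantedSite] = []
    exonic_weights: list[float] = []
    intronic_cands: list[PlantedSite] = []

    for t in annotation.representatives():
        mrna = transcript_mrna_sequence(genome, t)
        for a_off in _sense_rac_positions(mrna):
            idx = t.exon_index_of(a_off)
            es, ee = t.exon_tspan(idx)
            w = 1.0
            if idx == t.n_exons - 1:
                w *= config.last_exon_enrichment
            dists = []
            if idx > 0:
                dists.append(a_off - es)
            if idx < t.n_exons - 1:
                dists.append(ee - 1 - a_off)
            if dists and min(dists) < config.splice_depletion_span:
                w *= config.splice_depletion
            exonic_cands.append(
                PlantedSite(
                    chrom=t.chrom, pos=t.transcript_to_genomic(a_off),
                    strand=t.strand, transcript_id=t.transcript_id,
                    exonic=True, exon_index=idx, intron_index=None,
                    tpos=a_off, motif=_motif_context(mrna, a_off),
                    present_in_ko=False,
                )
            )
            exonic_weights.append(w)
        for gi, (istart, iend) in enumerate(t.introns()):
            # gi is the genomic-order intron index, matching retention keys
            iseq = genome[t.chrom][istart:iend]
            sense = iseq if t.strand == "+" else revcomp(iseq)
            for a_off in _sense_rac_positions(sense):
                gpos = istart + a_off if t.strand == "+" else iend - 1 - a_off
                intronic_cands.append(
                    PlantedSite(
                        chrom=t.chrom, pos=gpos, strand=t.strand,
                        transcript_id=t.transcript_id, exonic=False,
                        exon_index=None, intron_index=gi, tpos=None,
                        motif=_motif_context(sense, a_off),
                        present_in_ko=False,
                    )
                )

    n_exonic = min(int(round(config.n_sites * config.frac_exonic)),
                   len(exonic_cands))
    n_intronic = min(config.n_sites - n_exonic, len(intronic_cands))
    w = np.asarray(exonic_weights)
    chosen_e = rng.choice(len(exonic_cands), size=n_exonic, replace=False,
                          p=w / w.sum())
    chosen_i = rng.choice(len(intronic_cands), size=n_intronic, replace=False)
    sites = [exonic_cands[i] for i in sorted(chosen_e)] + [
        intronic_cands[i] for i in sorted(chosen_i)
    ]
    for s in sites:
        s.present_in_ko = bool(rng.random() >= config.ko_removal_frac)

    # decay truth: k = k0 + delta * (exonic sites on the mRNA)
    k_wt, k_ko, a0 = {}, {}, {}
    for t in annotation.representatives():
        tid = t.transcript_id
        n_wt = sum(1 for s in sites if s.transcript_id == tid and s.exonic)
        n_ko = sum(
            1 for s in sites
            if s.transcript_id == tid and s.exonic and s.present_in_ko
        )
        k_wt[tid] = config.k0 + config.delta_k * n_wt
        k_ko[tid] = config.k0 + config.delta_k * n_ko
        a0[tid] = float(rng.uniform(*config.a0_range))

    retention: dict[str, float] = {}
    for t in annotation.representatives():
        n_introns = t.n_exons - 1
        draws = np.sort(rng.uniform(*config.ca_retention, size=n_introns))
        if not config.retention_increases_3prime:
            rng.shuffle(draws)
        order = range(n_introns) if t.strand == "+" else range(n_introns - 1, -1, -1)
        # transcript-order intron j maps to genomic-order intron via strand
        for j, gi in enumerate(order):
            retention[f"{t.transcript_id}:{gi}"] = float(draws[j])

    size_factors = {
        f"{cond}:{tp:g}:{rep}": float(rng.lognormal(0.0, config.size_factor_sigma))
        for cond in ("WT", "KO")
        for tp in config.timepoints
        for rep in range(1, config.replicates + 1)
    }
    return GroundTruth(sites=sites, retention=retention, k_wt=k_wt, k_ko=k_ko,
                       a0=a0, size_factors=size_factors)


# ---- CLIP read simulation ------------------------------------------------

class _MoleculeMap:
    """Molecule (5'->3') to genome mapping for one RNA molecule."""

    def __init__(self, t: TranscriptModel, retained: set[int]):
        # segments in transcript order: exon i, then intron i if retained
        segs: list[tuple[int, int]] = []  # genomic (start, end) per segment
        introns = t.introns()
        exons_t = t.exons_in_transcript_order()
        n = t.n_exons
        for i, (es, ee) in enumerate(exons_t):
            segs.append((es, ee))
            if i < n - 1:
                gi = i if t.strand == "+" else n - 2 - i
                if gi in retained:
                    segs.append(introns[gi])
        self.t = t
        self.segs = segs
        self.offsets = np.concatenate(
            ([0], np.cumsum([e - s for s, e in segs]))
        )
        self.length = int(self.offsets[-1])

    def genomic_blocks(self, m_start: int, m_end: int) -> tuple[tuple[int, int], ...]:
        blocks: list[tuple[int, int]] = []
        for i, (gs, ge) in enumerate(self.segs):
            lo = max(m_start, int(self.offsets[i]))
            hi = min(m_end, int(self.offsets[i + 1]))
            if lo >= hi:
                continue
            o = lo - int(self.offsets[i])
            ln = hi - lo
            if self.t.strand == "+":
                blocks.append((gs + o, gs + o + ln))
            else:
                blocks.append((ge - o - ln, ge - o))
        blocks.sort()
        merged = [list(blocks[0])]
        for s, e in blocks[1:]:
            if s == merged[-1][1]:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        return tuple((s, e) for s, e in merged)

    def molecule_pos(self, gpos: int) -> int | None:
        for i, (gs, ge) in enumerate(self.segs):
            if gs <= gpos < ge:
                o = gpos - gs if self.t.strand == "+" else ge - 1 - gpos
                return int(self.offsets[i]) + o
        return None


def simulate_clip_reads(truth: GroundTruth, annotation: GeneAnnotation,
                        config: SimulationConfig, compartment: str = "CA",
                        condition: str = "WT", seed: int | None = None,
                        depth: int | None = None
                        ) -> tuple[list[ReadAlignment], list[ReadAlignment]]:
    """Simulate one compartment's IP and input libraries.

    Input fragments are drawn uniformly from the compartment's RNA
    population (CA molecules retain each intron with its planted
    probability; other compartments are fully spliced, so intronic
    sites vanish there by construction). IP fragments covering an
    active site are oversampled by ``ip_enrichment`` and carry
    substitution/deletion/5'-truncation artifacts at the methylated A.
    """
    rng = np.random.default_rng(
        ((config.seed if seed is None else seed)
         + _compartment_offset(compartment, condition)) & 0x7FFFFFFF
    )
    depth = config.reads_per_library if depth is None else depth
    reps = annotation.representatives()
    sites_by_tid: dict[str, list[PlantedSite]] = {}
    for t in reps:
        sites_by_tid[t.transcript_id] = truth.sites_for(t.transcript_id, condition)

    ip_reads: list[ReadAlignment] = []
    input_reads: list[ReadAlignment] = []
    for library, out in (("input", input_reads), ("IP", ip_reads)):
        count = 0
        while count < depth:
            t = reps[int(rng.integers(len(reps)))]
            retained: set[int] = set()
            if compartment == "CA":
                for gi in range(t.n_exons - 1):
                    if rng.random() < truth.retention[f"{t.transcript_id}:{gi}"]:
                        retained.add(gi)
            mol = _MoleculeMap(t, retained)
            flen = int(np.clip(
                round(rng.normal(config.fragment_mean, config.fragment_sd)),
                *config.fragment_bounds,
            ))
            flen = min(flen, mol.length)
            m_start = int(rng.integers(0, mol.length - flen + 1))
            m_end = m_start + flen

            site_mpos = []
            for s in sites_by_tid[t.transcript_id]:
                if not s.exonic and s.intron_index not in retained:
                    continue
                mp = mol.molecule_pos(s.pos)
                if mp is not None and m_start <= mp < m_end:
                    site_mpos.append((mp, s))
            covered = bool(site_mpos)

            if library == "IP":
                weight = config.ip_enrichment if covered else 1.0
                if rng.random() >= weight / config.ip_enrichment:
                    continue

            subs: list[int] = []
            dels: list[int] = []
            truncated = False
            if library == "IP" and covered:
                mp, s = site_mpos[int(rng.integers(len(site_mpos)))]
                if rng.random() < config.truncation_rate:
                    m_start = mp  # cDNA stops at the cross-linked A
                    truncated = True
                if rng.random() < config.substitution_rate and m_start <= mp < m_end:
                    subs.append(s.pos)
                elif rng.random() < config.deletion_rate and m_start <= mp < m_end:
                    dels.append(s.pos)

            out.append(
                ReadAlignment(
                    chrom=t.chrom, strand=t.strand,
                    blocks=mol.genomic_blocks(m_start, m_end),
                    library=library, sample=compartment, condition=condition,
                    substitutions=tuple(subs), deletions=tuple(dels),
                    truncated=truncated,
                    read_id=f"{compartment}_{condition}_{library}_{count}",
                )
            )
            count += 1
    return ip_reads, input_reads


def _compartment_offset(compartment: str, condition: str) -> int:
    key = f"{compartment}:{condition}"
    return 1000 + (hash_stable(key) % 100000)


def hash_stable(text: str) -> int:
    """Deterministic small hash (Python's hash() is salted per process)."""
    h = 0
    for ch in text:
        h = (h * 131 + ord(ch)) % 1_000_003
    return h


# ---- decay time courses --------------------------------------------------

def simulate_timecourse(truth: GroundTruth, config: SimulationConfig,
                        condition: str = "WT", seed: int | None = None):
    """Poisson counts around A0 exp(-k t) x size factor, per replicate.

    Returns (tidy DataFrame, size-factor DataFrame).
    """
    import pandas as pd

    rng = np.random.default_rng(
        ((config.seed if seed is None else seed)
         + 7 + (0 if condition == "WT" else 13)) & 0x7FFFFFFF
    )
    k = truth.k_wt if condition == "WT" else truth.k_ko
    rows = []
    for tid in sorted(k):
        for tp in config.timepoints:
            for rep in range(1, config.replicates + 1):
                sf = truth.size_factors[f"{condition}:{tp:g}:{rep}"]
                lam = truth.a0[tid] * np.exp(-k[tid] * tp) * sf
                rows.append(
                    {"transcript_id": tid, "time_h": tp, "replicate": rep,
                     "abundance": int(rng.poisson(lam))}
                )
    sf_rows = [
        {"time_h": tp, "replicate": rep,
         "size_factor": truth.size_factors[f"{condition}:{tp:g}:{rep}"]}
        for tp in config.timepoints
        for rep in range(1, config.replicates + 1)
    ]
    return pd.DataFrame(rows), pd.DataFrame(sf_rows)


def simulate_junction_evidence(retention: float, reads_per_boundary: int,
                               rng) -> tuple[int, int]:
    """Junction read-outs for one intron at a given boundary depth.

    Reads fall uniformly on molecules that retain the intron with
    probability ``retention``. A retained molecule exposes two boundary
    windows (donor and acceptor), a spliced molecule one exon-exon
    junction window, so with a per-window rate of ``reads_per_boundary``
    the counts are s ~ Pois(N(1-r)) and u_d, u_a ~ Pois(Nr). Returns
    (spliced, unspliced_pooled); see
    :func:`m6aclip.splicing.retention_estimate` for the matching
    estimator.
    """
    n = reads_per_boundary
    spliced = int(rng.poisson(n * (1.0 - retention)))
    unspliced = int(rng.poisson(n * retention)) + int(rng.poisson(n * retention))
    return spliced, unspliced
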