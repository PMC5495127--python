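"""Peak-region construction, enrichment testing and precise-site calls."""

import numpy as np
import pytest

from m6aclip.alignio import ReadAlignment
from m6aclip.peaks import (
    build_candidate_regions,
    call_peaks,
    call_precise_sites,
    coverage_array,
    rpkm,
    select_partially_spliced,
)
from m6aclip.peaks import test_region as region_enrichment_p
from tests.test_stats import fisher_oracle


def read(start, end, strand="+", library="IP", **kw):
    return ReadAlignment(
        chrom="chr1", strand=strand, blocks=((start, end),), library=library, **kw
    )


# ---- candidate regions ---------------------------------------------------

def test_no_coverage_no_candidates():
    assert build_candidate_regions([], {"chr1": 1000}) == []


def test_single_stack_one_candidate():
    reads = [read(100, 180) for _ in range(10)]
    assert build_candidate_regions(reads, {"chr1": 1000}) == [("chr1", 100, 180)]


def test_two_stacks_split_by_gap():
    reads = [read(100, 180) for _ in range(8)] + [read(400, 480) for _ in range(8)]
    assert build_candidate_regions(reads, {"chr1": 1000}) == [
        ("chr1", 100, 180), ("chr1", 400, 480),
    ]


def test_candidates_match_bruteforce_coverage_scan(rng):
    """Candidate runs equal a literal per-base coverage scan oracle."""
    for _ in range(20):
        reads = [
            read(int(s), int(s) + int(rng.integers(30, 90)))
            for s in rng.integers(0, 900, size=40)
        ]
        got = build_candidate_regions(
            reads, {"chr1": 1000}, min_cov=3, max_width=10_000, min_width=1
        )
        cov = coverage_array(reads, "chr1", 1000)
        runs, start = [], None
        for i, c in enumerate(cov):
            if c >= 3 and start is None:
                start = i
            elif c < 3 and start is not None:
                runs.append(("chr1", start, i))
                start = None
        if start is not None:
            runs.append(("chr1", start, 1000))
        assert got == runs


def test_wide_runs_split_to_max_width():
    reads = [read(s, s + 80) for s in range(0, 400, 5) for _ in range(3)]
    cands = build_candidate_regions(reads, {"chr1": 1000}, max_width=100)
    assert all(e - s <= 100 for _, s, e in cands)
    # splits are contiguous over the original run
    for (_, _, e1), (_, s2, _) in zip(cands, cands[1:]):
        assert e1 == s2


# ---- region test and RPKM ------------------------------------------------

def test_region_p_equals_hypergeometric_tail():
    assert region_enrichment_p(10, 90, 2, 98) == pytest.approx(
        fisher_oracle(10, 90, 2, 98, "greater"), rel=1e-9
    )


def test_region_directionality():
    assert region_enrichment_p(10, 90, 10, 90) >= 0.5  # identical proportions
    assert region_enrichment_p(5, 95, 0, 100) < 1.0  # IP-only signal
    assert region_enrichment_p(0, 0, 0, 0) == 1.0


def test_rpkm_definition_and_proportionality():
    assert rpkm(10, 1000, 10**6) == 10.0
    assert rpkm(0, 1000, 10**6) == 0.0
    assert rpkm(10, 1000, 2 * 10**6) == 5.0
    with pytest.raises(ValueError):
        rpkm(10, 0, 10**6)


# ---- peak calling --------------------------------------------------------

def _mini_library(site_start, n_signal=40, n_bg=100, seed=7):
    """IP stack over one window plus matched uniform backgrounds."""
    rng = np.random.default_rng(seed)
    ip = [read(site_start, site_start + 80) for _ in range(n_signal)]
    ip += [read(int(s), int(s) + 80) for s in rng.integers(0, 3900, size=n_bg)]
    inp = [read(int(s), int(s) + 80, library="input")
           for s in rng.integers(0, 3900, size=n_bg + n_signal)]
    return ip, inp


def test_planted_enrichment_called_and_labelled(three_exon_transcript):
    from m6aclip.annotation import GeneAnnotation

    ann = GeneAnnotation({"tx_test": three_exon_transcript},
                         representative_ids={"tx_test"})
    # exonic window inside the internal exon [400, 600)
    ip, inp = _mini_library(450)
    cands = build_candidate_regions(ip, {"chr1": 4000})
    peaks = call_peaks(ip, inp, cands, ann)
    assert any(p.start <= 490 < p.end and p.label == "exonic" for p in peaks)
    # intronic window inside the intron [200, 400)
    ip, inp = _mini_library(210)
    cands = build_candidate_regions(ip, {"chr1": 4000})
    peaks = call_peaks(ip, inp, cands, ann)
    assert any(p.start <= 250 < p.end and p.label == "intronic" for p in peaks)


def test_called_peak_invariants(small_sim):
    from m6aclip.peaks import build_candidate_regions, call_peaks

    sizes = {c: len(s) for c, s in small_sim["genome"].items()}
    cands = build_candidate_regions(small_sim["ip"], sizes)
    peaks = call_peaks(small_sim["ip"], small_sim["input"], cands,
                       small_sim["annotation"])
    assert peaks, "planted simulation should yield peaks"
    for p in peaks:
        assert p.fdr >= p.p_value
        assert 0 < p.p_value <= 1
        assert p.ip_count >= 0 and p.input_count >= 0
        assert p.label in ("exonic", "intronic", "intergenic")


# ---- precise sites -------------------------------------------------------

def _genome_with(motif, at, length=600):
    seq = list("T" * length)  # T background: no spurious RAC
    seq[at:at + len(motif)] = motif
    return {"chr1": "".join(seq)}


def test_cims_substitutions_yield_rrACU_site():
    genome = _genome_with("GGACT", 298)  # A at 300
    from m6aclip.peaks import PeakRegion

    peak = PeakRegion(chrom="chr1", start=260, end=340, strand="+",
                      peak_id="pk1")
    reads = [read(260, 340) for _ in range(40)]
    for r in reads[:8]:  # 20% substitution frequency at the A
        r.substitutions = (300,)
    sites = call_precise_sites(reads, genome, [peak])
    assert len(sites) == 1
    s = sites[0]
    assert (s.coordinate, s.evidence_class, s.motif) == (300, "CIMS", "RRACU")
    assert genome["chr1"][s.coordinate] == "A"
    assert peak.start <= s.coordinate < peak.end


def test_no_rac_no_site():
    genome = {"chr1": "T" * 600}
    from m6aclip.peaks import PeakRegion

    peak = PeakRegion(chrom="chr1", start=260, end=340, strand="+", peak_id="pk")
    reads = [read(260, 340) for _ in range(40)]
    for r in reads[:8]:
        r.substitutions = (300,)
    assert call_precise_sites(reads, genome, [peak]) == []


def test_truncation_stack_yields_truncation_site():
    genome = _genome_with("TGACA", 298)  # RAC with A at 300, not RRACU
    from m6aclip.peaks import PeakRegion

    peak = PeakRegion(chrom="chr1", start=260, end=340, strand="+", peak_id="pk")
    reads = [read(int(s), int(s) + 70)
             for s in np.random.default_rng(3).integers(260, 280, size=20)]
    reads += [read(300, 340, truncated=True) for _ in range(12)]
    sites = call_precise_sites(reads, genome, [peak])
    assert len(sites) == 1
    s = sites[0]
    assert s.evidence_class in ("MITS", "CITS")
    assert (s.coordinate, s.motif) == (300, "RAC")


def test_precise_sites_on_minus_strand_sense_motif():
    # genomic AGTCC is the reverse complement of sense GGACT
    seq = list("T" * 600)
    seq[298:303] = "AGTCC"
    genome = {"chr1": "".join(seq)}
    from m6aclip.peaks import PeakRegion

    peak = PeakRegion(chrom="chr1", start=260, end=340, strand="-", peak_id="pk")
    reads = [read(260, 340, strand="-") for _ in range(40)]
    for r in reads[:8]:
        r.substitutions = (300,)  # sense-strand A maps to genomic position 300
    sites = call_precise_sites(reads, genome, [peak])
    assert len(sites) == 1
    assert sites[0].motif == "RRACU"
    assert genome["chr1"][sites[0].coordinate] == "T"  # A on the sense strand


def test_simulated_sites_land_on_planted_adenosines(small_sim):
    sizes = {c: len(s) for c, s in small_sim["genome"].items()}
    cands = build_candidate_regions(small_sim["ip"], sizes)
    peaks = call_peaks(small_sim["ip"], small_sim["input"], cands,
                       small_sim["annotation"])
    sites = call_precise_sites(small_sim["ip"], small_sim["genome"], peaks)
    assert sites
    planted = {(s.chrom, s.pos) for s in small_sim["truth"].sites}
    by_id = {p.peak_id: p for p in peaks}
    n_on_planted = 0
    for s in sites:
        parent = by_id[s.peak_id]
        assert parent.start <= s.coordinate < parent.end
        base = small_sim["genome"][s.chrom][s.coordinate]
        assert base == ("A" if s.strand == "+" else "T")
        n_on_planted += (s.chrom, s.coordinate) in planted
    assert n_on_planted / len(sites) > 0.8


# ---- partially spliced transcript filter ---------------------------------

@pytest.mark.parametrize(
    "exonic,intronic,kept",
    [(100, 300, True), (100, 150, False), (100, 200, True),
     (0, 50, True), (100, 0, False)],
)
def test_select_partially_spliced_boundaries(exonic, intronic, kept):
    result = select_partially_spliced({"t": (exonic, intronic)})
    assert ("t" in result) is kept
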