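"""Annotation loading, isoform selection and positional queries."""

import pytest

from m6aclip.annotation import (
    GeneAnnotation,
    GtfParseError,
    TranscriptModel,
    distance_to_splice_sites,
    feature_of_tpos,
    load_annotation,
    segment_transcript,
    select_representative_isoforms,
    write_gtf,
)


def gtf_line(chrom, feature, start, end, strand, gene, tx):
    return (
        f"{chrom}\ttest\t{feature}\t{start}\t{end}\t.\t{strand}\t.\t"
        f'gene_id "{gene}"; transcript_id "{tx}";'
    )


def write_lines(tmp_path, lines, name="test.gtf"):
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return path


# ---- GTF loading ---------------------------------------------------------

def test_coordinate_conversion_single_exon(tmp_path):
    """GTF 1-based inclusive 100..200 becomes 0-based half-open [99, 200)."""
    ann = load_annotation(
        write_lines(tmp_path, [gtf_line("chr1", "exon", 100, 200, "+", "g1", "t1")])
    )
    t = ann.transcripts["t1"]
    assert t.exons == [(99, 200)]
    assert t.mrna_length == 101


def test_two_exon_mrna_length(tmp_path):
    ann = load_annotation(
        write_lines(
            tmp_path,
            [
                gtf_line("chr1", "exon", 100, 200, "+", "g1", "t1"),
                gtf_line("chr1", "exon", 301, 400, "+", "g1", "t1"),
            ],
        )
    )
    assert ann.transcripts["t1"].mrna_length == 201


def test_reversed_coordinates_raise_with_line_number(tmp_path):
    path = write_lines(
        tmp_path,
        [
            gtf_line("chr1", "exon", 100, 200, "+", "g1", "t1"),
            gtf_line("chr1", "exon", 400, 300, "+", "g1", "t1"),
        ],
    )
    with pytest.raises(GtfParseError, match="line 2"):
        load_annotation(path)


def test_zero_exon_transcript_rejected(tmp_path, caplog):
    path = write_lines(
        tmp_path,
        [
            gtf_line("chr1", "exon", 100, 200, "+", "g1", "t1"),
            gtf_line("chr1", "transcript", 500, 900, "+", "g2", "t2"),
        ],
    )
    with caplog.at_level("WARNING"):
        ann = load_annotation(path)
    assert "t2" not in ann.transcripts
    assert "t1" in ann.transcripts


def test_cds_converted_to_transcript_space(tmp_path):
    ann = load_annotation(
        write_lines(
            tmp_path,
            [
                gtf_line("chr1", "exon", 101, 200, "+", "g1", "t1"),
                gtf_line("chr1", "exon", 301, 400, "+", "g1", "t1"),
                gtf_line("chr1", "CDS", 151, 200, "+", "g1", "t1"),
                gtf_line("chr1", "CDS", 301, 350, "+", "g1", "t1"),
            ],
        )
    )
    t = ann.transcripts["t1"]
    assert (t.cds_start, t.cds_end) == (50, 150)


def test_gtf_round_trip(tmp_path, small_sim):
    """Simulator annotation survives write -> load unchanged."""
    path = tmp_path / "rt.gtf"
    write_gtf(small_sim["annotation"], path)
    reloaded = load_annotation(path)
    for tid, t in small_sim["annotation"].transcripts.items():
        r = reloaded.transcripts[tid]
        assert r.exons == t.exons
        assert (r.cds_start, r.cds_end) == (t.cds_start, t.cds_end)
        assert (r.strand, r.chrom, r.gene_id) == (t.strand, t.chrom, t.gene_id)


# ---- representative isoforms --------------------------------------------

def _tx(tid, gene, exons, strand="+"):
    return TranscriptModel(tid, gene, "chr1", strand, exons)


def test_longest_isoform_kept_and_tie_break():
    ann = GeneAnnotation(
        {
            "a_long": _tx("a_long", "g1", [(0, 3000)]),
            "a_short": _tx("a_short", "g1", [(0, 2000)]),
            "b2": _tx("b2", "g2", [(5000, 6000)]),
            "b1": _tx("b1", "g2", [(5000, 6000)]),
        }
    )
    reps = select_representative_isoforms(ann).representative_ids
    assert "a_long" in reps and "a_short" not in reps
    assert "b1" in reps and "b2" not in reps  # equal length: smaller id


def test_distal_3prime_policy():
    """The alternative isoform policy keeps the most distal 3' end."""
    ann = GeneAnnotation(
        {
            "short_distal": _tx("short_distal", "g1", [(0, 100), (4000, 4100)]),
            "long_proximal": _tx("long_proximal", "g1", [(0, 3000)]),
            "m_distal": _tx("m_distal", "g2", [(8000, 8100), (9000, 9100)], "-"),
            "m_proximal": _tx("m_proximal", "g2", [(8500, 9100)], "-"),
        }
    )
    reps = select_representative_isoforms(ann, policy="distal_3prime")
    assert "short_distal" in reps.representative_ids  # ends at 4100 vs 3000
    assert "m_distal" in reps.representative_ids  # minus strand: 3' end = start
    with pytest.raises(ValueError):
        select_representative_isoforms(ann, policy="bogus")


def test_overlapping_genes_both_removed():
    ann = GeneAnnotation(
        {
            "t1": _tx("t1", "g1", [(0, 1000)]),
            "t2": _tx("t2", "g2", [(900, 2000)], strand="-"),
            "t3": _tx("t3", "g3", [(5000, 6000)]),
        }
    )
    reps = select_representative_isoforms(ann).representative_ids
    assert reps == {"t3"}


def test_representatives_pairwise_non_overlapping(small_sim):
    reps = select_representative_isoforms(small_sim["annotation"]).representatives()
    spans = sorted((t.span.start, t.span.end) for t in reps)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 <= s2


# ---- position classification --------------------------------------------

def test_classification_uses_all_isoforms():
    """Exonic in a minor isoform wins over intronic in the major one."""
    ann = GeneAnnotation(
        {
            "major": _tx("major", "g1", [(0, 100), (500, 600)]),
            "minor": _tx("minor", "g1", [(0, 100), (200, 300), (500, 600)]),
        }
    )
    assert ann.classify_position("chr1", 250) == "exonic"
    assert ann.classify_position("chr1", 350) == "intronic"
    assert ann.classify_position("chr1", 5000) == "intergenic"


def test_unknown_chromosome_is_intergenic(caplog):
    ann = GeneAnnotation({"t1": _tx("t1", "g1", [(0, 100)])})
    with caplog.at_level("WARNING"):
        assert ann.classify_position("chrUn", 50) == "intergenic"


def test_classification_is_exhaustive(small_sim, rng):
    ann = small_sim["annotation"]
    chrom_len = len(small_sim["genome"]["chr1"])
    for pos in rng.integers(0, chrom_len, size=200):
        assert ann.classify_position("chr1", int(pos)) in (
            "exonic", "intronic", "intergenic",
        )


# ---- segmentation --------------------------------------------------------

def test_segmentation_partitions_mrna(small_sim):
    for t in small_sim["annotation"].representatives():
        seg = segment_transcript(t)
        pieces = [p for p in (seg["utr5"], seg["cds"], seg["utr3"]) if p]
        pieces.sort()
        assert pieces[0][0] == 0 and pieces[-1][1] == t.mrna_length
        for (s1, e1), (s2, e2) in zip(pieces, pieces[1:]):
            assert e1 == s2  # no gaps, no overlaps


def test_stop_codon_last_exon_flag():
    in_last = _tx("a", "g", [(0, 100), (200, 400)])
    in_last.cds_start, in_last.cds_end = 10, 250
    assert segment_transcript(in_last)["stop_in_last_exon"] is True
    in_penult = _tx("b", "g", [(0, 100), (200, 400)])
    in_penult.cds_start, in_penult.cds_end = 10, 90
    assert segment_transcript(in_penult)["stop_in_last_exon"] is False


def test_single_exon_labelled_first_and_last():
    seg = segment_transcript(_tx("a", "g", [(0, 500)]))
    assert seg["exon_labels"] == [frozenset({"first", "last"})]


def test_feature_of_tpos():
    t = _tx("a", "g", [(0, 300)])
    t.cds_start, t.cds_end = 100, 200
    assert feature_of_tpos(t, 50) == "5UTR"
    assert feature_of_tpos(t, 150) == "CDS"
    assert feature_of_tpos(t, 250) == "3UTR"


# ---- splice-site distances ----------------------------------------------

def test_splice_distance_boundaries(three_exon_transcript):
    t = three_exon_transcript
    # first nt of the internal exon (tpos 200)
    d = distance_to_splice_sites(t, 200)
    assert d == {"dist_to_3ss": 0, "dist_to_5ss": 199, "exon_index": 1}
    # center of the 200-nt internal exon
    d = distance_to_splice_sites(t, 300)
    assert d["dist_to_3ss"] == 100 and d["dist_to_5ss"] == 99


def test_splice_distance_rejects_outside_positions(three_exon_transcript):
    with pytest.raises(ValueError):
        distance_to_splice_sites(three_exon_transcript, 600)


def test_minus_strand_mirror():
    """Transcript-space quantities are invariant under a genome mirror.

    Brute-force oracle: mirror all coordinates around a fixed span and
    flip the strand; every transcript-space distance must be unchanged.
    """
    plus = _tx("p", "g", [(100, 300), (500, 700), (900, 1200)])
    L = 1300
    mirrored = [(L - e, L - s) for s, e in plus.exons]
    minus = TranscriptModel("m", "g", "chr1", "-", mirrored)
    assert plus.mrna_length == minus.mrna_length
    for tpos in (0, 1, 57, 199, 200, 350, 420, plus.mrna_length - 1):
        assert distance_to_splice_sites(plus, tpos) == distance_to_splice_sites(
            minus, tpos
        )
        # coordinate transforms are mutually inverse on both strands
        assert minus.genomic_to_transcript(minus.transcript_to_genomic(tpos)) == tpos
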