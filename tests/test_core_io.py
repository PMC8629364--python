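import pytest

from sloperon.core_io import (GeneModel, LabelTable, attach_labels,
                              parse_gene_annotation, parse_repeat_track,
                              write_gff3)

GFF_HEADER = "##gff-version 3\n"


def _gff_gene(scaffold, gid, start1, end1, strand, exons1=None):
    """GFF3 text for one gene; coordinates 1-based inclusive as on disk."""
    lines = [f"{scaffold}\tsrc\tgene\t{start1}\t{end1}\t.\t{strand}\t.\tID={gid}",
             f"{scaffold}\tsrc\tmRNA\t{start1}\t{end1}\t.\t{strand}\t.\tID={gid}.t;Parent={gid}"]
    for i, (s, e) in enumerate(exons1 or [(start1, end1)]):
        lines.append(f"{scaffold}\tsrc\texon\t{s}\t{e}\t.\t{strand}\t.\tID={gid}.e{i};Parent={gid}.t")
    return "\n".join(lines) + "\n"


def test_gff3_coordinates_convert_to_zero_based_half_open(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text(GFF_HEADER + _gff_gene("scf1", "g1", 101, 200, "+"))
    (g,) = parse_gene_annotation(p)
    assert (g.start, g.end, g.strand) == (100, 200, "+")
    assert g.end - g.start == 200 - 101 + 1


def test_bed12_coordinates_are_kept_as_is(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("scf1\t100\t200\tg1\t0\t+\t100\t200\t0\t2\t30,40\t0,60\n")
    (g,) = parse_gene_annotation(p, dialect="bed12")
    assert (g.start, g.end) == (100, 200)
    assert g.exons == ((100, 130), (160, 200))


def test_genes_returned_sorted_by_scaffold_and_start(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text(GFF_HEADER + _gff_gene("scf1", "g2", 501, 600, "+")
                 + _gff_gene("scf1", "g1", 101, 200, "-"))
    genes = parse_gene_annotation(p)
    assert [g.gene_id for g in genes] == ["g1", "g2"]


def test_malformed_gff3_record_error_names_line(tmp_path):
    p = tmp_path / "bad.gff3"
    p.write_text(GFF_HEADER + "scf1\tsrc\tgene\tnotanumber\t200\t.\t+\t.\tID=g1\n")
    with pytest.raises(ValueError, match=":2"):
        parse_gene_annotation(p)


def test_gff3_round_trip_preserves_structure(tmp_path):
    genes = [
        GeneModel("gA", "scf1", "+", 100, 500, ((100, 200), (300, 500))),
        GeneModel("gB", "scf2", "-", 0, 90, ((0, 40), (60, 90))),
    ]
    p = tmp_path / "rt.gff3"
    write_gff3(genes, p)
    back = parse_gene_annotation(p)
    assert [(g.gene_id, g.scaffold, g.strand, g.start, g.end, g.exons) for g in back] == \
           [(g.gene_id, g.scaffold, g.strand, g.start, g.end, g.exons) for g in genes]


def test_repeat_track_keeps_overlapping_intervals_and_converts_rm_out(tmp_path):
    bed = tmp_path / "r.bed"
    bed.write_text("scf1\t10\t20\n" + "scf1\t15\t30\n")
    track = parse_repeat_track(bed)
    assert track.intervals["scf1"] == [(10, 20), (15, 30)]

    empty = tmp_path / "empty.bed"
    empty.write_text("")
    assert parse_repeat_track(empty).n_intervals() == 0

    rm = tmp_path / "r.out"
    rm.write_text(
        "   SW   perc perc perc  query      position in query\n"
        "score   div. del. ins.  sequence   begin end\n"
        "\n"
        "  463   1.3  0.6  1.7  scf1        101 200 (0) + AT_rich Simple_repeat 1 100 (0) 1\n")
    track = parse_repeat_track(rm, dialect="repeatmasker")
    assert track.intervals["scf1"] == [(100, 200)]


def test_gene_model_invariants_are_enforced():
    with pytest.raises(ValueError):
        GeneModel("g", "s", "+", 10, 10, ())
    with pytest.raises(ValueError):
        GeneModel("g", "s", "*", 0, 10, ())
    with pytest.raises(ValueError):  # exon outside span
        GeneModel("g", "s", "+", 10, 20, ((0, 5),))
    with pytest.raises(ValueError):  # overlapping exons
        GeneModel("g", "s", "+", 0, 20, ((0, 10), (5, 20)))


def test_attach_labels_matches_defaults_and_duplicates(tmp_path):
    genes = [GeneModel("g1", "s", "+", 0, 100, ((0, 100),)),
             GeneModel("g2", "s", "+", 200, 300, ((200, 300),))]
    p = tmp_path / "labels.tsv"
    p.write_text("gene_id\tts_status\tcons_class\tcell_label\n"
                 "g1\tTS\tconserved\tneoblast\n"
                 "g9\tnonTS\tnon-coding\tnone\n")
    labeled = attach_labels(genes, LabelTable.from_tsv(p))
    assert labeled[0].ts_status == "TS" and labeled[0].cell_label == "neoblast"
    assert labeled[1].ts_status == "unknown"  # untouched default

    assert attach_labels(genes, LabelTable()) == genes  # empty table is identity

    dup = tmp_path / "dup.tsv"
    dup.write_text("gene_id\tts_status\tcons_class\tcell_label\n"
                   "g1\tTS\tconserved\tnone\ng1\tnonTS\tconserved\tnone\n")
    with pytest.raises(ValueError, match="duplicate"):
        LabelTable.from_tsv(dup)
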