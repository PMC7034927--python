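import numpy as np
import pytest

from chefind.genome import (
    AnnotationValidationError,
    GenomeAnnotation,
    GtfParseError,
    PositionalClass,
    TranscriptModel,
    classify_position,
    classify_positions,
    flanking_genes,
    overlaps,
    read_gtf,
    write_gtf,
)
from chefind.simulate import SimulationConfig, simulate_annotation


def t(id, start, end, strand="+", chrom="chr1", biotype="other", exons=None):
    return TranscriptModel(id=id, chrom=chrom, start=start, end=end,
                           strand=strand, biotype=biotype, exons=exons or [])


# ---------------------------------------------------------------------------
# model invariants


def test_transcript_validation():
    with pytest.raises(AnnotationValidationError):
        t("bad", 100, 100)
    with pytest.raises(AnnotationValidationError):
        t("bad", 100, 200, exons=[(50, 150)])  # exon outside span
    with pytest.raises(AnnotationValidationError):
        t("bad", 0, 200, exons=[(0, 100), (50, 200)])  # overlapping exons
    tm = t("ok", 100, 200)
    assert tm.exons == [(100, 200)]  # default single exon
    assert tm.length == 100


@pytest.mark.parametrize("strand,expected_tss", [("+", 100), ("-", 200)])
def test_tss_is_strand_dependent(strand, expected_tss):
    assert t("x", 100, 200, strand).tss == expected_tss


def test_duplicate_ids_rejected():
    with pytest.raises(AnnotationValidationError):
        GenomeAnnotation.from_transcripts([t("a", 0, 10), t("a", 20, 30)])


# ---------------------------------------------------------------------------
# GTF I/O


def test_gtf_parse_and_coordinate_convention(tmp_path):
    gtf = tmp_path / "x.gtf"
    gtf.write_text(
        'chr1\tsrc\ttranscript\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; gene_biotype "protein_coding";\n'
        'chr1\tsrc\texon\t101\t140\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        'chr1\tsrc\texon\t161\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
    )
    ann = read_gtf(gtf)
    assert len(ann) == 1
    tr = ann["t1"]
    # 1-based inclusive [101,200] -> 0-based half-open (100,200)
    assert (tr.start, tr.end) == (100, 200)
    assert tr.length == 100
    assert tr.exons == [(100, 140), (160, 200)]
    assert tr.biotype == "protein_coding"


def test_gtf_parse_error_carries_line_number(tmp_path):
    gtf = tmp_path / "bad.gtf"
    gtf.write_text("chr1\tonly\tthree\n")
    with pytest.raises(GtfParseError, match="line 1"):
        read_gtf(gtf)


def test_gtf_exon_outside_transcript_rejected(tmp_path):
    gtf = tmp_path / "bad.gtf"
    gtf.write_text(
        'chr1\ts\ttranscript\t101\t200\t.\t+\t.\ttranscript_id "t1";\n'
        'chr1\ts\texon\t50\t90\t.\t+\t.\ttranscript_id "t1";\n'
    )
    with pytest.raises(AnnotationValidationError):
        read_gtf(gtf)


def test_gtf_round_trip_identity(tmp_path):
    cfg = SimulationConfig(seed=3, n_coding=30, n_intergenic=15,
                           n_antisense=5, n_noise=0, n_chroms=2)
    ann, _ = simulate_annotation(cfg)
    assert len(ann) == 50
    p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
    write_gtf(ann, p1)
    back = read_gtf(p1)
    assert set(back.transcripts) == set(ann.transcripts)
    for tid, orig in ann.transcripts.items():
        got = back[tid]
        assert (got.chrom, got.start, got.end, got.strand) == (
            orig.chrom, orig.start, orig.end, orig.strand)
        assert got.exons == orig.exons
        assert got.biotype == orig.biotype
        assert got.annotated == orig.annotated
    # write -> read -> write is byte-identical
    write_gtf(back, p2)
    assert p1.read_bytes() == p2.read_bytes()


# ---------------------------------------------------------------------------
# overlap engine


@pytest.mark.parametrize(
    "a,b,same_strand,expected",
    [
        ((0, 100, "+"), (99, 200, "+"), True, True),    # 1-base overlap counts
        ((0, 100, "+"), (100, 200, "+"), False, False),  # half-open adjacency
        ((0, 100, "+"), (50, 60, "-"), True, False),     # strand gate on
        ((0, 100, "+"), (50, 60, "-"), False, True),     # strand gate off
    ],
)
def test_overlaps_examples(a, b, same_strand, expected):
    ta = t("a", a[0], a[1], a[2])
    tb = t("b", b[0], b[1], b[2])
    assert overlaps(ta, tb, same_strand=same_strand) is expected


def test_overlaps_min_bases_validation():
    with pytest.raises(ValueError):
        overlaps(t("a", 0, 10), t("b", 5, 15), min_bases=0)


def test_overlaps_matches_base_set_oracle(rng):
    """Span overlap agrees with brute-force base-set intersection and is
    symmetric, over all pairs of 200 random intervals."""
    ivs = []
    for i in range(200):
        s = int(rng.integers(0, 5000))
        ln = int(rng.integers(1, 300))
        ivs.append(t(f"i{i}", s, s + ln))
    for i in range(0, 200, 7):
        for j in range(200):
            a, b = ivs[i], ivs[j]
            expected = len(set(range(a.start, a.end)) & set(range(b.start, b.end))) >= 1
            assert overlaps(a, b) == expected
            assert overlaps(b, a) == overlaps(a, b)


# ---------------------------------------------------------------------------
# positional classification


def test_classify_rule_order():
    coding = [t("g1", 1000, 5000, "+", biotype="protein_coding"),
              t("g2", 20000, 25000, "-", biotype="protein_coding")]
    inside_same = t("x1", 2000, 3000, "+")
    assert classify_position(inside_same, coding) is PositionalClass.SENSE_OVERLAP
    antisense = t("x2", 2000, 3000, "-")
    assert classify_position(antisense, coding) is PositionalClass.ANTISENSE
    far = t("x3", 40000, 41000, "+")
    assert classify_position(far, coding) is PositionalClass.INTERGENIC
    # same-strand rule wins when both apply
    spans_both = t("x4", 4500, 21000, "+")
    assert classify_position(spans_both, coding) is PositionalClass.SENSE_OVERLAP


def test_classify_requires_coding_set():
    with pytest.raises(ValueError):
        classify_position(t("x", 0, 10), [])


def test_classes_partition_transcripts(dataset):
    """Every transcript receives exactly one positional class, and the
    generated annotation's classes match the construction."""
    ann = dataset.annotation
    classes = classify_positions(ann.transcripts.values(), ann.coding_genes)
    assert set(classes) == set(ann.transcripts)
    truth = dataset.truth.table
    for tid, cls in classes.items():
        assert cls.value == truth.loc[tid, "positional"]


# ---------------------------------------------------------------------------
# flanking genes


def test_flanking_sides_and_boundaries():
    coding = [t("left", 0, 5000, biotype="protein_coding"),
              t("right", 12000, 15000, biotype="protein_coding")]
    x = t("x", 10000, 10500)
    up, down = flanking_genes(x, coding, same_strand=True)
    assert up.id == "left" and down.id == "right"
    # at chromosome start there is no upstream gene
    y = t("y", 1000, 1500)
    up, down = flanking_genes(y, [t("g", 5000, 9000, biotype="protein_coding")])
    assert up is None and down.id == "g"


def test_flanking_matches_brute_force(rng):
    """Nearest-by-gap flank selection agrees with an exhaustive scan on 100
    random layouts."""
    for _ in range(100):
        n_genes = int(rng.integers(2, 12))
        genes = []
        pos = 0
        for g in range(n_genes):
            pos += int(rng.integers(500, 4000))
            ln = int(rng.integers(500, 3000))
            genes.append(t(f"g{g}", pos, pos + ln, biotype="protein_coding"))
            pos += ln
        qs = int(rng.integers(0, pos + 2000))
        q = t("q", qs, qs + int(rng.integers(50, 400)))
        nonov = [g for g in genes if g.end <= q.start or g.start >= q.end]
        ups = [g for g in nonov if g.end <= q.start]
        downs = [g for g in nonov if g.start >= q.end]
        exp_up = min(ups, key=lambda g: (q.start - g.end, g.start)) if ups else None
        exp_down = min(downs, key=lambda g: (g.start - q.end, g.start)) if downs else None
        up, down = flanking_genes(q, genes, same_strand=True)
        assert (up.id if up else None) == (exp_up.id if exp_up else None)
        assert (down.id if down else None) == (exp_down.id if exp_down else None)
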