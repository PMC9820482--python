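"""Annotation parsing and positional TE classification.

The classifier is checked against a per-base brute-force oracle that
materializes gene bodies, exon unions, and codon positions as explicit
coordinate sets.
"""

import numpy as np
import pytest

from telex.intervals import (
    AnnotationParseError,
    GeneModel,
    GenomicInterval,
    TELabel,
    TELocus,
    associate_intergenic,
    classify_all,
    classify_te_locus,
    merge_intervals,
    read_gene_annotation,
    read_te_annotation,
    write_te_bed,
)
from telex.simulate import SimulationConfig, generate_annotation

from conftest import make_te


# --- brute-force per-base oracle -------------------------------------------

def _positions(iv):
    return set(range(iv.start, iv.end))


def oracle_classify(te, genes):
    """Per-base re-derivation of the classification rules."""
    chrom_genes = [g for g in genes if g.body.chrom == te.locus.chrom]
    te_pos = _positions(te.locus)
    overlapping = [g for g in chrom_genes if te_pos & _positions(g.body)]
    if not overlapping:
        if not chrom_genes:
            return ("INTERGENIC", None, 0)
        def gap(g):
            if te.locus.start >= g.body.end:
                return te.locus.start - g.body.end
            if g.body.start >= te.locus.end:
                return g.body.start - te.locus.end
            return 0
        best = min(chrom_genes, key=lambda g: (gap(g), g.gene_id))
        return ("INTERGENIC", best.gene_id, gap(best))
    for g in overlapping:
        union = set()
        for part in g.exons + [g.start_codon, g.stop_codon]:
            if part is not None:
                union |= _positions(part)
        if te_pos <= union:
            return ("DISCARDED", None, 0)
    host = min(
        overlapping,
        key=lambda g: (-len(te_pos & _positions(g.body)), g.gene_id),
    )
    if host.start_codon and te_pos & _positions(host.start_codon):
        return ("START_CODON", host.gene_id, 0)
    if host.stop_codon and te_pos & _positions(host.stop_codon):
        return ("STOP_CODON", host.gene_id, 0)
    exon_pos = set()
    for e in host.exons:
        exon_pos |= _positions(e)
    if te_pos & exon_pos:
        return ("EXON", host.gene_id, 0)
    return ("INTRONIC", host.gene_id, 0)


# --- parsing ----------------------------------------------------------------

GTF_ONE_GENE = (
    'chr1\tsrc\tgene\t101\t1000\t.\t+\t.\tgene_id "g1"; gene_name "G1";\n'
    'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1";\n'
    'chr1\tsrc\texon\t801\t1000\t.\t+\t.\tgene_id "g1";\n'
    'chr1\tsrc\tstart_codon\t111\t113\t.\t+\t.\tgene_id "g1";\n'
    'chr1\tsrc\tstop_codon\t988\t990\t.\t+\t.\tgene_id "g1";\n'
    'chr1\tsrc\tCDS\t111\t200\t.\t+\t.\tgene_id "g1";\n'
)


def test_gtf_coordinates_converted_to_half_open(tmp_path):
    path = tmp_path / "genes.gtf"
    path.write_text(GTF_ONE_GENE)
    genes = read_gene_annotation(path)
    assert len(genes) == 1
    g = genes[0]
    assert g.body == GenomicInterval("chr1", 100, 1000, "+")
    assert [(e.start, e.end) for e in g.exons] == [(100, 200), (800, 1000)]
    assert (g.start_codon.start, g.start_codon.end) == (110, 113)
    assert (g.stop_codon.start, g.stop_codon.end) == (987, 990)


def test_gtf_gene_without_exons_kept_body_only(tmp_path):
    path = tmp_path / "genes.gtf"
    path.write_text('chr2\tsrc\tgene\t51\t150\t.\t-\t.\tgene_id "g9";\n')
    (g,) = read_gene_annotation(path)
    assert g.exons == [] and g.body.start == 50 and g.body.end == 150


def test_gtf_empty_file_warns(tmp_path, caplog):
    path = tmp_path / "empty.gtf"
    path.write_text("")
    with caplog.at_level("WARNING"):
        assert read_gene_annotation(path) == []
    assert "empty" in caplog.text


@pytest.mark.parametrize(
    "line",
    [
        "chr1\tsrc\texon\t101\t200\n",             # too few columns
        'chr1\tsrc\texon\tX\t200\t.\t+\t.\tgene_id "g1";\n',  # bad coord
        'chr1\tsrc\texon\t101\t200\t.\t+\t.\tfoo "bar";\n',   # no gene_id
    ],
)
def test_gtf_malformed_line_names_line_number(tmp_path, line):
    path = tmp_path / "bad.gtf"
    path.write_text('chr1\tsrc\tgene\t1\t10\t.\t+\t.\tgene_id "g0";\n' + line)
    with pytest.raises(AnnotationParseError, match="line 2"):
        read_gene_annotation(path)


def test_bed_parse_and_class_rejection(tmp_path, caplog):
    path = tmp_path / "tes.bed"
    path.write_text(
        "chr1\t150\t180\tAluSq2:Alu:SINE\t0\t+\n"
        "chr1\t300\t400\tALR:Satellite:Satellite\t0\t-\n"
        "chr1\t150\t180\tL1HS:L1:LINE\t0\t+\n"
    )
    with caplog.at_level("WARNING"):
        loci = read_te_annotation(path)
    assert [t.subfamily for t in loci] == ["AluSq2", "L1HS"]
    assert "Satellite" in caplog.text
    # duplicate coordinates, different subfamily: both kept, distinct ids
    assert len({t.te_id for t in loci}) == 2
    with pytest.raises(AnnotationParseError, match="Satellite"):
        read_te_annotation(path, strict=True)
    t = loci[0]
    assert (t.family, t.te_class, t.locus.start, t.locus.end) == ("Alu", "SINE", 150, 180)


def test_bed_round_trip(tmp_path):
    cfg = SimulationConfig(seed=5, n_genes=10, n_te=40)
    ann = generate_annotation(cfg)
    path = tmp_path / "roundtrip.bed"
    write_te_bed(ann.tes, path)
    again = read_te_annotation(path)
    assert [(t.te_id, t.locus) for t in again] == [
        (t.te_id, t.locus) for t in ann.tes
    ]


# --- classification ---------------------------------------------------------

def test_te_fully_inside_exon_discarded(toy_gene):
    te = make_te("chr1", 150, 180)
    c = classify_te_locus(te, [toy_gene])
    assert c.label is TELabel.DISCARDED and c.associated_gene_id is None


def test_te_straddling_exon_boundary_is_exonic(toy_gene):
    c = classify_te_locus(make_te("chr1", 190, 250), [toy_gene])
    assert c.label is TELabel.EXON and c.associated_gene_id == "g1"


def test_te_in_intron(toy_gene):
    c = classify_te_locus(make_te("chr1", 300, 400), [toy_gene])
    assert c.label is TELabel.INTRONIC and c.associated_gene_id == "g1"


def test_intergenic_distance(toy_gene):
    c = classify_te_locus(make_te("chr1", 5000, 5300), [toy_gene])
    assert c.label is TELabel.INTERGENIC
    assert c.associated_gene_id == "g1" and c.distance_bp == 4000


def test_codon_priority_over_exon(toy_gene):
    # overlaps start codon and exon while poking outside the gene
    c = classify_te_locus(make_te("chr1", 90, 130), [toy_gene])
    assert c.label is TELabel.START_CODON
    c = classify_te_locus(make_te("chr1", 985, 1050), [toy_gene])
    assert c.label is TELabel.STOP_CODON


def test_equidistant_tie_breaks_to_smaller_gene_id(toy_gene):
    g2 = GeneModel(
        "g2", "G2",
        GenomicInterval("chr1", 8300, 9000, "+"),
        [GenomicInterval("chr1", 8300, 9000, "+")],
    )
    # [6000, 6300): 5000 to g1's end (1000), 2000 to g2's start -> g2
    gene_id, dist = associate_intergenic(make_te("chr1", 6000, 6300), [toy_gene, g2])
    assert (gene_id, dist) == ("g2", 2000)
    # equidistant: 1000 beyond g1.end=1000 vs 1000 before... construct exact tie
    te = make_te("chr1", 2000, 7300)  # gap 1000 both sides
    gene_id, dist = associate_intergenic(te, [toy_gene, g2])
    assert (gene_id, dist) == ("g1", 1000)


def test_te_on_chromosome_without_genes(toy_gene, caplog):
    with caplog.at_level("WARNING"):
        c = classify_te_locus(make_te("chrX", 10, 50), [toy_gene])
    assert c.label is TELabel.INTERGENIC and c.associated_gene_id is None


def _random_scene(seed, n_genes, n_te):
    cfg = SimulationConfig(seed=seed, n_genes=n_genes, n_te=4)
    ann = generate_annotation(cfg)
    rng = np.random.default_rng(seed + 5000)
    tes = []
    for i in range(n_te):
        length = int(rng.integers(30, 6000))
        start = int(rng.integers(0, ann.chrom_length - length))
        tes.append(
            TELocus.from_fields("chrS", start, start + length, f"T{i}", "Alu", "SINE")
        )
    return ann.genes, tes


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_classification_matches_per_base_oracle(seed):
    genes, tes = _random_scene(seed, n_genes=25, n_te=120)
    results = classify_all(tes, genes)
    for te, got in zip(tes, results):
        expected = oracle_classify(te, genes)
        assert (got.label.value, got.associated_gene_id, got.distance_bp) == expected


def test_classification_is_partition_and_strand_agnostic():
    genes, tes = _random_scene(11, n_genes=20, n_te=80)
    results = classify_all(tes, genes)
    assert len(results) == len(tes)  # exactly one label each
    flipped = [
        TELocus(t.te_id, t.subfamily, t.family, t.te_class,
                GenomicInterval(t.locus.chrom, t.locus.start, t.locus.end,
                                "-" if t.locus.strand == "+" else "+"))
        for t in tes
    ]
    assert [
        (c.label, c.associated_gene_id, c.distance_bp) for c in classify_all(flipped, genes)
    ] == [(c.label, c.associated_gene_id, c.distance_bp) for c in results]


def test_merge_intervals():
    ivals = [
        GenomicInterval("c", 10, 20),
        GenomicInterval("c", 15, 30),
        GenomicInterval("c", 30, 40),
        GenomicInterval("c", 50, 60),
    ]
    merged = merge_intervals(ivals)
    assert [(m.start, m.end) for m in merged] == [(10, 40), (50, 60)]
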