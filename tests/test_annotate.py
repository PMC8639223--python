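"""Gene models, feature assignment and interval algebra."""

import numpy as np
import pandas as pd
import pytest

from tregmeth.annotate import (
    Gene,
    GeneModel,
    annotate_position,
    annotate_region,
    intersect_region_sets,
    load_gene_model,
    overlap_fraction,
    probes_in_regions,
    region_labels_at,
)
from tregmeth.containers import RegionSet


@pytest.fixture
def toy_model():
    # plus-strand gene with UTRs/exons, and a second gene whose promoter window
    # covers part of the first gene's body
    g1 = Gene(
        "g1", "GENE1", "chr1", "+", 10_000, 20_000,
        exons=((10_000, 10_500), (14_000, 14_300), (19_500, 20_000)),
        five_utr=((10_000, 10_100),),
        three_utr=((19_800, 20_000),),
    )
    g2 = Gene("g2", "GENE2", "chr1", "-", 22_000, 30_000, exons=((22_000, 22_400), (29_500, 30_000)))
    return GeneModel([g1, g2])


def test_position_at_tss_is_promoter(toy_model):
    call = annotate_position("chr1", 10_000, toy_model)
    assert call.feature == "promoter" and call.gene_id == "g1" and call.distance_to_tss == 0


def test_minus_strand_tss_is_interval_end(toy_model):
    call = annotate_position("chr1", 29_999, toy_model)
    assert call.feature == "promoter" and call.gene_id == "g2" and call.distance_to_tss == 0


def test_downstream_window(toy_model):
    assert annotate_position("chr1", 20_200, toy_model).feature == "downstream"
    # 300 bp or more past the end is no longer "immediately downstream" but it is
    # within GENE2's promoter window here, so probe far from both genes instead:
    far = annotate_position("chr1", 60_000, toy_model)
    assert far.feature == "distal_intergenic" and far.gene_id == "g2"


def test_intron_vs_exon(toy_model):
    # inside gene body, past the promoter window (tss + 3000 = 13000)
    assert annotate_position("chr1", 14_100, toy_model).feature == "exon"
    assert annotate_position("chr1", 15_000, toy_model).feature == "intron"
    assert annotate_position("chr1", 19_900, toy_model).feature == "three_utr"


def test_promoter_priority_over_exon():
    g_a = Gene("a", "A", "chr1", "+", 1000, 5000, exons=((1000, 5000),))
    g_b = Gene("b", "B", "chr1", "+", 4500, 9000)
    model = GeneModel([g_a, g_b])
    # pos 3000 is inside A's exon and within B's promoter window (tss 4500 +/- 3000)
    call = annotate_position("chr1", 3000, model)
    assert call.feature == "promoter" and call.gene_id == "b"


def test_unknown_chromosome_flagged(toy_model):
    call = annotate_position("chr9", 100, toy_model)
    assert call.feature == "distal_intergenic" and call.gene_id is None and call.flagged


def test_region_annotation_midpoint(toy_model):
    assert annotate_region("chr1", 9_900, 10_100, toy_model).feature == "promoter"
    assert annotate_region("chr1", 45_000, 46_000, toy_model).feature == "distal_intergenic"


def test_region_midpoint_matches_per_base_majority(toy_model):
    """For narrow regions spanning at most two features the midpoint call equals
    the per-base majority vote."""
    for start, end in [(9_500, 10_500), (14_050, 14_500), (19_000, 19_600), (20_100, 20_250)]:
        calls = [annotate_position("chr1", p, toy_model).feature for p in range(start, end)]
        majority = max(set(calls), key=calls.count)
        assert annotate_region("chr1", start, end, toy_model).feature == majority


# --- gene model I/O ----------------------------------------------------------

def test_gff3_round_trip(tmp_path, toy_model):
    path = tmp_path / "genes.gff3"
    toy_model.to_gff3(path)
    loaded = load_gene_model(path, "GFF3")
    assert len(loaded.genes) == 2
    g1 = next(g for g in loaded.genes if g.gene_id == "g1")
    assert (g1.start, g1.end, g1.strand) == (10_000, 20_000, "+")
    assert g1.exons == ((10_000, 10_500), (14_000, 14_300), (19_500, 20_000))
    assert g1.five_utr == ((10_000, 10_100),)


def test_gff3_one_based_conversion(tmp_path):
    path = tmp_path / "one.gff3"
    path.write_text(
        "##gff-version 3\n"
        "chr1\tx\tgene\t101\t500\t.\t+\t.\tID=g1;Name=G1\n"
    )
    model = load_gene_model(path, "GFF3")
    assert model.genes[0].start == 100 and model.genes[0].end == 500


def test_gff3_malformed_record_reports_line(tmp_path):
    path = tmp_path / "bad.gff3"
    path.write_text("##gff-version 3\nchr1\tx\tgene\t101\n")
    with pytest.raises(ValueError, match=":2:"):
        load_gene_model(path, "GFF3")


def test_bed12_minus_strand_tss_and_utrs(tmp_path):
    path = tmp_path / "genes.bed"
    # one minus-strand gene: span 1000-9000, CDS 1500-8500, two blocks
    path.write_text(
        "chr1\t1000\t9000\tgeneM\t0\t-\t1500\t8500\t0\t2\t1000,1000\t0,7000\n"
    )
    model = load_gene_model(path, "BED12")
    g = model.genes[0]
    assert g.tss == 8999 - 0  # minus strand: 5' end is the interval end - 1
    assert g.exons == ((1000, 2000), (8000, 9000))
    # minus strand: 5' UTR is the high-coordinate non-CDS exon piece
    assert g.five_utr == ((8500, 9000),)
    assert g.three_utr == ((1000, 1500),)


# --- interval algebra --------------------------------------------------------

@pytest.mark.parametrize(
    "a,b,expected",
    [((0, 100), (50, 150), 0.5), ((0, 100), (200, 300), 0.0), ((10, 20), (0, 100), 1.0)],
)
def test_overlap_fraction_examples(a, b, expected):
    assert overlap_fraction(a, b) == pytest.approx(expected)


def test_overlap_fraction_zero_length_rejected():
    with pytest.raises(ValueError):
        overlap_fraction((5, 5), (0, 10))


def test_overlap_fraction_reciprocity():
    rng = np.random.default_rng(0)
    for _ in range(50):
        a = sorted(rng.integers(0, 1000, 2))
        b = sorted(rng.integers(0, 1000, 2))
        if a[0] == a[1] or b[0] == b[1]:
            continue
        lhs = overlap_fraction(tuple(a), tuple(b)) * (a[1] - a[0])
        rhs = overlap_fraction(tuple(b), tuple(a)) * (b[1] - b[0])
        assert lhs == pytest.approx(rhs)


def _rs(name, ivals):
    return RegionSet(name, pd.DataFrame([("chr1", s, e, ".") for s, e in ivals],
                                        columns=["chrom", "start", "end", "label"]))


def test_intersect_examples():
    out = intersect_region_sets([_rs("a", [(0, 100)]), _rs("b", [(50, 150)])])
    assert list(zip(out.df["start"], out.df["end"])) == [(50, 100)]
    same = intersect_region_sets([_rs("a", [(0, 100), (200, 300)])] * 2)
    assert list(zip(same.df["start"], same.df["end"])) == [(0, 100), (200, 300)]
    with pytest.raises(ValueError):
        intersect_region_sets([_rs("a", [(0, 100)])])


def test_intersect_commutative_and_associative():
    rng = np.random.default_rng(1)
    for _ in range(10):
        sets = []
        for k in range(3):
            ivals = []
            for _ in range(rng.integers(1, 5)):
                s = int(rng.integers(0, 900))
                ivals.append((s, s + int(rng.integers(1, 200))))
            sets.append(_rs(f"s{k}", ivals))
        ab_c = intersect_region_sets([intersect_region_sets(sets[:2]), sets[2]])
        a_bc = intersect_region_sets([sets[0], intersect_region_sets(sets[1:])])
        cba = intersect_region_sets(sets[::-1])
        pd.testing.assert_frame_equal(ab_c.df, a_bc.df)
        pd.testing.assert_frame_equal(ab_c.df, cba.df)


def test_probes_in_regions_boundaries():
    mani = pd.DataFrame({"probe_id": ["p1", "p2"], "chrom": ["chr1", "chr1"], "pos": [101, 100]})
    rs = _rs("r", [(100, 200)])
    # pos 101 (1-based) is point 100 -> inside; pos 100 is point 99 -> outside
    assert probes_in_regions(mani, rs) == ["p1"]


def test_region_labels_default_for_uncovered():
    mani = pd.DataFrame({"probe_id": ["p1", "p2"], "chrom": ["chr1", "chr1"], "pos": [50, 150]})
    rs = RegionSet("states", pd.DataFrame([("chr1", 100, 200, "TssA")],
                                          columns=["chrom", "start", "end", "label"]))
    labels = region_labels_at(mani, rs)
    assert labels["p1"] == "unannotated" and labels["p2"] == "TssA"
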