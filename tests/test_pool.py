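import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magscreen.genome_io import GeneAnnotation, GenomeSequence
from magscreen.pool import (
    TnSeqReadModel,
    assign_gene,
    build_pool,
    map_junction,
    parse_tnseq_read,
    pool_qc,
    read_pool_tsv,
    write_pool_tsv,
)

MODEL = TnSeqReadModel(flank5="AATTCC", flank3="GGCCTT", min_junction_len=8)


def revcomp(s):
    return s[::-1].translate(str.maketrans("ACGT", "TGCA"))


def brute_force_map(junction, genome):
    """Independent oracle: enumerate every start on both strands."""
    hits = []
    for scaf in genome:
        seq = scaf.sequence
        for i in range(len(seq) - len(junction) + 1):
            window = seq[i : i + len(junction)]
            if window == junction:
                hits.append((scaf.scaffold_id, i + 1, "+"))
            elif window == revcomp(junction):
                hits.append((scaf.scaffold_id, i + 1, "-"))
    if len(hits) == 0:
        return "unmapped"
    if len(hits) > 1:
        return "multimapped"
    return hits[0]


class TestParseTnSeqRead:
    def test_success(self):
        barcode = "A" * 10 + "C" * 10
        junction = "ACGTACGTACGTACGTACGT"
        read = MODEL.flank5 + barcode + MODEL.flank3 + junction
        assert parse_tnseq_read(read, MODEL) == (barcode, junction)

    def test_flank5_missing(self):
        read = "TTTTTT" + "A" * 20 + MODEL.flank3 + "ACGTACGT"
        assert parse_tnseq_read(read, MODEL) == (None, "flank5_missing")

    def test_flank3_missing(self):
        read = MODEL.flank5 + "A" * 20 + "TTTTTT" + "ACGTACGT"
        assert parse_tnseq_read(read, MODEL) == (None, "flank3_missing")

    def test_barcode_with_n(self):
        read = MODEL.flank5 + "A" * 10 + "N" + "A" * 9 + MODEL.flank3 + "ACGTACGT"
        assert parse_tnseq_read(read, MODEL) == (None, "barcode_N")

    def test_junction_short(self):
        read = MODEL.flank5 + "A" * 20 + MODEL.flank3 + "ACG"
        assert parse_tnseq_read(read, MODEL) == (None, "junction_short")

    def test_truncated_read(self):
        read = MODEL.flank5 + "A" * 5
        assert parse_tnseq_read(read, MODEL)[0] is None


class TestMapJunction:
    def test_unique_forward_hit(self):
        genome = [GenomeSequence("s1", "AAAACCCCGGGGTTTT")]
        assert map_junction("CCCCGGGG", genome) == ("s1", 5, "+")
        assert brute_force_map("CCCCGGGG", genome) == ("s1", 5, "+")

    def test_reverse_complement_hit(self):
        genome = [GenomeSequence("s1", "AAAACCCTGGAGTTTT")]
        # revcomp of CCCTGGAG is CTCCAGGG, absent; search its rc on fwd strand
        j = revcomp("CCCTGGAG")
        got = map_junction(j, genome)
        assert got == ("s1", 5, "-")
        assert got == brute_force_map(j, genome)

    def test_two_occurrences_multimapped(self):
        genome = [GenomeSequence("s1", "ACGTACGTAC")]
        assert map_junction("GTAC", genome) == "multimapped"
        assert brute_force_map("GTAC", genome) == "multimapped"

    def test_unmapped(self):
        genome = [GenomeSequence("s1", "ACGTCGTCGTACGAC")]
        assert map_junction("AAAAAAAA", genome) == "unmapped"

    def test_empty_junction_error(self):
        with pytest.raises(ValueError):
            map_junction("", [GenomeSequence("s1", "ACGT")])

    def test_hit_across_scaffolds_multimapped(self):
        genome = [
            GenomeSequence("s1", "TTTTCCCCGGGGTTTT"),
            GenomeSequence("s2", "AAAACCCCGGGGAAAA"),
        ]
        assert map_junction("CCCCGGGG", genome) == "multimapped"

    @settings(max_examples=150, deadline=None)
    @given(data=st.data())
    def test_oracle_equivalence_random(self, data):
        seq = data.draw(
            st.text(alphabet="ACGT", min_size=30, max_size=300), label="genome"
        )
        genome = [GenomeSequence("s1", seq)]
        start = data.draw(st.integers(0, len(seq) - 8), label="start")
        junction = seq[start : start + 8]
        assert map_junction(junction, genome) == brute_force_map(junction, genome)


def make_read(barcode, junction):
    return MODEL.flank5 + barcode + MODEL.flank3 + junction


@pytest.fixture
def pool_genome():
    rng = np.random.default_rng(5)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
    return [GenomeSequence("s1", seq)]


@pytest.fixture
def pool_genes(pool_genome):
    return [
        GeneAnnotation("gA", "s1", 101, 500, "+"),
        GeneAnnotation("gB", "s1", 601, 1000, "-"),
    ]


class TestBuildPool:
    def test_single_barcode_ten_reads_central(self, pool_genome, pool_genes):
        seq = pool_genome[0].sequence
        junction = seq[299:319]  # pos 300, central in gA (141..460)
        barcode = "ACGT" * 5
        reads = [make_read(barcode, junction)] * 10
        pool = build_pool(reads, MODEL, pool_genome, pool_genes)
        assert len(pool) == 1
        row = pool.iloc[0]
        assert row.n_reads == 10
        assert row.pos == 300 and row.strand == "+"
        assert row.gene_id == "gA" and row.central and not row.multimapped

    def test_two_barcodes_same_position(self, pool_genome, pool_genes):
        seq = pool_genome[0].sequence
        junction = seq[299:319]
        reads = [make_read("A" * 20, junction), make_read("C" * 20, junction)]
        pool = build_pool(reads, MODEL, pool_genome, pool_genes)
        assert len(pool) == 2
        assert set(pool["pos"]) == {300}

    def test_minority_conflict_flags_multimapped(self, pool_genome, pool_genes):
        seq = pool_genome[0].sequence
        jx, jy = seq[299:319], seq[1499:1519]
        barcode = "G" * 20
        reads = [make_read(barcode, jx)] * 6 + [make_read(barcode, jy)] * 4
        pool = build_pool(reads, MODEL, pool_genome, pool_genes)
        row = pool.iloc[0]
        assert row.multimapped  # 4/10 > 0.25
        assert row.pos == 300 and row.n_reads == 6

    def test_small_minority_not_flagged(self, pool_genome, pool_genes):
        seq = pool_genome[0].sequence
        jx, jy = seq[299:319], seq[1499:1519]
        barcode = "G" * 20
        reads = [make_read(barcode, jx)] * 9 + [make_read(barcode, jy)]
        pool = build_pool(reads, MODEL, pool_genome, pool_genes)
        assert not pool.iloc[0].multimapped  # 1/10 <= 0.25

    def test_modal_tie_flags_multimapped(self, pool_genome, pool_genes):
        seq = pool_genome[0].sequence
        reads = [make_read("T" * 20, seq[299:319]), make_read("T" * 20, seq[1499:1519])]
        pool = build_pool(reads, MODEL, pool_genome, pool_genes)
        assert pool.iloc[0].multimapped

    def test_zero_usable_reads_error(self, pool_genome, pool_genes):
        with pytest.raises(ValueError, match="usable"):
            build_pool(["TTTT"], MODEL, pool_genome, pool_genes)

    def test_reads_order_invariant(self, pool_genome, pool_genes):
        seq = pool_genome[0].sequence
        reads = [
            make_read("A" * 20, seq[299:319]),
            make_read("C" * 20, seq[699:719]),
            make_read("A" * 20, seq[299:319]),
        ]
        a = build_pool(reads, MODEL, pool_genome, pool_genes)
        b = build_pool(reads[::-1], MODEL, pool_genome, pool_genes)
        pd.testing.assert_frame_equal(a, b)


class TestAssignGene:
    def test_central_single(self, pool_genes):
        assert assign_gene("s1", 300, pool_genes) == ("gA", True)

    def test_terminal_not_central(self, pool_genes):
        # gA spans 101..500 (len 400), central region 141..460
        assert assign_gene("s1", 110, pool_genes) == ("gA", False)

    def test_intergenic(self, pool_genes):
        assert assign_gene("s1", 550, pool_genes) == (None, False)

    def test_ambiguous_overlap_excluded(self):
        genes = [
            GeneAnnotation("g1", "s1", 100, 500, "+"),
            GeneAnnotation("g2", "s1", 200, 600, "-"),
        ]
        gene_id, central = assign_gene("s1", 300, genes)
        assert gene_id is None and not central


def make_pool_df(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "barcode", "scaffold", "pos", "strand", "n_reads",
            "gene_id", "central", "multimapped",
        ],
    )


class TestPoolQC:
    def test_hits_per_protein_mean(self):
        rows = []
        for gene, n in [("g1", 2), ("g2", 3), ("g3", 7)]:
            for i in range(n):
                rows.append([f"{gene}b{i}".ljust(20, "A"), "s1", 10, "+", 5,
                             gene, True, False])
        genes = [GeneAnnotation(g, "s1", 1, 100, "+") for g in ("g1", "g2", "g3")]
        qc = pool_qc(make_pool_df(rows), genes)
        assert qc.hits_per_protein_mean == 4.0
        assert qc.hits_per_protein_median == 3.0
        assert qc.n_hit_proteins == 3

    def test_read_bias(self):
        rows = []
        for gene, total in [("g1", 10), ("g2", 10), ("g3", 20), ("g4", 40)]:
            rows.append([f"{gene}bc".ljust(20, "A"), "s1", 10, "+", total,
                         gene, True, False])
        genes = [GeneAnnotation(g, "s1", 1, 100, "+") for g in ("g1", "g2", "g3", "g4")]
        qc = pool_qc(make_pool_df(rows), genes)
        assert qc.reads_per_hit_protein_mean == 20.0
        assert qc.reads_per_hit_protein_median == 15.0
        assert qc.read_bias == 5.0

    def test_identical_read_totals_zero_bias(self):
        rows = [
            [f"g{i}bc".ljust(20, "A"), "s1", 10, "+", 25, f"g{i}", True, False]
            for i in range(5)
        ]
        genes = [GeneAnnotation(f"g{i}", "s1", 1, 100, "+") for i in range(5)]
        assert pool_qc(make_pool_df(rows), genes).read_bias == 0.0

    def test_multimapped_and_noncentral_excluded(self):
        rows = [
            ["A" * 20, "s1", 10, "+", 5, "g1", True, False],
            ["C" * 20, "s1", 12, "+", 99, "g1", False, True],  # multimapped
            ["G" * 20, "s1", 14, "+", 99, "g1", False, False],  # not central
        ]
        genes = [GeneAnnotation("g1", "s1", 1, 100, "+")]
        qc = pool_qc(make_pool_df(rows), genes)
        assert qc.hits_per_protein_mean == 1.0
        assert qc.reads_per_hit_protein_mean == 5.0
        assert qc.n_unique_barcodes == 3

    def test_no_hit_proteins_error(self):
        rows = [["A" * 20, "s1", 10, "+", 5, None, False, False]]
        with pytest.raises(ValueError, match="no hit proteins"):
            pool_qc(make_pool_df(rows), [])


def test_pool_tsv_round_trip(tmp_path):
    rows = [
        ["A" * 20, "s1", 300, "+", 10, "gA", True, False],
        ["C" * 20, "s1", 550, "-", 3, None, False, False],
        ["G" * 20, "s1", 700, "+", 6, "gB", False, True],
    ]
    pool = make_pool_df(rows)
    p = tmp_path / "pool.tsv"
    write_pool_tsv(pool, p)
    back = read_pool_tsv(p)
    pd.testing.assert_frame_equal(back, pool)


def test_pool_tsv_duplicate_barcode_rejected(tmp_path):
    rows = [
        ["A" * 20, "s1", 300, "+", 10, "gA", True, False],
        ["A" * 20, "s1", 550, "-", 3, None, False, False],
    ]
    p = tmp_path / "pool.tsv"
    write_pool_tsv(make_pool_df(rows), p)
    with pytest.raises(ValueError, match="duplicate barcode"):
        read_pool_tsv(p)
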