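"""Tag collapsing, bounded-mismatch alignment and class summaries."""

import random

import pytest

from evsmallrna.annotate import (
    AnnotatedTag,
    Tag,
    align_tags,
    assign_classes,
    chromosome_abundance,
    class_composition,
    collapse_reads,
    length_distribution,
    read_collapsed_fasta,
    write_collapsed_fasta,
)
from evsmallrna.refdb import Catalog, Locus, ReferenceRecord, reverse_complement


class TestCollapse:
    def test_counts_and_order(self):
        ins = ["A" * 10 + "C" * 10, "A" * 10 + "C" * 10, "T" * 20]
        tags = collapse_reads(ins)
        assert [(t.seq[:1], t.count) for t in tags] == [("A", 2), ("T", 1)]
        assert tags == sorted(tags, key=lambda t: t.seq)

    def test_empty(self):
        assert collapse_reads([]) == []

    def test_conservation(self, small_library):
        tags = collapse_reads(small_library["clean"])
        assert sum(t.count for t in tags) == len(small_library["clean"])
        assert len({t.seq for t in tags}) == len(tags)

    def test_out_of_range_insert_is_fatal(self):
        with pytest.raises(ValueError):
            collapse_reads(["ACGT"])  # 4 nt < 17


def _brute_force_hits(tag_seq, catalog, max_mm):
    """Independent Hamming scan over every reference and strand."""
    hits = []
    for rec in catalog:
        ctx = catalog.precursor_of(rec) or rec.seq
        for strand, q in (("+", tag_seq), ("-", reverse_complement(tag_seq))):
            for i in range(len(ctx) - len(q) + 1):
                mm = sum(1 for a, b in zip(ctx[i : i + len(q)], q) if a != b or a == "N")
                if mm <= max_mm:
                    hits.append((rec.id, i, strand, mm))
    return hits


def _simple_catalog():
    recs = [
        ReferenceRecord("y1", "ACGTACGTAGCTTGCAACGGTCCAGT" + "GAT" * 10, "YRNA"),
        ReferenceRecord("y2", "TTGACCGGTTACGATCCGGAATACCA" + "CTA" * 10, "YRNA"),
        ReferenceRecord("r1", "CCGGATTACCAGGATACCATGGTACCAGGTAT" + "AC" * 10, "rRNA"),
    ]
    return Catalog(records=recs)


class TestAlign:
    def test_exact_unique_hit_offset_zero(self):
        cat = _simple_catalog()
        tag = Tag(cat.get("y1").seq[:20], 5)
        (at,) = align_tags([tag], cat, 0)
        assert at.unique and at.hits[0].reference_id == "y1"
        assert at.hits[0].offset == 0 and at.hits[0].mismatches == 0

    def test_tag_in_two_references_is_not_unique(self):
        shared = "ACGGATCCATTGCAGGTCAT"
        recs = [
            ReferenceRecord("a", shared + "GGGTTTCCCAAA", "YRNA"),
            ReferenceRecord("b", "TTTCCCGGGAAA" + shared, "rRNA"),
        ]
        (at,) = align_tags([Tag(shared, 1)], Catalog(records=recs), 0)
        assert not at.unique and len(at.hits) == 2

    def test_one_mismatch_hit(self):
        cat = _simple_catalog()
        seq = cat.get("y2").seq[:20]
        mutated = "G" + seq[1:] if seq[0] != "G" else "C" + seq[1:]
        (at0,) = align_tags([Tag(mutated, 1)], cat, 0)
        (at1,) = align_tags([Tag(mutated, 1)], cat, 1)
        assert at0.hits == []
        assert at1.unique and at1.hits[0].mismatches == 1

    def test_matches_brute_force_scan_on_random_fixtures(self, catalog):
        rng = random.Random(7)
        refs = list(catalog)
        for max_mm in (0, 1):
            for _ in range(60):
                rec = rng.choice(refs)
                ctx = catalog.precursor_of(rec) or rec.seq
                L = rng.randint(17, min(30, len(ctx)))
                start = rng.randint(0, len(ctx) - L)
                seq = list(ctx[start : start + L])
                for _ in range(rng.randint(0, max_mm)):
                    i = rng.randrange(L)
                    seq[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
                tag = Tag("".join(seq), 1)
                (at,) = align_tags([tag], catalog, max_mm)
                expect = _brute_force_hits(tag.seq, catalog, max_mm)
                best = min((h[3] for h in expect), default=None)
                got = sorted((h.reference_id, h.offset, h.strand, h.mismatches)
                             for h in at.hits)
                assert got == sorted(h for h in expect if h[3] == best)
                assert at.unique == (len(got) == 1)

    def test_reverse_strand_hit(self):
        cat = _simple_catalog()
        tag = Tag(reverse_complement(cat.get("r1").seq[5:27]), 3)
        (at,) = align_tags([tag], cat, 0)
        assert at.unique and at.hits[0].strand == "-"

    def test_invalid_max_mismatches(self):
        with pytest.raises(ValueError):
            align_tags([], _simple_catalog(), 3)


class TestClasses:
    def test_class_of_single_hit(self):
        cat = _simple_catalog()
        tag = Tag(cat.get("r1").seq[:20], 2)
        (at,) = assign_classes(align_tags([tag], cat, 0), cat)
        assert at.rna_class == "rRNA"

    def test_priority_resolves_equal_score_multiclass_tie(self):
        shared = "ACGGATCCATTGCAGGTCAT"
        recs = [
            ReferenceRecord("m", shared + "AC", "miRNA", precursor_id="p"),
            ReferenceRecord("r", shared + "GGCCTTAAGG", "rRNA"),
        ]
        cat = Catalog(records=recs)
        (at,) = assign_classes(align_tags([Tag(shared, 1)], cat, 0), cat)
        assert not at.unique  # two placements
        assert at.rna_class == "miRNA"  # priority wins the label

    def test_no_hit_is_other(self):
        cat = _simple_catalog()
        (at,) = assign_classes(align_tags([Tag("T" * 17 + "ACG", 1)], cat, 0), cat)
        assert at.rna_class == "other" and not at.unique


class TestComposition:
    def test_all_mirna_is_100_percent(self):
        tags = [AnnotatedTag(Tag("A" * 17, 5), unique=True)]
        tags[0].rna_class = "miRNA"
        assert class_composition(tags, 5) == {"miRNA": 100.0}

    def test_percentages_sum_to_100(self, small_library, catalog):
        tags = collapse_reads(small_library["clean"])
        ann = assign_classes(align_tags(tags, catalog, 0), catalog)
        comp = class_composition(ann, small_library["report"].clean_reads)
        assert sum(comp.values()) == pytest.approx(100.0)

    def test_planted_mixture_recovered_within_binomial_error(self, catalog):
        import math

        from evsmallrna.qcfilter import filter_reads
        from evsmallrna.simulate import SimulationConfig, simulate_library

        n = 100_000
        cfg = SimulationConfig(
            library_size=n, seed=4,
            class_weights={"miRNA": 0.5, "YRNA": 0.5}, artifact_rates={},
        )
        records, _ = simulate_library(cfg, catalog)
        clean, report, _ = filter_reads(records)
        ann = assign_classes(align_tags(collapse_reads(clean), catalog, 0), catalog)
        comp = class_composition(ann, report.clean_reads)
        sd_pct = 100 * math.sqrt(0.25 / n)
        assert comp["miRNA"] == pytest.approx(50.0, abs=3 * sd_pct)
        assert comp["YRNA"] == pytest.approx(50.0, abs=3 * sd_pct)

    def test_zero_clean_reads_is_error(self):
        with pytest.raises(ValueError):
            class_composition([], 0)


class TestLengthDistribution:
    def test_single_tag_rpm(self):
        at = AnnotatedTag(Tag("G" * 32, 10), unique=True)
        at.rna_class = "YRNA"
        dist = length_distribution([at], "YRNA", 10**6)
        assert dist[32] == 10.0
        assert sum(dist.values()) == 10.0

    def test_absent_class_all_zero(self):
        assert set(length_distribution([], "tRNA", 100).values()) == {0.0}


class TestChromosomeAbundance:
    def test_single_tag_bin(self):
        at = AnnotatedTag(Tag("G" * 20, 10), unique=True)
        from evsmallrna.annotate import Hit

        at.hits = [Hit("y", 5, "+", 0)]
        loci = {"y": Locus("chr7", 2_000_100, 2_000_200, "+")}
        table = chromosome_abundance([at], loci, 1_000_000, 10**6)
        assert table == {("chr7", 2): 10.0}

    def test_missing_locus_goes_unplaced(self):
        from evsmallrna.annotate import Hit

        at = AnnotatedTag(Tag("G" * 20, 4), unique=True)
        at.hits = [Hit("y", 0, "+", 0)]
        assert chromosome_abundance([at], {}, 1000, 10**6) == {("unplaced", 0): 4.0}

    def test_totals_conserved(self, small_library, catalog):
        tags = collapse_reads(small_library["clean"])
        ann = assign_classes(align_tags(tags, catalog, 0), catalog)
        clean = small_library["report"].clean_reads
        loci = {rec.id: rec.locus for rec in catalog if rec.locus}
        table = chromosome_abundance(ann, loci, 10_000_000, clean)
        unique_rpm = sum(a.tag.count for a in ann if a.unique) / clean * 1e6
        assert sum(table.values()) == pytest.approx(unique_rpm)


def test_collapsed_fasta_round_trip(tmp_path):
    tags = [Tag("ACGT" * 5, 7), Tag("TTGCA" * 4, 2)]
    p = tmp_path / "tags.fasta"
    write_collapsed_fasta(tags, p)
    assert read_collapsed_fasta(p) == tags
    assert ">seq_1_x7" in p.read_text()
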