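import pytest

from nesprintx.errors import (
    BoundsError,
    ModelError,
    NotFoundError,
    OrientationError,
    ParameterError,
)
from nesprintx.gene_model import (
    DomainAnnotation,
    Exon,
    GeneModel,
    fasta_string,
    format_utr_name,
    gff_string,
    load_gene,
    normalize_label,
    parse_label,
    primer_pair_spans_intron,
    segment_sequence,
    tile_queries,
    write_gff,
)


def small_model(**overrides):
    kwargs = dict(
        gene_id="g",
        chrom="c",
        strand="+",
        exons=[
            Exon("1", 10, 40),
            Exon("6'", 50, 71, cassette=True),
            Exon("7", 80, 110),
        ],
        locus_seq="ACGT" * 30,
    )
    kwargs.update(overrides)
    return GeneModel(**kwargs)


class TestLabels:
    def test_parse_plain_and_primed(self):
        assert parse_label("93") == (93, 0)
        assert parse_label("6'") == (6, 1)
        assert parse_label("6′") == (6, 1)
        assert parse_label("6") < parse_label("6'") < parse_label("7")

    def test_normalize(self):
        assert normalize_label("6′") == "6'"
        assert normalize_label("12") == "12"

    @pytest.mark.parametrize("bad", ["", "x", "6''", "'6", "6 ", "-1"])
    def test_malformed(self, bad):
        with pytest.raises(NotFoundError):
            parse_label(bad)


class TestModelValidation:
    def test_ok(self):
        m = small_model()
        assert m.exon_labels == ["1", "6'", "7"]

    def test_duplicate_labels(self):
        with pytest.raises(ModelError):
            small_model(exons=[Exon("1", 0, 5), Exon("1", 10, 15)])

    def test_out_of_order(self):
        with pytest.raises(ModelError):
            small_model(exons=[Exon("7", 0, 5), Exon("1", 10, 15)])

    def test_overlap(self):
        with pytest.raises(ModelError):
            small_model(exons=[Exon("1", 0, 20), Exon("2", 15, 30)])

    def test_zero_length_intron(self):
        with pytest.raises(ModelError):
            small_model(exons=[Exon("1", 0, 20), Exon("2", 20, 30)])

    def test_exon_beyond_locus(self):
        with pytest.raises(BoundsError):
            small_model(exons=[Exon("1", 0, 1000)])

    def test_bad_strand(self):
        with pytest.raises(ModelError):
            small_model(strand="x")

    def test_bad_bases(self):
        with pytest.raises(ModelError):
            small_model(locus_seq="ACGU" * 30)

    def test_empty_exon_rejected(self):
        with pytest.raises(ModelError):
            Exon("1", 5, 5)

    def test_kash_must_be_terminal(self):
        with pytest.raises(ModelError):
            small_model(domains=[DomainAnnotation("KASH", ("1", "6'"))])

    def test_sr_needs_index(self):
        with pytest.raises(ModelError):
            small_model(domains=[DomainAnnotation("SR", ("1", "7"))])

    def test_sr_indices_increase(self):
        with pytest.raises(ModelError):
            small_model(
                domains=[
                    DomainAnnotation("SR", ("1", "1"), sr_index=2),
                    DomainAnnotation("SR", ("7", "7"), sr_index=1),
                ]
            )

    def test_domain_unknown_exon(self):
        with pytest.raises(ModelError):
            small_model(domains=[DomainAnnotation("CH", ("1", "99"))])

    def test_unknown_domain_kind(self):
        with pytest.raises(ModelError):
            DomainAnnotation("ZZ", ("1", "2"))


class TestQueries:
    def test_exon_lookup_normalises(self):
        m = small_model()
        assert m.exon("6′").start == 50
        with pytest.raises(NotFoundError):
            m.exon("99")

    def test_introns(self):
        m = small_model()
        assert m.introns() == [("1/6'", 40, 50), ("6'/7", 71, 80)]
        assert m.intron("1/6′") == (40, 50)
        with pytest.raises(NotFoundError):
            m.intron("7/8")

    def test_intron_after(self):
        m = small_model()
        assert m.intron_after("6'") == ("6'/7", 71, 80)
        with pytest.raises(NotFoundError):
            m.intron_after("7")

    def test_sequence_bounds(self):
        m = small_model()
        assert m.sequence(0, 4) == "ACGT"
        with pytest.raises(BoundsError):
            m.sequence(-1, 4)
        with pytest.raises(BoundsError):
            m.sequence(0, 10_000)

    def test_segment_sequence(self):
        m = small_model()
        assert segment_sequence(m, "exon", "1") == m.locus_seq[10:40]
        assert segment_sequence(m, "intron", "1/6'") == m.locus_seq[40:50]
        with pytest.raises(ParameterError):
            segment_sequence(m, "cds", "1")


class TestTileQueries:
    def test_short_sequence_single_window(self):
        assert tile_queries("ACGT" * 10, window=1000, step=500) == [
            (0, 40, "ACGT" * 10)
        ]

    def test_regular_tiling(self):
        seq = "A" * 2000
        tiles = tile_queries(seq, window=1000, step=500)
        assert [(s, e) for s, e, _ in tiles] == [(0, 1000), (500, 1500), (1000, 2000)]

    def test_final_window_shifted(self):
        seq = "A" * 2300
        tiles = tile_queries(seq, window=1000, step=500)
        assert [(s, e) for s, e, _ in tiles][-1] == (1300, 2300)
        # full coverage, all windows full length
        covered = set()
        for s, e, w in tiles:
            assert e - s == 1000 and w == seq[s:e]
            covered.update(range(s, e))
        assert covered == set(range(2300))

    def test_bad_params(self):
        with pytest.raises(ParameterError):
            tile_queries("ACGT", window=100, step=100)
        with pytest.raises(ParameterError):
            tile_queries("", window=10, step=5)


class TestUTRNames:
    def test_intron_anchor(self):
        assert format_utr_name("N1", "5'", "14/15") == "N1-5′I14/15"

    def test_exon_anchor(self):
        assert format_utr_name("N1", "3'", "62") == "N1-3′E62"

    def test_typographic_side_accepted(self):
        assert format_utr_name("N2", "3′", "6′") == "N2-3′E6'"

    def test_bad_side(self):
        with pytest.raises(ParameterError):
            format_utr_name("N1", "4'", "1")


class TestPrimers:
    def test_spanning(self):
        m = small_model()
        assert primer_pair_spans_intron(m, (12, 32), (82, 102))

    def test_same_exon_not_spanning(self):
        m = small_model()
        assert not primer_pair_spans_intron(m, (10, 20), (25, 39))

    def test_gap_inside_intron_not_spanning(self):
        # both primers flank only part of the intron: no full intron between
        m = small_model()
        assert not primer_pair_spans_intron(m, (30, 42), (45, 60))

    def test_orientation_error(self):
        m = small_model()
        with pytest.raises(OrientationError):
            primer_pair_spans_intron(m, (80, 100), (10, 30))

    def test_bounds_error(self):
        m = small_model()
        with pytest.raises(BoundsError):
            primer_pair_spans_intron(m, (-2, 5), (50, 60))


class TestIO:
    def test_round_trip_plus(self, tmp_path, sim3):
        _, model, *_ = sim3
        gff = tmp_path / "g.gff3"
        fa = tmp_path / "g.fa"
        write_gff(model, gff, fa)
        loaded = load_gene(str(gff), str(fa), model.gene_id)
        assert loaded.exons == model.exons
        assert loaded.locus_seq == model.locus_seq
        assert loaded.domains == model.domains
        assert loaded.strand == "+"

    def test_round_trip_minus(self, tmp_path, nesp1):
        model, _ = nesp1
        minus = GeneModel(
            gene_id=model.gene_id,
            chrom=model.chrom,
            strand="-",
            exons=list(model.exons),
            locus_seq=model.locus_seq,
            domains=list(model.domains),
        )
        gff = tmp_path / "m.gff3"
        fa = tmp_path / "m.fa"
        write_gff(minus, gff, fa)
        loaded = load_gene(str(gff), str(fa), model.gene_id)
        # transcription-oriented view is invariant under strand flip
        assert loaded.strand == "-"
        assert loaded.exons == minus.exons
        assert loaded.locus_seq == minus.locus_seq
        assert loaded.domains == minus.domains

    def test_deterministic_text(self, nesp1):
        model, _ = nesp1
        assert gff_string(model) == gff_string(model)
        assert fasta_string(model) == fasta_string(model)

    def test_missing_gene(self, tmp_path, sim3):
        _, model, *_ = sim3
        gff = tmp_path / "g.gff3"
        fa = tmp_path / "g.fa"
        write_gff(model, gff, fa)
        with pytest.raises(NotFoundError):
            load_gene(str(gff), str(fa), "nope")
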