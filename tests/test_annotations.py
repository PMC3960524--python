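import io

import pytest
from hypothesis import given, settings, strategies as st

from tftarget import (
    FixtureSpec,
    GtfParseError,
    WINDOW_PRESETS,
    WindowSpec,
    build_fixture,
    build_regions,
    gene_regions,
    parse_gtf,
    regulatory_region,
    resolve_ids,
    transcript_regions,
    tss,
)
from tftarget.annotations import AmbiguousNameError, AnnotationError, strip_version, write_gtf

from conftest import make_transcript
from oracles import naive_targets

GTF_LINE = (
    '{chrom}\tsrc\t{feature}\t{start}\t{end}\t.\t{strand}\t.\t'
    'gene_id "{gid}"; transcript_id "{tid}"; gene_name "{gname}"; '
    'transcript_name "{tname}"; gene_type "lincRNA";'
)


def gtf(*rows):
    return io.StringIO("#!header\n" + "".join(r + "\n" for r in rows))


class TestParseGtf:
    def test_single_transcript_direct_mapping(self):
        line = GTF_LINE.format(chrom="chr1", feature="transcript", start=100, end=500,
                               strand="+", gid="G1", tid="T1", gname="LNC1", tname="LNC1-201")
        transcripts, genes = parse_gtf(gtf(line))
        (t,) = transcripts
        assert (t.chrom, t.start, t.end, t.strand) == ("chr1", 100, 500, "+")
        assert (t.gene_id, t.gene_name, t.transcript_name) == ("G1", "LNC1", "LNC1-201")
        (g,) = genes
        assert g.transcript_ids == ("T1",)

    def test_empty_stream(self):
        transcripts, genes = parse_gtf(gtf())
        assert transcripts == [] and genes == []

    def test_span_is_min_start_max_end_over_features(self):
        rows = [
            GTF_LINE.format(chrom="chr1", feature="exon", start=300, end=500,
                            strand="+", gid="G1", tid="T1", gname="", tname=""),
            GTF_LINE.format(chrom="chr1", feature="exon", start=100, end=200,
                            strand="+", gid="G1", tid="T1", gname="", tname=""),
        ]
        transcripts, _ = parse_gtf(gtf(*rows))
        assert (transcripts[0].start, transcripts[0].end) == (100, 500)

    def test_fixture_counts_known_by_construction(self):
        # 50 genes x exactly 2 transcripts each
        fx = build_fixture(FixtureSpec(seed=3, n_genes=50, transcripts_per_gene=(2, 2),
                                       n_null_datasets=0, peaks_per_dataset=0))
        buf = io.StringIO()
        write_gtf(fx.transcripts, buf)
        buf.seek(0)
        transcripts, genes = parse_gtf(buf)
        assert len(genes) == 50
        assert len(transcripts) == 100

    @pytest.mark.parametrize(
        "bad_row, match",
        [
            ("chr1\tsrc\texon\t100\t200", "9 tab-separated"),
            ('chr1\tsrc\texon\tabc\t200\t.\t+\t.\tgene_id "G"; transcript_id "T";', "non-integer"),
            ('chr1\tsrc\texon\t300\t200\t.\t+\t.\tgene_id "G"; transcript_id "T";', "start 300 > end"),
            ('chr1\tsrc\texon\t100\t200\t.\t.\t.\tgene_id "G"; transcript_id "T";', "strand"),
        ],
    )
    def test_malformed_line_errors_name_line_number(self, bad_row, match):
        with pytest.raises(GtfParseError, match=match) as err:
            parse_gtf(gtf(bad_row))
        assert "line 2" in str(err.value)

    def test_transcript_switching_chrom_is_error(self):
        rows = [
            GTF_LINE.format(chrom="chr1", feature="exon", start=100, end=200,
                            strand="+", gid="G1", tid="T1", gname="", tname=""),
            GTF_LINE.format(chrom="chr2", feature="exon", start=100, end=200,
                            strand="+", gid="G1", tid="T1", gname="", tname=""),
        ]
        with pytest.raises(GtfParseError, match="switches chrom/strand"):
            parse_gtf(gtf(*rows))

    def test_gene_with_transcripts_on_both_strands_is_error(self):
        rows = [
            GTF_LINE.format(chrom="chr1", feature="transcript", start=100, end=200,
                            strand="+", gid="G1", tid="T1", gname="", tname=""),
            GTF_LINE.format(chrom="chr1", feature="transcript", start=400, end=600,
                            strand="-", gid="G1", tid="T2", gname="", tname=""),
        ]
        with pytest.raises(GtfParseError, match="disagree"):
            parse_gtf(gtf(*rows))

    def test_biotype_filter_drops_other_biotypes(self):
        rows = [
            GTF_LINE.format(chrom="chr1", feature="transcript", start=100, end=200,
                            strand="+", gid="G1", tid="T1", gname="", tname=""),
            'chr1\tsrc\ttranscript\t500\t900\t.\t+\t.\tgene_id "G2"; transcript_id "T2"; gene_type "protein_coding";',
        ]
        transcripts, genes = parse_gtf(gtf(*rows), feature_filter={"lincRNA"})
        assert [t.transcript_id for t in transcripts] == ["T1"]
        assert [g.gene_id for g in genes] == ["G1"]

    def test_roundtrip_is_idempotent(self, planted_fixture):
        buf = io.StringIO()
        write_gtf(planted_fixture.transcripts, buf)
        buf.seek(0)
        once_t, once_g = parse_gtf(buf)
        buf2 = io.StringIO()
        write_gtf(once_t, buf2)
        buf2.seek(0)
        twice_t, twice_g = parse_gtf(buf2)
        assert once_t == planted_fixture.transcripts
        assert twice_t == once_t and twice_g == once_g

    def test_agrees_with_gffutils_on_small_fixture(self, tmp_path):
        gffutils = pytest.importorskip("gffutils")
        fx = build_fixture(FixtureSpec(seed=5, n_genes=10, n_null_datasets=0,
                                       peaks_per_dataset=0))
        path = tmp_path / "mini.gtf"
        with open(path, "w") as fh:
            write_gtf(fx.transcripts, fh)
        transcripts, _ = parse_gtf(open(path))
        db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                                merge_strategy="create_unique",
                                disable_infer_genes=True, disable_infer_transcripts=True)
        theirs = {f.id: (f.seqid, f.start, f.end, f.strand)
                  for f in db.features_of_type("transcript")}
        ours = {t.transcript_id: (t.chrom, t.start, t.end, t.strand) for t in transcripts}
        assert ours == theirs


class TestTssAndRegions:
    @pytest.mark.parametrize(
        "start, end, strand, expected",
        [(100, 500, "+", 100), (100, 500, "-", 500), (7, 7, "+", 7)],
    )
    def test_tss_is_five_prime_end(self, start, end, strand, expected):
        rec = make_transcript(start=start, end=end, strand=strand)
        assert tss(rec) == ("chr1", expected, strand)

    def test_plus_strand_window(self):
        rec = make_transcript(start=10_000, end=20_000, strand="+")
        r = regulatory_region(rec, WindowSpec(2_000, 1_000))
        assert (r.start, r.end) == (7_999, 11_000)  # 1-based [8000, 11000]

    def test_minus_strand_window_is_mirrored(self):
        rec = make_transcript(start=1_000, end=10_000, strand="-")
        r = regulatory_region(rec, WindowSpec(2_000, 1_000))
        assert (r.start, r.end) == (8_999, 12_000)  # 1-based [9000, 12000]

    def test_left_clamp_at_chromosome_start(self):
        rec = make_transcript(start=500, end=900, strand="+")
        r = regulatory_region(rec, WindowSpec(2_000, 1_000))
        assert (r.start, r.end) == (0, 1_500)  # 1-based [1, 1500]

    @given(
        t=st.integers(min_value=1, max_value=10**8),
        u=st.integers(min_value=0, max_value=60_000),
        d=st.integers(min_value=0, max_value=10_000),
        strand=st.sampled_from("+-"),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_window_contains_tss_and_has_expected_length(self, t, u, d, strand):
        rec = (make_transcript(start=t, end=t + 100, strand="+") if strand == "+"
               else make_transcript(start=max(1, t - 100), end=t, strand="-"))
        r = regulatory_region(rec, WindowSpec(u, d))
        assert r.start <= t - 1 < r.end  # TSS base (0-based t-1) inside
        if (t - u if strand == "+" else t - d) >= 1:
            assert r.end - r.start == u + d + 1
        else:
            assert r.end - r.start < u + d + 1

    @given(
        t=st.integers(min_value=100_000, max_value=10**7),
        u=st.integers(min_value=0, max_value=50_000),
        d=st.integers(min_value=0, max_value=5_000),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_strand_mirror_property(self, t, u, d):
        plus = regulatory_region(make_transcript(start=t, end=t + 10, strand="+"),
                                 WindowSpec(u, d))
        minus = regulatory_region(make_transcript(start=t - 10, end=t, strand="-"),
                                  WindowSpec(u, d))
        # reflect the plus-strand window about the TSS base t (1-based):
        # 1-based [t-u, t+d] maps to [t-d, t+u]
        assert (minus.start, minus.end) == (t - d - 1, t + u)

    def test_window_presets_are_the_five_named_pairs(self):
        assert {k: (w.upstream_bp, w.downstream_bp) for k, w in WINDOW_PRESETS.items()} == {
            "2k1k": (2_000, 1_000),
            "10k1k": (10_000, 1_000),
            "20k1k": (20_000, 1_000),
            "30k2k": (30_000, 2_000),
            "50k5k": (50_000, 5_000),
        }


class TestGeneRegions:
    def test_single_transcript_gene_equals_transcript_region(self):
        rec = make_transcript()
        from tftarget.annotations import GeneRecord
        gene = GeneRecord("G1", "", "chr1", "+", ("TX1",))
        (r,) = gene_regions(gene, {"TX1": rec}, WindowSpec(2_000, 1_000))
        tr = regulatory_region(rec, WindowSpec(2_000, 1_000))
        assert (r.start, r.end) == (tr.start, tr.end)
        assert r.feature_id == "G1"

    def test_shared_tss_transcripts_give_identical_regions(self):
        from tftarget.annotations import GeneRecord
        txs = {f"T{i}": make_transcript(transcript_id=f"T{i}", start=50_000, end=50_000 + 500 * i)
               for i in (1, 2, 3)}
        gene = GeneRecord("G1", "", "chr1", "+", ("T1", "T2", "T3"))
        regions = gene_regions(gene, txs, WindowSpec(2_000, 1_000))
        assert len(regions) == 3
        assert len({(r.start, r.end) for r in regions}) == 1

    def test_union_rule_targets_gene_via_either_tss(self):
        # two TSSs 1 kb apart; a peak in either window marks the gene targeted
        from tftarget.annotations import GeneRecord
        from tftarget.peaks import Peak
        txs = {
            "T1": make_transcript(transcript_id="T1", start=50_000, end=55_000),
            "T2": make_transcript(transcript_id="T2", start=51_000, end=55_000),
        }
        gene = GeneRecord("G1", "", "chr1", "+", ("T1", "T2"))
        regions = gene_regions(gene, txs, WindowSpec(2_000, 1_000))
        assert len(regions) == 2
        # peak only in T2's extra downstream stretch (1-based 51001..52000)
        peak = Peak("chr1", 51_500, 51_600)
        assert naive_targets([peak], regions) == {"G1"}

    def test_dangling_transcript_id_errors(self):
        from tftarget.annotations import GeneRecord
        gene = GeneRecord("G1", "", "chr1", "+", ("MISSING",))
        with pytest.raises(AnnotationError, match="MISSING"):
            gene_regions(gene, {}, WindowSpec(2_000, 1_000))

    def test_build_regions_levels(self, planted_fixture):
        fx = planted_fixture
        g = build_regions(fx.transcripts, fx.genes, level="gene")
        t = build_regions(fx.transcripts, fx.genes, level="transcript")
        assert len(g) == len(t) == len(fx.transcripts)
        assert {r.feature_id for r in g} == {gn.gene_id for gn in fx.genes}
        assert {r.feature_id for r in t} == {tx.transcript_id for tx in fx.transcripts}


class TestResolveIds:
    @pytest.fixture()
    def annotation(self):
        transcripts = [
            make_transcript(transcript_id="ENST001.3", transcript_name="LNC1-201",
                            gene_id="ENSG001.7", gene_name="LNC1"),
            make_transcript(transcript_id="ENST002.1", transcript_name="LNC2-201",
                            gene_id="ENSG002.2", gene_name="LNC2", start=100_000, end=101_000),
        ]
        from tftarget.annotations import GeneRecord
        genes = [
            GeneRecord("ENSG001.7", "LNC1", "chr1", "+", ("ENST001.3",)),
            GeneRecord("ENSG002.2", "LNC2", "chr1", "+", ("ENST002.1",)),
        ]
        return transcripts, genes

    def test_exact_versioned_and_stripped_ids_resolve(self, annotation):
        transcripts, genes = annotation
        resolved, unknown = resolve_ids(["ENSG001.7", "ENSG002"], transcripts, genes)
        assert resolved == ["ENSG001.7", "ENSG002.2"]
        assert unknown == []

    def test_names_resolve_and_unknowns_are_dropped(self, annotation):
        transcripts, genes = annotation
        resolved, unknown = resolve_ids(["LNC2", "NOPE"], transcripts, genes)
        assert resolved == ["ENSG002.2"]
        assert unknown == ["NOPE"]

    def test_duplicates_collapse_after_resolution(self, annotation):
        transcripts, genes = annotation
        resolved, _ = resolve_ids(["ENSG001.7", "ENSG001", "LNC1"], transcripts, genes)
        assert resolved == ["ENSG001.7"]

    def test_ambiguous_name_errors_with_candidates(self, annotation):
        transcripts, genes = annotation
        from tftarget.annotations import GeneRecord
        genes = genes + [GeneRecord("ENSG003.1", "LNC1", "chr1", "+", ("ENST001.3",))]
        with pytest.raises(AmbiguousNameError, match="ENSG003.1"):
            resolve_ids(["LNC1"], transcripts, genes)

    def test_transcript_level_resolution(self, annotation):
        transcripts, genes = annotation
        resolved, _ = resolve_ids(["ENST001", "LNC2-201"], transcripts, genes,
                                  level="transcript")
        assert resolved == ["ENST001.3", "ENST002.1"]

    def test_version_stripping_can_be_disabled(self, annotation):
        transcripts, genes = annotation
        resolved, unknown = resolve_ids(["ENSG001"], transcripts, genes,
                                        strip_versions=False)
        assert resolved == [] and unknown == ["ENSG001"]

    def test_strip_version_only_touches_trailing_numeric_suffix(self):
        assert strip_version("ENSG0001.7") == "ENSG0001"
        assert strip_version("LNC1-201") == "LNC1-201"
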