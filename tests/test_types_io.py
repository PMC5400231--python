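"""Domain types, coordinate conventions, and format round-trips."""

import pytest
from hypothesis import given, settings, strategies as st

from rvburden.io import (
    RecordError,
    read_gene_sets,
    read_ranked_list,
    read_sample_sheet,
    read_variant_calls,
    write_gene_sets,
    write_ranked_list,
    write_sample_sheet,
    write_variant_calls,
)
from rvburden.types import (
    GeneSet,
    GenomicInterval,
    RankedGeneList,
    VariantAnnotation,
    VariantCall,
    Zygosity,
    EffectRaw,
    normalize_chrom,
)


class TestGenomicInterval:
    def test_rejects_degenerate_interval(self):
        with pytest.raises(ValueError):
            GenomicInterval("1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 1)

    def test_half_open_overlap_semantics(self):
        a = GenomicInterval("1", 100, 200)
        assert a.overlaps(GenomicInterval("1", 150, 160))
        assert not a.overlaps(GenomicInterval("1", 200, 300))  # touching
        assert not a.overlaps(GenomicInterval("2", 100, 200))

    def test_chrom_prefix_normalization(self):
        assert normalize_chrom("chr22") == "22" == normalize_chrom("22")
        assert GenomicInterval("chr22", 0, 10).overlaps(GenomicInterval("22", 5, 6))


class TestVariantCall:
    def test_ref_equal_alt_rejected(self):
        with pytest.raises(ValueError):
            VariantCall(GenomicInterval("1", 99, 100), "A", "A", "S1", Zygosity.HETEROZYGOUS)


def _mini_vcf(tmp_path, gt="0/1"):
    vcf = tmp_path / "m.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        f"1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t{gt}\n"
    )
    tsv = tmp_path / "m.tsv"
    tsv.write_text(
        "chrom\tpos\tref\talt\tgene\teffect\tphylop_pm\tphylop_100v\tsift\t"
        "polyphen2\tmutation_assessor\tcadd_phred\tmutation_taster\tfreq_a\n"
        "1\t100\tA\tT\tGENE1\tmissense\t.\t.\t.\t.\t.\t.\t.\t0.005\n"
    )
    return vcf, tsv


class TestVariantCallReader:
    def test_vcf_coordinates_become_zero_based_half_open(self, tmp_path):
        """A VCF record at 1-based position 100 maps to interval [99, 100)."""
        vcf, tsv = _mini_vcf(tmp_path)
        [(call, ann)] = read_variant_calls(vcf, tsv)
        assert (call.interval.start, call.interval.end) == (99, 100)
        assert call.zygosity is Zygosity.HETEROZYGOUS
        assert call.subject_id == "S1"

    def test_missing_scores_stay_absent(self, tmp_path):
        """A '.' score column must not be imputed to any number."""
        vcf, tsv = _mini_vcf(tmp_path)
        [(_, ann)] = read_variant_calls(vcf, tsv)
        assert "sift" not in ann.scores
        assert ann.allele_freqs == {"freq_a": 0.005}

    @pytest.mark.parametrize(
        "gt,zyg",
        [("0/1", Zygosity.HETEROZYGOUS), ("1/1", Zygosity.HOMOZYGOUS), ("1", Zygosity.HEMIZYGOUS)],
    )
    def test_genotype_to_zygosity(self, tmp_path, gt, zyg):
        vcf, tsv = _mini_vcf(tmp_path, gt=gt)
        [(call, _)] = read_variant_calls(vcf, tsv)
        assert call.zygosity is zyg

    def test_missing_sidecar_key_names_the_variant(self, tmp_path):
        vcf, tsv = _mini_vcf(tmp_path)
        tsv.write_text(tsv.read_text().replace("1\t100", "1\t101"))
        with pytest.raises(RecordError, match="1:100"):
            read_variant_calls(vcf, tsv)


class TestRoundTrips:
    def test_variant_records_round_trip(self, small_bundle, tmp_path):
        """write then read preserves every subject-variant record."""
        records = small_bundle.records[:200]
        write_variant_calls(tmp_path / "rt.vcf", tmp_path / "rt.tsv", records)
        back = read_variant_calls(tmp_path / "rt.vcf", tmp_path / "rt.tsv")
        key = lambda ca: (*ca[0].site_key, ca[0].subject_id)
        assert sorted(records, key=key) == sorted(back, key=key)

    def test_sample_sheet_round_trip(self, small_bundle, tmp_path):
        write_sample_sheet(tmp_path / "s.tsv", small_bundle.subjects)
        back = read_sample_sheet(tmp_path / "s.tsv")
        assert back == small_bundle.subjects

    def test_ranked_list_round_trip(self, small_bundle, tmp_path):
        write_ranked_list(tmp_path / "r.tsv", small_bundle.ranked)
        assert read_ranked_list(tmp_path / "r.tsv") == small_bundle.ranked

    @given(pos=st.integers(min_value=1, max_value=250_000_000))
    @settings(max_examples=50, derandomize=True)
    def test_coordinate_conversion_is_self_inverse(self, pos):
        """toVCF(fromVCF(x)) == x for 1-based positions."""
        internal = pos - 1
        assert internal + 1 == pos
        iv = GenomicInterval("1", internal, internal + 1)
        assert iv.start + 1 == pos


class TestGeneSetFormats:
    def test_gmt_duplicates_collapse_with_warning(self, tmp_path, caplog):
        p = tmp_path / "s.gmt"
        p.write_text("s1\tdesc\tA\tB\tA\n")
        import logging

        with caplog.at_level(logging.WARNING):
            [gs] = read_gene_sets(p)
        assert gs.genes == frozenset({"A", "B"})
        assert any("duplicate" in r.message for r in caplog.records)

    def test_empty_gene_set_is_an_error(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("s1\tdesc\t\n")
        with pytest.raises(RecordError):
            read_gene_sets(p)

    @pytest.mark.parametrize("n", [43, 46])
    def test_candidate_set_sizes(self, tmp_path, n):
        """Candidate gene-set fixtures keep the defined membership sizes
        (43 known-disease candidates; 46 deletion-region genes)."""
        from rvburden import fixtures

        gs = fixtures.known_pd_gene_set() if n == 43 else fixtures.deletion_region_gene_set()
        write_gene_sets(tmp_path / "c.gmt", [gs])
        [back] = read_gene_sets(tmp_path / "c.gmt")
        assert len(back) == n
        assert back.genes == gs.genes


class TestRankedList:
    def test_valid_two_entry_list(self):
        rl = RankedGeneList(entries=(("G1", 1), ("G2", 2)))
        assert len(rl) == 2

    def test_duplicate_symbol_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            RankedGeneList(entries=(("G1", 1), ("G1", 2)))

    def test_non_contiguous_ranks_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            RankedGeneList(entries=(("G1", 1), ("G2", 3)))

    def test_reference_table_gene_ranks(self):
        """TTN sits at rank 57 and LARS2 at 921 in the priority fixture."""
        from rvburden.fixtures import ranked_list_fixture

        rl = ranked_list_fixture(1000)
        assert rl.rank_of("TTN") == 57
        assert rl.rank_of("LARS2") == 921
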