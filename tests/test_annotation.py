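"""Feature-table / GenBank parsing and strand-aware gene extraction."""

import textwrap

import pytest

from mitophylo.annotation import (
    CoordinateError,
    FeatureTableError,
    GeneFeature,
    MitoGenome,
    extract_gene,
    normalize_gene_name,
    read_feature_table,
    read_genbank,
    reverse_complement,
    write_feature_table,
)

HEADER = "name\tclass\tstrand\tstart\tend\tstart_codon\tstop_codon\n"


def _write_table(tmp_path, body, meta="#circular=false\n#length=20000\n"):
    p = tmp_path / "features.tsv"
    p.write_text(meta + HEADER + body)
    return p


class TestReadFeatureTable:
    def test_row_sizes_match_declared_coordinates(self, tmp_path):
        p = _write_table(
            tmp_path,
            "ND1\tPCG\tH\t2752\t3707\tATG\tTA-\n"
            "tRNA-Ser1\ttRNA\tH\t11,647\t11,705\t-\t-\n",
        )
        genome = read_feature_table(p)
        nd1, ser1 = genome.features
        assert nd1.size() == 956
        assert ser1.size() == 59  # comma'd coordinates are accepted
        assert nd1.declared_stop_codon == "TA-"
        assert ser1.declared_start_codon is None

    def test_empty_file_is_an_error_not_an_empty_genome(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(FeatureTableError):
            read_feature_table(p)

    def test_header_only_file_is_an_error(self, tmp_path):
        p = _write_table(tmp_path, "")
        with pytest.raises(FeatureTableError):
            read_feature_table(p)

    def test_malformed_coordinate_names_the_row(self, tmp_path):
        p = _write_table(tmp_path, "ND1\tPCG\tH\tabc\t3707\t-\t-\n")
        with pytest.raises(FeatureTableError, match="ND1"):
            read_feature_table(p)

    def test_end_before_start_on_linear_genome_is_coordinate_error(self, tmp_path):
        p = _write_table(tmp_path, "D-loop\tcontrol_region\tH\t15459\t100\t-\t-\n")
        with pytest.raises((CoordinateError, FeatureTableError)):
            read_feature_table(p)

    def test_wrap_around_allowed_when_circular(self, tmp_path):
        p = _write_table(
            tmp_path,
            "D-loop\tcontrol_region\tH\t15459\t100\t-\t-\n",
            meta="#circular=true\n#length=16000\n",
        )
        genome = read_feature_table(p)
        assert genome.features[0].wraps_origin
        assert genome.features[0].size(16000) == (16000 - 15459 + 1) + 100

    def test_round_trip_write_read(self, tmp_path, table2_genome):
        out = tmp_path / "rt.tsv"
        write_feature_table(table2_genome, out)
        again = read_feature_table(out)
        assert [f.name for f in again.features] == [
            f.name for f in table2_genome.features
        ]
        assert again.total_composition == table2_genome.total_composition
        assert again.length == table2_genome.length


class TestBundledTable:
    def test_gene_inventory(self, table2_genome):
        g = table2_genome
        by_class = {
            c: len(g.features_by_class(c))
            for c in ("PCG", "tRNA", "rRNA", "control_region")
        }
        assert by_class == {"PCG": 13, "tRNA": 22, "rRNA": 2, "control_region": 1}
        n_genes = sum(v for c, v in by_class.items() if c != "control_region")
        assert n_genes == 37

    def test_total_span(self, table2_genome):
        assert max(f.end for f in table2_genome.features) == 16771
        assert table2_genome.length == 16771

    def test_overlapping_features_preserved(self, table2_genome):
        atp8 = table2_genome.feature("ATP8")
        atp6 = table2_genome.feature("ATP6")
        assert atp8.start == 7799 and atp8.end == 8002
        assert atp6.start == 7960 and atp6.end == 8640
        assert atp8.end >= atp6.start  # overlap is legal and kept

    def test_feature_order_reconstructible_by_start(self, table2_genome):
        feats = table2_genome.features
        # the published order is start-sorted up to the known overlaps
        starts = [f.start for f in feats]
        assert starts == sorted(starts)


GENBANK_TWO_GENES = textwrap.dedent("""\
    LOCUS       SYNTH001                  60 bp    DNA     circular MAM 01-JAN-2024
    DEFINITION  synthetic two-gene test record.
    ACCESSION   SYNTH001
    FEATURES             Location/Qualifiers
         source          1..60
         CDS             5..16
                         /gene="ND1"
         CDS             complement(21..32)
                         /gene="nad2"
    ORIGIN
            1 aaaaatgaaa tttaaacccc ccggttccaa ttttggggaa aacccggaat tccggaaccg
    //
    """)


class TestReadGenBank:
    def test_two_gene_record_with_complement(self, tmp_path):
        p = tmp_path / "two.gb"
        p.write_text(GENBANK_TWO_GENES)
        genome = read_genbank(p)
        assert len(genome.features) == 2
        assert genome.is_circular
        nd1, nd2 = genome.features
        assert nd1.name == "ND1" and nd1.strand == "H"
        assert nd2.name == "ND2" and nd2.strand == "L"
        assert extract_gene(genome, nd2) == reverse_complement(
            genome.sequence[20:32]
        )

    def test_origin_wrapping_join_equals_manual_splice(self, tmp_path):
        seq = "atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc atgcatgcaa ccggttaacc"
        gb = textwrap.dedent(f"""\
            LOCUS       SYNTH002                  60 bp    DNA     circular MAM 01-JAN-2024
            DEFINITION  synthetic wrap test record.
            ACCESSION   SYNTH002
            FEATURES             Location/Qualifiers
                 source          1..60
                 CDS             join(55..60,1..6)
                                 /gene="Cytb"
            ORIGIN
                    1 {seq}
            //
            """)
        p = tmp_path / "wrap.gb"
        p.write_text(gb)
        genome = read_genbank(p)
        (cytb,) = genome.features
        assert cytb.wraps_origin
        manual = genome.sequence[54:] + genome.sequence[:6]
        assert extract_gene(genome, cytb) == manual
        assert cytb.size(60) == 12

    def test_record_without_origin_is_an_error(self, tmp_path):
        gb = textwrap.dedent("""\
            LOCUS       SYNTH003                  60 bp    DNA     linear   MAM 01-JAN-2024
            DEFINITION  no sequence.
            ACCESSION   SYNTH003
            FEATURES             Location/Qualifiers
                 source          1..60
                 CDS             5..16
                                 /gene="ND1"
            //
            """)
        p = tmp_path / "noseq.gb"
        p.write_text(gb)
        with pytest.raises(ValueError):
            read_genbank(p)


class TestExtractGene:
    GENOME = MitoGenome(identifier="toy", sequence="AACGTT", is_circular=False)

    def _feat(self, strand):
        return GeneFeature(
            name="ND1", feature_class="PCG", strand=strand, start=1, end=4
        )

    def test_h_strand_is_plain_substring(self):
        assert extract_gene(self.GENOME, self._feat("H")) == "AACG"

    def test_l_strand_is_reverse_complement(self):
        assert extract_gene(self.GENOME, self._feat("L")) == "CGTT"

    def test_revcomp_is_an_involution(self):
        h = extract_gene(self.GENOME, self._feat("H"))
        l = extract_gene(self.GENOME, self._feat("L"))
        assert reverse_complement(l) == h

    def test_out_of_range_coordinates_raise(self):
        feat = GeneFeature(
            name="ND1", feature_class="PCG", strand="H", start=2, end=10
        )
        with pytest.raises(CoordinateError):
            extract_gene(self.GENOME, feat)

    def test_extraction_length_equals_declared_size(self, synthetic_genome):
        for f in synthetic_genome.features:
            assert len(extract_gene(synthetic_genome, f)) == f.size(
                synthetic_genome.length
            )


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("nad4L", "ND4L"),
        ("COIII", "COX3"),
        ("cob", "Cytb"),
        ("tRNA-Leu(UUR)", "tRNA-Leu2"),
        ("tRNA-Ser(AGY)", "tRNA-Ser1"),
        ("trnF", "tRNA-Phe"),
        ("12S ribosomal RNA", "12S-rRNA"),
        ("D-loop", "D-loop"),
        ("mystery_gene", "mystery_gene"),
    ],
)
def test_gene_name_normalization(raw, expected):
    assert normalize_gene_name(raw) == expected
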