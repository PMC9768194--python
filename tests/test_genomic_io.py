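"""Readers, coordinate conventions and allele normalization."""

import pytest
from hypothesis import given, settings, strategies as st

from mirvar.genomic_io import (
    GenomicVariant, Mature, MirnaLocus, SequenceStore, FrequencyTable,
    normalize_alleles, read_mirna_annotation, read_vcf, reverse_complement,
)

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr20,length=63000000>
##contig=<ID=chrX,length=156000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
"""


def _write_vcf(tmp_path, body, header=VCF_HEADER):
    p = tmp_path / "t.vcf"
    p.write_text(header + body)
    return p


class TestReverseComplement:
    @pytest.mark.parametrize("seq,rna,expected", [
        ("ATC", None, "GAT"),
        ("CAGCAGG", None, "CCTGCTG"),
        ("CAGCAGG", True, "CCUGCUG"),
        ("ACGU", None, "ACGU"),
    ])
    def test_known_values(self, seq, rna, expected):
        assert reverse_complement(seq, rna=rna) == expected

    @settings(derandomize=True, max_examples=100)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=60))
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_unknown_character_rejected(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGX")


class TestVariants:
    def test_vclass_derivation(self):
        assert GenomicVariant("1", 10, "G", "A").vclass == "snv"
        assert GenomicVariant("1", 10, "T", "TATC").vclass == "ins"
        assert GenomicVariant("1", 10, "TAC", "T").vclass == "del"

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GenomicVariant("1", 10, "G", "G")
        with pytest.raises(ValueError):
            GenomicVariant("1", 0, "G", "A")

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(1, 1000), st.text("ACGT", min_size=1, max_size=6),
           st.text("ACGT", min_size=1, max_size=6))
    def test_normalization_preserves_edit(self, pos, ref, alt):
        """Re-expanding normalized alleles in context gives the same edited
        sequence as the original representation."""
        if ref == alt:
            return
        npos, nref, nalt = normalize_alleles(pos, ref, alt)
        # embed in a fixed context and compare edits
        lead = "ACGTACGTAC" * 120
        s = lead[:pos - 1] + ref + lead[pos - 1 + len(ref):]
        edit_orig = lead[:pos - 1] + alt + lead[pos - 1 + len(ref):]
        edit_norm = s[:npos - 1] + nalt + s[npos - 1 + len(nref):]
        assert edit_orig == edit_norm
        assert nref and nalt

    def test_read_vcf_snv_and_genotypes(self, tmp_path):
        p = _write_vcf(tmp_path,
                       "chr20\t62550965\t.\tG\tA\t.\tPASS\t.\tGT\t0/1\t0/0\n")
        (v,) = read_vcf(p)
        assert v.key == "chr20:62550965:G>A"
        assert v.vclass == "snv"
        assert v.genotypes == {"S1": "het", "S2": "absent"}

    def test_read_vcf_multiallelic_split(self, tmp_path):
        p = _write_vcf(tmp_path,
                       "chr20\t100\t.\tG\tA,T\t.\tPASS\t.\tGT\t1/2\t0/1\n")
        vs = read_vcf(p)
        assert len(vs) == 2
        assert {(v.pos, v.ref, v.alt) for v in vs} == {(100, "G", "A"),
                                                       (100, "G", "T")}
        a = next(v for v in vs if v.alt == "A")
        t = next(v for v in vs if v.alt == "T")
        assert a.genotypes == {"S1": "het", "S2": "het"}
        assert t.genotypes == {"S1": "het", "S2": "absent"}

    def test_read_vcf_insertion(self, tmp_path):
        p = _write_vcf(tmp_path,
                       "chrX\t146342084\t.\tT\tTATC\t.\tPASS\t.\tGT\t1/1\t0/0\n")
        (v,) = read_vcf(p)
        assert v.vclass == "ins"
        assert v.genotypes["S1"] == "hom"

    def test_read_vcf_missing_gt_retained(self, tmp_path, caplog):
        header = VCF_HEADER.replace(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        p = _write_vcf(tmp_path,
                       "chr20\t100\t.\tG\tA\t.\tPASS\t.\tDP\t10\t12\n",
                       header=header)
        import logging
        with caplog.at_level(logging.WARNING):
            (v,) = read_vcf(p)
        assert all(z == "absent" for z in v.genotypes.values())


GFF = """##gff-version 3
chr1\tsrc\tmiRNA_primary_transcript\t1000\t1080\t.\t+\t.\tID=H1;Name=mir-a;confidence=high
chr1\tsrc\tmiRNA\t1002\t1023\t.\t+\t.\tID=H1m1;Name=mir-a-5p;Derives_from=H1
chr1\tsrc\tmiRNA\t1058\t1079\t.\t+\t.\tID=H1m2;Name=mir-a-3p;Derives_from=H1
chr1\tsrc\tmiRNA_primary_transcript\t2000\t2080\t.\t-\t.\tID=H2;Name=mir-b;confidence=high
chr1\tsrc\tmiRNA\t2056\t2077\t.\t-\t.\tID=H2m1;Name=mir-b-5p;Derives_from=H2
chr1\tsrc\tmiRNA_primary_transcript\t3000\t3080\t.\t+\t.\tID=H3;Name=mir-c
chr1\tsrc\tmiRNA\t3002\t3023\t.\t+\t.\tID=H3m1;Name=mir-c-5p;Derives_from=H3
chr1\tsrc\tmiRNA\t4000\t4021\t.\t+\t.\tID=orphan;Name=mir-x-5p;Derives_from=NOPE
"""


class TestMirnaAnnotation:
    def test_parse_and_confidence(self, tmp_path):
        p = tmp_path / "m.gff3"
        p.write_text(GFF)
        loci = read_mirna_annotation(p)
        assert len(loci) == 3
        byname = {l.name: l for l in loci}
        assert byname["mir-a"].high_confidence
        assert byname["mir-b"].high_confidence
        assert not byname["mir-c"].high_confidence
        assert len(byname["mir-a"].matures) == 2
        assert {m.arm for m in byname["mir-a"].matures} == {"5p", "3p"}

    def test_minus_strand_sense_mapping(self, tmp_path):
        """Mature genomic interval maps to sense position hairpin_end-x+1;
        cross-checked by locating the mature in the reverse-complemented
        hairpin string."""
        p = tmp_path / "m.gff3"
        p.write_text(GFF)
        loci = {l.name: l for l in read_mirna_annotation(p)}
        locus = loci["mir-b"]
        m = locus.matures[0]
        import numpy as np
        rng = np.random.default_rng(5)
        plus = "".join(rng.choice(list("ACGT"), 81))
        store = SequenceStore({"chr1": (2000, plus)})
        sense_hairpin = store.fetch("chr1", 2000, 2080, "-")
        mature_seq = store.fetch("chr1", m.start, m.end, "-")
        s0, s1 = locus.mature_sense_interval(m)
        assert locus.genomic_to_sense(m.end) == locus.hairpin[1] - m.end + 1
        assert sense_hairpin[s0 - 1:s1] == mature_seq

    def test_mature_invariants(self):
        with pytest.raises(ValueError):
            MirnaLocus("x", "1", "+", (100, 160),
                       (Mature("5p", 90, 120),))  # outside hairpin
        with pytest.raises(ValueError):
            MirnaLocus("x", "1", "+", (100, 160),
                       (Mature("5p", 101, 122), Mature("3p", 120, 141)))


class TestSequenceStore:
    def test_strand_fetch_is_revcomp(self):
        store = SequenceStore({"c": "ACGTTGCA"})
        for s, e in [(1, 8), (2, 5), (4, 4)]:
            assert store.fetch("c", s, e, "-") == \
                reverse_complement(store.fetch("c", s, e, "+"))

    def test_offset_coordinates(self):
        store = SequenceStore({"c": (1001, "ACGT")})
        assert store.fetch("c", 1001, 1004) == "ACGT"
        with pytest.raises(ValueError):
            store.fetch("c", 1000, 1002)


class TestFrequencyTable:
    def test_lookup_and_sources(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("chrom\tpos\tref\talt\tkg\tgnomad\n"
                     "1\t100\tG\tA\t0.005\t\n"
                     "1\t200\tC\tT\t0.02\t0.001\n")
        ft = FrequencyTable.from_tsv(p)
        assert ft.sources == ["kg", "gnomad"]
        assert ft.lookup("1:100:G>A") == {"kg": 0.005}
        assert ft.lookup("1:999:G>A") == {}

    def test_maf_range_enforced(self):
        with pytest.raises(ValueError):
            FrequencyTable({"1:1:A>C": {"kg": 1.5}}, ["kg", "g"])
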