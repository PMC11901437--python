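"""Variant model: parsing, normalization, summaries, length histogram."""

import subprocess

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from indelmark import (
    InDelVariant,
    IndelType,
    TypeSummary,
    VariantTable,
    Zygosity,
    left_normalize,
    length_histogram,
    parse_vcf,
    summarize_types,
    write_vcf,
)
from indelmark.variants import VcfParseError, ReferenceMismatchError, normalize_table

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=chr1,length=1000>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
)


def _write(tmp_path, body, header=VCF_HEADER):
    path = tmp_path / "in.vcf"
    path.write_text(header + body)
    return str(path)


class TestParseVcf:
    def test_insertion_genotypes_and_snp_exclusion(self, tmp_path):
        path = _write(
            tmp_path,
            "chr1\t10\t.\tA\tATTG\t.\tPASS\t.\tGT\t0/1\n"  # 3 bp het insertion
            "chr1\t20\t.\tG\tT\t.\tPASS\t.\tGT\t0/1\n"  # SNP: excluded
            "chr1\t30\t.\tGAA\tG\t.\tPASS\t.\tGT\t1/1\n"  # hom deletion
            "chr1\t40\t.\tC\tCT\t.\tPASS\t.\tGT\t0/0\n"  # not carried: dropped
            "chr1\t50\t.\tT\tTAC\t.\tPASS\t.\tGT\t./.\n",  # missing genotype kept
        )
        table = parse_vcf(path, "S1", "maternal")
        assert len(table) == 3
        ins = table.get(("chr1", 10, "A", "ATTG"))
        assert ins.indel_type is IndelType.INSERTION
        assert ins.indel_length == 3
        assert ins.zygosity is Zygosity.HETEROZYGOUS
        assert table.get(("chr1", 30, "GAA", "G")).zygosity is Zygosity.HOMOZYGOUS
        assert table.get(("chr1", 50, "T", "TAC")).zygosity is Zygosity.MISSING
        assert table.informative_keys() == {("chr1", 10, "A", "ATTG"), ("chr1", 30, "GAA", "G")}

    def test_multiallelic_decomposition(self, tmp_path):
        path = _write(tmp_path, "chr1\t10\t.\tA\tAT,ATT\t.\tPASS\t.\tGT\t1/2\n")
        table = parse_vcf(path, "S1", "maternal")
        assert table.keys() == {("chr1", 10, "A", "AT"), ("chr1", 10, "A", "ATT")}
        assert all(v.zygosity is Zygosity.HETEROZYGOUS for v in table)

    def test_unknown_sample_names_available(self, tmp_path):
        path = _write(tmp_path, "")
        with pytest.raises(VcfParseError, match="S1"):
            parse_vcf(path, "NOPE", "maternal")

    def test_population_vcf_reproduces_simulated_tables(self, study, sim_dir):
        """Parsing each sample of the emitted multi-sample VCF recovers exactly
        the generated per-sample call sets (the simulator's emission log)."""
        for mem in study.progeny.tables[:6]:
            parsed = parse_vcf(str(sim_dir / "progeny.vcf"), mem.sample_id, "maternal")
            assert len(parsed) == len(mem)
            assert parsed.keys() == mem.keys()
            assert parsed.informative_keys() == mem.informative_keys()

    def test_roundtrip_preserves_key_fields(self, study, tmp_path):
        table = study.parents.maternal_table
        out = tmp_path / "roundtrip.vcf"
        write_vcf(table, str(out), study.parents.contig_lengths())
        back = parse_vcf(str(out), table.sample_id, "maternal")
        assert back.keys() == table.keys()
        assert {k: v.zygosity for k, v in zip(sorted(back.keys()), back.sorted_variants())} == {
            k: v.zygosity for k, v in zip(sorted(table.keys()), table.sorted_variants())
        }


class TestLeftNormalize:
    REF = {"chr1": "GGTTTTACGTACGT"}

    def test_homopolymer_deletion_shifts_to_first_repeat(self):
        # deletion of one T inside TTTT reported at the 3rd T
        v = InDelVariant("maternal", "chr1", 4, "TT", "T")
        n = left_normalize(v, self.REF)
        assert (n.position, n.ref_allele, n.alt_allele) == (2, "GT", "G")
        assert n.indel_type is v.indel_type and n.indel_length == v.indel_length

    def test_already_left_aligned_unchanged(self):
        v = InDelVariant("maternal", "chr1", 7, "AC", "A")
        assert left_normalize(v, self.REF) == v

    def test_reference_mismatch_raises(self):
        v = InDelVariant("maternal", "chr1", 7, "TT", "T")
        with pytest.raises(ReferenceMismatchError):
            left_normalize(v, self.REF)

    def test_idempotent_on_simulated_indels(self, study):
        ref = study.parents.reference
        for v in list(study.parents.maternal_table)[:300]:
            once = left_normalize(v, ref)
            assert left_normalize(once, ref) == once

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        context=st.text(alphabet="ACGT", min_size=12, max_size=24),
        run_base=st.sampled_from("ACGT"),
        run_len=st.integers(2, 6),
        del_len=st.integers(1, 3),
        offset=st.integers(0, 5),
    )
    def test_normalization_idempotent_and_length_preserving(
        self, context, run_base, run_len, del_len, offset
    ):
        seq = context + run_base * run_len + context[::-1]
        pos = len(context) + min(offset, run_len - 1)  # anchor inside/near the run
        if pos + del_len >= len(seq):
            return
        ref_allele = seq[pos - 1 : pos + del_len]
        v = InDelVariant("maternal", "chr1", pos, ref_allele, ref_allele[0])
        n = left_normalize(v, {"chr1": seq})
        assert left_normalize(n, {"chr1": seq}) == n
        assert n.indel_length == v.indel_length
        assert n.indel_type is v.indel_type
        assert n.position <= v.position

    def test_agrees_with_bcftools_norm(self, tmp_path):
        """Independent oracle: bcftools norm left-aligns to the same records."""
        seq = "ACGTACGTTTTTTACGGGGGACTTACGTACGAC" * 4
        ref = {"chr1": seq}

        def deletion(pos, length):
            return InDelVariant("maternal", "chr1", pos, seq[pos - 1 : pos + length], seq[pos - 1])

        def insertion(pos, ins):
            return InDelVariant("maternal", "chr1", pos, seq[pos - 1], seq[pos - 1] + ins)

        variants = [
            deletion(11, 1),  # inside the T-run: must shift left
            insertion(17, "GG"),  # inside the G-run
            deletion(25, 3),
            insertion(40, "ACGT"),
        ]
        table = VariantTable("S1", "maternal", variants)
        fasta = tmp_path / "ref.fa"
        fasta.write_text(">chr1\n" + seq + "\n")
        vcf = tmp_path / "in.vcf"
        write_vcf(table, str(vcf), {"chr1": len(seq)})
        out = subprocess.run(
            ["bcftools", "norm", "-f", str(fasta), str(vcf)],
            capture_output=True,
            text=True,
            check=True,
        )
        bcf_keys = {
            (f[0], int(f[1]), f[3], f[4])
            for f in (line.split("\t") for line in out.stdout.splitlines() if not line.startswith("#"))
        }
        ours = {left_normalize(v, ref).key for v in variants}
        assert ours == bcf_keys


class TestSummaries:
    def test_published_partitions_conserve_totals(self):
        """The printed apple- and pear-frame partitions each sum to the
        printed totals, for both the type and the zygosity split."""
        apple = TypeSummary.from_parts(590_793, 875_194, 960_221, 505_766)
        assert apple.n_total == 1_465_987
        pear = TypeSummary.from_parts(638_362, 1_028_379, 1_141_718, 525_023)
        assert pear.n_total == 1_666_741

    def test_inconsistent_partition_rejected(self):
        with pytest.raises(ValueError):
            TypeSummary(n_total=10, n_insertion=4, n_deletion=5, n_heterozygous=5, n_homozygous=5)

    def test_empty_table_all_zero(self):
        s = summarize_types(VariantTable("S1", "maternal"))
        assert (s.n_total, s.n_insertion, s.n_deletion) == (0, 0, 0)

    def test_simulated_composition_recovered_exactly(self, study):
        table = study.parents.maternal_table
        s = summarize_types(table)
        assert s.n_total == len(table)
        truth_ins = sum(
            1 for v in table if len(v.alt_allele) > len(v.ref_allele)
        )
        assert s.n_insertion == truth_ins
        assert s.n_insertion + s.n_deletion == s.n_total
        assert s.n_heterozygous + s.n_homozygous + s.n_missing == s.n_total

    def test_normalize_table_preserves_count(self, study):
        table = study.parents.paternal_table
        normed = normalize_table(table, study.parents.reference)
        assert len(normed) == len(table)  # planted variants already normalized


class TestLengthHistogram:
    def test_boundary_is_strict_at_50(self):
        t = VariantTable(
            "S1",
            "maternal",
            [
                InDelVariant("maternal", "chr1", 10, "A", "A" + "C" * 51),
                InDelVariant("maternal", "chr1", 20, "A", "A" + "C" * 50),
            ],
        )
        hist = length_histogram(t, breaks=(50,))
        assert hist.counts == (1, 1)
        assert hist.count_greater_than(50) == 1

    def test_counts_sum_to_total_and_match_generator(self, study):
        table = study.parents.maternal_table
        hist = length_histogram(table)
        assert hist.n_total == len(table)
        truth_long = sum(1 for v in table if v.indel_length > 50)
        assert hist.count_greater_than(50) == truth_long

    def test_breaks_must_ascend(self):
        with pytest.raises(ValueError):
            length_histogram(VariantTable("S1", "maternal"), breaks=(10, 5))
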