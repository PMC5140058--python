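import itertools

import pytest

from ibcpipe.contexts import BASES, bin_index
from ibcpipe.errors import DomainError
from ibcpipe.variant_consensus import (
    CallSet,
    SomaticVariant,
    annotate_context,
    consensus_indels,
    consensus_snvs,
    left_normalize,
    mutation_burden,
    read_caller_vcf,
    read_variant_table,
    write_variant_table,
)

VCF_TEMPLATE = """##fileformat=VCFv4.2
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##contig=<ID=chr1,length=1000000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR
{records}"""


def write_vcf(path, records):
    body = "".join(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t.\tAD:DP\t{ref_d},{alt_d}:{ref_d + alt_d}\n"
                   for chrom, pos, ref, alt, filt, ref_d, alt_d in records)
    path.write_text(VCF_TEMPLATE.format(records=body))
    return path


def variant(chrom="chr1", pos=100, ref="C", alt="T", alt_depth=10, depth=100,
            callers=("mutect",)):
    from ibcpipe.variant_consensus import classify_alleles
    return SomaticVariant(chrom, pos, ref, alt, alt_depth, depth,
                          frozenset(callers), classify_alleles(ref, alt))


class TestReadCallerVcf:
    def test_pass_snv_vaf(self, tmp_path):
        path = write_vcf(tmp_path / "a.vcf", [("chr1", 100, "A", "G", "PASS", 90, 10)])
        cs = read_caller_vcf(path, "mutect")
        assert len(cs.variants) == 1
        assert cs.variants[0].vaf == pytest.approx(0.10)

    def test_non_pass_dropped(self, tmp_path):
        path = write_vcf(tmp_path / "b.vcf", [("chr1", 100, "A", "G", "LowQual", 90, 10)])
        assert read_caller_vcf(path, "mutect").variants == []

    def test_fixture_counts_match_manifest(self, fixture_dir):
        d, manifest = fixture_dir
        entry = manifest["samples"][0]
        for caller, rel in entry["vcfs"].items():
            cs = read_caller_vcf(d / rel, caller, sample=entry["sample"])
            assert len(cs.variants) == entry["caller_counts"][caller]


class TestConsensusSnvs:
    def cs(self, caller, variants):
        return CallSet(caller, "S1", [v for v in variants])

    def test_two_caller_snv_retained(self):
        v = variant(alt_depth=12, depth=100)
        out = consensus_snvs([self.cs("mutect", [v]), self.cs("strelka", [v])])
        assert len(out) == 1
        assert out[0].callers == {"mutect", "strelka"}

    def test_single_caller_dropped(self):
        v = variant(alt_depth=40, depth=100)
        out = consensus_snvs([self.cs("mutect", [v]), self.cs("strelka", [])])
        assert out == []

    def test_low_vaf_dropped_even_with_three_callers(self):
        v = variant(alt_depth=4, depth=100)
        out = consensus_snvs([self.cs(c, [v]) for c in ("mutect", "strelka", "varscan")])
        assert out == []

    def test_vaf_boundary_inclusive(self):
        v = variant(alt_depth=5, depth=100)  # exactly 5%
        out = consensus_snvs([self.cs("mutect", [v]), self.cs("strelka", [v])])
        assert len(out) == 1

    def test_sample_mismatch_rejected(self):
        a = CallSet("mutect", "S1", [variant()])
        b = CallSet("strelka", "S2", [variant()])
        with pytest.raises(DomainError):
            consensus_snvs([a, b])

    def test_order_invariance_idempotence_and_monotonicity(self, fixture_dir):
        d, manifest = fixture_dir
        entry = manifest["samples"][0]
        callsets = [read_caller_vcf(d / rel, c, sample=entry["sample"])
                    for c, rel in entry["vcfs"].items() if c != "pindel"]
        out = consensus_snvs(callsets)
        keys = {v.key for v in out}
        union = {v.key for cs in callsets for v in cs.variants if v.variant_class == "SNV"}
        assert keys <= union
        # order invariance
        out_rev = consensus_snvs(callsets[::-1])
        assert {v.key for v in out_rev} == keys
        # idempotence: feeding the consensus back per supporting caller
        again = consensus_snvs(
            [CallSet(c, entry["sample"], [v for v in out if c in v.callers])
             for c in ("mutect", "strelka", "varscan")])
        assert {v.key for v in again} == keys
        # monotonicity in both thresholds
        assert len(consensus_snvs(callsets, min_callers=3)) <= len(out)
        assert len(consensus_snvs(callsets, min_vaf=0.2)) <= len(out)

    def test_consensus_matches_truth_oracle(self, small_bundle, fixture_dir):
        """Consensus output equals the set derived from planted caller calls:
        SNVs called by >=2 pseudo-callers whose consensus-priority VAF >= 5%."""
        d, manifest = fixture_dir
        snv_callers = ("mutect", "strelka", "varscan")
        for sample_truth in small_bundle.samples:
            entry = next(e for e in manifest["samples"]
                         if e["sample"] == sample_truth.sample)
            callsets = [read_caller_vcf(d / entry["vcfs"][c], c,
                                        sample=sample_truth.sample)
                        for c in snv_callers]
            observed = {v.key for v in consensus_snvs(callsets)}
            snv_keys = {m.key for p in small_bundle.patients
                        for m in p.mutations if m.variant_class == "SNV"}
            expected = set()
            fp_support = {}
            for c in snv_callers:
                for fp in sample_truth.false_positives[c]:
                    fp_support.setdefault(
                        (fp.chromosome, fp.position, fp.ref, fp.alt), []).append(
                            (c, fp.alt_depth, fp.depth))
            for key in snv_keys:
                support = [c for c in snv_callers if key in sample_truth.calls[c]]
                if len(support) < 2:
                    continue
                alt, dep = sample_truth.reads[key]
                if alt / dep >= 0.05:
                    expected.add(key)
            for key, sup in fp_support.items():
                if len(sup) >= 2 and sup[0][1] / sup[0][2] >= 0.05:
                    expected.add(key)
            assert observed == expected


class TestIndels:
    def test_intersection_retained(self):
        v = variant(ref="AT", alt="A", alt_depth=20, depth=100)
        out = consensus_indels(CallSet("varscan", "S1", [v]),
                               CallSet("pindel", "S1", [v]))
        assert len(out) == 1
        assert out[0].callers == {"varscan", "pindel"}

    def test_single_caller_dropped(self):
        v = variant(ref="A", alt="AT", alt_depth=50, depth=100)
        out = consensus_indels(CallSet("varscan", "S1", [v]),
                               CallSet("pindel", "S1", []))
        assert out == []

    def test_snv_in_input_rejected(self):
        with pytest.raises(DomainError):
            consensus_indels(CallSet("varscan", "S1", [variant()]),
                             CallSet("pindel", "S1", []))

    def test_left_normalization_matches_alignments(self, tmp_path):
        """The same deletion written at two positions inside the repeat
        AAAT...AAAT matches after left-normalization against the reference."""
        from pyfaidx import Fasta
        fa = tmp_path / "toy.fa"
        fa.write_text(">chr1\nGGAAAATTTT\n")
        ref = Fasta(str(fa))
        # delete one A from the A-run: left-aligned at pos 2 (GA->G... using
        # anchor G at pos 2), right-shifted representation at pos 5 (AA->A)
        left = left_normalize("chr1", 2, "GA", "G", ref)
        right = left_normalize("chr1", 5, "AA", "A", ref)
        assert left == right

    def test_trim_only_normalization(self):
        assert left_normalize("chr1", 10, "CAG", "CG") == ("chr1", 10, "CA", "C")


class TestAnnotateContext:
    def make_fasta(self, tmp_path, seq):
        fa = tmp_path / "ref.fa"
        fa.write_text(f">chr1\n{seq}\n")
        return fa

    def test_pyrimidine_context(self, tmp_path):
        fa = self.make_fasta(tmp_path, "AACGTT")
        out = annotate_context([variant(pos=3, ref="C", alt="T")], fa)
        assert out[0].substitution == "C>T"
        assert out[0].context == "ACG"

    def test_purine_normalized(self, tmp_path):
        # G>A at CGT reverse-complements to C>T in context ACG
        fa = self.make_fasta(tmp_path, "ACGTTT")
        out = annotate_context([variant(pos=3, ref="G", alt="A")], fa)
        assert out[0].substitution == "C>T"
        assert out[0].context == "ACG"

    def test_contig_edge_leaves_context_absent(self, tmp_path):
        fa = self.make_fasta(tmp_path, "CGTTTT")
        out = annotate_context([variant(pos=1, ref="C", alt="A")], fa)
        assert out[0].context is None

    def test_96_way_exhaustive_enumeration(self, tmp_path):
        """A FASTA concatenating all 32 pyrimidine-centred trinucleotides,
        mutated to each of 3 alternates, covers each of the 96 bins once."""
        trinucs = [f"{f}{c}{t}" for c in "CT"
                   for f in BASES for t in BASES]
        fa = self.make_fasta(tmp_path, "".join(trinucs))
        variants = []
        for i, tri in enumerate(trinucs):
            center = tri[1]
            for alt in BASES:
                if alt != center:
                    variants.append(variant(pos=3 * i + 2, ref=center, alt=alt))
        out = annotate_context(variants, fa)
        bins = [bin_index(v.substitution, v.context) for v in out]
        assert sorted(bins) == list(range(96))


class TestBurdenAndTable:
    def test_empty(self):
        assert mutation_burden([]) == 0

    def test_mask_restricts(self):
        variants = [variant(pos=p) for p in range(1, 11)]
        mask = [("chr1", 1, 5)]  # half-open: positions 1-4
        assert mutation_burden(variants, mask) == 4
        assert mutation_burden(variants) == 10

    def test_variant_table_roundtrip(self, tmp_path):
        vs = [variant(pos=5, ref="C", alt="T"), variant(pos=9, ref="AT", alt="A")]
        path = tmp_path / "v.tsv"
        write_variant_table(vs, path, "S1")
        sample, back = read_variant_table(path)
        assert sample == "S1"
        assert [v.key for v in back] == [v.key for v in vs]
        assert back[1].variant_class == "deletion"
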