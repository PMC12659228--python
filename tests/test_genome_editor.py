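import numpy as np
import pytest

from conftest import apply_op
from splice_oracle import Op, SpliceOracle, random_script, replay

from somasim.genome_editor import (
    DELETED,
    EditError,
    HaplotypeGenome,
    PositionMap,
    apply_deletion,
    apply_insertion,
    apply_variant,
    edit_sample,
    init_map,
    resolve_ins_seq,
)
from somasim.var_model import (
    GenomeIndex,
    InsertionSpec,
    VariantSpec,
    parse_var,
    write_var,
)


def toy(seq="ACGTACGTAC"):
    return HaplotypeGenome.from_sequences({"chr1": seq})


class TestPositionMap:
    def test_init_is_identity(self):
        index = GenomeIndex(names=("c",), lengths={"c": 10})
        pmap = init_map(index)
        assert np.array_equal(pmap["c"], np.arange(10))
        assert pmap.n_surviving("c") == 10
        assert init_map(index) == pmap  # idempotent

    def test_deletion_shifts_downstream(self):
        """Deleting 3 bases at the start maps old position 5 to 2."""
        g = toy()
        apply_deletion(g, "chr1", 0, 3)
        assert g.pmap["chr1"][5] == 2
        assert list(g.pmap["chr1"][:3]) == [DELETED] * 3
        assert g.sequence("chr1") == "TACGTAC"

    def test_insertion_shifts_downstream(self):
        """Inserting 2 bases at the start maps old position 3 to 5."""
        g = toy()
        apply_insertion(g, "chr1", 0, "CA")
        assert g.pmap["chr1"][3] == 5
        assert g.sequence("chr1") == "CA" + "ACGTACGTAC"

    def test_full_chromosome_deletion(self):
        g = toy()
        apply_deletion(g, "chr1", 0, 10)
        assert g.sequence("chr1") == ""
        assert all(x == DELETED for x in g.pmap["chr1"])

    def test_insertion_then_same_span_deletion_restores_length(self):
        g = toy()
        apply_insertion(g, "chr1", 4, "GG")
        apply_deletion(g, "chr1", 4, 2)
        assert len(g.sequence("chr1")) == 10

    def test_overlapping_deletion_is_an_error(self):
        g = toy()
        apply_deletion(g, "chr1", 2, 3)
        with pytest.raises(EditError, match="already-deleted"):
            apply_deletion(g, "chr1", 3, 2)

    def test_deletion_past_end_is_an_error(self):
        with pytest.raises(EditError, match="past chromosome"):
            apply_deletion(toy(), "chr1", 8, 5)

    def test_insertion_on_deleted_position_is_an_error(self):
        g = toy()
        apply_deletion(g, "chr1", 2, 3)
        with pytest.raises(EditError, match="deleted"):
            apply_insertion(g, "chr1", 3, "A")

    def test_serialization_round_trip(self, tmp_path):
        g = toy()
        apply_deletion(g, "chr1", 1, 2)
        apply_insertion(g, "chr1", 5, "TTT")
        path = tmp_path / "map.txt"
        g.pmap.save(path)
        assert PositionMap.load(path) == g.pmap


class TestResolveInsSeq:
    def test_manual_literal(self):
        assert resolve_ins_seq(InsertionSpec(mode="manual", literal="ACTG"), toy()) == "ACTG"

    def test_self_extract_plain_window(self):
        g = HaplotypeGenome.from_sequences({"chr1": "TTACTGG"})
        spec = InsertionSpec(
            mode="self_extract", source_chrom="chr1", start=2, end=5,
            copies=1, orientation="forward",
        )
        assert resolve_ins_seq(spec, g) == "ACT"

    def test_self_extract_carries_earlier_snp(self):
        """A SNP inside the window is picked up by the extraction."""
        g = HaplotypeGenome.from_sequences({"chr1": "TTACTGG"})
        apply_variant(
            g,
            VariantSpec("s", "s", 0, "chr1", 3, True, 1, True,
                        InsertionSpec(mode="manual", literal="G")),
        )
        spec = InsertionSpec(
            mode="self_extract", source_chrom="chr1", start=2, end=5,
            copies=1, orientation="forward",
        )
        assert resolve_ins_seq(spec, g) == "AGT"

    def test_copies_and_reverse(self):
        g = HaplotypeGenome.from_sequences({"chr1": "TTACTGG"})
        spec = InsertionSpec(
            mode="self_extract", source_chrom="chr1", start=2, end=5,
            copies=2, orientation="reverse",
        )
        assert resolve_ins_seq(spec, g) == "AGTAGT"

    def test_random_is_seed_deterministic(self):
        spec = InsertionSpec(mode="random", length=8)
        a = resolve_ins_seq(spec, toy(), rng=np.random.default_rng(5))
        b = resolve_ins_seq(spec, toy(), rng=np.random.default_rng(5))
        assert a == b and len(a) == 8 and set(a) <= set("ACGT")

    def test_external_slice(self):
        spec = InsertionSpec(
            mode="external", external_path="viral.fa", source_chrom="v",
            start=1, end=4, copies=1, orientation="forward",
        )
        out = resolve_ins_seq(spec, toy(), externals={"viral.fa": {"v": "GATTACA"}})
        assert out == "ATT"

    def test_missing_external_is_an_error(self):
        spec = InsertionSpec(
            mode="external", external_path="nope.fa", source_chrom="v",
            start=0, end=2, copies=1, orientation="forward",
        )
        with pytest.raises(EditError, match="not provided"):
            resolve_ins_seq(spec, toy(), externals={})


class TestApplyVariant:
    def test_snp_records_ref_and_alt(self):
        g = HaplotypeGenome.from_sequences({"chr1": "AATAA"})
        rec = apply_variant(
            g,
            VariantSpec("v", "m", 0, "chr1", 2, True, 1, True,
                        InsertionSpec(mode="manual", literal="A")),
        )
        assert (rec.ref, rec.alt) == ("T", "A") and not rec.ref_equal_snp
        assert g.sequence("chr1") == "AAAAA"

    def test_ref_equal_snp_is_flagged(self):
        g = HaplotypeGenome.from_sequences({"chr1": "AACAA"})
        rec = apply_variant(
            g,
            VariantSpec("v", "m", 0, "chr1", 2, True, 1, True,
                        InsertionSpec(mode="manual", literal="C")),
        )
        assert rec.ref_equal_snp and g.sequence("chr1") == "AACAA"

    def test_delins_is_deletion_then_anchored_insertion(self):
        g = HaplotypeGenome.from_sequences({"chr1": "AAACCCGGG"})
        apply_variant(
            g,
            VariantSpec("v", "m", 0, "chr1", 3, True, 3, True,
                        InsertionSpec(mode="manual", literal="GGG")),
        )
        oracle = SpliceOracle("AAACCCGGG")
        oracle.delins(3, 3, "GGG")
        assert g.sequence("chr1") == oracle.sequence()

    def test_delins_at_chromosome_end_appends(self):
        g = HaplotypeGenome.from_sequences({"chr1": "AAACC"})
        apply_variant(
            g,
            VariantSpec("v", "m", 0, "chr1", 3, True, 2, True,
                        InsertionSpec(mode="manual", literal="TT")),
        )
        assert g.sequence("chr1") == "AAATT"


class TestOrderSensitivity:
    """The same two variants in swapped order act on different loci."""

    def test_del_then_ins(self):
        # 10-nt chromosome: DEL span 3 at p=0, then INS "CA" at p=5.
        # After the DEL, p=5 maps to 2, so "CA" lands left of index 2.
        g = toy("AAATTTGGGC")
        apply_deletion(g, "chr1", 0, 3)
        assert g.pmap["chr1"][5] == 2
        apply_insertion(g, "chr1", 5, "CA")
        assert g.sequence("chr1") == "TT" + "CA" + "TGGGC"

    def test_ins_then_del(self):
        # INS "CA" at p=0, then DEL span 3 at p=3: p=3 maps to 5, and the
        # deletion removes 3 bases starting at index 5.
        g = toy("AAATTTGGGC")
        apply_insertion(g, "chr1", 0, "CA")
        assert g.pmap["chr1"][3] == 5
        apply_deletion(g, "chr1", 3, 3)
        assert g.sequence("chr1") == "CAAAAGGGC"

    def test_swapped_scripts_differ(self):
        a = toy("AAATTTGGGC")
        apply_deletion(a, "chr1", 0, 3)
        apply_insertion(a, "chr1", 5, "CA")
        b = toy("AAATTTGGGC")
        apply_insertion(b, "chr1", 0, "CA")
        apply_deletion(b, "chr1", 3, 3)
        assert a.sequence("chr1") != b.sequence("chr1")
        assert not np.array_equal(a.pmap["chr1"], b.pmap["chr1"])


class TestSpliceOracleAgreement:
    @pytest.mark.parametrize("seed", range(12))
    def test_random_scripts_match_oracle(self, seed):
        """Sequence, length bookkeeping and map consistency against the
        independent splice-replay oracle."""
        rng = np.random.default_rng(seed)
        n = 250
        seqs, _ = __import__("somasim.fixtures", fromlist=["make_genome"]).make_genome(
            {"chr1": n}, seed=seed
        )
        g = HaplotypeGenome.from_sequences(seqs)
        oracle = SpliceOracle(seqs["chr1"])
        total_ins = total_del = 0
        for op in random_script(rng, n, n_ops=25):
            rec = apply_op(g, op, rng=rng)
            replay(oracle, op)
            total_ins += len(rec.alt)
            total_del += len(rec.ref)
            assert g.sequence("chr1") == oracle.sequence()
        # length conservation
        assert len(g.sequence("chr1")) == n + total_ins - total_del
        # map/sequence consistency for every surviving template position
        j = g.pmap["chr1"]
        for t in range(n):
            idx = oracle.index_of_tag(t)
            if idx is None:
                assert j[t] == DELETED
            else:
                assert j[t] == idx
        # surviving-entry count matches the deletion budget
        assert g.pmap.n_surviving("chr1") == n - total_del + (
            # delins re-inserts content but never un-deletes map entries
            0
        )


class TestEditSample:
    def _write(self, tmp_path, variants, seq="ACGTACGTAC" * 30):
        from somasim.genome_editor import write_fasta

        fasta = tmp_path / "t.fa"
        write_fasta({"chr1": seq}, fasta)
        var = tmp_path / "s.var"
        write_var(variants, var)
        return var, fasta

    def test_empty_var_reproduces_template(self, tmp_path):
        var, fasta = self._write(tmp_path, [])
        res = edit_sample(var, fasta, tmp_path / "out", flank=10, seed=0)
        for h in (0, 1):
            assert res.haplotypes[h].sequence("chr1") == res.haplotypes[h].template_sequence("chr1")
        vcf_lines = [
            l for l in (tmp_path / "out" / "truth.vcf").read_text().splitlines()
            if not l.startswith("#")
        ]
        assert vcf_lines == []

    def test_homozygous_snp_hits_both_haplotypes(self, tmp_path):
        variants = [
            VariantSpec("v0", "m0", 0, "chr1", 5, True, 1, True,
                        InsertionSpec(mode="manual", literal="T")),
            VariantSpec("v1", "m0", 1, "chr1", 5, True, 1, True,
                        InsertionSpec(mode="manual", literal="T")),
        ]
        var, fasta = self._write(tmp_path, variants)
        res = edit_sample(var, fasta, tmp_path / "out", seed=0)
        assert res.haplotypes[0].sequence("chr1")[5] == "T"
        assert res.haplotypes[1].sequence("chr1")[5] == "T"
        (entry,) = res.truth
        assert entry["zygosity"] == "hom"
        vcf = (tmp_path / "out" / "truth.vcf").read_text()
        assert "1/1" in vcf

    def test_het_variant_leaves_hap1_untouched(self, tmp_path):
        variants = [
            VariantSpec("v0", "m0", 0, "chr1", 5, True, 1, True,
                        InsertionSpec(mode="manual", literal="T")),
        ]
        var, fasta = self._write(tmp_path, variants)
        res = edit_sample(var, fasta, tmp_path / "out", seed=0)
        assert res.haplotypes[1].sequence("chr1") == res.haplotypes[1].template_sequence("chr1")
        assert res.truth[0]["zygosity"] == "het"
        assert "0/1" in (tmp_path / "out" / "truth.vcf").read_text()

    def test_invalid_var_aborts_with_vid(self, tmp_path):
        variants = [
            VariantSpec("vBAD", "m0", 0, "chr1", 10_000, True, 1, True,
                        InsertionSpec(mode="manual", literal="T")),
        ]
        var, fasta = self._write(tmp_path, variants)
        with pytest.raises(EditError, match="vBAD"):
            edit_sample(var, fasta, tmp_path / "out", seed=0)

    def test_bed_regions_are_clipped_and_centered(self, tmp_path):
        variants = [
            VariantSpec("v0", "m0", 0, "chr1", 5, True, 1, True,
                        InsertionSpec(mode="manual", literal="T")),
        ]
        var, fasta = self._write(tmp_path, variants)
        edit_sample(var, fasta, tmp_path / "out", flank=50, seed=0)
        line = (tmp_path / "out" / "regions.bed").read_text().splitlines()[0]
        chrom, start, end, name = line.split("\t")
        assert (chrom, int(start), int(end)) == ("chr1", 0, 55)

    def test_random_var_agrees_with_oracle_and_groups_mids(self, tmp_path):
        """50 designed variants per haplotype: both sequences equal the
        splice-replay oracle; one VCF record per MID."""
        rng = np.random.default_rng(77)
        n = 2000
        from somasim.fixtures import make_genome

        seqs, _ = make_genome({"chr1": n}, seed=78)
        variants = []
        oracles = {0: SpliceOracle(seqs["chr1"]), 1: SpliceOracle(seqs["chr1"])}
        scripts = {0: random_script(rng, n, 50), 1: random_script(rng, n, 50)}
        k = 0
        for hap in (0, 1):
            for op in scripts[hap]:
                if op.kind == "del":
                    v = VariantSpec(f"v{k}", f"m{k}", hap, "chr1", op.t, True, op.span, False)
                elif op.kind == "ins":
                    v = VariantSpec(f"v{k}", f"m{k}", hap, "chr1", op.t, False, 0, True,
                                    InsertionSpec(mode="manual", literal=op.seq))
                elif op.kind == "delins":
                    v = VariantSpec(f"v{k}", f"m{k}", hap, "chr1", op.t, True, op.span, True,
                                    InsertionSpec(mode="manual", literal=op.seq))
                else:
                    v = VariantSpec(f"v{k}", f"m{k}", hap, "chr1", op.t, False, 0, True,
                                    InsertionSpec(mode="self_extract", source_chrom="chr1",
                                                  start=op.start, end=op.end,
                                                  copies=op.copies, orientation=op.orientation))
                variants.append(v)
                k += 1
        var, fasta = self._write(tmp_path, variants, seq=seqs["chr1"])
        res = edit_sample(var, fasta, tmp_path / "out", seed=1)
        for hap in (0, 1):
            for op in scripts[hap]:
                replay(oracles[hap], op)
            assert res.haplotypes[hap].sequence("chr1") == oracles[hap].sequence()
        vcf_records = [
            l for l in (tmp_path / "out" / "truth.vcf").read_text().splitlines()
            if not l.startswith("#")
        ]
        assert len(vcf_records) == len({v.mid for v in variants})

    def test_parallel_samples_are_independent(self, tmp_path):
        """Two VAR files applied to copies of one template do not share state."""
        v_a = [VariantSpec("a", "a", 0, "chr1", 3, True, 2, False)]
        v_b = [VariantSpec("b", "b", 0, "chr1", 7, False, 0, True,
                           InsertionSpec(mode="manual", literal="GG"))]
        var_a, fasta = self._write(tmp_path, v_a)
        var_b = tmp_path / "b.var"
        write_var(v_b, var_b)
        res_a = edit_sample(var_a, fasta, tmp_path / "oa", seed=0)
        res_b = edit_sample(var_b, fasta, tmp_path / "ob", seed=0)
        assert res_a.haplotypes[0].sequence("chr1") != res_b.haplotypes[0].sequence("chr1")
        res_a2 = edit_sample(var_a, fasta, tmp_path / "oa2", seed=0)
        assert res_a.haplotypes[0].sequence("chr1") == res_a2.haplotypes[0].sequence("chr1")
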