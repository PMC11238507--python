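"""SNV enumeration, consequence calls, contexts, rarity filter, joins."""
import numpy as np
import pandas as pd
import pytest

from hmconstraint import domainmap, varspace
from hmconstraint.errors import DataError, ModelError
from hmconstraint.varspace import (
    TranscriptModel,
    apply_rarity_filter,
    enumerate_snvs,
    join_meta_positions,
    revcomp,
    trinucleotide_context,
)

from conftest import oracle_consequence, place_cds, random_cds


def simple_transcript(cds, strand="+"):
    t, _ = place_cds(cds, strand=strand)
    return t


class TestTranscriptModel:
    def test_rejects_length_not_multiple_of_three(self):
        with pytest.raises(ModelError):
            simple_transcript("ATGG")

    def test_rejects_internal_stop(self):
        with pytest.raises(ModelError):
            simple_transcript("ATGTAAGCTTAA")

    def test_rejects_exon_cds_length_mismatch(self):
        with pytest.raises(ModelError):
            TranscriptModel("T", "G", "c", "+", [(0, 5)], "ATGTAA")

    def test_minus_strand_genomic_positions_descend(self):
        t = simple_transcript("ATGGCTGACTAA", strand="-")
        pos = t.genomic_positions()
        assert (np.diff(pos) < 0).all() or len(t.cds_exons) == 2
        assert pos[0] > pos[-1]


class TestEnumerate:
    def test_single_codon_yields_nine(self):
        t = TranscriptModel("T", "G", "c", "+", [(0, 3)], "ATGTAA"[:3] + "")
        # a one-codon CDS is degenerate (no stop), use two codons instead
        t = TranscriptModel("T", "G", "c", "+", [(0, 6)], "ATGTAA")
        df = enumerate_snvs(t)
        assert len(df) == 18
        assert (df.groupby("cds_pos").size() == 3).all()

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_consequences_match_retranslation_oracle(self, strand):
        cds = "ATGGCTTAA"
        t, genome = place_cds(cds, strand=strand)
        df = enumerate_snvs(t, genome)
        assert len(df) == 27
        for row in df.itertuples():
            # recover the coding-strand alt from the genomic record
            alt = row.alt if strand == "+" else revcomp(row.alt)
            aa_ref, aa_alt, cons = oracle_consequence(cds, row.cds_pos - 1, alt)
            assert (row.aa_ref, row.aa_alt, row.consequence) == (aa_ref, aa_alt, cons)

    def test_random_cds_consequence_partition(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            cds = random_cds(rng, int(rng.integers(4, 12)))
            t, genome = place_cds(cds, strand=rng.choice(["+", "-"]))
            df = enumerate_snvs(t, genome)
            assert len(df) == 3 * len(cds)
            assert set(df["consequence"]) <= set(varspace.CONSEQUENCES)
            for row in df.sample(20, random_state=1).itertuples():
                alt = row.alt if t.strand == "+" else revcomp(row.alt)
                assert oracle_consequence(cds, row.cds_pos - 1, alt)[2] == row.consequence

    def test_strand_mirror_consequence_multiset(self):
        cds = "ATGGCTGACCGATGGTAA"
        plus, gplus = place_cds(cds, strand="+")
        minus, gminus = place_cds(cds, strand="-")
        cp = enumerate_snvs(plus, gplus)["consequence"].value_counts().to_dict()
        cm = enumerate_snvs(minus, gminus)["consequence"].value_counts().to_dict()
        assert cp == cm

    def test_genomic_ref_matches_genome(self):
        cds = "ATGGCTGACCGATGGTAA"
        for strand in "+-":
            t, genome = place_cds(cds, strand=strand)
            df = enumerate_snvs(t, genome)
            seq = genome[t.chrom]
            assert all(seq[p - 1] == r for p, r in zip(df["pos"], df["ref"]))


class TestContext:
    def test_direct_readoff(self):
        t, _ = place_cds("ATGGCTTAA", split=7)  # junction after cds_pos 7
        assert trinucleotide_context(t, 2) == "ATG"
        assert trinucleotide_context(t, 5) == "GCT"

    def test_edge_without_flank_is_n(self):
        t, _ = place_cds("ATGGCTTAA")
        # no genome passed: CDS edge has no left flank
        assert trinucleotide_context(t, 1) == "NAT"

    def test_edge_with_genome_uses_genomic_flank(self):
        t, genome = place_cds("ATGGCTTAA", strand="+")
        ctx = trinucleotide_context(t, 1, genome)
        seq = genome[t.chrom]
        g = int(t.genomic_positions()[0])
        assert ctx == seq[g - 1 : g + 2]

    def test_junction_context_is_genomic_not_spliced(self):
        cds = "ATGGCTGACTAA"
        t, genome = place_cds(cds, split=5)
        # cds_pos 5 is the last base of exon 1: its right genomic
        # neighbour is intronic, not the next CDS base
        ctx = trinucleotide_context(t, 5, genome)
        seq = genome[t.chrom]
        g = int(t.genomic_positions()[4])
        assert ctx == seq[g - 1 : g + 2]
        assert trinucleotide_context(t, 5) == "GCN"  # no genome -> soft fail

    def test_minus_strand_context_is_revcomp_of_genomic_window(self):
        cds = "ATGGCTGACTAA"
        t, genome = place_cds(cds, strand="-")
        seq = genome[t.chrom]
        for p in range(2, len(cds)):
            g = int(t.genomic_positions()[p - 1])
            expected = revcomp(seq[g - 1 : g + 2])
            assert trinucleotide_context(t, p, genome) == expected


class TestRarityFilter:
    @pytest.fixture
    def possible(self):
        t, genome = place_cds("ATGGCTTAA")
        return enumerate_snvs(t, genome)

    def test_af_classes(self, possible):
        keys = possible[["chrom", "pos", "ref", "alt"]].iloc[[0, 1, 2]]
        observed = keys.assign(af=[0.0, 0.0005, 0.002])
        out = apply_rarity_filter(possible, observed)
        assert not out.iloc[0]["observed_rare"] and not out.iloc[0]["common"]
        assert out.iloc[1]["observed_rare"] and not out.iloc[1]["common"]
        assert not out.iloc[2]["observed_rare"] and out.iloc[2]["common"]
        # unmatched variants are neither observed nor common
        assert not out.iloc[5]["observed_rare"] and not out.iloc[5]["common"]

    def test_duplicate_records_keep_max_af(self, possible, caplog):
        key = possible[["chrom", "pos", "ref", "alt"]].iloc[[0, 0]]
        observed = key.assign(af=[0.0005, 0.05])
        with caplog.at_level("WARNING"):
            out = apply_rarity_filter(possible, observed)
        assert out.iloc[0]["common"]  # max AF wins
        assert "duplicate" in caplog.text

    def test_bad_af_rejected(self, possible):
        observed = possible[["chrom", "pos", "ref", "alt"]].iloc[[0]].assign(af=[1.5])
        with pytest.raises(DataError):
            apply_rarity_filter(possible, observed)


class TestJoin:
    def test_toy_join(self, toy_stockholm):
        fam = domainmap.read_alignment(toy_stockholm)
        meta = domainmap.meta_positions_to_frame(domainmap.build_meta_positions([fam]))
        # protein A1: residues 3..7 map to columns 0,1,2,4,5; build a
        # transcript whose protein is 8 residues so codon 3 == residue 3
        rng = np.random.default_rng(0)
        cds = random_cds(rng, 9)
        t, genome = place_cds(cds)
        t.protein_id = "A1"
        df = enumerate_snvs(t, genome)
        out = join_meta_positions(df, meta)
        at3 = out[out["codon_index"] == 3]
        assert (at3["family_id"] == "PFTOY").all()
        assert (at3["column"] == 0).all()
        # synonymous variants at the same codon are joined too
        syn = at3[at3["consequence"] == "synonymous"]
        if len(syn):
            assert syn["family_id"].notna().all()
        # residues outside the envelope stay unannotated
        outside = out[out["codon_index"] == 2]
        assert outside["family_id"].isna().all()

    def test_insert_residue_unannotated(self, toy_stockholm):
        fam = domainmap.read_alignment(toy_stockholm)
        meta = domainmap.meta_positions_to_frame(domainmap.build_meta_positions([fam]))
        rng = np.random.default_rng(1)
        t, genome = place_cds(random_cds(rng, 9))
        t.protein_id = "B1"  # residue 3 of B1 is an insert-state residue
        out = join_meta_positions(enumerate_snvs(t, genome), meta)
        assert out.loc[out["codon_index"] == 3, "family_id"].isna().all()
        assert (out.loc[out["codon_index"] == 1, "column"] == 0).all()


class TestObservedIO:
    def test_tsv_and_vcf_agree(self, tmp_path):
        obs = pd.DataFrame(
            {"chrom": ["c1", "c1"], "pos": [5, 9], "ref": ["A", "C"],
             "alt": ["G", "T"], "af": [0.0005, 0.002]}
        )
        tsv = tmp_path / "obs.tsv"
        obs.to_csv(tsv, sep="\t", index=False)
        vcf = tmp_path / "obs.vcf"
        with open(vcf, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="AF">\n')
            fh.write("##contig=<ID=c1>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for r in obs.itertuples():
                fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\tAF={r.af}\n")
        a = varspace.read_observed_variants(tsv)
        b = varspace.read_observed_variants(vcf)
        pd.testing.assert_frame_equal(
            a.sort_values("pos").reset_index(drop=True),
            b.sort_values("pos").reset_index(drop=True),
            check_dtype=False, atol=1e-6,
        )
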