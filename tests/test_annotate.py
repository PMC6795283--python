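"""Codon effects, EMS reachability, conservation logo."""

import numpy as np
import pytest
from Bio.Seq import Seq

from scampr import (annotate_effect, compute_logo, conservation_at,
                    conserved_serine_column, ems_reachable_substitutions,
                    s830n_site)
from scampr.annotate import load_alignment


class TestAnnotateEffect:
    def test_canonical_missense_ser_to_asn(self, gene):
        pos, alt = s830n_site(gene)
        eff = annotate_effect(gene, pos, alt)
        assert eff.effect_class == "missense"
        assert (eff.ref_aa, eff.alt_aa) == ("S", "N")
        assert eff.codon_index == 830
        assert (eff.ref_codon, eff.alt_codon) == ("AGC", "AAC")
        assert eff.motif_offset == 10

    def test_synonymous_third_position(self, gene):
        # AGC -> AGT is still serine
        pos, _ = s830n_site(gene)
        eff = annotate_effect(gene, pos + 1, "T")
        assert eff.effect_class == "synonymous"
        assert eff.ref_aa == eff.alt_aa == "S"
        assert eff.alt_codon == "AGT"

    def test_nonsense_from_tryptophan(self, gene):
        # the motif W codon: TGG with middle G->A gives TAG (stop)
        anchor = gene.motif_anchors["QXXRW"]
        w_index = anchor + 4
        codon_start = gene.cds_to_genomic(3 * (w_index - 1) + 1)
        assert gene.cds_sequence()[3 * (w_index - 1):3 * w_index] == "TGG"
        eff = annotate_effect(gene, codon_start + 1, "A")
        assert eff.effect_class == "nonsense"
        assert eff.alt_codon == "TAG"

    def test_intron_positions(self, gene):
        intron_start = gene.exons[0][1] + 1  # first base past exon 1
        eff = annotate_effect(gene, intron_start,
                              "A" if gene.base_at(intron_start) != "A" else "C")
        assert eff.effect_class == "splice_adjacent"
        deep = intron_start + 50
        eff2 = annotate_effect(gene, deep,
                               "A" if gene.base_at(deep) != "A" else "C")
        assert eff2.effect_class == "noncoding"
        assert eff2.codon_index is None

    def test_rejects_bad_input(self, gene):
        pos, _ = s830n_site(gene)
        with pytest.raises(ValueError):
            annotate_effect(gene, pos, gene.base_at(pos))
        with pytest.raises(IndexError):
            annotate_effect(gene, 10**7, "A")

    def test_oracle_equivalence_full_mutant_translation(self, gene):
        """1000 random exonic substitutions: codon-level annotation must
        agree with brute-force translation of the whole mutant CDS."""
        rng = np.random.default_rng(17)
        cds = gene.cds_sequence()
        exonic = [p for s, e in gene.exons for p in range(s, e + 1)]
        for pos in rng.choice(exonic, size=1000, replace=True):
            pos = int(pos)
            ref = gene.base_at(pos)
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            eff = annotate_effect(gene, pos, alt)
            cds_pos = gene.genomic_to_cds(pos)
            mutant = cds[:cds_pos - 1] + alt + cds[cds_pos:]
            ref_prot = str(Seq(cds).translate())
            alt_prot = str(Seq(mutant).translate())
            diffs = [i for i, (a, b) in enumerate(zip(ref_prot, alt_prot))
                     if a != b]
            if eff.effect_class == "synonymous":
                assert not diffs and "*" not in alt_prot
            elif eff.effect_class == "nonsense":
                assert alt_prot[eff.codon_index - 1] == "*"
            else:
                assert diffs == [eff.codon_index - 1]
                assert alt_prot[eff.codon_index - 1] == eff.alt_aa


class TestEmsReachable:
    def test_agc_reaches_only_asn_missense(self):
        subs = ems_reachable_substitutions("AGC")
        assert subs == {("AAC", "N", "missense"), ("AGT", "S", "synonymous")}
        missense = {s for s in subs if s[2] == "missense"}
        assert missense == {("AAC", "N", "missense")}

    def test_codon_without_g_or_c_unreachable(self):
        assert ems_reachable_substitutions("TTT") == set()
        assert ems_reachable_substitutions("ATA") == set()

    def test_tgg_reaches_two_stops(self):
        subs = ems_reachable_substitutions("TGG")
        assert subs == {("TAG", "*", "nonsense"), ("TGA", "*", "nonsense")}

    def test_invalid_codon_rejected(self):
        with pytest.raises(ValueError):
            ems_reachable_substitutions("AG")
        with pytest.raises(ValueError):
            ems_reachable_substitutions("AGX")

    @pytest.mark.parametrize("codon", ["GGG", "CCC", "GCA", "ACG", "TCG"])
    def test_subset_of_single_base_neighbors_and_ems_consistent(self, codon):
        neighbors = {codon[:i] + b + codon[i + 1:]
                     for i in range(3) for b in "ACGT"} - {codon}
        subs = ems_reachable_substitutions(codon)
        for alt_codon, _, _ in subs:
            assert alt_codon in neighbors
            changed = [(r, a) for r, a in zip(codon, alt_codon) if r != a]
            assert changed in ([("G", "A")], [("C", "T")])


class TestLogo:
    def test_table1_serine_column_fully_conserved(self, table1_alignment):
        names, seqs = table1_alignment
        assert names[0] == "BdCESA1" and len(seqs) == 7
        col = conserved_serine_column(seqs)
        columns = compute_logo(seqs)
        assert columns[col - 1].residue_frequencies == {"S": 1.0}
        assert columns[col - 1].letter_heights == {"S": 1.0}
        assert conservation_at(seqs, col, "S") == 1.0

    def test_equal_counts_give_equal_heights(self):
        cols = compute_logo(["A", "C", "D", "E"])
        assert cols[0].letter_heights == {r: 0.25 for r in "ACDE"}

    def test_all_gap_column_is_empty(self):
        cols = compute_logo(["-A", "-C"])
        assert cols[0].residue_frequencies == {}
        assert cols[0].letter_heights == {}

    def test_frequencies_sum_to_one(self, table1_alignment):
        _, seqs = table1_alignment
        for col in compute_logo(seqs):
            if col.residue_frequencies:
                assert sum(col.residue_frequencies.values()) == pytest.approx(1.0)

    def test_information_mode_bounded_by_log2_20(self, table1_alignment):
        _, seqs = table1_alignment
        for col in compute_logo(seqs, mode="information"):
            total = sum(col.letter_heights.values())
            assert 0 <= total <= np.log2(20) + 1e-9

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            compute_logo(["AB", "A"])

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            compute_logo(["ACDEF"])

    def test_conservation_of_identical_pair(self):
        seqs = ["ACDEF", "ACDEF"]
        for j in range(1, 6):
            assert conservation_at(seqs, j, seqs[0][j - 1]) == 1.0

    def test_absent_residue_is_zero(self, table1_alignment):
        _, seqs = table1_alignment
        assert conservation_at(seqs, 30, "W") == 0.0

    def test_out_of_range_column(self, table1_alignment):
        _, seqs = table1_alignment
        with pytest.raises(IndexError):
            conservation_at(seqs, 61, "S")


def test_alignment_fixture_shape(table1_alignment):
    names, seqs = table1_alignment
    assert len(names) == 7
    assert {len(s) for s in seqs} == {60}


def test_load_plain_text_block(tmp_path):
    path = tmp_path / "aln.txt"
    path.write_text("seq1 AC-DE\nseq2 ACDDE\n")
    names, seqs = load_alignment(path)
    assert names == ["seq1", "seq2"]
    assert seqs == ["AC-DE", "ACDDE"]


def test_logo_tsv_and_plot(table1_alignment, tmp_path):
    from scampr.annotate import write_logo_tsv, plot_logo
    _, seqs = table1_alignment
    cols = compute_logo(seqs)
    write_logo_tsv(cols, tmp_path / "logo.tsv")
    assert (tmp_path / "logo.tsv").read_text().startswith("column\tresidue")
    plot_logo(cols[:20], tmp_path / "logo.png",
              highlight=conserved_serine_column(seqs))
    assert (tmp_path / "logo.png").stat().st_size > 0
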