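"""Translation, allele grouping and polymorphic-site labeling."""

import itertools

import pytest
from hypothesis import given, strategies as st

from opsinadapt import (
    Haplotype,
    allele_frequencies,
    group_alleles,
    simulate_coding_alleles,
    site_table,
    translate,
)
from opsinadapt.alleles import _forward_table, translate_codon
from opsinadapt.core import Alignment, IUPAC_CODES


class TestTranslate:
    def test_standard_code(self):
        assert translate("ATGGCT") == "MA"

    def test_empty_cds_gives_empty_protein(self):
        assert translate("ACGTACGT", cds_coords=[]) == ""

    def test_cds_coords_are_one_based_inclusive(self):
        # 'xxATGGCTxx' with CDS 3..8
        assert translate("TTATGGCTAA", cds_coords=[(3, 8)]) == "MA"

    def test_length_not_divisible_by_three_fails(self):
        with pytest.raises(ValueError, match="divisible"):
            translate("ATGG")

    def test_internal_stop_warns_but_translates(self):
        with pytest.warns(UserWarning, match="stop"):
            assert translate("ATGTAAGCT") == "M*A"

    @pytest.mark.parametrize("codon,expected", [
        ("GCN", "A"),   # all expansions alanine
        ("GGR", "G"),   # GGA/GGG both glycine
        ("ATN", "X"),   # ATA/ATC/ATT Ile but ATG Met
        ("NNN", "X"),
        ("TTY", "F"),   # TTC/TTT both Phe
    ])
    def test_ambiguous_codons_by_expansion(self, codon, expected):
        assert translate(codon) == expected

    @given(st.text(alphabet="ACGTRYSWKMN", min_size=3, max_size=3))
    def test_ambiguity_resolution_matches_exhaustive_expansion(self, codon):
        fwd = _forward_table(1)
        residues = {
            fwd[a + b + c]
            for a, b, c in itertools.product(*(IUPAC_CODES[x] for x in codon))
        }
        expected = residues.pop() if len(residues) == 1 else "X"
        assert translate_codon(codon, fwd) == expected


class TestGroupAlleles:
    def test_synonymous_variants_collapse_to_one_group(self):
        haps = [Haplotype("a", "ATGGCT"), Haplotype("b", "ATGGCC")]
        groups, failures = group_alleles(haps)
        assert len(groups) == 1 and not failures
        assert sorted(groups[0].member_ids) == ["a", "b"]

    def test_single_haplotype_forms_single_group(self):
        groups, _ = group_alleles([Haplotype("x", "ATGGCT")])
        assert len(groups) == 1 and groups[0].member_ids == ["x"]

    def test_recovers_generator_ground_truth_partition(self):
        aln, truth = simulate_coding_alleles(6, 4, 60, 3, 2, seed=42)
        haps = [Haplotype(i, s) for i, s in aln]
        groups, failures = group_alleles(haps)
        assert not failures
        assert len(groups) == 6
        recovered = {frozenset(g.member_ids) for g in groups}
        expected = {
            frozenset(i for i, lab in truth.items() if lab == g)
            for g in set(truth.values())
        }
        assert recovered == expected

    def test_partition_invariant_to_input_order(self):
        aln, _ = simulate_coding_alleles(4, 3, 40, 2, 1, seed=9)
        haps = [Haplotype(i, s) for i, s in aln]
        g1, _ = group_alleles(haps)
        g2, _ = group_alleles(list(reversed(haps)))
        assert {frozenset(g.member_ids) for g in g1} == \
               {frozenset(g.member_ids) for g in g2}

    def test_reference_proteins_supply_labels(self):
        haps = [Haplotype("a", "ATGGCT"), Haplotype("b", "ATGTCT")]
        refs = {"M3": "MA", "Sp": "MS"}
        groups, _ = group_alleles(haps, reference_proteins=refs)
        labels = {g.label: g.member_ids for g in groups}
        assert labels == {"M3": ["a"], "Sp": ["b"]}

    def test_ambiguous_haplotype_assigned_iff_unique_reference_match(self):
        refs = {"M3": "MA", "Sp": "MS"}
        ok = Haplotype("amb", "ATGKCT")  # K=G/T: MA or MS -> ambiguous
        groups, failures = group_alleles([ok], reference_proteins=refs)
        assert failures and failures[0][0] == "amb"
        unique = Haplotype("amb2", "ATGGCN")  # GCN always Ala -> MA
        groups, failures = group_alleles([unique], reference_proteins=refs)
        assert not failures
        assert groups[0].label == "M3"

    def test_untranslatable_haplotype_reported_separately(self):
        haps = [Haplotype("good", "ATGGCT"), Haplotype("bad", "ATGG")]
        groups, failures = group_alleles(haps)
        assert len(groups) == 1
        assert failures[0][0] == "bad"


class TestSiteTable:
    def test_invariant_alignment_gives_empty_table(self):
        aln = Alignment(["a", "b"], ["ATGGCT", "ATGGCT"])
        assert site_table(aln).empty

    def test_third_position_synonymous_change_labeled_s(self):
        aln = Alignment(["a", "b"], ["GCT", "GCC"])
        df = site_table(aln)
        assert list(df["position"]) == [3]
        assert list(df["class"]) == ["s"]

    def test_first_position_ala_ser_change_labeled_n(self):
        aln = Alignment(["a", "b"], ["GCT", "TCT"])
        df = site_table(aln)
        assert list(df["class"]) == ["n"]

    def test_noncoding_columns_labeled(self):
        aln = Alignment(["a", "b"], ["AGCTT", "TGCTC"])
        df = site_table(aln, cds_coords=[(2, 4)])
        by_pos = dict(zip(df["position"], df["class"]))
        assert by_pos[1] == "noncoding"
        assert by_pos[5] == "noncoding"

    def test_generator_planted_sites_all_labeled_correctly(self):
        aln, truth = simulate_coding_alleles(3, 4, 50, 2, 2, seed=21)
        df = site_table(aln)
        # translation oracle: a site is synonymous iff swapping in any
        # observed variant never changes any observed codon's translation
        for _, row in df.iterrows():
            col = row["position"] - 1
            start = (col // 3) * 3
            off = col - start
            variants = {seq[col] for _, seq in aln}
            contexts = {seq[start:start + 3] for _, seq in aln}
            synonymous = all(
                len({translate(ctx[:off] + v + ctx[off + 1:]) for v in variants}) == 1
                for ctx in contexts
            )
            assert row["class"] == ("s" if synonymous else "n")


class TestAlleleFrequencies:
    def _make(self, spec):
        """spec: list of (id, group_label, species)"""
        from opsinadapt.alleles import AlleleGroup
        haps = [Haplotype(i, "ATG", species=sp) for i, _, sp in spec]
        labels = {lab for _, lab, _ in spec}
        groups = [
            AlleleGroup(lab, "M", [i for i, l, _ in spec if l == lab])
            for lab in sorted(labels)
        ]
        return groups, haps

    def test_single_allele_frequency_one(self):
        groups, haps = self._make([("a", "H", "sp1"), ("b", "H", "sp1")])
        df = allele_frequencies(groups, haps)
        assert df["frequency"].tolist() == [1.0]
        assert df["dominant"].all()

    def test_three_to_one_counts(self):
        groups, haps = self._make(
            [("a", "H", "s"), ("b", "H", "s"), ("c", "H", "s"), ("d", "D", "s")])
        df = allele_frequencies(groups, haps).set_index("allele")
        assert df.loc["H", "frequency"] == pytest.approx(0.75)
        assert df.loc["D", "frequency"] == pytest.approx(0.25)
        assert bool(df.loc["H", "dominant"]) is True

    def test_proportions_sum_to_one_per_stratum(self):
        groups, haps = self._make(
            [("a", "H", "s1"), ("b", "D", "s1"), ("c", "D", "s2"),
             ("d", "P", "s2"), ("e", "P", "s2")])
        df = allele_frequencies(groups, haps)
        sums = df.groupby("stratum")["frequency"].sum()
        assert all(abs(v - 1.0) < 1e-12 for v in sums)

    def test_missing_metadata_goes_to_unknown(self):
        groups, haps = self._make([("a", "H", "")])
        df = allele_frequencies(groups, haps)
        assert df["stratum"].tolist() == ["unknown"]
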