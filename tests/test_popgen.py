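"""SNP calling, Nei–Li diversity, haplotype grouping, trait association."""

import itertools

import numpy as np
import pytest

from triadpipe import (
    PromoterPanel,
    StatisticsError,
    ValidationError,
    call_variant_sites,
    generate_promoter_panel,
    group_haplotypes,
    haplotype_association,
    nucleotide_diversity,
)
from triadpipe.popgen import default_positions


def panel_of(seqs, ids=None):
    ids = ids or [f"s{i}" for i in range(len(seqs))]
    return PromoterPanel(ids, seqs, default_positions(len(seqs[0])))


def brute_force_pi(seqs):
    """Independent oracle: plain-python average pairwise difference."""
    n, L = len(seqs), len(seqs[0])
    used = [j for j in range(L) if all(s[j] in "ACGT" for s in seqs)]
    total = sum(
        sum(a[j] != b[j] for j in used)
        for a, b in itertools.combinations(seqs, 2)
    )
    n_pairs = n * (n - 1) // 2
    return total / (n_pairs * len(used))


class TestVariantSites:
    def test_identical_panel_has_no_variants(self):
        m = call_variant_sites(panel_of(["ACGTA"] * 4))
        assert m.n_sites == 0

    def test_single_biallelic_column(self):
        m = call_variant_sites(panel_of(["AAAAA", "AAAAA", "AACAA"]))
        assert m.n_sites == 1
        assert (m.alleles.iloc[:, 0] == "C").sum() == 1  # minor count 1

    def test_positions_are_atg_relative(self):
        # variant in the last column → position +1; second-to-last → −1
        m = call_variant_sites(panel_of(["AACAT", "AACAA", "AACGA"]))
        assert m.positions == [-1, 1]

    def test_gap_and_n_columns_excluded_under_complete_deletion(self):
        m = call_variant_sites(panel_of(["ACN", "AGN", "AG-"]))
        assert m.n_sites == 1 and m.positions == [-1]

    def test_multiallelic_flagged(self):
        m = call_variant_sites(panel_of(["AAA", "ACA", "AGA"]))
        assert m.multiallelic == [-1]

    def test_default_fixture_has_nine_sites(self):
        m = call_variant_sites(generate_promoter_panel(seed=5))
        assert m.n_sites == 9

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            panel_of(["AAA", "AAAA"])


class TestNucleotideDiversity:
    def test_identical_sequences_give_zero(self):
        est = nucleotide_diversity(panel_of(["ACGT" * 25] * 5))
        assert est.pi == 0.0

    def test_single_pair_closed_form(self):
        a = "A" * 100
        b = "A" * 99 + "C"
        est = nucleotide_diversity(panel_of([a, b]))
        assert est.pi == pytest.approx(0.01)
        assert est.l_effective == 100

    def test_matches_brute_force_oracle_on_random_panels(self):
        rng = np.random.default_rng(17)
        for n, L in [(4, 50), (5, 120), (6, 200)]:
            seqs = ["".join(rng.choice(list("ACGT"), L)) for _ in range(n)]
            est = nucleotide_diversity(panel_of(seqs))
            assert est.pi == pytest.approx(brute_force_pi(seqs))

    def test_invariant_under_sequence_reordering(self):
        rng = np.random.default_rng(23)
        seqs = ["".join(rng.choice(list("ACGT"), 80)) for _ in range(5)]
        assert nucleotide_diversity(panel_of(seqs)).pi == pytest.approx(
            nucleotide_diversity(panel_of(seqs[::-1])).pi
        )

    def test_unchanged_when_every_column_duplicated(self):
        rng = np.random.default_rng(29)
        seqs = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(4)]
        doubled = ["".join(c * 2 for c in s) for s in seqs]
        assert nucleotide_diversity(panel_of(doubled)).pi == pytest.approx(
            nucleotide_diversity(panel_of(seqs)).pi
        )

    def test_pairwise_deletion_handles_missing_cells(self):
        est = nucleotide_diversity(panel_of(["ACGT", "ACNT", "TCGT"]),
                                   deletion="pairwise")
        assert est.pi > 0

    def test_single_sequence_rejected(self):
        with pytest.raises(StatisticsError):
            nucleotide_diversity(panel_of(["ACGT"]))


class TestHaplotypeGrouping:
    def test_monomorphic_panel_rejected_identical_single_hap(self):
        m = call_variant_sites(panel_of(["AATA", "AACA", "AACA"]))
        g = group_haplotypes(m)
        assert g.n_haplotypes == 2
        assert g.patterns.loc["Hap1", "n_lines"] == 2  # most frequent first

    def test_default_fixture_structure(self):
        panel = generate_promoter_panel(seed=31)
        g = group_haplotypes(call_variant_sites(panel))
        assert g.n_haplotypes == 4
        assert list(g.patterns["n_lines"]) == [27, 15, 12, 8]
        assert sorted(g.patterns["diffs_vs_hap1"]) == [0, 1, 2, 6]

    def test_labels_partition_the_panel(self):
        panel = generate_promoter_panel(seed=31)
        g = group_haplotypes(call_variant_sites(panel))
        assert sorted(g.labels) == sorted(panel.ids)
        assert g.patterns["n_lines"].sum() == panel.n

    def test_input_order_only_breaks_frequency_ties(self):
        # distinct frequencies: reversing the input must not change groups
        panel = generate_promoter_panel(seed=31)
        m = call_variant_sites(panel)
        rev = PromoterPanel(panel.ids[::-1], panel.sequences[::-1], panel.positions)
        g1 = group_haplotypes(m)
        g2 = group_haplotypes(call_variant_sites(rev))
        assert g1.labels == g2.labels

    def test_ambiguous_base_resolved_or_flagged(self):
        # Two known patterns (C and T at the single SNP): an N is
        # compatible with both → ambiguous. With one known pattern the
        # N-tolerant match resolves uniquely.
        m = call_variant_sites(panel_of(["AAT", "AAC", "AAC", "AAT", "AAC"]))
        m.alleles.iloc[0, 0] = "N"
        g = group_haplotypes(m)
        assert g.labels["s0"] == "ambiguous"
        m2 = call_variant_sites(panel_of(["AAT", "AAC", "AAC"]))
        m2.alleles.iloc[0, 0] = "N"
        g2 = group_haplotypes(m2)
        assert g2.labels["s0"] == "Hap1"


class TestAssociation:
    def _labels(self):
        return {f"l{i}": f"Hap{i % 4 + 1}" for i in range(16)}

    def test_constant_trait_shares_one_letter(self):
        labels = self._labels()
        traits = {k: 5.0 + 0.001 * i for i, k in enumerate(labels)}
        res = haplotype_association(labels, traits)
        assert len(set("".join(res.summary["letters"]))) == 1
        assert res.p_value > 0.5

    def test_shifted_haplotype_gets_distinct_letter(self):
        rng = np.random.default_rng(13)
        labels = self._labels()
        traits = {
            k: float(rng.normal(10.0 + (10.0 if v == "Hap3" else 0.0), 1.0))
            for k, v in labels.items()
        }
        res = haplotype_association(labels, traits)
        hap3 = set(res.summary.loc["Hap3", "letters"])
        others = set(
            "".join(res.summary.drop(index="Hap3")["letters"])
        )
        assert not hap3 & others
        assert res.p_value < 0.001

    def test_four_by_four_design_accepted(self):
        labels = self._labels()
        traits = {k: float(i) for i, k in enumerate(labels)}
        res = haplotype_association(labels, traits)
        assert (res.summary["n"] == 4).all()

    def test_small_haplotype_excluded_with_warning(self):
        labels = {"a": "Hap1", "b": "Hap1", "c": "Hap2", "d": "Hap2", "e": "Hap3"}
        traits = {k: float(i) for i, k in enumerate(labels)}
        with pytest.warns(UserWarning):
            res = haplotype_association(labels, traits)
        assert res.excluded == ["Hap3"]
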