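"""Peptide→homoeolog mapping: exact matching, assignment rules, summaries."""

import pytest

from triadpipe import (
    AssignmentConflictError,
    HomoeologAssignment,
    SimulationSpec,
    ValidationError,
    assign_protein,
    generate_subgenome_proteome,
    index_proteome,
    map_peptide,
    summarize_assignment,
    tryptic_digest,
)
from triadpipe.mapping import round_percent
from triadpipe.proteome import ProteinRecord, SubgenomeProteinDB


def naive_scan(peptide, db):
    return frozenset(r.locus_id for r in db if peptide in r.sequence)


class TestPeptideIndex:
    def test_empty_db_everything_unmatched(self):
        index = index_proteome(SubgenomeProteinDB([]))
        assert map_peptide("AAAAAA", index).specificity == "unmatched"

    def test_direct_substring_hit(self):
        db = SubgenomeProteinDB([ProteinRecord("L1", "A", "1A", "F1", "MKAAA")])
        index = index_proteome(db)
        assert map_peptide("AAA", index).loci == {"L1"}

    def test_agrees_with_naive_scan_on_random_dbs(self):
        # Oracle equivalence: the k-mer-seeded index must reproduce a
        # position-by-position scan for peptides of every length class.
        for seed in (0, 1, 2):
            spec = SimulationSpec(seed=seed, n_families=6,
                                  protein_length_range=(50, 120))
            db = generate_subgenome_proteome(spec)
            index = index_proteome(db)
            queries = []
            for rec in db:
                queries.extend(tryptic_digest(rec.sequence, 2, 30, 1)[:8])
            queries += ["AAAA", "MWNCDE", "KRKRKRKR"]
            assert len(queries) >= 100
            for pep in queries:
                assert index.lookup(pep) == naive_scan(pep, db), pep

    def test_lookup_order_independent(self, small_db):
        reversed_db = SubgenomeProteinDB(list(small_db)[::-1])
        a, b = index_proteome(small_db), index_proteome(reversed_db)
        for pep in ("SHAREDPEPK", "WWWWDDDDK", "CCCCCCCCC"):
            assert a.lookup(pep) == b.lookup(pep)

    def test_invalid_peptide_characters_rejected(self, small_db):
        index = index_proteome(small_db)
        with pytest.raises(ValidationError):
            map_peptide("AAXB", index)
        with pytest.raises(ValidationError):
            map_peptide("", index)

    def test_isoleucine_leucine_equivalence_optional(self):
        db = SubgenomeProteinDB([ProteinRecord("L1", "A", "1A", "F1", "MKIIIK")])
        strict = index_proteome(db)
        folded = index_proteome(db, il_equivalent=True)
        assert strict.lookup("LLLK") == frozenset()
        assert folded.lookup("LLLK") == {"L1"}


class TestMapPeptide:
    @pytest.mark.parametrize(
        "peptide, specificity, n_loci",
        [
            ("WWWWDDDDK", "locus_unique", 1),
            ("SHAREDPEPK", "family_shared", 3),
            ("CCCCCCCCC", "cross_family", 2),
            ("QQQQQQ", "unmatched", 0),
        ],
    )
    def test_specificity_classes(self, small_db, peptide, specificity, n_loci):
        match = map_peptide(peptide, index_proteome(small_db))
        assert match.specificity == specificity
        assert len(match.loci) == n_loci

    def test_specificity_only_moves_toward_shared_when_db_grows(self, small_db):
        # Mapping monotonicity: adding sequences can only widen a hit.
        base = [r for r in small_db if r.locus_id == "F1.4B"]
        order = []
        for extra in (
            [],
            [ProteinRecord("F1.4D2", "D", "4D", "F1", "MWWWWDDDDKR")],
            [ProteinRecord("F9.5A", "A", "5A", "F9", "MWWWWDDDDKR")],
        ):
            db = SubgenomeProteinDB(base + extra)
            order.append(map_peptide("WWWWDDDDK", index_proteome(db)).specificity)
        assert order == ["locus_unique", "family_shared", "cross_family"]


class TestAssignProtein:
    def _match(self, pep, db):
        return map_peptide(pep, index_proteome(db))

    def test_unique_peptides_to_one_homoeolog(self, small_db):
        a = assign_protein(
            "p1",
            [self._match("WWWWDDDDK", small_db), self._match("SHAREDPEPK", small_db)],
            small_db,
        )
        assert a.category == "B"
        assert a.bias_flag == "single_bias"
        assert a.assigned_loci == {"F1.4B"}

    def test_singleton_family(self, small_db):
        a = assign_protein("p2", [self._match("HHHHHHHH", small_db)], small_db)
        assert a.category == "D"
        assert a.bias_flag == "singleton"

    def test_two_homoeolog_protein(self, small_db):
        a = assign_protein(
            "p3",
            [self._match("WWWWDDDDK", small_db), self._match("EEEEEEEK", small_db)],
            small_db,
        )
        assert a.category == "B+D"
        assert a.bias_flag == "multi"

    def test_family_shared_only_is_unassigned_with_family(self, small_db):
        a = assign_protein("p4", [self._match("SHAREDPEPK", small_db)], small_db)
        assert a.category == "unassigned"
        assert a.bias_flag == "unassigned"
        assert a.family_id == "F1"

    def test_cross_family_only_is_unassigned(self, small_db):
        a = assign_protein("p5", [self._match("CCCCCCCCC", small_db)], small_db)
        assert a.category == "unassigned"
        assert a.family_id is None

    def test_conflicting_unique_evidence_raises(self, small_db):
        with pytest.raises(AssignmentConflictError):
            assign_protein(
                "p6",
                [self._match("WWWWDDDDK", small_db), self._match("HHHHHHHH", small_db)],
                small_db,
            )

    def test_no_matches_rejected(self, small_db):
        with pytest.raises(ValidationError):
            assign_protein("p7", [], small_db)


class TestAssignmentSummary:
    @staticmethod
    def _bulk(flag, n, category="A"):
        return [
            HomoeologAssignment(f"{flag}{i}", "F", frozenset({"x"}), category, flag)
            for i in range(n)
        ]

    def test_reported_percentages_for_published_bias_counts(self):
        # 738 biased + 62 singletons + 215 multi over 1015 assigned.
        assignments = (
            self._bulk("single_bias", 738)
            + self._bulk("singleton", 62)
            + self._bulk("multi", 215, category="A+B")
        )
        summary = summarize_assignment(assignments)
        assert summary.assigned == 1015
        assert summary.bias_percent("single_bias") == 72.7
        assert summary.bias_percent("singleton") == 6.1

    def test_empty_input_gives_zero_summary(self):
        summary = summarize_assignment([])
        assert summary.total == summary.assigned == 0
        assert summary.bias_percent("single_bias") == 0.0

    def test_category_counts_partition_assigned_total(self, small_db):
        index = index_proteome(small_db)
        assignments = [
            assign_protein("q1", [map_peptide("WWWWDDDDK", index)], small_db),
            assign_protein("q2", [map_peptide("HHHHHHHH", index)], small_db),
            assign_protein("q3", [map_peptide("SHAREDPEPK", index)], small_db),
        ]
        summary = summarize_assignment(assignments, small_db)
        assert sum(summary.category_counts.values()) == summary.assigned == 2
        assert sum(summary.bias_counts.values()) == summary.assigned

    def test_half_up_rounding(self):
        assert round_percent(1, 16) == 6.3  # 6.25 rounds up, not to even


class TestRecoveryOnSyntheticData:
    def test_single_expressed_homoeolog_recovered(self):
        # Only one homoeolog per family expressed; with 5% divergence the
        # unique peptides must recover the true locus for ≥99% of proteins.
        spec = SimulationSpec(seed=21, n_families=120, homoeolog_divergence=0.05,
                              singleton_fraction=0.0)
        db = generate_subgenome_proteome(spec)
        index = index_proteome(db)
        correct = total = 0
        for family in db.families.values():
            truth = family[0]
            peptides = tryptic_digest(truth.sequence, 6, 50, 0)[:8]
            matches = [map_peptide(p, index) for p in peptides]
            a = assign_protein(truth.locus_id, matches, db)
            total += 1
            if a.assigned_loci == {truth.locus_id}:
                correct += 1
        assert correct / total >= 0.99
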