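"""Peptide→homoeolog mapping and expression-category assignment.

Peptides are matched against the subgenome-partitioned proteome at
100% identity — i.e. exact, full-length substring matches — searching
the A, B and D subgenome entries jointly but keeping track of which
homoeolog family each hit belongs to. A protein is assigned to
specific homoeologs only through locus-unique peptides; proteins
supported solely by peptides shared across a whole family (or across
families) cannot be placed on a specific subgenome and stay
unassigned. Assigned proteins are then classified by which subgenomes
contribute (A, B, D, A+B, A+D, B+D, A+B+D) and by homoeolog
expression bias: a family with ≥2 loci detected from only one of them
is biased (``single_bias``); a single-locus family is a ``singleton``;
detection from ≥2 homoeologs is ``multi``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence

import pandas as pd

from .errors import AssignmentConflictError, ValidationError
from .proteome import AMINO_ACIDS, SubgenomeProteinDB

SPECIFICITIES = ("locus_unique", "family_shared", "cross_family", "unmatched")
CATEGORIES = ("A", "B", "D", "A+B", "A+D", "B+D", "A+B+D")
BIAS_FLAGS = ("single_bias", "singleton", "multi", "unassigned")


@dataclass(frozen=True)
class PeptideMatch:
    """Exact-match outcome of one peptide against the proteome."""

    peptide: str
    loci: FrozenSet[str]
    specificity: str

    @property
    def is_unique(self) -> bool:
        return self.specificity == "locus_unique"


class PeptideIndex:
    """Exact-substring index over a subgenome proteome.

    Seeds candidate loci from a k-mer table (k = ``seed_k``) and
    verifies with a full substring test; queries shorter than k fall
    back to a linear scan. Lookup results are independent of record
    insertion order. With ``il_equivalent`` both index and queries
    collapse I onto L, since mass spectrometry cannot tell the two
    residues apart (off by default: the genomic database distinguishes
    them).
    """

    def __init__(
        self, db: SubgenomeProteinDB, seed_k: int = 5, il_equivalent: bool = False
    ):
        self.db = db
        self.seed_k = seed_k
        self.il_equivalent = il_equivalent
        self._kmers: Dict[str, set] = {}
        self._sequences: Dict[str, str] = {}
        for rec in db:
            seq = self._canon(rec.sequence)
            self._sequences[rec.locus_id] = seq
            for i in range(len(seq) - seed_k + 1):
                self._kmers.setdefault(seq[i : i + seed_k], set()).add(rec.locus_id)

    def _canon(self, seq: str) -> str:
        return seq.replace("I", "L") if self.il_equivalent else seq

    def lookup(self, peptide: str) -> FrozenSet[str]:
        """All loci whose sequence contains the peptide as a substring."""
        if not peptide:
            raise ValidationError("empty peptide")
        bad = set(peptide) - AMINO_ACIDS
        if bad:
            raise ValidationError(f"peptide has invalid characters {sorted(bad)}")
        pep = self._canon(peptide)
        if len(pep) < self.seed_k:
            return frozenset(
                lid for lid, seq in self._sequences.items() if pep in seq
            )
        candidates = self._kmers.get(pep[: self.seed_k], set())
        return frozenset(lid for lid in candidates if pep in self._sequences[lid])


def index_proteome(
    db: SubgenomeProteinDB, il_equivalent: bool = False
) -> PeptideIndex:
    """Build the exact-substring peptide index for a proteome."""
    return PeptideIndex(db, il_equivalent=il_equivalent)


def map_peptide(peptide: str, index: PeptideIndex) -> PeptideMatch:
    """Match one peptide at 100% identity and classify its specificity.

    ``locus_unique``: exactly one locus; ``family_shared``: ≥2 loci all
    in one homoeolog family; ``cross_family``: loci spanning families;
    ``unmatched``: no hit.
    """
    loci = index.lookup(peptide)
    if not loci:
        specificity = "unmatched"
    elif len(loci) == 1:
        specificity = "locus_unique"
    else:
        families = {index.db.locus(lid).family_id for lid in loci}
        specificity = "family_shared" if len(families) == 1 else "cross_family"
    return PeptideMatch(peptide, loci, specificity)


@dataclass(frozen=True)
class HomoeologAssignment:
    """Per-protein outcome of homoeolog-specific assignment."""

    protein_id: str
    family_id: Optional[str]
    assigned_loci: FrozenSet[str]
    category: str  # one of CATEGORIES or "unassigned"
    bias_flag: str  # one of BIAS_FLAGS


def _category(subgenomes: Iterable[str]) -> str:
    return "+".join(sorted(set(subgenomes)))


def assign_protein(
    protein_id: str,
    matches: Sequence[PeptideMatch],
    db: SubgenomeProteinDB,
) -> HomoeologAssignment:
    """Assign a protein to specific homoeologs from its peptide matches.

    Only locus-unique peptides provide homoeolog-specific evidence;
    their loci must all fall in one family (otherwise the evidence is
    contradictory and an :class:`AssignmentConflictError` is raised so
    the caller can exclude the protein). Family-shared-only evidence
    pins down the family but not the locus → unassigned with the
    family recorded. Cross-family-only evidence → unassigned.
    """
    if not matches:
        raise ValidationError(f"{protein_id}: no peptide matches supplied")
    unique_loci = set()
    for m in matches:
        if m.is_unique:
            unique_loci.update(m.loci)
    if unique_loci:
        families = {db.locus(lid).family_id for lid in unique_loci}
        if len(families) > 1:
            raise AssignmentConflictError(
                f"{protein_id}: locus-unique peptides span families {sorted(families)}"
            )
        family_id = families.pop()
        family_size = db.family_size(family_id)
        subgenomes = [db.locus(lid).subgenome for lid in unique_loci]
        if len(unique_loci) == 1:
            bias = "singleton" if family_size == 1 else "single_bias"
        else:
            bias = "multi"
        return HomoeologAssignment(
            protein_id,
            family_id,
            frozenset(unique_loci),
            _category(subgenomes),
            bias,
        )
    # No locus-unique evidence: record the family when it is unambiguous.
    shared_families = {
        db.locus(lid).family_id
        for m in matches
        if m.specificity == "family_shared"
        for lid in m.loci
    }
    family_id = shared_families.pop() if len(shared_families) == 1 else None
    return HomoeologAssignment(protein_id, family_id, frozenset(), "unassigned", "unassigned")


def round_percent(count: int, total: int, decimals: int = 1) -> float:
    """Percentage with half-up rounding (738/1015 → 72.7)."""
    if total == 0:
        return 0.0
    q = Decimal(10) ** -decimals
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP)
    )


@dataclass
class AssignmentSummary:
    """Counts and percentages over assigned proteins (Fig. 1b-style)."""

    total: int
    assigned: int
    category_counts: Dict[str, int]
    bias_counts: Dict[str, int]
    subgenome_counts: Dict[str, int]  # single-homoeolog proteins per subgenome
    chromosome_counts: Dict[str, int]  # one count per assigned locus

    def category_percent(self, category: str) -> float:
        return round_percent(self.category_counts.get(category, 0), self.assigned)

    def bias_percent(self, flag: str) -> float:
        return round_percent(self.bias_counts.get(flag, 0), self.assigned)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat in CATEGORIES:
            rows.append(
                ("category", cat, self.category_counts.get(cat, 0), self.category_percent(cat))
            )
        for flag in ("single_bias", "singleton", "multi"):
            rows.append(
                ("bias", flag, self.bias_counts.get(flag, 0), self.bias_percent(flag))
            )
        return pd.DataFrame(rows, columns=["kind", "label", "count", "percent"])


def summarize_assignment(
    assignments: Sequence[HomoeologAssignment],
    db: Optional[SubgenomeProteinDB] = None,
) -> AssignmentSummary:
    """Tabulate assignment categories, bias flags and per-locus locations.

    Percentages are computed over the assigned total with half-up
    rounding to one decimal. Chromosome counts need the database to
    resolve loci and count one per assigned locus (a two-homoeolog
    protein contributes to two chromosomes).
    """
    assigned = [a for a in assignments if a.category != "unassigned"]
    category_counts = Counter(a.category for a in assigned)
    bias_counts = Counter(a.bias_flag for a in assigned)
    subgenome_counts: Counter = Counter()
    for a in assigned:
        if len(a.assigned_loci) == 1 and a.category in ("A", "B", "D"):
            subgenome_counts[a.category] += 1
    chromosome_counts: Counter = Counter()
    if db is not None:
        for a in assigned:
            for lid in a.assigned_loci:
                chromosome_counts[db.locus(lid).chromosome] += 1
    return AssignmentSummary(
        total=len(assignments),
        assigned=len(assigned),
        category_counts=dict(category_counts),
        bias_counts=dict(bias_counts),
        subgenome_counts=dict(subgenome_counts),
        chromosome_counts=dict(chromosome_counts),
    )


def map_peptide_table(
    peptides: Iterable[str], index: PeptideIndex
) -> Dict[str, PeptideMatch]:
    """Map every distinct peptide once; returns peptide → match."""
    return {pep: map_peptide(pep, index) for pep in dict.fromkeys(peptides)}
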