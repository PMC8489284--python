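"""Promoter-panel population genetics: SNPs, π, haplotypes, trait association.

The panel is a set of equal-length, pre-aligned promoter sequences with
an ATG-anchored coordinate system: position +1 is the A of the start
codon, upstream positions are negative, and there is no position 0.

Nucleotide diversity is the Nei–Li estimator — the average number of
differences per used site over all unordered sequence pairs:

    π = Σ_{i<j} d_ij / ( C(n,2) · L_eff )

For haplotype-resolved data this equals the frequency-weighted
per-site heterozygosity form, so no distinction is drawn here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import StatisticsError, ValidationError
from . import stats as stats_core

NUCLEOTIDES = frozenset("ACGT")
PANEL_ALPHABET = frozenset("ACGTN-")


def default_positions(length: int) -> List[int]:
    """ATG-relative positions for an alignment whose last column is +1.

    Columns run −(L−1) … −1, +1 (no position 0), matching a promoter
    window that ends at the first base of the start codon.
    """
    return list(range(-(length - 1), 0)) + [1]


@dataclass
class PromoterPanel:
    """Aligned promoter sequences with an ATG-relative coordinate map."""

    ids: List[str]
    sequences: List[str]
    positions: List[int]

    def __post_init__(self):
        if len(self.ids) != len(self.sequences):
            raise ValidationError("ids and sequences differ in length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValidationError(f"unequal sequence lengths: {sorted(lengths)}")
        if self.sequences:
            L = len(self.sequences[0])
            if len(self.positions) != L:
                raise ValidationError("coordinate map length != alignment length")
            bad = set("".join(self.sequences)) - PANEL_ALPHABET
            if bad:
                raise ValidationError(f"invalid alignment characters {sorted(bad)}")
        if 0 in self.positions:
            raise ValidationError("ATG-relative coordinates have no position 0")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def column_of(self, position: int) -> int:
        try:
            return self.positions.index(position)
        except ValueError:
            raise KeyError(f"position {position} not in panel") from None

    def as_array(self) -> np.ndarray:
        return np.array([list(s) for s in self.sequences], dtype="U1")

    def to_fasta(self, path: str | Path) -> None:
        SeqIO.write(
            [
                SeqRecord(Seq(s), id=i, description="")
                for i, s in zip(self.ids, self.sequences)
            ],
            str(path),
            "fasta",
        )

    @classmethod
    def from_fasta(
        cls, path: str | Path, positions: Optional[Sequence[int]] = None
    ) -> "PromoterPanel":
        ids, seqs = [], []
        for sr in SeqIO.parse(str(path), "fasta"):
            ids.append(sr.id)
            seqs.append(str(sr.seq).upper())
        if not seqs:
            raise ValidationError(f"no sequences in {path}")
        pos = list(positions) if positions is not None else default_positions(len(seqs[0]))
        return cls(ids, seqs, pos)


def _used_columns(arr: np.ndarray, deletion: str) -> np.ndarray:
    """Boolean mask of columns used under the gap/N policy."""
    clean = np.isin(arr, list("ACGT"))
    if deletion == "complete":
        return clean.all(axis=0)
    if deletion == "pairwise":
        return clean.any(axis=0)
    raise ValidationError(f"unknown deletion policy {deletion!r}")


@dataclass
class SnpMatrix:
    """Variant sites of a panel: position → allele per sequence."""

    positions: List[int]
    alleles: pd.DataFrame  # index: sequence ids; columns: positions
    multiallelic: List[int] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.positions)


def call_variant_sites(panel: PromoterPanel, deletion: str = "complete") -> SnpMatrix:
    """Report alignment columns with ≥2 distinct unambiguous alleles.

    Columns containing gap or N characters are handled by the deletion
    policy: ``complete`` (default) excludes them outright; ``pairwise``
    keeps them, leaving ambiguous cells as N. Sites with >2 alleles are
    kept and flagged in ``multiallelic``.
    """
    if panel.n == 0:
        return SnpMatrix([], pd.DataFrame(index=[]))
    arr = panel.as_array()
    used = _used_columns(arr, deletion)
    positions, cols, multi = [], [], []
    for j in np.nonzero(used)[0]:
        col = arr[:, j]
        distinct = set(col) & NUCLEOTIDES
        if len(distinct) >= 2:
            positions.append(panel.positions[j])
            cols.append(col)
            if len(distinct) > 2:
                multi.append(panel.positions[j])
    alleles = pd.DataFrame(
        np.array(cols).T if cols else np.empty((panel.n, 0), dtype="U1"),
        index=panel.ids,
        columns=positions,
    )
    return SnpMatrix(positions, alleles, multi)


@dataclass(frozen=True)
class DiversityEstimate:
    pi: float
    n: int
    l_effective: int


def nucleotide_diversity(
    panel: PromoterPanel, deletion: str = "complete"
) -> DiversityEstimate:
    """Nei–Li nucleotide diversity of the panel.

    With complete deletion, π = Σ_{i<j} d_ij / (C(n,2)·L_eff) over the
    columns free of gaps/N. With pairwise deletion each pair is scored
    per comparable site and the per-pair rates are averaged.
    """
    if panel.n < 2:
        raise StatisticsError("nucleotide diversity needs at least 2 sequences")
    arr = panel.as_array()
    if deletion == "complete":
        used = _used_columns(arr, "complete")
        l_eff = int(used.sum())
        if l_eff == 0:
            raise StatisticsError("no usable columns after complete deletion")
        sub = arr[:, used]
        total = 0
        for i in range(panel.n):
            diff = (sub[i + 1 :] != sub[i]).sum(axis=1)
            total += int(diff.sum())
        n_pairs = panel.n * (panel.n - 1) // 2
        return DiversityEstimate(total / (n_pairs * l_eff), panel.n, l_eff)
    if deletion == "pairwise":
        clean = np.isin(arr, list("ACGT"))
        rates = []
        for i in range(panel.n):
            for j in range(i + 1, panel.n):
                ok = clean[i] & clean[j]
                if not ok.any():
                    raise StatisticsError(
                        f"pair ({panel.ids[i]}, {panel.ids[j]}) shares no usable column"
                    )
                rates.append((arr[i, ok] != arr[j, ok]).mean())
        l_eff = int(np.isin(arr, list("ACGT")).all(axis=0).sum())
        return DiversityEstimate(float(np.mean(rates)), panel.n, l_eff)
    raise ValidationError(f"unknown deletion policy {deletion!r}")


@dataclass
class HaplotypeGrouping:
    """Partition of panel sequences into identical-allele-vector groups."""

    labels: Dict[str, str]  # sequence id → "Hap1" … (or "ambiguous")
    patterns: pd.DataFrame  # index: haplotype; columns: positions + n_lines + diffs_vs_hap1

    @property
    def n_haplotypes(self) -> int:
        return len(self.patterns)


def group_haplotypes(m: SnpMatrix) -> HaplotypeGrouping:
    """Group sequences by their allele vector over the variant sites.

    Labels Hap1, Hap2, … are ordered by descending frequency, ties
    broken by first occurrence in the input. Sequences with an N at a
    variant site are matched N-tolerantly; if more than one pattern is
    compatible they are labelled ``ambiguous``. The pattern table
    records each haplotype's alleles and its SNP-count difference from
    Hap1 (the reference, most frequent haplotype).
    """
    if len(m.alleles) == 0:
        raise ValidationError("empty SNP matrix")
    vectors: Dict[tuple, List[str]] = {}
    order: List[tuple] = []
    ambiguous: List[Tuple[str, tuple]] = []
    for seq_id, row in m.alleles.iterrows():
        vec = tuple(row)
        if any(a not in NUCLEOTIDES for a in vec):
            ambiguous.append((seq_id, vec))
            continue
        if vec not in vectors:
            vectors[vec] = []
            order.append(vec)
        vectors[vec].append(seq_id)

    ranked = sorted(order, key=lambda v: (-len(vectors[v]), order.index(v)))
    names = {vec: f"Hap{k + 1}" for k, vec in enumerate(ranked)}
    labels = {sid: names[vec] for vec in ranked for sid in vectors[vec]}

    for seq_id, vec in ambiguous:
        compatible = [
            v
            for v in ranked
            if all(a == b or a not in NUCLEOTIDES for a, b in zip(vec, v))
        ]
        labels[seq_id] = names[compatible[0]] if len(compatible) == 1 else "ambiguous"

    ref = ranked[0] if ranked else ()
    rows = []
    for vec in ranked:
        diffs = sum(a != b for a, b in zip(vec, ref))
        rows.append(list(vec) + [len(vectors[vec]), diffs])
    patterns = pd.DataFrame(
        rows,
        index=[names[v] for v in ranked],
        columns=list(m.positions) + ["n_lines", "diffs_vs_hap1"],
    )
    return HaplotypeGrouping(labels, patterns)


@dataclass
class AssociationResult:
    """Haplotype–trait association: group summaries, ANOVA, Duncan letters."""

    summary: pd.DataFrame  # index: haplotype; columns mean, sd, n, letters
    f_statistic: float
    p_value: float
    excluded: List[str]


def haplotype_association(
    labels: Dict[str, str],
    traits: Dict[str, float],
    alpha: float = 0.05,
) -> AssociationResult:
    """One-way ANOVA of a trait across promoter haplotypes, with Duncan's
    multiple range test letters (groups sharing a letter do not differ
    at the given alpha).

    Haplotypes with fewer than 2 phenotyped lines are excluded with a
    warning; ``ambiguous`` sequences are never used.
    """
    groups: Dict[str, List[float]] = {}
    for line_id, hap in labels.items():
        if hap == "ambiguous" or line_id not in traits:
            continue
        groups.setdefault(hap, []).append(float(traits[line_id]))
    excluded = sorted(h for h, v in groups.items() if len(v) < 2)
    for h in excluded:
        warnings.warn(f"haplotype {h} has <2 phenotyped lines; excluded")
        del groups[h]
    if len(groups) < 2:
        raise StatisticsError("need ≥2 haplotypes with ≥2 lines each")
    f_stat, _, _, p = stats_core.one_way_anova(groups)
    letters = stats_core.duncan_mrt(groups, alpha=alpha)
    rows = {
        h: {
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)),
            "n": len(v),
            "letters": letters[h],
        }
        for h, v in groups.items()
    }
    summary = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return AssociationResult(summary, f_stat, p, excluded)
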