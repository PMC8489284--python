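"""Homoeolog balance testing and chromosome distribution summaries.

For proteins detected from two or three homoeologs, locus-resolved
abundances (from locus-unique peptides only) are compared across the
contributing loci by one-way ANOVA on log abundances; p < alpha calls
the family's expression unbalanced. With two loci the ANOVA reduces to
the two-sample pooled t-test (F = t²).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import StatisticsError, ValidationError
from .mapping import HomoeologAssignment
from .proteome import SubgenomeProteinDB
from .simulate import ReplicateDesign
from . import stats as stats_core

CHROMOSOMES = tuple(f"{g}{sg}" for g in range(1, 8) for sg in "ABD")


@dataclass
class LocusAbundanceMatrix:
    """Replicate abundances for the 2–3 contributing loci of one family."""

    family_id: str
    abundances: Dict[str, Sequence[float]]  # locus id → replicate abundances

    def __post_init__(self):
        if len(self.abundances) < 2:
            raise ValidationError(
                f"{self.family_id}: need ≥2 loci with abundances"
            )
        for locus, values in self.abundances.items():
            arr = np.asarray(values, dtype=float)
            if arr.size < 2:
                raise ValidationError(f"{locus}: need ≥2 replicates")
            if (arr <= 0).any():
                raise ValidationError(f"{locus}: abundances must be > 0")


@dataclass(frozen=True)
class BalanceResult:
    family_id: str
    balanced: bool
    p_value: float
    f_statistic: float


def test_balance(m: LocusAbundanceMatrix, alpha: float = 0.05) -> BalanceResult:
    """One-way ANOVA across loci on log abundances.

    p < alpha ⇒ unbalanced. Zero variance everywhere with equal means
    is balanced with p = 1 by convention (handled in the ANOVA).
    """
    groups = {
        locus: np.log(np.asarray(v, dtype=float))
        for locus, v in m.abundances.items()
    }
    f_stat, _, _, p = stats_core.one_way_anova(groups)
    return BalanceResult(m.family_id, p >= alpha, p, f_stat)


def locus_matrices(
    quants: pd.DataFrame,
    assignments: Sequence[HomoeologAssignment],
    db: SubgenomeProteinDB,
    design: Optional[ReplicateDesign] = None,
    condition: str = "both",
) -> Tuple[List[LocusAbundanceMatrix], List[str]]:
    """Build per-family locus×replicate matrices for multi-homoeolog proteins.

    ``condition`` selects which channels feed the balance test:
    ``both`` (default), ``control`` or ``treatment``. Families whose
    multi-homoeolog protein lacks quantified unique-peptide abundances
    for ≥2 loci are returned as untestable.
    """
    design = design or ReplicateDesign()
    if condition == "both":
        channels = design.channels
    elif condition == "control":
        channels = design.control_channels
    elif condition == "treatment":
        channels = design.treatment_channels
    else:
        raise ValidationError(f"unknown condition {condition!r}")
    matrices, untestable = [], []
    for a in assignments:
        if a.bias_flag != "multi":
            continue
        abund = {}
        for lid in sorted(a.assigned_loci):
            if lid in quants.index and bool(quants.loc[lid, "quantified"]):
                values = quants.loc[lid, channels].to_numpy(dtype=float)
                if np.isfinite(values).all() and (values > 0).all():
                    abund[lid] = values
        if len(abund) >= 2:
            matrices.append(LocusAbundanceMatrix(a.family_id, abund))
        else:
            untestable.append(a.family_id)
    return matrices, untestable


def balance_report(
    matrices: Sequence[LocusAbundanceMatrix], alpha: float = 0.05
) -> pd.DataFrame:
    """TSV-ready balance report: family, loci, F, p, class."""
    rows = []
    for m in matrices:
        res = test_balance(m, alpha=alpha)
        rows.append(
            [
                m.family_id,
                ",".join(sorted(m.abundances)),
                res.f_statistic,
                res.p_value,
                "balanced" if res.balanced else "unbalanced",
            ]
        )
    return pd.DataFrame(
        rows, columns=["family_id", "loci", "F", "p_value", "balance"]
    )


def chromosome_distribution(
    assignments: Sequence[HomoeologAssignment],
    db: SubgenomeProteinDB,
) -> Dict[str, int]:
    """Counts over the 21 wheat chromosome labels (1A…7D).

    One count per assigned locus, so a protein expressed from two
    homoeologs contributes to two chromosomes. Unknown labels are
    reported via a warning key and skipped.
    """
    counts: Counter = Counter()
    skipped = 0
    for a in assignments:
        for lid in a.assigned_loci:
            chrom = db.locus(lid).chromosome
            if chrom in CHROMOSOMES:
                counts[chrom] += 1
            else:
                skipped += 1
    out = {c: counts.get(c, 0) for c in CHROMOSOMES}
    if skipped:
        import warnings

        warnings.warn(f"{skipped} assigned loci had unknown chromosome labels")
    return out
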