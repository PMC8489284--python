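"""Subgenome-partitioned protein database for allohexaploid wheat.

Bread wheat carries three homoeologous subgenomes (A, B, D); most genes
exist as a triplet of homoeologs, one copy per subgenome, grouped here
into "families". The database keeps every locus tagged with its
subgenome, chromosome (e.g. ``4B``) and homoeolog-family identifier so
that peptide matches can be resolved to specific homoeologs.

FASTA header contract: ``>locus_id|subgenome|chromosome|family_id``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError

SUBGENOMES = ("A", "B", "D")

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein locus with its subgenome bookkeeping tags."""

    locus_id: str
    subgenome: str
    chromosome: str
    family_id: str
    sequence: str

    def validate(self) -> None:
        if self.subgenome not in SUBGENOMES:
            raise ValidationError(
                f"{self.locus_id}: subgenome {self.subgenome!r} not one of A/B/D"
            )
        if not self.chromosome.endswith(self.subgenome):
            raise ValidationError(
                f"{self.locus_id}: chromosome {self.chromosome!r} inconsistent "
                f"with subgenome {self.subgenome!r}"
            )
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValidationError(
                f"{self.locus_id}: non-amino-acid characters {sorted(bad)}"
            )


class SubgenomeProteinDB:
    """Locus-resolved protein sequences grouped into homoeolog families.

    Parameters
    ----------
    records
        Protein records; locus ids must be unique.
    strict
        When true (default), a family with more than one locus on the
        same subgenome is rejected. In permissive mode the extra loci
        are split off into fresh single-locus families (suffix ``.pN``),
        mirroring how within-subgenome paralogs would be kept apart.
    """

    def __init__(self, records: Iterable[ProteinRecord], strict: bool = True):
        self._records: List[ProteinRecord] = []
        self._by_locus: Dict[str, ProteinRecord] = {}
        self._families: Dict[str, List[ProteinRecord]] = {}
        seen_slots: Dict[tuple, str] = {}
        n_extra = 0
        for rec in records:
            rec.validate()
            if rec.locus_id in self._by_locus:
                raise ValidationError(f"duplicate locus_id {rec.locus_id!r}")
            slot = (rec.family_id, rec.subgenome)
            if slot in seen_slots:
                if strict:
                    raise ValidationError(
                        f"family {rec.family_id!r} has >1 locus on subgenome "
                        f"{rec.subgenome!r} ({seen_slots[slot]!r}, {rec.locus_id!r})"
                    )
                n_extra += 1
                rec = ProteinRecord(
                    rec.locus_id,
                    rec.subgenome,
                    rec.chromosome,
                    f"{rec.family_id}.p{n_extra}",
                    rec.sequence,
                )
            else:
                seen_slots[slot] = rec.locus_id
            self._records.append(rec)
            self._by_locus[rec.locus_id] = rec
            self._families.setdefault(rec.family_id, []).append(rec)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self._records)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._by_locus

    @property
    def records(self) -> List[ProteinRecord]:
        return list(self._records)

    @property
    def families(self) -> Dict[str, List[ProteinRecord]]:
        return {k: list(v) for k, v in self._families.items()}

    def locus(self, locus_id: str) -> ProteinRecord:
        try:
            return self._by_locus[locus_id]
        except KeyError:
            raise KeyError(f"unknown locus_id {locus_id!r}") from None

    def family_of(self, locus_id: str) -> List[ProteinRecord]:
        return list(self._families[self.locus(locus_id).family_id])

    def family_size(self, family_id: str) -> int:
        return len(self._families[family_id])

    # ------------------------------------------------------------------ I/O

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(
                Seq(r.sequence),
                id=f"{r.locus_id}|{r.subgenome}|{r.chromosome}|{r.family_id}",
                description="",
            )
            for r in self._records
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(
        cls,
        path: str | Path,
        strict: bool = True,
        locus_map: Optional[Dict[str, tuple]] = None,
    ) -> "SubgenomeProteinDB":
        """Load a proteome FASTA.

        Headers follow ``locus|subgenome|chromosome|family``. For real
        data with plain headers, supply ``locus_map`` mapping locus id
        to ``(subgenome, chromosome, family_id)``.
        """
        records = []
        for sr in SeqIO.parse(str(path), "fasta"):
            if locus_map is not None and sr.id in locus_map:
                sg, chrom, fam = locus_map[sr.id]
                records.append(ProteinRecord(sr.id, sg, chrom, fam, str(sr.seq)))
                continue
            parts = sr.id.split("|")
            if len(parts) != 4:
                raise ValidationError(
                    f"header {sr.id!r} does not follow locus|subgenome|chromosome|family"
                )
            records.append(ProteinRecord(*parts, str(sr.seq)))
        return cls(records, strict=strict)
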