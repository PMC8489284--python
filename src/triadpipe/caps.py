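"""In-silico restriction digestion and CAPS marker design.

A CAPS (cleaved amplified polymorphic sequence) marker genotypes a SNP
by amplifying the surrounding region and digesting the amplicon with a
restriction endonuclease whose recognition site is created or destroyed
by the SNP. The design step screens enzymes for sites present in
exactly one allele of the amplicon and predicts the gel band pattern
(fragment lengths) for each allele.

Recognition sequences may contain IUPAC degeneracy codes (e.g. Fnu4HI
recognises ``GCNGC``). ``N`` in the *target* sequence never matches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

from .errors import ValidationError

# IUPAC nucleotide codes expanded over the unambiguous alphabet only:
# an N (or any ambiguity) in the scanned sequence is never a match.
IUPAC: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Enzyme:
    """Restriction endonuclease: IUPAC recognition plus top-strand cut offset.

    ``cut_offset`` counts bases from the site start to the top-strand
    cut position (0 = cut immediately before the site).
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self):
        bad = set(self.recognition.upper()) - set(IUPAC)
        if bad:
            raise ValidationError(
                f"enzyme {self.name}: invalid IUPAC codes {sorted(bad)}"
            )
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValidationError(
                f"enzyme {self.name}: cut_offset {self.cut_offset} outside "
                f"[0, {len(self.recognition)}]"
            )
        object.__setattr__(self, "recognition", self.recognition.upper())

    @property
    def is_palindromic(self) -> bool:
        """True when the recognition equals its own reverse complement."""
        return self.recognition == reverse_complement(self.recognition)

    def _regex(self) -> re.Pattern:
        # Lookahead so overlapping sites are all reported.
        body = "".join(f"[{IUPAC[c]}]" for c in self.recognition)
        return re.compile(f"(?=({body}))")


FNU4HI = Enzyme("Fnu4HI", "GCNGC", 2)


@dataclass(frozen=True)
class Site:
    """One recognition-site hit: 0-based start on the given strand."""

    position: int
    strand: str = "+"


def find_sites(seq: str, enzyme: Enzyme) -> List[Site]:
    """All recognition-site positions in ``seq`` (0-based, overlap-allowed).

    Top-strand matches carry strand ``+``. For non-palindromic
    recognitions the bottom strand is scanned too and hits are reported
    with strand ``-`` at their top-strand start coordinate.
    """
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValidationError(f"sequence contains non-ACGTN characters {sorted(bad)}")
    pattern = enzyme._regex()
    sites = [Site(m.start(), "+") for m in pattern.finditer(seq)]
    if not enzyme.is_palindromic:
        m = len(enzyme.recognition)
        rc = reverse_complement(seq)
        for hit in pattern.finditer(rc):
            sites.append(Site(len(seq) - hit.start() - m, "-"))
    return sorted(sites, key=lambda s: (s.position, s.strand))


def cut_positions(seq: str, enzyme: Enzyme) -> List[int]:
    """Deduplicated, sorted top-strand cut coordinates (0 < c < len)."""
    cuts = set()
    m = len(enzyme.recognition)
    for site in find_sites(seq, enzyme):
        if site.strand == "+":
            c = site.position + enzyme.cut_offset
        else:
            c = site.position + (m - enzyme.cut_offset)
        if 0 < c < len(seq):
            cuts.add(c)
    return sorted(cuts)


def digest(seq: str, enzyme: Enzyme) -> List[int]:
    """Ordered fragment lengths after complete digestion.

    No site means a single full-length fragment; fragment lengths always
    sum to ``len(seq)``.
    """
    cuts = cut_positions(seq, enzyme)
    bounds = [0] + cuts + [len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


@dataclass(frozen=True)
class CandidateMarker:
    """A site present in exactly one allele, with both predicted digests."""

    enzyme: Enzyme
    position: int
    strand: str
    present_in: str  # "A" or "B"
    fragments_a: Tuple[int, ...]
    fragments_b: Tuple[int, ...]

    @property
    def resolvability(self) -> int:
        """Crude gel-separability score: total absolute difference of the
        size-sorted fragment patterns (padded with zeros)."""
        fa = sorted(self.fragments_a, reverse=True)
        fb = sorted(self.fragments_b, reverse=True)
        n = max(len(fa), len(fb))
        fa += [0] * (n - len(fa))
        fb += [0] * (n - len(fb))
        return sum(abs(x - y) for x, y in zip(fa, fb))


def design_caps(
    allele_a: str, allele_b: str, enzymes: Sequence[Enzyme]
) -> List[CandidateMarker]:
    """Screen enzymes for allele-discriminating sites.

    For each enzyme, recognition sites present in exactly one of the two
    equal-length amplicons become candidate markers, each annotated with
    the complete predicted digest of both alleles. Candidates are sorted
    by decreasing fragment-pattern difference (gel resolvability).
    """
    if len(allele_a) != len(allele_b):
        raise ValidationError("amplicons must have equal length")
    candidates: List[CandidateMarker] = []
    for enzyme in enzymes:
        sites_a = {(s.position, s.strand) for s in find_sites(allele_a, enzyme)}
        sites_b = {(s.position, s.strand) for s in find_sites(allele_b, enzyme)}
        if sites_a == sites_b:
            continue
        frags_a = tuple(digest(allele_a, enzyme))
        frags_b = tuple(digest(allele_b, enzyme))
        for pos, strand in sorted(sites_a ^ sites_b):
            present = "A" if (pos, strand) in sites_a else "B"
            candidates.append(
                CandidateMarker(enzyme, pos, strand, present, frags_a, frags_b)
            )
    return sorted(candidates, key=lambda c: -c.resolvability)


def load_enzymes(path: str | Path | None = None) -> List[Enzyme]:
    """Read the enzyme table (TSV: name, recognition, cut_offset).

    Defaults to the small table shipped with the package, seeded with
    Fnu4HI and a few common second-choice enzymes.
    """
    if path is None:
        source = resources.files("triadpipe").joinpath("data/enzymes.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    enzymes = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "name":
            continue
        if len(fields) != 3:
            raise ValidationError(f"bad enzyme table row: {line!r}")
        enzymes.append(Enzyme(fields[0], fields[1], int(fields[2])))
    return enzymes
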