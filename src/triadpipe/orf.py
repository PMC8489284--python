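"""Small sequence utilities: strict ORF translation."""

from __future__ import annotations

from Bio.Seq import Seq

from .errors import ValidationError


def translate_orf(cds: str) -> str:
    """Translate a complete coding sequence under the standard code.

    The CDS must start with ATG, have length divisible by 3, and
    contain exactly one stop codon, at the end. Returns the protein
    (without the stop), so a valid 1566-nt CDS yields 521 residues.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValidationError(f"CDS length {len(cds)} not divisible by 3")
    if not cds.startswith("ATG"):
        raise ValidationError("CDS does not start with ATG")
    protein = str(Seq(cds).translate(table=1))
    if not protein.endswith("*"):
        raise ValidationError("CDS does not end with a stop codon")
    body = protein[:-1]
    if "*" in body:
        raise ValidationError(f"internal stop codon at residue {body.index('*') + 1}")
    return body


def random_orf(n_codons: int, rng) -> str:
    """A random valid ORF of ``n_codons`` codons (incl. start and stop).

    Used to build worked examples: ``random_orf(522, rng)`` is a
    1566-nt CDS translating to 521 residues.
    """
    import numpy as np

    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    nts = list("ACGT")
    while len(codons) < n_codons - 1:
        codon = "".join(rng.choice(nts, size=3))
        if codon not in stops:
            codons.append(codon)
    codons.append("TAA")
    return "".join(codons)
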