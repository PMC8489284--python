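"""Synthetic data with the statistical structure the analyses assume.

Everything downstream — peptide→homoeolog mapping, reporter-based
differential abundance, promoter diversity, CAPS design — is testable
against data generated here, with planted ground truth. All generators
are pure functions of their spec (seed included): the same spec yields
byte-identical output.

The proteome generator emulates a subgenome-partitioned hexaploid
protein database: homoeolog triplet families (one locus per A/B/D
subgenome) derived from a common ancestral sequence by i.i.d.
substitutions, plus a fraction of single-locus families. The iTRAQ
generator emulates a 3 control (CK) + 3 phosphate-starved (NP)
replicate reporter design with multiplicative log-normal noise and
planted per-protein fold changes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .caps import FNU4HI, Enzyme, find_sites
from .errors import ConfigurationError, ValidationError
from .popgen import PromoterPanel, default_positions
from .proteome import AMINO_ACIDS, ProteinRecord, SubgenomeProteinDB, SUBGENOMES

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"


@dataclass(frozen=True)
class ReplicateDesign:
    """Reporter channel layout: 3 control + 3 treatment replicates."""

    n_control: int = 3
    n_treatment: int = 3
    control_label: str = "CK"
    treatment_label: str = "NP"

    @property
    def control_channels(self) -> List[str]:
        return [f"{self.control_label}{i + 1}" for i in range(self.n_control)]

    @property
    def treatment_channels(self) -> List[str]:
        return [f"{self.treatment_label}{i + 1}" for i in range(self.n_treatment)]

    @property
    def channels(self) -> List[str]:
        return self.control_channels + self.treatment_channels


@dataclass
class SimulationSpec:
    """Parameters of the synthetic proteomics experiment.

    ``homoeolog_divergence`` is the expected substitutions per site
    between a homoeolog and the family's ancestral sequence;
    ``singleton_fraction`` is the probability a family has a single
    locus (default 0.061, the singleton share observed among assigned
    wheat root proteins); ``cv`` is the coefficient of variation of the
    multiplicative log-normal reporter noise; ``planted_effects`` maps
    locus id → true treatment/control fold change (unlisted loci have
    fold change 1).
    """

    seed: int = 0
    n_families: int = 200
    homoeolog_divergence: float = 0.05
    singleton_fraction: float = 0.061
    protein_length_range: Tuple[int, int] = (150, 600)
    design: ReplicateDesign = field(default_factory=ReplicateDesign)
    planted_effects: Dict[str, float] = field(default_factory=dict)
    cv: float = 0.1
    # Log-scale sd of a locus's deviation from its family's baseline
    # abundance; 0 makes homoeologs of a family exactly balanced.
    locus_abundance_sd: float = 0.5

    def __post_init__(self):
        if self.locus_abundance_sd < 0:
            raise ConfigurationError("locus_abundance_sd must be ≥ 0")
        if not 0 <= self.homoeolog_divergence < 1:
            raise ConfigurationError("homoeolog_divergence must be in [0, 1)")
        if not 0 <= self.singleton_fraction <= 1:
            raise ConfigurationError("singleton_fraction must be in [0, 1]")
        if self.cv < 0:
            raise ConfigurationError("cv must be ≥ 0")
        lo, hi = self.protein_length_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("empty protein_length_range")
        if self.n_families < 0:
            raise ConfigurationError("n_families must be ≥ 0")
        if any(fc <= 0 for fc in self.planted_effects.values()):
            raise ConfigurationError("planted fold changes must be > 0")


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate == 0:
        return seq.copy()
    out = seq.copy()
    mask = rng.random(seq.size) < rate
    for i in np.nonzero(mask)[0]:
        choices = [a for a in _AA if a != seq[i]]
        out[i] = choices[rng.integers(len(choices))]
    return out


def generate_subgenome_proteome(spec: SimulationSpec) -> SubgenomeProteinDB:
    """Simulate a subgenome-partitioned proteome of homoeolog families.

    Each family carries one locus per subgenome (A/B/D) derived from a
    common ancestral random sequence by i.i.d. substitutions at the
    configured divergence, unless sampled as a singleton, in which case
    the single subgenome is drawn uniformly. Family i sits on
    homoeologous chromosome group (i mod 7) + 1; locus ids read
    ``F0012.3B`` (family, group, subgenome).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.protein_length_range
    records: List[ProteinRecord] = []
    for i in range(spec.n_families):
        family = f"F{i:04d}"
        group = i % 7 + 1
        length = int(rng.integers(lo, hi + 1))
        ancestral = rng.choice(list(_AA), size=length)
        if rng.random() < spec.singleton_fraction:
            subgenomes = [SUBGENOMES[rng.integers(3)]]
        else:
            subgenomes = list(SUBGENOMES)
        for sg in subgenomes:
            seq = "".join(_mutate(ancestral, spec.homoeolog_divergence, rng))
            records.append(
                ProteinRecord(
                    locus_id=f"{family}.{group}{sg}",
                    subgenome=sg,
                    chromosome=f"{group}{sg}",
                    family_id=family,
                    sequence=seq,
                )
            )
    return SubgenomeProteinDB(records)


_CLEAVE = re.compile(r"(?<=[KR])(?!P)")


def tryptic_digest(
    protein: str,
    min_len: int = 6,
    max_len: int = 50,
    missed_cleavages: int = 0,
) -> List[str]:
    """In-silico trypsin digestion: cleave after K/R except before P.

    Returns peptides in N→C order (for each start, increasing missed
    cleavage count), filtered to ``[min_len, max_len]``. With
    ``missed_cleavages = m`` every concatenation of ≤ m+1 consecutive
    fully-cleaved fragments is considered.
    """
    if not protein:
        return []
    bad = set(protein) - AMINO_ACIDS
    if bad:
        raise ValidationError(f"non-amino-acid characters {sorted(bad)}")
    fragments = [f for f in _CLEAVE.split(protein) if f]
    peptides = []
    for i in range(len(fragments)):
        for m in range(missed_cleavages + 1):
            if i + m >= len(fragments):
                break
            pep = "".join(fragments[i : i + m + 1])
            if min_len <= len(pep) <= max_len:
                peptides.append(pep)
    return peptides


def simulate_itraq_experiment(
    db: SubgenomeProteinDB,
    spec: SimulationSpec,
    max_peptides_per_protein: int = 8,
    peptide_min_len: int = 6,
    peptide_max_len: int = 50,
) -> pd.DataFrame:
    """Simulate identified-peptide reporter intensities for a proteome.

    Each family gets a log-uniform baseline abundance; each locus
    deviates from it by a log-normal factor with log-scale sd
    ``locus_abundance_sd`` (0 ⇒ homoeologs exactly balanced). A locus's
    tryptic peptides (up to ``max_peptides_per_protein``, sampled without
    replacement) inherit that baseline scaled by a per-peptide
    ionisation efficiency. Treatment channels are multiplied by the
    planted fold change; every channel intensity carries independent
    log-normal noise with the spec's coefficient of variation (median
    1, so the expected protein-level ratio equals the planted fold
    change and is exact at cv = 0).

    Returns a peptide quant table: one row per (peptide, source locus)
    with columns ``peptide``, ``protein_id``, then one per channel.
    """
    unknown = [k for k in spec.planted_effects if k not in db]
    if unknown:
        raise ConfigurationError(f"planted_effects reference unknown loci: {unknown}")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    sigma = float(np.sqrt(np.log1p(spec.cv**2)))
    design = spec.design
    n_ck, n_np = design.n_control, design.n_treatment
    rows = []
    family_base: Dict[str, float] = {}
    for rec in db:
        fc = spec.planted_effects.get(rec.locus_id, 1.0)
        if rec.family_id not in family_base:
            family_base[rec.family_id] = 10.0 ** rng.uniform(4.5, 6.0)
        base = family_base[rec.family_id] * float(
            np.exp(rng.normal(0.0, spec.locus_abundance_sd))
            if spec.locus_abundance_sd > 0
            else 1.0
        )
        peptides = tryptic_digest(rec.sequence, peptide_min_len, peptide_max_len, 0)
        if len(peptides) > max_peptides_per_protein:
            idx = np.sort(
                rng.choice(len(peptides), size=max_peptides_per_protein, replace=False)
            )
            peptides = [peptides[i] for i in idx]
        for pep in peptides:
            efficiency = float(np.exp(rng.normal(0.0, 0.4)))
            mu = base * efficiency
            if spec.cv > 0:
                noise = np.exp(rng.normal(0.0, sigma, size=n_ck + n_np))
            else:
                noise = np.ones(n_ck + n_np)
            ck = mu * noise[:n_ck]
            np_ = mu * fc * noise[n_ck:]
            rows.append([pep, rec.locus_id, *ck, *np_])
    return pd.DataFrame(rows, columns=["peptide", "protein_id"] + design.channels)


# --------------------------------------------------------------------------
# Promoter panel fixture
# --------------------------------------------------------------------------

# Default promoter variation: 9 SNP positions forming 4 haplotypes.
# Relative to the reference haplotype (Hap1), Hap2 differs at six
# positions, Hap3 at two (the −799/−796 C→G pair that destroys the
# Fnu4HI site) and Hap4 at one.
DEFAULT_SNPS: Dict[int, Tuple[str, str]] = {  # position → (ref, alt)
    -1350: ("T", "C"),
    -1105: ("A", "G"),
    -890: ("G", "T"),
    -799: ("C", "G"),
    -796: ("C", "G"),
    -620: ("C", "A"),
    -281: ("A", "T"),
    -150: ("G", "A"),
    -45: ("T", "G"),
}
_HAP2_POSITIONS = (-1350, -1105, -890, -620, -281, -150)
_HAP3_POSITIONS = (-799, -796)
_HAP4_POSITIONS = (-45,)


def default_haplotype_patterns() -> List[Dict[int, str]]:
    """Four promoter haplotype patterns differing from Hap1 by 6/2/1 SNPs."""
    hap1 = {pos: ref for pos, (ref, _) in DEFAULT_SNPS.items()}
    hap2 = dict(hap1)
    for pos in _HAP2_POSITIONS:
        hap2[pos] = DEFAULT_SNPS[pos][1]
    hap3 = dict(hap1)
    for pos in _HAP3_POSITIONS:
        hap3[pos] = DEFAULT_SNPS[pos][1]
    hap4 = dict(hap1)
    for pos in _HAP4_POSITIONS:
        hap4[pos] = DEFAULT_SNPS[pos][1]
    return [hap1, hap2, hap3, hap4]


DEFAULT_HAPLOTYPE_COUNTS = (27, 15, 12, 8)  # 62 lines; Hap1 most frequent


def _apportion(frequencies: Sequence[float], n: int) -> List[int]:
    """Largest-remainder rounding of frequencies to integer counts."""
    raw = [f * n for f in frequencies]
    counts = [int(np.floor(r)) for r in raw]
    remainders = sorted(
        range(len(raw)), key=lambda i: (raw[i] - counts[i]), reverse=True
    )
    for i in remainders[: n - sum(counts)]:
        counts[i] += 1
    return counts


def generate_promoter_panel(
    n_seqs: int = 62,
    length: int = 1514,
    haplotype_patterns: Optional[Sequence[Dict[int, str]]] = None,
    frequencies: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> PromoterPanel:
    """Simulate an aligned promoter panel carrying planted haplotypes.

    The default fixture is 62 equal-length sequences over the window
    −1513…+1 (ATG-anchored) carrying 9 SNP positions that form 4
    haplotypes whose SNP-count differences from the reference pattern
    are 6, 2 and 1. Sequences within a haplotype are identical; the
    background is random but shared, with a concrete ``GCAGC`` context
    around −800 so the −799/−796 reference alleles complete an Fnu4HI
    site.
    """
    patterns = (
        list(haplotype_patterns)
        if haplotype_patterns is not None
        else default_haplotype_patterns()
    )
    if frequencies is None:
        if len(patterns) == len(DEFAULT_HAPLOTYPE_COUNTS):
            frequencies = [c / sum(DEFAULT_HAPLOTYPE_COUNTS) for c in DEFAULT_HAPLOTYPE_COUNTS]
        else:
            frequencies = [1.0 / len(patterns)] * len(patterns)
    if len(frequencies) != len(patterns):
        raise ConfigurationError("frequencies and patterns differ in length")
    if abs(sum(frequencies) - 1.0) > 1e-9:
        raise ConfigurationError("frequencies must sum to 1")
    key_sets = {frozenset(p) for p in patterns}
    if len(key_sets) != 1:
        raise ConfigurationError("all patterns must share the same SNP position set")
    for pat in patterns:
        for pos, allele in pat.items():
            if allele not in _NT:
                raise ConfigurationError(f"invalid allele {allele!r} at {pos}")

    positions = default_positions(length)
    col_of = {pos: i for i, pos in enumerate(positions)}
    snp_positions = sorted(patterns[0], reverse=False)
    missing = [p for p in snp_positions if p not in col_of]
    if missing:
        raise ConfigurationError(f"SNP positions outside the panel window: {missing}")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    background = rng.choice(list(_NT), size=length)
    background[-1] = "A"  # +1 = A of ATG
    # Fixed context so the reference −799/−796 alleles sit in G C n G C.
    for pos, base in ((-800, "G"), (-798, "A"), (-797, "G")):
        if pos in col_of:
            background[col_of[pos]] = base

    counts = _apportion(frequencies, n_seqs)
    ids, seqs = [], []
    line = 0
    for pat, count in zip(patterns, counts):
        hap_seq = background.copy()
        for pos, allele in pat.items():
            hap_seq[col_of[pos]] = allele
        hap_str = "".join(hap_seq)
        for _ in range(count):
            line += 1
            ids.append(f"cv{line:03d}")
            seqs.append(hap_str)
    return PromoterPanel(ids, seqs, positions)


# --------------------------------------------------------------------------
# CAPS amplicon fixture
# --------------------------------------------------------------------------


@dataclass
class CapsFixtureSpec:
    """A two-allele amplicon pair with an allele-dependent restriction site.

    The default is a 703-bp amplicon where the cut allele carries a
    single Fnu4HI site whose degenerate positions are completed by the
    two C alleles of the −799/−796 SNP pair; the uncut allele carries
    the G alleles and no site at all. The site is placed so that the
    cut allele digests into 457 + 246 bp.
    """

    amplicon_length: int = 703
    enzyme: Enzyme = field(default_factory=lambda: FNU4HI)
    site_start: int = 455
    snp_site_offsets: Tuple[int, ...] = (1, 4)
    cut_bases: Tuple[str, ...] = ("C", "C")
    uncut_bases: Tuple[str, ...] = ("G", "G")
    seed: int = 0

    def __post_init__(self):
        m = len(self.enzyme.recognition)
        if m > self.amplicon_length:
            raise ConfigurationError("recognition longer than amplicon")
        if not 0 <= self.site_start <= self.amplicon_length - m:
            raise ConfigurationError("site_start outside amplicon")
        if len(self.snp_site_offsets) != len(self.cut_bases) or len(
            self.cut_bases
        ) != len(self.uncut_bases):
            raise ConfigurationError("SNP offset/base lists differ in length")
        if any(not 0 <= o < m for o in self.snp_site_offsets):
            raise ConfigurationError("SNP offsets must fall inside the site")


def generate_caps_fixture(spec: CapsFixtureSpec) -> Tuple[str, str]:
    """Build (cut_allele, uncut_allele) amplicons for a CAPS marker.

    The cut allele contains exactly one recognition site, spanning the
    SNP positions; the uncut allele contains none. The two alleles
    differ only at the SNP positions. Stray sites arising in the random
    background are scrubbed deterministically.
    """
    m = len(spec.enzyme.recognition)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    seq = rng.choice(list(_NT), size=spec.amplicon_length)
    # Concretize the recognition site (first base of each IUPAC class).
    from .caps import IUPAC

    site_region = range(spec.site_start, spec.site_start + m)
    for k, code in enumerate(spec.enzyme.recognition):
        seq[spec.site_start + k] = IUPAC[code][0]
    cut = seq.copy()
    for offset, base in zip(spec.snp_site_offsets, spec.cut_bases):
        cut[spec.site_start + offset] = base
    uncut = seq.copy()
    for offset, base in zip(spec.snp_site_offsets, spec.uncut_bases):
        uncut[spec.site_start + offset] = base

    # Scrub stray sites (outside the designed one) from both alleles in
    # lockstep so the alleles keep differing only at the SNPs.
    for _ in range(10 * spec.amplicon_length):
        stray = None
        for allele in (cut, uncut):
            for site in find_sites("".join(allele), spec.enzyme):
                if allele is cut and site.position == spec.site_start:
                    continue
                stray = site
                break
            if stray:
                break
        if stray is None:
            break
        # Mutate one background base inside the stray site, at a
        # position whose recognition code actually constrains the base
        # (mutating under an N would not break the match).
        for k in range(m):
            pos = stray.position + k
            code = spec.enzyme.recognition[k]
            if pos not in site_region and code != "N":
                allowed = IUPAC[code]
                replacement = next(b for b in "TAGC" if b not in allowed)
                cut[pos] = replacement
                uncut[pos] = replacement
                break
        else:
            raise ConfigurationError("cannot scrub a stray site overlapping the design")
    else:
        raise ConfigurationError("failed to build a unique-site amplicon")

    cut_s, uncut_s = "".join(cut), "".join(uncut)
    cut_sites = [s.position for s in find_sites(cut_s, spec.enzyme)]
    if cut_sites != [spec.site_start] or find_sites(uncut_s, spec.enzyme):
        raise ConfigurationError("fixture construction failed its own invariants")
    return cut_s, uncut_s
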