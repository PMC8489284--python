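# Methods

## Scope and data model

The package covers the two computational arms of a homoeolog-aware
phosphate-starvation proteomics study in hexaploid wheat, starting from
*identified* peptides with reporter-ion areas (no spectral search, FDR
control or isotope correction) and from *pre-aligned* promoter panels
(no de novo alignment). The central containers are:

* `SubgenomeProteinDB` — protein loci tagged with subgenome (A/B/D),
  chromosome (e.g. `4B`) and homoeolog family; at most one locus per
  subgenome per family (a permissive mode splits within-subgenome
  paralogs into fresh families instead of rejecting them).
* peptide quant tables — pandas DataFrames with one row per (peptide,
  source protein) and six intensity columns, CK1–3 and NP1–3.
* `PromoterPanel` — equal-length sequences with an ATG-anchored
  coordinate map: +1 is the A of ATG, upstream positions are negative,
  there is no position 0 (a window of 1514 columns spans −1513…+1).

## Peptide→homoeolog assignment

Peptide matching is exact, full-length substring search against all
locus sequences — the operational equivalent of a protein-level
alignment search with a 100% identity cutoff, without the external
dependency. Isoleucine and leucine are kept distinct by default because
the genomic database distinguishes them; an `il_equivalent` switch
collapses them for data where the isobaric ambiguity of mass
spectrometry matters. The index seeds candidates from 5-mers and
verifies by substring test; shorter queries fall back to a linear scan.
An oracle test asserts equality with a naive scan.

Assignment is deliberately conservative: a protein is placed on
specific homoeologs only through locus-unique peptides, and those must
all fall within one family (contradictory unique evidence raises a
conflict that the pipeline reports and excludes). Proteins supported
only by family-shared peptides keep their family but stay unassigned —
we chose the strict unique-peptide rule because shared peptides cannot,
even in principle, distinguish near-identical homoeologs. Bias classes
follow from the assigned locus set: `single_bias` (one locus detected,
family has ≥2), `singleton` (family has exactly one locus), `multi`
(≥2 loci detected). Reported percentages use half-up rounding to one
decimal, computed with exact decimal arithmetic so that counts such as
738/1015 and 62/1015 print as 72.7% and 6.1%.

Chromosome distributions count one per assigned locus, so a
two-homoeolog protein contributes to two chromosomes; this is the
reading under which per-chromosome totals can exceed the number of
assigned proteins.

## Quantification and responsive-protein calling

Protein abundance per channel is the sum of reporter areas over the
protein's locus-unique peptides. The fold change is

    ratio = mean_i( NP_i / mean(CK) ),

chosen because it is robust to a single noisy treatment channel and
recovers a planted fold change exactly in the noise-free limit. Calls
use inclusive thresholds, up ≥ 1.20 and down ≤ 0.83, applied to the
ratio alone by default; a two-sided pooled Student's t-test on
natural-log abundances is always computed and can additionally gate
calls (`p_filter_enabled`). Proteins missing any channel are
`not_quantified` when all replicates are required. Channel
normalisation (total-sum or median equalisation) is available but off
by default, since the simulator generates channels on a common scale.

Concordance between two quantification runs (e.g. discovery vs
targeted validation) counts a protein as concordant when both the sign
of its log ratio and its regulation class agree.

## Homoeolog balance

For proteins expressed from 2–3 homoeologs, locus-resolved abundances
(unique peptides only) are compared across loci by one-way ANOVA on
log abundances; p < α (default 0.05) calls the family unbalanced. With
two loci this is exactly the pooled t-test (F = t²), so one procedure
serves both family sizes. All six channels feed the test by default;
`condition="control"`/`"treatment"` restricts it, since a planted
treatment effect differing between loci otherwise contributes to the
between-locus signal. Families lacking usable abundances for ≥2 loci
are reported untestable rather than silently dropped.

## Statistical primitives

`student_t` (pooled default, Welch optional) and `one_way_anova` wrap
scipy with explicit degenerate-case conventions: identical constant
samples give t = 0, p = 1; zero within-group variance with unequal
means gives F = ∞, p = 0. Duncan's multiple range test computes its
critical points from the studentized range quantile at Duncan's
protection level 1 − (1 − α)^(p−1) — no shipped tables, any error df —
with the harmonic mean group size for unbalanced designs, and assigns
letters by the standard step-down rule: the range spanning p ordered
means is homogeneous when it does not exceed R_p, and homogeneous
ranges are not subdivided. Null p-values of the t-test are checked for
uniformity by a Kolmogorov–Smirnov test in the suite.

## Promoter population genetics

SNP calling reports columns with ≥2 distinct unambiguous alleles;
columns containing gaps or N are excluded outright under the default
complete-deletion policy (deterministic effective length, the standard
choice for diversity estimation), with pairwise deletion available.
Nucleotide diversity is the Nei–Li average pairwise difference per
used site; for haplotype-resolved panels this coincides with the
frequency-weighted per-site heterozygosity form, so no separate
estimator is provided. Haplotype labels are ordered by descending
frequency with first-occurrence tie-breaking, and the pattern table
reports each haplotype's SNP-count difference from the most frequent
haplotype (the reference). Sequences with N at a variant site are
matched N-tolerantly and labelled `ambiguous` only when more than one
known pattern is compatible. Trait association runs ANOVA plus Duncan
letters per haplotype, excluding haplotypes with fewer than two
phenotyped lines.

## CAPS design

Recognition sites are scanned under IUPAC expansion with overlaps
allowed and every cut applied; N in the target never matches. For
non-palindromic recognitions the bottom strand is scanned as well and
reported with a strand flag (Fnu4HI's GCNGC is its own reverse
complement, so one pass suffices). Fragment sizes derive from
top-strand cut positions only — overhangs shift band sizes by at most
a few bases and never change the cut/uncut readout. Candidate markers
are sites present in exactly one allele, sorted by the total absolute
difference of the size-sorted fragment patterns as a crude gel
resolvability score. The enzyme table ships as an editable TSV seeded
with Fnu4HI and a few common enzymes; it is not a full commercial
catalogue.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of their spec (seed included); equal
specs give byte-identical output.

* **Proteome**: homoeolog triplets derive from a random ancestral
  sequence by i.i.d. substitutions at `homoeolog_divergence`
  (default 0.05/site, enough that typical tryptic peptides are
  locus-unique); `singleton_fraction` defaults to 0.061, the singleton
  share among assigned wheat root proteins; family i sits on
  homoeologous group (i mod 7) + 1, and a singleton's subgenome is
  drawn uniformly. Real homoeologs share domain structure and indels;
  the i.i.d. model only reproduces peptide-sharing rates, which is
  what the mapping logic consumes.
* **Reporter intensities**: per-family log-uniform baseline (10^4.5 to
  10^6), per-locus log-normal deviation (`locus_abundance_sd`,
  default 0.5; 0 gives exactly balanced homoeologs), per-peptide
  ionisation efficiency, and per-channel multiplicative log-normal
  noise with median 1 and the configured coefficient of variation —
  the standard error model for reporter areas, which keeps planted
  fold changes unbiased at cv = 0. Missing values, interference and
  ratio compression are not modelled, so passing calibration tests
  demonstrates correctness of the calling logic, not robustness to
  every artefact of real reporter data.
* **Promoter panel**: 62 sequences × 1514 columns with 9 SNP positions
  whose alternative alleles are split 6/2/1 across three non-reference
  haplotypes; haplotype counts 27/15/12/8 (per-haplotype frequencies
  are not published, so the reference haplotype was fixed as the most
  frequent once and not revisited). The −799/−796 reference alleles
  complete a GCNGC context so the promoter and CAPS fixtures agree.
* **CAPS amplicon**: 703 bp, designed site at position 455 (top-strand
  cut at 457, giving the 457 + 246 bp split), stray background sites
  scrubbed deterministically and identically in both alleles so the
  alleles differ only at the SNPs.

## Problem sizes and numerical choices

Calibration checks use 67 triplet families (~201 proteins) for the
responsive-protein caller and 1000 simulated families for the balance
test's false-positive rate, sizes at which Monte-Carlo error is small
relative to the tested margins. Demo runs default to 150 families.
p = 0 is clipped to the smallest positive double before −log10 for
volcano coordinates. ORF translation is strict: ATG start, length a
multiple of three, exactly one terminal stop; a valid CDS of length L
yields L/3 − 1 residues (so the minimal ORF `ATGTAA` translates to a
single methionine).

## Known limitations

No spectral-level simulation, no FDR control across proteins, no
proportional allocation of shared peptides, no primer design or
thermodynamics in the CAPS arm, and no neutrality statistics beyond π.
Printed diversity values from real cultivar panels depend on the
original panel's sequences and deletion policy and are therefore not
reproduced here; only the estimator's definition is.
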