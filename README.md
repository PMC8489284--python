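# triadpipe

Homoeolog-aware quantitative proteomics and promoter population
genetics for allohexaploid bread wheat (*Triticum aestivum*, genomes
BBAADD), built for studies of phosphate (Pi) starvation responses but
applicable to any treatment/control reporter design on a polyploid.

Bread wheat carries three homoeologous subgenomes (A, B, D); most genes
exist as a triplet of near-identical homoeologs. When root proteins are
quantified by isobaric reporter tags (iTRAQ-style, 3 control "CK" + 3
Pi-starved "NP" replicates), two questions arise that this package
answers computationally:

1. **Which homoeolog is actually expressed?** Peptides are matched
   against a subgenome-partitioned protein database at 100% identity
   (exact substring matching). Only *locus-unique* peptides place a
   protein on a specific homoeolog; a protein detected from just one of
   its 2–3 homoeologs shows *homoeolog expression bias*. Proteins whose
   abundance ratio r = mean_i(NP_i / mean(CK)) satisfies r ≥ 1.20 or
   r ≤ 0.83 (inclusive) are called Pi-deficiency-responsive; for
   proteins expressed from several homoeologs, balance across loci is
   tested by one-way ANOVA on log abundances (two loci reduce to
   Student's t, F = t²).

2. **Which promoter variant is worth breeding for?** For a panel of
   aligned promoter sequences the package calls SNPs, estimates Nei–Li
   nucleotide diversity π = Σ_{i<j} d_ij / (C(n,2)·L), groups identical
   allele vectors into haplotypes, associates haplotypes with traits
   (ANOVA + Duncan's multiple range test), and designs CAPS markers:
   restriction sites, found by IUPAC-degenerate scanning (e.g. Fnu4HI,
   GCNGC), that exist in exactly one allele of a PCR amplicon so the
   digest pattern genotypes the haplotype on a gel.

A synthetic-data module generates every input — homoeolog triplet
families with tunable divergence, reporter tables with planted fold
changes and log-normal noise, a 62-line promoter panel with 9 SNPs
forming 4 haplotypes, and a 703-bp amplicon with an allele-dependent
Fnu4HI site — so the entire pipeline is testable with no downloads and
known ground truth.

## Worked example

```python
from triadpipe import (CapsFixtureSpec, FNU4HI, digest,
                       generate_caps_fixture, generate_promoter_panel,
                       call_variant_sites, group_haplotypes,
                       nucleotide_diversity)

panel = generate_promoter_panel(seed=3)          # 62 aligned promoters
snps = call_variant_sites(panel)
print(snps.n_sites)                              # 9
print(nucleotide_diversity(panel).pi)            # 2.048e-03
g = group_haplotypes(snps)
print(g.n_haplotypes)                            # 4
print(list(g.patterns["diffs_vs_hap1"]))         # [0, 6, 2, 1]

cut, uncut = generate_caps_fixture(CapsFixtureSpec(seed=0))
print(digest(cut, FNU4HI))                       # [457, 246]
print(digest(uncut, FNU4HI))                     # [703]
```

Nine SNPs partition the 62 lines into four haplotypes; Hap2/Hap3/Hap4
differ from the most frequent haplotype by 6, 2 and 1 SNPs. The two
linked SNPs carried by Hap3 destroy the Fnu4HI site, so its 703-bp
amplicon stays intact while the other haplotypes' amplicons cut into
457 + 246 bp — a codominant CAPS marker.

The `examples/` directory holds one short narrative script per
capability (peptide mapping, responsive-protein calling, bias
classification, promoter diversity, CAPS design). A thin CLI is also
installed:

```bash
triadpipe demo --seed 1 --outdir out/        # run every stage, write TSV reports
triadpipe diversity promoters.fasta          # pi + SNP count for an aligned FASTA
triadpipe translate ATGAAATTTTGA             # strict ORF translation
```

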