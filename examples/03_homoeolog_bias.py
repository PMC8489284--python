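"""Classify homoeolog expression bias and test balance across loci.

Runs the full demo pipeline: families express 1-3 of their homoeologs,
peptide evidence assigns each detected protein to its expressed loci,
and multi-homoeolog proteins are tested for balanced expression by
one-way ANOVA on log abundances.
"""

from triadpipe import PipelineConfig, run_demo
from triadpipe.mapping import round_percent

res = run_demo(seed=8, config=PipelineConfig(n_families=100))
summary = res["assignment_summary"]

print(f"{summary.assigned} proteins assigned to specific homoeologs")
for flag in ("single_bias", "singleton", "multi"):
    n = summary.bias_counts.get(flag, 0)
    print(f"  {flag:<12s} {n:>4d} ({round_percent(n, summary.assigned)}%)")

print("\nper-category counts (which subgenomes contribute):")
for cat, n in sorted(summary.category_counts.items()):
    print(f"  {cat:<6s} {n}")

balance = res["balance"]
unbalanced = (balance["balance"] == "unbalanced").sum()
print(f"\nmulti-homoeolog families tested for balance: {len(balance)}")
print(f"unbalanced at p < 0.05: {unbalanced}")
# single_bias dominates: most families are detected from only one of
# their 2-3 homoeologs, the hallmark of homoeolog expression bias.
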