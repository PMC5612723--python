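"""Correlation-based gene selection on a small synthetic cohort.

Simulates 400 genes (10% with diversity planted to track cell-type number at
rho = 0.9), correlates each gene's D_F vector with the complexity axis, and
selects genes whose Pearson r exceeds the two-tailed 5% critical value for
their orthologue count.
"""

from funcdiv import (
    SimConfig,
    build_orthologue_sets,
    cohort_summary,
    correlate_and_select,
    critical_r,
    score_all,
    simulate_dataset,
)

data = simulate_dataset(SimConfig(seed=4, n_genes=400))
scores = score_all(data.records)
osets = build_orthologue_sets(data.records)
results = correlate_and_select(osets, scores, data.species)

selected = [r for r in results if r.selected]
print(f"{len(osets)} orthologue groups, {len(results)} eligible (>= 6 orthologues)")
print(f"{len(selected)} selected ({100 * len(selected) / len(osets):.1f}% of input)\n")

print("critical r by orthologue count (two-tailed p < 0.05):")
for n in (9, 8, 7, 6):
    print(f"  n={n}: r_crit = {critical_r(n):.3f}")

print("\ncohort summary (machine twin of a first-seen stratification table):")
print(cohort_summary(results).to_string(index=False))

truth = data.truth.set_index("human_symbol")["signal"]
hits = sum(truth[r.human_symbol] for r in selected)
print(
    f"\nOf the selected genes, {hits} carry planted signal and "
    f"{len(selected) - hits} are false positives — the boundary admits about "
    "2.5% of null genes (the positive half of the two-tailed 5%)."
)
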