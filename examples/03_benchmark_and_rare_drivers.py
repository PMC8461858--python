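"""Benchmark a ranking against a known-driver list and flag rare drivers.

Uses the planted drivers of a simulated cohort as the benchmark catalog.
Precision at k is the fraction of the top k that are catalog genes; recall
divides hits by the number of catalog genes actually mutated in the cohort.
Rare drivers are top-ranked genes mutated in under 2% of patients — the genes
a pure frequency ranking would miss.
"""

from menc import (GeneSet, build_merged_graph, call_degs,
                  compute_mutation_scores, evaluate_ranking,
                  flag_rare_drivers, generate_cohort, rank_drivers)

cohort = generate_cohort(seed=11)
m = cohort.mutation
scores = compute_mutation_scores(m)
degs = call_degs(cohort.expression)
mutated = GeneSet("mutated", m.mutated_genes())
merged = build_merged_graph(cohort.ppi, mutated, degs)
ranking = rank_drivers(merged, scores, m)

curve = evaluate_ranking(ranking, cohort.planted_drivers, mutated, max_k=20)
print("k   precision  recall  F1")
for k in (1, 5, 10, 20):
    p, r, f1 = curve.at(k)
    print(f"{k:<3} {p:9.3f} {r:7.3f} {f1:5.3f}")

records = flag_rare_drivers(ranking, m, cohort.planted_drivers, top_n=20)
print(f"\n{len(records)} genes in the top 20 are mutated in <2% of patients:")
print("rank  gene      mut  freq(%)  in catalog")
for rec in records[:8]:
    print(f"{rec.rank:>4}  {rec.gene:<8} {rec.mut_count:>4}  "
          f"{rec.frequency_pct:7.3f}  {'YES' if rec.in_cgc else 'NO'}")
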