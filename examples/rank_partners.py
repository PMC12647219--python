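"""Guilt-by-association ranking: recover a planted module from a cohort.

Builds a synthetic 300-protein × 200-sample cohort containing one
co-regulated 8-protein module (target intra-module Spearman 0.7) with 20%
detection-limit missingness, correlates everything against everything, and
prints the top-10 association list for a module member used as the query.
"""

import gbacorr as g

spec = g.CohortSpec(
    n_proteins=300, n_samples=200, modules=[(8, 0.7)],
    missingness=g.MissingnessSpec(global_rate=0.2, detection_slope=1.0),
    seed=7,
)
matrix, truth = g.generate_cohort(spec)
corr = g.correlation_matrix(matrix)

query = truth.module_members[0][0]
top10 = g.top_k(g.rank_associations(corr, query), 10)

print(f"query: {query}  (true module: {', '.join(truth.module_members[0])})")
print(top10.entries.to_string(index=False))
partners = set(truth.module_members[0]) - {query}
found = partners & set(top10.entries["partner_id"])
print(f"\n{len(found)}/7 true module partners rank in the top 10: the query's"
      "\nco-regulated partners stand far above the independent background,"
      "\nwhich is how correlation ranking flags shared-pathway candidates.")
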