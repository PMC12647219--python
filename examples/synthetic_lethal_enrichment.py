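"""Pair-set enrichment: correlations of curated pairs vs the background.

Emulates a synthetic-lethal pair list: pairs drawn from inside planted
modules ("functionally related") and pairs drawn between independent
proteins, each compared with the distribution of all correlations. Also
calibrates the shift against an empirical random-set null.
"""

import gbacorr as g

spec = g.CohortSpec(n_proteins=400, n_samples=250, modules=[(10, 0.6)],
                    missingness=g.MissingnessSpec(0.15, 1.0), seed=21)
matrix, truth = g.generate_cohort(spec)
corr = g.correlation_matrix(matrix)
ids = matrix.protein_ids

related = g.generate_pair_set(truth, ids, n_planted=30, n_null=0, seed=22)
unrelated = g.generate_pair_set(truth, ids, n_planted=0, n_null=30, seed=23)

for name, ps in (("related (within-module)", related),
                 ("unrelated (independent)", unrelated)):
    res = g.pair_set_enrichment(corr, ps)
    print(f"{name:<26} set median {res.set_distribution.median:+.4f}  "
          f"background {res.background_distribution.median:+.4f}  "
          f"shift {res.shift:+.4f}")

null = g.random_set_null(corr, set_size=10, n_draws=200, seed=24)
print(f"\nrandom-set null median (200 draws of 10 proteins): {null.median:+.4f}")
print("\nA positive shift for the related pairs — absent for unrelated pairs")
print("and for random sets — is the signature of shared function in the")
print("correlation structure.")
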