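"""Term-coherence validation: median-of-correlations per annotation term.

Generates a cohort with two planted modules, annotates each module as a
coherent term alongside 30 random terms, and compares the distribution of
per-term median correlations against the global background median — the
check that functionally related proteins correlate more than bulk proteins.
"""

import numpy as np

import gbacorr as g

spec = g.CohortSpec(n_proteins=400, n_samples=250,
                    modules=[(8, 0.7), (6, 0.5)],
                    missingness=g.MissingnessSpec(0.15, 1.0), seed=11)
matrix, truth = g.generate_cohort(spec)
corr = g.correlation_matrix(matrix)

ann = g.generate_annotation(truth, matrix.protein_ids,
                            n_random_terms=30, random_term_size=7, seed=12)
profiles, medians, background = g.all_term_medians(corr, ann)

coherent = [p for p in profiles if p.term_id.startswith("TERM:M")]
random_terms = [p for p in profiles if p.term_id.startswith("TERM:R")]

print("term                n_members  n_pairs  median_rho")
for p in coherent:
    print(f"{p.term_id:<20}{p.n_members_present:>9}{p.n_pairs_used:>9}"
          f"{p.median_rho:>12.3f}")
rand_meds = [p.median_rho for p in random_terms if p.median_rho is not None]
print(f"\nmedian over random-term medians: {np.median(rand_meds):+.4f}")
print(f"global background median:        {background.median:+.4f}")
print("\nCoherent (module-derived) terms sit far above the background and")
print("the random terms do not — the median-of-medians shift that validates")
print("guilt-by-association on a dataset.")
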