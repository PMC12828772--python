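"""Discover composition subtypes by consensus clustering and name them.

Compositions are z-scored per component, clustered with resampled PAM over
k = 2..6, the cluster count is chosen from the consensus-CDF area profile,
and the three clusters are named TCE / EPCE / TASCE by their enriched cell
types.
"""

from sklearn.metrics import adjusted_rand_score

import tmesubtypes as tms

reference = tms.generate_reference(seed=1)
cfg = tms.SimulationConfig(n_patients=300, seed=7)
expression, _, _, truth = tms.simulate_cohort(cfg, reference)

composition = tms.deconvolve_cohort(expression, reference)
z = tms.zscore(composition)
result = tms.consensus_cluster(z, k_range=(2, 6), n_resamples=250, seed=11)
k = tms.select_k(result)
naming = tms.assign_subtype_names(result.labels[3], z)

print(f"chosen number of clusters: {k}")
print(f"ARI vs planted subtypes at k=3: "
      f"{adjusted_rand_score(truth.sample_subtype.to_numpy(), result.labels[3]):.3f}")
print(f"subtype sizes: {naming.labels.value_counts().to_dict()}")
print("\nper-cluster mean z (the enrichment table behind the names):")
print(naming.enrichment.round(2))
print("\nk=3 means the cohort splits into three composition subtypes; ARI 1.0")
print("would be a perfect match with the planted labels.")
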