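"""Alpha diversity across groups: Fisher's alpha and rarefied Shannon.

Computes Fisher's log-series alpha per sample on the whole community and
on each sample's core-only / satellite-only submatrix, then tests for
group differences with Kruskal-Wallis (pairwise Mann-Whitney U,
Bonferroni-adjusted).
"""

from coresat import (SimulationConfig, simulate_counts, partition_all_groups,
                     diversity_by_group, fishers_alpha)

m, _ = simulate_counts(SimulationConfig(seed=7))
parts = partition_all_groups(m)

res = diversity_by_group(m, parts, metric="fisher")
print("Fisher's alpha, group means by stratum:")
means = res.values.groupby(["stratum", "group"])["value"].mean()
print(means.round(2).to_string())
print("\nKruskal-Wallis across groups:")
for stratum, t in res.omnibus.items():
    print(f"  {stratum:10s} H={t.statistic:6.2f} P={t.pvalue:.3f}")

sh = diversity_by_group(m, parts, metric="shannon", seed=0)
print("\nShannon (rarefied) whole-community KW "
      f"P={sh.omnibus['whole'].pvalue:.3f}")
print("\nFisher's alpha solves S = alpha*ln(1 + N/alpha); e.g. a sample with")
S, N = 100, 50_000
print(f"S={S} taxa in N={N} reads gives alpha={fishers_alpha(S, N):.2f}.")
print("Satellite diversity exceeding core diversity reflects the planted")
print("many-rare-taxa structure of the cohort.")
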