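"""Community structure: Bray-Curtis similarity, ANOSIM, SIMPER, PCoA.

Asks whether the groups differ in composition (ANOSIM on Bray-Curtis
ranks), which taxa drive the difference (SIMPER), and what the ordination
looks like (PCoA with a 95 % ellipse per group).
"""

from coresat import (SimulationConfig, simulate_counts, to_relative_abundance,
                     bray_curtis, group_similarity_summary, anosim,
                     pairwise_anosim, simper, pcoa, confidence_ellipse)

m, _ = simulate_counts(SimulationConfig(seed=7))
rel = to_relative_abundance(m)
D = bray_curtis(rel)

print("within/between-group Bray-Curtis similarity (mean +/- SD):")
for _, row in group_similarity_summary(D, m.groups).iterrows():
    print(f"  {row['kind']:5s} {row['group_a']:>9s}|{row['group_b']:<9s} "
          f"{row['mean_similarity']:.3f} +/- {row['sd_similarity']:.3f}")

res = anosim(D, m.groups, n_perm=999, seed=0)
print(f"\nANOSIM: R={res.r:.3f}, P={res.pvalue:.4f} ({res.n_permutations} perms)")
for (a, b), r in pairwise_anosim(D, m.groups, n_perm=999, seed=0).items():
    print(f"  {a} vs {b}: R={r.r:.3f}, Bonferroni P={r.adjusted_pvalue:.4f}")

tab = simper(rel, m.groups, "control", "disease_1")
print(f"\nSIMPER control vs disease_1 "
      f"(overall dissimilarity {tab.attrs['overall_dissimilarity']:.3f}):")
print(tab.head(5)[["pct_contribution", "mean_abundance_a",
                   "mean_abundance_b"]].round(2).to_string())

coords = pcoa(D).coordinates
ell = confidence_ellipse(coords.loc[m.samples_in_group("control")].iloc[:, :2])
print(f"\ncontrol 95% ellipse: centre={ell.center.round(3)}, "
      f"semi-axes={ell.semi_axes.round(3)}")
print("\nR > 0 with small P says between-group rank distances exceed")
print("within-group ones; the SIMPER table names the taxa responsible.")
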