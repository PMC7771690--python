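"""Tree robustness under random reaction-content noise.

At noise level zeta, each organism trades a zeta-fraction of its reactions
for uniformly chosen absent ones (network size conserved).  The perturbed
matrix is re-clustered and compared with the unperturbed reference tree; the
mean similarity K(zeta) and per-organism placement stability quantify how
much annotation noise the tree tolerates.
"""

from metabotree import generate_clade_matrix, stability_analysis, two_clade_spec

spec = two_clade_spec(n_per_clade=10, seed=5)
matrix = generate_clade_matrix(spec)
report = stability_analysis(matrix, zetas=[0.01, 0.05, 0.1, 0.2], L=100, seed=5)

print("zeta    mean K(zeta)")
for z in report.zetas:
    print(f"{z:5.2f}   {report.mean_K[z]:.3f}")
# K stays near 1 at small zeta (the tree is robust to a few percent of
# misannotated reactions) and degrades as noise overwhelms clade signal

worst = min(report.placement_probability[0.2], key=report.placement_probability[0.2].get)
print(f"least stable organism at zeta=0.2: {worst} "
      f"(placed correctly in {report.placement_probability[0.2][worst]:.0%} of replicates)")
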