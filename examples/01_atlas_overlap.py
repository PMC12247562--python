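"""Quantify spatial agreement between atlas variants with Dice overlap.

Builds two synthetic atlas families on a sphere (a base parcellation and a
perturbed variant each), tabulates the Dice similarity coefficient for
every network over every unordered variant pair, and runs the group
comparison between intra-atlas and inter-atlas pairs.
"""

import numpy as np

from netgrowth import (build_dsc_table, kruskal_wallis,
                       make_sphere_parcellation, perturb_parcellation,
                       rank_sum_test)

base_a = make_sphere_parcellation(642, 5, 3, seed=1)
base_b = make_sphere_parcellation(642, 5, 3, seed=2)
variants = {
    "A-v1": base_a,
    "A-v2": perturb_parcellation(base_a, 0.05, seed=3),   # same family
    "B-v1": base_b,
    "B-v2": perturb_parcellation(base_b, 0.05, seed=4),
}
families = {name: name[0] for name in variants}
networks = {k: f"NET{k}" for k in range(1, 6)}

table = build_dsc_table(variants, networks, families)
print(table.groupby("pair_class")["dsc"].median().rename("median DSC"))
print(f"\noverall median DSC = {table['dsc'].median():.2f} "
      f"(range {table['dsc'].min():.2f}-{table['dsc'].max():.2f})")

intra = table.loc[table.pair_class == "intra-atlas", "dsc"]
inter = table.loc[table.pair_class == "inter-atlas", "dsc"]
w, p = rank_sum_test(intra, inter)
print(f"intra- vs inter-atlas rank-sum: W = {w:.0f}, p = {p:.2g}")

h, p_kw = kruskal_wallis([g["dsc"].to_numpy()
                          for _, g in table.groupby("network_name")])
print(f"Kruskal-Wallis across networks: H = {h:.2f}, p = {p_kw:.2g}")
print("\nVariants of one family overlap far more than variants of "
      "different families — the inter-atlas disagreement the analysis "
      "is designed to quantify.")
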