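"""Full analysis of the packaged reference survey (three-pipeline corridor).

Classifies the eight desert-steppe species from their importance-value
profiles, assigns disturbance-response groups, and estimates the effect
extent.  K2 is the distance at which the suppressed original dominants'
integrated importance value settles at its far-field level — the
headline extent of construction impact; K3 brackets the belt where
community dominance flips back from pioneers to the original dominants
(the edge-effect transition zone).
"""

import vegextent as vx
from vegextent.twinspan import modified_twinspan

table = vx.table1_fixture()
layout = vx.table1_layout()

clustering = modified_twinspan(table.IV, n_clusters=3)
print("Species clusters (dendrogram order):")
for label, members in clustering.cluster_members().items():
    print(f"  {label}: {', '.join(members)}")

iiv = vx.integrated_iv(table, clustering)
print("\nIntegrated importance values (3 decimals):")
print(iiv.rounded(3).T.to_string())

groups = vx.assign_groups(iiv, layout)
print("\nResponse groups:", groups.mapping)

est = vx.effect_extent(iiv, groups, layout)
print(f"\nK2 (effect extent, G2 stabilization): {est.K2.K:g} m")
print(f"K3 (dominance crossover interval):    ({est.K3.lower:g} m, "
      f"{est.K3.upper:g} m]")
print("K1 (G1 stabilization):                ",
      f"{est.K1.K:g} m" if est.K1 and est.K1.resolved else "unresolved")
print("\nThe pioneer group dominates out to 50 m; the original community "
      "is dominant and steady from 100 m outward.")
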