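"""Population-assay scoring and the Fisher exact comparison.

Spermathecae are scored occupied/unoccupied (plus fragment/liquid and emo
categories); conditions are compared on unoccupied vs the pooled rest.
"""

from spermacal import compare_populations, score_population, significance_stars

records = (
    [("control", "occupied")] * 18 + [("control", "unoccupied")] * 2
    + [("gsa1_kd", "unoccupied")] * 15 + [("gsa1_kd", "occupied")] * 4
    + [("gsa1_kd", "emo")] * 1
)
table = score_population(records)
for cond in table.conditions:
    print(f"{cond:9s} n={table.n(cond):3d}  occupancy={table.occupancy_fraction(cond):.0%}")

for row in compare_populations(table, control="control"):
    print(f"{row['comparison']}: p = {row['p']:.3g} {row['stars']}")
# a low p here means the knockdown leaves significantly more spermathecae empty.
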