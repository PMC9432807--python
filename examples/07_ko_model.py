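"""Ploidy-aware gene-knockout probability curves.

Converts per-cell somatic burdens into the expected number of deleterious
hits n = burden x damaging fraction x ploidy factor (p = 0.5 diploid,
0.125 tetraploid) and evaluates
Pr(KO | pi, D, n) = pi (1-(1-D)^n) + (1-pi)(1-exp(-nD)), where pi = 0.17
is the fraction of dosage-sensitive (high-pLI) genes. Diploid genomes
accumulate knockouts faster: polyploidy buffers deleterious mutations.
"""

import numpy as np
import pandas as pd

from cardiosnv import ko

rng = np.random.default_rng(71)
ages = [0.4, 2.0, 30.0, 49.2, 66.0, 75.3, 82.2]
rows = []
for j, age in enumerate(ages):
    for i in range(4):  # tetraploid burdens ~124 sSNV/cell/yr
        rows.append({
            "cell_id": f"d{j}c{i}", "donor_id": f"d{j}", "age": age,
            "est_count": max(rng.normal(124 * age / 10, 30), 1.0),
        })
burdens = pd.DataFrame(rows)

curve, stats_out = ko.cohort_ko_curve(burdens, ko.KOParams(D=1e-4))
wide = curve.pivot_table(index="age", columns="ploidy", values="mean")
print("per-donor mean KO probability:")
print(wide.rename(columns={2: "diploid", 4: "tetraploid"}).round(5).to_string())
for ploidy, fit in stats_out["exp_fit"].items():
    if fit:
        print(f"ploidy {ploidy}: Pr ~ {fit['a']:.2e} * exp({fit['b']:.4f} * age)")
print(f"paired Wilcoxon diploid vs tetraploid: "
      f"p = {stats_out['p_wilcoxon_diploid_vs_tetraploid']:.2e}")
print("The diploid curve dominates at every age: with a quarter of the")
print("per-gene hit probability, tetraploid cells are protected.")
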