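"""One-off construction of the synthetic reference signature fixtures.

Regenerating overwrites src/cardiosnv/data/synthetic_reference_signatures.tsv
with byte-identical content (fixed seed).
"""
import sys
from pathlib import Path

import numpy as np
sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from cardiosnv.contexts import CONTEXT_96, parse_class

rng = np.random.default_rng(20260930)

def build(base_weights, jitter=0.25):
    w = np.zeros(96)
    for i, lab in enumerate(CONTEXT_96):
        five, ref, alt, three = parse_class(lab)
        w[i] = base_weights(five, ref, alt, three)
    w *= rng.lognormal(0, jitter, 96)
    return w / w.sum()

# SBS5-like: flat clock-like, spread over C>T and T>C with broad support
sbs5 = build(lambda f, r, a, t: {"C>A":0.25,"C>G":0.2,"C>T":1.0,"T>A":0.3,"T>C":1.1,"T>G":0.25}[f"{r}>{a}"])
# SBS18-like: reactive-oxygen C>A
sbs18 = build(lambda f, r, a, t: (1.0 if (r,a)==("C","A") else 0.04) * (2.0 if (r,a)==("C","A") and t in "AT" else 1.0))
# SBS44-like: MMR-deficiency flavour, C>T at CpG plus T>C component
sbs44 = build(lambda f, r, a, t: (1.5 if (r,a)==("C","T") and t=="G" else 0.0) + (0.5 if (r,a)==("T","C") and f=="A" else 0.0) + (0.35 if (r,a)==("C","A") and f=="C" else 0.0) + 0.02)
# scE-like MDA artifact: C>T biased to 5' purine contexts, minor T>G
sce = build(lambda f, r, a, t: (1.0 if (r,a)==("C","T") and f in "AG" and t!="G" else 0.0) + (0.25 if (r,a)==("T","G") else 0.0) + 0.01)
# scF-like MDA artifact: C>T depleted at CpG, 5' pyrimidine contexts
scf = build(lambda f, r, a, t: (1.2 if (r,a)==("C","T") and f in "CT" and t!="G" else 0.0) + (0.15 if (r,a)==("C","A") and f=="T" else 0.0) + 0.005)

sigs = {"SBS5_like": sbs5, "SBS18_like": sbs18, "SBS44_like": sbs44, "scE_like": sce, "scF_like": scf}
M = np.column_stack(list(sigs.values()))
names = list(sigs)
print("pairwise cosines:")
for i in range(5):
    for j in range(i+1, 5):
        c = M[:,i] @ M[:,j] / np.linalg.norm(M[:,i]) / np.linalg.norm(M[:,j])
        print(f"  {names[i]} vs {names[j]}: {c:.3f}")
with open(Path(__file__).resolve().parents[1] / "src/cardiosnv/data/synthetic_reference_signatures.tsv", "w") as fh:
    fh.write("context\t" + "\t".join(names) + "\n")
    for i, lab in enumerate(CONTEXT_96):
        fh.write(lab + "\t" + "\t".join(f"{M[i,j]:.6g}" for j in range(5)) + "\n")
print("C>T mass scF:", scf[32:48].sum(), "scE:", sce[32:48].sum())
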