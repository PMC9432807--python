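"""Age-group mutation spectra, net increase, and transcriptional strand bias.

Builds infant and aged catalogues, computes the per-type net-increase
spectrum (aged minus infant, in absolute counts), and tests for
transcriptional strand bias over synthetic gene models with the exact
binomial (conditional Poisson) test.
"""

import pandas as pd

from cardiosnv import spectra, synthetic

ref = synthetic.generate_reference(n_chrom=2, chrom_length=5_000_000, seed=41)
mix = {"SBS5_like": 0.7, "SBS18_like": 0.3}

groups = {}
for name, age, n in (("infant", 1.0, 6), ("aged", 80.0, 6)):
    frames = [
        synthetic.generate_somatic(ref, age, 0.010, 0.05, 4, mix, seed=42 + i)
        for i in range(n)
    ]
    allv = pd.concat(frames, ignore_index=True)
    groups[name] = spectra.AgeGroupSpectrum(
        group=name,
        proportions=spectra.spectrum_from_contexts(allv["context"], granularity=6),
        mean_burden=len(allv) / n,
        n_cells=n,
    )
    print(f"{name}: mean burden {groups[name].mean_burden:.1f} sSNVs/cell")

net = spectra.net_increase_spectrum(groups["aged"], groups["infant"])
print("net increase by substitution type (counts per cell):")
print(net.round(1).to_string())

genes, _ = synthetic.generate_annotation(ref, n_genes=60, seed=43)
aged_vars = pd.concat(
    [synthetic.generate_somatic(ref, 80.0, 0.010, 0.05, 4, mix, seed=60 + i)
     for i in range(6)],
    ignore_index=True,
)
tab = spectra.strand_bias_table(aged_vars, genes)
print(tab.to_string(index=False))
print("With strand-symmetric simulation no type should show p << 0.05;")
print("in real aged tissue transcription-coupled repair skews C>T/T>C.")
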