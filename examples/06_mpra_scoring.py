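"""Score a barcoded reporter assay and classify elements.

Each element's activity is the mean log2 RNA/DNA ratio over its
barcode-replicate units, normalized to the basal promoter; a Welch
t-test against the basal units plus BH correction gives q-values, and
elements at least twofold above/below basal with q < 0.05 are called
enhancers/silencers.
"""

from cellcis import mpra
from cellcis.simulate import SimulationConfig, simulate_mpra

config = SimulationConfig(seed=11, mpra_depth=100.0)
activities = {"enh1": 2.0, "enh2": 1.5, "neutral": 0.0, "sil1": -2.0}
counts, truth = simulate_mpra(activities, config, barcodes_per_element=3,
                              basal_barcodes=25, replicates=4)
print(f"{counts['barcode'].nunique()} barcodes x 4 replicates "
      f"({(counts['element'] == 'basal').sum()} basal units)")

activity = mpra.score_elements(counts, dna_min=10)
classes = mpra.classify_elements(activity, fold=2.0, q_max=0.05)
table = activity.join(classes)
print(table[["log2fc", "p", "q", "class"]].round(4).to_string())
print("\nlog2fc ~ +2 means 4x the basal RNA/DNA ratio; 'neutral' stays "
      "inactive because its fold change and q fail the twofold/0.05 rule.")
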