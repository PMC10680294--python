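"""Fine-map a GWAS block with annotation priors and colocalize with a
molecular QTL.

Per-variant evidence is the Wakefield log approximate Bayes factor;
under a single causal variant per LD block, PIP_j = pi_j ABF_j /
sum_k pi_k ABF_k with annotation-informed priors pi.  Colocalization
enumerates the five sharing hypotheses H0-H4 from the two traits' ABFs.
"""

import numpy as np
import pandas as pd

from cellcis import gwas
from cellcis.simulate import SimulationConfig, simulate_genotypes, simulate_gwas_block

config = SimulationConfig(seed=2, ld_decay=0.3)
genotypes = simulate_genotypes(config, 50, spacing_bp=1000)
causal = genotypes.variants.index[25]

gsum, qsum, truth = simulate_gwas_block(
    genotypes, causal, config, z_causal=8.0, n_gwas=50_000,
    annotations={causal: 2}, paired_qtl="shared",
)
labf = pd.Series(
    gwas.wakefield_abf(gsum["beta"].to_numpy(), gsum["se"].to_numpy()),
    index=pd.Index(gsum["variant_id"]),
)

# annotation-informed prior: the causal sits in a linked cis-regulatory
# element (category 2) with log-enrichment 2 over unannotated variants
cats = pd.Series(0, index=labf.index)
cats[causal] = 2
prior = gwas.category_priors(cats, np.array([0.0, 0.0, 2.0, 0.0, 0.0]))
res = gwas.finemap_block(labf, prior)

i = list(res.variants).index(causal)
print(f"causal variant {causal}:")
print(f"  functional PIP {res.pip[i]:.3f} vs uniform PIP "
      f"{res.pip_uniform[i]:.3f}")
print(f"  95% credible set size: {len(res.credible_set)} "
      f"(contains causal: {causal in res.credible_set})")
print("the annotation prior concentrates posterior mass on the "
      "regulatory-element variant.\n")

coloc = gwas.coloc_abf(gsum, qsum)
print("colocalization with the shared-causal QTL trait:")
print("  " + ", ".join(f"PP{i}={coloc[f'PP{i}']:.3f}" for i in range(5)))
print("PP4 (one shared causal variant) dominates, as planted.")
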