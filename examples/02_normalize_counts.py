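"""Filter and TMM-normalize a simulated count matrix.

Shows the standard count workflow: keep genes with >=1 cpm in >=5
libraries, estimate TMM scaling factors, and compute cpm on effective
library sizes.
"""

import numpy as np

from ohnodiverge import exprio, simdata

cfg = simdata.SimulationConfig(seed=7, n_orthogroups=80, design="smolt", n_replicates=6)
_, truth = simdata.simulate_gene_trees(cfg)
bundle = simdata.simulate_expression(cfg, truth)

bundle.norm_factors = exprio.tmm_factors(bundle)
norm = exprio.cpm(bundle)
kept, filtered = exprio.filter_low_expression(norm)

print(f"samples               : {bundle.counts.shape[1]}")
print(f"library sizes         : {bundle.library_sizes.min():.0f} .. "
      f"{bundle.library_sizes.max():.0f}")
print(f"TMM factors           : {bundle.norm_factors.min():.3f} .. "
      f"{bundle.norm_factors.max():.3f} (geometric mean "
      f"{np.exp(np.mean(np.log(bundle.norm_factors))):.6f})")
print(f"genes kept by filter  : {len(kept)} / {len(bundle.counts)}")
print(f"mesor of {kept[0]} in gill: "
      f"{exprio.condition_mesor(filtered, bundle.meta, kept[0], 'gill'):.1f} cpm")
# TMM factors correct sample-composition bias so cpm values are comparable
# across libraries; the geometric mean of the factors is 1 by construction.
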