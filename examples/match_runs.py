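"""Link anonymous donors across two runs by genotype concordance.

Inferred donors carry no identity, and component numbering is arbitrary
per run. Two batches from the same individuals can still be linked:
reconstructed genotypes of the same person agree on nearly all
well-covered variants, different people on far fewer.
"""

import numpy as np

from scdemux import (
    AlleleCountData,
    FitConfig,
    SimConfig,
    filter_variants,
    fit,
    genotype_concordance,
    match_donors,
    simulate_pool,
)

# one pool, split into two "batches" of cells
cfg = SimConfig(
    n_donors=4, cells_per_donor=200, n_variants=800,
    coverage_rate=0.12, doublet_rate=0.0, seed=3,
)
data, truth = simulate_pool(cfg)
data = filter_variants(data)

rng = np.random.default_rng(0)
idx = rng.permutation(data.n_cells)
half = data.n_cells // 2


def take(cells):
    cells = np.sort(cells)
    return AlleleCountData(
        data.A[:, cells].tocsr(), data.D[:, cells].tocsr(),
        [data.cells[j] for j in cells], data.variants,
    )


batch_a, batch_b = take(idx[:half]), take(idx[half:])

fit_a = fit(batch_a, 4, config=FitConfig(n_init=10, seed=1), with_doublets=False)
fit_b = fit(batch_b, 4, config=FitConfig(n_init=10, seed=2), with_doublets=False)

cm = genotype_concordance(
    fit_a.genotype, fit_a.donor_depth(batch_a),
    fit_b.genotype, fit_b.donor_depth(batch_b),
)
print("concordance matrix (rows: run A donors, cols: run B donors):")
print(np.array_str(cm.values, precision=3))

mapping, scores = match_donors(cm)
for k, (l, s) in enumerate(zip(mapping, scores)):
    print(f"run A donor {k} == run B donor {l} (concordance {s:.3f})")
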