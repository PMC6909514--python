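"""Design a minimal variant panel that distinguishes the pooled donors.

After demultiplexing, a handful of variants whose joint genotype
patterns separate all donors can confirm donor identity by targeted
genotyping (e.g. qPCR). The greedy search adds the variant with the
largest information gain on the donor partition until all donors are
separated (log2 K bits).
"""

from scdemux import (
    FitConfig,
    SimConfig,
    filter_variants,
    fit,
    panel_table,
    select_discriminatory_variants,
    simulate_pool,
)

cfg = SimConfig(
    n_donors=6, cells_per_donor=250, n_variants=1000, doublet_rate=0.0, seed=5
)
data, truth = simulate_pool(cfg)
data = filter_variants(data)

result = fit(data, 6, config=FitConfig(n_init=15, seed=1), with_doublets=False)

panel = select_discriminatory_variants(
    result.genotype, result.donor_depth(data), min_umis=20
)
print(f"selected {len(panel.variants)} variants, "
      f"{panel.entropy:.2f} of {2.585:.2f} bits, complete={panel.complete}")
print(panel_table(panel, result.genotype, data.variants).to_string(index=False))
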