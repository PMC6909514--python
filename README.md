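# scdemux

Genotype-free demultiplexing of pooled single-cell RNA-seq.

Pooling cells from several genetically distinct donors into one
droplet-based scRNA-seq run cuts cost and batch effects, but every cell
must then be assigned back to its donor of origin. `scdemux` does this
using only the natural genetic variation already present in the reads:
the ALT/total UMI counts at common SNVs. No genotype reference is
required — the donor genotypes are reconstructed jointly with the cell
assignments — and a reference can be supplied for any subset of donors
when available.

The package provides:

- **Demultiplexing** by variational Bayesian inference in a binomial
  mixture model, genotype-free or genotype-informed.
- **Doublet detection** via pseudo-donors for every donor pair, whose
  genotype profile is the combination of the two members'.
- **Pool-size estimation** from the evidence-lower-bound elbow across
  candidate donor numbers.
- **Donor matching across runs** by genotype concordance (linking
  anonymous donors between batches, or to bulk profiles).
- **Discriminatory variant panels**: a minimal set of variants whose
  joint genotypes distinguish all donors, for identity confirmation by
  targeted genotyping.
- **A generative pool simulator** with ground truth, plus evaluation
  metrics (ARI–recall curve, doublet ROC, genotype precision).

## The model

At variant $i$ and cell $j$, the ALT read count is binomial in the
total depth,

$$a_{ij} \mid d_{ij}, z_j = k, G_{ik} = t \;\sim\; \mathrm{Binom}(d_{ij},\, \theta_t),$$

where $z_j \in \{1..K\}$ is the cell's (latent) donor,
$G_{ik} \in \{0, 1, 2\}$ the donor's (latent) genotype — copies of the
ALT allele — and $\theta_t$ the ALT-read rate of genotype state $t$,
with conjugate beta priors concentrated near 0, ½ and 1:
$\theta_0 \sim \mathrm{Beta}(0.3, 29.7)$,
$\theta_1 \sim \mathrm{Beta}(3, 3)$,
$\theta_2 \sim \mathrm{Beta}(29.7, 0.3)$.
Genotypes have a categorical prior $U$ (uniform when unknown; a relaxed
encoding of known genotypes otherwise).

Inference maximizes the evidence lower bound over a fully factorized
variational posterior $q(Z)\,q(G)\,q(\theta)$ by coordinate ascent, with
many short random restarts on an over-specified component space to
escape local optima. Doublets are handled by appending $K(K-1)/2$
pseudo-donors — one per donor pair — whose genotype distribution over
the extended states $\{0, \tfrac12, 1, \tfrac32, 2\}$ is the convolution
of the two members' and whose ALT-rate pseudo-priors interpolate the
singlet states. Cells are called by posterior probability: a confident
singlet (`prob_max > 0.9`), a doublet (`prob_doublet > 0.9`), or
unassigned.

See [docs/methods.md](docs/methods.md) for the full model, update
equations, and every default with its rationale.

## Quick start (library)

```python
from scdemux import (FitConfig, SimConfig, simulate_pool, filter_variants,
                     fit, evaluation_report)

cfg = SimConfig(n_donors=4, cells_per_donor=250, n_variants=1000,
                doublet_rate=0.05, seed=7)
data, truth = simulate_pool(cfg)
data = filter_variants(data)                      # >=20 UMIs, minor >=10%
result = fit(data, 4, config=FitConfig(n_init=20, seed=1))
print(evaluation_report(result, data, truth))
```

Running this (it is `examples/simulate_and_demux.py`) prints:

```
pool: 1000 variants x 1050 cells (50 doublets)
784 variants pass filtering
ELBO -28090.6, converged=True, doublet prior eta=0.0105
1000 confident singlets, 50 doublets, 0 unassigned
                 singlet_ari: 1.0000
             ari_recall_area: 1.0000
                 doublet_auc: 1.0000
         doublet_sensitivity: 1.0000
         doublet_specificity: 1.0000
  genotype_precision_overall: 0.9935
      genotype_precision_het: 0.9874
               donor_mapping: [3, 2, 1, 0]
```

All 1000 true singlets are assigned to the right donor, all 50 doublets
are caught, and the reconstructed genotypes are >99% correct at
adequately covered sites. The other example scripts cover
genotype-informed fitting (`known_genotypes.py`), pool-size estimation
(`estimate_pool_size.py`), donor matching across batches
(`match_runs.py`) and panel design (`variant_panel.py`).

## Quick start (CLI)

```bash
# synthetic pool with ground truth
scdemux simulate -o pool/ --n-donors 4 --cells-per-donor 250 --seed 7

# demultiplex (genotype-free); add --donor-vcf ref.vcf for reference mode
scdemux demux pool/ -k 4 -o fit/ --seed 1

# score against the simulator truth
scdemux evaluate --count-dir pool/ --fit-dir fit/

# how many donors are in this pool?
scdemux scan-k pool/ --k-min 2 --k-max 7 -o scan.tsv

# link donors between two runs; design an identity panel
scdemux match --fit-a fitA/GT_donors.vcf --fit-b fitB/GT_donors.vcf
scdemux panel --fit fit/GT_donors.vcf
```

`demux` reads the standard sparse pileup layout (`cellSNP.tag.AD.mtx`,
`cellSNP.tag.DP.mtx`, `cellSNP.base.vcf`, `cellSNP.samples.tsv`) and
writes `donor_ids.tsv` (per-cell calls and probabilities),
`GT_donors.vcf` (reconstructed donor genotypes with posteriors and
aggregate depths) and `fit_summary.json`.

## Tests

```bash
python -m pytest -q tests/
```

The suite contains independent scalar-loop oracles for every update
equation, an exhaustive-enumeration oracle for the exact posterior on
tiny instances (θ integrated analytically), property-based tests, and
end-to-end recovery tests on simulated pools.

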