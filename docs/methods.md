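# Methods

This document specifies the probabilistic model, the inference
algorithm, every tunable parameter with its default and rationale, the
simulator, and the numerical choices. Notation: $N$ variants, $M$
cells, $K$ donors; $a_{ij}$ ALT UMIs and $d_{ij}$ total UMIs at variant
$i$ in cell $j$; $b_{ij} = d_{ij} - a_{ij}$.

## 1. Model

Each cell belongs to one donor, $z_j \in \{1..K\}$ with prior
$p(z_j = k) = \pi_k$ (uniform during the singlet fit). Each donor has a
genotype per variant, $G_{ik} \in \{0, 1, 2\}$ (ALT-allele copies), with
categorical prior $U_{ik}$. ALT counts are binomial:

$$p(a_{ij} \mid d_{ij}, z_j = k, G_{ik} = t, \theta) =
  \binom{d_{ij}}{a_{ij}} \theta_t^{a_{ij}} (1-\theta_t)^{b_{ij}}.$$

The ALT rate of each genotype state has a beta prior:

| state $t$ | meaning   | prior                 | prior mean |
|-----------|-----------|-----------------------|------------|
| 0         | hom-REF   | Beta(0.3, 29.7)       | 0.01       |
| 1         | het       | Beta(3, 3)            | 0.5        |
| 2         | hom-ALT   | Beta(29.7, 0.3)       | 0.99       |

The hom priors are deliberately asymmetric and broad enough to absorb
sequencing error and allelic imbalance; the het prior is weak because
allele-specific expression makes the het rate variable.

Entries with $d_{ij} = 0$ contribute nothing; all count matrices are
stored sparse (CSR) throughout.

## 2. Variational inference

The posterior is approximated by the fully factorized
$q(Z)\,q(G)\,q(\theta)$ with categorical $q(z_j) = r_{j\cdot}$,
categorical $q(G_{ik}) = g_{ik\cdot}$ and
$q(\theta_t) = \mathrm{Beta}(\alpha_t, \beta_t)$. With
$E_t = \psi(\alpha_t) - \psi(\alpha_t + \beta_t)$ and
$\bar E_t = \psi(\beta_t) - \psi(\alpha_t + \beta_t)$ ($\psi$ the
digamma function), the expected per-entry log-likelihood is the
*complete* form

$$\mathbb{E}[\log p(a_{ij}\mid\cdot)] = a_{ij} E_t + b_{ij} \bar E_t + \log\binom{d_{ij}}{a_{ij}}.$$

The $-(a+b)\,\psi(\alpha_t+\beta_t)$ component must not be dropped from
the softmax over components: the beta concentrations
$\alpha_t + \beta_t$ differ across genotype states, so it is not a
shared constant. This is verified in the tests against scalar oracles
and exact enumeration.

Coordinate updates (in the order genotype → θ → assignment):

- $\log g_{ikt} \propto \log U_{ikt} + \sum_j r_{jk}(a_{ij} E_t + b_{ij}\bar E_t)$
- $\alpha_t = \alpha_{0t} + \sum_{ijk} r_{jk} g_{ikt} a_{ij}$, and
  $\beta_t$ analogously with $b_{ij}$
- $\log r_{jk} \propto \log \pi_k + \sum_{it} g_{ikt}(a_{ij} E_t + b_{ij}\bar E_t)$

Each update is exact for its factor, so the ELBO is monotone
non-decreasing (property-tested on random instances).

**ELBO.** The reported objective includes the binomial coefficients
once, so it is a true lower bound on $\log p(A, D)$:

$$\mathcal{L} = \mathbb{E}_q[\log p(A \mid D, Z, G, \theta)]
 + \mathbb{E}_q\!\left[\log\frac{p(Z)}{q(Z)}\right]
 + \mathbb{E}_q\!\left[\log\frac{p(G)}{q(G)}\right]
 - \mathrm{KL}(q(\theta)\,\|\,p(\theta)).$$

The beta KL is closed-form; an exhaustive-enumeration oracle (all
$(Z, G)$ configurations, θ integrated analytically by beta-binomial
conjugacy) upper-bounds every reported ELBO in the tests.

**Complexity.** The genotype-state sum is folded into two dense
$N \times K$ matrices ($g \cdot E$ and $g \cdot \bar E$), so each
assignment update costs two sparse matrix products
($A^\top$ and $B^\top$ against them); the genotype and θ updates
likewise reduce to $A r$, $B r$ and einsums. One full iteration at the
default scale (~2000 filtered variants × 8640 cells, K=11 during
warm-up) takes ~30 ms.

## 3. Fitting procedure

1. **Warm-up**: `n_init` = 50 restarts × `warmup_iters` = 15 iterations
   on an over-specified model with $K + \lceil\sqrt K\rceil$ components
   (surplus components carry uniform genotype priors). Random
   initialization draws $g^{(0)}_{ik\cdot} \sim \mathrm{Dirichlet}(1,1,1)$;
   entries where the genotype prior is informative start at the prior
   instead (see §5). The restart with the best ELBO wins.
2. **Pruning**: the $K$ components with the largest soft cell mass
   $\sum_j r_{jk}$ are kept. Surviving original columns stay at their
   own positions (so an informative prior stays aligned); surviving
   surplus columns fill the pruned slots.
3. **Refinement**: coordinate ascent to convergence
   ($|\Delta\mathcal{L}| <$ `elbo_tol` = 0.01, at most `max_iters` = 200
   iterations; a warning is raised otherwise).
4. **Doublet stage** (§4): the assignment posterior is recomputed once
   over the extended component space with $q(G)$, $q(\theta)$ frozen.

Everything is deterministic given `FitConfig.seed`.

*Rationale for the restart scheme*: the mixture objective is non-convex
with label-switching symmetry; many cheap restarts on an over-specified
space find the dominant structure far more reliably than a single long
run, and self-pruning of surplus components is the same mechanism that
makes over-specified $K$ benign (§6).

## 4. Doublet detection

A droplet with cells from two donors $k \ne l$ shows allele fractions
intermediate between the two genotypes. For each of the $K(K-1)/2$
unordered pairs a pseudo-donor is appended whose genotype distribution
over the extended states $\{0, \tfrac12, 1, \tfrac32, 2\}$ combines the
members':

$$\tilde g_s = \sum_{t_1 + t_2 = 2s} g^{(k)}_{t_1} g^{(l)}_{t_2},$$

e.g. state $\tfrac12$ arises from hom-REF × het. The pseudo-states'
ALT-rate parameters interpolate the ordinary ones: the mean is the
arithmetic mean of the two neighbouring state means, the concentration
$\alpha + \beta$ their geometric mean (for the default prior this gives
$\alpha_{0.5} \approx 3.4212$, $\beta_{0.5} \approx 9.9952$). The
extended prior puts $(1-\eta)/K$ on each singlet donor and $\eta/K_2$ on
each pair, with $\eta$ = `doublet_prior`; the default `"auto"` applies
the droplet loading rule $\eta = M / 100{,}000$ (capped at 0.5).

The extended assignment is computed **once** with $q(G)$ and
$q(\theta)$ frozen: with those factors fixed, a single softmax is
already the coordinate optimum, and freezing prevents doublets from
contaminating the reconstructed genotypes. Cells with zero coverage
fall back to the prior, so their doublet probability equals $\eta$.

Calls: `prob_doublet` $> 0.9$ → doublet; otherwise `prob_max` $> 0.9$ →
that donor; otherwise unassigned. Both thresholds are exposed.

## 5. Genotype-informed fitting

Known genotypes are encoded as a relaxed prior: mass $1-\xi$ on the
stated genotype and $\xi/2$ on each other state, `relax_rate`
$\xi = 0.05$ by default (tolerates genotyping error and annotation
mismatches; $\xi = 0$ encodes certainty). VCF tags: `GT` is relaxed as
above; `GP` is renormalized and used directly; `GL` is
$10^x$-renormalized; missing calls become uniform. Variants are matched
by exact (chrom, pos, ref, alt).

- **Full reference** (`fit_with_full_genotype`): only variants known in
  at least one donor are used; $q(G)$ is clamped at the prior and only
  $q(\theta)$, $q(Z)$ iterate. No restarts are needed — the clamped
  genotypes remove the label-switching symmetry — and components
  inherit donor identity. A prior with no information at all falls back
  to the genotype-free fit (with a warning).
- **Partial reference** (`fit_with_partial_genotype`): (1) genotype-free
  fit; (2) each known donor is matched to an inferred component by
  genotype concordance (globally optimal one-to-one); (3) the genotype
  prior is rebuilt with the known genotypes placed at the matched
  components (uniform elsewhere); (4) refit. Known donors whose best
  concordance is below `match_threshold` = 0.7 are reported unmatched
  and left un-anchored (same-individual concordance is near 1,
  different-individual near ⅓–½, so 0.7 separates the modes with wide
  margin).

When the prior is informative, warm-up restarts initialize $q(G)$ at
the prior for the known entries (random elsewhere). Without this,
restarts converge to label-permuted optima that the relaxed prior is
too weak to flip afterwards, and anchoring silently fails.

## 6. Pool-size estimation

`scan_n_donors` fits each $K$ in a range (restart seeds shared across
$K$ so curves are comparable) and reports the ELBO curve plus the
per-component soft cell mass. The evidence rises steeply until $K$
reaches the true pool size and then flattens — surplus components
attract almost no cells. The numeric elbow rule picks the last $K$
before the first ELBO gain below `elbow_fraction` = 0.1 of the largest
gain in the scan; it is a convenience heuristic and the raw curve is
always returned.

## 7. Donor matching and variant panels

**Concordance**: over variants with ≥ `min_umis` = 10 aggregate UMIs in
both donors, the fraction of agreeing hard (argmax) genotype calls.
**Matching**: maximum-weight one-to-one assignment on the concordance
matrix (`scipy.optimize.linear_sum_assignment`), with an epsilon bias
toward low-index pairs for deterministic ties; missing concordances
count as 0; surplus donors ($K_1 > K_2$) come back unmatched (−1).

**Panels**: candidates need ≥ `min_umis` = 20 UMIs in every donor
(hard calls are unreliable below that). Starting from the one-block
donor partition, the greedy step adds the variant whose genotype
pattern maximally increases the partition entropy (bits), breaking ties
by higher total depth then lower index, stopping at $\log_2 K$ (all
donors separated) or when no variant adds information — then the
unresolved donor blocks are reported in a warning.

## 8. Variant filtering

`filter_variants` keeps variants with total depth ≥ 20 UMIs **and**
minor-allele pseudo-bulk fraction ≥ 10%. Below ~20 UMIs a variant
cannot contribute a reliable genotype for any donor; near-monomorphic
variants carry no assignment information. Removing them shrinks the
problem by roughly half at default simulation scale without touching
accuracy. The filter is idempotent and order-preserving.

## 9. Simulator

`simulate_pool(SimConfig)` generates a pool with ground truth:

| parameter | default | rationale |
|---|---|---|
| `n_donors` | 8 | typical multiplexing scale |
| `cells_per_donor` | 1000 | scalar or per-donor list (biased pools) |
| `doublet_rate` | `"auto"` | loading rule $n_\text{singlets}/100{,}000$ → 8% at 8×1000 |
| `n_variants` | 2000 | with `coverage_rate` gives ~100 covered variants/cell |
| `maf_range` | (0.05, 0.5) | common variants; genotypes drawn per Hardy–Weinberg |
| `coverage_rate` | 0.05 | per-cell, per-variant coverage probability |
| `depth_mean` | 2.0 | geometric (support ≥ 1) UMI depth per covered variant |
| `theta` | (0.01, 0.5, 0.99) | ALT rate per genotype incl. error |
| `depth_subsample` | 1.0 | binomial thinning emulating read subsampling |
| `seed` | 0 | bit-identical output per seed |

Doublets are sums of two independently drawn singlet count profiles
from distinct donors, appended after the singlets. Scope and limits:
counts are generated directly from genotypes (no read-level/BAM
simulation, no UMI deduplication, no expression model beyond variant
coverage); ALT rates are homogeneous across variants, so real-data
complications (allele-specific expression gradients, ambient RNA) are
absent — simulated pools are *cleaner* than real ones, and end-to-end
accuracy targets are treated as lower bounds.

## 10. Numerical choices

- All softmaxes in log space with row-max subtraction.
- $0 \log 0 := 0$ throughout entropy terms.
- Binomial-coefficient total via `gammaln` sums over the stored sparse
  entries of $D$, $A$, and $B = D - A$ (zero entries contribute
  $\log\Gamma(1) = 0$).
- Beta KL in closed form via `betaln`/`digamma`.
- Warm-up computes the ELBO only at the last iteration of each restart
  (selection is unchanged; saves ~40% of warm-up time).
- Non-finite ELBO or expected log-likelihood raises immediately.

## 11. Evaluation metrics

- **ARI–recall curve**: for each confidence cutoff τ, ARI between
  argmax and true donors over true singlets with `prob_max` > τ versus
  the retained fraction; area by trapezoid over recall ∈ [0, 1].
- **Doublet ROC**: ROC/AUC of `prob_doublet` against true doublet
  labels, plus sensitivity/specificity at the 0.9 cutoff.
- **Genotype precision**: over (variant, donor) entries with ≥ 10
  aggregate UMIs, after concordance-matching inferred donors to truth:
  overall argmax accuracy and per-predicted-state precision.

## 12. Default problem sizes used in the tests

- Shared fixture: 4 donors × 150 cells, 800 variants, 8% doublets —
  fast, recoverable (ARI > 0.95).
- Acceptance (headline numbers): 8 donors × 1000 cells, 2000 variants,
  auto (8%) doublets, five fixed seeds.
- Model-selection acceptance: 4 donors × 300 cells, 1000 variants —
  the <1% surplus-mass property needs this many cells.
- Exactness oracles: $N, M \le 3$, $K = 2$ with exhaustive enumeration
  (θ integrated analytically), and converged fits (30 restarts × 30
  iterations, tolerance $10^{-6}$, no surplus components) when
  comparing to the exact posterior argmax.
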