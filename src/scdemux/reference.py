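"""Fitting with full or partial reference genotypes.

With genotypes for all K donors, q(G) is clamped to the (relaxed) known
distribution and only the allele-rate posterior and the cell assignment
iterate; no random restarts are needed because the remaining objective
has no label-switching ambiguity.  With genotypes for a subset of
donors, a two-step procedure is used: a genotype-free fit first, then
the known donors are anchored to inferred components via genotype
concordance and the prior on G is rebuilt with the known genotypes in
those components before a second fit.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .doublets import assign_extended, build_extension
from .inference import FitConfig, _singlet_ascent, fit
from .io import AlleleCountData, GenotypePriorMatrix
from .matching import genotype_concordance, match_donors
from .model import (
    DemuxFit,
    GenotypePosterior,
    ThetaPrior,
    log_binom_coeff_total,
)

log = logging.getLogger(__name__)


def fit_with_full_genotype(
    data: AlleleCountData,
    prior_U: GenotypePriorMatrix,
    config: FitConfig | None = None,
    with_doublets: bool = True,
) -> DemuxFit:
    """Demultiplex against a complete genotype reference.

    Only variants with a known genotype in at least one donor are used;
    q(G) is fixed at the relaxed reference and never updated.  A prior
    with no information at all (nothing known) degenerates to the
    genotype-free fit.
    """
    config = config or FitConfig()
    K = prior_U.n_donors
    if prior_U.U.shape[0] != data.n_variants:
        raise ValueError("prior and count data disagree on the number of variants")
    if prior_U.n_known == 0:
        warnings.warn(
            "reference prior contains no genotype information; "
            "falling back to the genotype-free fit"
        )
        return fit(data, K, None, config, with_doublets)

    # restrict to variants with at least one known genotype
    keep = np.nonzero(prior_U.known_mask.any(axis=1))[0]
    sub = data.subset_variants(keep)
    U = prior_U.U[keep]

    theta_prior = ThetaPrior()
    genotype = GenotypePosterior(U.copy())
    pi = np.full(K, 1.0 / K)
    log_binom_const = log_binom_coeff_total(sub)
    assignment, genotype, theta, trace, converged = _singlet_ascent(
        sub, genotype.g, U, theta_prior, pi,
        config.max_iters, config.elbo_tol, log_binom_const,
        clamp_genotype=True,
    )

    eta = config.resolve_eta(sub.n_cells)
    if with_doublets and K >= 2:
        extension = build_extension(genotype, theta, eta, K, sub.n_cells)
        assignment = assign_extended(sub, extension, genotype, theta)
    else:
        eta = 0.0
    fit_result = DemuxFit(
        assignment=assignment,
        genotype=genotype,
        theta=theta,
        elbo_trace=trace,
        n_donors=K,
        converged=converged,
        seed=config.seed,
        doublet_prior=eta,
    )
    fit_result.variant_subset = keep  # indices into the input data
    return fit_result


def fit_with_partial_genotype(
    data: AlleleCountData,
    prior_partial: GenotypePriorMatrix,
    K: int,
    config: FitConfig | None = None,
    match_threshold: float = 0.7,
    min_umis: int = 10,
) -> DemuxFit:
    """Two-step demultiplexing with genotypes for K0 < K donors.

    Step 1 fits genotype-free; step 2 anchors each known donor to an
    inferred component by genotype concordance (one-to-one, globally
    optimal); step 3 rebuilds the prior on G with the known genotypes in
    the matched components (uniform elsewhere); step 4 refits.  Known
    donors whose best concordance falls below ``match_threshold`` are
    reported as unmatched and left un-anchored.
    """
    config = config or FitConfig()
    k0 = prior_partial.n_donors
    if not (1 <= k0 <= K):
        raise ValueError(f"need 1 <= K0 <= K, got K0={k0}, K={K}")
    if prior_partial.U.shape[0] != data.n_variants:
        raise ValueError("prior and count data disagree on the number of variants")

    first = fit(data, K, None, config, with_doublets=False)

    # concordance of known genotypes vs inferred components
    known_g = GenotypePosterior(prior_partial.U)
    # known donors have no read depth; gate only on covered known entries
    depth_known = np.where(prior_partial.known_mask, np.inf, 0.0)
    depth_inferred = first.donor_depth(data)
    cm = genotype_concordance(
        known_g, depth_known, first.genotype, depth_inferred, min_umis=min_umis
    )
    mapping, scores = match_donors(cm)
    used = [comp for comp, s in zip(mapping, scores) if s >= match_threshold]
    if len(set(used)) < len(used):
        raise ValueError(
            f"two known donors matched the same component; concordance matrix:\n"
            f"{cm.values}"
        )

    U = np.full((data.n_variants, K, 3), 1.0 / 3.0)
    mask = np.zeros((data.n_variants, K), dtype=bool)
    matched, unmatched = {}, []
    for d0, (comp, score) in enumerate(zip(mapping, scores)):
        if score >= match_threshold:
            U[:, comp, :] = prior_partial.U[:, d0, :]
            mask[:, comp] = prior_partial.known_mask[:, d0]
            matched[d0] = (int(comp), float(score))
        else:
            unmatched.append(d0)
            log.warning(
                "known donor %d unmatched (best concordance %.3f < %.2f)",
                d0, score, match_threshold,
            )
    prior_mixed = GenotypePriorMatrix(U, prior_partial.relax_rate, mask)

    second = fit(data, K, prior_mixed, config)
    second.known_donor_map = matched
    second.unmatched_known_donors = unmatched
    return second
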