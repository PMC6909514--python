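"""Coordinate-ascent variational inference for the donor mixture model.

The fit proceeds in three phases:

1. Warm-up: many short random restarts (default 50 x 15 iterations) on
   an over-specified model with K + ceil(sqrt(K)) components, keeping
   the restart with the highest ELBO.  This guards against local optima
   of the non-convex mixture objective.
2. Pruning and refinement: the K components with the most softly
   assigned cells are kept and coordinate ascent (genotype -> theta ->
   assignment) runs to ELBO convergence.
3. Doublet stage: K(K-1)/2 doublet pseudo-donors with combined genotype
   distributions are appended and the assignment posterior is recomputed
   once over the extended component space while q(G) and q(theta) stay
   frozen (the extended assignment does not feed back into them).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import AlleleCountData, GenotypePriorMatrix
from .model import (
    AssignmentPosterior,
    DemuxFit,
    GenotypePosterior,
    ThetaPosterior,
    ThetaPrior,
    compute_elbo,
    expected_loglik_matrix,
    log_binom_coeff_total,
)

log = logging.getLogger(__name__)


@dataclass
class FitConfig:
    """Tuning knobs of the variational fit.

    ``doublet_prior`` is the prior probability eta that a cell is a
    doublet; "auto" sets eta = M / 100,000 (a standard loading-rate rule
    for droplet platforms).
    """

    n_init: int = 50
    warmup_iters: int = 15
    max_iters: int = 200
    elbo_tol: float = 1e-2
    seed: int = 0
    n_extra_clusters: int | None = None  # default ceil(sqrt(K))
    doublet_prior: float | str = "auto"

    def __post_init__(self) -> None:
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        if self.warmup_iters > self.max_iters:
            raise ValueError("warmup_iters must not exceed max_iters")

    def resolve_eta(self, n_cells: int) -> float:
        if self.doublet_prior == "auto":
            return min(n_cells / 100_000.0, 0.5)
        eta = float(self.doublet_prior)
        if not (0.0 <= eta < 1.0):
            raise ValueError("doublet prior must be in [0, 1)")
        return eta

    def extra_clusters(self, K: int) -> int:
        if self.n_extra_clusters is None:
            return math.ceil(math.sqrt(K))
        return int(self.n_extra_clusters)


def _normalise_log_rows(logw: np.ndarray) -> np.ndarray:
    logw = logw - logw.max(axis=-1, keepdims=True)
    w = np.exp(logw)
    w /= w.sum(axis=-1, keepdims=True)
    return w


def update_assignment(
    data: AlleleCountData,
    genotype: GenotypePosterior,
    theta: ThetaPosterior,
    pi: np.ndarray,
) -> AssignmentPosterior:
    """Variational update of q(Z): softmax of the expected log-likelihood.

    Cells with no covered variants have zero data term and fall back to
    the prior pi.  All normalisation is log-space with max-subtraction.
    """
    S = expected_loglik_matrix(data, genotype, theta)
    r = _normalise_log_rows(S + np.log(pi))
    return AssignmentPosterior(r, np.asarray(pi, float), genotype.n_donors)


def update_genotype(
    data: AlleleCountData,
    assignment: AssignmentPosterior,
    theta: ThetaPosterior,
    prior_U: GenotypePriorMatrix | np.ndarray,
) -> GenotypePosterior:
    """Variational update of q(G).

    Variants with no coverage in any cell softly assigned to donor k
    accumulate a zero data term and revert to the prior u.
    """
    U = prior_U.U if isinstance(prior_U, GenotypePriorMatrix) else np.asarray(prior_U)
    r = assignment.r
    el_t, el_1mt = theta.expected_log()
    AR = np.asarray(data.A @ r)  # (N, K)
    BR = np.asarray(data.B @ r)
    with np.errstate(divide="ignore"):
        logg = np.log(U) + AR[:, :, None] * el_t + BR[:, :, None] * el_1mt
    g = _normalise_log_rows(logg)
    return GenotypePosterior(g)


def update_theta(
    data: AlleleCountData,
    assignment: AssignmentPosterior,
    genotype: GenotypePosterior,
    theta_prior: ThetaPrior,
) -> ThetaPosterior:
    """Conjugate variational update of q(theta).

    alpha_t = alpha0_t + sum_ijk r[j,k] g[i,k,t] a_ij (beta analogous);
    only singlet assignment components contribute.
    """
    K = genotype.n_donors
    r = assignment.r[:, :K]
    AR = np.asarray(data.A @ r)
    BR = np.asarray(data.B @ r)
    alpha = theta_prior.alpha0 + np.einsum("ik,ikt->t", AR, genotype.g)
    beta = theta_prior.beta0 + np.einsum("ik,ikt->t", BR, genotype.g)
    return ThetaPosterior(alpha, beta)


def _random_genotype(rng: np.random.Generator, n: int, k: int) -> GenotypePosterior:
    # symmetric Dirichlet(1,1,1) per (variant, component)
    g = rng.dirichlet(np.ones(3), size=(n, k))
    return GenotypePosterior(g)


def _singlet_ascent(
    data: AlleleCountData,
    g_init: np.ndarray,
    prior_U,
    theta_prior: ThetaPrior,
    pi: np.ndarray,
    n_iters: int,
    elbo_tol: float | None,
    log_binom_const: float,
    clamp_genotype: bool = False,
):
    """Run coordinate ascent from a genotype initialisation.

    Returns (assignment, genotype, theta, elbo_trace, converged).  With
    ``clamp_genotype`` the genotype posterior stays fixed (reference-
    genotype mode) and only theta and the assignment iterate.
    """
    genotype = GenotypePosterior(np.asarray(g_init))
    theta = ThetaPosterior.from_prior(theta_prior)
    assignment = update_assignment(data, genotype, theta, pi)
    trace: list[float] = []
    converged = False
    for it in range(n_iters):
        if not clamp_genotype:
            genotype = update_genotype(data, assignment, theta, prior_U)
        theta = update_theta(data, assignment, genotype, theta_prior)
        assignment = update_assignment(data, genotype, theta, pi)
        # during fixed-length warm-up only the final ELBO is needed
        if elbo_tol is not None or it == n_iters - 1:
            trace.append(
                compute_elbo(
                    data, assignment, genotype, theta, prior_U, theta_prior,
                    log_binom_const,
                )
            )
        if elbo_tol is not None and len(trace) > 1:
            if abs(trace[-1] - trace[-2]) < elbo_tol:
                converged = True
                break
    return assignment, genotype, theta, np.array(trace), converged


def fit(
    data: AlleleCountData,
    K: int,
    prior_U: GenotypePriorMatrix | None = None,
    config: FitConfig | None = None,
    with_doublets: bool = True,
) -> DemuxFit:
    """Fit the K-donor mixture to allele counts without reference genotypes.

    Deterministic given ``config.seed``.  The returned fit carries the
    extended (doublet-aware) assignment posterior when ``with_doublets``
    and K >= 2; otherwise a singlet-only posterior.
    """
    from .doublets import build_extension, assign_extended

    config = config or FitConfig()
    n, m = data.n_variants, data.n_cells
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > m:
        raise ValueError(f"K={K} exceeds the number of cells M={m}")
    if data.D.nnz == 0:
        raise ValueError("count matrices contain no data")
    if prior_U is None:
        prior_U = GenotypePriorMatrix.uniform(n, K)
    if prior_U.U.shape[:2] != (n, K):
        raise ValueError(
            f"prior shape {prior_U.U.shape[:2]} != (n_variants={n}, K={K})"
        )

    rng = np.random.default_rng(config.seed)
    theta_prior = ThetaPrior()
    log_binom_const = log_binom_coeff_total(data)

    # --- warm-up restarts on an over-specified component space
    extra = min(config.extra_clusters(K), max(m - K, 0))
    h0 = K + extra
    # surplus components carry a uniform genotype prior
    if extra:
        U_wide = np.concatenate(
            [prior_U.U, np.full((n, extra, 3), 1.0 / 3.0)], axis=1
        )
    else:
        U_wide = prior_U.U
    pi_wide = np.full(h0, 1.0 / h0)

    best = None
    warmup_elbos = np.empty(config.n_init)
    # where the prior carries genotype information, start q(G) at the
    # prior: restarts then only explore the unknown entries and anchored
    # components keep their identity instead of label-switching
    known = prior_U.known_mask[:, :, None] if prior_U.n_known else None
    for init in range(config.n_init):
        g0 = _random_genotype(rng, n, h0)
        if known is not None:
            g0.g[:, :K, :] = np.where(known, prior_U.U, g0.g[:, :K, :])
        result = _singlet_ascent(
            data, g0.g, U_wide, theta_prior, pi_wide,
            config.warmup_iters, None, log_binom_const,
        )
        warmup_elbos[init] = result[3][-1]
        if best is None or result[3][-1] > best[3][-1]:
            best = result
    assignment, genotype, theta, _, _ = best

    # --- prune to the K components with most softly assigned cells
    if extra:
        mass = assignment.r.sum(axis=0)
        order = np.argsort(-mass, kind="stable")  # ties -> lower index first
        kept = np.sort(order[:K])
        # surviving original columns stay at their own positions so an
        # informative prior stays aligned; surviving surplus columns
        # fill the slots of pruned original columns
        keep = np.empty(K, dtype=int)
        surplus = iter(c for c in kept if c >= K)
        kept_orig = {c for c in kept if c < K}
        for p in range(K):
            keep[p] = p if p in kept_orig else next(surplus)
        genotype = GenotypePosterior(genotype.g[:, keep, :])
        log.debug("pruned components, kept %s (soft mass %s)", keep, mass[keep])

    pi = np.full(K, 1.0 / K)
    assignment, genotype, theta, trace, converged = _singlet_ascent(
        data, genotype.g, prior_U, theta_prior, pi,
        config.max_iters, config.elbo_tol, log_binom_const,
    )
    if not converged:
        last = abs(trace[-1] - trace[-2]) if len(trace) > 1 else float("nan")
        warnings.warn(
            f"ELBO not converged after {config.max_iters} iterations "
            f"(last change {last:.3g})",
            RuntimeWarning,
        )

    # --- doublet stage: extend the component space, q(G), q(theta) frozen
    eta = config.resolve_eta(m)
    if with_doublets and K >= 2:
        extension = build_extension(genotype, theta, eta, K, m)
        assignment = assign_extended(data, extension, genotype, theta)
    else:
        eta = 0.0

    return DemuxFit(
        assignment=assignment,
        genotype=genotype,
        theta=theta,
        elbo_trace=trace,
        n_donors=K,
        converged=converged,
        seed=config.seed,
        doublet_prior=eta,
        warmup_elbos=warmup_elbos,
    )
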