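"""Probabilistic core of the binomial-mixture demultiplexing model.

ALT-allele counts a_ij at variant i in cell j are binomial given the
depth d_ij with a rate theta_t set by the genotype state t in {0, 1, 2}
(copies of the ALT allele).  Cells cluster into K donors via a latent
assignment Z; donor genotypes G are themselves latent with a categorical
prior U.  Conjugate beta priors on theta encode that hom-REF cells show
almost no ALT reads, heterozygous cells about half, hom-ALT nearly all.

Variational inference uses a fully factorised q(Z) q(G) q(theta) with
categorical q(Z), q(G) and beta q(theta); this module provides the
expected log-likelihood building blocks and the evidence lower bound
(ELBO).  The expected log-binomial term is implemented in full,
a_ij E[log theta_t] + b_ij E[log(1 - theta_t)], including the
-(a+b) psi(alpha+beta) part that a softmax over components cannot drop
because the beta concentrations differ across states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.special import betaln, digamma, gammaln

from .io import AlleleCountData, GenotypePriorMatrix

#: beta hyperparameters for the ALT-allele rate of genotype states 0, 1, 2
DEFAULT_THETA_ALPHA = np.array([0.3, 3.0, 29.7])
DEFAULT_THETA_BETA = np.array([29.7, 3.0, 0.3])


@dataclass
class ThetaPrior:
    """Beta prior beta(alpha0_t, beta0_t) on the ALT rate per genotype state."""

    alpha0: np.ndarray = field(default_factory=lambda: DEFAULT_THETA_ALPHA.copy())
    beta0: np.ndarray = field(default_factory=lambda: DEFAULT_THETA_BETA.copy())

    def __post_init__(self) -> None:
        self.alpha0 = np.asarray(self.alpha0, dtype=float)
        self.beta0 = np.asarray(self.beta0, dtype=float)
        if np.any(self.alpha0 <= 0) or np.any(self.beta0 <= 0):
            raise ValueError("beta prior parameters must be positive")


@dataclass
class ThetaPosterior:
    """Posterior beta(alpha_t, beta_t) per genotype state.

    ``states`` is (0, 1, 2) for the singlet model; the doublet extension
    adds pseudo-states 0.5 and 1.5 for mixed genotypes.
    """

    alpha: np.ndarray
    beta: np.ndarray
    states: tuple = (0.0, 1.0, 2.0)

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if np.any(self.alpha <= 0) or np.any(self.beta <= 0):
            raise ValueError("beta posterior parameters must be positive")

    @property
    def mean(self) -> np.ndarray:
        return self.alpha / (self.alpha + self.beta)

    def expected_log(self) -> tuple[np.ndarray, np.ndarray]:
        """E[log theta_t] and E[log(1 - theta_t)] under the beta posterior."""
        total = digamma(self.alpha + self.beta)
        return digamma(self.alpha) - total, digamma(self.beta) - total

    @staticmethod
    def from_prior(prior: ThetaPrior) -> "ThetaPosterior":
        return ThetaPosterior(prior.alpha0.copy(), prior.beta0.copy())


@dataclass
class GenotypePosterior:
    """Variational categorical posterior g[i, k, t] over genotype states."""

    g: np.ndarray  # (N, K, 3)

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        if self.g.ndim != 3:
            raise ValueError("genotype posterior must have shape (N, K, T)")
        if not np.allclose(self.g.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("genotype posterior rows must sum to 1")

    @property
    def n_donors(self) -> int:
        return self.g.shape[1]

    def hard_calls(self) -> np.ndarray:
        """(N, K) argmax genotype states."""
        return np.argmax(self.g, axis=2)


@dataclass
class AssignmentPosterior:
    """Variational categorical posterior r[j, h] over assignment components.

    The first K columns are singlet donors; any further columns are
    doublet pseudo-donors (unordered donor pairs).  ``prob_max`` is each
    cell's highest singlet probability, ``prob_doublet`` the summed
    doublet probability.
    """

    r: np.ndarray  # (M, H)
    pi: np.ndarray  # (H,)
    n_donors: int
    doublet_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.r.shape[1] != self.pi.shape[0]:
            raise ValueError("r and pi component counts differ")
        if self.r.shape[1] != self.n_donors + len(self.doublet_pairs):
            raise ValueError("component count != n_donors + n_pairs")
        if not np.allclose(self.r.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("assignment rows must sum to 1")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-9):
            raise ValueError("pi must sum to 1")

    @property
    def n_cells(self) -> int:
        return self.r.shape[0]

    @property
    def prob_max(self) -> np.ndarray:
        return self.r[:, : self.n_donors].max(axis=1)

    @property
    def prob_doublet(self) -> np.ndarray:
        return self.r[:, self.n_donors:].sum(axis=1)

    @property
    def best_donor(self) -> np.ndarray:
        return np.argmax(self.r[:, : self.n_donors], axis=1)

    @property
    def best_doublet_pair(self) -> np.ndarray:
        """(M, 2) donor pair of the highest-probability doublet component."""
        if not self.doublet_pairs:
            return np.zeros((0, 2), dtype=int)
        idx = np.argmax(self.r[:, self.n_donors:], axis=1)
        pairs = np.asarray(self.doublet_pairs)
        return pairs[idx]


@dataclass
class DemuxFit:
    """Result of a variational fit: posteriors, ELBO trace, bookkeeping."""

    assignment: AssignmentPosterior
    genotype: GenotypePosterior
    theta: ThetaPosterior
    elbo_trace: np.ndarray
    n_donors: int
    converged: bool
    seed: int | None = None
    doublet_prior: float = 0.0
    warmup_elbos: np.ndarray | None = None

    @property
    def elbo(self) -> float:
        return float(self.elbo_trace[-1])

    def donor_depth(self, data: AlleleCountData, doublet_thresh: float = 0.9) -> np.ndarray:
        """Aggregate UMI depth per (variant, donor).

        Cells called doublets (prob_doublet > threshold) are excluded;
        remaining cells contribute their depth to their argmax donor.
        """
        hard = self.assignment.best_donor
        keep = self.assignment.prob_doublet <= doublet_thresh
        R = np.zeros((data.n_cells, self.n_donors))
        R[np.nonzero(keep)[0], hard[keep]] = 1.0
        return np.asarray(data.D @ R)


# ---------------------------------------------------------------------------
# expected likelihood terms


def expected_binom_loglik(
    data: AlleleCountData, theta: ThetaPosterior
) -> list[sp.csr_matrix]:
    """Per-entry expected log-binomial contribution for each state t.

    Returns one sparse N x M matrix per state with entries
    a_ij E[log theta_t] + b_ij E[log(1 - theta_t)]; entries with no
    depth contribute nothing (they are not stored).  The binomial
    coefficient is constant in the latent variables and excluded here.
    """
    el_t, el_1mt = theta.expected_log()
    if not np.all(np.isfinite(el_t)) or not np.all(np.isfinite(el_1mt)):
        bad = np.nonzero(~(np.isfinite(el_t) & np.isfinite(el_1mt)))[0]
        raise FloatingPointError(
            f"non-finite expected log-likelihood for state index {bad[0]}"
        )
    A = data.A
    B = data.B
    out = []
    for t in range(len(theta.alpha)):
        W = (A * el_t[t] + B * el_1mt[t]).tocsr()
        out.append(W)
    return out


def log_binom_coeff_total(data: AlleleCountData) -> float:
    """Sum of log C(d_ij, a_ij) over stored entries (constant data term).

    Decomposes as sum gammaln(d+1) - gammaln(a+1) - gammaln(b+1) over the
    stored patterns of D, A and B = D - A; unstored (zero) factors are
    gammaln(1) = 0, so each sum can run over its own matrix's data.
    """
    B = data.D - data.A
    return float(
        gammaln(data.D.data + 1).sum()
        - gammaln(data.A.data + 1).sum()
        - gammaln(B.data + 1).sum()
    )


def beta_kl(alpha, beta, alpha0, beta0) -> np.ndarray:
    """KL(beta(alpha, beta) || beta(alpha0, beta0)) elementwise."""
    alpha, beta = np.asarray(alpha, float), np.asarray(beta, float)
    alpha0, beta0 = np.asarray(alpha0, float), np.asarray(beta0, float)
    return (
        betaln(alpha0, beta0)
        - betaln(alpha, beta)
        + (alpha - alpha0) * digamma(alpha)
        + (beta - beta0) * digamma(beta)
        + (alpha0 - alpha + beta0 - beta) * digamma(alpha + beta)
    )


def _xlogy(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # 0 log 0 := 0
    out = np.zeros_like(x)
    mask = x > 0
    out[mask] = x[mask] * np.log(y[mask])
    return out


def expected_loglik_matrix(
    data: AlleleCountData,
    genotype: GenotypePosterior,
    theta: ThetaPosterior,
) -> np.ndarray:
    """(M, K) expected data log-likelihood of each cell under each donor.

    S[j, k] = sum_i sum_t g[i,k,t] (a_ij E[log theta_t] +
    b_ij E[log(1-theta_t)]), computed by folding the state sum into two
    dense N x K matrices so only two sparse products are needed.
    """
    el_t, el_1mt = theta.expected_log()
    Gt = genotype.g @ el_t  # (N, K)
    G1 = genotype.g @ el_1mt
    return np.asarray(data.A.T @ Gt + data.B.T @ G1)


def compute_elbo(
    data: AlleleCountData,
    assignment: AssignmentPosterior,
    genotype: GenotypePosterior,
    theta: ThetaPosterior,
    prior_U: GenotypePriorMatrix | np.ndarray,
    theta_prior: ThetaPrior,
    log_binom_const: float | None = None,
) -> float:
    """Evidence lower bound L(q) of the singlet model.

    L(q) = E_q[log p(A,D|Z,G,theta)] + E_q[log p(Z|pi) - log q(Z)]
         + E_q[log p(G|U) - log q(G)] - KL(q(theta) || p(theta)),
    with the binomial coefficients included once in the data term so the
    reported value is an actual lower bound on log p(A, D).
    """
    if assignment.doublet_pairs:
        raise ValueError("ELBO is defined for the singlet model only")
    U = prior_U.U if isinstance(prior_U, GenotypePriorMatrix) else np.asarray(prior_U)
    r = assignment.r
    g = genotype.g
    if log_binom_const is None:
        log_binom_const = log_binom_coeff_total(data)

    S = expected_loglik_matrix(data, genotype, theta)
    e_data = float(np.sum(r * S)) + log_binom_const

    log_pi = np.log(assignment.pi)
    e_z = float(np.sum(r * log_pi)) - float(np.sum(_xlogy(r, r)))

    e_g = float(np.sum(_xlogy(g, U))) - float(np.sum(_xlogy(g, g)))

    e_theta = -float(
        np.sum(beta_kl(theta.alpha, theta.beta, theta_prior.alpha0, theta_prior.beta0))
    )

    elbo = e_data + e_z + e_g + e_theta
    if not np.isfinite(elbo):
        raise FloatingPointError("non-finite ELBO")
    return elbo
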