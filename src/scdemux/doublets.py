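"""Doublet pseudo-donors: combined genotypes and doublet-aware assignment.

A droplet containing cells from two distinct donors shows allele
fractions intermediate between the two donor genotypes.  The model
captures this by appending K(K-1)/2 pseudo-donors, one per unordered
donor pair, whose genotype distribution over the extended state space
{0, 0.5, 1, 1.5, 2} is the convolution of the two donors' (scaled by
1/2): e.g. state 0.5 arises from a hom-REF cell mixed with a
heterozygous one.  The ALT rates of the pseudo-states 0.5 and 1.5 get
beta distributions whose mean is the arithmetic mean of the two
component means and whose concentration is the geometric mean of the
two concentrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import AlleleCountData
from .model import (
    AssignmentPosterior,
    GenotypePosterior,
    ThetaPosterior,
    expected_loglik_matrix,
)

EXTENDED_STATES = (0.0, 0.5, 1.0, 1.5, 2.0)
#: positions of the ordinary genotypes 0, 1, 2 within the extended states
SINGLET_STATE_IDX = np.array([0, 2, 4])


@dataclass
class DoubletExtension:
    """Doublet pseudo-donor components of the extended mixture."""

    pairs: list[tuple[int, int]]
    g_doublet: np.ndarray  # (N, K2, 5)
    theta_extended: ThetaPosterior  # 5 states
    pi_extended: np.ndarray  # (K + K2,)
    eta: float

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def combine_genotype_probs(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Genotype distribution of a two-donor mixture.

    ``x`` and ``y`` are probability 3-vectors (or stacks of them, last
    axis 3) over states {0, 1, 2}; the result is over {0, 0.5, 1, 1.5, 2}.
    Symmetric in (x, y) and normalised whenever the inputs are.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x0, x1, x2 = x[..., 0], x[..., 1], x[..., 2]
    y0, y1, y2 = y[..., 0], y[..., 1], y[..., 2]
    return np.stack(
        [
            x0 * y0,
            x0 * y1 + x1 * y0,
            x1 * y1 + x0 * y2 + x2 * y0,
            x1 * y2 + x2 * y1,
            x2 * y2,
        ],
        axis=-1,
    )


def doublet_theta_params(theta: ThetaPosterior) -> ThetaPosterior:
    """Beta parameters over the extended 5-state space.

    For each pseudo-state the mean is the arithmetic mean of the two
    neighbouring ordinary-state means and the concentration
    alpha + beta is the geometric mean of their concentrations.
    """
    a, b = theta.alpha, theta.beta
    if len(a) != 3:
        raise ValueError("expected a 3-state theta posterior")
    mean = a / (a + b)
    conc = a + b

    def _pseudo(i: int, j: int) -> tuple[float, float]:
        mu = 0.5 * (mean[i] + mean[j])
        s = np.sqrt(conc[i] * conc[j])
        return mu * s, (1.0 - mu) * s

    a05, b05 = _pseudo(0, 1)
    a15, b15 = _pseudo(1, 2)
    return ThetaPosterior(
        np.array([a[0], a05, a[1], a15, a[2]]),
        np.array([b[0], b05, b[1], b15, b[2]]),
        states=EXTENDED_STATES,
    )


def donor_pairs(K: int) -> list[tuple[int, int]]:
    return [(k, l) for k in range(K) for l in range(k + 1, K)]


def build_extension(
    genotype: GenotypePosterior,
    theta: ThetaPosterior,
    eta: float | str,
    K: int,
    M: int,
) -> DoubletExtension:
    """Construct the doublet components from a fitted singlet model.

    Prior mass is (1 - eta)/K per singlet donor and eta/K2 per doublet
    pair; eta = "auto" resolves to M / 100,000.
    """
    if eta == "auto":
        eta = min(M / 100_000.0, 0.5)
    eta = float(eta)
    if K < 2:
        warnings.warn("doublet extension needs K >= 2; returning empty extension")
        return DoubletExtension(
            [], np.zeros((genotype.g.shape[0], 0, 5)),
            doublet_theta_params_or_none(theta), np.full(max(K, 1), 1.0 / max(K, 1)),
            0.0,
        )
    pairs = donor_pairs(K)
    k2 = len(pairs)
    ka = np.array([p[0] for p in pairs])
    kb = np.array([p[1] for p in pairs])
    g_doublet = combine_genotype_probs(genotype.g[:, ka, :], genotype.g[:, kb, :])
    pi_ext = np.concatenate(
        [np.full(K, (1.0 - eta) / K), np.full(k2, eta / k2)]
    )
    return DoubletExtension(pairs, g_doublet, doublet_theta_params(theta), pi_ext, eta)


def doublet_theta_params_or_none(theta: ThetaPosterior) -> ThetaPosterior:
    try:
        return doublet_theta_params(theta)
    except ValueError:
        return theta


def assign_extended(
    data: AlleleCountData,
    extension: DoubletExtension,
    genotype: GenotypePosterior,
    theta: ThetaPosterior,
) -> AssignmentPosterior:
    """Assignment posterior over K singlet + K2 doublet components.

    The singlet columns use the 3-state genotype posterior and theta;
    doublet columns use the combined 5-state genotypes and the extended
    theta.  Zero-coverage cells fall back to the extended prior, so their
    summed doublet probability equals eta.
    """
    K = genotype.n_donors
    if not extension.pairs:
        pi = np.full(K, 1.0 / K)
        from .inference import update_assignment

        return update_assignment(data, genotype, theta, pi)

    th_ext = extension.theta_extended
    el_t, el_1mt = th_ext.expected_log()

    # embed the singlet 3-state posterior into the 5-state space so the
    # whole expected log-likelihood is two sparse products
    g_sing = np.zeros((genotype.g.shape[0], K, 5))
    g_sing[:, :, SINGLET_STATE_IDX] = genotype.g
    g_all = np.concatenate([g_sing, extension.g_doublet], axis=1)

    ext_genotype = GenotypePosterior.__new__(GenotypePosterior)
    ext_genotype.g = g_all  # bypass validation: doublet rows sum to 1 anyway
    S = expected_loglik_matrix(data, ext_genotype, th_ext)
    logr = S + np.log(extension.pi_extended)
    logr -= logr.max(axis=1, keepdims=True)
    r = np.exp(logr)
    r /= r.sum(axis=1, keepdims=True)
    return AssignmentPosterior(r, extension.pi_extended, K, list(extension.pairs))
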