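"""Donor alignment across runs and discriminatory variant panels.

Inferred donors carry no identity.  Two fits on data from the same
individuals (different batches, or single-cell vs bulk) can be linked by
comparing their reconstructed genotypes: over variants with adequate
coverage in both donors, the fraction of agreeing hard genotype calls is
a sharp similarity signal (same individual ~1, different individuals
well below).  A globally optimal one-to-one matching on that concordance
matrix aligns the two runs.

The panel designer picks a minimal set of variants whose joint genotype
patterns distinguish all K donors, greedily maximising information gain
on the partition of donors; it is useful for confirming donor identity
by targeted (e.g. qPCR) genotyping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .model import GenotypePosterior


@dataclass
class ConcordanceMatrix:
    """Pairwise donor genotype concordance between two fits.

    ``values[k, l]`` is the fraction of shared well-covered variants on
    which donors k (run A) and l (run B) agree; NaN when no variant
    qualifies.  ``n_shared_variants`` counts the qualifying variants.
    """

    values: np.ndarray  # (K1, K2), fractions or NaN
    n_shared_variants: np.ndarray  # (K1, K2) ints


def genotype_concordance(
    gA: GenotypePosterior,
    depthA: np.ndarray,
    gB: GenotypePosterior,
    depthB: np.ndarray,
    min_umis: int = 10,
) -> ConcordanceMatrix:
    """Fraction of concordant hard genotypes between donor pairs.

    Both fits must share the same variant universe (same row order).
    Only variants with aggregate depth >= ``min_umis`` in both donors of
    a pair enter the comparison.
    """
    if gA.g.shape[0] != gB.g.shape[0]:
        raise ValueError("fits do not share a variant universe")
    hardA = gA.hard_calls()
    hardB = gB.hard_calls()
    okA = np.asarray(depthA) >= min_umis  # (N, K1)
    okB = np.asarray(depthB) >= min_umis  # (N, K2)
    k1, k2 = hardA.shape[1], hardB.shape[1]
    values = np.full((k1, k2), np.nan)
    counts = np.zeros((k1, k2), dtype=int)
    for k in range(k1):
        both = okA[:, [k]] & okB  # (N, K2)
        agree = (hardA[:, [k]] == hardB) & both
        n = both.sum(axis=0)
        counts[k] = n
        with np.errstate(invalid="ignore"):
            values[k] = np.where(n > 0, agree.sum(axis=0) / np.maximum(n, 1), np.nan)
    return ConcordanceMatrix(values, counts)


def match_donors(cm: ConcordanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Globally optimal one-to-one donor matching.

    Returns ``(mapping, scores)`` where ``mapping[k]`` is the run-B donor
    matched to run-A donor k (-1 if unmatched, which happens only when
    K1 > K2) and ``scores[k]`` the concordance of that match.  Missing
    concordance values count as 0.  Ties are broken towards the
    lowest-index pairing.
    """
    values = np.nan_to_num(cm.values, nan=0.0)
    k1, k2 = values.shape
    # epsilon preference for low-index pairs makes ties deterministic
    eps = np.finfo(float).eps * 64
    bias = eps * (np.arange(k1)[:, None] + np.arange(k2)[None, :])
    rows, cols = linear_sum_assignment(values - bias, maximize=True)
    mapping = np.full(k1, -1, dtype=int)
    scores = np.zeros(k1)
    mapping[rows] = cols
    scores[rows] = values[rows, cols]
    return mapping, scores


# ---------------------------------------------------------------------------
# discriminatory variant panels


def _partition_entropy(labels: np.ndarray) -> float:
    """Entropy (bits) of a donor partition with block-size weights."""
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _refine(labels: np.ndarray, pattern: np.ndarray) -> np.ndarray:
    """Split each block of ``labels`` by ``pattern``; canonical block ids."""
    _, new = np.unique(
        np.stack([labels, pattern]), axis=1, return_inverse=True
    )
    return new


@dataclass
class VariantPanel:
    """Result of the greedy panel search."""

    variants: list[int]  # selected variant indices, in selection order
    partition: np.ndarray  # final block label per donor
    entropy: float  # bits; log2(K) means all donors distinguished
    complete: bool
    unresolved_blocks: list[list[int]]


def select_discriminatory_variants(
    g: GenotypePosterior,
    donor_depth: np.ndarray,
    K: int | None = None,
    min_umis: int = 20,
    exclude_all_hom_alt: bool = False,
) -> VariantPanel:
    """Greedy minimal panel of variants that separates the donors.

    Candidates must carry >= ``min_umis`` aggregate depth in every donor
    (their hard genotype calls are otherwise unreliable); optionally
    variants called hom-ALT in every donor are dropped.  Starting from
    the trivial one-block partition (entropy 0), each step adds the
    variant whose hard genotype pattern maximally raises the partition
    entropy, stopping at log2(K) bits (all donors separated) or when no
    variant adds information (donors with identical usable genotypes).
    Ties are broken by higher total depth, then lower variant index.
    """
    hard = g.hard_calls()
    n, k = hard.shape
    if K is None:
        K = k
    if K < 2:
        raise ValueError("panel design needs at least two donors")
    depth = np.asarray(donor_depth)
    usable = (depth >= min_umis).all(axis=1)
    if exclude_all_hom_alt:
        usable &= ~(hard == 2).all(axis=1)
    candidates = np.nonzero(usable)[0]
    total_depth = depth.sum(axis=1)

    labels = np.zeros(k, dtype=int)
    h_now = 0.0
    h_target = np.log2(K)
    selected: list[int] = []
    remaining = list(candidates)
    while h_now < h_target - 1e-12 and remaining:
        best = None  # (gain, depth, -index, variant, refined_labels)
        for v in remaining:
            refined = _refine(labels, hard[v])
            gain = _partition_entropy(refined) - h_now
            key = (gain, total_depth[v], -v)
            if best is None or key > best[0]:
                best = (key, v, refined)
        gain = best[0][0]
        if gain <= 1e-12:
            break
        _, v, refined = best
        selected.append(int(v))
        remaining.remove(v)
        labels = refined
        h_now += gain

    complete = h_now >= h_target - 1e-9
    unresolved = []
    if not complete:
        for block in np.unique(labels):
            members = np.nonzero(labels == block)[0].tolist()
            if len(members) > 1:
                unresolved.append(members)
        warnings.warn(
            f"donors not fully separable from usable variants; "
            f"unresolved donor blocks: {unresolved}"
        )
    return VariantPanel(selected, labels, h_now, complete, unresolved)


def panel_table(panel: VariantPanel, g: GenotypePosterior, variants) -> pd.DataFrame:
    """Tabulate a panel: variant id plus each donor's hard genotype."""
    hard = g.hard_calls()
    rows = []
    for v in panel.variants:
        row = {"variant": variants.ids[v]}
        row.update({f"donor{k}": int(hard[v, k]) for k in range(hard.shape[1])})
        rows.append(row)
    return pd.DataFrame(rows)
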