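"""Evaluation metrics against simulated ground truth.

Covers the three headline views of demultiplexing quality: the
ARI-recall curve for singlet assignment (clustering agreement among the
cells retained at a confidence cutoff, swept over cutoffs), the ROC of
the doublet score, and the precision of the reconstructed donor
genotypes at adequately covered sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, roc_auc_score, roc_curve

from .model import AssignmentPosterior, GenotypePosterior
from .simulate import SimTruth


@dataclass
class AriRecallCurve:
    thresholds: np.ndarray
    recall: np.ndarray
    ari: np.ndarray
    area: float


def ari_recall_curve(
    assignment: AssignmentPosterior,
    truth: SimTruth,
    thresholds: np.ndarray | None = None,
) -> AriRecallCurve:
    """ARI of confident singlet assignments versus retained recall.

    For each threshold tau, cells that are true singlets with
    prob_max > tau are retained; recall is the retained fraction of true
    singlets and ARI compares argmax donor to the true donor over the
    retained cells.  The area is the trapezoid integral of ARI over
    recall on [0, 1] (tau = 0 retains everything, recall 1).
    """
    if thresholds is None:
        thresholds = np.linspace(0.0, 0.99, 34)
    singlet = ~truth.is_doublet
    if assignment.n_cells != truth.is_doublet.size:
        raise ValueError("assignment and truth cover different cells")
    prob_max = assignment.prob_max
    best = assignment.best_donor
    n_singlets = singlet.sum()

    recs, aris, taus = [], [], []
    for tau in np.sort(thresholds):
        sel = singlet & (prob_max > tau)
        if not sel.any():
            continue
        recs.append(sel.sum() / n_singlets)
        aris.append(adjusted_rand_score(truth.donor_of_cell[sel], best[sel]))
        taus.append(tau)
    recall = np.asarray(recs)
    ari = np.asarray(aris)
    order = np.argsort(recall)
    # extend the curve to recall 0 with the last (most confident) ARI so
    # the integral spans [0, 1]
    r_grid = np.concatenate([[0.0], recall[order]])
    a_grid = np.concatenate([[ari[order][0]], ari[order]])
    area = float(np.trapezoid(a_grid, r_grid))
    return AriRecallCurve(np.asarray(taus), recall, ari, area)


@dataclass
class DoubletRoc:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    sensitivity: float  # at the operating threshold
    specificity: float
    threshold: float


def doublet_roc(
    assignment: AssignmentPosterior,
    truth: SimTruth,
    threshold: float = 0.9,
) -> DoubletRoc:
    """ROC of the doublet score against true doublet labels.

    Also reports sensitivity and specificity of the hard call
    prob_doublet > ``threshold``.
    """
    y = truth.is_doublet.astype(int)
    if y.min() == y.max():
        raise ValueError("truth contains a single class; ROC undefined")
    score = assignment.prob_doublet
    fpr, tpr, _ = roc_curve(y, score)
    auc = float(roc_auc_score(y, score))
    called = score > threshold
    sens = float(called[y == 1].mean())
    spec = float((~called[y == 0]).mean())
    return DoubletRoc(fpr, tpr, auc, sens, spec, threshold)


def genotype_precision(
    genotype: GenotypePosterior,
    donor_depth: np.ndarray,
    truth: SimTruth,
    mapping: np.ndarray,
    min_umis: int = 10,
    variants=None,
) -> dict:
    """Precision of reconstructed genotypes at covered sites.

    ``mapping[k]`` gives the true donor matched to inferred component k.
    Over (variant, donor) entries with aggregate depth >= ``min_umis``,
    overall precision is the fraction of correct argmax calls; per-state
    precision conditions on the predicted state.  Pass ``variants`` (the
    fitted, possibly filtered variant table) to align the truth rows.
    """
    true_genotypes = (
        truth.genotypes_for(variants) if variants is not None else truth.genotypes
    )
    hard = genotype.hard_calls()
    k = hard.shape[1]
    pred, true = [], []
    for comp in range(k):
        if mapping[comp] < 0:
            continue
        ok = np.asarray(donor_depth)[:, comp] >= min_umis
        pred.append(hard[ok, comp])
        true.append(true_genotypes[ok, mapping[comp]])
    if not pred or not np.concatenate(pred).size:
        raise ValueError(f"no (variant, donor) entries with depth >= {min_umis}")
    pred = np.concatenate(pred)
    true = np.concatenate(true)
    out = {"overall": float((pred == true).mean()), "n": int(pred.size)}
    for t, name in enumerate(["hom_ref", "het", "hom_alt"]):
        sel = pred == t
        out[name] = float((true[sel] == t).mean()) if sel.any() else float("nan")
        out[f"n_{name}"] = int(sel.sum())
    return out


def evaluation_report(fit, data, truth, min_umis: int = 10) -> dict:
    """End-to-end evaluation of a fit against simulator truth.

    Matches inferred donors to true donors by genotype concordance and
    returns singlet ARI, ARI-recall area, doublet ROC summary and
    genotype precision as a flat dict.
    """
    from .matching import genotype_concordance, match_donors

    singlet = ~truth.is_doublet
    ari = adjusted_rand_score(
        truth.donor_of_cell[singlet], fit.assignment.best_donor[singlet]
    )
    curve = ari_recall_curve(fit.assignment, truth)
    roc = doublet_roc(fit.assignment, truth)
    depth = fit.donor_depth(data)
    aligned = truth.genotypes_for(data.variants)
    true_g = GenotypePosterior(np.eye(3)[aligned])
    depth_true = np.full(aligned.shape, np.inf)
    cm = genotype_concordance(fit.genotype, depth, true_g, depth_true, min_umis)
    mapping, scores = match_donors(cm)
    precision = genotype_precision(
        fit.genotype, depth, truth, mapping, min_umis, variants=data.variants
    )
    return {
        "singlet_ari": float(ari),
        "ari_recall_area": curve.area,
        "doublet_auc": roc.auc,
        "doublet_sensitivity": roc.sensitivity,
        "doublet_specificity": roc.specificity,
        "genotype_precision_overall": precision["overall"],
        "genotype_precision_het": precision["het"],
        "donor_mapping": mapping.tolist(),
        "mapping_concordance": [float(s) for s in scores],
    }
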