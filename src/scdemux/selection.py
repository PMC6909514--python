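"""Estimating the number of pooled donors.

Fitting the mixture at increasing K and comparing the converged evidence
lower bounds gives an elbow-shaped curve: the bound rises steeply until
K reaches the true pool size and then flattens, because surplus
components attract almost no cells (the variational treatment is
self-regularising).  Both signals — the elbow and the per-component soft
cell mass — are exposed here; the numeric elbow rule is a convenience
heuristic and the raw curve is always returned.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .inference import FitConfig, fit
from .io import AlleleCountData


@dataclass
class DonorNumberScan:
    """ELBOs and component occupancies across candidate pool sizes."""

    table: pd.DataFrame  # columns: K, elbo, converged
    soft_counts: dict[int, np.ndarray]  # K -> sorted soft cell mass per component
    elbow_k: int | None  # None for single-K scans
    elbow_fraction: float


def scan_n_donors(
    data: AlleleCountData,
    k_range,
    config: FitConfig | None = None,
    elbow_fraction: float = 0.1,
) -> DonorNumberScan:
    """Fit the model for each K in ``k_range`` and summarise the ELBOs.

    All fits share the same restart seeds so the curves are comparable.
    The elbow is the last K before the ELBO gain first drops below
    ``elbow_fraction`` of the largest gain in the scan.
    """
    ks = sorted(int(k) for k in k_range)
    if not ks:
        raise ValueError("empty K range")
    if ks[0] < 1 or ks[-1] > data.n_cells:
        raise ValueError(f"K range {ks[0]}..{ks[-1]} outside [1, M]")
    config = config or FitConfig()

    rows = []
    soft_counts: dict[int, np.ndarray] = {}
    for k in ks:
        f = fit(data, k, None, replace(config), with_doublets=False)
        mass = f.assignment.r.sum(axis=0)
        soft_counts[k] = np.sort(mass)[::-1]
        rows.append({"K": k, "elbo": f.elbo, "converged": f.converged})
    table = pd.DataFrame(rows)

    elbow_k = None
    if len(ks) > 1:
        elbos = table["elbo"].to_numpy()
        gains = np.diff(elbos)
        max_gain = gains.max()
        low = np.nonzero(gains < elbow_fraction * max(max_gain, 0))[0]
        if max_gain <= 0:
            elbow_k = ks[0]
        elif low.size:
            elbow_k = ks[low[0]]  # K before the first weak gain
        else:
            elbow_k = ks[-1]
    return DonorNumberScan(table, soft_counts, elbow_k, elbow_fraction)
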