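"""Generative simulator for pooled single-cell allele counts.

Donor genotypes are drawn per variant under Hardy-Weinberg equilibrium
with a uniform minor-allele-frequency law; each singlet cell covers a
sparse random subset of variants (droplet scRNA-seq genotypes on the
order of a hundred expressed variants per cell) with geometric UMI
depths, and ALT counts are binomial with a rate set by the cell's donor
genotype.  Doublets are sums of two independently drawn singlet count
profiles from distinct donors, appended to the pool at a configurable
rate (default: the droplet loading rule, number of cells / 100,000,
i.e. 8% for the default 8 donors x 1000 cells).

Everything is deterministic given the seed, and the ground truth (donor
labels, doublet flags, genotypes) is returned for evaluation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import (
    AlleleCountData,
    GenotypePriorMatrix,
    VariantTable,
    write_count_matrices,
)


@dataclass
class SimConfig:
    """Design of a simulated pool.

    ``cells_per_donor`` may be a single count or a per-donor list to
    emulate biased pools.  ``doublet_rate`` "auto" applies the loading
    rule n_singlets / 100,000.  ``coverage_rate`` is the probability
    that a cell covers a given variant; with the defaults (2000 variants
    x 0.05) each cell covers ~100 variants.  ``depth_mean`` is the mean
    of the geometric (support >= 1) UMI depth per covered variant.
    ``theta`` gives the ALT-read rate for genotypes 0, 1, 2.
    """

    n_donors: int = 8
    cells_per_donor: int | list[int] = 1000
    doublet_rate: float | str = "auto"
    n_variants: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    coverage_rate: float = 0.05
    depth_mean: float = 2.0
    theta: tuple[float, float, float] = (0.01, 0.5, 0.99)
    depth_subsample: float = 1.0  # binomial thinning of depths, emulates
    # read subsampling of the library
    seed: int = 0

    def cells_vector(self) -> np.ndarray:
        if np.isscalar(self.cells_per_donor):
            return np.full(self.n_donors, int(self.cells_per_donor))
        v = np.asarray(self.cells_per_donor, dtype=int)
        if v.shape != (self.n_donors,):
            raise ValueError("cells_per_donor list must have one entry per donor")
        return v

    def resolve_doublet_rate(self) -> float:
        n_singlets = int(self.cells_vector().sum())
        if self.doublet_rate == "auto":
            return n_singlets / 100_000.0
        rate = float(self.doublet_rate)
        if not (0.0 <= rate < 1.0):
            raise ValueError("doublet rate must be in [0, 1)")
        return rate


@dataclass
class SimTruth:
    """Ground truth emitted with each simulated pool."""

    donor_of_cell: np.ndarray  # (M,) donor index; for doublets, first member
    second_donor: np.ndarray  # (M,) second member of the pair, or -1
    is_doublet: np.ndarray  # (M,) bool
    genotypes: np.ndarray  # (N, K) hard genotypes
    variant_ids: np.ndarray | None = None  # ids aligned with genotype rows

    def genotypes_for(self, variants) -> np.ndarray:
        """Genotype rows aligned to a (possibly filtered) variant table."""
        if self.variant_ids is None:
            return self.genotypes
        lookup = {v: i for i, v in enumerate(self.variant_ids)}
        idx = np.array([lookup[v] for v in variants.ids])
        return self.genotypes[idx]

    @property
    def n_singlets(self) -> int:
        return int((~self.is_doublet).sum())

    def labels(self) -> np.ndarray:
        """String labels: 'donorK' for singlets, 'donorK,donorL' for doublets."""
        out = np.array([f"donor{d}" for d in self.donor_of_cell], dtype=object)
        dbl = np.nonzero(self.is_doublet)[0]
        for j in dbl:
            out[j] = f"donor{self.donor_of_cell[j]},donor{self.second_donor[j]}"
        return out

    def to_frame(self, cells: list[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell": cells,
                "label": self.labels(),
                "donor": self.donor_of_cell,
                "second_donor": self.second_donor,
                "is_doublet": self.is_doublet.astype(int),
            }
        )

    def prior_matrix(self, relax_rate: float = 0.05) -> GenotypePriorMatrix:
        """The true genotypes encoded as a (relaxed) reference prior."""
        return GenotypePriorMatrix.from_hard_genotypes(self.genotypes, relax_rate)


def _singlet_counts(
    rng: np.random.Generator,
    genotypes: np.ndarray,
    donor: int,
    cfg: SimConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sparse (variant_idx, depth, alt) triplets for one singlet cell."""
    n = cfg.n_variants
    covered = np.nonzero(rng.random(n) < cfg.coverage_rate)[0]
    if covered.size == 0:
        return covered, np.empty(0, int), np.empty(0, int)
    p_geom = 1.0 / cfg.depth_mean
    d = rng.geometric(p_geom, size=covered.size)
    if cfg.depth_subsample < 1.0:
        d = rng.binomial(d, cfg.depth_subsample)
        keep = d > 0
        covered, d = covered[keep], d[keep]
    theta = np.asarray(cfg.theta)[genotypes[covered, donor]]
    a = rng.binomial(d, theta)
    return covered, d, a


def simulate_pool(config: SimConfig) -> tuple[AlleleCountData, SimTruth]:
    """Generate a pooled dataset plus ground truth.

    Singlet cells are grouped by donor in the emitted order; doublets
    are appended at the end (ordering carries no information the model
    can exploit).
    """
    cfg = config
    if cfg.n_donors < 1:
        raise ValueError("need at least one donor")
    rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n_variants, cfg.n_donors
    cells_per_donor = cfg.cells_vector()
    n_singlets = int(cells_per_donor.sum())
    rate = cfg.resolve_doublet_rate()
    n_doublets = int(round(rate * n_singlets))
    if n_doublets > 0 and k < 2:
        raise ValueError("doublets require at least two donors")

    maf = rng.uniform(*cfg.maf_range, size=n)
    genotypes = rng.binomial(2, maf[:, None], size=(n, k))

    rows, cols, dd, aa = [], [], [], []
    donor_of_cell = np.empty(n_singlets + n_doublets, dtype=int)
    second_donor = np.full(n_singlets + n_doublets, -1, dtype=int)
    is_doublet = np.zeros(n_singlets + n_doublets, dtype=bool)

    j = 0
    for donor, count in enumerate(cells_per_donor):
        for _ in range(count):
            v, d, a = _singlet_counts(rng, genotypes, donor, cfg)
            rows.append(v)
            cols.append(np.full(v.size, j))
            dd.append(d)
            aa.append(a)
            donor_of_cell[j] = donor
            j += 1

    for _ in range(n_doublets):
        d1, d2 = rng.choice(k, size=2, replace=False)
        agg: dict[int, list[int]] = {}
        for donor in (d1, d2):
            v, d, a = _singlet_counts(rng, genotypes, donor, cfg)
            for vi, di, ai in zip(v, d, a):
                if vi in agg:
                    agg[vi][0] += di
                    agg[vi][1] += ai
                else:
                    agg[vi] = [di, ai]
        v = np.fromiter(agg.keys(), dtype=int, count=len(agg))
        d = np.array([agg[vi][0] for vi in v], dtype=int)
        a = np.array([agg[vi][1] for vi in v], dtype=int)
        rows.append(v)
        cols.append(np.full(v.size, j))
        dd.append(d)
        aa.append(a)
        donor_of_cell[j] = min(d1, d2)
        second_donor[j] = max(d1, d2)
        is_doublet[j] = True
        j += 1

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    m = n_singlets + n_doublets
    D = sp.csr_matrix((np.concatenate(dd), (rows, cols)), shape=(n, m))
    A = sp.csr_matrix(
        (np.concatenate(aa).astype(float), (rows, cols)), shape=(n, m)
    )
    A.eliminate_zeros()

    variants = VariantTable.from_arrays(
        chrom=np.full(n, "1"),
        pos=np.arange(1, n + 1) * 100,
        ref=np.full(n, "A"),
        alt=np.full(n, "G"),
    )
    cells = [f"CELL{j:06d}" for j in range(m)]
    data = AlleleCountData(A, D, cells, variants)
    truth = SimTruth(
        donor_of_cell, second_donor, is_doublet, genotypes, variants.ids
    )
    return data, truth


def write_pool(
    data: AlleleCountData, truth: SimTruth, dir_path: str | os.PathLike
) -> None:
    """Write a simulated pool in the standard sparse layout plus truth.tsv
    and a donor genotype VCF (GT tag) for reference-based runs."""
    dir_path = str(dir_path)
    write_count_matrices(data, dir_path)
    truth.to_frame(data.cells).to_csv(
        os.path.join(dir_path, "truth.tsv"), sep="\t", index=False
    )
    _write_truth_vcf(
        truth.genotypes, data.variants, os.path.join(dir_path, "donors.vcf")
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1"}


def _write_truth_vcf(genotypes: np.ndarray, variants: VariantTable, path: str) -> None:
    n, k = genotypes.shape
    names = [f"donor{j}" for j in range(k)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(variants.df["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(names) + "\n"
        )
        for i, row in enumerate(variants.df.itertuples(index=False)):
            gts = "\t".join(_GT_STR[int(genotypes[i, j])] for j in range(k))
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )
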