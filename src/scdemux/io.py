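"""Reading and writing of on-disk artifacts.

The expected input layout is the sparse pileup produced by cell-level
variant counting tools: two Matrix-Market matrices of per-variant,
per-cell UMI counts (ALT allele and total depth), a VCF listing the
variants, and a plain list of cell barcodes.  This module also encodes
donor genotype VCFs as soft priors over the three genotype states and
serialises fitted results (per-cell assignments, per-donor genotype
calls).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
import scipy.io
import scipy.sparse as sp

log = logging.getLogger(__name__)

#: default file names of the sparse pileup layout
AD_FILE = "cellSNP.tag.AD.mtx"
DP_FILE = "cellSNP.tag.DP.mtx"
VCF_FILE = "cellSNP.base.vcf"
BARCODE_FILE = "cellSNP.samples.tsv"


class CountDataError(ValueError):
    """Raised when count matrices, variants and barcodes disagree."""


@dataclass
class VariantTable:
    """Bi-allelic SNVs, one row per variant.

    ``df`` has columns ``chrom, pos, ref, alt, id`` with 1-based ``pos``.
    Variant ids default to ``chrom_pos_ref_alt`` when the VCF ID is ".".
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "ref", "alt", "id"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"variant table missing columns: {sorted(missing)}")
        if self.df["id"].duplicated().any():
            dup = self.df["id"][self.df["id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate variant id: {dup}")
        if (self.df["pos"] < 1).any():
            raise ValueError("variant positions must be 1-based (>= 1)")
        if (self.df["ref"] == self.df["alt"]).any():
            raise ValueError("REF and ALT alleles must differ")

    @property
    def n_variants(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> np.ndarray:
        return self.df["id"].to_numpy()

    def subset(self, idx) -> "VariantTable":
        return VariantTable(self.df.iloc[np.asarray(idx)].reset_index(drop=True))

    @staticmethod
    def from_arrays(chrom, pos, ref, alt, vid=None) -> "VariantTable":
        df = pd.DataFrame(
            {"chrom": chrom, "pos": np.asarray(pos, dtype=int), "ref": ref, "alt": alt}
        )
        if vid is None:
            vid = [None] * len(df)
        df["id"] = [
            v if v not in (None, ".", "") else f"{c}_{p}_{r}_{a}"
            for v, c, p, r, a in zip(vid, df.chrom, df.pos, df.ref, df.alt)
        ]
        return VariantTable(df)


@dataclass
class AlleleCountData:
    """Sparse ALT-allele (``A``) and total-depth (``D``) UMI counts.

    Both matrices are N variants x M cells; every stored ALT count must
    have a stored depth with ``0 <= a_ij <= d_ij``.
    """

    A: sp.csr_matrix
    D: sp.csr_matrix
    cells: list[str]
    variants: VariantTable

    def __post_init__(self) -> None:
        self.A = sp.csr_matrix(self.A)
        self.D = sp.csr_matrix(self.D)
        if self.A.shape != self.D.shape:
            raise CountDataError(
                f"ALT matrix shape {self.A.shape} != depth matrix shape {self.D.shape}"
            )
        n, m = self.D.shape
        if m != len(self.cells):
            raise CountDataError(
                f"matrix has {m} cells but barcode list has {len(self.cells)}"
            )
        if n != self.variants.n_variants:
            raise CountDataError(
                f"matrix has {n} variants but variant table has "
                f"{self.variants.n_variants}"
            )
        _check_integrity(self.A, self.D)

    @property
    def n_variants(self) -> int:
        return self.D.shape[0]

    @property
    def n_cells(self) -> int:
        return self.D.shape[1]

    @property
    def B(self) -> sp.csr_matrix:
        """REF-allele counts b_ij = d_ij - a_ij (computed on demand)."""
        B = (self.D - self.A).tocsr()
        B.eliminate_zeros()
        return B

    def vars_per_cell(self) -> np.ndarray:
        """Number of variants with nonzero depth in each cell."""
        return self.D.getnnz(axis=0)

    def subset_variants(self, idx) -> "AlleleCountData":
        idx = np.asarray(idx)
        return AlleleCountData(
            self.A[idx], self.D[idx], list(self.cells), self.variants.subset(idx)
        )


def _check_integrity(A: sp.csr_matrix, D: sp.csr_matrix) -> None:
    Ab = A.astype(bool)
    Db = D.astype(bool)
    orphan = Ab > Db  # stored in A but not in D
    if orphan.nnz:
        i, j = orphan.nonzero()
        raise CountDataError(
            f"ALT count present without depth at variant {i[0]}, cell {j[0]}"
        )
    excess = A - D
    if excess.nnz and excess.max() > 0:
        coo = excess.tocoo()
        k = int(np.argmax(coo.data))
        raise CountDataError(
            f"ALT count exceeds depth at variant {coo.row[k]}, cell {coo.col[k]}"
        )
    if A.nnz and A.min() < 0:
        raise CountDataError("negative ALT counts")


@dataclass
class GenotypePriorMatrix:
    """Per-(variant, donor) prior over genotype states {0, 1, 2}.

    ``U[i, k]`` is a probability 3-vector.  Where no genotype is known
    (``known_mask`` false) the prior is uniform; where a hard genotype t
    was supplied it is relaxed to 1 - xi on t and xi / 2 on the other
    two states, keeping rows normalised while preserving the stated
    confidence 1 - xi.
    """

    U: np.ndarray  # (N, K, 3)
    relax_rate: float = 0.05
    known_mask: np.ndarray | None = None  # (N, K) bool
    donor_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        if self.U.ndim != 3 or self.U.shape[2] != 3:
            raise ValueError("prior matrix must have shape (N, K, 3)")
        if not (0.0 <= self.relax_rate <= 1.0):
            raise ValueError("relax rate must be in [0, 1]")
        rowsums = self.U.sum(axis=2)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError("prior rows must sum to 1")
        if self.known_mask is None:
            self.known_mask = np.zeros(self.U.shape[:2], dtype=bool)

    @property
    def n_donors(self) -> int:
        return self.U.shape[1]

    @property
    def n_known(self) -> int:
        return int(self.known_mask.sum())

    @staticmethod
    def uniform(n_variants: int, n_donors: int) -> "GenotypePriorMatrix":
        U = np.full((n_variants, n_donors, 3), 1.0 / 3.0)
        return GenotypePriorMatrix(U)

    @staticmethod
    def from_hard_genotypes(
        genotypes: np.ndarray, relax_rate: float = 0.05,
        donor_names: list[str] | None = None,
    ) -> "GenotypePriorMatrix":
        """Encode an (N, K) hard genotype matrix as a relaxed prior.

        Entries < 0 are treated as missing (uniform prior).
        """
        genotypes = np.asarray(genotypes)
        n, k = genotypes.shape
        U = np.full((n, k, 3), 1.0 / 3.0)
        mask = genotypes >= 0
        ii, kk = np.nonzero(mask)
        tt = genotypes[ii, kk].astype(int)
        U[ii, kk] = relax_rate / 2.0
        U[ii, kk, tt] = 1.0 - relax_rate
        return GenotypePriorMatrix(U, relax_rate, mask, donor_names)


# ---------------------------------------------------------------------------
# readers


def read_variant_vcf(path: str | os.PathLike) -> VariantTable:
    """Read bi-allelic SNVs from a VCF; multi-allelic sites and indels
    are dropped with a log message."""
    chrom, pos, ref, alt, vid = [], [], [], [], []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if (
                rec.alts is None
                or len(rec.alts) != 1
                or len(rec.ref) != 1
                or len(rec.alts[0]) != 1
            ):
                n_skipped += 1
                continue
            chrom.append(rec.chrom)
            pos.append(rec.pos)
            ref.append(rec.ref)
            alt.append(rec.alts[0])
            vid.append(rec.id)
    if n_skipped:
        log.info("skipped %d non-bi-allelic/non-SNV records in %s", n_skipped, path)
    return VariantTable.from_arrays(chrom, pos, ref, alt, vid)


def _read_mtx(path: str) -> sp.csr_matrix:
    try:
        mat = scipy.io.mmread(path)
    except Exception as exc:  # pragma: no cover - message formatting
        raise CountDataError(f"failed to read Matrix-Market file {path}: {exc}")
    return sp.csr_matrix(mat)


def read_count_matrices(
    dir_path: str | os.PathLike,
    ad_file: str = AD_FILE,
    dp_file: str = DP_FILE,
    vcf_file: str | None = None,
    barcode_file: str = BARCODE_FILE,
) -> AlleleCountData:
    """Load the sparse pileup layout from ``dir_path``.

    Dimension mismatches raise :class:`CountDataError` naming the
    offending file; ALT entries without depth, or exceeding depth, raise
    an integrity error with the variant and cell index.
    """
    dir_path = str(dir_path)
    if not os.path.isdir(dir_path):
        raise FileNotFoundError(f"count directory not found: {dir_path}")
    if vcf_file is None:
        vcf_file = VCF_FILE
        if not os.path.exists(os.path.join(dir_path, vcf_file)):
            vcf_file = VCF_FILE + ".gz"
    A = _read_mtx(os.path.join(dir_path, ad_file))
    D = _read_mtx(os.path.join(dir_path, dp_file))
    variants = read_variant_vcf(os.path.join(dir_path, vcf_file))
    with open(os.path.join(dir_path, barcode_file)) as fh:
        cells = [line.strip() for line in fh if line.strip()]
    if A.shape != D.shape:
        raise CountDataError(
            f"{ad_file} has shape {A.shape} but {dp_file} has shape {D.shape}"
        )
    if D.shape[0] != variants.n_variants:
        raise CountDataError(
            f"{dp_file} has {D.shape[0]} variants but {vcf_file} lists "
            f"{variants.n_variants}"
        )
    if D.shape[1] != len(cells):
        raise CountDataError(
            f"{dp_file} has {D.shape[1]} cells but {barcode_file} lists {len(cells)}"
        )
    return AlleleCountData(A, D, cells, variants)


def write_count_matrices(data: AlleleCountData, dir_path: str | os.PathLike) -> None:
    """Write ``data`` in the sparse pileup layout (lossless round trip)."""
    dir_path = str(dir_path)
    os.makedirs(dir_path, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(dir_path, AD_FILE), data.A.astype(np.int64), field="integer"
    )
    scipy.io.mmwrite(
        os.path.join(dir_path, DP_FILE), data.D.astype(np.int64), field="integer"
    )
    with open(os.path.join(dir_path, BARCODE_FILE), "w") as fh:
        fh.write("\n".join(data.cells) + "\n")
    _write_sites_vcf(data.variants, os.path.join(dir_path, VCF_FILE))


def _write_sites_vcf(variants: VariantTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(variants.df["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in variants.df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\t.\t.\n"
            )


# ---------------------------------------------------------------------------
# variant filtering


def filter_variants(
    data: AlleleCountData,
    min_total_umis: int = 20,
    min_minor_frac: float = 0.10,
) -> AlleleCountData:
    """Keep variants with enough aggregate evidence to be informative.

    A variant is retained when its total UMI depth across all cells is
    at least ``min_total_umis`` and its minor (second most abundant)
    allele carries at least ``min_minor_frac`` of the total UMIs.
    Idempotent; order preserving.
    """
    total = np.asarray(data.D.sum(axis=1)).ravel()
    alt = np.asarray(data.A.sum(axis=1)).ravel()
    minor = np.minimum(alt, total - alt)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, minor / np.maximum(total, 1), 0.0)
    keep = (total >= min_total_umis) & (frac >= min_minor_frac)
    if not keep.any():
        raise CountDataError(
            "all variants removed by filtering; consider relaxing "
            f"min_total_umis={min_total_umis} or min_minor_frac={min_minor_frac}"
        )
    return data.subset_variants(np.nonzero(keep)[0])


# ---------------------------------------------------------------------------
# genotype priors from VCF

_GT_STATE = {
    (0, 0): 0,
    (0, 1): 1,
    (1, 0): 1,
    (1, 1): 2,
}


def read_genotype_prior(
    vcf_path: str | os.PathLike,
    donors: list[str] | None,
    variants: VariantTable,
    tag: str = "GT",
    relax_rate: float = 0.05,
) -> GenotypePriorMatrix:
    """Build a genotype prior from a donor VCF.

    Variants are matched by exact (chrom, pos, ref, alt).  GT calls map
    0/0 -> state 0, 0/1 or 1/0 (phased alike) -> 1, 1/1 -> 2 and are
    relaxed by ``relax_rate``; GP 3-vectors are renormalised and used
    directly; GL values are exponentiated from log10 and renormalised.
    Unmatched or missing entries stay uniform.
    """
    if tag not in ("GT", "GP", "GL"):
        raise ValueError(f"unsupported genotype tag: {tag}")
    key = {
        (c, p, r, a): i
        for i, (c, p, r, a) in enumerate(
            zip(
                variants.df["chrom"],
                variants.df["pos"],
                variants.df["ref"],
                variants.df["alt"],
            )
        )
    }
    with pysam.VariantFile(str(vcf_path)) as vf:
        samples = list(vf.header.samples)
        if donors is None:
            donors = samples
        missing_donors = [d for d in donors if d not in samples]
        if missing_donors:
            raise ValueError(f"donors not in VCF: {missing_donors}")
        if tag != "GT" and tag not in vf.header.formats:
            raise ValueError(f"FORMAT tag {tag} absent from {vcf_path}")

        n, k = variants.n_variants, len(donors)
        U = np.full((n, k, 3), 1.0 / 3.0)
        mask = np.zeros((n, k), dtype=bool)
        n_missing = 0
        gt_seen = False
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            i = key.get((rec.chrom, rec.pos, rec.ref, rec.alts[0]))
            if i is None:
                continue
            for kk, donor in enumerate(donors):
                call = rec.samples[donor]
                vec = _prior_vector(call, tag, relax_rate)
                if vec is None:
                    n_missing += 1
                    continue
                gt_seen = True
                U[i, kk] = vec
                mask[i, kk] = True
    if not mask.any():
        if not gt_seen and tag == "GT":
            raise ValueError(f"FORMAT tag GT absent or all missing in {vcf_path}")
        raise ValueError(
            f"no variants in {vcf_path} overlap the count data "
            "(matched by chrom, pos, ref, alt)"
        )
    if n_missing:
        log.info("%d missing genotype calls treated as uniform prior", n_missing)
    return GenotypePriorMatrix(U, relax_rate, mask, list(donors))


def _prior_vector(call, tag: str, relax_rate: float) -> np.ndarray | None:
    if tag == "GT":
        gt = call.get("GT")
        if gt is None or any(x is None for x in gt) or len(gt) != 2:
            return None
        state = _GT_STATE.get(tuple(gt))
        if state is None:
            return None
        vec = np.full(3, relax_rate / 2.0)
        vec[state] = 1.0 - relax_rate
        return vec
    vals = call.get(tag)
    if vals is None or len(vals) != 3 or any(v is None for v in vals):
        return None
    vals = np.asarray(vals, dtype=float)
    if tag == "GL":
        vals = 10.0 ** (vals - vals.max())
    if vals.sum() <= 0:
        return None
    return vals / vals.sum()


# ---------------------------------------------------------------------------
# writers for fitted results


def write_assignments(
    fit,
    data: AlleleCountData,
    path: str | os.PathLike,
    singlet_thresh: float = 0.9,
    doublet_thresh: float = 0.9,
) -> pd.DataFrame:
    """Write the per-cell assignment table (TSV) and return it.

    A cell is labelled with its best donor when confident, "doublet"
    when the summed doublet probability exceeds ``doublet_thresh``, and
    "unassigned" when the best singlet probability is at or below
    ``singlet_thresh``.
    """
    df = assignment_table(fit, data, singlet_thresh, doublet_thresh)
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")
    return df


def assignment_table(
    fit,
    data: AlleleCountData,
    singlet_thresh: float = 0.9,
    doublet_thresh: float = 0.9,
) -> pd.DataFrame:
    asg = fit.assignment
    k = fit.n_donors
    best = np.argmax(asg.r[:, :k], axis=1)
    donor_id = np.array([f"donor{b}" for b in best], dtype=object)
    donor_id[asg.prob_max <= singlet_thresh] = "unassigned"
    donor_id[asg.prob_doublet > doublet_thresh] = "doublet"
    pairs = np.array(
        [f"donor{a},donor{b}" for a, b in asg.best_doublet_pair]
        if len(asg.best_doublet_pair)
        else ["."] * data.n_cells,
        dtype=object,
    )
    return pd.DataFrame(
        {
            "cell": data.cells,
            "donor_id": donor_id,
            "prob_max": asg.prob_max,
            "prob_doublet": asg.prob_doublet,
            "n_vars": data.vars_per_cell(),
            "best_doublet_pair": pairs,
        }
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_donor_vcf(
    genotype,
    data: AlleleCountData,
    path: str | os.PathLike,
    donor_depth: np.ndarray | None = None,
    donor_names: list[str] | None = None,
) -> None:
    """Serialise inferred donor genotypes as a VCF.

    One sample column per donor with GT (argmax state), GP (posterior
    3-vector) and DP (aggregate UMI depth).  Rows with an effectively
    uniform posterior (no evidence) get GT "./.".
    """
    g = genotype.g
    n, k, _ = g.shape
    if donor_names is None:
        donor_names = [f"donor{j}" for j in range(k)]
    if donor_depth is None:
        donor_depth = np.zeros((n, k), dtype=int)
    hard = np.argmax(g, axis=2)
    uniform = np.ptp(g, axis=2) < 1e-6
    with open(str(path), "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=GP,Number=G,Type=Float,'
            'Description="Posterior genotype probability">\n'
        )
        fh.write(
            '##FORMAT=<ID=DP,Number=1,Type=Integer,'
            'Description="Aggregate UMI depth for the donor">\n'
        )
        for c in pd.unique(data.variants.df["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(donor_names)
            + "\n"
        )
        for i, row in enumerate(data.variants.df.itertuples(index=False)):
            fields = [
                row.chrom, str(row.pos), row.id, row.ref, row.alt,
                ".", "PASS", ".", "GT:GP:DP",
            ]
            for j in range(k):
                gt = "./." if uniform[i, j] else _GT_STR[int(hard[i, j])]
                gp = ",".join(f"{p:.6f}" for p in g[i, j])
                fields.append(f"{gt}:{gp}:{int(donor_depth[i, j])}")
            fh.write("\t".join(fields) + "\n")
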