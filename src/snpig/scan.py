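"""All-pairs interaction-gain scan with LD filtering and gene annotation.

The scan enumerates every unordered distinct SNP pair — C(M, 2) pairs for M
SNPs — and computes for each the interaction gain, its mutual-information
components, genotype-correlation r², a location-based interaction form and
the base-pair distance.  Pairs are processed in column blocks; each block
task is a pure function of its inputs and results are merged in canonical
order, so output is identical for any worker count.

Counting is vectorized: per phenotype class and genotype value, boolean
indicator matrices are multiplied (indicator^T @ indicator) to produce all
3 x 3 x 2 contingency tables of a block pair at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .infotheory import DegeneratePhenotypeError

__all__ = [
    "SnpAnnotation",
    "ScanConfig",
    "FilterResult",
    "PAIR_FORMS",
    "pair_count",
    "map_snps_to_genes",
    "classify_pair",
    "ld_r2",
    "allpairs_ig_values",
    "scan_all_pairs",
    "filter_pairs",
    "distance_stratified_summary",
]

#: The five location forms a SNP pair can take.
PAIR_FORMS = (
    "within-gene",
    "gene-gene",
    "intergenic-intergenic",
    "gene-intergenic",
    "cross-chromosome",
)

RECORD_COLUMNS = ["snp_a", "snp_b", "ig", "mi_xy", "cmi", "r2", "form", "distance_bp"]


@dataclass(frozen=True)
class SnpAnnotation:
    """Genomic location of one SNP; ``gene_id`` is None when intergenic."""

    snp_id: str
    chromosome: str
    position: int  # 1-based
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1 (1-based)")


@dataclass(frozen=True)
class ScanConfig:
    """Scan thresholds and parallelism knobs.

    ``alpha`` is the IG selection threshold (0.1 by default) and
    ``r2_cutoff`` the LD-pruning cutoff (pairs with r² above it are
    discarded; 0.8 by default).
    """

    alpha: float = 0.1
    r2_cutoff: float = 0.8
    n_workers: int = 1
    chunk_size: int = 256

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not (0 < self.r2_cutoff <= 1):
            raise ValueError("r2_cutoff must lie in (0, 1]")
        if self.n_workers < 1 or self.chunk_size < 1:
            raise ValueError("n_workers and chunk_size must be >= 1")


def pair_count(m: int) -> int:
    """Number of unordered distinct SNP pairs among m SNPs: C(m, 2)."""
    return m * (m - 1) // 2


def map_snps_to_genes(
    annotations: Sequence[SnpAnnotation],
    gene_intervals: Iterable[tuple[str, int, int, str]],
) -> tuple[list[SnpAnnotation], dict]:
    """Assign each SNP the gene whose interval contains its position.

    ``gene_intervals`` are (chromosome, start, end, gene_id) with 1-based
    inclusive coordinates.  A SNP covered by several genes gets the one
    with the smallest (start, gene_id); SNPs covered by none stay
    intergenic.  Returns the annotated list plus a mapping summary with the
    on-gene / intergenic / distinct-gene counts.
    """
    intervals = sorted(gene_intervals, key=lambda g: (g[0], g[1], g[3]))
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    snp_chroms = {a.chromosome for a in annotations}
    for chrom, start, end, gene in intervals:
        if start > end:
            raise ValueError(f"gene {gene}: start {start} > end {end}")
        if chrom not in snp_chroms:
            warnings.warn(
                f"gene {gene} on chromosome {chrom} matches no SNP chromosome",
                stacklevel=2,
            )
        by_chrom.setdefault(chrom, []).append((start, end, gene))

    out: list[SnpAnnotation] = []
    genes_hit: set[str] = set()
    for ann in annotations:
        gene_id = None
        for start, end, gene in by_chrom.get(ann.chromosome, ()):
            if start <= ann.position <= end:
                gene_id = gene
                break
        if gene_id is not None:
            genes_hit.add(gene_id)
        out.append(
            SnpAnnotation(ann.snp_id, ann.chromosome, ann.position, gene_id)
        )
    n_on = sum(a.gene_id is not None for a in out)
    summary = {
        "n_snps": len(out),
        "n_on_gene": n_on,
        "n_between_gene": len(out) - n_on,
        "n_genes": len(genes_hit),
    }
    return out, summary


def classify_pair(a: SnpAnnotation, b: SnpAnnotation) -> str:
    """One of the five interaction forms; cross-chromosome wins."""
    if a.chromosome != b.chromosome:
        return "cross-chromosome"
    if a.gene_id is not None and b.gene_id is not None:
        return "within-gene" if a.gene_id == b.gene_id else "gene-gene"
    if a.gene_id is None and b.gene_id is None:
        return "intergenic-intergenic"
    return "gene-intergenic"


def ld_r2(x, y) -> float:
    """Composite LD r²: squared Pearson correlation of minor-allele counts.

    Returns NaN (undefined LD) when either vector is monomorphic; such
    pairs are retained by :func:`filter_pairs`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _default_annotations(snp_ids: Sequence[str]) -> list[SnpAnnotation]:
    """Placeholder annotations: one chromosome, position = column index + 1."""
    return [SnpAnnotation(s, "0", j + 1, None) for j, s in enumerate(snp_ids)]


def _ig_stack(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(ig, mi, cmi) for a stack of tables; counts shape (..., 3, 3, 2)."""
    c = counts.astype(np.float64)
    n = c.sum(axis=(-3, -2, -1), keepdims=True)
    p = c / np.where(n > 0, n, 1.0)

    def _safe_sum(num, den, weight):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = weight * np.log2(num / den)
        return np.where(weight > 0, term, 0.0)

    pxy = p.sum(axis=-1)
    px = pxy.sum(axis=-1, keepdims=True)
    py = pxy.sum(axis=-2, keepdims=True)
    mi = _safe_sum(pxy, px * py, pxy).sum(axis=(-2, -1))

    pc = p.sum(axis=(-3, -2), keepdims=True)
    pxc = p.sum(axis=-2, keepdims=True)
    pyc = p.sum(axis=-3, keepdims=True)
    # sum_xyc p(x,y,c) log2[ p(x,y,c) p(c) / (p(x,c) p(y,c)) ]  ==  I(X;Y|C)
    cmi = _safe_sum(p * pc, pxc * pyc, p).sum(axis=(-3, -2, -1))
    return cmi - mi, mi, cmi


class _ScanWorkspace:
    """Precomputed per-class genotype indicators shared by all block tasks.

    For complete data only the g = 1 and g = 2 indicators are materialized;
    the remaining contingency cells follow from per-column genotype counts,
    cutting the matrix products per class from 9 to 4.  With missing
    genotypes (negative codes) all three indicators are used, which drops
    individuals missing at either SNP of a pair (pairwise deletion).
    """

    def __init__(self, geno: np.ndarray, pheno: np.ndarray) -> None:
        self.has_missing = bool((geno < 0).any())
        self.ind: list[list[np.ndarray]] = []
        self.colcounts: list[np.ndarray] = []  # (3, M) per class
        self.n_class: list[int] = []
        genos = (0, 1, 2) if self.has_missing else (1, 2)
        for c in (0, 1):
            sub = geno[pheno == c]
            self.n_class.append(sub.shape[0])
            self.ind.append([(sub == g).astype(np.float32) for g in genos])
            self.colcounts.append(
                np.stack([(sub == g).sum(axis=0) for g in (0, 1, 2)])
            )

    def block_counts(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(len(rows), len(cols), 3, 3, 2) contingency tables."""
        out = np.empty((rows.size, cols.size, 3, 3, 2), dtype=np.float64)
        for c in (0, 1):
            if self.has_missing:
                ind = self.ind[c]
                for ga in range(3):
                    for gb in range(3):
                        out[:, :, ga, gb, c] = ind[ga][:, rows].T @ ind[gb][:, cols]
            else:
                a1, a2 = (m[:, rows] for m in self.ind[c])
                b1, b2 = (m[:, cols] for m in self.ind[c])
                c11 = a1.T @ b1
                c12 = a1.T @ b2
                c21 = a2.T @ b1
                c22 = a2.T @ b2
                nr = self.colcounts[c][:, rows]  # (3, len rows)
                nc = self.colcounts[c][:, cols]
                c10 = nr[1][:, None] - c11 - c12
                c20 = nr[2][:, None] - c21 - c22
                c01 = nc[1][None, :] - c11 - c21
                c02 = nc[2][None, :] - c12 - c22
                c00 = nr[0][:, None] - c01 - c02
                for (ga, gb), v in {
                    (0, 0): c00, (0, 1): c01, (0, 2): c02,
                    (1, 0): c10, (1, 1): c11, (1, 2): c12,
                    (2, 0): c20, (2, 1): c21, (2, 2): c22,
                }.items():
                    out[:, :, ga, gb, c] = v
        return out


def _scan_block_pair(
    ws: _ScanWorkspace, rows: np.ndarray, cols: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """IG components for all pairs (i in rows) x (j in cols) with i < j."""
    counts = ws.block_counts(rows, cols)
    ig, mi, cmi = _ig_stack(counts)
    ii, jj = np.meshgrid(rows, cols, indexing="ij")
    keep = ii < jj
    return ii[keep], jj[keep], ig[keep], mi[keep], cmi[keep]


def allpairs_ig_values(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    chunk_size: int = 256,
    n_workers: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """IG of every unordered distinct pair, without annotation bookkeeping.

    Returns (i_index, j_index, ig) with i < j in canonical order; the lean
    kernel behind both the full scan and the power/permutation machinery.
    """
    geno = np.asarray(genotypes)
    pheno = np.asarray(phenotype)
    m = geno.shape[1]
    ws = _ScanWorkspace(geno, pheno)
    blocks = [np.arange(s, min(s + chunk_size, m)) for s in range(0, m, chunk_size)]
    tasks = [(blocks[a], blocks[b]) for a in range(len(blocks)) for b in range(a, len(blocks))]
    if n_workers == 1:
        results = [_scan_block_pair(ws, r, c) for r, c in tasks]
    else:
        results = Parallel(n_jobs=n_workers, backend="threading")(
            delayed(_scan_block_pair)(ws, r, c) for r, c in tasks
        )
    i_idx = np.concatenate([r[0] for r in results])
    j_idx = np.concatenate([r[1] for r in results])
    ig = np.concatenate([r[2] for r in results])
    order = np.lexsort((j_idx, i_idx))
    return i_idx[order], j_idx[order], ig[order]


def _pairwise_r2(geno: np.ndarray) -> np.ndarray:
    """M x M genotype-correlation r² matrix; NaN for monomorphic columns."""
    g = geno.astype(np.float64)
    g[g < 0] = np.nan  # missing
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mask = ~np.isnan(g)
        gz = np.where(mask, g - np.nanmean(g, axis=0), 0.0)
        cov = gz.T @ gz
        var = (gz**2).sum(axis=0)
        denom = np.sqrt(np.outer(var, var))
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = (cov / denom) ** 2
    r2[:, var == 0] = np.nan
    r2[var == 0, :] = np.nan
    return r2


def scan_all_pairs(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    annotations: Sequence[SnpAnnotation] | None = None,
    config: ScanConfig | None = None,
    snp_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Interaction-gain records for every unordered distinct SNP pair.

    Returns a DataFrame with one row per pair and columns
    ``snp_a, snp_b, ig, mi_xy, cmi, r2, form, distance_bp`` (``snp_a`` <
    ``snp_b`` lexicographically; ``distance_bp`` is NaN cross-chromosome).
    Row content and order are independent of ``n_workers``/``chunk_size``.
    """
    config = config or ScanConfig()
    geno = np.asarray(genotypes)
    pheno = np.asarray(phenotype)
    if geno.ndim != 2 or geno.shape[1] < 2:
        raise ValueError("need an N x M genotype matrix with M >= 2")
    classes = np.unique(pheno)
    if not np.array_equal(classes, [0, 1]):
        raise DegeneratePhenotypeError(
            f"phenotype must contain both classes 0 (case) and 1 (control); got {classes}"
        )
    m = geno.shape[1]
    if snp_ids is None:
        snp_ids = (
            [a.snp_id for a in annotations]
            if annotations is not None
            else [f"x{j + 1}" for j in range(m)]
        )
    if annotations is None:
        annotations = _default_annotations(snp_ids)
    if len(annotations) != m or len(snp_ids) != m:
        raise ValueError("annotations/snp_ids length must match SNP count")

    ws = _ScanWorkspace(geno, pheno)
    blocks = [
        np.arange(s, min(s + config.chunk_size, m))
        for s in range(0, m, config.chunk_size)
    ]
    tasks = [
        (blocks[a], blocks[b])
        for a in range(len(blocks))
        for b in range(a, len(blocks))
    ]
    if config.n_workers == 1:
        results = [_scan_block_pair(ws, r, c) for r, c in tasks]
    else:
        results = Parallel(n_jobs=config.n_workers, backend="threading")(
            delayed(_scan_block_pair)(ws, r, c) for r, c in tasks
        )

    i_idx = np.concatenate([r[0] for r in results])
    j_idx = np.concatenate([r[1] for r in results])
    ig = np.concatenate([r[2] for r in results])
    mi = np.concatenate([r[3] for r in results])
    cmi = np.concatenate([r[4] for r in results])
    order = np.lexsort((j_idx, i_idx))  # canonical (i, j) order
    i_idx, j_idx, ig, mi, cmi = (v[order] for v in (i_idx, j_idx, ig, mi, cmi))

    r2_mat = _pairwise_r2(geno)
    r2 = r2_mat[i_idx, j_idx]

    chrom = np.array([a.chromosome for a in annotations])
    pos = np.array([a.position for a in annotations], dtype=np.int64)
    gene = np.array([a.gene_id or "" for a in annotations])
    same_chrom = chrom[i_idx] == chrom[j_idx]
    dist = np.where(same_chrom, np.abs(pos[i_idx] - pos[j_idx]), np.nan)
    ga, gb = gene[i_idx], gene[j_idx]
    form = np.where(
        ~same_chrom,
        "cross-chromosome",
        np.where(
            (ga != "") & (gb != ""),
            np.where(ga == gb, "within-gene", "gene-gene"),
            np.where((ga == "") & (gb == ""), "intergenic-intergenic", "gene-intergenic"),
        ),
    )

    ids = np.asarray(snp_ids, dtype=object)
    a_ids, b_ids = ids[i_idx], ids[j_idx]
    swap = a_ids > b_ids  # canonical lexicographic orientation
    a_ids, b_ids = np.where(swap, b_ids, a_ids), np.where(swap, a_ids, b_ids)

    return pd.DataFrame(
        {
            "snp_a": a_ids,
            "snp_b": b_ids,
            "ig": ig,
            "mi_xy": mi,
            "cmi": cmi,
            "r2": r2,
            "form": form,
            "distance_bp": dist,
        }
    )


@dataclass(frozen=True)
class FilterResult:
    """Surviving records plus the count removed by each rule."""

    records: pd.DataFrame = field(repr=False)
    n_removed_alpha: int = 0
    n_removed_ld: int = 0


def filter_pairs(records: pd.DataFrame, config: ScanConfig | None = None) -> FilterResult:
    """Keep records with IG > alpha and (r² missing or r² <= cutoff).

    The alpha rule is applied first; the surviving set does not depend on
    the order.  Idempotent.
    """
    config = config or ScanConfig()
    pass_alpha = records["ig"] > config.alpha
    after_alpha = records[pass_alpha]
    pass_ld = after_alpha["r2"].isna() | (after_alpha["r2"] <= config.r2_cutoff)
    surviving = after_alpha[pass_ld].reset_index(drop=True)
    return FilterResult(
        records=surviving,
        n_removed_alpha=int((~pass_alpha).sum()),
        n_removed_ld=int((~pass_ld).sum()),
    )


def distance_stratified_summary(
    records: pd.DataFrame, n_bins_per_decade: int = 1
) -> pd.DataFrame:
    """Mean/max IG per (form, log-distance bin) for same-chromosome pairs.

    Supports the qualitative check that high interaction gain is reached
    only between physically close SNPs.  Distance bins are decades of base
    pairs (optionally subdivided); pairs at distance 0 go in the first bin.
    """
    same = records[records["distance_bp"].notna()].copy()
    if same.empty:
        return pd.DataFrame(
            columns=["form", "bin_lo_bp", "bin_hi_bp", "n_pairs", "mean_ig", "max_ig"]
        )
    d = same["distance_bp"].to_numpy(dtype=float)
    logd = np.log10(np.maximum(d, 1.0))
    idx = np.floor(logd * n_bins_per_decade).astype(int)
    same["_bin"] = idx
    rows = []
    for (form, b), grp in same.groupby(["form", "_bin"], sort=True):
        rows.append(
            {
                "form": form,
                "bin_lo_bp": 10.0 ** (b / n_bins_per_decade),
                "bin_hi_bp": 10.0 ** ((b + 1) / n_bins_per_decade),
                "n_pairs": len(grp),
                "mean_ig": grp["ig"].mean(),
                "max_ig": grp["ig"].max(),
            }
        )
    return pd.DataFrame(rows)
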