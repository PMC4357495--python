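"""Permutation-based statistical validation of interaction-gain thresholds.

The null hypothesis — no SNP-SNP or SNP-phenotype association — is built by
independently permuting each SNP column across individuals, which preserves
per-SNP genotype frequencies exactly while destroying all association
structure.  Re-scanning permuted data yields a null distribution of IG
scores from which empirical p-values, a Bonferroni family-wise threshold
and a per-threshold empirical false discovery rate are derived.

The Bonferroni test count supports both conventions: the scan's C(M, 2)
unordered pairs (default) and the self-inclusive ordered M^2 convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scan import allpairs_ig_values, pair_count

__all__ = [
    "NullDistribution",
    "permute_genotypes",
    "build_null",
    "empirical_pvalue",
    "n_tests",
    "bonferroni_threshold",
    "empirical_fdr",
    "validation_report",
]


@dataclass(frozen=True)
class NullDistribution:
    """IG scores recomputed on column-permuted data."""

    scores: np.ndarray = field(repr=False)
    n_permutations: int
    n_pairs_per_permutation: int
    seed: int

    def __post_init__(self) -> None:
        s = np.asarray(self.scores)
        if s.size and not np.all(np.isfinite(s)):
            raise ValueError("null scores must be finite")
        if s.size != self.n_permutations * self.n_pairs_per_permutation:
            raise ValueError("scores size inconsistent with permutation counts")


def permute_genotypes(genotypes: np.ndarray, seed: int) -> np.ndarray:
    """Independently permute each SNP column across individuals.

    Phenotype labels are untouched by construction (they are not part of
    the matrix); per-SNP genotype multisets are preserved exactly.
    Deterministic given ``seed``.
    """
    geno = np.asarray(genotypes)
    rng = np.random.default_rng(seed)
    out = np.empty_like(geno)
    for j in range(geno.shape[1]):
        out[:, j] = geno[rng.permutation(geno.shape[0]), j]
    return out


def build_null(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    n_permutations: int,
    seed: int,
    chunk_size: int = 256,
    n_workers: int = 1,
) -> NullDistribution:
    """All-pairs IG scores over ``n_permutations`` column permutations."""
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    m = np.asarray(genotypes).shape[1]
    scores = []
    for b in range(n_permutations):
        perm = permute_genotypes(genotypes, seed + b)
        _, _, ig = allpairs_ig_values(perm, phenotype, chunk_size, n_workers)
        scores.append(ig)
    return NullDistribution(
        scores=np.concatenate(scores),
        n_permutations=n_permutations,
        n_pairs_per_permutation=pair_count(m),
        seed=seed,
    )


def empirical_pvalue(observed: float, null: NullDistribution) -> float:
    """Add-one estimator: (1 + #{null >= observed}) / (1 + #null).

    Never returns exactly 0, reflecting that a finite permutation sample
    cannot rule out the observed score arising under the null.
    """
    scores = np.asarray(null.scores)
    if scores.size == 0:
        raise ValueError("empty null distribution")
    return float((1 + (scores >= observed).sum()) / (1 + scores.size))


def n_tests(m: int, convention: str = "choose2") -> int:
    """Number of pairwise tests among m SNPs.

    ``choose2`` counts unordered distinct pairs C(m, 2); ``squared`` is the
    self-inclusive ordered convention m^2.
    """
    if convention == "choose2":
        return pair_count(m)
    if convention == "squared":
        return m * m
    raise ValueError(f"unknown convention {convention!r}")


def bonferroni_threshold(beta: float, n: int) -> float:
    """Family-wise significance threshold beta / n."""
    if not (0 < beta < 1):
        raise ValueError("beta must lie in (0, 1)")
    if n < 1:
        raise ValueError("n_tests must be >= 1")
    return beta / n


def empirical_fdr(
    alpha_threshold: float, observed_ig: np.ndarray, null: NullDistribution
) -> float:
    """FDR(alpha): mean null exceedance count per permutation over the
    observed exceedance count, clipped to [0, 1]; 1 when nothing observed
    exceeds alpha.
    """
    observed_ig = np.asarray(observed_ig)
    n_obs = int((observed_ig > alpha_threshold).sum())
    if n_obs == 0:
        return 1.0
    null_mean = (np.asarray(null.scores) > alpha_threshold).sum() / null.n_permutations
    return float(min(1.0, null_mean / n_obs))


def validation_report(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    alpha_grid,
    n_permutations: int,
    seed: int,
    beta: float = 0.05,
    convention: str = "choose2",
    chunk_size: int = 256,
    n_workers: int = 1,
) -> pd.DataFrame:
    """Per-threshold selected-pair counts, p-values, Bonferroni level, FDR.

    One row per alpha in ``alpha_grid``: the number of observed pairs with
    IG above alpha, the empirical p-value of the alpha cutoff score under
    the permutation null, the Bonferroni family-wise threshold
    beta / n_tests, and the empirical FDR.  Deterministic given ``seed``.
    """
    geno = np.asarray(genotypes)
    _, _, observed = allpairs_ig_values(geno, phenotype, chunk_size, n_workers)
    null = build_null(geno, phenotype, n_permutations, seed, chunk_size, n_workers)
    bonf = bonferroni_threshold(beta, n_tests(geno.shape[1], convention))
    rows = []
    for alpha in alpha_grid:
        rows.append(
            {
                "alpha": alpha,
                "n_pairs_selected": int((observed > alpha).sum()),
                "p_value": empirical_pvalue(alpha, null),
                "bonferroni_threshold": bonf,
                "fdr": empirical_fdr(alpha, observed, null),
            }
        )
    return pd.DataFrame(rows)
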