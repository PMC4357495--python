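"""Entropy, mutual information and the interaction-gain statistic.

All quantities are in bits (log base 2).  The interaction gain of two SNPs
X, Y with respect to a case/control phenotype P,

    IG(X; Y; P) = I(X; Y | P) - I(X; Y),

measures the information about the phenotype carried *jointly* by the two
loci beyond their separate contributions.  It is 0 when the SNPs are
independent of each other given the phenotype structure and reaches 1 bit
for a pure XOR penetrance pattern with balanced classes.

Probabilities are maximum-likelihood plug-in frequencies from a 3 x 3 x 2
contingency table (genotype of SNP1, genotype of SNP2, phenotype class with
0 = case, 1 = control), with the 0*log(0) = 0 convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiscreteDistribution",
    "ContingencyTable",
    "IgResult",
    "entropy",
    "joint_entropy",
    "mutual_information",
    "conditional_mutual_information",
    "build_contingency",
    "interaction_gain",
    "ig_from_counts",
]

_PROB_TOL = 1e-12


class InvalidDistributionError(ValueError):
    """Probabilities negative or not summing to one."""


class InvalidGenotypeError(ValueError):
    """Genotype codes outside {0, 1, 2} or phenotype outside {0, 1}."""


class DegeneratePhenotypeError(ValueError):
    """Only one phenotype class present."""


@dataclass(frozen=True)
class DiscreteDistribution:
    """Probability mass function over arbitrary category labels.

    ``probabilities`` maps a category label (any hashable; tuples for joint
    distributions) to its probability.  Validated on construction.
    """

    probabilities: dict

    def __post_init__(self) -> None:
        p = np.asarray(list(self.probabilities.values()), dtype=float)
        if p.size == 0:
            raise InvalidDistributionError("empty distribution")
        if np.any(p < 0):
            raise InvalidDistributionError("negative probability")
        if abs(p.sum() - 1.0) > 1e-9:
            raise InvalidDistributionError(f"probabilities sum to {p.sum()!r}, not 1")

    def as_array(self) -> np.ndarray:
        return np.asarray(list(self.probabilities.values()), dtype=float)


@dataclass(frozen=True)
class ContingencyTable:
    """3 x 3 x 2 genotype/phenotype counts for one SNP pair.

    Axis order: (genotype of SNP1, genotype of SNP2, phenotype class);
    phenotype 0 = case, 1 = control.
    """

    counts: np.ndarray
    n: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3, 2):
            raise ValueError(f"expected shape (3, 3, 2), got {c.shape}")
        if np.any(c < 0):
            raise ValueError("negative count")
        if int(c.sum()) != self.n:
            raise ValueError("counts do not sum to n")

    def genotype_combination_counts(self) -> np.ndarray:
        """The 9 genotype-combination counts, marginalized over phenotype."""
        return np.asarray(self.counts).sum(axis=2)


@dataclass(frozen=True)
class IgResult:
    """Interaction gain and its two components, all in bits."""

    ig: float
    mi_xy: float
    cmi_xy_given_p: float

    def __post_init__(self) -> None:
        if abs(self.ig - (self.cmi_xy_given_p - self.mi_xy)) > _PROB_TOL:
            raise ValueError("ig must equal cmi_xy_given_p - mi_xy")


def _xlog2x(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with 0 log 0 = 0."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def entropy(dist: DiscreteDistribution) -> float:
    """Shannon entropy H(X) = -sum p log2 p, in bits."""
    return float(-_xlog2x(dist.as_array()).sum())


def joint_entropy(joint: DiscreteDistribution) -> float:
    """Joint entropy H(X, Y); identical formula applied to the joint pmf."""
    return float(-_xlog2x(joint.as_array()).sum())


def _mi_from_joint_array(pxy: np.ndarray) -> float:
    """I(X;Y) in bits from a 2-D joint probability array."""
    pxy = np.asarray(pxy, dtype=float)
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    denom = px * py  # > 0 wherever pxy > 0
    nz = pxy > 0
    out = np.zeros_like(pxy)
    out[nz] = pxy[nz] * np.log2(pxy[nz] / denom[nz])
    return float(out.sum())


def mutual_information(joint: DiscreteDistribution) -> float:
    """I(X;Y) = sum p(x,y) log2 [p(x,y) / (p(x) p(y))], in bits.

    Category labels must be 2-tuples (x, y).
    """
    pxy = _joint_to_array(joint, 2)
    return _mi_from_joint_array(pxy)


def conditional_mutual_information(joint: DiscreteDistribution) -> float:
    """I(X;Y|Z) = sum p(x,y,z) log2 [p(x,y|z) / (p(x|z) p(y|z))], in bits.

    Category labels must be 3-tuples (x, y, z).  Strata with p(z) = 0
    contribute nothing.
    """
    pxyz = _joint_to_array(joint, 3)
    return _cmi_from_joint_array(pxyz)


def _joint_to_array(joint: DiscreteDistribution, ndim: int) -> np.ndarray:
    labels = list(joint.probabilities)
    for lab in labels:
        if not isinstance(lab, tuple) or len(lab) != ndim:
            raise ValueError(f"labels must be {ndim}-tuples, got {lab!r}")
    axes = [sorted({lab[d] for lab in labels}) for d in range(ndim)]
    index = [{v: i for i, v in enumerate(ax)} for ax in axes]
    arr = np.zeros([len(ax) for ax in axes])
    for lab, p in joint.probabilities.items():
        arr[tuple(index[d][lab[d]] for d in range(ndim))] += p
    return arr


def _cmi_from_joint_array(pxyz: np.ndarray) -> float:
    """I(X;Y|Z) from a joint array with Z on the last axis."""
    pxyz = np.asarray(pxyz, dtype=float)
    pz = pxyz.sum(axis=(0, 1))
    total = 0.0
    for k in range(pxyz.shape[-1]):
        if pz[k] <= 0:
            continue
        total += pz[k] * _mi_from_joint_array(pxyz[..., k] / pz[k])
    return float(total)


def build_contingency(x, y, pheno) -> ContingencyTable:
    """Count the 3 x 3 x 2 genotype/phenotype table for one SNP pair.

    ``x`` and ``y`` are minor-allele-count vectors in {0, 1, 2}; ``pheno``
    is 0 for case, 1 for control.  All three must have equal length.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    pheno = np.asarray(pheno)
    if not (x.shape == y.shape == pheno.shape) or x.ndim != 1:
        raise ValueError("x, y, pheno must be 1-D vectors of equal length")
    for name, v, hi in (("genotype", x, 2), ("genotype", y, 2), ("phenotype", pheno, 1)):
        if v.size and (np.any(v < 0) or np.any(v > hi) or not np.issubdtype(v.dtype, np.integer)):
            raise InvalidGenotypeError(f"{name} codes must be integers in [0, {hi}]")
    flat = (x.astype(np.int64) * 3 + y) * 2 + pheno
    counts = np.bincount(flat, minlength=18).reshape(3, 3, 2)
    return ContingencyTable(counts=counts, n=int(x.size))


def ig_from_counts(counts: np.ndarray) -> IgResult:
    """Interaction gain from a 3 x 3 x 2 count (or frequency) table."""
    c = np.asarray(counts, dtype=float)
    n = c.sum()
    if n <= 0:
        raise ValueError("empty table")
    p = c / n
    if np.any(p.sum(axis=(0, 1)) == 0):
        raise DegeneratePhenotypeError("both phenotype classes must be present")
    mi = _mi_from_joint_array(p.sum(axis=2))
    cmi = _cmi_from_joint_array(p)
    return IgResult(ig=cmi - mi, mi_xy=mi, cmi_xy_given_p=cmi)


def interaction_gain(x, y, pheno) -> IgResult:
    """IG(X; Y; P) = I(X; Y | P) - I(X; Y) from genotype/phenotype vectors.

    Symmetric in (x, y); finite for all valid inputs; raises
    :class:`DegeneratePhenotypeError` when only one phenotype class occurs.
    """
    table = build_contingency(x, y, pheno)
    return ig_from_counts(table.counts)
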