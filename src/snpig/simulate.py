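"""Case/control genotype simulation under two-locus epistatic odds models.

Four classical two-locus disease models are supported, each defined by a
3 x 3 table of disease odds

    odds(g1, g2) = delta * (1 + t)^e(g1, g2),

where g1, g2 count capital (risk, minor) alleles at the two disease loci,
``delta`` is the baseline odds when there is no epistatic contribution and
``t`` is the increment applied when there is.  Penetrance is
f = odds / (1 + odds).  The exponent tables:

* model 1 — multiplicative: e = g1 * g2;
* model 2 — an epistatic pattern used for handedness / swine coat colour;
* model 3 — a classical epistasis pattern;
* model 4 — the XOR model (risk iff g1 + g2 is odd).

Given a target disease prevalence K = P(D) and heritability
h^2 = sum_g pi(g) (f(g) - K)^2 / (K (1 - K)) under Hardy-Weinberg genotype
frequencies, (delta, t) are solved numerically by nested bisection.

Datasets carry one interacting pair placed at the first and last SNP index
and background null SNPs with MAFs drawn uniformly from a configured range,
all in Hardy-Weinberg equilibrium and independent of the phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MODEL_EXPONENTS",
    "EpistasisModel",
    "SimulationConfig",
    "SimulatedDataset",
    "hwe_genotype_probs",
    "penetrance_table",
    "prevalence_and_heritability",
    "solve_parameters",
    "simulate_dataset",
]

# Exponent e(g1, g2) of (1+t), rows = genotype of SNP1 (aa, Aa, AA),
# columns = genotype of SNP2 (bb, Bb, BB), i.e. minor-allele counts 0/1/2.
MODEL_EXPONENTS: dict[int, np.ndarray] = {
    1: np.array([[0, 0, 0], [0, 1, 2], [0, 2, 4]]),
    2: np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]]),
    3: np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]]),
    4: np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]]),
}


class ParameterError(ValueError):
    """Simulation parameter outside its valid range."""


class InfeasibleTargetError(ValueError):
    """No (delta, t) reproduces the requested prevalence/heritability."""


@dataclass(frozen=True)
class EpistasisModel:
    """One of the four two-locus odds models with solved (delta, t)."""

    model_id: int
    delta: float
    t: float

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_EXPONENTS:
            raise ParameterError(f"unknown model id {self.model_id}")
        if self.delta <= 0:
            raise ParameterError("delta must be positive")
        if self.t < 0:
            raise ParameterError("t must be nonnegative")

    @property
    def exponents(self) -> np.ndarray:
        return MODEL_EXPONENTS[self.model_id]

    def odds_table(self) -> np.ndarray:
        return self.delta * (1.0 + self.t) ** self.exponents


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults follow the power-evaluation protocol: 800 cases, 800 controls,
    1000 SNPs with the interacting pair at the first and last index,
    prevalence 0.1, and null-SNP MAFs uniform on [0.05, 0.5].
    """

    model_id: int = 1
    maf_disease: float = 0.1
    prevalence: float = 0.1
    heritability: float = 0.03
    n_cases: int = 800
    n_controls: int = 800
    n_snps: int = 1000
    maf_null_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.maf_disease <= 0.5):
            raise ParameterError("maf_disease must lie in (0, 0.5]")
        if not (0 < self.prevalence < 1):
            raise ParameterError("prevalence must lie in (0, 1)")
        if not (0 <= self.heritability < 1):
            raise ParameterError("heritability must lie in [0, 1)")
        if self.n_snps < 2:
            raise ParameterError("need at least the two disease SNPs")
        lo, hi = self.maf_null_range
        if not (0 < lo <= hi <= 0.5):
            raise ParameterError("maf_null_range must be within (0, 0.5]")
        if min(self.n_cases, self.n_controls) < 1:
            raise ParameterError("need at least one case and one control")


@dataclass(frozen=True)
class SimulatedDataset:
    """Genotype matrix (N x M minor-allele counts), phenotype, truth pair."""

    genotypes: np.ndarray
    phenotype: np.ndarray
    truth: tuple[int, int]
    model: EpistasisModel
    config: SimulationConfig = field(repr=False)

    @property
    def snp_ids(self) -> list[str]:
        return [f"x{j + 1}" for j in range(self.genotypes.shape[1])]


def hwe_genotype_probs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities ((1-q)^2, 2q(1-q), q^2).

    Indexed by minor-allele count 0/1/2 for minor-allele frequency q.
    """
    if not (0 < maf <= 0.5):
        raise ParameterError("maf must lie in (0, 0.5]")
    q = float(maf)
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


def penetrance_table(model: EpistasisModel) -> np.ndarray:
    """P(disease | g1, g2) = odds / (1 + odds), a 3 x 3 array in (0, 1)."""
    odds = model.odds_table()
    return odds / (1.0 + odds)


def prevalence_and_heritability(model: EpistasisModel, maf: float) -> tuple[float, float]:
    """Population prevalence K and heritability h^2 implied by the model.

    K = sum pi(g1) pi(g2) f(g1, g2); h^2 = Var_g(f) / (K (1 - K)), with
    genotype weights pi from Hardy-Weinberg at the disease-SNP MAF.
    """
    pi = hwe_genotype_probs(maf)
    w = np.outer(pi, pi)
    f = penetrance_table(model)
    k = float((w * f).sum())
    h2 = float((w * (f - k) ** 2).sum() / (k * (1.0 - k)))
    return k, h2


def solve_parameters(
    model_id: int,
    maf: float,
    prevalence: float,
    heritability: float,
    *,
    tol: float = 1e-12,
) -> EpistasisModel:
    """Solve (delta, t) so the model attains the target (K, h^2).

    Nested bisection: for each trial t, delta is solved so the prevalence
    matches (prevalence is increasing in delta); h^2 at that delta is
    increasing in t, so an outer bracket on t closes the system.  Raises
    :class:`InfeasibleTargetError` with the attainable h^2 range when the
    target cannot be bracketed.
    """
    if not (0 < prevalence < 1):
        raise ParameterError("prevalence must lie in (0, 1)")
    if not (0 <= heritability < 1):
        raise ParameterError("heritability must lie in [0, 1)")

    def delta_for(t: float) -> float:
        def gap(d: float) -> float:
            m = EpistasisModel(model_id=model_id, delta=d, t=t)
            return prevalence_and_heritability(m, maf)[0] - prevalence

        return brentq(gap, 1e-9, 1e6, xtol=tol)

    def h2_gap(t: float) -> float:
        m = EpistasisModel(model_id=model_id, delta=delta_for(t), t=t)
        return prevalence_and_heritability(m, maf)[1] - heritability

    if heritability == 0:
        return EpistasisModel(model_id=model_id, delta=delta_for(0.0), t=0.0)
    t_hi = 1e3
    if h2_gap(t_hi) < 0:
        m = EpistasisModel(model_id=model_id, delta=delta_for(t_hi), t=t_hi)
        reachable = prevalence_and_heritability(m, maf)[1]
        raise InfeasibleTargetError(
            f"h^2 target {heritability} unattainable for model {model_id} at "
            f"maf {maf}: achievable range is [0, {reachable:.6g}]"
        )
    t = brentq(h2_gap, 0.0, t_hi, xtol=tol)
    return EpistasisModel(model_id=model_id, delta=delta_for(t), t=t)


def disease_pair_distributions(
    model: EpistasisModel, maf: float
) -> tuple[np.ndarray, np.ndarray]:
    """Joint genotype distributions of the disease pair in cases / controls.

    P(g1, g2 | case) ∝ pi(g1) pi(g2) f(g1, g2) and
    P(g1, g2 | control) ∝ pi(g1) pi(g2) (1 - f(g1, g2)); 3 x 3 arrays.
    """
    pi = hwe_genotype_probs(maf)
    w = np.outer(pi, pi)
    f = penetrance_table(model)
    case = w * f
    ctrl = w * (1.0 - f)
    return case / case.sum(), ctrl / ctrl.sum()


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw one case/control dataset under the configured model.

    Disease-pair genotypes are sampled directly from the exact conditional
    distributions given phenotype; null-SNP genotypes are sampled from HWE
    with per-SNP MAF uniform on ``maf_null_range``, independent of
    phenotype.  Cases come first in the returned matrix (phenotype 0),
    controls after (phenotype 1).  Deterministic given ``config.seed``.
    """
    model = solve_parameters(
        config.model_id, config.maf_disease, config.prevalence, config.heritability
    )
    return simulate_dataset_with_model(config, model)


def simulate_dataset_with_model(
    config: SimulationConfig, model: EpistasisModel
) -> SimulatedDataset:
    """As :func:`simulate_dataset` but with (delta, t) already solved."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    m = config.n_snps

    case_p, ctrl_p = disease_pair_distributions(model, config.maf_disease)
    cells_case = rng.choice(9, size=config.n_cases, p=case_p.ravel())
    cells_ctrl = rng.choice(9, size=config.n_controls, p=ctrl_p.ravel())
    cells = np.concatenate([cells_case, cells_ctrl])

    geno = np.empty((n, m), dtype=np.int8)
    geno[:, 0] = cells // 3
    geno[:, m - 1] = cells % 3
    if m > 2:
        lo, hi = config.maf_null_range
        null_mafs = rng.uniform(lo, hi, size=m - 2)
        probs = np.stack([hwe_genotype_probs(q) for q in null_mafs])  # (m-2, 3)
        u = rng.random((n, m - 2))
        cum = probs.cumsum(axis=1)[None, :, :]  # (1, m-2, 3)
        geno[:, 1 : m - 1] = (u[:, :, None] > cum).sum(axis=2).astype(np.int8)

    pheno = np.concatenate(
        [np.zeros(config.n_cases, dtype=np.int8), np.ones(config.n_controls, dtype=np.int8)]
    )
    return SimulatedDataset(
        genotypes=geno, phenotype=pheno, truth=(0, m - 1), model=model, config=config
    )


def replicate_configs(base: SimulationConfig, n_replicates: int) -> list[SimulationConfig]:
    """Configs for a replicate batch; replicate i uses seed = base seed + i."""
    return [replace(base, seed=base.seed + i) for i in range(n_replicates)]
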