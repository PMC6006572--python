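"""Case-control cohort construction: inclusion weights, waffect, pair counts.

Phenotypes follow independent Bernoulli laws with individual-specific disease
probabilities p_k given by the penetrance table.  A fixed case count n1 is
obtained by exact conditional sampling ("waffect"): a backward dynamic
program computes B[i][j] = P(individuals i..N-1 contribute j cases), and a
forward pass draws each phenotype from its exact conditional law.  The DP is
carried in log space so it remains stable for thousands of individuals with
small penetrances.

``simulate_pair_counts`` is the direct two-SNP simulator: case and control
genotype tables are drawn from the Bayes-inverted conditional distributions
P(G|D) = P(D|G) P(G) / K and P(G|not D) = (1 - P(D|G)) P(G) / (1 - K).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .disease import DiseaseScenario, PenetranceTable, solve_penetrance, two_locus_genotype_freqs
from .resample import SimulatedPopulation

__all__ = [
    "CaseControlCohort",
    "PairTable",
    "disease_probability",
    "inclusion_probabilities",
    "waffect",
    "waffect_sample",
    "sample_cohort",
    "simulate_pair_counts",
]


@dataclass
class CaseControlCohort:
    """Selected samples with binary phenotype; exactly n1 cases, n0 controls."""

    genotypes: np.ndarray
    phenotype: np.ndarray  # 1 = case
    causal_pair: tuple[int, int]
    seed: int
    loci: list | None = None

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        if self.phenotype.shape[0] != self.genotypes.shape[0]:
            raise ValueError("phenotype length must match genotype rows")

    @property
    def n1(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n0(self) -> int:
        return int((1 - self.phenotype).sum())


@dataclass
class PairTable:
    """2x3x3 tensor of genotype counts: counts[d, i, j], d=1 for cases."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (2, 3, 3):
            raise ValueError("pair table must be 2x3x3")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n0(self) -> int:
        return int(self.counts[0].sum())

    @property
    def n1(self) -> int:
        return int(self.counts[1].sum())

    def transposed(self) -> "PairTable":
        return PairTable(self.counts.transpose(0, 2, 1).copy())


def disease_probability(
    pop: SimulatedPopulation, pair: tuple[int, int], pen: PenetranceTable
) -> np.ndarray:
    """Per-individual P(D | genotype at the causal pair)."""
    a, b = pair
    return pen.p[pop.genotypes[:, a], pop.genotypes[:, b]]


def inclusion_probabilities(
    p: np.ndarray, K: float, n0: int, n1: int, m: int, cap_warn_frac: float = 1e-3
) -> np.ndarray:
    """Cohort inclusion weight n1 p_k / (m K) + n0 (1 - p_k) / (m - m K).

    Weights are capped at 1; a warning is emitted when more than
    ``cap_warn_frac`` of individuals hit the cap.
    """
    if not 0 < K < 1:
        raise ValueError("prevalence K must lie strictly in (0, 1)")
    if m < n0 + n1:
        raise ValueError("population smaller than requested cohort")
    p = np.asarray(p, dtype=float)
    w = n1 * p / (m * K) + n0 * (1 - p) / (m - m * K)
    n_capped = int((w > 1).sum())
    if n_capped > cap_warn_frac * p.size:
        warnings.warn(
            f"{n_capped} of {p.size} inclusion probabilities capped at 1",
            RuntimeWarning,
            stacklevel=2,
        )
    return np.minimum(w, 1.0)


def _waffect_backward(p: np.ndarray, n1: int) -> np.ndarray:
    """Log-space DP table B[i, j] = log P(suffix i.. has exactly j successes)."""
    N = p.size
    with np.errstate(divide="ignore"):
        lp = np.log(p)
        lq = np.log1p(-p)
    B = np.full((N + 1, n1 + 1), -np.inf)
    B[N, 0] = 0.0
    for i in range(N - 1, -1, -1):
        prev = B[i + 1]
        stay = prev + lq[i]
        jump = np.full(n1 + 1, -np.inf)
        jump[1:] = prev[:-1] + lp[i]
        B[i] = np.logaddexp(stay, jump)
    return B


def waffect(p: np.ndarray, n1: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw one binary vector ~ independent Bernoulli(p) given sum == n1.

    Exact conditional sampling via backward DP and forward draws.  Raises if
    the conditioning event has probability zero.
    """
    return waffect_sample(p, n1, size=1, seed=seed)[0]


def waffect_sample(
    p: np.ndarray, n1: int, size: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Vector of ``size`` independent waffect draws sharing one DP table."""
    p = np.asarray(p, dtype=float)
    N = p.size
    if not 0 <= n1 <= N:
        raise ValueError("n1 must lie in [0, N]")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    B = _waffect_backward(p, n1)
    if np.isneginf(B[0, n1]):
        raise ValueError("conditional event has probability zero")
    out = np.zeros((size, N), dtype=np.int8)
    need = np.full(size, n1, dtype=np.int64)
    with np.errstate(divide="ignore"):
        lp = np.log(p)
    for i in range(N):
        # P(X_i = 1 | need j more) = p_i * B[i+1, j-1] / B[i, j]
        j = need
        log_p1 = np.where(
            j > 0,
            lp[i] + B[i + 1, np.maximum(j - 1, 0)] - B[i, j],
            -np.inf,
        )
        take = np.log(rng.random(size)) < log_p1
        out[take, i] = 1
        need = need - take.astype(np.int64)
    assert (need == 0).all()
    return out


def sample_cohort(
    pop: SimulatedPopulation,
    pair: tuple[int, int],
    pen: PenetranceTable,
    n0: int,
    n1: int,
    seed: int = 0,
    K: float | None = None,
) -> CaseControlCohort:
    """Select n0+n1 individuals by weighted sampling without replacement and
    assign exactly n1 cases on the selected subset with waffect.

    ``K`` is the model prevalence entering the inclusion weights; when not
    given, the population-empirical mean disease probability is used (the two
    agree up to causal-pair sampling noise).
    """
    rng = np.random.default_rng(seed)
    p = disease_probability(pop, pair, pen)
    if K is None:
        K = float(p.mean())
    w = inclusion_probabilities(p, K, n0, n1, pop.m)
    chosen = rng.choice(pop.m, size=n0 + n1, replace=False, p=w / w.sum())
    pheno = waffect(p[chosen], n1, seed=rng)
    return CaseControlCohort(
        genotypes=pop.genotypes[chosen],
        phenotype=pheno,
        causal_pair=pair,
        seed=seed,
        loci=list(pop.loci),
    )


def pair_conditional_distributions(
    s: DiseaseScenario,
) -> tuple[np.ndarray, np.ndarray]:
    """(P(G|D), P(G|not D)) 3x3 matrices for the scenario, via Bayes' rule."""
    freqs = two_locus_genotype_freqs(s.maf_a, s.maf_b, s.r2)
    pen = solve_penetrance(s, freqs).p
    K = s.prevalence
    case = pen * freqs / K
    ctrl = (1 - pen) * freqs / (1 - K)
    # Normalize away float round-off; both sums equal 1 analytically.
    return case / case.sum(), ctrl / ctrl.sum()


def simulate_pair_counts(
    s: DiseaseScenario, n0: int, n1: int, seed: int | np.random.Generator = 0
) -> PairTable:
    """Draw a 2x3x3 case/control genotype table for the two-SNP design.

    Case cells ~ Multinomial(n1, P(G|D)); control cells ~
    Multinomial(n0, P(G|not D)).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    case_d, ctrl_d = pair_conditional_distributions(s)
    case = rng.multinomial(n1, case_d.ravel()).reshape(3, 3)
    ctrl = rng.multinomial(n0, ctrl_d.ravel()).reshape(3, 3)
    return PairTable(np.stack([ctrl, case]))


def simulate_pair_counts_batch(
    s: DiseaseScenario, n0: int, n1: int, reps: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """(reps, 2, 3, 3) array of independent two-SNP tables (vectorized)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    case_d, ctrl_d = pair_conditional_distributions(s)
    case = rng.multinomial(n1, case_d.ravel(), size=reps).reshape(reps, 3, 3)
    ctrl = rng.multinomial(n0, ctrl_d.ravel(), size=reps).reshape(reps, 3, 3)
    return np.stack([ctrl, case], axis=1)
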