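"""Two-locus disease models: epistasis matrices, penetrance tables, scenarios.

The disease architecture is a 3x3 penetrance surface over the genotypes of a
causal SNP pair (a, b).  The relative risk of genotype (i, j) versus (0, 0)
factorizes as R_ij = r_{a,i} * r_{b,j} * rho_ij, with dominant-coded main
effects (r_{x,0} = 1, r_{x,1} = r_{x,2} = r_x) and an epistasis matrix
rho_ij drawn from a small catalogue of canonical models (null,
dominant-dominant, recessive-recessive, multiplicative, alternative).  Given
genotype frequencies, prevalence K pins the baseline penetrance:
p00 = K / E[R], p_ij = p00 * R_ij.

Epistasis is understood statistically as departure from additivity on the
logit scale; ``penetrance_to_logit`` exposes that decomposition exactly
(intercept, two length-2 main-effect vectors, one 2x2 interaction matrix)
and is the inverse of ``logit_to_penetrance``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.special import expit, logit

from .resample import SimulatedPopulation, ld_r2

__all__ = [
    "EPISTASIS_MODELS",
    "DiseaseScenario",
    "PenetranceTable",
    "LogitParams",
    "epistasis_matrix",
    "relative_risk_table",
    "two_locus_genotype_freqs",
    "solve_penetrance",
    "penetrance_to_logit",
    "logit_to_penetrance",
    "select_causal_pair",
    "enumerate_scenarios",
]

EPISTASIS_MODELS = ("M0", "M1", "M2", "M3", "M4")

# Interaction parameter grids per model in the canonical 234-scenario design.
_RHO_GRID = {"M1": (2, 3, 5), "M2": (2, 5, 10), "M3": (2, 3, 5), "M4": (2, 3, 5)}
_MAF_GRID = ((0.15, 0.15), (0.3, 0.3))
_R2_GRID = (0.0, 0.2, 0.5)
_MAIN_GRID = ((1.0, 1.0), (1.5, 1.5), (1.0, 1.5))


@dataclass(frozen=True)
class DiseaseScenario:
    """One cell of the scenario grid: prevalence, MAFs, LD, effects, model."""

    model: str
    prevalence: float = 0.15
    maf_a: float = 0.3
    maf_b: float = 0.3
    r2: float = 0.0
    rr_a: float = 1.0
    rr_b: float = 1.0
    rho: float | None = None

    def __post_init__(self) -> None:
        if self.model not in EPISTASIS_MODELS:
            raise ValueError(f"unknown epistasis model {self.model!r}")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        for f in (self.maf_a, self.maf_b):
            if not 0 < f <= 0.5:
                raise ValueError("MAF must lie in (0, 0.5]")
        if self.model != "M0" and (self.rho is None or self.rho < 1):
            raise ValueError("rho >= 1 required for models M1-M4")

    def label(self) -> str:
        rho = "" if self.rho is None else f"_rho{self.rho:g}"
        return (
            f"{self.model}_f{self.maf_a:g}-{self.maf_b:g}_r2{self.r2:g}"
            f"_rr{self.rr_a:g}-{self.rr_b:g}{rho}"
        )


@dataclass
class PenetranceTable:
    """3x3 matrix of P(disease | G_a = i, G_b = j)."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (3, 3):
            raise ValueError("penetrance table must be 3x3")
        if ((self.p < 0) | (self.p > 1)).any():
            raise ValueError("penetrances must lie in [0, 1]")

    @property
    def p00(self) -> float:
        return float(self.p[0, 0])


@dataclass
class LogitParams:
    """Exact logit-scale decomposition of a 3x3 penetrance table."""

    alpha: float
    beta_a: np.ndarray  # length 2, genotype levels 1 and 2
    beta_b: np.ndarray  # length 2
    beta_ab: np.ndarray  # 2x2 interaction


def epistasis_matrix(model: str, rho: float | None = None) -> np.ndarray:
    """The canonical 3x3 interaction matrix rho_ij for one model.

    M0 null, M1 dominant-dominant, M2 recessive-recessive, M3 multiplicative
    (rho ** (i>0 indicator products: rho, rho^2, rho^4)), M4 alternative.
    """
    if model == "M0":
        return np.ones((3, 3))
    if rho is None or rho < 1:
        raise ValueError("rho >= 1 required for models M1-M4")
    r = float(rho)
    if model == "M1":
        return np.array([[1, 1, 1], [1, r, r], [1, r, r]], dtype=float)
    if model == "M2":
        return np.array([[1, 1, 1], [1, 1, 1], [1, 1, r]], dtype=float)
    if model == "M3":
        return np.array([[1, 1, 1], [1, r, r**2], [1, r**2, r**4]], dtype=float)
    if model == "M4":
        return np.array([[1, 1, 1], [1, 1, r], [r, r, r]], dtype=float)
    raise ValueError(f"unknown epistasis model {model!r}")


def relative_risk_table(s: DiseaseScenario) -> np.ndarray:
    """R_ij = r_{a,i} r_{b,j} rho_ij with dominant-coded main effects."""
    ra = np.array([1.0, s.rr_a, s.rr_a])
    rb = np.array([1.0, s.rr_b, s.rr_b])
    return np.outer(ra, rb) * epistasis_matrix(s.model, s.rho)


def two_locus_genotype_freqs(f_a: float, f_b: float, r2: float) -> np.ndarray:
    """Joint 3x3 genotype distribution of two loci with given MAFs and LD r^2.

    Haplotype frequencies take the positive-D solution
    D = sqrt(r2 * f_a (1-f_a) f_b (1-f_b)); genotypes arise from random union
    of two independent haplotypes (Hardy-Weinberg expansion).
    """
    for f in (f_a, f_b):
        if not 0 < f <= 0.5:
            raise ValueError("MAF must lie in (0, 0.5]")
    if not 0 <= r2 <= 1:
        raise ValueError("r2 must lie in [0, 1]")
    d = np.sqrt(r2 * f_a * (1 - f_a) * f_b * (1 - f_b))
    d_max = min(f_a * (1 - f_b), f_b * (1 - f_a))
    if d > d_max + 1e-12:
        r2_max = d_max**2 / (f_a * (1 - f_a) * f_b * (1 - f_b))
        raise ValueError(
            f"r2={r2} infeasible for MAFs ({f_a}, {f_b}); maximum r2 is {r2_max:.6f}"
        )
    d = min(d, d_max)
    # hap[u, v] = P(haplotype carries u copies at a, v copies at b), u, v in {0,1}
    hap = np.array(
        [
            [(1 - f_a) * (1 - f_b) + d, (1 - f_a) * f_b - d],
            [f_a * (1 - f_b) - d, f_a * f_b + d],
        ]
    )
    geno = np.zeros((3, 3))
    for (u1, v1), (u2, v2) in product(product(range(2), repeat=2), repeat=2):
        geno[u1 + u2, v1 + v2] += hap[u1, v1] * hap[u2, v2]
    return geno


def solve_penetrance(s: DiseaseScenario, geno_freqs: np.ndarray) -> PenetranceTable:
    """Penetrance table meeting the prevalence and relative-risk constraints.

    With R fixed by the scenario, prevalence is linear in the baseline:
    p00 = K / sum_ij freq_ij R_ij; p_ij = p00 R_ij.  Raises if any cell
    exceeds 1 (scenario infeasible at this prevalence).
    """
    geno_freqs = np.asarray(geno_freqs, dtype=float)
    if geno_freqs.shape != (3, 3) or abs(geno_freqs.sum() - 1) > 1e-9:
        raise ValueError("geno_freqs must be a 3x3 probability matrix")
    rr = relative_risk_table(s)
    p00 = s.prevalence / float((geno_freqs * rr).sum())
    p = p00 * rr
    if (p > 1).any():
        raise ValueError(
            f"scenario infeasible at prevalence K={s.prevalence}: "
            f"max penetrance {p.max():.4f} > 1"
        )
    return PenetranceTable(p)


def penetrance_to_logit(t: PenetranceTable) -> LogitParams:
    """Exact logit decomposition; requires all penetrances strictly in (0, 1)."""
    p = t.p
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("penetrances must lie strictly in (0, 1)")
    lg = logit(p)
    alpha = lg[0, 0]
    beta_a = lg[1:, 0] - alpha
    beta_b = lg[0, 1:] - alpha
    beta_ab = lg[1:, 1:] - alpha - beta_a[:, None] - beta_b[None, :]
    return LogitParams(float(alpha), beta_a, beta_b, beta_ab)


def logit_to_penetrance(lp: LogitParams) -> PenetranceTable:
    """Inverse of :func:`penetrance_to_logit`."""
    lg = np.empty((3, 3))
    lg[0, 0] = lp.alpha
    lg[1:, 0] = lp.alpha + lp.beta_a
    lg[0, 1:] = lp.alpha + lp.beta_b
    lg[1:, 1:] = lp.alpha + lp.beta_a[:, None] + lp.beta_b[None, :] + lp.beta_ab
    return PenetranceTable(expit(lg))


def select_causal_pair(
    pop: SimulatedPopulation,
    s: DiseaseScenario,
    w: float = 1.0,
    max_dist_bp: int = 1_000_000,
) -> tuple[int, int, float, float, float]:
    """Pick the locus pair whose MAFs and LD best match the scenario targets.

    Minimizes (maf_a_hat - f_a)^2 + (maf_b_hat - f_b)^2 + w (r2_hat - r2)^2.
    For r2 = 0 candidates are all cross-chromosome pairs; otherwise all
    within-chromosome pairs closer than ``max_dist_bp``.  Both orientations
    of each pair are scored.  Returns (a, b, maf_a_hat, maf_b_hat, r2_hat).
    """
    maf = pop.maf()
    poly = maf > 0
    chrom = np.array([loc.chromosome for loc in pop.loci])
    pos = np.array([loc.position for loc in pop.loci])
    idx = np.flatnonzero(poly)
    if idx.size < 2:
        raise ValueError("need at least two polymorphic loci")
    pairs: list[tuple[int, int]] = []
    for ii, a in enumerate(idx):
        for b in idx[ii + 1 :]:
            if s.r2 == 0:
                if chrom[a] != chrom[b]:
                    pairs.append((int(a), int(b)))
            else:
                if chrom[a] == chrom[b] and abs(int(pos[a]) - int(pos[b])) <= max_dist_bp:
                    pairs.append((int(a), int(b)))
    if not pairs:
        raise ValueError("empty candidate pair set for this scenario")
    best = None
    g = pop.genotypes
    for a, b in pairs:
        r2_hat = ld_r2(g[:, a], g[:, b])
        for x, y in ((a, b), (b, a)):
            obj = (
                (maf[x] - s.maf_a) ** 2
                + (maf[y] - s.maf_b) ** 2
                + w * (r2_hat - s.r2) ** 2
            )
            if best is None or obj < best[0]:
                best = (obj, x, y, float(maf[x]), float(maf[y]), float(r2_hat))
    _, a, b, fa, fb, r2 = best
    return a, b, fa, fb, r2


def enumerate_scenarios(prevalence: float = 0.15) -> list[DiseaseScenario]:
    """The full canonical scenario grid (234 scenarios).

    Grid: MAF pairs {(0.15, 0.15), (0.3, 0.3)}, LD r^2 {0, 0.2, 0.5}, main
    effects {(1,1), (1.5,1.5), (1,1.5)}, and per-model interaction values
    (M1/M3/M4: 2,3,5; M2: 2,5,10); M0 carries no interaction parameter.
    """
    out: list[DiseaseScenario] = []
    for model in EPISTASIS_MODELS:
        rhos: tuple[float | None, ...] = (
            (None,) if model == "M0" else _RHO_GRID[model]
        )
        for (fa, fb), r2, (ra, rb), rho in product(
            _MAF_GRID, _R2_GRID, _MAIN_GRID, rhos
        ):
            out.append(
                DiseaseScenario(
                    model=model,
                    prevalence=prevalence,
                    maf_a=fa,
                    maf_b=fb,
                    r2=r2,
                    rr_a=ra,
                    rr_b=rb,
                    rho=None if rho is None else float(rho),
                )
            )
    return out
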