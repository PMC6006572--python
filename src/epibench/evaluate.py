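"""Thresholding and performance metrics for exhaustive pair scans.

Detection is assessed at two resolutions: the SNP level (did the causal SNP
pair itself pass the p-value threshold; how many non-causal pairs did) and
the LD-block level, where SNP pairs are first mapped to block pairs and a
block pair counts as detected when any member SNP pair passes.  A
piecewise-linear ROC over the ranking of the single causal pair against all
others yields a per-replicate AUC.  Bonferroni and Benjamini-Hochberg
selection and a simple greedy r^2 block builder complete the layer, together
with the sparse-table diagnostic: the probability that a cohort contains no
double-recessive genotype at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate as _integrate

from .resample import ld_r2

__all__ = [
    "BlockMap",
    "EvalResult",
    "bonferroni_threshold",
    "snp_level_rates",
    "block_level_rates",
    "roc_auc",
    "bh_fdr",
    "greedy_r2_blocks",
    "empty_cell_probability",
]


@dataclass
class BlockMap:
    """Partition of loci into contiguous per-chromosome blocks."""

    block_of: np.ndarray  # locus index -> block id
    blocks: list[tuple[int, int, int]]  # (chromosome, start locus, end locus) inclusive

    def __post_init__(self) -> None:
        self.block_of = np.asarray(self.block_of, dtype=np.int64)
        for bid, (c, start, end) in enumerate(self.blocks):
            if start > end:
                raise ValueError("block start after end")
            if not (self.block_of[start : end + 1] == bid).all():
                raise ValueError("block_of inconsistent with block spans")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @classmethod
    def singletons(cls, n_loci: int, chromosomes: np.ndarray | None = None) -> "BlockMap":
        chroms = np.ones(n_loci, dtype=int) if chromosomes is None else chromosomes
        return cls(
            np.arange(n_loci),
            [(int(chroms[i]), i, i) for i in range(n_loci)],
        )


@dataclass
class EvalResult:
    scenario: str
    method: str
    tpr_snp: float
    fpr_snp: float
    tpr_block: float
    fpr_block: float
    auc: float


def bonferroni_threshold(n_snps: int, alpha: float = 0.05) -> float:
    """alpha / C(n_snps, 2): the study-wide pairwise threshold (log-safe)."""
    if n_snps < 2:
        raise ValueError("need at least two SNPs")
    log_pairs = np.log(n_snps) + np.log(n_snps - 1) - np.log(2)
    return float(np.exp(np.log(alpha) - log_pairs))


def snp_level_rates(
    results: dict[tuple[int, int], float],
    causal: tuple[int, int],
    p0: float,
    n_pairs: int | None = None,
) -> tuple[int, int, float]:
    """(causal detected, false-positive count, false-positive rate).

    ``results`` maps unordered SNP pairs to p-values; missing pairs count as
    p = 1.  ``n_pairs`` defaults to the number of scored pairs.
    """
    causal = tuple(sorted(causal))
    total = len(results) if n_pairs is None else n_pairs
    tp = 0
    fp = 0
    for pair, p in results.items():
        if p < p0:
            if tuple(sorted(pair)) == causal:
                tp = 1
            else:
                fp += 1
    return tp, fp, fp / max(total, 1)


def block_level_rates(
    results: dict[tuple[int, int], float],
    block_map: BlockMap,
    causal: tuple[int, int],
    p0: float,
) -> tuple[int, float]:
    """(causal block pair detected, non-causal block-pair detection rate).

    A block pair is detected when at least one member SNP pair falls below
    the threshold.  The causal block pair must involve two distinct blocks.
    Same-block SNP pairs are outside the block-pair universe and ignored.
    """
    bo = block_map.block_of
    ca, cb = sorted((int(bo[causal[0]]), int(bo[causal[1]])))
    if ca == cb:
        raise ValueError("causal SNPs fall in the same LD block; block-level rates undefined")
    detected: set[tuple[int, int]] = set()
    for (a, b), p in results.items():
        if p < p0:
            ba, bb = sorted((int(bo[a]), int(bo[b])))
            if ba != bb:
                detected.add((ba, bb))
    nb = block_map.n_blocks
    n_block_pairs = nb * (nb - 1) // 2
    tp = 1 if (ca, cb) in detected else 0
    fp = len(detected) - tp
    return tp, fp / max(n_block_pairs, 1)


def roc_auc(scores: dict[tuple[int, int], float], causal: tuple[int, int]) -> float:
    """AUC of ranking the single causal pair against all non-causal pairs.

    Equals the normalized rank of the causal pair's score (ties averaged);
    1 means top-ranked, 0.5 is the all-ties / random baseline.
    """
    causal = tuple(sorted(causal))
    try:
        s_causal = scores[causal] if causal in scores else scores[(causal[1], causal[0])]
    except KeyError:
        raise ValueError("causal pair missing from the score set") from None
    others = np.array(
        [v for k, v in scores.items() if tuple(sorted(k)) != causal], dtype=float
    )
    if others.size == 0:
        raise ValueError("need at least one non-causal pair")
    below = (others < s_causal).sum()
    ties = (others == s_causal).sum()
    return float((below + 0.5 * ties) / others.size)


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up selection mask at FDR level q."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    crit = q * np.arange(1, m + 1) / m
    passing = np.flatnonzero(ranked <= crit)
    mask = np.zeros(m, dtype=bool)
    if passing.size:
        mask[order[: passing[-1] + 1]] = True
    return mask


def greedy_r2_blocks(
    genotypes: np.ndarray,
    loci,
    r2_min: float = 0.5,
    max_span_kb: int = 500,
) -> BlockMap:
    """Greedy LD-block builder: a block absorbs the next locus while its r^2
    with the block's first locus stays >= r2_min and the bp span stays within
    ``max_span_kb``.  Loci that join nothing become singleton blocks.

    A deliberately simple stand-in for confidence-interval haplotype-block
    algorithms; block maps from external tooling can be loaded instead.
    """
    chrom = np.array([loc.chromosome for loc in loci])
    pos = np.array([loc.position for loc in loci])
    n = len(loci)
    block_of = np.empty(n, dtype=np.int64)
    blocks: list[tuple[int, int, int]] = []
    i = 0
    bid = 0
    while i < n:
        j = i
        while (
            j + 1 < n
            and chrom[j + 1] == chrom[i]
            and (pos[j + 1] - pos[i]) <= max_span_kb * 1000
            and ld_r2(genotypes[:, i], genotypes[:, j + 1]) >= r2_min
        ):
            j += 1
        block_of[i : j + 1] = bid
        blocks.append((int(chrom[i]), i, j))
        bid += 1
        i = j + 1
    return BlockMap(block_of, blocks)


def empty_cell_probability(
    n_samples: int, f_low: float = 0.05, f_high: float = 0.5
) -> float:
    """P(no double-recessive genotype in a cohort), MAF ~ Uniform(f_low, f_high).

    For two independent loci with common MAF f, an individual is double
    recessive with probability f^4; integrating (1 - f^4)^n over the MAF
    prior gives the chance that an n-sample contingency table has an empty
    (2, 2) cell.
    """
    if not 0 < f_low < f_high <= 0.5:
        raise ValueError("require 0 < f_low < f_high <= 0.5")
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    val, _ = _integrate.quad(
        lambda f: (1 - f**4) ** n_samples, f_low, f_high, epsrel=1e-9
    )
    return float(val / (f_high - f_low))
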