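"""Synthetic template genotype panels with block-structured LD, and panel QC.

A template panel plays the role of a reference genotype set (such as a
continental subset of a sequencing project) from which a large study
population is later resampled.  Genotypes are coded 0/1/2 as counts of the
allele that is *minor in the panel*; this orientation is frozen at panel
creation and inherited by everything downstream.

The generator builds each chromosome as a sequence of contiguous LD blocks.
Within a block every haplotype descends from a small pool of founder
haplotypes that are perfect copies/complements of one block pattern, so the
pre-noise inter-locus correlation is |r| = 1; per-locus "replacement" noise
(with probability eps the allele is redrawn from its marginal law) then
attenuates pairwise r^2 by (1-eps)^4 while leaving allele frequencies
untouched.  Setting eps = 1 - within_block_r2**0.25 therefore targets a
typical within-block r^2 near the requested value without moving the MAF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "LocusInfo",
    "TemplatePanel",
    "generate_template_panel",
    "hwe_test",
    "qc_filter",
]


@dataclass(frozen=True)
class LocusInfo:
    """Metadata for one biallelic locus."""

    locus_id: str
    chromosome: int
    position: int
    minor_allele: str = "A"
    major_allele: str = "G"

    def __post_init__(self) -> None:
        if self.chromosome < 1:
            raise ValueError("chromosome must be >= 1")
        if self.position < 0:
            raise ValueError("position must be >= 0")


@dataclass
class TemplatePanel:
    """A set of template genotypes: n_templates x p matrix of 0/1/2 codes."""

    genotypes: np.ndarray
    loci: list[LocusInfo]
    block_of: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        if self.genotypes.shape[1] != len(self.loci):
            raise ValueError("column count does not match locus list")
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("genotype entries must be in {0, 1, 2}")
        ids = [loc.locus_id for loc in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("locus_ids must be unique")
        for c in self.chromosomes():
            pos = [loc.position for loc in self.loci if loc.chromosome == c]
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_templates(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def chromosomes(self) -> list[int]:
        seen: dict[int, None] = {}
        for loc in self.loci:
            seen.setdefault(loc.chromosome, None)
        return list(seen)

    def chromosome_slices(self) -> dict[int, slice]:
        """Contiguous column slice of each chromosome (loci are stored in order)."""
        out: dict[int, slice] = {}
        chroms = np.array([loc.chromosome for loc in self.loci])
        for c in self.chromosomes():
            idx = np.flatnonzero(chroms == c)
            out[c] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def maf(self) -> np.ndarray:
        """Empirical frequency of the coded (minor-at-creation) allele per locus."""
        return self.genotypes.mean(axis=0) / 2.0


def hwe_test(n0: int, n1: int, n2: int) -> float:
    """Chi-square (1 df) goodness-of-fit p-value for Hardy-Weinberg equilibrium.

    ``n0, n1, n2`` are genotype counts for 0/1/2 copies of the coded allele.
    Expected counts use the observed allele frequency.  A monomorphic locus
    fits HWE trivially and returns p = 1.
    """
    n = n0 + n1 + n2
    if n <= 0:
        raise ValueError("empty genotype counts")
    f = (n1 + 2 * n2) / (2 * n)
    if f == 0.0 or f == 1.0:
        return 1.0
    expected = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2]) * n
    chi2 = float((((np.array([n0, n1, n2]) - expected) ** 2) / expected).sum())
    return float(_sps.chi2.sf(chi2, df=1))


def _block_lengths(p_c: int, lo: int, hi: int, rng: np.random.Generator) -> list[int]:
    lengths: list[int] = []
    left = p_c
    while left > 0:
        n = int(rng.integers(lo, hi + 1))
        lengths.append(min(n, left))
        left -= lengths[-1]
    return lengths


def _simulate_block(
    n_templates: int,
    length: int,
    maf_lo: float,
    maf_hi: float,
    eps: float,
    n_founders: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One block of haplotypes -> genotype columns (n_templates x length)."""
    q = float(rng.uniform(maf_lo, maf_hi))
    # Block pattern: founder haplotypes are the pattern or its complement.
    pattern = rng.integers(0, 2, size=length).astype(np.int8)
    n_carrier = max(1, n_founders // 2)
    founder_is_carrier = np.zeros(n_founders, dtype=bool)
    founder_is_carrier[:n_carrier] = True
    w = np.where(founder_is_carrier, q / n_carrier, (1 - q) / (n_founders - n_carrier))
    # Two haplotypes per template individual.
    choice = rng.choice(n_founders, size=(n_templates, 2), p=w)
    carrier = founder_is_carrier[choice]  # (n, 2) bool
    hap = np.where(carrier[:, :, None], 1 - pattern[None, None, :], pattern[None, None, :])
    # Replacement noise: with prob eps redraw the allele from its marginal law.
    if eps > 0:
        marg = np.where(pattern[None, None, :] == 1, 1 - q, q)  # P(allele = 1)
        redraw = rng.random(hap.shape) < eps
        fresh = (rng.random(hap.shape) < marg).astype(np.int8)
        hap = np.where(redraw, fresh, hap)
    return hap.sum(axis=1).astype(np.int8)


def generate_template_panel(
    n_templates: int,
    chrom_sizes: Sequence[int],
    block_len_range: tuple[int, int] = (5, 10),
    maf_range: tuple[float, float] = (0.05, 0.5),
    within_block_r2: float = 0.8,
    seed: int = 0,
    n_founders: int = 4,
    bp_spacing: int = 5_000,
    max_block_attempts: int = 1000,
) -> TemplatePanel:
    """Generate a synthetic multi-chromosome template panel with block LD.

    Parameters
    ----------
    n_templates
        Number of template individuals (>= 4).
    chrom_sizes
        Loci per chromosome; each must be at least the maximum block length.
    block_len_range
        Inclusive range of block lengths (in loci).
    maf_range
        Every locus is regenerated until its empirical MAF falls in this
        closed interval (an error is raised if the interval contains no
        attainable frequency k/(2 n_templates)).
    within_block_r2
        Target for the typical pairwise r^2 inside a block; 0 gives
        independent loci, 1 gives perfectly correlated blocks.
    seed
        Seed for the private random generator; identical inputs give a
        bit-identical panel.
    """
    if n_templates < 4:
        raise ValueError("n_templates must be >= 4")
    lo, hi = block_len_range
    if not (1 <= lo <= hi):
        raise ValueError("invalid block_len_range")
    if any(s < hi for s in chrom_sizes):
        raise ValueError("every chromosome must hold at least one max-length block")
    maf_lo, maf_hi = maf_range
    if not (0 < maf_lo <= maf_hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    # Attainable empirical MAFs are multiples of 1/(2 n_templates).
    grid = np.arange(0, 2 * n_templates + 1) / (2 * n_templates)
    grid = np.minimum(grid, 1 - grid)
    if not ((grid >= maf_lo) & (grid <= maf_hi)).any():
        raise ValueError(
            f"maf_range {maf_range} infeasible with n_templates={n_templates}"
        )
    if not 0 <= within_block_r2 <= 1:
        raise ValueError("within_block_r2 must be in [0, 1]")
    eps = 1.0 - within_block_r2**0.25

    rng = np.random.default_rng(seed)
    columns: list[np.ndarray] = []
    loci: list[LocusInfo] = []
    block_of: list[int] = []
    block_id = 0
    for ci, p_c in enumerate(chrom_sizes):
        chrom = ci + 1
        offset = len(loci)
        for length in _block_lengths(p_c, lo, hi, rng):
            for _ in range(max_block_attempts):
                g = _simulate_block(
                    n_templates, length, maf_lo, maf_hi, eps, n_founders, rng
                )
                freq = g.mean(axis=0) / 2.0
                maf = np.minimum(freq, 1 - freq)
                if ((maf >= maf_lo) & (maf <= maf_hi)).all():
                    break
            else:
                raise RuntimeError(
                    "could not realize a block with every MAF in "
                    f"{maf_range} after {max_block_attempts} attempts"
                )
            columns.append(g)
            block_of.extend([block_id] * length)
            block_id += 1
        for j in range(p_c):
            loci.append(
                LocusInfo(
                    locus_id=f"snp{chrom}_{j}",
                    chromosome=chrom,
                    position=(j + 1) * bp_spacing,
                )
            )
        assert len(loci) - offset == p_c
    genotypes = np.concatenate(columns, axis=1)
    # Re-orient so code 2 counts the panel-minor allele.
    flip = genotypes.mean(axis=0) / 2.0 > 0.5
    genotypes[:, flip] = 2 - genotypes[:, flip]
    return TemplatePanel(genotypes, loci, block_of=np.array(block_of))


def qc_filter(
    panel: TemplatePanel,
    maf_min: float = 0.05,
    hwe_alpha: float = 1e-3,
) -> tuple[TemplatePanel, list[dict]]:
    """Remove loci with MAF < maf_min or Hardy-Weinberg p-value < hwe_alpha.

    Returns the filtered panel (locus order preserved) and a report listing
    every removed locus with its MAF, HWE p-value and the reason ("MAF" is
    reported first when both filters fail).
    """
    keep: list[int] = []
    report: list[dict] = []
    for j, loc in enumerate(panel.loci):
        col = panel.genotypes[:, j]
        counts = np.bincount(col, minlength=3)
        maf = float(col.mean() / 2.0)
        maf = min(maf, 1.0 - maf)
        p = hwe_test(int(counts[0]), int(counts[1]), int(counts[2]))
        if maf < maf_min:
            report.append({"locus_id": loc.locus_id, "maf": maf, "hwe_p": p, "reason": "MAF"})
        elif p < hwe_alpha:
            report.append({"locus_id": loc.locus_id, "maf": maf, "hwe_p": p, "reason": "HWE"})
        else:
            keep.append(j)
    if not keep:
        raise ValueError("QC removed every locus")
    sub = panel.genotypes[:, keep]
    loci = [panel.loci[j] for j in keep]
    block_of = None if panel.block_of is None else panel.block_of[keep]
    return TemplatePanel(sub, loci, block_of=block_of), report
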