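"""Expand a template panel into a large simulated population preserving LD.

Each simulated chromosome is grown from a seed window copied verbatim from a
random template, then extended one locus at a time in both directions.  At
every extension step the new genotype is drawn uniformly among the template
individuals whose genotypes agree with the already-simulated values on the
2l-locus window adjacent to the new locus.  Long-range correlations thus decay
with distance while local LD mirrors the templates.

When no template matches the current window the matcher shrinks the window
one locus at a time from the far end until at least one template matches;
with an empty window it draws from the locus's marginal template
distribution.  Every shrink/marginal event increments ``fallback_count``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import LocusInfo, TemplatePanel

__all__ = ["SimulatedPopulation", "resample_population", "ld_r2"]


@dataclass
class SimulatedPopulation:
    """m x p genotype matrix sharing the source panel's locus metadata."""

    genotypes: np.ndarray
    loci: list[LocusInfo]
    seed: int
    fallback_count: int = 0
    block_of: np.ndarray | None = None

    @property
    def m(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def maf(self) -> np.ndarray:
        return self.genotypes.mean(axis=0) / 2.0

    def chromosome_slices(self) -> dict[int, slice]:
        out: dict[int, slice] = {}
        chroms = np.array([loc.chromosome for loc in self.loci])
        for c in dict.fromkeys(chroms.tolist()):
            idx = np.flatnonzero(chroms == c)
            out[int(c)] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out


def ld_r2(g1: np.ndarray, g2: np.ndarray, warn: list | None = None) -> float:
    """Squared Pearson correlation of two 0/1/2 genotype vectors (composite LD).

    A constant vector has undefined correlation; by convention 0 is returned
    and, if ``warn`` is a list, a message is appended to it.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape or g1.ndim != 1 or g1.size < 2:
        raise ValueError("genotype vectors must share a length >= 2")
    s1, s2 = g1.std(), g2.std()
    if s1 == 0.0 or s2 == 0.0:
        if warn is not None:
            warn.append("constant genotype vector; r^2 defined as 0")
        return 0.0
    r = float(np.corrcoef(g1, g2)[0, 1])
    return r * r


def _extend(
    tpl: np.ndarray,
    sim: np.ndarray,
    start: int,
    stop: int,
    step: int,
    w: int,
    rng: np.random.Generator,
) -> int:
    """Fill sim[start:stop:step] by window matching; returns fallback count.

    For step=+1 the matching window for locus j is sim[j-w:j]; for step=-1 it
    is sim[j+1:j+w+1].
    """
    n_tpl = tpl.shape[0]
    fallbacks = 0
    for j in range(start, stop, step):
        if step == 1:
            lo, hi = j - w, j
        else:
            lo, hi = j + 1, j + w + 1
        window = sim[lo:hi]
        rows = np.flatnonzero((tpl[:, lo:hi] == window).all(axis=1))
        shrink_lo, shrink_hi = lo, hi
        while rows.size == 0:
            fallbacks += 1
            # shrink from the end farthest from locus j
            if step == 1:
                shrink_lo += 1
            else:
                shrink_hi -= 1
            if shrink_lo >= shrink_hi:
                rows = np.arange(n_tpl)
                break
            rows = np.flatnonzero(
                (tpl[:, shrink_lo:shrink_hi] == sim[shrink_lo:shrink_hi]).all(axis=1)
            )
        k = rows[rng.integers(rows.size)]
        sim[j] = tpl[k, j]
    return fallbacks


def resample_population(
    panel: TemplatePanel, m: int, l: int = 5, seed: int = 0
) -> SimulatedPopulation:
    """Simulate ``m`` individuals whose LD structure mirrors the panel.

    Per individual and chromosome: a start locus d is drawn uniformly among
    loci whose (2l+1)-window fits inside the chromosome, the window
    [d-l, d+l] is copied from a uniformly drawn template, and the chromosome
    is completed by rightward then leftward window-matched extension.
    Chromosomes are independent.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if l < 1:
        raise ValueError("l must be >= 1")
    w = 2 * l
    slices = panel.chromosome_slices()
    for c, sl in slices.items():
        if sl.stop - sl.start < 2 * l + 1:
            raise ValueError(f"chromosome {c} shorter than 2l+1 = {2 * l + 1} loci")
    rng = np.random.default_rng(seed)
    out = np.empty((m, panel.n_loci), dtype=np.int8)
    fallbacks = 0
    n_tpl = panel.n_templates
    for c, sl in slices.items():
        tpl = np.ascontiguousarray(panel.genotypes[:, sl])
        p_c = tpl.shape[1]
        for k in range(m):
            sim = np.empty(p_c, dtype=np.int8)
            d = int(rng.integers(l, p_c - l))  # interior start locus
            t = int(rng.integers(n_tpl))
            sim[d - l : d + l + 1] = tpl[t, d - l : d + l + 1]
            fallbacks += _extend(tpl, sim, d + l + 1, p_c, 1, w, rng)
            fallbacks += _extend(tpl, sim, d - l - 1, -1, -1, w, rng)
            out[k, sl] = sim
    return SimulatedPopulation(
        genotypes=out,
        loci=list(panel.loci),
        seed=seed,
        fallback_count=fallbacks,
        block_of=None if panel.block_of is None else panel.block_of.copy(),
    )
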