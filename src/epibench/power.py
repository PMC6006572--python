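"""Two-SNP power estimation and the smallest detectable epistasis effect.

Power for a disease scenario is the fraction of Monte-Carlo replicates in
which a method's p-value on a simulated 2x3x3 case/control table falls below
the study-wide threshold (by default 0.05 Bonferroni-corrected for the
pairwise analysis of a 5e5-SNP chip, i.e. 0.05 / 1.25e10).  The smallest
interaction parameter rho_0.8 reaching 80% power is located with Brent's
root finder on power(rho) - 0.8; every evaluation reuses the same replicate
seeds (common random numbers), which renders the noisy power curve
effectively monotone in rho and lets the root finder converge.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize as _opt

from .cohort import simulate_pair_counts_batch
from .disease import DiseaseScenario, solve_penetrance, two_locus_genotype_freqs
from .stats import score_tables_batch

__all__ = [
    "PAIRWISE_THRESHOLD_5E5",
    "PowerEstimate",
    "RhoAtPower",
    "estimate_power",
    "rho_for_power",
    "power_table",
]

# 0.05 with a Bonferroni correction for ~C(5e5, 2) SNP pairs, as printed on
# chip-scale study designs.  The exact pair count of a 5e5-SNP chip is
# 1.2499975e11; both constants are exposed.
PAIRWISE_THRESHOLD_5E5 = 0.05 / 1.25e10
PAIRWISE_THRESHOLD_5E5_EXACT = 0.05 / (5e5 * (5e5 - 1) / 2)


@dataclass
class PowerEstimate:
    scenario: DiseaseScenario
    method: str
    n0: int
    n1: int
    p_threshold: float
    reps: int
    power: float
    seed: int

    @property
    def mc_se(self) -> float:
        return float(np.sqrt(self.power * (1 - self.power) / self.reps))


@dataclass
class RhoAtPower:
    """rho reaching the target power, or ``above_cap`` when even the cap fails."""

    method: str
    n: int
    maf: float
    r2: float
    rr_a: float
    rr_b: float
    model: str
    target_power: float
    rho: float | None  # None <=> above_cap
    cap: float = 20.0

    @property
    def above_cap(self) -> bool:
        return self.rho is None

    def render(self) -> str:
        return f"> {self.cap:g}" if self.rho is None else f"{self.rho:.1f}"


def _replicate_seed(seed: int, r: int) -> int:
    """Deterministic per-replicate substream seed (kept below 2**31)."""
    return int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2**31 - 1))


def estimate_power(
    s: DiseaseScenario,
    method: str,
    n0: int,
    n1: int,
    p_threshold: float = PAIRWISE_THRESHOLD_5E5,
    reps: int = 1000,
    seed: int = 0,
    chunk: int = 1000,
) -> PowerEstimate:
    """Monte-Carlo detection power of ``method`` under the two-SNP design.

    Each replicate r draws a fresh 2x3x3 table with a seed derived from
    (seed, r), scores it, and counts a detection when p < p_threshold.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    log10_thr = np.log10(p_threshold)
    hits = 0
    for start in range(0, reps, chunk):
        nrep = min(chunk, reps - start)
        tables = np.stack(
            [
                simulate_pair_counts_batch(
                    s, n0, n1, reps=1, seed=_replicate_seed(seed, start + r)
                )[0]
                for r in range(nrep)
            ]
        )
        log10_p = score_tables_batch(tables, method)
        hits += int((log10_p < log10_thr).sum())
    return PowerEstimate(s, method, n0, n1, p_threshold, reps, hits / reps, seed)


def max_feasible_rho(family: DiseaseScenario, cap: float = 20.0, tol: float = 1e-6) -> float:
    """Largest rho <= cap keeping every penetrance <= 1 for this family.

    The maximum penetrance K max(R) / E[R] grows with rho for all catalogued
    models, so a bisection on feasibility suffices.
    """

    def feasible(rho: float) -> bool:
        s = _dc_replace(family, rho=rho)
        freqs = two_locus_genotype_freqs(s.maf_a, s.maf_b, s.r2)
        try:
            solve_penetrance(s, freqs)
        except ValueError:
            return False
        return True

    if feasible(cap):
        return cap
    lo, hi = 1.0, cap
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            lo = mid
        else:
            hi = mid
    return lo


def rho_for_power(
    family: DiseaseScenario,
    method: str,
    target: float = 0.8,
    rho_bounds: tuple[float, float] = (1.001, 20.0),
    reps: int = 1000,
    tol: float = 0.05,
    p_threshold: float = PAIRWISE_THRESHOLD_5E5,
    n0: int = 1000,
    n1: int = 1000,
    seed: int = 0,
) -> RhoAtPower:
    """Brent search for the epistasis parameter rho reaching ``target`` power.

    ``family`` fixes everything but rho.  All power evaluations share the
    same replicate seeds (common random numbers).  The search bracket is
    clipped to the largest rho keeping every penetrance <= 1.  Because power
    is not monotone over the whole feasible range (at extreme rho the
    carrier cells of the control table empty out and the degenerate-score
    convention collapses the statistics), the search brackets the *first*
    upward crossing of the target on a coarse grid and then localizes it
    with Brent's method.  If power never reaches the target inside the
    feasible range the result is flagged ``above_cap`` (rendered "> 20").
    """
    lo, hi = rho_bounds
    hi = min(hi, max_feasible_rho(family, hi) - 1e-9)

    def power_at(rho: float) -> float:
        s = _dc_replace(family, rho=rho)
        return estimate_power(
            s, method, n0, n1, p_threshold=p_threshold, reps=reps, seed=seed
        ).power

    meta = dict(
        method=method,
        n=n1,
        maf=family.maf_a,
        r2=family.r2,
        rr_a=family.rr_a,
        rr_b=family.rr_b,
        model=family.model,
        target_power=target,
        cap=rho_bounds[1],
    )
    if power_at(lo) >= target:
        return RhoAtPower(rho=lo, **meta)
    grid = np.linspace(lo, hi, max(int(np.ceil((hi - lo) / 0.5)) + 1, 2))
    prev = lo
    prev_power = 0.0
    for r in grid[1:]:
        pw = power_at(r)
        if prev_power < target <= pw:
            root = _opt.brentq(lambda x: power_at(x) - target, prev, r, xtol=tol)
            return RhoAtPower(rho=float(root), **meta)
        prev, prev_power = r, pw
    return RhoAtPower(rho=None, **meta)


def power_table(
    model: str,
    mafs: Sequence[float],
    ns: Sequence[int],
    main_effects: Sequence[tuple[float, float]] = ((1.0, 1.0),),
    methods: Sequence[str] = ("gboost",),
    r2: float = 0.0,
    prevalence: float = 0.15,
    reps: int = 1000,
    p_threshold: float = PAIRWISE_THRESHOLD_5E5,
    seed: int = 0,
) -> pd.DataFrame:
    """Grid of rho_0.8 values over cohort sizes, MAFs, main effects, methods.

    Returns a tidy DataFrame with one row per cell; ``rho`` is NaN for cells
    whose power never reaches the target below the cap (rendered "> 20").
    """
    rows = []
    for (ra, rb) in main_effects:
        for n in ns:
            for f in mafs:
                family = DiseaseScenario(
                    model=model,
                    prevalence=prevalence,
                    maf_a=f,
                    maf_b=f,
                    r2=r2,
                    rr_a=ra,
                    rr_b=rb,
                    rho=2.0,
                )
                for mth in methods:
                    res = rho_for_power(
                        family,
                        mth,
                        reps=reps,
                        p_threshold=p_threshold,
                        n0=n,
                        n1=n,
                        seed=seed,
                    )
                    rows.append(
                        {
                            "model": model,
                            "method": mth,
                            "n": n,
                            "maf": f,
                            "r2": r2,
                            "rr_a": ra,
                            "rr_b": rb,
                            "rho": np.nan if res.above_cap else res.rho,
                            "rendered": res.render(),
                        }
                    )
    return pd.DataFrame(rows)
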