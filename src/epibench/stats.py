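"""Five exhaustive pairwise epistasis statistics on 2x3x3 case/control tables.

All five tests consume the same unit of data: the cross-tabulation of a SNP
pair's 3x3 genotypes in cases and controls.

* ``fastepi``   - allele-based LD contrast: difference of the log odds ratio
                  of the 2x2 joint allele-count tables between cases and
                  controls, standardized; chi-square, 1 df.
* ``shesisepi`` - genotype-based LD contrast: Fisher-z difference of the
                  case and control Pearson correlations of 0/1/2 genotype
                  codes; chi-square, 1 df.
* ``gboost``    - likelihood-ratio test of the saturated logistic model
                  against the main-effects model, computed as the deviance of
                  the log-linear model with all two-way margins
                  [DA][DB][AB] fitted by iterative proportional fitting;
                  chi-square, 4 df.
* ``indor``     - contrast of the four local (adjacent-cell) odds ratios of
                  the SNP-SNP 3x3 table between cases and controls, Wald
                  statistic with a delta-method covariance; chi-square, 4 df.
* ``dss``       - ROC-based gain: the best standardized improvement of the
                  9-cell pair ROC over the better single-SNP ROC, with a
                  Bonferroni adjustment over ROC vertices; reported on a
                  -log10 p scale.

Degenerate tables (zero cells that a statistic cannot absorb, singular
covariance) uniformly receive score 0 and p = 1 with the ``degenerate`` flag
set, so no statistic ever diverges on sparse tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from scipy import stats as _sps

from .cohort import CaseControlCohort, PairTable

__all__ = [
    "METHODS",
    "ScoreResult",
    "pair_table",
    "chi2_log_sf",
    "fastepi_score",
    "shesisepi_score",
    "gboost_score",
    "indor_score",
    "dss_score",
    "score_pair_table",
    "score_tables_batch",
    "scan_all_pairs",
]

METHODS = ("fastepi", "shesisepi", "gboost", "indor", "dss")

_LN10 = np.log(10.0)


@dataclass
class ScoreResult:
    method: str
    statistic: float
    df: int
    log10_p: float
    degenerate: bool = False


def pair_table(cohort: CaseControlCohort, a: int, b: int) -> PairTable:
    """Cross-tabulate genotypes at loci (a, b) by phenotype into a 2x3x3 tensor."""
    g = cohort.genotypes
    d = cohort.phenotype
    idx = (d.astype(np.int64) * 9 + g[:, a].astype(np.int64) * 3 + g[:, b]).ravel()
    counts = np.bincount(idx, minlength=18).reshape(2, 3, 3)
    return PairTable(counts)


def chi2_log_sf(x: float | np.ndarray, df: int) -> float | np.ndarray:
    """log10 of the chi-square upper-tail probability; stable far into the tail."""
    out = _sps.chi2.logsf(x, df) / _LN10
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# fastepi


def _fastepi_batch(tables: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(statistic, degenerate) for a (R, 2, 3, 3) stack of tables."""
    n = tables.astype(float)
    gen = np.arange(3.0)
    # T[r, d, u, v]: joint allele-pair table, u over SNP a, v over SNP b;
    # each individual contributes its four allele pairings (total 4n), which
    # calibrates the 1-df chi-square under the no-LD null.
    ca = np.stack([2 - gen, gen])  # c_0, c_1
    T = np.einsum("rdij,ui,vj->rduv", n, ca, ca)
    degen = (T == 0).any(axis=(1, 2, 3))
    Ts = np.where(T == 0, 1.0, T)  # placeholder; masked rows flagged degenerate
    ln_or = np.log(Ts[:, :, 1, 1]) + np.log(Ts[:, :, 0, 0]) - np.log(Ts[:, :, 1, 0]) - np.log(Ts[:, :, 0, 1])
    var = (1.0 / Ts).sum(axis=(2, 3))
    z = (ln_or[:, 1] - ln_or[:, 0]) / np.sqrt(var.sum(axis=1))
    stat = np.where(degen, 0.0, z * z)
    return stat, degen


def fastepi_score(t: PairTable) -> ScoreResult:
    """Allele-table LD-contrast chi-square (1 df).

    Per phenotype group the 2x2 joint allele-pair table is
    T[u][v] = sum_ij n_ij c_u(i) c_v(j) with c_1(x) = x, c_0(x) = 2 - x
    (every individual contributes its four allele pairings); the statistic is
    the squared standardized difference of log odds ratios between cases and
    controls with variance sum(1/T) over the eight cells.
    Any empty allele cell in either group is degenerate (score 0, p = 1).
    """
    stat, degen = _fastepi_batch(t.counts[None])
    return _result("fastepi", float(stat[0]), 1, bool(degen[0]))


# ---------------------------------------------------------------------------
# shesisepi


def _shesisepi_batch(tables: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = tables.astype(float)
    tot = n.sum(axis=(2, 3))  # (R, 2)
    gen = np.arange(3.0)
    safe_tot = np.where(tot == 0, 1.0, tot)
    ea = np.einsum("rdij,i->rd", n, gen) / safe_tot
    eb = np.einsum("rdij,j->rd", n, gen) / safe_tot
    eaa = np.einsum("rdij,i->rd", n, gen**2) / safe_tot
    ebb = np.einsum("rdij,j->rd", n, gen**2) / safe_tot
    eab = np.einsum("rdij,i,j->rd", n, gen, gen) / safe_tot
    va = eaa - ea**2
    vb = ebb - eb**2
    cov = eab - ea * eb
    degen = (va <= 0) | (vb <= 0) | (tot <= 3)
    r = cov / np.sqrt(np.where(degen, 1.0, va * vb))
    r = np.clip(r, -1.0, 1.0)
    degen = degen | (np.abs(r) >= 1.0)
    degen_any = degen.any(axis=1)
    z = np.arctanh(np.where(degen, 0.0, r))
    se2 = (1.0 / np.where(tot - 3 <= 0, 1.0, tot - 3)).sum(axis=1)
    stat = (z[:, 1] - z[:, 0]) ** 2 / se2
    stat = np.where(degen_any, 0.0, stat)
    return stat, degen_any


def shesisepi_score(t: PairTable) -> ScoreResult:
    """Genotype-correlation LD contrast via Fisher z (chi-square, 1 df).

    Pearson correlation of the 0/1/2 codes is computed from the 3x3 table in
    each group; the squared standardized difference of the Fisher
    z-transforms, with variances 1/(n-3), is the statistic.  A SNP that is
    monomorphic in either group is degenerate.
    """
    stat, degen = _shesisepi_batch(t.counts[None])
    return _result("shesisepi", float(stat[0]), 1, bool(degen[0]))


# ---------------------------------------------------------------------------
# gboost


def _ipf_main_effects(
    tables: np.ndarray, tol: float = 1e-9, max_sweeps: int = 5000
) -> np.ndarray:
    """IPF fit of the no-three-way log-linear model [DA][DB][AB].

    ``tables``: (R, 2, 3, 3) observed counts.  Returns fitted means of the
    same shape.  Zero observed margins produce zero fitted cells.
    """
    n = tables.astype(float)
    da = n.sum(axis=3, keepdims=True)  # (R, 2, 3, 1)
    db = n.sum(axis=2, keepdims=True)  # (R, 2, 1, 3)
    ab = n.sum(axis=1, keepdims=True)  # (R, 1, 3, 3)
    mu = np.ones_like(n)

    def _scale(target: np.ndarray, axis: int) -> None:
        cur = mu.sum(axis=axis, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(cur > 0, target / np.where(cur > 0, cur, 1.0), 0.0)
        np.multiply(mu, ratio, out=mu)

    for _ in range(max_sweeps):
        prev = mu.copy()
        _scale(da, 3)
        _scale(db, 2)
        _scale(ab, 1)
        if np.abs(mu - prev).max() < tol:
            break
    return mu


def _gboost_batch(tables: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = tables.astype(float)
    mu = _ipf_main_effects(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(n > 0, n * np.log(np.where(n > 0, n, 1.0) / np.where(mu > 0, mu, 1.0)), 0.0)
    stat = 2.0 * term.sum(axis=(1, 2, 3))
    stat = np.maximum(stat, 0.0)
    degen = np.zeros(stat.shape, dtype=bool)
    return stat, degen


def gboost_score(t: PairTable) -> ScoreResult:
    """BOOST-style likelihood-ratio test, saturated vs main effects (4 df).

    The main-effects logistic model is equivalent to the log-linear model
    with margins [DA][DB][AB]; its MLE is obtained by iterative proportional
    fitting (convergence: max fitted-count change < 1e-9, cap 5000 sweeps)
    and the statistic is the residual deviance 2 sum n log(n / mu).
    Empty cells are harmless (0 log 0 = 0; IPF preserves zero margins).
    """
    stat, degen = _gboost_batch(t.counts[None])
    return _result("gboost", float(stat[0]), 4, bool(degen[0]))


# ---------------------------------------------------------------------------
# indor

# Coefficient matrix of the four local log odds ratios on the 9 log-cells:
# theta_ij (i, j in {1, 2}) uses cells (i, j)+, (i-1, j-1)+, (i-1, j)-, (i, j-1)-.
_INDOR_C = np.zeros((4, 9))
for _k, (_i, _j) in enumerate([(1, 1), (1, 2), (2, 1), (2, 2)]):
    _INDOR_C[_k, 3 * _i + _j] += 1
    _INDOR_C[_k, 3 * (_i - 1) + (_j - 1)] += 1
    _INDOR_C[_k, 3 * (_i - 1) + _j] -= 1
    _INDOR_C[_k, 3 * _i + (_j - 1)] -= 1


def indor_score(t: PairTable, cond_max: float = 1e12) -> ScoreResult:
    """Local-odds-ratio contrast between cases and controls (Wald, 4 df).

    Phi stacks the case-minus-control differences of the four adjacent-cell
    log odds ratios of the 3x3 genotype table; V_Phi comes from the delta
    method (inverse cell counts, shared-cell covariances).  A zero cell
    entering any local OR, or an ill-conditioned V_Phi, takes the zero-score
    convention (statistic 0, p = 1, degenerate flag).
    """
    ctrl = t.counts[0].astype(float).ravel()
    case = t.counts[1].astype(float).ravel()
    if (ctrl == 0).any() or (case == 0).any():
        return _result("indor", 0.0, 4, True)
    phi = _INDOR_C @ (np.log(case) - np.log(ctrl))
    V = (_INDOR_C * (1.0 / case)) @ _INDOR_C.T + (_INDOR_C * (1.0 / ctrl)) @ _INDOR_C.T
    if np.linalg.cond(V) > cond_max:
        return _result("indor", 0.0, 4, True)
    stat = float(phi @ np.linalg.solve(V, phi))
    return _result("indor", max(stat, 0.0), 4, False)


# ---------------------------------------------------------------------------
# dss


def _roc_vertices(case_share: np.ndarray, ctrl_share: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative (FPR, TPR) vertices ranking cells by case:control ratio."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            ctrl_share > 0,
            case_share / np.where(ctrl_share > 0, ctrl_share, 1.0),
            np.where(case_share > 0, np.inf, -np.inf),
        )
    order = np.argsort(-ratio, kind="stable")
    tpr = np.cumsum(case_share[order])
    fpr = np.cumsum(ctrl_share[order])
    return fpr, tpr


def _roc_interp(fpr: np.ndarray, tpr: np.ndarray, x: np.ndarray) -> np.ndarray:
    xs = np.concatenate([[0.0], fpr, [1.0]])
    ys = np.concatenate([[0.0], tpr, [1.0]])
    keep = np.concatenate([[True], np.diff(xs) >= 0])
    return np.interp(x, xs[keep], ys[keep])


def dss_score(t: PairTable) -> ScoreResult:
    """ROC-gain statistic: does the SNP pair discriminate better than either
    single SNP?

    The 9 genotype cells, ranked by decreasing case:control density ratio,
    trace a piecewise-linear pair ROC; single-SNP ROCs use the 3 marginal
    cells.  At each pair-ROC vertex the pair TPR is compared with the better
    single-SNP ROC at the same FPR via a normal z for proportions (both on
    n1 cases); the statistic is the largest one-sided z^2 (negative gains
    truncate at 0), 1 df, with a Bonferroni factor for the 9 vertices.
    """
    n1 = t.n1
    n0 = t.n0
    if n1 == 0 or n0 == 0:
        return _result("dss", 0.0, 1, True)
    case = t.counts[1].astype(float)
    ctrl = t.counts[0].astype(float)
    s1, s0 = case / n1, ctrl / n0
    fpr_p, tpr_p = _roc_vertices(s1.ravel(), s0.ravel())
    fpr_a, tpr_a = _roc_vertices(s1.sum(axis=1), s0.sum(axis=1))
    fpr_b, tpr_b = _roc_vertices(s1.sum(axis=0), s0.sum(axis=0))
    single = np.maximum(
        _roc_interp(fpr_a, tpr_a, fpr_p), _roc_interp(fpr_b, tpr_b, fpr_p)
    )
    var = tpr_p * (1 - tpr_p) / n1 + single * (1 - single) / n1
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (tpr_p - single) / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    z = np.maximum(z, 0.0)
    stat = float((z**2).max())
    n_vertices = z.size
    log10_p = min(0.0, float(chi2_log_sf(stat, 1)) + np.log10(n_vertices))
    return ScoreResult("dss", stat, 1, log10_p, False)


# ---------------------------------------------------------------------------
# dispatch


def _result(method: str, stat: float, df: int, degenerate: bool) -> ScoreResult:
    if degenerate:
        return ScoreResult(method, 0.0, df, 0.0, True)
    return ScoreResult(method, stat, df, float(chi2_log_sf(stat, df)), False)


_SCORERS = {
    "fastepi": fastepi_score,
    "shesisepi": shesisepi_score,
    "gboost": gboost_score,
    "indor": indor_score,
    "dss": dss_score,
}


def score_pair_table(t: PairTable, method: str) -> ScoreResult:
    try:
        return _SCORERS[method](t)
    except KeyError:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}") from None


def score_tables_batch(tables: np.ndarray, method: str) -> np.ndarray:
    """log10 p-values for a (R, 2, 3, 3) stack of tables (degenerate -> 0).

    Vectorized for fastepi / shesisepi / gboost; per-table for indor / dss.
    """
    tables = np.asarray(tables)
    if method == "fastepi":
        stat, degen = _fastepi_batch(tables)
        out = np.where(degen, 0.0, chi2_log_sf(stat, 1))
    elif method == "shesisepi":
        stat, degen = _shesisepi_batch(tables)
        out = np.where(degen, 0.0, chi2_log_sf(stat, 1))
    elif method == "gboost":
        stat, degen = _gboost_batch(tables)
        out = np.where(degen, 0.0, chi2_log_sf(stat, 4))
    elif method in ("indor", "dss"):
        out = np.array(
            [score_pair_table(PairTable(tb), method).log10_p for tb in tables]
        )
    else:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    return out


def scan_all_pairs(
    cohort: CaseControlCohort,
    methods: Iterable[str] = METHODS,
    gboost_screen: float | None = None,
    force: bool = False,
    max_loci: int = 20_000,
) -> Iterator[tuple[tuple[int, int], ScoreResult]]:
    """Score every unordered locus pair with each requested method.

    ``gboost_screen`` suppresses GBOOST results at or below the screening
    threshold (genome-scale convention; 30 in large scans).  A guard refuses
    cohorts wider than ``max_loci`` loci unless ``force`` is set.
    """
    methods = list(methods)
    for mth in methods:
        if mth not in METHODS:
            raise ValueError(f"unknown method {mth!r}; choose from {METHODS}")
    p = cohort.genotypes.shape[1]
    if p > max_loci and not force:
        raise ValueError(
            f"{p} loci exceeds the desk-scale guard ({max_loci}); pass force=True"
        )
    for a in range(p):
        for b in range(a + 1, p):
            t = pair_table(cohort, a, b)
            for mth in methods:
                res = score_pair_table(t, mth)
                if (
                    mth == "gboost"
                    and gboost_screen is not None
                    and res.statistic <= gboost_screen
                ):
                    continue
                yield (a, b), res
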