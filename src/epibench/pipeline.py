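"""End-to-end orchestration: panel -> population -> cohort -> scan -> eval.

A run is fully described by a :class:`RunConfig` (loadable from TOML).  Every
stage draws its randomness from a seed derived deterministically from the
master seed with a fixed counter scheme (SeedSequence([master, stage_index])),
so a config reproduces every artifact bit-identically, and the manifest
records parameter echoes, per-stage seeds and SHA-256 hashes of all outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import sample_cohort
from .disease import (
    DiseaseScenario,
    select_causal_pair,
    solve_penetrance,
    two_locus_genotype_freqs,
)
from .evaluate import (
    BlockMap,
    EvalResult,
    bonferroni_threshold,
    block_level_rates,
    greedy_r2_blocks,
    roc_auc,
    snp_level_rates,
)
from .panel import generate_template_panel, qc_filter
from .plinkio import write_plink, write_qc_report
from .resample import resample_population
from .stats import METHODS, scan_all_pairs

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

_STAGES = ("panel", "resample", "cohort", "scan")


def stage_seed(master: int, stage: str, replicate: int = 0) -> int:
    """Deterministic per-stage (and per-replicate) seed below 2**31."""
    idx = _STAGES.index(stage)
    return int(
        np.random.SeedSequence([master, idx, replicate]).generate_state(1)[0]
        % (2**31 - 1)
    )


@dataclass
class RunConfig:
    seed: int
    scenario: DiseaseScenario
    out_dir: Path
    n_templates: int = 200
    chrom_sizes: tuple[int, ...] = (300, 300)
    block_len_range: tuple[int, int] = (5, 10)
    maf_range: tuple[float, float] = (0.05, 0.5)
    within_block_r2: float = 0.8
    m: int = 20_000
    l: int = 5
    n0: int = 1000
    n1: int = 1000
    methods: tuple[str, ...] = METHODS
    alpha: float = 0.05
    block_r2_min: float = 0.5
    write_genotypes: bool = False

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        scen = DiseaseScenario(**raw.pop("scenario"))
        raw["scenario"] = scen
        raw["out_dir"] = Path(raw["out_dir"])
        for key in ("chrom_sizes", "block_len_range", "maf_range", "methods"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full simulation and evaluation chain; returns the manifest.

    Artifacts written to ``config.out_dir``: QC report, scan TSV, evaluation
    TSV, manifest.json, and (optionally) PLINK triples for the population and
    cohort.
    """
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _echo_config(cfg), "stages": {}, "outputs": {}}

    def _stage(name):
        t0 = time.perf_counter()
        seed = stage_seed(cfg.seed, name) if name in _STAGES else None
        return t0, seed

    try:
        t0, seed = _stage("panel")
        panel = generate_template_panel(
            cfg.n_templates,
            cfg.chrom_sizes,
            cfg.block_len_range,
            cfg.maf_range,
            cfg.within_block_r2,
            seed=seed,
        )
        panel, report = qc_filter(panel)
        write_qc_report(report, out / "qc_report.tsv")
        manifest["stages"]["panel"] = {"seed": seed, "n_loci": panel.n_loci,
                                       "removed": len(report),
                                       "wall_s": round(time.perf_counter() - t0, 3)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'panel' failed: {exc}") from exc

    try:
        t0, seed = _stage("resample")
        pop = resample_population(panel, cfg.m, l=cfg.l, seed=seed)
        if cfg.write_genotypes:
            write_plink(pop, out / "population")
        manifest["stages"]["resample"] = {"seed": seed, "m": cfg.m,
                                          "fallbacks": pop.fallback_count,
                                          "wall_s": round(time.perf_counter() - t0, 3)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'resample' failed: {exc}") from exc

    try:
        t0, seed = _stage("cohort")
        a, b, fa, fb, r2 = select_causal_pair(pop, cfg.scenario)
        freqs = two_locus_genotype_freqs(cfg.scenario.maf_a, cfg.scenario.maf_b, cfg.scenario.r2)
        pen = solve_penetrance(cfg.scenario, freqs)
        cohort = sample_cohort(pop, (a, b), pen, cfg.n0, cfg.n1, seed=seed,
                               K=cfg.scenario.prevalence)
        if cfg.write_genotypes:
            write_plink(cohort, out / "cohort")
        manifest["stages"]["cohort"] = {
            "seed": seed, "causal_pair": [int(a), int(b)],
            "achieved": {"maf_a": fa, "maf_b": fb, "r2": r2},
            "wall_s": round(time.perf_counter() - t0, 3),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'cohort' failed: {exc}") from exc

    try:
        t0, _ = _stage("scan")
        rows = []
        for (x, y), res in scan_all_pairs(cohort, cfg.methods):
            rows.append({
                "snp_a": panel.loci[x].locus_id, "snp_b": panel.loci[y].locus_id,
                "ia": x, "ib": y, "method": res.method,
                "statistic": res.statistic, "df": res.df,
                "log10_p": res.log10_p, "degenerate": res.degenerate,
            })
        scan_df = pd.DataFrame(rows)
        scan_df.to_csv(out / "scan.tsv", sep="\t", index=False)
        manifest["stages"]["scan"] = {"n_rows": len(scan_df),
                                      "wall_s": round(time.perf_counter() - t0, 3)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'scan' failed: {exc}") from exc

    try:
        t0 = time.perf_counter()
        blocks = greedy_r2_blocks(pop.genotypes, pop.loci, r2_min=cfg.block_r2_min)
        p0 = bonferroni_threshold(panel.n_loci, cfg.alpha)
        eval_rows = []
        for mth in cfg.methods:
            sub = scan_df[scan_df["method"] == mth]
            pvals = {(int(r.ia), int(r.ib)): 10.0**r.log10_p for r in sub.itertuples()}
            scores = {(int(r.ia), int(r.ib)): r.statistic for r in sub.itertuples()}
            tp, _, fpr = snp_level_rates(pvals, (a, b), p0)
            try:
                tp_b, fpr_b = block_level_rates(pvals, blocks, (a, b), p0)
            except ValueError:
                tp_b, fpr_b = float("nan"), float("nan")
            eval_rows.append(EvalResult(cfg.scenario.label(), mth, tp, fpr, tp_b,
                                        fpr_b, roc_auc(scores, (a, b))))
        eval_df = pd.DataFrame([vars(r) for r in eval_rows])
        eval_df.to_csv(out / "eval.tsv", sep="\t", index=False)
        manifest["stages"]["eval"] = {"p0": p0, "n_blocks": blocks.n_blocks,
                                      "wall_s": round(time.perf_counter() - t0, 3)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'eval' failed: {exc}") from exc

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _echo_config(cfg: RunConfig) -> dict:
    d = dict(vars(cfg))
    d["scenario"] = vars(cfg.scenario)
    d["out_dir"] = str(cfg.out_dir)
    return d
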