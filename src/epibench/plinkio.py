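"""File formats: PLINK .bed/.bim/.fam triples, TSV reports, TOML scenarios.

The PLINK 1 binary format stores genotypes SNP-major, two bits per sample
(00 = two copies of allele A1, 10 = heterozygous, 11 = zero copies, 01 =
missing), four samples per byte, after a three-byte header 6c 1b 01.  A1 is
written as the panel-minor allele so the two-bit codes map directly onto the
0/1/2 minor-allele counts used throughout.  Write -> read round trips are
bit-exact.  Missing genotypes are rejected on read: the simulation pipeline
never produces them.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CaseControlCohort
from .disease import DiseaseScenario
from .panel import LocusInfo, TemplatePanel
from .resample import SimulatedPopulation

__all__ = [
    "write_plink",
    "read_plink",
    "write_text_matrix",
    "read_text_matrix",
    "write_qc_report",
    "write_scenario_toml",
    "read_scenario_toml",
    "write_scenario_grid",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


def _ext(prefix, suffix: str):
    return Path(str(prefix) + suffix)

# genotype code (minor-allele count) -> 2-bit PLINK code, A1 = minor
_GENO_TO_BITS = np.array([3, 2, 0], dtype=np.uint8)  # 0->11, 1->10, 2->00
_BITS_TO_GENO = np.full(4, -1, dtype=np.int8)
_BITS_TO_GENO[3], _BITS_TO_GENO[2], _BITS_TO_GENO[0] = 0, 1, 2  # 1 stays -1 (missing)


def _pack_bed(genotypes: np.ndarray) -> bytes:
    """SNP-major two-bit packing of an n x p genotype matrix."""
    n, p = genotypes.shape
    codes = _GENO_TO_BITS[genotypes.T]  # (p, n)
    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((p, pad), dtype=np.uint8)], axis=1
        )
    codes = codes.reshape(p, -1, 4)
    packed = (
        codes[:, :, 0]
        | (codes[:, :, 1] << 2)
        | (codes[:, :, 2] << 4)
        | (codes[:, :, 3] << 6)
    ).astype(np.uint8)
    return _BED_MAGIC + packed.tobytes()


def _unpack_bed(raw: bytes, n: int, p: int) -> np.ndarray:
    if raw[:3] != _BED_MAGIC:
        raise ValueError("not a SNP-major PLINK .bed file (bad magic bytes)")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * p
    if len(raw) != expected:
        raise ValueError(
            f".bed length {len(raw)} does not match expected {expected} bytes "
            f"for {n} samples x {p} SNPs"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(p, bytes_per_snp)
    twobit = np.stack(
        [(data >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2
    ).reshape(p, -1)[:, :n]
    geno = _BITS_TO_GENO[twobit]
    if (geno < 0).any():
        raise ValueError(".bed contains missing genotypes, which are unsupported")
    return np.ascontiguousarray(geno.T)


def write_plink(
    obj: TemplatePanel | SimulatedPopulation | CaseControlCohort, prefix: str | Path
) -> None:
    """Write genotypes + locus metadata as a .bed/.bim/.fam triple.

    Cohorts carry their phenotype in the .fam sixth column with PLINK 1/2
    control/case coding; panels and populations write -9 (unknown).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    g = np.asarray(obj.genotypes)
    loci = obj.loci
    with open(_ext(prefix, ".bed"), "wb") as fh:
        fh.write(_pack_bed(g))
    with open(_ext(prefix, ".bim"), "w") as fh:
        for loc in loci:
            fh.write(
                f"{loc.chromosome}\t{loc.locus_id}\t0\t{loc.position}"
                f"\t{loc.minor_allele}\t{loc.major_allele}\n"
            )
    pheno = None
    if isinstance(obj, CaseControlCohort):
        pheno = obj.phenotype + 1  # 1 = control, 2 = case
    with open(_ext(prefix, ".fam"), "w") as fh:
        for i in range(g.shape[0]):
            ph = -9 if pheno is None else int(pheno[i])
            fh.write(f"F{i} I{i} 0 0 0 {ph}\n")


def read_plink(prefix: str | Path) -> tuple[np.ndarray, list[LocusInfo], np.ndarray | None]:
    """Read a .bed/.bim/.fam triple -> (genotypes, loci, phenotype or None).

    The phenotype vector (0 = control, 1 = case) is returned only when the
    .fam sixth column uses 1/2 coding.
    """
    prefix = Path(prefix)
    loci: list[LocusInfo] = []
    with open(_ext(prefix, ".bim")) as fh:
        for line in fh:
            chrom, snp_id, _cm, pos, a1, a2 = line.split()
            loci.append(LocusInfo(snp_id, int(chrom), int(pos), a1, a2))
    fam_pheno: list[int] = []
    with open(_ext(prefix, ".fam")) as fh:
        for line in fh:
            fam_pheno.append(int(float(line.split()[5])))
    n, p = len(fam_pheno), len(loci)
    genotypes = _unpack_bed(_ext(prefix, ".bed").read_bytes(), n, p)
    pheno = np.array(fam_pheno)
    if set(np.unique(pheno)) <= {1, 2}:
        return genotypes, loci, (pheno - 1).astype(np.int8)
    return genotypes, loci, None


def write_text_matrix(genotypes: np.ndarray, path: str | Path) -> None:
    """Whitespace-delimited 0/1/2 genotype matrix (one row per individual)."""
    np.savetxt(path, np.asarray(genotypes), fmt="%d")


def read_text_matrix(path: str | Path) -> np.ndarray:
    g = np.loadtxt(path, dtype=np.int8, ndmin=2)
    if not np.isin(g, (0, 1, 2)).all():
        raise ValueError("text matrix entries must be 0/1/2")
    return g


def write_qc_report(report: list[dict], path: str | Path) -> None:
    """TSV of removed loci: locus_id, maf, hwe_p, reason."""
    pd.DataFrame(report, columns=["locus_id", "maf", "hwe_p", "reason"]).to_csv(
        path, sep="\t", index=False
    )


_SCENARIO_KEYS = {
    "model": "model",
    "rho": "rho",
    "K": "prevalence",
    "maf_a": "maf_a",
    "maf_b": "maf_b",
    "r2": "r2",
    "rr_a": "rr_a",
    "rr_b": "rr_b",
}


def write_scenario_toml(s: DiseaseScenario, path: str | Path) -> None:
    d = asdict(s)
    lines = []
    for key, attr in _SCENARIO_KEYS.items():
        v = d[attr]
        if v is None:
            continue
        lines.append(f'{key} = "{v}"' if isinstance(v, str) else f"{key} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_scenario_toml(path: str | Path) -> DiseaseScenario:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    kwargs = {}
    for key, attr in _SCENARIO_KEYS.items():
        if key in raw:
            kwargs[attr] = raw[key]
    return DiseaseScenario(**kwargs)


def write_scenario_grid(scenarios: list[DiseaseScenario], path: str | Path) -> None:
    """One TSV row per scenario of the canonical grid."""
    rows = [
        {
            "scenario": s.label(),
            "model": s.model,
            "K": s.prevalence,
            "maf_a": s.maf_a,
            "maf_b": s.maf_b,
            "r2": s.r2,
            "rr_a": s.rr_a,
            "rr_b": s.rr_b,
            "rho": "" if s.rho is None else s.rho,
        }
        for s in scenarios
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
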