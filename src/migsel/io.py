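"""Plain-text readers/writers for cohort data.

Genotypes: minimal VCF 4.2 with a per-sample DS (dosage) FORMAT field, or
a TSV matrix (rows = participants, columns = SNP ids).  Phenotypes: CSV
with ``participant_id``, ``migraine_status`` (none/prior/active), the ten
0/1 symptom columns (blank for participants never asked), ``age`` and
``pc1..pcM``.  Ground truth is a YAML sidecar.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import SYMPTOMS, Cohort, GenotypeMatrix
from .trinomial import ValidationError

__all__ = [
    "write_vcf", "read_vcf", "write_genotypes_tsv", "read_genotypes_tsv",
    "write_phenotypes_csv", "read_phenotypes_csv", "write_truth", "read_truth",
    "write_cohort",
]

_VCF_HEADER = """##fileformat=VCFv4.2
##source=migsel
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">
"""


def _sample_ids(n):
    return [f"P{i + 1:06d}" for i in range(n)]


def write_vcf(path, genotypes: GenotypeMatrix, sample_ids=None) -> None:
    """Write dosages as a minimal single-chromosome VCF 4.2 (FORMAT DS)."""
    n, m = genotypes.dosages.shape
    ids = sample_ids or _sample_ids(n)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids) + "\n")
        for j in range(m):
            ds = genotypes.dosages[:, j]
            row = [
                "1", str(j + 1), genotypes.snp_ids[j], "A", "G", ".", "PASS",
                f"AF={genotypes.maf_declared[j]:g}", "DS",
            ] + [f"{d:g}" for d in ds]
            fh.write("\t".join(row) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a DS-format VCF written by :func:`write_vcf` (or compatible)."""
    snp_ids, mafs, rows = [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 10:
                raise ValidationError(f"malformed VCF record: {line[:60]!r}")
            fmt = parts[8].split(":")
            try:
                ds_i = fmt.index("DS")
            except ValueError:
                raise ValidationError("VCF record lacks a DS FORMAT field")
            snp_ids.append(parts[2])
            af = np.nan
            for kv in parts[7].split(";"):
                if kv.startswith("AF="):
                    af = float(kv[3:])
            mafs.append(af)
            rows.append([float(s.split(":")[ds_i]) for s in parts[9:]])
    if not rows:
        raise ValidationError("no variant records in VCF")
    return GenotypeMatrix(dosages=np.array(rows, float).T, snp_ids=snp_ids,
                          maf_declared=np.array(mafs))


def write_genotypes_tsv(path, genotypes: GenotypeMatrix, sample_ids=None) -> None:
    n = genotypes.dosages.shape[0]
    df = pd.DataFrame(genotypes.dosages, columns=genotypes.snp_ids,
                      index=sample_ids or _sample_ids(n))
    df.index.name = "participant_id"
    df.to_csv(path, sep="\t", float_format="%g")


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix(dosages=df.to_numpy(float), snp_ids=list(df.columns),
                          maf_declared=np.full(df.shape[1], np.nan))


def write_phenotypes_csv(path, cohort: Cohort, sample_ids=None) -> None:
    n = cohort.n
    df = pd.DataFrame({"participant_id": sample_ids or _sample_ids(n),
                       "migraine_status": cohort.migraine_status})
    for i, s in enumerate(SYMPTOMS):
        col = cohort.symptoms[:, i]
        df[s] = pd.array([int(v) if np.isfinite(v) else None for v in col],
                         dtype="Int64")
    df["age"] = np.round(cohort.age, 3)
    for j in range(cohort.pcs.shape[1]):
        df[f"pc{j + 1}"] = np.round(cohort.pcs[:, j], 6)
    df.to_csv(path, index=False)


def read_phenotypes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [s for s in SYMPTOMS if s not in df.columns]
    if missing or "migraine_status" not in df.columns:
        raise ValidationError(f"phenotype CSV lacks columns: {missing}")
    return df


def write_truth(path, truth: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)


def read_truth(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_cohort(outdir, cohort: Cohort, basename: str = "cohort") -> dict[str, Path]:
    """Write VCF + TSV genotypes, phenotype CSV and truth YAML into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / f"{basename}.vcf",
        "tsv": outdir / f"{basename}_genotypes.tsv",
        "pheno": outdir / f"{basename}_phenotypes.csv",
        "truth": outdir / f"{basename}_truth.yaml",
    }
    write_vcf(paths["vcf"], cohort.genotypes)
    write_genotypes_tsv(paths["tsv"], cohort.genotypes)
    write_phenotypes_csv(paths["pheno"], cohort)
    write_truth(paths["truth"], cohort.truth)
    return paths
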