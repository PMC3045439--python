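"""Pedigree file formats.

The primary format is a documented tab-separated table with one row per
subject::

    family_id  subject_id  father_id  mother_id  sex  generation  role
    mating_type  snp1  [snp2]  phenotype

Genotypes are written as slash-separated allele pairs (``A/a``); parental
origin is never encoded in files - it is what the estimators infer.
Missing phenotypes are ``NA``.  A PLINK-style PED/MAP export is provided
for interoperability (phenotype ``-9`` when missing).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import PedigreeError, ThreeGenDataset

__all__ = ["read_pedigree", "write_pedigree", "export_ped"]

_BASE_COLUMNS = [
    "family_id", "subject_id", "father_id", "mother_id", "sex",
    "generation", "role", "mating_type",
]


def _geno_to_file(g: str) -> str:
    return f"{g[0]}/{g[1]}"


def _geno_from_file(g: str, snp: str) -> str:
    alleles = sorted(str(g).replace("|", "/").split("/"))
    if len(alleles) != 2:
        raise PedigreeError(f"malformed genotype {g!r} in column {snp}")
    return "".join(alleles)


def write_pedigree(data: ThreeGenDataset, path) -> None:
    """Write the observed part of a dataset (truth columns are dropped)."""
    cols = _BASE_COLUMNS + [f"snp{k + 1}" for k in range(data.n_snps)] + ["phenotype"]
    out = data.subjects[cols].copy()
    for k in range(data.n_snps):
        out[f"snp{k + 1}"] = out[f"snp{k + 1}"].map(_geno_to_file)
    out["phenotype"] = out["phenotype"].map(
        lambda v: "NA" if pd.isna(v) else format(float(v), ".10g")
    )
    out.to_csv(path, sep="\t", index=False)


def read_pedigree(path, n_snps: int = 1) -> ThreeGenDataset:
    """Read and validate a pedigree TSV.

    Raises :class:`~imprintgen.pedigree.PedigreeError` on missing columns or
    malformed genotypes and :class:`~imprintgen.pedigree.MendelianError` when
    a child genotype is impossible given its parents.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = _BASE_COLUMNS + [f"snp{k + 1}" for k in range(n_snps)] + ["phenotype"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise PedigreeError(f"{path}: missing columns {missing}")
    for k in range(n_snps):
        col = f"snp{k + 1}"
        df[col] = [_geno_from_file(g, col) for g in df[col]]
    df["generation"] = df["generation"].astype(int)
    df["mating_type"] = df["mating_type"].astype(int)
    df["phenotype"] = [np.nan if v in ("NA", "", "nan") else float(v) for v in df["phenotype"]]
    data = ThreeGenDataset(df[expected], n_snps=n_snps, meta={"source": str(path)})
    data.validate()
    return data


_SEX_CODE = {"M": "1", "F": "2"}


def export_ped(data: ThreeGenDataset, prefix) -> tuple:
    """PLINK-style PED + MAP export; returns the two paths written."""
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    lines = []
    for row in data.subjects.itertuples():
        pheno = "-9" if pd.isna(row.phenotype) else format(float(row.phenotype), ".10g")
        fields = [
            str(row.family_id), str(row.subject_id),
            str(row.father_id), str(row.mother_id),
            _SEX_CODE.get(row.sex, "0"), pheno,
        ]
        for k in range(data.n_snps):
            g = getattr(row, f"snp{k + 1}")
            fields.extend([g[0], g[1]])
        lines.append("\t".join(fields))
    ped_path.write_text("\n".join(lines) + "\n")
    map_lines = [f"1\tsnp{k + 1}\t0\t{(k + 1) * 1000}" for k in range(data.n_snps)]
    map_path.write_text("\n".join(map_lines) + "\n")
    return ped_path, map_path
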