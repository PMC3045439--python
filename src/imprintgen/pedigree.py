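"""Three-generation pedigree container and consistency checks.

The sampled design is: first-generation families (grandfather x grandmother),
one or more sons per family who become second-generation fathers, each
married to a mother drawn from the population, each couple with one or more
children.  Genotypes are observed for everyone; phenotypes only for the
second-generation fathers and the third-generation children, because only
their alleles' parental origins can be traced (grandparents and mothers are
founders with unknown allele origin).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROLES = ("grandfather", "grandmother", "father", "mother", "child")

#: Roles whose phenotype the design records.
PHENOTYPED_ROLES = ("father", "child")

#: Roles that are population founders (used for allele-frequency estimation).
FOUNDER_ROLES = ("grandfather", "grandmother", "mother")

GENO_COLUMNS = ("snp1", "snp2")

#: Observed columns compared for round-trip equality; truth columns excluded.
OBSERVED_COLUMNS = (
    "family_id",
    "subject_id",
    "father_id",
    "mother_id",
    "sex",
    "generation",
    "role",
    "mating_type",
    "snp1",
    "snp2",
    "phenotype",
)


class PedigreeError(ValueError):
    """Structural problem in a pedigree file or dataset."""


class MendelianError(PedigreeError):
    """A child genotype that cannot be produced by its recorded parents."""


def genotype_compatible(child: str, mother: str, father: str) -> bool:
    """True if some maternal x paternal allele draw yields the child genotype."""
    for am in mother:
        for ap in father:
            if "".join(sorted((am, ap))) == child:
                return True
    return False


@dataclass
class ThreeGenDataset:
    """A three-generation sample as a subject table.

    ``subjects`` has one row per person with columns ``family_id``,
    ``subject_id``, ``father_id``/``mother_id`` ("0" for founders), ``sex``,
    ``generation`` (1-3), ``role``, ``mating_type`` (grandparental cross of
    the first-generation family), genotype columns ``snp1`` (and ``snp2`` for
    two-SNP data) holding unordered genotypes, and ``phenotype`` (NaN where
    the design does not phenotype).  Simulated datasets additionally carry
    hidden truth columns (``config_true``, ``diplotype_true``) that no
    estimator reads.
    """

    subjects: pd.DataFrame
    n_snps: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in OBSERVED_COLUMNS[: 8 + self.n_snps] if c not in self.subjects.columns and c != "snp2"]
        if self.n_snps >= 2 and "snp2" not in self.subjects.columns:
            missing.append("snp2")
        if missing:
            raise PedigreeError(f"missing pedigree columns: {missing}")

    # -- convenience views -------------------------------------------------
    def rows(self, role: str) -> pd.DataFrame:
        return self.subjects[self.subjects["role"] == role]

    def fathers(self) -> pd.DataFrame:
        return self.rows("father")

    def children(self) -> pd.DataFrame:
        return self.rows("child")

    def founders(self) -> pd.DataFrame:
        return self.subjects[self.subjects["role"].isin(FOUNDER_ROLES)]

    def genotype_of(self) -> pd.Series:
        """subject_id -> snp1 genotype lookup."""
        return self.subjects.set_index("subject_id")["snp1"]

    def with_parent_genotypes(self, role: str, snp: str = "snp1") -> pd.DataFrame:
        """Rows of ``role`` with ``mother_geno``/``father_geno`` columns joined on ids."""
        geno = self.subjects.set_index("subject_id")[snp]
        out = self.rows(role).copy()
        out["mother_geno"] = out["mother_id"].map(geno)
        out["father_geno"] = out["father_id"].map(geno)
        return out

    # -- validation --------------------------------------------------------
    def validate(self, require_phenotype_pattern: bool = True) -> None:
        """Check parent links, genotype alphabet and Mendelian consistency.

        Raises :class:`PedigreeError`/:class:`MendelianError` listing the
        offending subjects.
        """
        df = self.subjects
        ids = set(df["subject_id"])
        alphabets = {"snp1": ("AA", "Aa", "aa"), "snp2": ("BB", "Bb", "bb")}

        for snp in GENO_COLUMNS[: self.n_snps]:
            bad = df[~df[snp].isin(alphabets[snp])]
            if len(bad):
                raise PedigreeError(
                    f"unknown {snp} genotypes for subjects "
                    f"{bad['subject_id'].tolist()[:5]}"
                )

        dangling = df[
            ((df["father_id"] != "0") & ~df["father_id"].isin(ids))
            | ((df["mother_id"] != "0") & ~df["mother_id"].isin(ids))
        ]
        if len(dangling):
            raise PedigreeError(
                f"dangling parent ids for subjects {dangling['subject_id'].tolist()[:5]}"
            )

        nonfounders = df[(df["father_id"] != "0") & (df["mother_id"] != "0")]
        violations = []
        for snp in GENO_COLUMNS[: self.n_snps]:
            geno = df.set_index("subject_id")[snp]
            for _, row in nonfounders.iterrows():
                if not genotype_compatible(
                    row[snp], geno[row["mother_id"]], geno[row["father_id"]]
                ):
                    violations.append((row["subject_id"], snp))
        if violations:
            raise MendelianError(f"Mendelian violations: {violations[:10]}")

        if require_phenotype_pattern:
            pheno = df["phenotype"].notna()
            stray = df[pheno & ~df["role"].isin(PHENOTYPED_ROLES)]
            if len(stray):
                # tolerated on input (value ignored by estimators) but flagged
                import warnings

                warnings.warn(
                    "phenotypes present on unphenotyped roles for subjects "
                    f"{stray['subject_id'].tolist()[:5]}; estimators ignore them",
                    stacklevel=2,
                )

    def equals_observed(self, other: "ThreeGenDataset") -> bool:
        """Equality on observed fields only (serialization round-trip check)."""
        cols = [c for c in OBSERVED_COLUMNS if c in self.subjects.columns and c in other.subjects.columns]
        a = self.subjects[cols].reset_index(drop=True)
        b = other.subjects[cols].reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in cols:
            if c == "phenotype":
                if not np.allclose(
                    a[c].astype(float), b[c].astype(float), equal_nan=True, atol=1e-9
                ):
                    return False
            elif not (a[c].astype(str) == b[c].astype(str)).all():
                return False
        return True
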