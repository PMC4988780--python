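"""Core domain containers for a single study cohort.

A cohort bundles four subject-aligned tables: an additive genotype dosage
matrix, a panel of raw biomarker measurements with per-analyte lower limits
of quantification (LLOQ), clinical covariates, and disease phenotypes.
All matrices are ``numpy`` arrays with ``NaN`` encoding missing values;
subject identifiers are kept alongside and every container validates that
its shapes and identifiers agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantInfo",
    "GenotypeMatrix",
    "AnalyteMeta",
    "BiomarkerPanel",
    "CovariateTable",
    "PhenotypeTable",
    "CohortBundle",
    "CELL_COUNT_COLUMNS",
]

#: optional complete-blood-count covariates, in canonical order
CELL_COUNT_COLUMNS = (
    "neutrophil",
    "lymphocyte",
    "monocyte",
    "eosinophil",
    "basophil",
    "red_blood_cells",
    "platelet",
)

CONTINUOUS_PHENOTYPES = ("emphysema_pct", "fev1pp")
BINARY_PHENOTYPES = ("chronic_bronchitis", "exacerbation_any")


@dataclass(frozen=True)
class VariantInfo:
    """Identity of one genotyped variant (1-based coordinates, VCF style)."""

    variant_id: str
    chromosome: str
    position: int
    allele_ref: str
    allele_alt: str  # the counted (dosage) allele

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1")
        if not self.allele_ref or not self.allele_alt:
            raise ValueError(f"{self.variant_id}: empty allele string")


@dataclass
class GenotypeMatrix:
    """Subjects x variants additive alt-allele dosages in {0, 1, 2, NaN}."""

    subjects: list[str]
    variants: list[VariantInfo]
    dosage: np.ndarray  # float64, NaN = missing

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.subjects), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.variants)} variants"
            )
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant identifiers")
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))]
            raise ValueError(f"dosage values outside {{0,1,2,NA}}: {bad[:5]}")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def variant_index(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"unknown variant {variant_id!r}") from None

    def dosage_of(self, variant_id: str) -> np.ndarray:
        return self.dosage[:, self.variant_index(variant_id)]

    def subset_variants(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            subjects=list(self.subjects),
            variants=[self.variants[i] for i in keep],
            dosage=self.dosage[:, keep].copy(),
        )

    def subset_subjects(self, order: Sequence[int]) -> "GenotypeMatrix":
        order = list(order)
        return GenotypeMatrix(
            subjects=[self.subjects[i] for i in order],
            variants=list(self.variants),
            dosage=self.dosage[order, :].copy(),
        )


@dataclass
class AnalyteMeta:
    """One biomarker analyte: encoding-gene locus and assay LLOQ.

    ``analysis_mode`` starts ``"unset"`` and is assigned by triage
    (drop / linear / tobit) during preprocessing.
    """

    analyte_id: str
    gene_symbol: str = ""
    gene_chromosome: str = ""
    gene_start: int = 0
    gene_end: int = 0
    lloq: float = float("nan")
    analysis_mode: str = "unset"

    def __post_init__(self) -> None:
        if np.isfinite(self.lloq) and self.lloq <= 0:
            raise ValueError(f"{self.analyte_id}: lloq must be > 0")
        if self.gene_start > self.gene_end:
            raise ValueError(f"{self.analyte_id}: gene_start > gene_end")

    @property
    def has_locus(self) -> bool:
        return bool(self.gene_chromosome) and self.gene_end >= self.gene_start >= 1


@dataclass
class BiomarkerPanel:
    """Subjects x analytes raw measurements plus the below-LLOQ mask."""

    subjects: list[str]
    analytes: list[AnalyteMeta]
    raw: np.ndarray  # assay units, NaN = missing
    below_lloq: np.ndarray  # bool, aligned with raw

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.below_lloq = np.asarray(self.below_lloq, dtype=bool)
        shape = (len(self.subjects), len(self.analytes))
        if self.raw.shape != shape or self.below_lloq.shape != shape:
            raise ValueError("biomarker matrix shapes do not match subjects x analytes")
        if np.any(self.below_lloq & ~np.isfinite(self.raw)):
            raise ValueError("below_lloq set for a missing measurement")

    @property
    def analyte_ids(self) -> list[str]:
        return [a.analyte_id for a in self.analytes]

    def analyte_index(self, analyte_id: str) -> int:
        try:
            return self.analyte_ids.index(analyte_id)
        except ValueError:
            raise KeyError(f"unknown analyte {analyte_id!r}") from None

    def subset_subjects(self, order: Sequence[int]) -> "BiomarkerPanel":
        order = list(order)
        return BiomarkerPanel(
            subjects=[self.subjects[i] for i in order],
            analytes=list(self.analytes),
            raw=self.raw[order, :].copy(),
            below_lloq=self.below_lloq[order, :].copy(),
        )

    @staticmethod
    def mask_from_lloq(raw: np.ndarray, lloqs: Sequence[float]) -> np.ndarray:
        """Below-LLOQ indicator: recorded value strictly below the analyte LLOQ."""
        lloqs = np.asarray(lloqs, dtype=float)
        with np.errstate(invalid="ignore"):
            return np.isfinite(raw) & (raw < lloqs[None, :])


REQUIRED_COVARIATES = ("site", "sex", "age", "bmi", "pack_years", "current_smoker")


@dataclass
class CovariateTable:
    """Clinical covariates, complete-case (no missing values).

    ``data`` columns: site (categorical), sex and current_smoker (0/1),
    age (years), bmi (kg/m2), pack_years, plus optional cell counts.
    """

    subjects: list[str]
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.data) != len(self.subjects):
            raise ValueError("covariate rows do not match subjects")
        missing = [c for c in REQUIRED_COVARIATES if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing covariate columns: {missing}")
        if self.data[list(REQUIRED_COVARIATES)].isna().any().any():
            raise ValueError("covariates must be complete-case")
        if self.data["site"].nunique() < 1:
            raise ValueError("site must have at least one level")
        for col in ("sex", "current_smoker"):
            vals = set(self.data[col].unique())
            if not vals <= {0, 1}:
                raise ValueError(f"{col} must be binary 0/1, saw {vals}")

    @property
    def has_cell_counts(self) -> bool:
        return all(c in self.data.columns for c in CELL_COUNT_COLUMNS)

    def subset_subjects(self, order: Sequence[int]) -> "CovariateTable":
        order = list(order)
        return CovariateTable(
            subjects=[self.subjects[i] for i in order],
            data=self.data.iloc[order].reset_index(drop=True),
        )


@dataclass
class PhenotypeTable:
    """Disease phenotypes: continuous (emphysema %, FEV1 %-predicted) and
    binary (chronic bronchitis, any exacerbation)."""

    subjects: list[str]
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.data) != len(self.subjects):
            raise ValueError("phenotype rows do not match subjects")
        for col in BINARY_PHENOTYPES:
            if col in self.data.columns:
                vals = self.data[col].dropna().unique()
                if not set(vals) <= {0, 1}:
                    raise ValueError(f"{col} must be coded 0/1")
        for col in CONTINUOUS_PHENOTYPES:
            if col in self.data.columns:
                vals = self.data[col].dropna().to_numpy(dtype=float)
                if vals.size and not np.isfinite(vals).all():
                    raise ValueError(f"{col} contains non-finite values")

    def subset_subjects(self, order: Sequence[int]) -> "PhenotypeTable":
        order = list(order)
        return PhenotypeTable(
            subjects=[self.subjects[i] for i in order],
            data=self.data.iloc[order].reset_index(drop=True),
        )


@dataclass
class CohortBundle:
    """All four subject-aligned tables for one cohort."""

    name: str
    genotypes: GenotypeMatrix
    biomarkers: BiomarkerPanel
    covariates: CovariateTable
    phenotypes: PhenotypeTable

    def __post_init__(self) -> None:
        subj = self.genotypes.subjects
        for part in (self.biomarkers, self.covariates, self.phenotypes):
            if part.subjects != subj:
                raise ValueError(
                    f"{self.name}: component subject lists differ or are reordered"
                )

    @property
    def n(self) -> int:
        return len(self.genotypes.subjects)

    @property
    def subjects(self) -> list[str]:
        return list(self.genotypes.subjects)
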