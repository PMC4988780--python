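"""Readers and writers for the native tab-separated cohort formats.

The native genotype format is a TSV with one row per variant
(``variant_id  chromosome  position  allele_ref  allele_alt`` followed by
one dosage column per subject, values in {0,1,2,NA}); biomarker, LLOQ
sidecar, covariate and phenotype tables are plain TSVs keyed by subject or
analyte identifier. VCF (GT only, via cyvcf2) and PLINK ``.ped``/``.map``
text are import adapters. All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    AnalyteMeta,
    BiomarkerPanel,
    CohortBundle,
    CovariateTable,
    GenotypeMatrix,
    PhenotypeTable,
    VariantInfo,
    REQUIRED_COVARIATES,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_genotype_table",
    "write_genotype_table",
    "read_biomarker_table",
    "write_biomarker_table",
    "read_lloq_table",
    "write_lloq_table",
    "read_covariate_table",
    "write_covariate_table",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_cohort",
    "read_vcf_genotypes",
    "read_plink_text",
    "write_association_table",
    "read_association_table",
    "ASSOCIATION_COLUMNS",
]


class FormatError(ValueError):
    """An input file could not be parsed; the message names file and line."""


GENOTYPE_META_COLUMNS = ["variant_id", "chromosome", "position", "allele_ref", "allele_alt"]


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path, sep="\t", dtype=kwargs.pop("dtype", None), **kwargs)
    except FileNotFoundError:
        raise
    except Exception as exc:  # surface the offending file
        raise FormatError(f"{path}: cannot parse as TSV ({exc})") from exc


# ---------------------------------------------------------------------------
# native genotype table


def write_genotype_table(g: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(GENOTYPE_META_COLUMNS + list(g.subjects)) + "\n")
        for j, v in enumerate(g.variants):
            row = g.dosage[:, j]
            cells = ["NA" if not np.isfinite(x) else str(int(x)) for x in row]
            fh.write(
                f"{v.variant_id}\t{v.chromosome}\t{v.position}\t"
                f"{v.allele_ref}\t{v.allele_alt}\t" + "\t".join(cells) + "\n"
            )


def read_genotype_table(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(GENOTYPE_META_COLUMNS)] != GENOTYPE_META_COLUMNS:
            raise FormatError(f"{path}:1: expected header starting with {GENOTYPE_META_COLUMNS}")
        subjects = header[len(GENOTYPE_META_COLUMNS):]
        variants: list[VariantInfo] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise FormatError(f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}")
            try:
                variants.append(
                    VariantInfo(parts[0], parts[1], int(parts[2]), parts[3], parts[4])
                )
            except (ValueError, TypeError) as exc:
                raise FormatError(f"{path}:{lineno}: bad variant metadata ({exc})") from exc
            vals = np.empty(len(subjects))
            for i, cell in enumerate(parts[5:]):
                if cell == "NA" or cell == "":
                    vals[i] = np.nan
                elif cell in ("0", "1", "2"):
                    vals[i] = float(cell)
                else:
                    raise FormatError(
                        f"{path}:{lineno}: dosage {cell!r} not in {{0,1,2,NA}}"
                    )
            rows.append(vals)
    dosage = np.vstack(rows).T if rows else np.empty((len(subjects), 0))
    return GenotypeMatrix(subjects=subjects, variants=variants, dosage=dosage)


# ---------------------------------------------------------------------------
# biomarker panel and LLOQ sidecar


def write_biomarker_table(panel: BiomarkerPanel, path: str | Path) -> None:
    df = pd.DataFrame(panel.raw, columns=panel.analyte_ids)
    df.insert(0, "subject_id", panel.subjects)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="NA")


def write_lloq_table(analytes: Iterable[AnalyteMeta], path: str | Path) -> None:
    rows = [
        (a.analyte_id, a.gene_symbol, a.gene_chromosome, a.gene_start, a.gene_end, a.lloq)
        for a in analytes
    ]
    pd.DataFrame(
        rows, columns=["analyte_id", "gene_symbol", "gene_chr", "gene_start", "gene_end", "lloq"]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_lloq_table(path: str | Path) -> list[AnalyteMeta]:
    df = _read_tsv(path)
    needed = {"analyte_id", "lloq"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}:1: LLOQ sidecar needs columns {sorted(needed)}")
    metas = []
    for _, r in df.iterrows():
        metas.append(
            AnalyteMeta(
                analyte_id=str(r["analyte_id"]),
                gene_symbol=str(r.get("gene_symbol", "") or ""),
                gene_chromosome=str(r.get("gene_chr", "") or ""),
                gene_start=int(r.get("gene_start", 0) or 0),
                gene_end=int(r.get("gene_end", 0) or 0),
                lloq=float(r["lloq"]),
            )
        )
    return metas


def read_biomarker_table(path: str | Path, analytes: Sequence[AnalyteMeta]) -> BiomarkerPanel:
    df = _read_tsv(path, na_values=["NA"])
    if "subject_id" not in df.columns:
        raise FormatError(f"{path}:1: biomarker table needs a subject_id column")
    by_id = {a.analyte_id: a for a in analytes}
    analyte_cols = [c for c in df.columns if c != "subject_id"]
    unknown = [c for c in analyte_cols if c not in by_id]
    if unknown:
        raise FormatError(f"{path}: analytes missing from LLOQ sidecar: {unknown}")
    metas = [by_id[c] for c in analyte_cols]
    raw = df[analyte_cols].to_numpy(dtype=float)
    mask = BiomarkerPanel.mask_from_lloq(raw, [a.lloq for a in metas])
    return BiomarkerPanel(
        subjects=[str(s) for s in df["subject_id"]],
        analytes=metas,
        raw=raw,
        below_lloq=mask,
    )


# ---------------------------------------------------------------------------
# covariates and phenotypes


def write_covariate_table(cov: CovariateTable, path: str | Path) -> None:
    df = cov.data.copy()
    df.insert(0, "subject_id", cov.subjects)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="NA")


def read_covariate_table(path: str | Path, drop_incomplete: bool = True) -> CovariateTable:
    df = _read_tsv(path, na_values=["NA"])
    if "subject_id" not in df.columns:
        raise FormatError(f"{path}:1: covariate table needs a subject_id column")
    missing = [c for c in REQUIRED_COVARIATES if c not in df.columns]
    if missing:
        raise FormatError(f"{path}:1: missing covariate columns {missing}")
    n_before = len(df)
    if drop_incomplete:
        df = df.dropna(subset=list(REQUIRED_COVARIATES)).reset_index(drop=True)
        if len(df) < n_before:
            logger.info(
                "%s: dropped %d subjects with missing covariate values",
                path, n_before - len(df),
            )
    subjects = [str(s) for s in df["subject_id"]]
    data = df.drop(columns=["subject_id"])
    data["site"] = data["site"].astype(str)
    for col in ("sex", "current_smoker"):
        data[col] = data[col].astype(int)
    return CovariateTable(subjects=subjects, data=data)


def write_phenotype_table(ph: PhenotypeTable, path: str | Path) -> None:
    df = ph.data.copy()
    df.insert(0, "subject_id", ph.subjects)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="NA")


def read_phenotype_table(path: str | Path) -> PhenotypeTable:
    df = _read_tsv(path, na_values=["NA"])
    if "subject_id" not in df.columns:
        raise FormatError(f"{path}:1: phenotype table needs a subject_id column")
    subjects = [str(s) for s in df["subject_id"]]
    return PhenotypeTable(subjects=subjects, data=df.drop(columns=["subject_id"]))


# ---------------------------------------------------------------------------
# cohort assembly


def read_cohort(
    genotype_path: str | Path,
    biomarker_path: str | Path,
    lloq_path: str | Path,
    covariate_path: str | Path,
    phenotype_path: str | Path,
    name: str = "cohort",
) -> CohortBundle:
    """Read all cohort tables and align them on the common subject set.

    Subjects are restricted to the intersection of the four tables (after
    dropping covariate-incomplete subjects) and ordered lexicographically
    so the result is independent of input file order.
    """
    genotypes = read_genotype_table(genotype_path)
    analytes = read_lloq_table(lloq_path)
    biomarkers = read_biomarker_table(biomarker_path, analytes)
    covariates = read_covariate_table(covariate_path)
    phenotypes = read_phenotype_table(phenotype_path)

    common = (
        set(genotypes.subjects)
        & set(biomarkers.subjects)
        & set(covariates.subjects)
        & set(phenotypes.subjects)
    )
    if not common:
        raise ValueError("empty subject intersection across cohort tables")
    order = sorted(common)
    n_union = len(
        set(genotypes.subjects) | set(biomarkers.subjects)
        | set(covariates.subjects) | set(phenotypes.subjects)
    )
    if len(order) < n_union:
        logger.info(
            "%s: %d subjects in common out of %d seen", name, len(order), n_union
        )

    def positions(subjects: list[str]) -> list[int]:
        idx = {s: i for i, s in enumerate(subjects)}
        return [idx[s] for s in order]

    return CohortBundle(
        name=name,
        genotypes=genotypes.subset_subjects(positions(genotypes.subjects)),
        biomarkers=biomarkers.subset_subjects(positions(biomarkers.subjects)),
        covariates=covariates.subset_subjects(positions(covariates.subjects)),
        phenotypes=phenotypes.subset_subjects(positions(phenotypes.subjects)),
    )


# ---------------------------------------------------------------------------
# import adapters


def read_vcf_genotypes(path: str | Path) -> GenotypeMatrix:
    """Alt-allele dosage matrix from a diploid VCF (GT field only).

    Multi-allelic records are skipped with a warning; missing genotypes
    become NaN dosages.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF import requires cyvcf2") from exc

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:
        raise FormatError(f"{path}: malformed VCF ({exc})") from exc
    subjects = list(vcf.samples)
    variants: list[VariantInfo] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            warnings.warn(
                f"{path}: skipping multi-allelic record {rec.CHROM}:{rec.POS}",
                stacklevel=2,
            )
            continue
        vid = rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}"
        variants.append(VariantInfo(vid, str(rec.CHROM), int(rec.POS), rec.REF, rec.ALT[0]))
        dos = np.empty(len(subjects))
        for i, gt in enumerate(rec.genotypes):
            alleles = gt[:-1]  # trailing element is phased flag
            if any(a < 0 for a in alleles):
                dos[i] = np.nan
            else:
                dos[i] = float(sum(1 for a in alleles if a == 1))
        rows.append(dos)
    dosage = np.vstack(rows).T if rows else np.empty((len(subjects), 0))
    return GenotypeMatrix(subjects=subjects, variants=variants, dosage=dosage)


def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """PLINK text pedigree import (.ped/.map).

    The counted (alt) allele per variant is the minor allele observed in
    the file, ties broken toward the lexicographically greater allele;
    '0' alleles are missing.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    variants_raw: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise FormatError(f"{map_path}:{lineno}: expected 4 fields")
            variants_raw.append((parts[1], parts[0], int(parts[3])))

    subjects: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            expected = 6 + 2 * len(variants_raw)
            if len(parts) != expected:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {expected} fields, got {len(parts)}"
                )
            subjects.append(parts[1])
            allele_rows.append(
                [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(len(variants_raw))]
            )

    n, m = len(subjects), len(variants_raw)
    dosage = np.full((n, m), np.nan)
    variants: list[VariantInfo] = []
    for j, (vid, chrom, pos) in enumerate(variants_raw):
        counts: dict[str, int] = {}
        for i in range(n):
            for a in allele_rows[i][j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if not counts:
            variants.append(VariantInfo(vid, chrom, pos, "N", "N"))
            continue
        if len(counts) > 2:
            raise FormatError(f"{ped_path}: variant {vid} has >2 alleles")
        # minor allele counted; tie -> lexicographically greater
        alleles = sorted(counts)
        if len(alleles) == 1:
            ref, alt = alleles[0], "N"
        else:
            a1, a2 = alleles
            if counts[a1] < counts[a2]:
                ref, alt = a2, a1
            else:  # includes the tie: a2 (greater) is counted
                ref, alt = a1, a2
        variants.append(VariantInfo(vid, chrom, pos, ref, alt))
        for i in range(n):
            a, b = allele_rows[i][j]
            if a == "0" or b == "0":
                continue
            dosage[i, j] = float((a == alt) + (b == alt))
    return GenotypeMatrix(subjects=subjects, variants=variants, dosage=dosage)


# ---------------------------------------------------------------------------
# association result tables

ASSOCIATION_COLUMNS = [
    "variant_id", "chr", "pos", "analyte", "cohort", "model", "n", "beta", "se", "z", "p",
]


def write_association_table(results, path: str | Path) -> None:
    """Write association records to TSV (S-table-like layout).

    ``results`` may be a DataFrame with the canonical columns or an
    iterable of AssociationResult-like records. Floats are written at 17
    significant digits so the table round-trips bitwise.
    """
    if isinstance(results, pd.DataFrame):
        df = results[ASSOCIATION_COLUMNS]
    else:
        df = pd.DataFrame(
            [
                (
                    r.variant_id, r.chromosome, r.position, r.analyte_id,
                    r.cohort, r.model, r.n_used, r.beta, r.se, r.z, r.p,
                )
                for r in results
            ],
            columns=ASSOCIATION_COLUMNS,
        )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="NA")


def read_association_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(
        path,
        na_values=["NA"],
        float_precision="round_trip",  # bitwise round trip of %.17g floats
        dtype={
            "variant_id": str, "chr": str, "analyte": str, "cohort": str, "model": str,
        },
    )
    missing = [c for c in ASSOCIATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}:1: association table missing columns {missing}")
    return df
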