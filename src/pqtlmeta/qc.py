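"""Variant-level quality control and covariate-adjusted genotype PCs.

Filters mirror standard GWAS practice: call-rate (missingness), minor
allele frequency, and an exact Hardy-Weinberg equilibrium test. Principal
components are computed on standardized dosages after the clinical
covariates have been regressed out of every variant, so that the leading
axes capture genetic rather than clinical structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .types import CovariateTable, GenotypeMatrix

__all__ = [
    "QcReport",
    "GenotypePcs",
    "variant_stats",
    "hwe_exact_p",
    "filter_variants",
    "genotype_pcs",
]


@dataclass
class QcReport:
    """Per-variant QC statistics and filter attribution.

    A removed variant is attributed to the first filter it fails, in the
    order missingness -> MAF -> HWE; the kept set itself is the
    intersection of all three filters and is order-invariant.
    """

    table: pd.DataFrame  # variant_id, missing_rate, maf, hwe_p, kept, removed_by

    @property
    def n_input_variants(self) -> int:
        return len(self.table)

    @property
    def n_removed_missing(self) -> int:
        return int((self.table["removed_by"] == "missing").sum())

    @property
    def n_removed_maf(self) -> int:
        return int((self.table["removed_by"] == "maf").sum())

    @property
    def n_removed_hwe(self) -> int:
        return int((self.table["removed_by"] == "hwe").sum())

    @property
    def n_kept(self) -> int:
        return int(self.table["kept"].sum())


@dataclass
class GenotypePcs:
    """Top-k genotype principal components (scores are zero-mean per column,
    ordered by decreasing eigenvalue; sign fixed so the largest-magnitude
    variant loading is positive)."""

    scores: np.ndarray  # subjects x k
    eigenvalues: np.ndarray  # length k, decreasing
    k: int


def variant_stats(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant missing rate, alt/minor allele frequency and genotype counts."""
    d = g.dosage
    n = d.shape[0]
    obs = np.isfinite(d)
    n_obs = obs.sum(axis=0)
    missing_rate = 1.0 - n_obs / n

    n_hom_ref = np.nansum(d == 0, axis=0)
    n_het = np.nansum(d == 1, axis=0)
    n_hom_alt = np.nansum(d == 2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(n_obs > 0, (n_het + 2 * n_hom_alt) / (2 * n_obs), np.nan)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    return pd.DataFrame(
        {
            "variant_id": g.variant_ids,
            "missing_rate": missing_rate,
            "alt_freq": alt_freq,
            "maf": maf,
            "n_obs": n_obs,
            "n_hom_ref": n_hom_ref.astype(int),
            "n_het": n_het.astype(int),
            "n_hom_alt": n_hom_alt.astype(int),
        }
    )


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test by heterozygote-count enumeration.

    Conditional on the observed allele counts, the p-value sums the exact
    probabilities of every heterozygote count whose probability does not
    exceed that of the observed count (no mid-p). Monomorphic tables
    return 1 by convention.
    """
    n_hom_ref, n_het, n_hom_alt = int(n_hom_ref), int(n_het), int(n_hom_alt)
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    n_a = 2 * n_hom_ref + n_het  # ref allele count
    n_b = 2 * n_hom_alt + n_het
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het = h | allele counts) up to the shared normalizer
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln((n_a - hets) / 2 + 1)
        - gammaln((n_b - hets) / 2 + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_het]
    if p_obs.size == 0:
        raise ValueError(
            f"heterozygote count {n_het} impossible for allele counts ({n_a},{n_b})"
        )
    p = probs[probs <= p_obs[0] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def filter_variants(
    g: GenotypeMatrix,
    missing_max: float = 0.05,
    maf_min: float = 0.01,
    hwe_alpha: float = 0.001,
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove variants failing call-rate, MAF or HWE thresholds.

    Kept variants satisfy missing_rate <= missing_max, maf >= maf_min and
    hwe_p >= hwe_alpha. All-missing variants are removed (undefined MAF).
    """
    stats = variant_stats(g)
    hwe_p = np.array(
        [
            hwe_exact_p(r.n_hom_ref, r.n_het, r.n_hom_alt) if r.n_obs > 0 else np.nan
            for r in stats.itertuples()
        ]
    )
    fail_missing = stats["missing_rate"].to_numpy() > missing_max
    maf = stats["maf"].to_numpy()
    fail_maf = ~(maf >= maf_min)  # NaN maf (all missing) fails here after missingness
    fail_hwe = ~(hwe_p >= hwe_alpha)
    kept = ~(fail_missing | fail_maf | fail_hwe)

    removed_by = np.full(len(stats), "", dtype=object)
    removed_by[fail_hwe] = "hwe"
    removed_by[fail_maf] = "maf"
    removed_by[fail_missing] = "missing"  # first-failed attribution wins

    report = QcReport(
        table=stats.assign(hwe_p=hwe_p, kept=kept, removed_by=removed_by)
    )
    if not kept.any():
        warnings.warn("no variants survive QC filtering", stacklevel=2)
    return g.subset_variants(np.flatnonzero(kept)), report


def _standardize_dosages(d: np.ndarray) -> np.ndarray:
    """Column-standardize dosages; missing values set to the column mean (0)."""
    mean = np.nanmean(d, axis=0)
    x = np.where(np.isfinite(d), d, mean)
    x = x - mean
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return x / sd


def covariate_design(cov: CovariateTable, cell_counts: bool = False) -> np.ndarray:
    """Intercept + site indicators (first alphabetical level as reference)
    + sex, age, bmi, pack_years, current_smoker [+ cell counts]."""
    from .assoc import build_design  # single source of truth for the layout

    X, _ = build_design(cov, cell_counts=cell_counts)
    return X


def genotype_pcs(
    g: GenotypeMatrix,
    covariates: CovariateTable | np.ndarray | None,
    k: int = 1,
) -> GenotypePcs:
    """Principal components of covariate-residualized standardized dosages.

    Each variant's standardized dosage vector is residualized on the
    covariate design, the subjects x variants residual matrix is
    decomposed by SVD, and the top-k left singular vectors (scaled by
    their singular values) are returned with eigenvalues for a scree
    decision.
    """
    n, m = g.dosage.shape
    if k < 1 or k > min(n, m):
        raise ValueError(f"k={k} outside [1, min(n_subjects, n_variants)]")
    x = _standardize_dosages(g.dosage)
    if covariates is not None:
        X = covariates if isinstance(covariates, np.ndarray) else covariate_design(covariates)
        beta, *_ = np.linalg.lstsq(X, x, rcond=None)
        x = x - X @ beta
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive
    for j in range(min(k, s.size)):
        i_max = np.argmax(np.abs(vt[j]))
        if vt[j, i_max] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    scores = u[:, :k] * s[:k]
    eigenvalues = s[:k] ** 2 / (n - 1)
    return GenotypePcs(scores=scores, eigenvalues=eigenvalues, k=k)
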