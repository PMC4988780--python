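"""Variance-explained decompositions and scan-sensitivity reports.

Hierarchical (sequential) R^2 partitions a biomarker's variance into the
part explained by clinical covariates, the increment from the top
independent pQTL SNP, the increment from the second independent SNP, and
an unexplained remainder; the order (clinical, snp1, snp2) is fixed.
The cell-count sensitivity report quantifies how much a scan's p-values
move when complete-blood-count covariates are added, as the Pearson
correlation of -log10 p across (variant, analyte) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import logistic_fit, ols_fit

__all__ = [
    "VarianceDecomposition",
    "SensitivityReport",
    "variance_decomposition",
    "phenotype_r2_comparison",
    "cellcount_sensitivity",
]


@dataclass
class VarianceDecomposition:
    analyte_id: str
    cohort: str
    r2_clinical: float
    r2_snp1: float
    r2_snp2: float
    r2_residual: float
    snp_ids: list[str]
    approximate: bool = False  # True for censoring-filled tobit analytes

    @property
    def components(self) -> np.ndarray:
        return np.array([self.r2_clinical, self.r2_snp1, self.r2_snp2, self.r2_residual])


@dataclass
class SensitivityReport:
    corr_all: float
    corr_significant: float
    corr_raw_p_all: float
    n_pairs: int
    n_significant: int
    table: pd.DataFrame  # per-pair p-values, both scans


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    fit = ols_fit(y, X)
    keep = np.isfinite(fit.params)
    resid = y - X[:, keep] @ fit.params[keep]
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0


def variance_decomposition(
    y: np.ndarray,
    X_clinical: np.ndarray,
    g1: np.ndarray,
    g2: np.ndarray | None = None,
    analyte_id: str = "",
    cohort: str = "",
    snp_ids: list[str] | None = None,
    approximate: bool = False,
) -> VarianceDecomposition:
    """Sequential R^2 of a transformed analyte on clinical covariates then
    one or two independent pQTL dosages; components sum to 1 exactly.

    For tobit-mode analytes call with conditional-expectation-filled
    values and ``approximate=True``.
    """
    y = np.asarray(y, dtype=float)
    cols = [X_clinical, np.asarray(g1, dtype=float).reshape(-1, 1)]
    if g2 is not None:
        cols.append(np.asarray(g2, dtype=float).reshape(-1, 1))
    rows = np.isfinite(y)
    for c in cols:
        rows &= np.isfinite(c).all(axis=1)
    y = y[rows]
    Xc = X_clinical[rows]
    r2_c = _r2(y, Xc)
    X1 = np.column_stack([Xc, cols[1][rows]])
    r2_1 = _r2(y, X1)
    if g2 is not None:
        X2 = np.column_stack([X1, cols[2][rows]])
        r2_2 = _r2(y, X2)
    else:
        r2_2 = r2_1
    return VarianceDecomposition(
        analyte_id=analyte_id,
        cohort=cohort,
        r2_clinical=r2_c,
        r2_snp1=r2_1 - r2_c,
        r2_snp2=r2_2 - r2_1,
        r2_residual=1.0 - r2_2,
        snp_ids=snp_ids or [],
        approximate=approximate,
    )


def phenotype_r2_comparison(
    d: np.ndarray,
    X_clinical: np.ndarray,
    biomarker: np.ndarray,
    g: np.ndarray,
    binary: bool = False,
) -> tuple[float, float, float]:
    """Nested-model R^2 triple for a disease phenotype: covariates only,
    + biomarker, + biomarker and SNP. Non-decreasing by construction for
    linear models; binary phenotypes use McFadden pseudo-R^2."""
    d = np.asarray(d, dtype=float)
    b = np.asarray(biomarker, dtype=float).reshape(-1, 1)
    g = np.asarray(g, dtype=float).reshape(-1, 1)
    rows = (
        np.isfinite(d) & np.isfinite(X_clinical).all(axis=1)
        & np.isfinite(b).all(axis=1) & np.isfinite(g).all(axis=1)
    )
    d, Xc, b, g = d[rows], X_clinical[rows], b[rows], g[rows]
    designs = [Xc, np.hstack([Xc, b]), np.hstack([Xc, b, g])]
    if not binary:
        return tuple(_r2(d, X) for X in designs)
    # McFadden: 1 - ll_model / ll_null
    ll_null = logistic_fit(d, np.ones((len(d), 1))).loglik
    out = []
    for X in designs:
        fit = logistic_fit(d, X)
        out.append(1.0 - fit.loglik / ll_null if ll_null != 0 else np.nan)
    return tuple(out)


def cellcount_sensitivity(
    scan_base: pd.DataFrame,
    scan_with_cbc: pd.DataFrame,
    significance_threshold: float = 8e-10,
) -> SensitivityReport:
    """Concordance of scan p-values with vs without cell-count covariates.

    Both scans must cover identical (variant, analyte) pairs. Reports the
    Pearson correlation of -log10 p over all pairs and over the subset
    significant in the base scan (raw-p correlation included for
    reference; it is dominated by the uniform null bulk).
    """
    key = ["variant_id", "analyte"]
    a = scan_base[key + ["p"]].rename(columns={"p": "p_base"})
    b = scan_with_cbc[key + ["p"]].rename(columns={"p": "p_cbc"})
    if len(a) != len(b):
        raise ValueError("scans cover different numbers of pairs")
    merged = a.merge(b, on=key, how="outer", indicator=True)
    bad = merged[merged["_merge"] != "both"]
    if len(bad):
        raise ValueError(
            f"scans cover different (variant, analyte) pairs; first differences:\n"
            f"{bad[key].head()}"
        )
    merged = merged.drop(columns="_merge")
    lp_base = -np.log10(merged["p_base"].to_numpy())
    lp_cbc = -np.log10(merged["p_cbc"].to_numpy())
    corr_all = float(np.corrcoef(lp_base, lp_cbc)[0, 1])
    corr_raw = float(np.corrcoef(merged["p_base"], merged["p_cbc"])[0, 1])
    sig = merged["p_base"].to_numpy() < significance_threshold
    corr_sig = (
        float(np.corrcoef(lp_base[sig], lp_cbc[sig])[0, 1]) if sig.sum() >= 3 else np.nan
    )
    return SensitivityReport(
        corr_all=corr_all,
        corr_significant=corr_sig,
        corr_raw_p_all=corr_raw,
        n_pairs=len(merged),
        n_significant=int(sig.sum()),
        table=merged,
    )
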