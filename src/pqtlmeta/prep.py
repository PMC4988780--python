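"""LLOQ-aware biomarker preprocessing.

Assay panels report a lower limit of quantification (LLOQ) per analyte;
measurements below it are left-censored. The fixed preprocessing order is:

1. triage each analyte by its censored fraction: >90% below LLOQ -> drop,
   <10% -> ordinary linear regression, 10-90% -> tobit (censored) regression;
2. impute below-LLOQ values as half the LLOQ;
3. rank-based inverse normal transform (average ranks for ties, offset
   (r - 1/2)/m), which makes the tobit normality assumption hold by
   construction;
4. for tobit analytes, set the truncation value c to the minimum
   transformed value among non-censored observations minus 1e-10.

When a censored analyte is later used as a *covariate* (trio models,
variance reports), censored entries are replaced by their conditional
expectation under a fitted tobit model (mean of a normal truncated above
at c).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr, ndtri
from scipy.stats import norm, rankdata

from .types import BiomarkerPanel, CovariateTable

__all__ = [
    "PreparedAnalyte",
    "BiomarkerPcCovariate",
    "triage_analyte",
    "impute_half_lloq",
    "inverse_normal_transform",
    "truncation_value",
    "conditional_expectation_fill",
    "prepare_analyte",
    "prepare_panel",
    "biomarker_pc1",
    "TRUNCATION_EPS",
]

#: small constant subtracted from the minimum uncensored transformed value
TRUNCATION_EPS = 1e-10


@dataclass
class PreparedAnalyte:
    """One analyte after censoring-aware preprocessing.

    ``y`` is on the normal-quantile scale (NaN = missing); ``c`` is the
    tobit truncation value and is None for linear-mode analytes.
    """

    analyte_id: str
    mode: str  # "linear" | "tobit"
    y: np.ndarray
    censored_mask: np.ndarray
    pct_below_lloq: float
    c: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "tobit"):
            raise ValueError(f"bad mode {self.mode!r}")
        if self.mode == "tobit" and self.c is None:
            raise ValueError("tobit-mode analyte needs a truncation value")


@dataclass
class BiomarkerPcCovariate:
    """First principal component of the biomarker panel, offered as a
    scan covariate when it is not explained by the clinical covariates."""

    scores: np.ndarray
    include_flag: bool
    screen_pvalues: dict[str, float] = field(default_factory=dict)


def triage_analyte(pct_below_lloq: float) -> str:
    """Analysis-mode triage from the below-LLOQ fraction.

    Strictly more than 90% censored -> "drop" (no analysis); strictly
    less than 10% -> "linear"; everything between (inclusive) -> "tobit".
    """
    if not 0.0 <= pct_below_lloq <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if pct_below_lloq > 0.90:
        return "drop"
    if pct_below_lloq < 0.10:
        return "linear"
    return "tobit"


def impute_half_lloq(raw: np.ndarray, below_lloq_mask: np.ndarray, lloq: float) -> np.ndarray:
    """Replace below-LLOQ measurements by LLOQ/2 (others unchanged)."""
    if lloq <= 0:
        raise ValueError("lloq must be > 0")
    out = np.asarray(raw, dtype=float).copy()
    out[np.asarray(below_lloq_mask, dtype=bool)] = lloq / 2.0
    return out


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform, Phi^-1((r - 1/2)/m).

    Ranks are averaged over ties so tied inputs (e.g. all half-LLOQ
    imputations) map to identical outputs; missing values stay missing.
    """
    values = np.asarray(values, dtype=float)
    out = np.full_like(values, np.nan)
    obs = np.isfinite(values)
    m = int(obs.sum())
    if m < 2:
        raise ValueError("need at least 2 non-missing values")
    v = values[obs]
    if np.all(v == v[0]):
        warnings.warn("all values identical; transform maps to 0", stacklevel=2)
        out[obs] = 0.0
        return out
    ranks = rankdata(v, method="average")
    out[obs] = ndtri((ranks - 0.5) / m)
    return out


def truncation_value(transformed: np.ndarray, censored_mask: np.ndarray) -> float:
    """Tobit truncation value: min transformed non-censored value - 1e-10."""
    transformed = np.asarray(transformed, dtype=float)
    censored_mask = np.asarray(censored_mask, dtype=bool)
    keep = ~censored_mask & np.isfinite(transformed)
    if not keep.any():
        raise ValueError("no non-censored values; analyte should have been dropped")
    return float(transformed[keep].min() - TRUNCATION_EPS)


def truncated_normal_mean(mu, sigma, c):
    """Mean of N(mu, sigma^2) truncated above at c: mu - sigma*phi(a)/Phi(a),
    a = (c - mu)/sigma, with the Mills ratio evaluated in log space."""
    mu = np.asarray(mu, dtype=float)
    a = (c - mu) / sigma
    mills = np.exp(norm.logpdf(a) - log_ndtr(a))
    return mu - sigma * mills


def conditional_expectation_fill(prepared: PreparedAnalyte, X: np.ndarray, fit=None) -> np.ndarray:
    """Replace censored entries by their tobit conditional expectation.

    Fits (or reuses) a tobit model of the prepared values on the design
    ``X``; each censored subject i gets the mean of a normal with its
    fitted linear predictor, truncated above at the truncation value c.
    Non-censored and missing entries are unchanged.
    """
    if prepared.mode != "tobit":
        return prepared.y.copy()
    if fit is None:
        from .assoc import tobit_fit

        fit = tobit_fit(prepared.y, X, prepared.c, prepared.censored_mask)
    filled = prepared.y.copy()
    cens = prepared.censored_mask & np.isfinite(prepared.y)
    if cens.any():
        mu = X[cens] @ fit.params
        filled[cens] = truncated_normal_mean(mu, fit.scale, prepared.c)
    return filled


def prepare_analyte(
    raw: np.ndarray,
    below_lloq_mask: np.ndarray,
    lloq: float,
    analyte_id: str = "",
) -> PreparedAnalyte | None:
    """Run the fixed pipeline for one analyte; returns None when dropped."""
    raw = np.asarray(raw, dtype=float)
    mask = np.asarray(below_lloq_mask, dtype=bool)
    obs = np.isfinite(raw)
    if obs.sum() < 2:
        return None
    pct = float(mask[obs].mean())
    mode = triage_analyte(pct)
    if mode == "drop":
        return None
    imputed = impute_half_lloq(raw, mask, lloq)
    y = inverse_normal_transform(imputed)
    c = truncation_value(y, mask) if mode == "tobit" else None
    return PreparedAnalyte(
        analyte_id=analyte_id,
        mode=mode,
        y=y,
        censored_mask=mask & obs,
        pct_below_lloq=pct,
        c=c,
    )


def prepare_panel(panel: BiomarkerPanel) -> tuple[list[PreparedAnalyte], list[str]]:
    """Prepare every analyte of a panel; second element lists dropped ids.

    The panel's AnalyteMeta.analysis_mode fields are updated in place.
    """
    prepared: list[PreparedAnalyte] = []
    dropped: list[str] = []
    for j, meta in enumerate(panel.analytes):
        p = prepare_analyte(
            panel.raw[:, j], panel.below_lloq[:, j], meta.lloq, meta.analyte_id
        )
        if p is None:
            meta.analysis_mode = "drop"
            dropped.append(meta.analyte_id)
        else:
            meta.analysis_mode = p.mode
            prepared.append(p)
    return prepared, dropped


def _pc1(values: np.ndarray) -> np.ndarray:
    """First principal component scores of a column-standardized matrix
    (missing entries set to the column mean; sign: largest loading positive)."""
    x = values.copy()
    mean = np.nanmean(x, axis=0)
    x = np.where(np.isfinite(x), x, mean) - mean
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    x /= sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    if vt[0, np.argmax(np.abs(vt[0]))] < 0:
        u[:, 0] = -u[:, 0]
    return u[:, 0] * s[0]


def biomarker_pc1(
    values: np.ndarray,
    covariates: CovariateTable,
    policy: str = "auto",
    alpha: float = 0.05,
) -> BiomarkerPcCovariate:
    """PC1 of the prepared biomarker matrix, screened against covariates.

    ``values`` is subjects x analytes on the transformed scale (tobit
    analytes conditional-expectation-filled). Under the default ``auto``
    policy the component is flagged for inclusion only when no clinical
    covariate associates with it at a Bonferroni-corrected level — i.e.
    when it reflects structure the covariates do not already carry.
    ``always`` / ``never`` override the screen.
    """
    from .assoc import build_design, ols_fit, wald_p

    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("need >=2 usable analytes for a biomarker PC")
    if policy not in ("auto", "always", "never"):
        raise ValueError(f"unknown policy {policy!r}")
    scores = _pc1(values)

    X, names = build_design(covariates)
    n_terms = X.shape[1] - 1  # non-intercept covariate terms
    pvals: dict[str, float] = {}
    intercept = np.ones((len(scores), 1))
    for j in range(1, X.shape[1]):
        design = np.hstack([intercept, X[:, j:j + 1]])
        fit = ols_fit(scores, design)
        pvals[names[j]] = float(wald_p(fit.params[1] / fit.se[1]))
    if policy == "always":
        include = True
    elif policy == "never":
        include = False
    else:
        include = all(p >= alpha / n_terms for p in pvals.values())
    return BiomarkerPcCovariate(scores=scores, include_flag=include, screen_pvalues=pvals)
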