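"""Two-cohort meta-analysis, replication, and recursive conditioning.

Per-cohort association results are combined by a sample-size-weighted
signed-Z statistic:

    z_i = sign(beta_i) * |Phi^-1(p_i / 2)|,
    Z   = (n1*z1 + n2*z2) / (n1 + n2),      meta_p = 2*Phi(-|Z|).

This arithmetic-mean denominator is implemented exactly as used by the
source analysis; note it is *not* the classical Stouffer normalization
(whose weights are sqrt(n) with a root-sum-square denominator) and is
conservative relative to it. The classical variant is available via
``method="classical"``.

Independent association signals per analyte are selected by recursive
conditioning (forward selection): starting from the top marginal meta
hit, every remaining candidate is refit per cohort with all previously
selected dosages added to the covariate design, the candidate's
conditional meta-p is computed, and the best candidate is accepted while
it beats a Bonferroni threshold 0.05/T shrinking with the remaining
candidate count T.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr, ndtri

try:  # scipy >= 1.9
    from scipy.special import ndtri_exp
except ImportError:  # pragma: no cover
    ndtri_exp = None

from .assoc import ols_fit, tobit_fit, wald_p
from .types import AnalyteMeta, VariantInfo

__all__ = [
    "MetaResult",
    "IndependentSignalSet",
    "CohortScanData",
    "signed_z",
    "stouffer_meta",
    "meta_log10_p",
    "call_significant",
    "bonferroni_threshold",
    "meta_analyze",
    "replication_check",
    "recursive_conditioning",
    "classify_local_distant",
    "LOCAL_WINDOW_BP",
]

#: local (cis) window around the analyte-encoding gene, basepairs
LOCAL_WINDOW_BP = 1_000_000

#: genome-wide significance default for the two-cohort meta scan
META_SIGNIFICANCE = 8e-10

#: marginal meta-p threshold defining the conditioning candidate pool
CONDITIONING_POOL_P = 1e-8


@dataclass
class MetaResult:
    variant_id: str
    analyte_id: str
    beta1: float
    p1: float
    n1: int
    beta2: float
    p2: float
    n2: int
    z1: float
    z2: float
    Z: float
    meta_p: float
    log10_meta_p: float
    significant: bool


@dataclass
class IndependentSignalSet:
    """Forward-selected independent signals for one analyte."""

    analyte_id: str
    selected: list[str]  # variant ids in selection order
    conditional_meta_p: list[float]  # meta-p at the round each was selected
    n_candidates: int  # K, initial pool size
    stop_reason: str


def signed_z(p: float, beta: float) -> float:
    """Signed z-score from a two-sided p-value and effect direction.

    z = sign(beta) * |Phi^-1(p/2)|; for p below ~1e-280 the quantile is
    evaluated from log(p) so extreme associations keep finite, accurate z.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p-value {p} outside (0, 1]")
    if p < 1e-280 and ndtri_exp is not None:
        q = float(ndtri_exp(np.log(p) - np.log(2.0)))
    else:
        q = float(ndtri(p / 2.0))
    return float(np.sign(beta) * abs(q))


def stouffer_meta(
    z1: float, n1: int, z2: float, n2: int, method: str = "sample-size"
) -> tuple[float, float]:
    """Combined Z and two-sided meta p-value for two cohorts.

    ``sample-size`` (default): Z = (n1*z1 + n2*z2)/(n1 + n2), the formula
    used throughout this pipeline. ``classical``: sqrt(n)-weighted
    Stouffer with unit null variance.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("cohort sizes must be >= 1")
    if method == "sample-size":
        Z = (n1 * z1 + n2 * z2) / (n1 + n2)
    elif method == "classical":
        Z = (np.sqrt(n1) * z1 + np.sqrt(n2) * z2) / np.sqrt(n1 + n2)
    else:
        raise ValueError(f"unknown meta method {method!r}")
    meta_p = float(2.0 * ndtr(-abs(Z)))
    return float(Z), max(meta_p, np.nextafter(0, 1))


def meta_log10_p(Z: float) -> float:
    """log10 of the two-sided meta p-value, exact far beyond float underflow."""
    return float((log_ndtr(-abs(Z)) + np.log(2.0)) / np.log(10.0))


def call_significant(meta_p, threshold: float = META_SIGNIFICANCE):
    """Strict-inequality significance call, meta_p < threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return np.asarray(meta_p) < threshold


def bonferroni_threshold(n_variants: int, n_analytes: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / (variants x analytes) for a user's own scan."""
    return alpha / (n_variants * n_analytes)


def meta_analyze(
    results1: pd.DataFrame,
    results2: pd.DataFrame,
    n1: int | None = None,
    n2: int | None = None,
    threshold: float = META_SIGNIFICANCE,
    method: str = "sample-size",
) -> pd.DataFrame:
    """Meta-combine two per-cohort association tables on (variant, analyte).

    Inputs are association frames (columns variant_id, analyte, beta, p, n);
    non-converged flagged results are excluded. Cohort sizes default to the
    per-association n columns.
    """
    keep_cols = ["variant_id", "analyte", "beta", "p", "n"]
    f1, f2 = results1, results2
    if "flag" in f1.columns:
        f1 = f1[f1["flag"] != "nonconverged"]
    if "flag" in f2.columns:
        f2 = f2[f2["flag"] != "nonconverged"]
    merged = f1[keep_cols].merge(
        f2[keep_cols], on=["variant_id", "analyte"], suffixes=("_1", "_2")
    )
    rows = []
    for r in merged.itertuples(index=False):
        z1 = signed_z(r.p_1, r.beta_1)
        z2 = signed_z(r.p_2, r.beta_2)
        m1 = int(n1 if n1 is not None else r.n_1)
        m2 = int(n2 if n2 is not None else r.n_2)
        Z, mp = stouffer_meta(z1, m1, z2, m2, method=method)
        rows.append(
            (
                r.variant_id, r.analyte, r.beta_1, r.p_1, m1, r.beta_2, r.p_2, m2,
                z1, z2, Z, mp, meta_log10_p(Z), bool(mp < threshold),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "variant_id", "analyte", "beta1", "p1", "n1", "beta2", "p2", "n2",
            "z1", "z2", "Z", "meta_p", "log10_meta_p", "significant",
        ],
    )


def replication_check(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    discovery_threshold: float = META_SIGNIFICANCE,
) -> tuple[pd.DataFrame, dict]:
    """Cross-cohort replication of cohort-A discoveries in cohort B.

    An association significant in A (p_A < discovery_threshold) replicates
    when p_B < 0.05/m_A (m_A = number of A discoveries) AND the effect
    directions agree. Associations absent from B are unreplicated and
    flagged missing.
    """
    disc = results_a[results_a["p"] < discovery_threshold].copy()
    m_a = len(disc)
    per_test = 0.05 / m_a if m_a else np.nan
    b_keyed = results_b.set_index(["variant_id", "analyte"])
    flags, missing = [], []
    for r in disc.itertuples(index=False):
        key = (r.variant_id, r.analyte)
        if key not in b_keyed.index:
            flags.append(False)
            missing.append(True)
            continue
        rb = b_keyed.loc[key]
        ok = bool(rb["p"] < per_test) and np.sign(rb["beta"]) == np.sign(r.beta)
        flags.append(ok)
        missing.append(False)
    disc["replicated"] = flags
    disc["missing_in_b"] = missing
    summary = {
        "m_discovery": m_a,
        "per_test_threshold": per_test,
        "n_replicated": int(sum(flags)),
        "replication_rate": float(np.mean(flags)) if m_a else np.nan,
    }
    return disc, summary


@dataclass
class CohortScanData:
    """Per-cohort inputs for conditional refitting of one analyte.

    ``dosages`` holds the candidate variants' dosage columns aligned with
    ``y`` and the covariate design ``X``; tobit analytes carry their
    truncation value and censoring mask.
    """

    y: np.ndarray
    X: np.ndarray
    dosages: np.ndarray  # subjects x K candidate columns
    n: int
    mode: str = "linear"  # "linear" | "tobit"
    c: float | None = None
    censored_mask: np.ndarray | None = None

    def fit_candidate(self, cand: int, selected: list[int]) -> tuple[float, float]:
        """(beta, p) of candidate ``cand`` conditional on selected dosages."""
        cols = [self.dosages[:, j] for j in selected] + [self.dosages[:, cand]]
        design = np.column_stack([self.X] + cols)
        if self.mode == "tobit":
            fit = tobit_fit(self.y, design, self.c, self.censored_mask)
        else:
            fit = ols_fit(self.y, design)
        beta, se = fit.params[-1], fit.se[-1]
        if not np.isfinite(beta) or not np.isfinite(se) or se <= 0:
            return np.nan, np.nan
        return float(beta), float(wald_p(beta / se))


def _dosage_r2(a: np.ndarray, b: np.ndarray) -> float:
    rows = np.isfinite(a) & np.isfinite(b)
    if rows.sum() < 3 or a[rows].std() == 0 or b[rows].std() == 0:
        return 0.0
    return float(np.corrcoef(a[rows], b[rows])[0, 1] ** 2)


def recursive_conditioning(
    analyte_id: str,
    candidate_ids: list[str],
    cohort1: CohortScanData,
    cohort2: CohortScanData,
    alpha: float = 0.05,
    collinear_r2: float = 0.99,
    method: str = "sample-size",
) -> IndependentSignalSet:
    """Forward selection of independent association signals.

    ``candidate_ids`` is the marginal candidate pool (in practice variants
    with marginal meta-p below 1e-8). Round 0 selects the top marginal
    meta hit; each later round refits every remaining candidate per cohort
    conditioning on all previously selected dosages, meta-combines the
    candidate slope, and accepts the best candidate while its conditional
    meta-p beats alpha/T with T the remaining candidate count. Candidates
    nearly collinear (r^2 > ``collinear_r2``) with a selected variant are
    skipped with a warning. Ties on meta-p break by larger |Z| then
    lexicographic variant id.
    """
    K = len(candidate_ids)
    if K == 0:
        raise ValueError("empty candidate pool")

    def meta_of(cand: int, selected: list[int]) -> tuple[float, float]:
        b1, p1 = cohort1.fit_candidate(cand, selected)
        b2, p2 = cohort2.fit_candidate(cand, selected)
        if not np.isfinite(p1) or not np.isfinite(p2):
            return 0.0, 1.0
        Z, mp = stouffer_meta(
            signed_z(p1, b1), cohort1.n, signed_z(p2, b2), cohort2.n, method=method
        )
        return Z, mp

    def best(remaining: list[int], selected: list[int]) -> tuple[int, float, float]:
        scored = []
        for cand in remaining:
            Z, mp = meta_of(cand, selected)
            scored.append((mp, -abs(Z), candidate_ids[cand], cand))
        scored.sort()
        mp, negZ, _, cand = scored[0]
        return cand, mp, -negZ

    selected: list[int] = []
    cond_p: list[float] = []
    # round 0: top marginal hit (no conditioning)
    cand, mp, _ = best(list(range(K)), [])
    selected.append(cand)
    cond_p.append(mp)
    stop_reason = "pool exhausted"
    if K == 1:
        return IndependentSignalSet(analyte_id, [candidate_ids[cand]], cond_p, K, "single candidate")

    remaining = [j for j in range(K) if j != cand]
    while remaining:
        usable = []
        for j in remaining:
            r2s = [
                _dosage_r2(cohort1.dosages[:, j], cohort1.dosages[:, s]) for s in selected
            ]
            if max(r2s) > collinear_r2:
                warnings.warn(
                    f"skipping {candidate_ids[j]}: r^2 > {collinear_r2} with a selected variant",
                    stacklevel=2,
                )
            else:
                usable.append(j)
        if not usable:
            stop_reason = "all remaining candidates collinear with selected"
            break
        T = len(remaining)
        cand, mp, _ = best(usable, selected)
        if mp < alpha / T:
            selected.append(cand)
            cond_p.append(mp)
            remaining = [j for j in remaining if j != cand]
        else:
            stop_reason = f"min conditional meta-p {mp:.3g} >= {alpha}/{T}"
            break
    return IndependentSignalSet(
        analyte_id=analyte_id,
        selected=[candidate_ids[j] for j in selected],
        conditional_meta_p=cond_p,
        n_candidates=K,
        stop_reason=stop_reason,
    )


def classify_local_distant(variant: VariantInfo, analyte: AnalyteMeta) -> str:
    """"local" when the variant lies within 1 Mb of the analyte-encoding
    gene interval on the same chromosome (distance 0 inside the gene),
    else "distant"; "unknown" when the gene locus is not annotated."""
    if not analyte.has_locus:
        return "unknown"
    if str(variant.chromosome) != str(analyte.gene_chromosome):
        return "distant"
    if variant.position < analyte.gene_start:
        dist = analyte.gene_start - variant.position
    elif variant.position > analyte.gene_end:
        dist = variant.position - analyte.gene_end
    else:
        dist = 0
    return "local" if dist <= LOCAL_WINDOW_BP else "distant"
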