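"""Causal-model classification of (SNP, biomarker, phenotype) trios.

Under a Mendelian-randomization assumption (genotype causes molecular and
clinical change, never the reverse), five directed models over a trio —
causal (SNP -> biomarker -> disease), reactive (SNP -> disease ->
biomarker), independent (biomarker <- SNP -> disease), collide
(SNP -> biomarker <- disease) and complete (all edges) — imply distinct
patterns of (conditional) dependence. Each dependence is read off a slope
in one of three regressions fit per cohort and meta-combined:

    M1:  D ~ g + C            -> b1, the marginal SNP-disease slope
    M2:  D ~ g + B + C        -> b3 (SNP | biomarker), b2 (biomarker | SNP)
    M3:  B ~ g + D + C        -> b5 (SNP | disease)

D is modeled by linear (continuous phenotype) or logistic (binary)
regression; B by OLS or tobit per the analyte's triaged mode, and when B
enters M2 as a covariate its censored entries are conditional-expectation
filled. A slope is called nonzero when its meta-p < alpha (default 0.01);
the significance pattern of (b1, b3, b2, b5) selects the category, with
any unmatched pattern reported as "other". Treating meta-p >= alpha as
evidence of conditional independence is inherent to the procedure: the
battery p-values are always emitted so margins can be judged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assoc import logistic_fit, ols_fit, tobit_fit, wald_p
from .meta import signed_z, stouffer_meta
from .prep import PreparedAnalyte, conditional_expectation_fill

__all__ = [
    "TrioTestBattery",
    "TrioClassification",
    "CohortTrioTests",
    "fit_trio_regressions",
    "meta_combine_tests",
    "classify_trio",
    "TRIO_ALPHA",
    "CATEGORIES",
]

TRIO_ALPHA = 0.01
CATEGORIES = ("causal", "reactive", "independent", "collide", "complete", "other")

#: battery test keys, in (b1, b3, b2, b5) order
TEST_KEYS = ("sd", "sd_given_b", "bd_given_s", "sb_given_d")


@dataclass
class CohortTrioTests:
    """Per-cohort (beta, p) for the four battery slopes, plus sample size."""

    tests: dict[str, tuple[float, float]]  # key -> (beta, p)
    n: int
    converged: bool = True
    reason: str = ""


@dataclass
class TrioTestBattery:
    """Meta-combined p-values (and per-cohort slope signs) for one trio."""

    meta_p: dict[str, float]  # key -> meta p
    meta_z: dict[str, float]
    sign1: dict[str, float]  # per-cohort slope signs, for concordance reports
    sign2: dict[str, float]
    single_cohort: bool = False


@dataclass
class TrioClassification:
    snp: str
    biomarker: str
    phenotype: str
    battery: TrioTestBattery
    category: str
    alpha: float


def fit_trio_regressions(
    g: np.ndarray,
    prepared: PreparedAnalyte,
    d: np.ndarray,
    X: np.ndarray,
    binary: bool = False,
    X_biomarker_response: np.ndarray | None = None,
) -> CohortTrioTests:
    """Fit M1-M3 for one cohort and extract the four battery slopes.

    ``X`` is the covariate design used when the phenotype is the response;
    ``X_biomarker_response`` (default: same as X) is used for M3 so that a
    biomarker-derived covariate such as biomarker PC1 can be excluded when
    the biomarker itself is the response.
    """
    g = np.asarray(g, dtype=float)
    d = np.asarray(d, dtype=float)
    Xb = X if X_biomarker_response is None else X_biomarker_response
    rows = (
        np.isfinite(g)
        & np.isfinite(d)
        & np.isfinite(prepared.y)
        & np.isfinite(X).all(axis=1)
        & np.isfinite(Xb).all(axis=1)
    )
    if g[rows].std() == 0:
        return CohortTrioTests({}, int(rows.sum()), False, "zero-variance genotype")

    # biomarker as covariate: conditional-expectation fill for censored entries
    if prepared.mode == "tobit":
        b_cov = conditional_expectation_fill(prepared, Xb)
    else:
        b_cov = prepared.y

    gr, dr, br = g[rows], d[rows], b_cov[rows]
    Xr, Xbr = X[rows], Xb[rows]
    fit_d = logistic_fit if binary else ols_fit

    def slope(fit, idx):
        beta, se = fit.params[idx], fit.se[idx]
        if not (np.isfinite(beta) and np.isfinite(se)) or se <= 0:
            return None
        return float(beta), float(wald_p(beta / se))

    try:
        m1 = fit_d(dr, np.column_stack([Xr, gr]))
        m2 = fit_d(dr, np.column_stack([Xr, gr, br]))
        design3 = np.column_stack([Xbr, gr, dr])
        if prepared.mode == "tobit":
            m3 = tobit_fit(prepared.y[rows], design3, prepared.c, prepared.censored_mask[rows])
        else:
            m3 = ols_fit(prepared.y[rows], design3)
    except (ValueError, np.linalg.LinAlgError) as exc:
        return CohortTrioTests({}, int(rows.sum()), False, str(exc))
    if not (m1.converged and m2.converged and m3.converged):
        return CohortTrioTests({}, int(rows.sum()), False, "component fit did not converge")

    extracted = {
        "sd": slope(m1, -1),  # b1
        "sd_given_b": slope(m2, -2),  # b3
        "bd_given_s": slope(m2, -1),  # b2
        "sb_given_d": slope(m3, -2),  # b5
    }
    if any(v is None for v in extracted.values()):
        return CohortTrioTests({}, int(rows.sum()), False, "degenerate slope standard error")
    return CohortTrioTests(tests=extracted, n=int(rows.sum()), converged=True)


def meta_combine_tests(
    tests1: CohortTrioTests | None,
    tests2: CohortTrioTests | None,
    n1: int | None = None,
    n2: int | None = None,
    method: str = "sample-size",
) -> TrioTestBattery:
    """Meta-combine the per-cohort batteries with the pQTL signed-Z scheme.

    When one cohort is missing or unusable, the other cohort's p-values
    are used directly and the battery is flagged single-cohort.
    """
    usable1 = tests1 is not None and tests1.converged
    usable2 = tests2 is not None and tests2.converged
    if not usable1 and not usable2:
        raise ValueError("no usable cohort fits to combine")
    if usable1 and usable2:
        m1 = n1 if n1 is not None else tests1.n
        m2 = n2 if n2 is not None else tests2.n
        meta_p, meta_z, s1, s2 = {}, {}, {}, {}
        for key in TEST_KEYS:
            b1, p1 = tests1.tests[key]
            b2, p2 = tests2.tests[key]
            Z, mp = stouffer_meta(signed_z(p1, b1), m1, signed_z(p2, b2), m2, method=method)
            meta_p[key], meta_z[key] = mp, Z
            s1[key], s2[key] = float(np.sign(b1)), float(np.sign(b2))
        return TrioTestBattery(meta_p, meta_z, s1, s2, single_cohort=False)
    only = tests1 if usable1 else tests2
    meta_p = {k: float(only.tests[k][1]) for k in TEST_KEYS}
    meta_z = {k: signed_z(only.tests[k][1], only.tests[k][0]) for k in TEST_KEYS}
    signs = {k: float(np.sign(only.tests[k][0])) for k in TEST_KEYS}
    empty = {k: float("nan") for k in TEST_KEYS}
    return TrioTestBattery(
        meta_p, meta_z,
        signs if usable1 else empty,
        signs if usable2 else empty,
        single_cohort=True,
    )


# significance pattern over (sd, sd_given_b, bd_given_s, sb_given_d) -> category;
# each row is the d-separation signature of the corresponding directed model
_DECISION_TABLE = {
    (True, False, True, True): "causal",
    (True, True, True, False): "reactive",
    (True, True, False, True): "independent",
    (False, True, True, True): "collide",
    (True, True, True, True): "complete",
}


def classify_trio(battery: TrioTestBattery, alpha: float = TRIO_ALPHA) -> str:
    """Map the battery's significance pattern at ``alpha`` to a category.

    A slope is "dependent" when its meta-p < alpha. Patterns matching no
    model signature return "other". Pure function of the battery.
    """
    pattern = tuple(bool(battery.meta_p[k] < alpha) for k in TEST_KEYS)
    return _DECISION_TABLE.get(pattern, "other")


def classify_trio_full(
    snp: str,
    biomarker: str,
    phenotype: str,
    tests1: CohortTrioTests | None,
    tests2: CohortTrioTests | None,
    n1: int | None = None,
    n2: int | None = None,
    alpha: float = TRIO_ALPHA,
) -> TrioClassification:
    """Convenience wrapper: combine cohorts and classify in one step."""
    battery = meta_combine_tests(tests1, tests2, n1, n2)
    return TrioClassification(
        snp=snp,
        biomarker=biomarker,
        phenotype=phenotype,
        battery=battery,
        category=classify_trio(battery, alpha),
        alpha=alpha,
    )
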