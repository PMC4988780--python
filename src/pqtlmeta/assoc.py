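"""Per-cohort association engines.

Three regression engines share one fit container: ordinary least squares
(closed-form normal equations), a left-censored Gaussian (tobit) maximum
likelihood fit optimized in (beta, log sigma), and logistic regression
(delegated to statsmodels' Newton MLE). Inference is Wald throughout:
z = beta/se and p = 2*Phi(-|z|).

``scan_analyte`` applies the analyte's triaged engine to every variant of
a genotype matrix with the cohort covariate design; for linear-mode
analytes with complete dosages the scan is vectorized via the
Frisch-Waugh-Lovell residual regression, which is algebraically identical
to refitting the full model per variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import qr as scipy_qr
from scipy.optimize import minimize
from scipy.special import log_ndtr, ndtr
from scipy.stats import norm

from .prep import PreparedAnalyte
from .types import CovariateTable, GenotypeMatrix, CELL_COUNT_COLUMNS

__all__ = [
    "RegressionFit",
    "AssociationResult",
    "build_design",
    "ols_fit",
    "tobit_fit",
    "logistic_fit",
    "wald_p",
    "scan_analyte",
    "results_to_frame",
]


@dataclass
class RegressionFit:
    """One fitted regression: coefficients, Wald SEs, scale and likelihood."""

    params: np.ndarray
    se: np.ndarray
    scale: float  # residual SD (ols) or sigma-hat (tobit); NaN for logistic
    loglik: float
    n_used: int
    converged: bool
    model: str  # "ols" | "tobit" | "logistic"


@dataclass
class AssociationResult:
    """Association of one variant with one analyte or phenotype in one cohort."""

    variant_id: str
    chromosome: str
    position: int
    analyte_id: str
    cohort: str
    model: str
    beta: float
    se: float
    z: float
    p: float
    n_used: int
    flag: str = ""


def wald_p(z) -> np.ndarray | float:
    """Two-sided Wald p-value, p = 2*Phi(-|z|)."""
    return 2.0 * ndtr(-np.abs(z))


def build_design(
    covariates: CovariateTable,
    genotype_pcs: np.ndarray | None = None,
    biomarker_pc: np.ndarray | None = None,
    cell_counts: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Covariate design matrix with intercept.

    Site enters as one-hot indicators with the first alphabetical level as
    reference (omitted entirely when there is a single site); genotype PCs
    and the biomarker PC1 are appended when provided.
    """
    df = covariates.data
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    levels = sorted(df["site"].astype(str).unique())
    for lev in levels[1:]:
        cols.append((df["site"].astype(str) == lev).to_numpy(dtype=float))
        names.append(f"site[{lev}]")
    for c in ("sex", "age", "bmi", "pack_years", "current_smoker"):
        cols.append(df[c].to_numpy(dtype=float))
        names.append(c)
    if cell_counts:
        missing = [c for c in CELL_COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cell-count columns not available: {missing}")
        for c in CELL_COUNT_COLUMNS:
            cols.append(df[c].to_numpy(dtype=float))
            names.append(c)
    if genotype_pcs is not None:
        pcs = np.atleast_2d(np.asarray(genotype_pcs, dtype=float))
        if pcs.shape[0] != n:
            pcs = pcs.T
        for j in range(pcs.shape[1]):
            cols.append(pcs[:, j])
            names.append(f"geno_pc{j + 1}")
    if biomarker_pc is not None:
        cols.append(np.asarray(biomarker_pc, dtype=float))
        names.append("biomarker_pc1")
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# OLS


def _independent_columns(X: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (pivoted QR)."""
    _, r, piv = scipy_qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return np.sort(piv[:rank])


def ols_fit(y: np.ndarray, X: np.ndarray) -> RegressionFit:
    """Least squares with classical Wald SEs, sigma^2 = RSS/(n - p).

    Rows with any missing value are dropped; aliased (collinear) columns
    are dropped with a warning and carry NaN coefficients.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    rows = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[rows], X[rows]
    n, p_all = X.shape
    keep = _independent_columns(X)
    if keep.size < p_all:
        warnings.warn(f"dropping {p_all - keep.size} aliased design columns", stacklevel=2)
    Xk = X[:, keep]
    p = Xk.shape[1]
    if n <= p:
        raise ValueError(f"n={n} <= {p} design columns")
    beta_k, _, _, _ = np.linalg.lstsq(Xk, y, rcond=None)
    resid = y - Xk @ beta_k
    rss = float(resid @ resid)
    sigma2 = rss / (n - p)
    xtx_inv = np.linalg.inv(Xk.T @ Xk)
    se_k = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    params = np.full(p_all, np.nan)
    se = np.full(p_all, np.nan)
    params[keep] = beta_k
    se[keep] = se_k
    sigma = np.sqrt(sigma2)
    loglik = float(
        -0.5 * n * np.log(2 * np.pi) - n * np.log(sigma if sigma > 0 else 1.0)
        - 0.5 * (rss / sigma2 if sigma2 > 0 else 0.0)
    )
    return RegressionFit(params, se, sigma, loglik, n, True, "ols")


# ---------------------------------------------------------------------------
# tobit (left-censored Gaussian MLE)


def _tobit_nll_grad(theta, y, X, c, cens):
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    xb = X @ beta
    nll = 0.0
    grad_beta = np.zeros(X.shape[1])
    grad_ls = 0.0

    unc = ~cens
    if unc.any():
        r = (y[unc] - xb[unc]) / sigma
        nll += float(0.5 * (r @ r) + unc.sum() * (log_sigma + 0.5 * np.log(2 * np.pi)))
        grad_beta += -(X[unc].T @ r) / sigma
        grad_ls += float(unc.sum() - r @ r)
    if cens.any():
        a = (c - xb[cens]) / sigma
        log_phi = log_ndtr(a)
        nll += float(-log_phi.sum())
        mills = np.exp(norm.logpdf(a) - log_phi)  # phi(a)/Phi(a), stable
        grad_beta += (X[cens].T @ mills) / sigma
        grad_ls += float(mills @ a)
    return nll, np.append(grad_beta, grad_ls)


def tobit_fit(
    y: np.ndarray,
    X: np.ndarray,
    c: float,
    censored_mask: np.ndarray,
    max_iter: int = 200,
    grad_tol: float = 1e-6,
) -> RegressionFit:
    """Left-censored Gaussian MLE maximized in (beta, log sigma).

    The log-likelihood sums the normal density over uncensored rows and
    log Phi((c - x*beta)/sigma) over censored rows. Quasi-Newton (BFGS)
    with the analytic gradient; SEs come from the inverse observed
    information (numerical Hessian of the negative log-likelihood at the
    optimum). The fit is flagged non-converged when the final gradient
    norm exceeds ``grad_tol`` or sigma collapses toward zero.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    cens = np.asarray(censored_mask, dtype=bool)
    rows = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X, cens = y[rows], X[rows], cens[rows]
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} <= {p} design columns")
    if (~cens).sum() == 0:
        raise ValueError("all observations censored")
    if y[~cens].min() <= c:
        raise ValueError("truncation value c must lie below all uncensored values")

    start = ols_fit(y, X)
    beta0 = np.where(np.isfinite(start.params), start.params, 0.0)
    sigma0 = start.scale if start.scale > 1e-8 else 1.0
    theta0 = np.append(beta0, np.log(sigma0))

    def hessian(theta):
        # observed information: central differences of the analytic gradient
        k = theta.size
        H = np.empty((k, k))
        for j in range(k):
            h = 1e-5 * (1.0 + abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            _, gp = _tobit_nll_grad(tp, y, X, c, cens)
            _, gm = _tobit_nll_grad(tm, y, X, c, cens)
            H[:, j] = (gp - gm) / (2 * h)
        return 0.5 * (H + H.T)

    with np.errstate(over="ignore", invalid="ignore"):
        res = minimize(
            _tobit_nll_grad,
            theta0,
            args=(y, X, c, cens),
            jac=True,
            method="BFGS",
            options={"gtol": 1e-9, "maxiter": max_iter},
        )
    theta = res.x
    nll, grad = _tobit_nll_grad(theta, y, X, c, cens)
    # Newton polish: BFGS can stall on precision loss with a gradient a few
    # orders above tolerance; damped Newton steps finish the job
    for _ in range(25):
        if np.linalg.norm(grad, np.inf) < 0.1 * grad_tol:
            break
        try:
            step = np.linalg.solve(hessian(theta), grad)
        except np.linalg.LinAlgError:
            break
        t = 1.0
        for _ in range(30):
            nll_new, grad_new = _tobit_nll_grad(theta - t * step, y, X, c, cens)
            if np.isfinite(nll_new) and nll_new <= nll + 1e-12:
                theta, nll, grad = theta - t * step, nll_new, grad_new
                break
            t *= 0.5
        else:
            break
    sigma = float(np.exp(theta[-1]))
    converged = bool(np.linalg.norm(grad, np.inf) < grad_tol) and sigma > 1e-8
    H = hessian(theta)
    try:
        cov = np.linalg.inv(H)
        se_theta = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se_theta = np.full(k, np.nan)
        converged = False
    return RegressionFit(
        params=theta[:-1],
        se=se_theta[:-1],
        scale=sigma,
        loglik=float(-nll),
        n_used=n,
        converged=converged,
        model="tobit",
    )


# ---------------------------------------------------------------------------
# logistic


def logistic_fit(y01: np.ndarray, X: np.ndarray, max_iter: int = 100) -> RegressionFit:
    """Logistic regression MLE (Newton-Raphson via statsmodels), Wald SEs.

    Perfect separation (diverging coefficients) is flagged as
    non-converged rather than raised.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    y = np.asarray(y01, dtype=float)
    X = np.asarray(X, dtype=float)
    rows = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[rows], X[rows]
    classes = set(np.unique(y))
    if not classes <= {0.0, 1.0}:
        raise ValueError("response must be coded 0/1")
    if len(classes) < 2:
        raise ValueError("both outcome classes must be present")
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(method="newton", maxiter=max_iter, disp=0)
        converged = bool(fit.mle_retvals.get("converged", False))
        params, bse, llf = np.asarray(fit.params), np.asarray(fit.bse), float(fit.llf)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        params = np.full(X.shape[1], np.nan)
        bse = np.full(X.shape[1], np.nan)
        llf = np.nan
        converged = False
    if converged and (np.abs(params).max() > 1e3 or not np.isfinite(bse).all()):
        converged = False  # separation heuristic: runaway coefficients
    return RegressionFit(params, bse, np.nan, llf, len(y), converged, "logistic")


# ---------------------------------------------------------------------------
# genome-wide scan


def _result(v, analyte_id, cohort, model, beta, se, n_used, flag=""):
    if se > 0 and np.isfinite(se):
        z = beta / se
        p = float(wald_p(z))
    else:
        z, p = 0.0, 1.0
    return AssociationResult(
        variant_id=v.variant_id,
        chromosome=v.chromosome,
        position=v.position,
        analyte_id=analyte_id,
        cohort=cohort,
        model=model,
        beta=float(beta),
        se=float(se),
        z=float(z),
        p=p,
        n_used=int(n_used),
        flag=flag,
    )


def _monomorphic_result(v, analyte_id, cohort, model, n_used):
    return AssociationResult(
        variant_id=v.variant_id,
        chromosome=v.chromosome,
        position=v.position,
        analyte_id=analyte_id,
        cohort=cohort,
        model=model,
        beta=0.0,
        se=np.nan,
        z=0.0,
        p=1.0,
        n_used=int(n_used),
        flag="monomorphic",
    )


def scan_analyte(
    prepared: PreparedAnalyte,
    genotypes: GenotypeMatrix,
    X: np.ndarray,
    cohort: str = "",
) -> list[AssociationResult]:
    """One association result per variant for one prepared analyte.

    The design is [covariates X | dosage]; the reported beta is the
    additive dosage slope. Complete cases are taken per variant on the
    dosage; monomorphic-in-sample variants get beta=0, p=1 and a flag.
    Non-converged tobit fits are flagged ``nonconverged`` (to be excluded
    downstream).
    """
    y = np.asarray(prepared.y, dtype=float)
    D = genotypes.dosage
    base_rows = np.isfinite(y) & np.isfinite(X).all(axis=1)
    results: list[AssociationResult] = []

    if prepared.mode == "linear":
        yb = y[base_rows]
        Xb = X[base_rows]
        Db = D[base_rows]
        complete = np.isfinite(Db).all(axis=0)
        # FWL residual regression for the complete-dosage variants
        coef_y, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
        ry = yb - Xb @ coef_y
        idx_fast = np.flatnonzero(complete)
        if idx_fast.size:
            G = Db[:, idx_fast]
            coef_g, *_ = np.linalg.lstsq(Xb, G, rcond=None)
            Rg = G - Xb @ coef_g
            gg = np.einsum("ij,ij->j", Rg, Rg)
            gy = ry @ Rg
            df = yb.size - Xb.shape[1] - 1
            for pos, j in enumerate(idx_fast):
                v = genotypes.variants[j]
                if gg[pos] <= 1e-12 or np.nanstd(G[:, pos]) == 0:
                    results.append(
                        _monomorphic_result(v, prepared.analyte_id, cohort, "ols", yb.size)
                    )
                    continue
                beta = gy[pos] / gg[pos]
                rss = float(ry @ ry) - beta * gy[pos]
                sigma2 = max(rss, 0.0) / df
                se = np.sqrt(sigma2 / gg[pos])
                results.append(
                    _result(v, prepared.analyte_id, cohort, "ols", beta, se, yb.size)
                )
        for j in np.flatnonzero(~complete):
            v = genotypes.variants[j]
            rows = base_rows & np.isfinite(D[:, j])
            g = D[rows, j]
            if g.size < X.shape[1] + 2 or g.std() == 0:
                results.append(
                    _monomorphic_result(v, prepared.analyte_id, cohort, "ols", g.size)
                )
                continue
            fit = ols_fit(y[rows], np.column_stack([X[rows], g]))
            results.append(
                _result(
                    v, prepared.analyte_id, cohort, "ols",
                    fit.params[-1], fit.se[-1], fit.n_used,
                )
            )
        results.sort(key=lambda r: genotypes.variant_index(r.variant_id))
        return results

    # tobit mode: per-variant censored fits
    for j, v in enumerate(genotypes.variants):
        rows = base_rows & np.isfinite(D[:, j])
        g = D[rows, j]
        if g.size < X.shape[1] + 2 or g.std() == 0:
            results.append(
                _monomorphic_result(v, prepared.analyte_id, cohort, "tobit", g.size)
            )
            continue
        fit = tobit_fit(
            y[rows], np.column_stack([X[rows], g]), prepared.c, prepared.censored_mask[rows]
        )
        flag = "" if fit.converged else "nonconverged"
        results.append(
            _result(
                v, prepared.analyte_id, cohort, "tobit",
                fit.params[-1], fit.se[-1], fit.n_used, flag,
            )
        )
    return results


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Canonical association table layout (see io.ASSOCIATION_COLUMNS)."""
    return pd.DataFrame(
        [
            (
                r.variant_id, r.chromosome, r.position, r.analyte_id, r.cohort,
                r.model, r.n_used, r.beta, r.se, r.z, r.p, r.flag,
            )
            for r in results
        ],
        columns=[
            "variant_id", "chr", "pos", "analyte", "cohort", "model",
            "n", "beta", "se", "z", "p", "flag",
        ],
    )
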