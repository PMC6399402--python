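"""Per-gene burden and SKAT tests on independent rare variants.

Two complementary tests run per gene, both adjusted for stratification
covariates (normally 10 principal components):

* the case-control **burden test** — logistic regression of status on the
  per-individual sum of minor alleles across the gene's rare variants;
  a significant aggregate odds ratio above / below 1 reads as risk /
  protective rare variation acting in one direction;
* **SKAT** — a variance-component score test whose statistic
  ``Q = (y - mu)' G W G' (y - mu)`` is distributed, under the logistic
  null, as a weighted mixture of 1-df chi-squares with weights equal to
  the nonzero eigenvalues of ``W^{1/2} G' P0 G W^{1/2}``; it retains
  power when effects within the gene point in both directions.

Mixture p-values come from the Liu-Tang-Zhang moment-matching
approximation, cross-checked by Imhof characteristic-function
integration for small p.  Logistic fits use an in-package IRLS solver
(validated against statsmodels in the test suite) so that the
permutation-based multiple-testing correction, which re-runs the
identical test tens of thousands of times, stays fast; quasi-complete
separation falls back to Firth's penalized likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import integrate
from scipy.special import expit
from scipy.stats import beta as beta_dist
from scipy.stats import chi2, ncx2, norm

from raregene.containers import GeneRegion, GenotypeMatrix
from raregene.results import BurdenResult, GeneAssociationResult, SkatResult
from raregene.varclass import column_macs, column_mafs

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# logistic fitting
# ---------------------------------------------------------------------------

class SeparationError(RuntimeError):
    """Raised when ordinary ML logistic fitting diverges."""


def logit_fit(
    x: np.ndarray, y: np.ndarray, max_iter: int = 60, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood logistic regression by Newton-Raphson (IRLS).

    Returns ``(beta, cov)``.  Raises :class:`SeparationError` when the
    fit diverges (quasi-complete separation).
    """
    n, p = x.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = x @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = x.T @ (y - mu)
        hess = (x * w[:, None]).T @ x
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular information matrix") from exc
        beta = beta + step
        if np.abs(beta).max() > 50.0:
            raise SeparationError("coefficients diverging")
        if np.abs(step).max() < tol:
            cov = np.linalg.inv(hess)
            return beta, cov
    raise SeparationError("IRLS did not converge")


def firth_logit_fit(
    x: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Firth bias-reduced logistic regression.

    The score is modified by the hat-matrix diagonal,
    ``U*(beta) = X'(y - mu + h (1/2 - mu))``, which keeps estimates
    finite under separation.  Returns ``(beta, cov)``.
    """
    n, p = x.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        mu = expit(x @ beta)
        w = mu * (1.0 - mu)
        xw = x * np.sqrt(w)[:, None]
        info = xw.T @ xw
        info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", xw, info_inv, xw)
        grad = x.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ grad
        # damped steps for stability far from the optimum
        if np.abs(step).max() > 5.0:
            step = step * 5.0 / np.abs(step).max()
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    mu = expit(x @ beta)
    w = mu * (1.0 - mu)
    cov = np.linalg.pinv((x * w[:, None]).T @ x)
    return beta, cov


@dataclass
class NullModel:
    """Covariates-only logistic null: fitted probabilities and residuals."""

    x: np.ndarray  # design (intercept + covariates)
    mu: np.ndarray  # fitted case probabilities, in (0, 1)
    y: np.ndarray

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.mu


def fit_null_model(status: np.ndarray, covariates: np.ndarray | None = None) -> NullModel:
    """Fit the covariates-only logistic model used by both tests."""
    y = np.asarray(status, dtype=float)
    n = y.size
    x = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        x = np.column_stack([x, np.asarray(covariates, dtype=float)])
    try:
        beta, _ = logit_fit(x, y)
    except SeparationError:
        beta, _ = firth_logit_fit(x, y)
    mu = expit(x @ beta)
    eps = 1e-10
    return NullModel(x=x, mu=np.clip(mu, eps, 1 - eps), y=y)


# ---------------------------------------------------------------------------
# gene regions and burden scores
# ---------------------------------------------------------------------------

def assign_variants(
    regions: Sequence[GeneRegion], variants, log_empty: bool = True
) -> list[GeneRegion]:
    """Assign variant indices to every gene whose body contains them.

    A variant inside two overlapping genes is assigned to both.  The
    imputation buffer is NOT used here: the test set is the gene body.
    """
    chrom = variants["chrom"].to_numpy(dtype=str)
    pos = variants["pos"].to_numpy(dtype=int)
    out = []
    for region in regions:
        mask = (chrom == region.chrom) & (pos >= region.start) & (pos <= region.end)
        idx = np.flatnonzero(mask)
        if idx.size == 0 and log_empty:
            logger.info("gene %s has no assigned variants", region.gene_id)
        out.append(region.with_variants(idx))
    return out


def minor_oriented(dosages: np.ndarray) -> np.ndarray:
    """Orient each dosage column to count minor alleles; missing -> 0.

    A column whose ALT frequency exceeds 0.5 is flipped (2 - dosage) on
    its called entries; ties keep the ALT orientation.
    """
    sub = np.array(dosages, dtype=float)
    called = ~np.isnan(sub)
    flip = np.nansum(sub, axis=0) > called.sum(axis=0)  # ALT freq > 0.5
    sub[:, flip] = 2.0 - sub[:, flip]
    return np.nan_to_num(sub, nan=0.0)


def burden_score(gene_dosages: np.ndarray) -> np.ndarray:
    """Per-sample sum of minor-allele dosages over a gene's variants."""
    if gene_dosages.shape[1] == 0:
        return np.zeros(gene_dosages.shape[0])
    return minor_oriented(gene_dosages).sum(axis=1)


# ---------------------------------------------------------------------------
# burden test
# ---------------------------------------------------------------------------

def burden_score_test_p(scores: np.ndarray, null_model: NullModel) -> float:
    """Efficient-score-test p-value for the burden coefficient.

    Under the covariates-only logistic null, the score
    ``U = s~' (y - mu)`` with ``s~`` the V-weighted projection of the
    burden score off the covariate design has variance ``s' P0 s``;
    ``U^2 / V`` is 1-df chi-square.  Exactly the statistic re-run per
    replicate by the permutation correction.
    """
    s = np.asarray(scores, dtype=float)
    x, mu = null_model.x, null_model.mu
    v = mu * (1.0 - mu)
    xtvx = (x * v[:, None]).T @ x
    s_t = s - x @ np.linalg.solve(xtvx, (x * v[:, None]).T @ s)
    u = float(s_t @ null_model.residuals)
    var = float(s_t @ (v * s_t))
    if var <= 0.0:
        return 1.0
    return float(chi2.sf(u * u / var, df=1))


def burden_test(
    scores: np.ndarray,
    status: np.ndarray,
    covariates: np.ndarray | None = None,
    n_markers: int = 0,
    nmaf_cases: int = 0,
    nmaf_controls: int = 0,
    p_type: str = "score",
    null_model: NullModel | None = None,
) -> BurdenResult:
    """Logistic regression of case status on the gene burden score.

    The odds ratio and its 95% CI come from the ML (or, under
    separation, Firth penalized) fit; the default p-value is the
    covariate-adjusted score test, which stays calibrated for sparse
    burdens where the Wald p is conservative (``p_type`` selects
    "score", "wald" or "lrt").  Constant scores yield an untestable
    result.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(status, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("both statuses must be present")
    if np.ptp(scores) == 0.0:
        return BurdenResult(
            beta=np.nan, se=np.nan, or_=np.nan, ci95_lo=np.nan, ci95_hi=np.nan,
            p_raw=np.nan, n_markers=n_markers, nmaf_cases=nmaf_cases,
            nmaf_controls=nmaf_controls, method="none", testable=False,
        )
    n = y.size
    x = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        x = np.column_stack([x, np.asarray(covariates, dtype=float)])
    x0 = x
    x = np.column_stack([x, scores])
    method = "ml"
    try:
        beta, cov = logit_fit(x, y)
    except SeparationError:
        beta, cov = firth_logit_fit(x, y)
        method = "firth"
    b = float(beta[-1])
    se = float(np.sqrt(cov[-1, -1]))
    if p_type == "wald":
        p = float(2.0 * norm.sf(abs(b / se)))
    elif p_type == "lrt":
        try:
            beta0, _ = logit_fit(x0, y)
        except SeparationError:
            beta0, _ = firth_logit_fit(x0, y)
        ll1 = _log_likelihood(x, y, beta)
        ll0 = _log_likelihood(x0, y, beta0)
        p = float(chi2.sf(2.0 * (ll1 - ll0), df=1))
    elif p_type == "score":
        if null_model is None:
            null_model = fit_null_model(y, covariates)
        p = burden_score_test_p(scores, null_model)
    else:
        raise ValueError(f"unknown p_type {p_type!r}")
    return BurdenResult(
        beta=b,
        se=se,
        or_=float(np.exp(b)),
        ci95_lo=float(np.exp(b - 1.959963984540054 * se)),
        ci95_hi=float(np.exp(b + 1.959963984540054 * se)),
        p_raw=max(p, 1e-300),
        n_markers=n_markers,
        nmaf_cases=nmaf_cases,
        nmaf_controls=nmaf_controls,
        method=f"{method}+{p_type}",
    )


def _log_likelihood(x: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    mu = np.clip(expit(x @ beta), 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


# ---------------------------------------------------------------------------
# SKAT
# ---------------------------------------------------------------------------

def beta_maf_weights(mafs: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """SKAT's conventional Beta(MAF; a, b) density weights."""
    return beta_dist.pdf(np.clip(np.asarray(mafs, dtype=float), 1e-12, 1.0), a, b)


def mixture_chi2_sf(q: float, lambdas: np.ndarray, method: str = "auto") -> tuple[float, str]:
    """Upper-tail probability of ``sum_k lambda_k chi2_1`` at ``q``.

    ``method``: "liu" (moment matching), "imhof" (numeric
    characteristic-function integration) or "auto" (Liu, re-evaluated by
    Imhof when the Liu p-value falls below 0.01).
    """
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 1e-10 * max(lam.max(initial=0.0), 1.0)]
    if lam.size == 0:
        raise ValueError("all eigenvalues are (numerically) zero")
    if method in ("liu", "auto"):
        p = _liu_sf(q, lam)
        if method == "liu" or p >= 0.01:
            return p, "moment-matching"
    p = _imhof_sf(q, lam)
    return p, "numeric-integration"


def _liu_sf(q: float, lam: np.ndarray) -> float:
    c1, c2, c3, c4 = (np.sum(lam**k) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        d = s1 * a**3 - a**2
        dof = a**2 - 2.0 * d
    else:
        dof = 1.0 / s2
        a = np.sqrt(dof)
        d = 0.0
    mu_q, sigma_q = c1, np.sqrt(2.0 * c2)
    mu_x, sigma_x = dof + d, np.sqrt(2.0) * a
    t = (q - mu_q) / sigma_q * sigma_x + mu_x
    if d > 0:
        p = float(ncx2.sf(t, df=dof, nc=d))
    else:
        p = float(chi2.sf(t, df=dof))
    return min(max(p, 1e-300), 1.0)


def _imhof_sf(q: float, lam: np.ndarray) -> float:
    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        rho = np.exp(0.25 * np.sum(np.log1p((lam * u) ** 2)))
        return np.sin(theta) / (u * rho)

    import warnings

    with warnings.catch_warnings():
        # the integrand is oscillatory; quad's subdivision warning is benign
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, 0.0, np.inf, limit=800)
    p = 0.5 + val / np.pi
    return min(max(p, 1e-300), 1.0)


def skat_test(
    gene_dosages: np.ndarray,
    null_model: NullModel,
    weights: np.ndarray | str | Callable | None = "beta:1,25",
    method: str = "auto",
    small_sample_adjust: bool = True,
    n_perm: int = 100_000,
    seed: int = 0,
) -> SkatResult:
    """SKAT variance-component score test for one gene.

    ``gene_dosages`` is the samples x variants dosage submatrix (any
    orientation; the statistic is invariant to flipping a column once
    weights are computed from MAF).  ``weights`` may be "beta:a,b",
    "flat", an explicit per-variant array, or a callable of the MAF
    vector.  ``method`` is "auto" (moment matching, re-evaluated by
    Imhof integration below p = 0.01), "liu", "imhof" or "permutation"
    (seeded residual permutation with ``n_perm`` draws).

    With ``small_sample_adjust`` the mixture null is rescaled to the
    exact variance of Q under independent centered-Bernoulli residuals
    (the normal-score approximation overstates Var(Q) for binary
    traits, making unadjusted p-values conservative at modest n).
    """
    g = np.asarray(gene_dosages, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    if g.shape[1] == 0:
        return SkatResult(q_stat=np.nan, p_raw=np.nan, testable=False)
    mafs = column_mafs(g)
    g = minor_oriented(g)
    w = _resolve_weights(weights, mafs)
    r = null_model.residuals
    gw = g * w[None, :]
    s = r @ gw
    q = float(s @ s)
    v = null_model.mu * (1.0 - null_model.mu)
    x = null_model.x
    if method == "permutation":
        p = _skat_permutation_sf(q, gw, r, n_perm, seed)
        return SkatResult(q_stat=q, p_raw=p, p_method="permutation")
    # G~ = G W projected off the covariates (V-weighted); then
    # G~' V G~ = W^1/2 G' P0 G W^1/2 up to the weight similarity
    xtvx = (x * v[:, None]).T @ x
    gt = gw - x @ np.linalg.solve(xtvx, (x * v[:, None]).T @ gw)
    a = (gt * v[:, None]).T @ gt
    lam = np.linalg.eigvalsh((a + a.T) / 2.0)
    if lam.max(initial=0.0) <= 1e-12:
        return SkatResult(q_stat=q, p_raw=np.nan, testable=False)
    lam = lam[lam > 1e-12 * lam.max()]
    q_eval = q
    if small_sample_adjust:
        mu_q = float(lam.sum())
        var_mix = 2.0 * float((lam**2).sum())
        # exact 4th-moment correction: m4 - 3 v^2 = v (1 - 6v) per sample
        diag_a = (gt**2).sum(axis=1)
        var_exact = var_mix + float((diag_a**2 * v * (1.0 - 6.0 * v)).sum())
        if var_exact > 0:
            q_eval = mu_q + (q - mu_q) * np.sqrt(var_mix / var_exact)
    p, p_method = mixture_chi2_sf(q_eval, lam, method=method)
    return SkatResult(q_stat=q, p_raw=p, eigenvalues=lam, p_method=p_method)


def _skat_permutation_sf(
    q: float, gw: np.ndarray, r: np.ndarray, n_perm: int, seed: int
) -> float:
    """Upper-tail p of Q under seeded residual permutation (chunked)."""
    rng = np.random.default_rng(seed)
    n = r.size
    exceed = 0
    chunk = max(1, min(n_perm, 20_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((b, n)), axis=1)
        qs = ((r[idx] @ gw) ** 2).sum(axis=1)
        exceed += int((qs >= q).sum())
        done += b
    return (exceed + 1.0) / (n_perm + 1.0)


def _resolve_weights(weights, mafs: np.ndarray) -> np.ndarray:
    if weights is None or weights == "flat":
        return np.ones(mafs.size)
    if callable(weights):
        return np.asarray(weights(mafs), dtype=float)
    if isinstance(weights, str):
        if weights.startswith("beta:"):
            a, b = (float(v) for v in weights[5:].split(","))
            return beta_maf_weights(mafs, a, b)
        raise ValueError(f"unknown weight spec {weights!r}")
    w = np.asarray(weights, dtype=float)
    if w.size != mafs.size:
        raise ValueError("weight vector length mismatch")
    return w


# ---------------------------------------------------------------------------
# all-genes driver
# ---------------------------------------------------------------------------

def run_all_genes(
    geno: GenotypeMatrix,
    regions: Sequence[GeneRegion],
    covariates: np.ndarray | None = None,
    weights: np.ndarray | str | None = "beta:1,25",
    maf_max: float = 0.01,
) -> list[GeneAssociationResult]:
    """Run burden + SKAT for every gene on its rare polymorphic variants.

    ``geno`` should already be restricted to the pruned independent
    marker set; variants above ``maf_max`` or monomorphic are excluded
    per gene.  Genes with zero testable markers are skipped with a log
    entry.  Raw p-values only; genomic-control and empirical corrections
    are applied downstream.
    """
    status = geno.status
    null = fit_null_model(status, covariates)
    cases = status == 1
    macs = column_macs(geno.dosages)
    mafs = column_mafs(geno.dosages)
    rare_ok = (macs > 0) & (mafs <= maf_max)
    results: list[GeneAssociationResult] = []
    for region in regions:
        idx = region.variant_idx[rare_ok[region.variant_idx]]
        if idx.size == 0:
            logger.info("gene %s skipped: no polymorphic rare variants", region.gene_id)
            continue
        sub = geno.dosages[:, idx]
        minor = minor_oriented(sub)
        scores = minor.sum(axis=1)
        burden = burden_test(
            scores,
            status,
            covariates,
            n_markers=int(idx.size),
            nmaf_cases=int(round(minor[cases].sum())),
            nmaf_controls=int(round(minor[~cases].sum())),
            null_model=null,
        )
        skat = skat_test(sub, null, weights)
        results.append(GeneAssociationResult(region.gene_id, burden, skat))
    return results
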