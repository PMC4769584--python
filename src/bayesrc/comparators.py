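"""Comparator methods: single-SNP GWAS and SNP-BLUP / GBLUP.

GWAS replaces the whole-genome term Wv with one SNP regression at a time,
keeping the fixed effects, the reliability weighting and (optionally) a
pedigree polygenic background. SNP-BLUP assigns every variant an effect from
one common normal distribution N(0, sigma2_g/m); it is mathematically
equivalent to GBLUP with G = WW'/m and serves as the architectural contrast
to the mixture model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .genodata import PhenotypeTable, StandardizedDesign
from .pedigree import AMatrix


@dataclass
class GwasResult:
    table: pd.DataFrame  # variant_id, beta, se, stat, p, neglog10p


@dataclass
class GblupResult:
    vbar: np.ndarray
    b: np.ndarray
    sigma2_v: float
    sigma2_e: float
    h2: float


def _design(pheno: PhenotypeTable):
    return (
        np.asarray(pheno.y, float),
        np.asarray(pheno.X, float),
        np.asarray(pheno.weights, float),
    )


def gwas_single_snp(
    pheno: PhenotypeTable,
    W,
    A: AMatrix | None = None,
    h2: float | None = None,
    reml: bool = False,
    variant_ids: list | None = None,
) -> GwasResult:
    """Single-SNP regressions of phenotype on genotype.

    Without a pedigree this is weighted least squares with the fixed-effect
    covariates projected out and a t test (df = n - p - 1). With ``A`` the
    model adds a polygenic background N(0, A sigma2_a); variance components
    come from ``h2`` (fixed) or REML, and Wald tests use the normal
    approximation. Monomorphic variants yield NA with a warning.
    """
    W = W.W if isinstance(W, StandardizedDesign) else np.asarray(W, float)
    y, X, w = _design(pheno)
    n, m = W.shape
    if variant_ids is None:
        variant_ids = [f"var{j}" for j in range(m)]

    if A is None:
        sw = np.sqrt(w)
        ys = sw * y
        Xs = sw[:, None] * X
        Ws = sw[:, None] * W
        Q, _ = np.linalg.qr(Xs)
        yt = ys - Q @ (Q.T @ ys)
        Wt = Ws - Q @ (Q.T @ Ws)
        sxx = (Wt * Wt).sum(axis=0)
        ok = sxx > 0
        beta = np.full(m, np.nan)
        se = np.full(m, np.nan)
        pval = np.full(m, np.nan)
        df = n - X.shape[1] - 1
        syy = float(yt @ yt)
        beta[ok] = (Wt[:, ok].T @ yt) / sxx[ok]
        rss = syy - beta[ok] ** 2 * sxx[ok]
        s2 = rss / df
        se[ok] = np.sqrt(s2 / sxx[ok])
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = beta[ok] / se[ok]
        pval[ok] = 2.0 * stats.t.sf(np.abs(tstat), df)
        stat = np.full(m, np.nan)
        stat[ok] = tstat
        if not ok.all():
            import warnings

            warnings.warn(f"{int((~ok).sum())} singular (monomorphic) variants -> NA")
    else:
        Amat = A.reorder(pheno.ids).values if list(A.ids) != list(pheno.ids) else A.values
        if reml:
            s2a, s2e = reml_variance_components(y, X, Amat, weights=w)
        else:
            if h2 is None:
                raise ValueError("supply h2 or set reml=True for the polygenic model")
            var_p = _adjusted_variance(y, X, w)
            s2a, s2e = h2 * var_p, (1 - h2) * var_p
        V = s2a * Amat + s2e * np.diag(1.0 / w)
        Vinv = np.linalg.inv(V)
        VX = Vinv @ X
        P = Vinv - VX @ np.linalg.solve(X.T @ VX, VX.T)
        Py = P @ y
        xPy = W.T @ Py
        xPx = np.einsum("ij,ij->j", W, P @ W)
        ok = xPx > 0
        beta = np.full(m, np.nan)
        se = np.full(m, np.nan)
        pval = np.full(m, np.nan)
        beta[ok] = xPy[ok] / xPx[ok]
        se[ok] = np.sqrt(1.0 / xPx[ok])
        stat = beta / se
        pval[ok] = 2.0 * stats.norm.sf(np.abs(stat[ok]))

    with np.errstate(divide="ignore"):
        neglog = -np.log10(pval)
    return GwasResult(
        table=pd.DataFrame(
            {
                "variant_id": variant_ids,
                "beta": beta,
                "se": se,
                "stat": stat,
                "p": pval,
                "neglog10p": neglog,
            }
        )
    )


def _adjusted_variance(y, X, w):
    Xw = X * w[:, None]
    b = np.linalg.solve(X.T @ Xw, Xw.T @ y)
    r = y - X @ b
    return float(np.sum(w * r * r) / np.sum(w))


def reml_variance_components(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    weights: np.ndarray | None = None,
    tol: float = 1e-6,
) -> tuple[float, float]:
    """REML estimates (sigma2_k, sigma2_e) for y = Xb + g + e, g ~ N(0, K s2k).

    The weighted model (e ~ N(0, diag(1/w) s2e)) is rotated to the
    eigenbasis of sqrt(w) K sqrt(w), where the profile restricted
    log-likelihood is a scalar function of the variance ratio, optimised to
    ``tol``.
    """
    n = y.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    sw = np.sqrt(w)
    Ks = sw[:, None] * K * sw[None, :]
    ys = sw * y
    Xs = sw[:, None] * X
    vals, U = np.linalg.eigh(Ks)
    vals = np.maximum(vals, 0.0)
    yt = U.T @ ys
    Xt = U.T @ Xs
    p = X.shape[1]

    def neg_rll(log_lam: float) -> float:
        lam = np.exp(log_lam)  # sigma2_k / sigma2_e
        d = lam * vals + 1.0
        Xd = Xt / d[:, None]
        XtVX = Xt.T @ Xd
        b = np.linalg.solve(XtVX, Xd.T @ yt)
        r = yt - Xt @ b
        ss = float(np.sum(r * r / d))
        s2e = ss / (n - p)
        ll = (
            -0.5 * np.sum(np.log(d))
            - 0.5 * (n - p) * np.log(s2e)
            - 0.5 * np.linalg.slogdet(XtVX)[1]
        )
        return -ll

    res = minimize_scalar(
        neg_rll, bounds=(-12.0, 12.0), method="bounded", options={"xatol": tol}
    )
    if not res.success:
        raise RuntimeError(f"REML failed to converge: {res}")
    lam = float(np.exp(res.x))
    d = lam * vals + 1.0
    Xd = Xt / d[:, None]
    b = np.linalg.solve(Xt.T @ Xd, Xd.T @ yt)
    r = yt - Xt @ b
    s2e = float(np.sum(r * r / d) / (n - p))
    return lam * s2e, s2e


def gblup_fit(
    pheno: PhenotypeTable,
    design,
    h2: float | None = 0.5,
    reml: bool = False,
) -> GblupResult:
    """SNP-BLUP: v̂ = (W'R⁻¹W + I sigma2_e/(sigma2_g/m))⁻¹ W'R⁻¹ ỹ.

    Fixed effects are absorbed by GLS under V = sigma2_v WW' + sigma2_e E.
    When m > n the dual (individual-level GBLUP) form is used; both forms
    agree to numerical precision. Variance components default to a fixed
    user h2 (the comparator's role is architectural contrast); REML is
    optional and requires the eigen-rotation above.
    """
    W = design.W if isinstance(design, StandardizedDesign) else np.asarray(design, float)
    y, X, w = _design(pheno)
    n, m = W.shape
    if reml:
        G = (W @ W.T) / m
        s2g, s2e = reml_variance_components(y, X, G, weights=w)
    else:
        if h2 is None:
            raise ValueError("supply h2 or set reml=True")
        var_p = _adjusted_variance(y, X, w)
        s2g, s2e = h2 * var_p, (1 - h2) * var_p
    s2v = s2g / m
    Einv = w  # E^-1 diagonal

    # GLS fixed effects under the full covariance
    V = s2v * (W @ W.T) + s2e * np.diag(1.0 / w)
    Vinv = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y) if X.shape[1] else np.zeros(0)
    yt = y - X @ b if X.shape[1] else y

    if m <= n:
        lhs = (W * Einv[:, None]).T @ W
        lhs[np.diag_indices(m)] += s2e / s2v
        vhat = np.linalg.solve(lhs, (W * Einv[:, None]).T @ yt)
    else:
        vhat = s2v * (W.T @ (Vinv @ yt))
    return GblupResult(vbar=vhat, b=b, sigma2_v=s2v, sigma2_e=s2e, h2=s2g / (s2g + s2e))
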