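"""Gibbs sampler for the BayesR / BayesRC mixture model.

Model:  y = X b + Z a + W v + e,  with
  b      fixed effects (flat prior),
  a      polygenic values, a ~ N(0, A sigma2_a) for a pedigree relationship
         matrix A (optional; omitted when no pedigree is supplied),
  v      variant effects, each drawn from a four-component normal mixture
         N(0, gamma_d * sigma2_g) with gamma = (0, 0.0001, 0.001, 0.01),
  e      residuals, e ~ N(0, E sigma2_e) with E = diag(1/w_j) encoding
         per-record reliability weights.

BayesRC: every variant belongs to an annotation class c and each class keeps
its own mixture proportions P_c with a Dirichlet prior, updated each
iteration as P_c ~ Dirichlet(alpha_c + beta_c) where beta_c counts the class
members currently in each component. BayesR is the single-class special
case and shares this exact code path.

sigma2_g is held fixed (supplied, or derived as h2 * weighted phenotypic
variance); an optional switch re-estimates it from the current variant
effects each iteration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular

from ._kernel import mixture_sweep, mixture_sweep_dosage, sweep_tables
from .genodata import (
    GenotypeMatrix,
    PhenotypeTable,
    StandardizedDesign,
    VariantClassMap,
    standardize as _standardize,
)
from .pedigree import AMatrix

logger = logging.getLogger(__name__)

N_COMP = 4
_PROP_FLOOR = 1e-300

#: default run lengths used for full-scale analyses
DEFAULT_N_ITER = 40_000
DEFAULT_BURN_IN = 20_000
DEFAULT_N_CHAINS = 5


class DivergenceError(RuntimeError):
    """Chain produced a non-finite state."""


@dataclass
class MixtureSpec:
    """Mixture-component variances and per-class Dirichlet hyperparameters.

    Component variances are ``variance_fractions`` x ``sigma2_g``; the first
    fraction must be exactly 0 (the null spike). ``dirichlet_alpha`` may be a
    length-4 vector (shared by all classes) or a C x 4 matrix.
    """

    sigma2_g: float
    variance_fractions: tuple = (0.0, 0.0001, 0.001, 0.01)
    dirichlet_alpha: np.ndarray = field(default_factory=lambda: np.ones(N_COMP))

    def __post_init__(self) -> None:
        self.dirichlet_alpha = np.asarray(self.dirichlet_alpha, dtype=np.float64)
        vf = self.variance_fractions
        if len(vf) != N_COMP or vf[0] != 0.0:
            raise ValueError("variance_fractions must be length 4 with a 0 first tier")
        if any(b < a for a, b in zip(vf, vf[1:])):
            raise ValueError("variance_fractions must be nondecreasing")
        if self.sigma2_g <= 0:
            raise ValueError("sigma2_g must be positive")
        if np.any(self.dirichlet_alpha <= 0):
            raise ValueError("Dirichlet alphas must be positive")

    def component_variances(self) -> np.ndarray:
        return np.asarray(self.variance_fractions) * self.sigma2_g

    def alpha_for(self, n_classes: int) -> np.ndarray:
        a = self.dirichlet_alpha
        if a.ndim == 1:
            return np.tile(a, (n_classes, 1))
        if a.shape != (n_classes, N_COMP):
            raise ValueError("dirichlet_alpha shape does not match class count")
        return a


@dataclass
class ChainState:
    """Current parameters of one Gibbs chain."""

    b: np.ndarray
    a: np.ndarray
    v: np.ndarray
    z: np.ndarray           # 0-based component indices, 0 = null
    P: np.ndarray           # C x 4 mixture proportions
    sigma2_a: float
    sigma2_e: float
    resid: np.ndarray


@dataclass
class PosteriorSummary:
    """Post-burn-in means for one chain (or the across-chain average)."""

    pip: np.ndarray
    vbar: np.ndarray
    class_component_counts: np.ndarray  # C x 4 mean beta counts
    proportions: np.ndarray             # C x 4 mean P_c
    sigma2_e: float
    sigma2_a: float
    b: np.ndarray
    n_post: int


@dataclass
class MultiChainSummary:
    """Across-chain average of per-chain post-burn-in means, with the
    per-chain summaries retained; spread is SD/sqrt(n_chains)."""

    chains: list
    pip: np.ndarray
    vbar: np.ndarray
    class_component_counts: np.ndarray
    proportions: np.ndarray
    sigma2_e: float
    sigma2_a: float

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def spread(self, attr: str) -> float | np.ndarray:
        vals = np.array([getattr(c, attr) for c in self.chains])
        return vals.std(axis=0, ddof=1) / np.sqrt(len(self.chains))


# ---------------------------------------------------------------------------
# reference (pure-python) conditional updates; the sweep kernel must agree
# ---------------------------------------------------------------------------


def component_log_likelihoods(
    rhs: float, Sw: float, sigma2_e: float, tau2: np.ndarray, logP_row: np.ndarray
) -> np.ndarray:
    """Log full-conditional component weights for one variant.

    ``rhs`` = W_i' E^-1 r (residual including the variant's own
    contribution), ``Sw`` = W_i' E^-1 W_i; both in weight units, not divided
    by sigma2_e.
    """
    L = np.empty(N_COMP)
    L[0] = logP_row[0]
    for d in range(1, N_COMP):
        den = tau2[d] * Sw + sigma2_e
        L[d] = (
            logP_row[d]
            - 0.5 * np.log(den / sigma2_e)
            + 0.5 * rhs * rhs * tau2[d] / (sigma2_e * den)
        )
    return L


def sample_component_and_effect(
    i: int,
    resid: np.ndarray,
    v: np.ndarray,
    z: np.ndarray,
    W: np.ndarray,
    weights: np.ndarray,
    logP_row: np.ndarray,
    tau2: np.ndarray,
    sigma2_e: float,
    u: float,
    gauss: float,
) -> None:
    """Reference single-variant update (mirrors the compiled sweep).

    Samples z_i from the softmax of the component log-likelihoods and, for a
    non-null draw, v_i from its conjugate normal conditional; updates resid,
    v and z in place.
    """
    col = W[:, i].astype(np.float64)
    Sw = float(np.sum(weights * col * col))
    rhs = float(np.sum(col * weights * resid)) + Sw * v[i]
    L = component_log_likelihoods(rhs, Sw, sigma2_e, tau2, logP_row)
    p = np.exp(L - L.max())
    p /= p.sum()
    zi = int(np.searchsorted(np.cumsum(p), u * 1.0))
    zi = min(zi, N_COMP - 1)
    if zi == 0:
        v_new = 0.0
    else:
        prec = Sw / sigma2_e + 1.0 / tau2[zi]
        v_new = rhs / (sigma2_e * prec) + gauss / np.sqrt(prec)
    resid += col * (v[i] - v_new)
    v[i] = v_new
    z[i] = zi


def sample_mixture_proportions(
    beta_counts: np.ndarray, alpha: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One draw P_c ~ Dirichlet(alpha_c + beta_c)."""
    beta_counts = np.asarray(beta_counts)
    if np.any(beta_counts < 0):
        raise ValueError("negative component count")
    return rng.dirichlet(np.asarray(alpha, dtype=float) + beta_counts)


def sample_residual_variance(
    resid: np.ndarray,
    weights: np.ndarray,
    rng: np.random.Generator,
    prior_df: float = -2.0,
    prior_scale: float = 0.0,
) -> float:
    """sigma2_e ~ scaled inverse-chi^2 from the weighted residual sum of
    squares; the default (nu0=-2, scale 0) is the uninformative choice."""
    n = resid.shape[0]
    ss = float(np.sum(weights * resid * resid)) + prior_df * prior_scale
    df = n + prior_df
    draw = ss / rng.chisquare(df)
    if not np.isfinite(draw) or draw <= 0:
        raise DivergenceError("nonpositive residual-variance draw")
    return draw


def sample_polygenic(
    resid_plus_a: np.ndarray,
    weights: np.ndarray,
    A_inv: np.ndarray,
    sigma2_a: float,
    sigma2_e: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw the polygenic vector from its multivariate-normal conditional.

    One record per individual (Z = I): precision = diag(w)/sigma2_e +
    A^-1/sigma2_a; ``resid_plus_a`` is the residual with the current a added
    back.
    """
    prec = A_inv / sigma2_a
    prec[np.diag_indices_from(prec)] += weights / sigma2_e
    L = cholesky(prec, lower=True)
    mean = cho_solve((L, True), weights * resid_plus_a / sigma2_e)
    return mean + solve_triangular(L.T, rng.standard_normal(len(mean)), lower=False)


def sample_polygenic_variance(
    a: np.ndarray,
    A_inv: np.ndarray,
    rng: np.random.Generator,
    prior_df: float = -2.0,
    prior_scale: float = 0.0,
) -> float:
    q = a.shape[0]
    ss = float(a @ A_inv @ a) + prior_df * prior_scale
    return ss / rng.chisquare(q + prior_df)


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------


class GibbsSampler:
    """One MCMC chain for the BayesRC mixture model.

    Parameters
    ----------
    pheno : PhenotypeTable
        Trait values, reliability weights and fixed-effect design.
    design : StandardizedDesign or ndarray
        Centred, unit-variance variant design matrix (training scale).
    classes : VariantClassMap or None
        Annotation classes; ``None`` means a single class (BayesR).
    A : AMatrix or None
        Pedigree relationship matrix for the polygenic term; ``None``
        disables it (a = 0 throughout, identical to omitting Za).
    spec : MixtureSpec
        Component variances and Dirichlet hyperparameters.
    fixed_proportions : ndarray or None
        Pin P_c at these values and skip the Dirichlet update (used for
        conjugate checks and degenerate-proportion contracts).
    fix_sigma2_e : float or None
        Pin the residual variance (used for oracle comparisons).
    variance_prior : (df, scale)
        Scaled inverse-chi^2 prior for sigma2_e and sigma2_a; the default
        (-2, 0) is uninformative (posterior entirely data-driven).
    """

    def __init__(
        self,
        pheno: PhenotypeTable,
        design=None,
        classes: VariantClassMap | None = None,
        spec: MixtureSpec | None = None,
        A: AMatrix | None = None,
        seed: int = 0,
        fixed_proportions: np.ndarray | None = None,
        fix_sigma2_e: float | None = None,
        variance_prior: tuple = (-2.0, 0.0),
        update_sigma2_g: bool = False,
        resid_check_interval: int = 500,
        genotypes: GenotypeMatrix | None = None,
    ) -> None:
        if spec is None:
            raise ValueError("a MixtureSpec is required")
        if genotypes is not None and np.all(genotypes.dosages == np.floor(genotypes.dosages)):
            # dosage fast path: int8 matrix with centering/scaling folded into
            # per-column scalars (identical math, one byte per genotype);
            # requires integer dosages (mean-imputed matrices fall back to the
            # generic float32 path below)
            if design is None:
                design = _standardize(genotypes)
            self.X8 = np.asfortranarray(genotypes.dosages, dtype=np.int8)
            self._mu = np.asarray(design.column_means, dtype=np.float64)
            self._inv_s = 1.0 / np.asarray(design.column_scales, dtype=np.float64)
            n, m = self.X8.shape
        elif genotypes is not None and design is None:
            self.X8 = None
            design = _standardize(genotypes)
            W = design.W
            n, m = W.shape
        elif design is not None:
            self.X8 = None
            W = design.W if isinstance(design, StandardizedDesign) else np.asarray(design)
            n, m = W.shape
        else:
            raise ValueError("supply a standardized design or raw genotypes")
        if pheno.n != n:
            raise ValueError("phenotype / design row mismatch")
        if classes is None:
            classes = VariantClassMap.single_class(m)
        if classes.class_index.shape[0] != m:
            raise ValueError("classes do not cover all design columns")
        sizes = classes.class_sizes()
        if np.any(sizes < 50):
            warnings.warn(
                "annotation class with < 50 variants: per-class mixture "
                "proportions are prior-dominated below roughly a thousand "
                "members"
            )

        self.pheno = pheno
        self.W32 = None if self.X8 is not None else np.asfortranarray(W, dtype=np.float32)
        self.classes = classes
        self.spec = spec
        self.A = A
        self.rng = np.random.default_rng(seed)
        self.fixed_proportions = fixed_proportions
        self.fix_sigma2_e = fix_sigma2_e
        self.variance_prior = variance_prior
        self.update_sigma2_g = update_sigma2_g
        self.resid_check_interval = resid_check_interval

        self.n, self.m = n, m
        self.n_classes = classes.n_classes
        self.cls0 = np.asarray(classes.class_index - 1, dtype=np.int64)
        self.alpha = spec.alpha_for(self.n_classes)
        self.w = np.asarray(pheno.weights, dtype=np.float64)
        self.y = np.asarray(pheno.y, dtype=np.float64)
        self.X = np.asarray(pheno.X, dtype=np.float64)
        if self.X8 is not None:
            X64 = self.X8.astype(np.float64)
            Wc = (X64 - self._mu) * self._inv_s
            self.Sw = (self.w[:, None] * Wc * Wc).sum(axis=0)
            self._wcolsum = (self.w[:, None] * Wc).sum(axis=0)
            del X64, Wc
        else:
            W64 = self.W32.astype(np.float64)
            self.Sw = (self.w[:, None] * W64 * W64).sum(axis=0)
            del W64
        self.tau2 = spec.component_variances()
        self.sigma2_g = spec.sigma2_g
        if A is not None:
            if list(A.ids) != list(pheno.ids):
                A = A.reorder(pheno.ids)
                self.A = A
            self._A_inv = A.inverse()
        else:
            self._A_inv = None

        self.it = 0
        self.state = self._initial_state()

    # -- initialization ------------------------------------------------------

    def _wls_fixed_effects(self, target: np.ndarray) -> np.ndarray:
        if self.X.shape[1] == 0:
            return np.zeros(0)
        Xw = self.X * self.w[:, None]
        return np.linalg.solve(self.X.T @ Xw, Xw.T @ target)

    def _initial_state(self) -> ChainState:
        b = self._wls_fixed_effects(self.y)
        v = np.zeros(self.m)
        z = np.zeros(self.m, dtype=np.int64)
        if self.fixed_proportions is not None:
            P = np.tile(np.asarray(self.fixed_proportions, float), (self.n_classes, 1))
        else:
            P = np.full((self.n_classes, N_COMP), 1.0 / N_COMP)
        vary = float(np.var(self.y, ddof=1))
        s2e = self.fix_sigma2_e if self.fix_sigma2_e is not None else 0.5 * vary
        resid = self.y - self.X @ b
        return ChainState(
            b=b,
            a=np.zeros(self.n),
            v=v,
            z=z,
            P=P,
            sigma2_a=0.05 * vary,
            sigma2_e=float(s2e),
            resid=resid,
        )

    # -- per-iteration updates ----------------------------------------------

    def _update_fixed_effects(self) -> None:
        st = self.state
        if self.X.shape[1] == 0:
            return
        target = st.resid + self.X @ st.b
        Xw = self.X * self.w[:, None]
        XtX = self.X.T @ Xw / st.sigma2_e
        L = cholesky(XtX, lower=True)
        mean = cho_solve((L, True), Xw.T @ target / st.sigma2_e)
        b_new = mean + solve_triangular(
            L.T, self.rng.standard_normal(len(mean)), lower=False
        )
        st.resid = target - self.X @ b_new
        st.b = b_new

    def _update_polygenic(self) -> None:
        st = self.state
        target = st.resid + st.a
        a_new = sample_polygenic(
            target, self.w, self._A_inv, st.sigma2_a, st.sigma2_e, self.rng
        )
        st.resid = target - a_new
        st.a = a_new
        st.sigma2_a = sample_polygenic_variance(
            a_new, self._A_inv, self.rng, *self.variance_prior
        )

    def _log_proportions(self) -> np.ndarray:
        return np.log(np.maximum(self.state.P, _PROP_FLOOR))

    def step(self) -> None:
        """One full Gibbs iteration: b, (a, sigma2_a), variant sweep,
        per-class P_c, sigma2_e."""
        st = self.state
        self._update_fixed_effects()
        if self._A_inv is not None:
            self._update_polygenic()

        perm = self.rng.permutation(self.m)
        unif = self.rng.random(self.m)
        gauss = self.rng.standard_normal(self.m)
        halflogdet, halfcoef = sweep_tables(self.Sw, self.tau2, st.sigma2_e)
        wr32 = (self.w * st.resid).astype(np.float32)
        if self.X8 is not None:
            swr = np.array([float(np.sum(self.w * st.resid))])
            mixture_sweep_dosage(
                self.X8, self._mu, self._inv_s, self._wcolsum,
                self.w, st.resid, wr32, swr, st.v, st.z,
                self._log_proportions(), self.cls0, self.Sw,
                halflogdet, halfcoef, self.tau2, st.sigma2_e,
                perm, unif, gauss,
            )
        else:
            mixture_sweep(
                self.W32, self.w, st.resid, wr32, st.v, st.z,
                self._log_proportions(), self.cls0, self.Sw,
                halflogdet, halfcoef, self.tau2, st.sigma2_e,
                perm, unif, gauss,
            )

        beta = self.component_counts()
        if self.fixed_proportions is None:
            for c in range(self.n_classes):
                st.P[c] = sample_mixture_proportions(beta[c], self.alpha[c], self.rng)

        if self.update_sigma2_g:
            nz = st.z > 0
            if nz.any():
                frac = np.asarray(self.spec.variance_fractions)[st.z[nz]]
                ss = float(np.sum(st.v[nz] ** 2 / frac))
                self.sigma2_g = ss / self.rng.chisquare(int(nz.sum()) + 2)
                self.tau2 = np.asarray(self.spec.variance_fractions) * self.sigma2_g

        if self.fix_sigma2_e is None:
            st.sigma2_e = sample_residual_variance(
                st.resid, self.w, self.rng, *self.variance_prior
            )

        self.it += 1
        if self.resid_check_interval and self.it % self.resid_check_interval == 0:
            self._check_residual()

    def component_counts(self) -> np.ndarray:
        """beta: C x 4 counts of variants per (class, component)."""
        flat = np.bincount(
            self.cls0 * N_COMP + self.state.z, minlength=self.n_classes * N_COMP
        )
        return flat.reshape(self.n_classes, N_COMP)

    def recomputed_residual(self) -> np.ndarray:
        st = self.state
        if self.X8 is not None:
            vs = st.v * self._inv_s
            wv = self.X8 @ vs - float(self._mu @ vs)
        else:
            wv = self.W32 @ st.v
        return self.y - self.X @ st.b - st.a - wv

    def _check_residual(self) -> None:
        fresh = self.recomputed_residual()
        gap = float(np.max(np.abs(fresh - self.state.resid)))
        if not np.isfinite(gap):
            raise DivergenceError(f"non-finite residual at iteration {self.it}")
        if gap > 1e-6:
            raise DivergenceError(
                f"residual bookkeeping drifted to {gap:.2e} at iteration {self.it}"
            )
        self.state.resid = fresh

    def set_phenotypes(self, y_new: np.ndarray) -> None:
        """Replace y keeping all parameters (used by prior-recovery checks)."""
        self.y = np.asarray(y_new, dtype=np.float64)
        self.state.resid = self.recomputed_residual()

    # -- full run ------------------------------------------------------------

    def run(
        self, n_iter: int, burn_in: int, store_traces: bool = True
    ) -> "ChainResult":
        if not 0 <= burn_in < n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        C = self.n_classes
        traces = (
            {
                "sigma2_e": np.empty(n_iter),
                "sigma2_a": np.empty(n_iter),
                "P": np.empty((n_iter, C, N_COMP)),
                "beta": np.empty((n_iter, C, N_COMP), dtype=np.int64),
            }
            if store_traces
            else None
        )
        n_post = n_iter - burn_in
        pip_acc = np.zeros(self.m)
        v_acc = np.zeros(self.m)
        beta_acc = np.zeros((C, N_COMP))
        P_acc = np.zeros((C, N_COMP))
        s2e_acc = s2a_acc = 0.0
        b_acc = np.zeros(self.X.shape[1])

        for it in range(n_iter):
            self.step()
            st = self.state
            if traces is not None:
                traces["sigma2_e"][it] = st.sigma2_e
                traces["sigma2_a"][it] = st.sigma2_a
                traces["P"][it] = st.P
                traces["beta"][it] = self.component_counts()
            if it >= burn_in:
                pip_acc += st.z > 0
                v_acc += st.v
                beta_acc += self.component_counts()
                P_acc += st.P
                s2e_acc += st.sigma2_e
                s2a_acc += st.sigma2_a
                b_acc += st.b

        summary = PosteriorSummary(
            pip=pip_acc / n_post,
            vbar=v_acc / n_post,
            class_component_counts=beta_acc / n_post,
            proportions=P_acc / n_post,
            sigma2_e=s2e_acc / n_post,
            sigma2_a=s2a_acc / n_post,
            b=b_acc / n_post,
            n_post=n_post,
        )
        return ChainResult(summary=summary, traces=traces)


@dataclass
class ChainResult:
    summary: PosteriorSummary
    traces: dict | None


def run_chain(
    pheno: PhenotypeTable,
    design,
    classes: VariantClassMap | None,
    spec: MixtureSpec,
    n_iter: int,
    burn_in: int,
    seed: int = 0,
    A: AMatrix | None = None,
    store_traces: bool = True,
    **kwargs,
) -> ChainResult:
    """Run one chain and return its draws and post-burn-in summary."""
    sampler = GibbsSampler(pheno, design, classes, spec, A=A, seed=seed, **kwargs)
    return sampler.run(n_iter, burn_in, store_traces=store_traces)


def summarize_chains(chains: list) -> MultiChainSummary:
    """Average per-chain post-burn-in means across chains.

    Per-chain means are computed first and then averaged, so each chain
    contributes equally; chains must share length. Spread over chains is
    reported as SD/sqrt(n_chains).
    """
    summaries = [c.summary if isinstance(c, ChainResult) else c for c in chains]
    if not summaries:
        raise ValueError("need at least one chain")
    if len({s.n_post for s in summaries}) != 1:
        raise ValueError("chains have unequal post-burn-in lengths")
    mean = lambda attr: np.mean([getattr(s, attr) for s in summaries], axis=0)
    return MultiChainSummary(
        chains=summaries,
        pip=mean("pip"),
        vbar=mean("vbar"),
        class_component_counts=mean("class_component_counts"),
        proportions=mean("proportions"),
        sigma2_e=float(mean("sigma2_e")),
        sigma2_a=float(mean("sigma2_a")),
    )


def default_sigma2_g(pheno: PhenotypeTable, h2: float) -> float:
    """sigma2_g as h2 times the weighted variance of fixed-effect-adjusted y."""
    X, y, w = pheno.X, pheno.y, pheno.weights
    if X.shape[1]:
        Xw = X * w[:, None]
        b = np.linalg.solve(X.T @ Xw, Xw.T @ y)
        r = y - X @ b
    else:
        r = y - np.average(y, weights=w)
    var_w = float(np.sum(w * r * r) / np.sum(w))
    return h2 * var_w


def fit_bayesrc(
    pheno: PhenotypeTable,
    design,
    classes: VariantClassMap | None,
    h2: float = 0.5,
    spec: MixtureSpec | None = None,
    n_iter: int = DEFAULT_N_ITER,
    burn_in: int = DEFAULT_BURN_IN,
    n_chains: int = DEFAULT_N_CHAINS,
    seed: int = 0,
    A: AMatrix | None = None,
    store_traces: bool = False,
    **kwargs,
) -> MultiChainSummary:
    """Fit BayesRC with replicate chains; returns the across-chain summary.

    ``spec`` defaults to the standard variance grid with sigma2_g = h2 x
    weighted phenotypic variance. Chain seeds are ``seed * 1000 + chain``.
    """
    if spec is None:
        spec = MixtureSpec(sigma2_g=default_sigma2_g(pheno, h2))
    results = []
    for chain in range(n_chains):
        chain_seed = int(seed) * 1000 + chain
        logger.info("chain %d/%d (seed %d)", chain + 1, n_chains, chain_seed)
        results.append(
            run_chain(
                pheno,
                design,
                classes,
                spec,
                n_iter,
                burn_in,
                seed=chain_seed,
                A=A,
                store_traces=store_traces,
                **kwargs,
            )
        )
    return summarize_chains(results)


def fit_bayesr(
    pheno: PhenotypeTable,
    design,
    h2: float = 0.5,
    **kwargs,
) -> MultiChainSummary:
    """BayesR: the single-class special case of BayesRC (same code path)."""
    return fit_bayesrc(pheno, design, classes=None, h2=h2, **kwargs)
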