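"""Genotype and phenotype containers with QC, LD pruning and standardization.

The containers here feed the mixture sampler: a dosage matrix (individuals x
variants, allele counts in {0,1,2}), per-variant annotation classes, and a
phenotype table carrying trait values, reliability weights and a fixed-effect
design. Quality control follows standard genomic-prediction practice: minor
allele frequency (MAF) filtering and sliding-window LD pruning on the squared
genotypic correlation r^2, with cross-category priority so putatively
functional variants survive pruning in preference to array fillers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: categories eligible for cross-category LD-prune priority, most-retained first
CATEGORY_PRIORITY = ("NSC", "REG", "CHIP")


class GenotypeError(ValueError):
    """Malformed or inconsistent genotype input."""


@dataclass
class GenotypeMatrix:
    """Allele-dosage matrix with variant coordinates.

    Dosages count copies of the alternate (or A1) allele, stored as float32
    with NaN marking missing calls. Positions are 1-based and must be sorted
    within each chromosome.
    """

    individual_ids: list
    variant_ids: list
    chrom: np.ndarray
    pos: np.ndarray
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float32)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n, m = self.dosages.shape
        if len(self.individual_ids) != n or len(self.variant_ids) != m:
            raise GenotypeError("id lists do not match dosage matrix shape")
        if len(set(self.individual_ids)) != n:
            raise GenotypeError("duplicate individual ids")
        if len(set(self.variant_ids)) != m:
            raise GenotypeError("duplicate variant ids")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad & ~np.isnan(self.dosages)):
            raise GenotypeError("dosage entries must lie in [0, 2] or be missing")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise GenotypeError(f"positions not sorted within chromosome {c}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    def subset_variants(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            individual_ids=self.individual_ids,
            variant_ids=[self.variant_ids[i] for i in index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            dosages=self.dosages[:, index],
        )

    def subset_individuals(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            individual_ids=[self.individual_ids[i] for i in index],
            variant_ids=self.variant_ids,
            chrom=self.chrom,
            pos=self.pos,
            dosages=self.dosages[index, :],
        )


@dataclass
class StandardizedDesign:
    """Centred, unit-variance variant design matrix W with its training scales.

    ``column_means`` / ``column_scales`` are retained so validation genotypes
    can be transformed with the *training* statistics.
    """

    W: np.ndarray
    column_means: np.ndarray
    column_scales: np.ndarray
    variant_ids: list = field(default_factory=list)

    def transform(self, dosages: np.ndarray) -> np.ndarray:
        """Apply the stored training means/scales to new dosage columns."""
        d = np.asarray(dosages, dtype=np.float64)
        if d.shape[1] != self.W.shape[1]:
            raise GenotypeError(
                f"variant count mismatch: {d.shape[1]} != {self.W.shape[1]}"
            )
        return (d - self.column_means) / self.column_scales


@dataclass
class VariantClassMap:
    """Per-variant annotation class (1..C) plus raw category tags.

    ``class_index`` drives the per-class Dirichlet mixture proportions of
    BayesRC; ``category`` carries the underlying annotation (NSC / REG / CHIP
    analogues) used for LD-prune priority.
    """

    class_index: np.ndarray
    class_labels: list
    category: np.ndarray

    def __post_init__(self) -> None:
        self.class_index = np.asarray(self.class_index, dtype=np.int64)
        self.category = np.asarray(self.category)
        C = len(self.class_labels)
        if C < 1:
            raise ValueError("need at least one class")
        if self.class_index.min() < 1 or self.class_index.max() > C:
            raise ValueError("class_index entries must lie in 1..C")
        counts = np.bincount(self.class_index, minlength=C + 1)[1:]
        if np.any(counts == 0):
            empty = [self.class_labels[i] for i in np.flatnonzero(counts == 0)]
            raise ValueError(f"empty class(es): {empty}")

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.class_index, minlength=self.n_classes + 1)[1:]

    def subset(self, index) -> "VariantClassMap":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return VariantClassMap(
            class_index=self.class_index[index],
            class_labels=list(self.class_labels),
            category=self.category[index],
        )

    @classmethod
    def single_class(cls, n_variants: int, label: str = "ALL") -> "VariantClassMap":
        return cls(
            class_index=np.ones(n_variants, dtype=np.int64),
            class_labels=[label],
            category=np.array([label] * n_variants),
        )


@dataclass
class PhenotypeTable:
    """Trait records: values y, reliability weights w_j and fixed-effect design.

    Weights enter the model through the residual covariance diag(1/w_j);
    higher weight means a more reliable record. Rank-deficient columns of X
    are dropped at construction with a warning.
    """

    ids: list
    y: np.ndarray
    weights: np.ndarray = None
    X: np.ndarray = None
    fixed_effect_labels: list = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        n = self.y.shape[0]
        if np.any(~np.isfinite(self.y)):
            raise ValueError("missing/non-finite phenotype in training rows")
        if self.weights is None:
            self.weights = np.ones(n)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if np.any(self.weights <= 0):
            raise ValueError("all reliability weights must be positive")
        if self.X is None:
            self.X = np.ones((n, 1))
            self.fixed_effect_labels = ["intercept"]
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.fixed_effect_labels is None:
            self.fixed_effect_labels = [f"x{j}" for j in range(self.X.shape[1])]
        if self.X.shape[0] != n or len(self.ids) != n:
            raise ValueError("phenotype table row mismatch")
        self._drop_rank_deficient()

    def _drop_rank_deficient(self) -> None:
        X = self.X
        if X.shape[1] == 0:
            return
        keep: list[int] = []
        for j in range(X.shape[1]):
            cand = X[:, keep + [j]]
            if np.linalg.matrix_rank(cand) == len(keep) + 1:
                keep.append(j)
            else:
                warnings.warn(
                    f"dropping rank-deficient fixed-effect column "
                    f"'{self.fixed_effect_labels[j]}'"
                )
        if len(keep) < X.shape[1]:
            self.X = X[:, keep]
            self.fixed_effect_labels = [self.fixed_effect_labels[j] for j in keep]

    @property
    def n(self) -> int:
        return self.y.shape[0]


# ---------------------------------------------------------------------------
# QC operations
# ---------------------------------------------------------------------------


def resolve_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by their column mean.

    The sampler assumes a complete matrix; mean imputation keeps column means
    (hence allele frequencies) unchanged. A fully missing column is an error.
    """
    if not g.has_missing():
        return g
    d = g.dosages.copy()
    nan_mask = np.isnan(d)
    n_obs = (~nan_mask).sum(axis=0)
    if np.any(n_obs == 0):
        j = int(np.flatnonzero(n_obs == 0)[0])
        raise GenotypeError(f"variant {g.variant_ids[j]} is entirely missing")
    col_mean = np.nansum(d, axis=0, dtype=np.float64) / n_obs
    jj = np.nonzero(nan_mask)[1]
    d[nan_mask] = col_mean[jj].astype(np.float32)
    return GenotypeMatrix(g.individual_ids, g.variant_ids, g.chrom, g.pos, d)


def compute_maf(g: GenotypeMatrix) -> np.ndarray:
    """Minor allele frequency per variant: min(p, 1-p), p = sum(dosage)/(2n)."""
    if g.n_individuals == 0:
        raise GenotypeError("empty genotype matrix")
    if g.has_missing():
        raise GenotypeError("resolve missing genotypes before computing MAF")
    p = g.dosages.sum(axis=0, dtype=np.float64) / (2.0 * g.n_individuals)
    return np.minimum(p, 1.0 - p)


def filter_by_maf(g: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Drop variants with MAF strictly below ``threshold`` (order preserved)."""
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    maf = compute_maf(g)
    keep = maf >= threshold
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("MAF filter (< %g): removed %d variants", threshold, n_drop)
    return g.subset_variants(keep)


def _pairwise_r2(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Squared genotypic correlation among columns; zero-variance columns
    are flagged and excluded from any pair (r2 set to 0)."""
    X = np.asarray(block, dtype=np.float64)
    sd = X.std(axis=0)
    poly = sd > 0
    r2 = np.zeros((X.shape[1], X.shape[1]))
    if poly.sum() >= 2:
        with np.errstate(invalid="ignore"):
            c = np.corrcoef(X[:, poly], rowvar=False)
        r2[np.ix_(poly, poly)] = c * c
    return r2, poly


def ld_prune(
    g: GenotypeMatrix,
    classes: VariantClassMap | None = None,
    r2_threshold: float = 0.999,
    window: int = 500,
    step: int = 50,
) -> tuple[GenotypeMatrix, list]:
    """Sliding-window LD pruning on the squared genotypic correlation.

    Windows contain ``window`` adjacent variants and advance by ``step``
    variants within each chromosome. Pruning runs in passes: first within
    each annotation category, then removing lower-priority members of
    cross-category pairs (NSC over REG over CHIP). For a same-category pair
    the variant later in position order is removed. Monomorphic columns are
    excluded from r^2 computation (with a warning) but retained.

    Returns the pruned matrix and the list of removed variant ids.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must lie in (0, 1]")
    if window < step:
        raise ValueError("window must be >= step")
    m = g.n_variants
    cats = (
        classes.category if classes is not None else np.array(["ALL"] * m, dtype=object)
    )
    cats = np.asarray(cats)
    keep = np.ones(m, dtype=bool)
    if np.any(g.dosages.std(axis=0) == 0):
        warnings.warn("monomorphic variants excluded from r^2 computation")

    present = [c for c in CATEGORY_PRIORITY if c in cats]
    others = sorted(set(np.unique(cats)) - set(CATEGORY_PRIORITY))
    ordered = present + others

    # (eligible-as-A categories, eligible-as-B categories); A has priority
    passes: list[tuple[set, set]] = [({c}, {c}) for c in ordered]
    for k, high in enumerate(present[:-1]):
        lower = set(present[k + 1 :])
        passes.append(({high}, lower))

    def run_pass(cat_a: set, cat_b: set) -> None:
        elig = keep & (np.isin(cats, list(cat_a | cat_b)))
        for c in np.unique(g.chrom):
            idx = np.flatnonzero(elig & (g.chrom == c))
            if idx.size < 2:
                continue
            for start in range(0, idx.size, step):
                win = idx[start : start + window]
                if win.size < 2:
                    continue
                r2, _ = _pairwise_r2(g.dosages[:, win])
                for a in range(win.size):
                    ia = win[a]
                    if not keep[ia]:
                        continue
                    for b in range(a + 1, win.size):
                        ib = win[b]
                        if not keep[ib] or r2[a, b] <= r2_threshold:
                            continue
                        ca, cb = cats[ia], cats[ib]
                        if cat_a == cat_b:  # within-category: drop the later
                            keep[ib] = False
                        elif ca in cat_a and cb in cat_b:
                            keep[ib] = False
                        elif cb in cat_a and ca in cat_b:
                            keep[ia] = False
                            break  # ia removed; stop scanning its pairs

    for cat_a, cat_b in passes:
        run_pass(cat_a, cat_b)

    removed = [g.variant_ids[i] for i in np.flatnonzero(~keep)]
    if removed:
        logger.info("LD pruning removed %d variants", len(removed))
    return g.subset_variants(keep), removed


def standardize(g: GenotypeMatrix) -> StandardizedDesign:
    """Centre and scale each dosage column to unit sample variance.

    Uses the sample standard deviation (ddof=1). Zero-variance columns are an
    error — MAF-filter first.
    """
    if g.has_missing():
        raise GenotypeError("resolve missing genotypes before standardizing")
    d = np.asarray(g.dosages, dtype=np.float64)
    means = d.mean(axis=0)
    scales = d.std(axis=0, ddof=1)
    if np.any(scales == 0):
        j = int(np.flatnonzero(scales == 0)[0])
        raise GenotypeError(
            f"zero-variance variant {g.variant_ids[j]}: apply MAF filtering first"
        )
    W = (d - means) / scales
    return StandardizedDesign(
        W=W, column_means=means, column_scales=scales, variant_ids=list(g.variant_ids)
    )
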