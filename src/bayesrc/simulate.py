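"""Synthetic multi-population genotypes, annotation classes and complex traits.

The generator emulates the statistical structure of a dairy-cattle style
study: two (or more) populations with drifted allele frequencies, local LD in
blocks, variant annotation categories (non-synonymous-coding, regulatory and
array analogues: NSC/REG/CHIP), tiered additive QTL effects drawn from three
normal distributions with variances 0.0001/0.001/0.01 of a nominal additive
genetic variance, a trait with heritability 0.6 and a population (breed)
offset drawn from N(10, 1) applied to the first population.

LD model: each haplotype is a thresholded latent Gaussian that follows an
AR(1) process within blocks of ``ld_block_length`` adjacent variants
(independent across blocks), i.e. a Gaussian copula over haplotypes. Dosage
is the sum of two independent haplotypes.

All randomness derives from a single integer seed, with independent
deterministic sub-streams per stage, so a configuration fully determines the
data set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import norm

from .genodata import GenotypeMatrix, PhenotypeTable, VariantClassMap

_STAGE = {"genotypes": 1, "classes": 2, "qtl": 3, "phenotypes": 4, "weights": 5}

#: category mix approximating a pruned sequence-variant panel
DEFAULT_CATEGORY_FRACTIONS = {"NSC": 0.05, "REG": 0.58, "CHIP": 0.37}


@dataclass
class SimulationConfig:
    """Study-design knobs for one synthetic replicate.

    Defaults define a desk-scale analogue of a full study: 2 x 1000 training
    individuals, 10,000 variants in 20-variant LD blocks, 200 QTL at tier
    ratio 174:25:1 (a 1/20 scale of 3485:500:15), h^2 = 0.6, breed effect
    N(10,1), 100 candidate-gene regions.
    """

    n_per_population: tuple = (1000, 1000)
    n_validation_per_population: tuple = (250, 250)
    n_variants: int = 10_000
    ld_block_length: int = 20
    within_block_corr: float = 0.7
    base_freq_range: tuple = (0.05, 0.95)
    drift_sd: float = 0.1
    n_qtl_per_tier: tuple = (174, 25, 1)
    tier_variances: tuple = (0.0001, 0.001, 0.01)
    sigma2_g: float = 1.0
    heritability: float = 0.6
    breed_effect_mean: float = 10.0
    breed_effect_sd: float = 1.0
    enrichment_scheme: str = "candidate_gene"
    qtl_placement: str | None = None  # default: follow enrichment_scheme
    n_candidate_genes: int = 100
    gene_length_variants: int = 20
    gene_window_variants: int = 10
    category_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_FRACTIONS)
    )
    weight_scheme: str = "uniform"  # or "two_point" (bull-like vs cow-like)
    weight_two_point: tuple = (10.0, 1.0, 0.3)  # high, low, fraction high
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.heritability <= 1.0:
            raise ValueError("heritability must lie in (0, 1]")
        if not 0.0 <= self.within_block_corr < 1.0:
            raise ValueError("within_block_corr must lie in [0, 1)")
        if any(k < 0 for k in self.n_qtl_per_tier):
            raise ValueError("tier QTL counts must be >= 0")
        tv = self.tier_variances
        if not all(b > a for a, b in zip(tv, tv[1:])):
            raise ValueError("tier variances must be strictly increasing")
        if self.enrichment_scheme not in ("candidate_gene", "category_only", "uniform"):
            raise ValueError(f"unknown enrichment_scheme {self.enrichment_scheme!r}")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STAGE[stage]])

    @property
    def n_total_per_population(self) -> tuple:
        return tuple(
            a + b for a, b in zip(self.n_per_population, self.n_validation_per_population)
        )


@dataclass
class TruthSet:
    """Simulated causal architecture: which variants are QTL, their effects,
    tier labels and the resulting per-individual true genetic values."""

    qtl_indices: np.ndarray
    qtl_variant_ids: list
    qtl_effects: np.ndarray
    qtl_tiers: np.ndarray
    genetic_values: np.ndarray
    class_enrichment: dict

    def is_qtl_mask(self, n_variants: int) -> np.ndarray:
        mask = np.zeros(n_variants, dtype=bool)
        mask[self.qtl_indices] = True
        return mask

    def to_json(self, path: str, variant_ids: list | None = None) -> None:
        obj = {
            "qtl_indices": self.qtl_indices.tolist(),
            "qtl_variant_ids": list(self.qtl_variant_ids),
            "qtl_effects": self.qtl_effects.tolist(),
            "qtl_tiers": self.qtl_tiers.tolist(),
            "genetic_values": self.genetic_values.tolist(),
            "class_enrichment": self.class_enrichment,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path: str) -> "TruthSet":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            qtl_indices=np.array(obj["qtl_indices"], dtype=int),
            qtl_variant_ids=obj["qtl_variant_ids"],
            qtl_effects=np.array(obj["qtl_effects"]),
            qtl_tiers=np.array(obj["qtl_tiers"], dtype=int),
            genetic_values=np.array(obj["genetic_values"]),
            class_enrichment=obj["class_enrichment"],
        )


def simulate_genotypes(cfg: SimulationConfig) -> tuple[GenotypeMatrix, np.ndarray]:
    """Draw dosages for all populations; returns (genotypes, population index).

    Each population has its own allele frequencies (base frequency plus a
    truncated normal drift), and haplotypes are AR(1) latent Gaussians within
    LD blocks thresholded at the population frequency quantile.
    """
    rng = cfg.rng("genotypes")
    m = cfg.n_variants
    n_pops = len(cfg.n_per_population)
    lo, hi = cfg.base_freq_range
    base = rng.uniform(lo, hi, size=m)
    freqs = np.clip(
        base[None, :] + rng.normal(0.0, cfg.drift_sd, size=(n_pops, m)), 0.02, 0.98
    )

    rho = cfg.within_block_corr
    counts = cfg.n_total_per_population
    n_total = sum(counts)
    pop = np.repeat(np.arange(n_pops), counts)
    thresholds = norm.ppf(freqs)[pop]  # n_total x m

    dosage = np.zeros((n_total, m), dtype=np.float32)
    innov = np.sqrt(1.0 - rho * rho)
    for _hap in range(2):
        eps = rng.standard_normal((n_total, m))
        z = np.empty_like(eps)
        for j in range(m):
            if j % cfg.ld_block_length == 0:
                z[:, j] = eps[:, j]
            else:
                z[:, j] = rho * z[:, j - 1] + innov * eps[:, j]
        dosage += (z < thresholds[:, : m]).astype(np.float32)

    ids = [f"pop{p+1}_{k:05d}" for p, c in enumerate(counts) for k in range(c)]
    g = GenotypeMatrix(
        individual_ids=ids,
        variant_ids=[f"var{j:06d}" for j in range(m)],
        chrom=np.array(["1"] * m),
        pos=np.arange(1, m + 1, dtype=np.int64) * 1000,
        dosages=dosage,
    )
    return g, pop


def _draw_gene_starts(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    hi = cfg.n_variants - cfg.gene_length_variants
    if hi <= 0:
        raise ValueError("gene_length_variants exceeds n_variants")
    return np.sort(
        rng.choice(hi, size=min(cfg.n_candidate_genes, hi), replace=False)
    )


def gene_region_masks(
    starts: np.ndarray, cfg: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (gene bodies, bodies plus flanking window) over variants."""
    m = cfg.n_variants
    in_gene = np.zeros(m, dtype=bool)
    in_window = np.zeros(m, dtype=bool)
    w = cfg.gene_window_variants
    L = cfg.gene_length_variants
    for s in starts:
        in_gene[s : s + L] = True
        in_window[max(0, s - w) : min(m, s + L + w)] = True
    return in_gene, in_window


def assign_classes(
    g: GenotypeMatrix, cfg: SimulationConfig
) -> tuple[VariantClassMap, np.ndarray]:
    """Assign annotation categories and BayesRC classes.

    candidate_gene: class I = coding-analogue (NSC) variants inside gene
    bodies, class II = other variants within the gene window, class III =
    everything else. category_only: classes are the categories themselves.
    uniform: a single class. Returns the map and the gene start indices
    (empty for non-gene schemes).
    """
    rng = cfg.rng("classes")
    m = g.n_variants
    cats = np.array(list(cfg.category_fractions))
    probs = np.array(list(cfg.category_fractions.values()), dtype=float)
    category = rng.choice(cats, size=m, p=probs / probs.sum())

    if cfg.enrichment_scheme == "uniform":
        cmap = VariantClassMap(
            class_index=np.ones(m, dtype=np.int64),
            class_labels=["ALL"],
            category=category,
        )
        return cmap, np.array([], dtype=int)

    if cfg.enrichment_scheme == "category_only":
        labels = list(cats)
        lut = {c: i + 1 for i, c in enumerate(labels)}
        cmap = VariantClassMap(
            class_index=np.array([lut[c] for c in category]),
            class_labels=labels,
            category=category,
        )
        return cmap, np.array([], dtype=int)

    starts = _draw_gene_starts(rng, cfg)
    in_gene, in_window = gene_region_masks(starts, cfg)
    class_index = np.full(m, 3, dtype=np.int64)
    class_i = in_gene & (category == "NSC")
    class_index[in_window] = 2
    class_index[class_i] = 1
    counts = np.bincount(class_index, minlength=4)[1:]
    if np.any(counts == 0):
        raise ValueError(
            "empty annotation class; increase n_candidate_genes (classes "
            "should hold well over a thousand variants to inform the "
            "per-class mixture proportions)"
        )
    cmap = VariantClassMap(
        class_index=class_index,
        class_labels=["I", "II", "III"],
        category=category,
    )
    return cmap, starts


def simulate_qtl(
    g: GenotypeMatrix,
    classes: VariantClassMap,
    cfg: SimulationConfig,
    gene_starts: np.ndarray | None = None,
) -> TruthSet:
    """Place tiered QTL and compute true genetic values.

    Placement (``cfg.qtl_placement``, defaulting to the enrichment scheme):
    candidate_gene restricts QTL to gene regions (classes I/II),
    category_only to NSC/REG variants genome-wide, uniform to all variants.
    Effects for tier t are N(0, tier_variances[t] * sigma2_g) applied to the
    raw 0/1/2 dosages.
    """
    rng = cfg.rng("qtl")
    m = g.n_variants
    placement = cfg.qtl_placement or cfg.enrichment_scheme
    if placement == "candidate_gene":
        if classes.n_classes < 3:
            raise ValueError("candidate_gene placement needs gene-based classes")
        eligible = np.flatnonzero(classes.class_index < 3)
    elif placement == "category_only":
        eligible = np.flatnonzero(np.isin(classes.category, ["NSC", "REG"]))
    elif placement == "uniform":
        eligible = np.arange(m)
    else:
        raise ValueError(f"unknown qtl_placement {placement!r}")

    n_qtl = int(sum(cfg.n_qtl_per_tier))
    if n_qtl > eligible.size:
        raise ValueError(
            f"requested {n_qtl} QTL but only {eligible.size} eligible variants"
        )
    qtl_idx = rng.choice(eligible, size=n_qtl, replace=False)
    tiers = np.repeat(np.arange(1, 4), cfg.n_qtl_per_tier)
    effects = np.zeros(n_qtl)
    for t, frac in enumerate(cfg.tier_variances, start=1):
        k = tiers == t
        effects[k] = rng.normal(0.0, np.sqrt(frac * cfg.sigma2_g), size=k.sum())

    gv = (
        np.asarray(g.dosages[:, qtl_idx], dtype=np.float64) @ effects
        if n_qtl
        else np.zeros(g.n_individuals)
    )

    enrich = {}
    qtl_mask = np.zeros(m, dtype=bool)
    qtl_mask[qtl_idx] = True
    for c, lab in enumerate(classes.class_labels, start=1):
        members = classes.class_index == c
        enrich[lab] = float(qtl_mask[members].mean()) if members.any() else 0.0

    return TruthSet(
        qtl_indices=qtl_idx,
        qtl_variant_ids=[g.variant_ids[i] for i in qtl_idx],
        qtl_effects=effects,
        qtl_tiers=tiers,
        genetic_values=gv,
        class_enrichment=enrich,
    )


def simulate_phenotypes(
    g: GenotypeMatrix,
    truth: TruthSet,
    cfg: SimulationConfig,
    populations: np.ndarray,
) -> PhenotypeTable:
    """Phenotypes: breed offset + genetic value + environmental noise.

    The environmental variance is scaled from the *realized* genetic-value
    variance so the target heritability holds per replicate; the breed offset
    (one N(mean, sd) draw) is added to the first population only.
    """
    rng = cfg.rng("phenotypes")
    gv = truth.genetic_values
    n = gv.shape[0]
    var_g = float(np.var(gv, ddof=1)) if n > 1 else 0.0
    if cfg.heritability < 1.0 and var_g == 0.0:
        raise ValueError(
            "zero genetic variance with h2 < 1: environmental variance undefined"
        )
    var_e = var_g * (1.0 - cfg.heritability) / cfg.heritability
    e = rng.normal(0.0, np.sqrt(var_e), size=n) if var_e > 0 else np.zeros(n)
    offset = rng.normal(cfg.breed_effect_mean, cfg.breed_effect_sd)
    y = gv + e + offset * (populations == 0)

    n_pops = int(populations.max()) + 1
    cols = [np.ones(n)]
    labels = ["intercept"]
    for p in range(1, n_pops):
        cols.append((populations == p).astype(float))
        labels.append(f"pop{p+1}")

    if cfg.weight_scheme == "uniform":
        w = np.ones(n)
    elif cfg.weight_scheme == "two_point":
        hi, lo_w, frac = cfg.weight_two_point
        wrng = cfg.rng("weights")
        w = np.where(wrng.random(n) < frac, hi, lo_w)
    else:
        raise ValueError(f"unknown weight_scheme {cfg.weight_scheme!r}")

    return PhenotypeTable(
        ids=list(g.individual_ids),
        y=y,
        weights=w,
        X=np.column_stack(cols),
        fixed_effect_labels=labels,
    )


@dataclass
class SimulatedDataset:
    """One replicate: genotypes, populations, classes, truth, phenotypes and
    the training/validation index split."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    populations: np.ndarray
    classes: VariantClassMap
    gene_starts: np.ndarray
    truth: TruthSet
    phenotypes: PhenotypeTable
    train_index: np.ndarray
    val_index: np.ndarray

    def training_phenotypes(self) -> PhenotypeTable:
        i = self.train_index
        return PhenotypeTable(
            ids=[self.phenotypes.ids[k] for k in i],
            y=self.phenotypes.y[i],
            weights=self.phenotypes.weights[i],
            X=self.phenotypes.X[i],
            fixed_effect_labels=list(self.phenotypes.fixed_effect_labels),
        )


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Run all simulation stages; validation individuals are the trailing
    ``n_validation_per_population`` block of each population."""
    g, pop = simulate_genotypes(cfg)
    classes, gene_starts = assign_classes(g, cfg)
    truth = simulate_qtl(g, classes, cfg, gene_starts)
    pheno = simulate_phenotypes(g, truth, cfg, pop)

    train, val = [], []
    offset = 0
    for n_tr_val, n_val in zip(cfg.n_total_per_population, cfg.n_validation_per_population):
        n_tr = n_tr_val - n_val
        train.extend(range(offset, offset + n_tr))
        val.extend(range(offset + n_tr, offset + n_tr_val))
        offset += n_tr_val
    return SimulatedDataset(
        config=cfg,
        genotypes=g,
        populations=pop,
        classes=classes,
        gene_starts=gene_starts,
        truth=truth,
        phenotypes=pheno,
        train_index=np.array(train, dtype=int),
        val_index=np.array(val, dtype=int),
    )


def config_to_yaml_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
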