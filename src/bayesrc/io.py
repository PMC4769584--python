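"""Readers and writers for genotype, annotation, phenotype and pedigree files.

Supported genotype formats: PLINK .bed/.bim/.fam (variant-major binary),
VCF (diploid GT, via cyvcf2) and a plain delimited matrix (header row of
variant ids, first column the individual id). Dosages count the VCF ALT
allele / PLINK A1 allele.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .genodata import GenotypeError, GenotypeMatrix, PhenotypeTable, VariantClassMap

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK codes (variant-major): 00=hom A1, 01=missing, 10=het, 11=hom A2.
# Dosage counts A1 copies: code -> dosage.
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0], dtype=np.float32)


def load_genotypes(path: str, format: str = "matrix") -> GenotypeMatrix:
    """Read genotypes from ``path`` in one of {plink, vcf, matrix}.

    For PLINK, ``path`` is the fileset prefix (without extension). Missing
    genotypes are flagged as NaN, not imputed.
    """
    if format == "matrix":
        return read_matrix(path)
    if format == "vcf":
        return read_vcf(path)
    if format == "plink":
        return read_plink(path)
    raise ValueError(f"unknown genotype format {format!r}")


# -- plain delimited matrix --------------------------------------------------


def read_matrix(path: str) -> GenotypeMatrix:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        dos = df.to_numpy(dtype=np.float32)
    except Exception as exc:  # pragma: no cover - message formatting
        raise GenotypeError(f"malformed matrix file {path}: {exc}") from exc
    m = dos.shape[1]
    return GenotypeMatrix(
        individual_ids=[str(i) for i in df.index],
        variant_ids=[str(c) for c in df.columns],
        chrom=np.array(["1"] * m),
        pos=np.arange(1, m + 1, dtype=np.int64),
        dosages=dos,
    )


def write_matrix(path: str, g: GenotypeMatrix, sep: str = "\t") -> None:
    df = pd.DataFrame(g.dosages, index=g.individual_ids, columns=g.variant_ids)
    df.to_csv(path, sep=sep)


# -- VCF ---------------------------------------------------------------------


def read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(path)
    ids = [str(s) for s in vcf.samples]
    chroms, poss, vids, cols = [], [], [], []
    for rec_no, v in enumerate(vcf, 1):
        gts = v.genotype.array()
        if gts.shape[1] - 1 != 2:  # last column is the phasing flag
            raise GenotypeError(
                f"record {rec_no} ({v.CHROM}:{v.POS}): only diploid GT supported"
            )
        alleles = gts[:, :2]
        missing = (alleles < 0).any(axis=1)
        dose = (alleles > 0).sum(axis=1).astype(np.float32)
        dose[missing] = np.nan
        chroms.append(v.CHROM)
        poss.append(v.POS)
        vids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        cols.append(dose)
    if not cols:
        raise GenotypeError(f"no variant records in {path}")
    return GenotypeMatrix(
        individual_ids=ids,
        variant_ids=vids,
        chrom=np.array(chroms),
        pos=np.array(poss, dtype=np.int64),
        dosages=np.column_stack(cols),
    )


# -- PLINK bed/bim/fam -------------------------------------------------------


def read_plink(prefix: str) -> GenotypeMatrix:
    bim = pd.read_csv(
        prefix + ".bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "vid", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "vid": str},
    )
    fam = pd.read_csv(
        prefix + ".fam",
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype=str,
    )
    n, m = len(fam), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        raw = fh.read()
    if raw[:3] != _BED_MAGIC:
        raise GenotypeError(f"{prefix}.bed: bad magic bytes (not variant-major bed)")
    bytes_per = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != bytes_per * m:
        raise GenotypeError(f"{prefix}.bed: size inconsistent with .bim/.fam")
    body = body.reshape(m, bytes_per)
    # expand each byte into four 2-bit codes (individuals minor within byte)
    codes = np.empty((m, bytes_per * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    dos = _BED_DECODE[codes[:, :n]].T  # n x m
    return GenotypeMatrix(
        individual_ids=list(fam["iid"]),
        variant_ids=list(bim["vid"]),
        chrom=bim["chrom"].to_numpy(),
        pos=bim["pos"].to_numpy(dtype=np.int64),
        dosages=dos,
    )


def write_plink(prefix: str, g: GenotypeMatrix) -> None:
    """Write a variant-major PLINK fileset (A1 is the counted allele)."""
    n, m = g.dosages.shape
    bim = pd.DataFrame(
        {
            "chrom": g.chrom,
            "vid": g.variant_ids,
            "cm": 0,
            "pos": g.pos,
            "a1": "A",
            "a2": "B",
        }
    )
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": g.individual_ids,
            "iid": g.individual_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)

    d = g.dosages.T  # m x n
    codes = np.full(d.shape, 1, dtype=np.uint8)  # missing
    codes[d == 2] = 0b00
    codes[d == 1] = 0b10
    codes[d == 0] = 0b11
    pad = (-n) % 4
    if pad:
        codes = np.hstack([codes, np.full((m, pad), 0b11, dtype=np.uint8)])
    packed = np.zeros((m, codes.shape[1] // 4), dtype=np.uint8)
    for k in range(4):
        packed |= codes[:, k::4] << (2 * k)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# -- annotation / phenotype tables ------------------------------------------


def read_class_table(path: str, variant_ids: list) -> VariantClassMap:
    """TSV with columns variant_id, class_label, category -> VariantClassMap
    aligned to ``variant_ids`` order. Every variant must be annotated."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"variant_id", "class_label", "category"}
    if not required.issubset(df.columns):
        raise ValueError(f"class table needs columns {sorted(required)}")
    df = df.set_index("variant_id")
    missing = [v for v in variant_ids if v not in df.index]
    if missing:
        raise ValueError(f"{len(missing)} variants missing from class table, "
                         f"e.g. {missing[:3]}")
    sub = df.loc[variant_ids]
    labels = sorted(sub["class_label"].unique())
    lut = {lab: i + 1 for i, lab in enumerate(labels)}
    return VariantClassMap(
        class_index=np.array([lut[v] for v in sub["class_label"]]),
        class_labels=labels,
        category=sub["category"].to_numpy(),
    )


def write_class_table(path: str, variant_ids: list, classes: VariantClassMap) -> None:
    pd.DataFrame(
        {
            "variant_id": variant_ids,
            "class_label": [classes.class_labels[i - 1] for i in classes.class_index],
            "category": classes.category,
        }
    ).to_csv(path, sep="\t", index=False)


def read_phenotypes(
    path: str,
    trait: str = "y",
    weight_col: str | None = "weight",
    covariates: list | None = None,
) -> PhenotypeTable:
    """Delimited phenotype table: id column first, trait column, optional
    weight column and covariate columns. An intercept is always included."""
    df = pd.read_csv(path, sep="\t")
    idc = df.columns[0]
    if trait not in df.columns:
        raise ValueError(f"trait column {trait!r} not in {path}")
    n = len(df)
    w = None
    if weight_col and weight_col in df.columns:
        w = df[weight_col].to_numpy(dtype=float)
    cols = [np.ones(n)]
    labels = ["intercept"]
    for c in covariates or []:
        vals = df[c]
        if vals.dtype.kind in "OUS":  # categorical: drop-first indicators
            levels = sorted(vals.unique())
            for lev in levels[1:]:
                cols.append((vals == lev).to_numpy(dtype=float))
                labels.append(f"{c}={lev}")
        else:
            cols.append(vals.to_numpy(dtype=float))
            labels.append(c)
    return PhenotypeTable(
        ids=[str(i) for i in df[idc]],
        y=df[trait].to_numpy(dtype=float),
        weights=w,
        X=np.column_stack(cols),
        fixed_effect_labels=labels,
    )


def write_phenotypes(path: str, pheno: PhenotypeTable, extra: dict | None = None) -> None:
    data = {"id": pheno.ids, "y": pheno.y, "weight": pheno.weights}
    for j, lab in enumerate(pheno.fixed_effect_labels):
        if lab != "intercept":
            data[lab] = pheno.X[:, j]
    data.update(extra or {})
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
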