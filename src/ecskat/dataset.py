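"""Dataset container and readers for phenotype / covariate / genotype data.

A :class:`Dataset` bundles the three aligned pieces every test consumes: a
trait vector ``y`` (continuous, or 0/1 for binary traits), a non-genetic
covariate matrix ``X`` (no intercept column; the null model adds one), and a
genotype matrix ``G`` of minor-allele counts in {0, 1, 2} for a single gene
set. Rows are aligned by sample id across the three sources.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "impute_missing",
    "orient_minor_allele",
]

MISSING = -1  # sentinel for missing genotype calls

TRAIT_TYPES = ("continuous", "binary")


class DatasetError(ValueError):
    """Raised when input data violate the dataset contract."""


@dataclass
class Dataset:
    """Aligned trait, covariates and genotypes for one gene set.

    Parameters
    ----------
    y : (n,) float array
        Trait values; for ``trait_type='binary'`` must be coded 0/1 with both
        classes present.
    X : (n, m) float array
        Non-genetic covariates. May have m = 0 columns. Must not contain a
        constant column (the intercept is handled by the null model).
    G : (n, p) array
        Minor-allele counts, entries in {0, 1, 2}.
    trait_type : {'continuous', 'binary'}
    variant_ids, sample_ids : optional label sequences.
    """

    y: np.ndarray
    X: np.ndarray
    G: np.ndarray
    trait_type: str
    variant_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.size == 0:
            self.X = np.empty((self.y.size, 0))
        self.G = np.asarray(self.G, dtype=float)
        if self.G.ndim == 1:
            self.G = self.G[:, None]
        n = self.y.size
        if self.X.shape[0] != n or self.G.shape[0] != n:
            raise DatasetError(
                f"row mismatch: y has {n}, X has {self.X.shape[0]}, G has {self.G.shape[0]}"
            )
        if self.trait_type not in TRAIT_TYPES:
            raise DatasetError(f"trait_type must be one of {TRAIT_TYPES}")
        if not np.isin(self.G, (0.0, 1.0, 2.0)).all():
            raise DatasetError("G entries must be in {0, 1, 2}; impute missing values first")
        if self.trait_type == "binary":
            classes = np.unique(self.y)
            if not np.isin(classes, (0.0, 1.0)).all():
                raise DatasetError("binary trait must be coded 0/1")
            if classes.size < 2:
                raise DatasetError("binary trait contains a single class")
        if not self.variant_ids:
            self.variant_ids = [f"v{j}" for j in range(self.p)]
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if len(self.variant_ids) != self.p or len(self.sample_ids) != n:
            raise DatasetError("id label lengths do not match matrix dimensions")
        _reject_constant_columns(self.X)

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def m(self) -> int:
        return self.X.shape[1]

    @property
    def p(self) -> int:
        return self.G.shape[1]

    def subset(self, idx: np.ndarray) -> "Dataset":
        """Row-subset (used by the train/test split); keeps variant labels."""
        idx = np.asarray(idx)
        return replace(
            self,
            y=self.y[idx],
            X=self.X[idx],
            G=self.G[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )


def _reject_constant_columns(X: np.ndarray) -> None:
    if X.shape[1] and np.any(np.ptp(X, axis=0) == 0):
        raise DatasetError(
            "covariate matrix contains a constant column; the intercept is added internally"
        )


def impute_missing(G_raw: np.ndarray, sentinel: float = MISSING, strategy: str = "mean") -> np.ndarray:
    """Replace missing genotype entries, keeping the {0,1,2} domain.

    ``strategy='mean'`` (default) uses the per-variant mean of observed calls
    rounded to the nearest integer; ``'mode'`` uses the per-variant mode.
    A variant with every call missing is an error.
    """
    G = np.asarray(G_raw, dtype=float).copy()
    if G.ndim == 1:
        G = G[:, None]
    miss = (G == sentinel) | np.isnan(G)
    if not miss.any():
        return G
    for j in np.flatnonzero(miss.any(axis=0)):
        obs = G[~miss[:, j], j]
        if obs.size == 0:
            raise DatasetError(f"variant column {j} has all genotypes missing")
        if strategy == "mean":
            fill = float(np.rint(obs.mean()))
        elif strategy == "mode":
            vals, counts = np.unique(obs, return_counts=True)
            fill = float(vals[np.argmax(counts)])
        else:
            raise ValueError(f"unknown imputation strategy {strategy!r}")
        G[miss[:, j], j] = fill
    return G


def orient_minor_allele(G: np.ndarray, variant_ids: list[str] | None = None) -> np.ndarray:
    """Flip variants coded on the major allele (sample AF > 0.5) to g -> 2 - g.

    MAF-keyed weights assume minor-allele counts, so columns whose sample
    allele frequency exceeds one half are re-oriented with a warning.
    """
    G = np.asarray(G, dtype=float)
    af = G.mean(axis=0) / 2.0
    flip = af > 0.5
    if flip.any():
        labels = (
            [variant_ids[j] for j in np.flatnonzero(flip)] if variant_ids else np.flatnonzero(flip).tolist()
        )
        warnings.warn(f"flipping {int(flip.sum())} variant(s) to minor-allele coding: {labels}")
        G = G.copy()
        G[:, flip] = 2.0 - G[:, flip]
    return G


def _read_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    return df.set_index(df.columns[0])


def _read_vcf(path: str) -> pd.DataFrame:
    """Minor-allele-count matrix from a VCF (GT field, diploid, first ALT)."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(f"skipping multi-allelic site {var.CHROM}:{var.POS}")
            continue
        counts = np.full(len(samples), MISSING, dtype=float)
        for i, call in enumerate(var.genotypes):
            alleles = [a for a in call[:-1] if a >= 0]
            if alleles:
                counts[i] = sum(1 for a in alleles if a == 1)
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        cols[vid] = counts
    if not cols:
        raise DatasetError(f"no usable biallelic sites in {path}")
    return pd.DataFrame(cols, index=samples)


def read_dataset(
    pheno_path: str,
    covar_path: str | None,
    geno_path: str,
    trait_type: str,
    format: str = "tsv",
    impute: str = "mean",
) -> Dataset:
    """Read and align the three data sources into a :class:`Dataset`.

    Samples are matched by id; the dataset is restricted to the intersection
    (ordered as in the phenotype file). For ``format='vcf'`` genotypes are
    extracted from GT fields and converted to minor-allele counts; TSV
    genotypes are expected in {0,1,2} with -1 or NA marking missing calls.
    """
    pheno = _read_table(pheno_path)
    if pheno.shape[1] != 1:
        raise DatasetError("phenotype file must have exactly one value column")
    covar = _read_table(covar_path) if covar_path is not None else None

    if format == "tsv":
        geno = _read_table(geno_path).astype(float)
    elif format == "vcf":
        geno = _read_vcf(geno_path)
    else:
        raise ValueError(f"unknown format {format!r}")

    ids = [i for i in pheno.index if i in set(geno.index)]
    if covar is not None:
        cset = set(covar.index)
        ids = [i for i in ids if i in cset]
    if not ids:
        raise DatasetError("no overlapping sample ids across input files")

    y = pheno.loc[ids].to_numpy(dtype=float).ravel()
    X = covar.loc[ids].to_numpy(dtype=float) if covar is not None else np.empty((len(ids), 0))
    G = impute_missing(geno.loc[ids].to_numpy(dtype=float), strategy=impute)
    if not np.isin(G, (0.0, 1.0, 2.0)).all():
        raise DatasetError("genotypes outside {0,1,2} after conversion/imputation")
    G = orient_minor_allele(G, list(geno.columns))
    return Dataset(
        y=y,
        X=X,
        G=G,
        trait_type=trait_type,
        variant_ids=list(geno.columns),
        sample_ids=list(ids),
    )


def write_dataset(ds: Dataset, pheno_path: str, covar_path: str, geno_path: str) -> None:
    """Write a dataset back to the three-TSV layout read by :func:`read_dataset`."""
    pd.DataFrame({"sample_id": ds.sample_ids, "y": ds.y}).to_csv(pheno_path, sep="\t", index=False)
    cv = pd.DataFrame(ds.X, columns=[f"x{j}" for j in range(ds.m)])
    cv.insert(0, "sample_id", ds.sample_ids)
    cv.to_csv(covar_path, sep="\t", index=False)
    gn = pd.DataFrame(ds.G.astype(int), columns=ds.variant_ids)
    gn.insert(0, "sample_id", ds.sample_ids)
    gn.to_csv(geno_path, sep="\t", index=False)
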