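"""Containers and I/O for additively coded SNP genotype cohorts.

Genotypes are stored as a dense samples x SNPs matrix of minor-allele
counts (0, 1, 2) with ``NaN`` marking missing calls.  Every SNP carries a
map record (id, autosome 1-22, 1-based position); samples carry an
optional covariate table and a binary class label (0 = responder,
1 = non-responder).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AUTOSOMES = tuple(range(1, 23))
VALID_ALLELES = frozenset("ACGT")

SNP_MAP_COLUMNS = ["snp_id", "chrom", "pos"]


class MalformedCallError(ValueError):
    """A genotype call contains an allele outside {major, minor}."""


class StratificationError(ValueError):
    """A class is too small to be represented in every split part."""


def encode_genotype(call, minor_allele, snp_id="?"):
    """Additively encode one genotype call as its minor-allele count.

    Parameters
    ----------
    call : pair of alleles (e.g. ``("A", "T")``) or None/NaN for missing
    minor_allele : the dataset-level minor allele of this SNP
    snp_id : identifier used in error messages

    Returns
    -------
    0, 1 or 2 (number of minor alleles), or ``numpy.nan`` for a missing
    call.
    """
    if call is None or (isinstance(call, float) and math.isnan(call)):
        return np.nan
    a, b = call
    if a is None or b is None:
        return np.nan
    for allele in (a, b, minor_allele):
        if allele not in VALID_ALLELES:
            raise MalformedCallError(
                f"SNP {snp_id}: allele {allele!r} is not one of A/C/G/T"
            )
    return int(a == minor_allele) + int(b == minor_allele)


@dataclass
class CovariateSchema:
    """Declared coding of one clinical/socio-demographic covariate."""

    name: str
    kind: str  # binary | ordinal | categorical
    allowed_codes: tuple = ()

    def validate(self, values: pd.Series) -> pd.Series:
        """Return a boolean mask flagging values outside the schema."""
        if self.kind not in ("binary", "ordinal", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        ok = values.isna() | values.isin(self.allowed_codes)
        return ~ok


@dataclass
class DatasetView:
    """A modelling view: genotype codes plus (optionally) covariates.

    ``X`` columns are SNPs first (aligned with ``snp_meta``) then
    covariates; ``is_snp`` flags which columns are SNPs.
    """

    X: np.ndarray
    y: np.ndarray | None
    feature_names: list[str]
    is_snp: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list[str]

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def select_features(self, mask: np.ndarray) -> "DatasetView":
        mask = np.asarray(mask, dtype=bool)
        snp_keep = mask[self.is_snp]
        return DatasetView(
            X=self.X[:, mask],
            y=self.y,
            feature_names=[n for n, m in zip(self.feature_names, mask) if m],
            is_snp=self.is_snp[mask],
            snp_meta=self.snp_meta.iloc[snp_keep].reset_index(drop=True),
            sample_ids=self.sample_ids,
        )

    def take_samples(self, idx: np.ndarray) -> "DatasetView":
        return DatasetView(
            X=self.X[idx],
            y=None if self.y is None else self.y[idx],
            feature_names=self.feature_names,
            is_snp=self.is_snp,
            snp_meta=self.snp_meta,
            sample_ids=[self.sample_ids[i] for i in idx],
        )


@dataclass
class GenotypeDataset:
    """Samples x SNPs additive genotype matrix with map, covariates, labels."""

    X: np.ndarray
    snp_map: pd.DataFrame
    y: np.ndarray | None = None
    covariates: pd.DataFrame | None = None
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(self.X.shape[0])]
        self.validate()

    # -- invariants -------------------------------------------------
    def validate(self):
        n, p = self.X.shape
        if len(self.snp_map) != p:
            raise ValueError(
                f"snp_map has {len(self.snp_map)} rows for {p} genotype columns"
            )
        missing_cols = [c for c in SNP_MAP_COLUMNS if c not in self.snp_map.columns]
        if missing_cols:
            raise ValueError(f"snp_map lacks columns {missing_cols}")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=int)
            if self.y.shape[0] != n:
                raise ValueError("label vector length mismatch")
            if not np.isin(self.y, [0, 1]).all():
                raise ValueError("labels must be binary 0/1")
        if self.covariates is not None and len(self.covariates) != n:
            raise ValueError("covariate table length mismatch")
        bad_chrom = ~self.snp_map["chrom"].isin(AUTOSOMES)
        if bad_chrom.any():
            raise ValueError(
                f"{int(bad_chrom.sum())} SNPs on non-autosomal chromosomes"
            )
        finite = self.X[~np.isnan(self.X)]
        if finite.size and not np.isin(finite, [0.0, 1.0, 2.0]).all():
            raise ValueError("genotype codes must be 0, 1, 2 or missing")

    # -- basic properties -------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_snps(self) -> int:
        return self.X.shape[1]

    def chromosomes(self) -> list[int]:
        return sorted(self.snp_map["chrom"].unique())

    # -- views ------------------------------------------------------
    def take(self, idx: Sequence[int]) -> "GenotypeDataset":
        idx = np.asarray(idx, dtype=int)
        return GenotypeDataset(
            X=self.X[idx],
            snp_map=self.snp_map,
            y=None if self.y is None else self.y[idx],
            covariates=None
            if self.covariates is None
            else self.covariates.iloc[idx].reset_index(drop=True),
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def view(
        self,
        chromosome: int | None = None,
        snp_columns: np.ndarray | None = None,
        include_covariates: bool = True,
    ) -> DatasetView:
        """Build a modelling view restricted to one chromosome (or an
        explicit SNP column subset), with covariates appended as extra
        numeric features."""
        if snp_columns is not None:
            cols = np.asarray(snp_columns, dtype=int)
        elif chromosome is not None:
            cols = np.flatnonzero(self.snp_map["chrom"].to_numpy() == chromosome)
        else:
            cols = np.arange(self.n_snps)
        Xs = self.X[:, cols]
        names = list(self.snp_map["snp_id"].iloc[cols])
        meta = self.snp_map.iloc[cols].reset_index(drop=True)
        if include_covariates and self.covariates is not None:
            C = self.covariates.to_numpy(dtype=float)
            Xs = np.hstack([Xs, C])
            names = names + list(self.covariates.columns)
        is_snp = np.zeros(len(names), dtype=bool)
        is_snp[: len(cols)] = True
        return DatasetView(
            X=Xs,
            y=self.y,
            feature_names=names,
            is_snp=is_snp,
            snp_meta=meta,
            sample_ids=list(self.sample_ids),
        )


@dataclass
class SplitBundle:
    """Disjoint train / stability / test partition of one cohort."""

    train: GenotypeDataset
    stability: GenotypeDataset
    test: GenotypeDataset
    seed: int

    def parts(self):
        return {"train": self.train, "stability": self.stability, "test": self.test}


# ---------------------------------------------------------------------------
# stratified splitting
# ---------------------------------------------------------------------------


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _allocate_per_class(class_counts: np.ndarray, frac: float, total: int) -> np.ndarray:
    """Largest-remainder allocation of ``total`` across classes in
    proportion ``frac`` of each class count; ties go to the earlier class."""
    exact = class_counts * frac
    base = np.floor(exact).astype(int)
    rem = exact - base
    short = total - int(base.sum())
    if short < 0:  # can happen when frac*count are all integers and total rounds down
        order = np.argsort(rem, kind="stable")
        for i in order[: -short]:
            base[i] -= 1
    else:
        order = np.argsort(-rem, kind="stable")
        for i in order[:short]:
            base[i] += 1
    return base


def stratified_allocation(class_counts: np.ndarray, frac: float) -> tuple[int, np.ndarray]:
    """Part size and per-class composition for one stratified split.

    Total part size is round-half-away(n * frac); per-class counts follow
    the largest-remainder rule so the composition tracks the cohort's
    class proportions to within one sample.
    """
    n = int(class_counts.sum())
    total = _round_half_away(n * frac)
    per_class = _allocate_per_class(np.asarray(class_counts, dtype=float), frac, total)
    return total, per_class


def stratified_three_way_split(
    data: GenotypeDataset,
    test_frac: float = 0.2,
    stability_frac_of_remainder: float = 0.5,
    seed: int = 0,
) -> SplitBundle:
    """Split a labelled cohort into disjoint train / stability / test sets.

    The cohort is first split into a test part of ``test_frac`` and a
    preliminary part; the preliminary part is then split into stability
    (``stability_frac_of_remainder``) and train.  All splits are
    stratified by class and deterministic under ``seed``.
    """
    if data.y is None:
        raise ValueError("split requires labels")
    for frac in (test_frac, stability_frac_of_remainder):
        if not 0.0 < frac < 1.0:
            raise ValueError("split fractions must lie strictly in (0, 1)")
    classes, counts = np.unique(data.y, return_counts=True)
    if (counts < 2).any():
        raise StratificationError(
            "every class needs at least 2 members to stratify a 3-way split"
        )
    rng = np.random.default_rng(seed)

    # shuffle indices within each class once; carve consecutive slices
    per_class_idx = {}
    for c in classes:
        idx = np.flatnonzero(data.y == c)
        rng.shuffle(idx)
        per_class_idx[c] = list(idx)

    _, test_per_class = stratified_allocation(counts, test_frac)
    test_idx, rest_counts = [], []
    for c, k in zip(classes, test_per_class):
        pool = per_class_idx[c]
        test_idx.extend(pool[:k])
        per_class_idx[c] = pool[k:]
        rest_counts.append(len(pool) - k)
    rest_counts = np.asarray(rest_counts)
    if (rest_counts < 2).any() or (test_per_class < 1).any():
        raise StratificationError("a class is too small to appear in every part")

    _, stab_per_class = stratified_allocation(rest_counts, stability_frac_of_remainder)
    stab_idx, train_idx = [], []
    for c, k in zip(classes, stab_per_class):
        pool = per_class_idx[c]
        stab_idx.extend(pool[:k])
        train_idx.extend(pool[k:])
    if min(len(train_idx), len(stab_idx)) == 0:
        raise StratificationError("empty split part")

    def _sorted(ix):
        return np.sort(np.asarray(ix, dtype=int))

    return SplitBundle(
        train=data.take(_sorted(train_idx)),
        stability=data.take(_sorted(stab_idx)),
        test=data.take(_sorted(test_idx)),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _parse_chrom(raw) -> int | None:
    s = str(raw)
    if s.lower().startswith("chr"):
        s = s[3:]
    try:
        c = int(s)
    except ValueError:
        return None
    return c if c in AUTOSOMES else None


def read_genotypes(
    path,
    fmt: str = "dosage-tsv",
    snp_map_path=None,
    covariates_path=None,
    labels_path=None,
) -> GenotypeDataset:
    """Read a genotype cohort from a VCF or an additive-dosage TSV.

    Dosage TSV layout: header row of SNP ids, first column the sample id,
    cells in {0,1,2,NA}; the SNP map (snp_id, chrom, pos) comes from
    ``snp_map_path``.  VCF records are additively encoded through
    :func:`encode_genotype` with the dataset-level minor allele;
    non-autosomal records are dropped (count logged) and multi-allelic
    records raise.
    """
    if fmt == "dosage-tsv":
        ds = _read_dosage_tsv(path, snp_map_path)
    elif fmt == "vcf":
        ds = _read_vcf(path)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path, sep="\t", index_col=0)
        ds.covariates = cov.loc[ds.sample_ids].reset_index(drop=True)
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep="\t", index_col=0)
        ds.y = lab.loc[ds.sample_ids].iloc[:, 0].to_numpy(dtype=int)
    ds.validate()
    return ds


def _read_dosage_tsv(path, snp_map_path) -> GenotypeDataset:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if snp_map_path is None:
        raise ValueError("dosage-tsv input requires a SNP map path")
    snp_map = pd.read_csv(snp_map_path, sep="\t")
    snp_map = snp_map.rename(columns={"chromosome": "chrom", "position": "pos"})
    order = {sid: i for i, sid in enumerate(snp_map["snp_id"])}
    missing = [c for c in df.columns if c not in order]
    if missing:
        raise ValueError(f"SNP map lacks entries for columns {missing[:5]}")
    df = df[sorted(df.columns, key=order.__getitem__)]
    return GenotypeDataset(
        X=df.to_numpy(dtype=float),
        snp_map=snp_map.reset_index(drop=True),
        sample_ids=[str(s) for s in df.index],
    )


def _read_vcf(path) -> GenotypeDataset:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    alt_counts, meta = [], []
    n_dropped = 0
    for i, var in enumerate(vcf):
        chrom = _parse_chrom(var.CHROM)
        if chrom is None:
            n_dropped += 1
            continue
        if len(var.ALT) != 1:
            raise ValueError(
                f"record {i + 1} ({var.ID or var.POS}): multi-allelic sites unsupported"
            )
        row = np.full(len(samples), np.nan)
        for j, g in enumerate(var.genotypes):
            alleles = g[:-1]
            if len(alleles) != 2:
                raise ValueError(
                    f"record {i + 1} ({var.ID or var.POS}): mixed ploidy"
                )
            if -1 in alleles:
                continue
            row[j] = float(sum(alleles))
        alt_counts.append(row)
        meta.append(
            {
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": chrom,
                "pos": int(var.POS),
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
    if n_dropped:
        logger.info("dropped %d non-autosomal VCF records", n_dropped)
    if not meta:
        raise ValueError("no autosomal biallelic records in VCF")
    A = np.vstack(alt_counts).T  # samples x SNPs, alt-allele counts
    # minor allele per dataset: lower-frequency allele, ties toward alt
    with np.errstate(invalid="ignore"):
        alt_freq = np.nanmean(A, axis=0) / 2.0
    X = np.where(np.isnan(A), np.nan, np.where(alt_freq[None, :] <= 0.5, A, 2.0 - A))
    return GenotypeDataset(
        X=X,
        snp_map=pd.DataFrame(meta),
        sample_ids=samples,
    )


def write_genotypes(ds: GenotypeDataset, prefix) -> dict[str, Path]:
    """Write a cohort as dosage TSV + SNP map (+ covariates, labels).

    Returns the paths written, keyed by role.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}
    geno = pd.DataFrame(
        ds.X, index=pd.Index(ds.sample_ids, name="sample_id"), columns=ds.snp_map["snp_id"]
    )
    # keep integer look for non-missing codes
    paths["genotypes"] = prefix.with_suffix(".dosage.tsv")
    geno.to_csv(paths["genotypes"], sep="\t", na_rep="NA", float_format="%.0f")
    paths["snp_map"] = prefix.with_suffix(".snps.tsv")
    ds.snp_map.to_csv(paths["snp_map"], sep="\t", index=False)
    if ds.covariates is not None:
        paths["covariates"] = prefix.with_suffix(".covariates.tsv")
        cov = ds.covariates.copy()
        cov.insert(0, "sample_id", ds.sample_ids)
        cov.to_csv(paths["covariates"], sep="\t", index=False)
    if ds.y is not None:
        paths["labels"] = prefix.with_suffix(".labels.tsv")
        pd.DataFrame({"sample_id": ds.sample_ids, "label": ds.y}).to_csv(
            paths["labels"], sep="\t", index=False
        )
    return paths
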