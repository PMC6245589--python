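"""GWAS-Catalog association loading, deduplication, trait-vocabulary
filtering and intersection with framework-selected SNPs.

The catalog ships as a v1.0-style association TSV (CHR_ID, CHR_POS,
SNPS, DISEASE/TRAIT, P-VALUE columns).  Multi-SNP interaction entries
are discarded, records are deduplicated to unique (chromosome, position,
trait) triples, and only genome-wide-suggestive associations
(p < 1e-6 by default) are retained.  Trait filtering is exact-string
(after whitespace normalization) against shipped vocabularies of
lung-cancer-related and cancer-related trait names, the narrow list
being a subset of the broad one.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

logger = logging.getLogger(__name__)

CATALOG_COLUMNS = {
    "chrom": "CHR_ID",
    "pos": "CHR_POS",
    "rsid": "SNPS",
    "trait": "DISEASE/TRAIT",
    "pvalue": "P-VALUE",
}

P_VALUE_THRESHOLD = 1e-6

_INTERACTION = re.compile(r"\bx\b|;|,")  # multi-SNP entry markers in SNPS


class GenomeBuildError(ValueError):
    """Selected SNPs and catalog declare different genome builds."""


def _normalize_trait(s: str) -> str:
    return " ".join(str(s).split())


@dataclass
class TraitVocabulary:
    """A named list of exact trait strings (case-sensitive)."""

    name: str
    traits: frozenset

    @classmethod
    def from_lines(cls, name: str, lines) -> "TraitVocabulary":
        traits = {
            _normalize_trait(t)
            for t in lines
            if t.strip() and not t.lstrip().startswith("#")
        }
        return cls(name=name, traits=frozenset(traits))

    @classmethod
    def shipped(cls, name: str) -> "TraitVocabulary":
        """Load one of the shipped vocabularies: LUNG or CANCER."""
        fname = {"LUNG": "lung_traits.txt", "CANCER": "cancer_traits.txt"}
        if name not in fname:
            raise ValueError(f"no shipped vocabulary named {name!r}")
        text = (
            resources.files("chromstab").joinpath(f"vocab/{fname[name]}").read_text()
        )
        return cls.from_lines(name, text.splitlines())


@dataclass
class CatalogTable:
    """Deduplicated catalog records with provenance."""

    records: pd.DataFrame  # columns: chrom, pos, rsid, trait, pvalue
    provenance: str = ""
    build: str | None = None

    def __post_init__(self):
        dup = self.records.duplicated(subset=["chrom", "pos", "trait"])
        if dup.any():
            raise ValueError("catalog records are not deduplicated")
        pv = self.records["pvalue"]
        if len(pv) and not ((pv > 0) & (pv <= 1)).all():
            raise ValueError("p-values must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.records)


def load_catalog(
    path,
    p_threshold: float = P_VALUE_THRESHOLD,
    provenance: str = "",
    build: str | None = None,
) -> CatalogTable:
    """Load and clean a GWAS-Catalog association TSV.

    Discards multi-SNP interaction entries, skips rows whose chromosome
    or position does not parse (count logged), deduplicates to unique
    (chromosome, position, trait) triples keeping the first occurrence,
    and drops associations with p >= ``p_threshold``.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CATALOG_COLUMNS.values() if c not in raw.columns]
    if missing:
        raise ValueError(f"catalog TSV lacks standard columns {missing}")
    std = raw.rename(columns={v: k for k, v in CATALOG_COLUMNS.items()})
    std = std[list(CATALOG_COLUMNS)]
    rows, n_skipped = [], 0
    for rec in std.itertuples(index=False):
        rsid = str(rec.rsid)
        if _INTERACTION.search(rsid):
            continue  # SNP x SNP interaction entry
        try:
            pos = int(str(rec.pos).strip())
            pv = float(rec.pvalue)
        except (TypeError, ValueError):
            n_skipped += 1
            continue
        rows.append(
            {
                "chrom": str(rec.chrom).strip().removeprefix("chr"),
                "pos": pos,
                "rsid": rsid.strip(),
                "trait": _normalize_trait(rec.trait),
                "pvalue": pv,
            }
        )
    if n_skipped:
        logger.info("skipped %d catalog rows with unparseable positions", n_skipped)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "rsid", "trait", "pvalue"])
    df = df.drop_duplicates(subset=["chrom", "pos", "trait"], keep="first")
    df = df[df["pvalue"] < p_threshold].reset_index(drop=True)
    return CatalogTable(records=df, provenance=provenance, build=build)


def filter_traits(table: CatalogTable, vocabulary: TraitVocabulary) -> CatalogTable:
    """Keep records whose trait string exactly matches a vocabulary entry
    (case-sensitive, whitespace-normalized)."""
    if not vocabulary.traits:
        raise ValueError("empty trait vocabulary")
    keep = table.records["trait"].map(_normalize_trait).isin(vocabulary.traits)
    return CatalogTable(
        records=table.records[keep].reset_index(drop=True),
        provenance=f"{table.provenance}|{vocabulary.name}",
        build=table.build,
    )


@dataclass
class IntersectionHit:
    snp_id: str
    chrom: str
    pos: int
    trait: str
    pvalue: float


def intersect_snps(
    selected: pd.DataFrame,
    table: CatalogTable,
    mode: str = "position",
    build: str | None = None,
) -> list[IntersectionHit]:
    """Join framework-selected SNPs against catalog records.

    ``selected`` needs columns (snp_id, chrom, pos) in position mode or
    (snp_id,) with rsid-style ids in rsid mode.  Both sides must declare
    the same genome build in position mode; no liftover is attempted.
    """
    if mode not in ("position", "rsid"):
        raise ValueError(f"unknown intersection mode {mode!r}")
    if mode == "position":
        if build is None or table.build is None or build != table.build:
            raise GenomeBuildError(
                f"genome builds must be declared and equal "
                f"(selected={build!r}, catalog={table.build!r})"
            )
        key = {
            (str(r.chrom), int(r.pos)): str(r.snp_id)
            for r in selected.itertuples(index=False)
        }
        hits = []
        for rec in table.records.itertuples(index=False):
            k = (str(rec.chrom), int(rec.pos))
            if k in key:
                hits.append(
                    IntersectionHit(key[k], rec.chrom, rec.pos, rec.trait, rec.pvalue)
                )
        return hits
    ids = {str(s) for s in selected["snp_id"]}
    return [
        IntersectionHit(rec.rsid, rec.chrom, rec.pos, rec.trait, rec.pvalue)
        for rec in table.records.itertuples(index=False)
        if rec.rsid in ids
    ]


def intersection_counts(
    selected: pd.DataFrame,
    catalog_all: CatalogTable,
    mode: str = "position",
    build: str | None = None,
) -> dict:
    """Hit counts against the full catalog and the LUNG/CANCER vocabularies,
    formatted like a per-pipeline intersection summary row."""
    lung = filter_traits(catalog_all, TraitVocabulary.shipped("LUNG"))
    cancer = filter_traits(catalog_all, TraitVocabulary.shipped("CANCER"))
    return {
        "n_features": len(selected),
        "cat_ALL": len(intersect_snps(selected, catalog_all, mode, build)),
        "cat_LUNG": len(intersect_snps(selected, lung, mode, build)),
        "cat_CANCER": len(intersect_snps(selected, cancer, mode, build)),
    }
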