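"""Shared in-memory containers for the GRS/eQTL scanning pipeline.

The pipeline moves four tabular objects around: a dosage matrix of risk-allele
counts, a per-variant weight table (log odds ratios from GWAS), a gene
expression matrix and a covariate table.  All of them are thin wrappers over
numpy arrays / pandas frames with the alignment invariants the scan relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "VariantWeightTable",
    "ExpressionMatrix",
    "Cohort",
    "LoadReport",
    "AssociationRecord",
    "combination_key",
    "parse_combination_key",
]


def combination_key(members: Iterable[str]) -> str:
    """Canonical string key for a variant combination.

    Variant IDs are sorted lexicographically and joined with ``+`` so that a
    combination has exactly one name regardless of input order.
    """
    ms = sorted(str(m) for m in members)
    if len(ms) != len(set(ms)):
        raise ValueError(f"duplicate variant ids in combination: {ms}")
    if not ms:
        raise ValueError("empty combination")
    return "+".join(ms)


def parse_combination_key(key: str) -> tuple[str, ...]:
    """Inverse of :func:`combination_key`."""
    members = tuple(key.split("+"))
    if any(not m for m in members):
        raise ValueError(f"malformed combination key: {key!r}")
    return members


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with per-variant metadata.

    ``dosage[j, i]`` counts copies of the *risk* allele (0, 1 or 2) carried by
    individual ``j`` at variant ``i``.  ``variant_meta`` is indexed by variant
    ID and carries ``chrom``, ``pos``, ``risk_allele``, ``other_allele`` and
    ``maf`` (minor allele frequency on the loaded sample set).
    """

    sample_ids: np.ndarray
    variant_ids: np.ndarray
    dosage: np.ndarray
    variant_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.dosage = np.asarray(self.dosage)
        n, m = self.dosage.shape
        if n != len(self.sample_ids) or m != len(self.variant_ids):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids are not unique")
        if len(set(self.variant_ids)) != m:
            raise ValueError("variant_ids are not unique")
        if self.dosage.size and (self.dosage.min() < 0 or self.dosage.max() > 2):
            raise ValueError("dosages must lie in {0, 1, 2}")
        if list(self.variant_meta.index) != list(self.variant_ids):
            raise ValueError("variant_meta index must equal variant_ids in order")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def _variant_indices(self, variants: Sequence[str]) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.variant_ids)}
        try:
            return np.array([lookup[v] for v in variants], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown variant id: {exc.args[0]!r}") from None

    def dosage_for(self, variants: Sequence[str]) -> np.ndarray:
        """Dosage sub-matrix (samples x len(variants)) in the given order."""
        return self.dosage[:, self._variant_indices(variants)]

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([lookup[s] for s in sample_ids], dtype=int)
        return GenotypeMatrix(
            sample_ids=np.asarray(list(sample_ids), dtype=object),
            variant_ids=self.variant_ids.copy(),
            dosage=self.dosage[idx],
            variant_meta=self.variant_meta.copy(),
        )


@dataclass
class VariantWeightTable:
    """Per-variant GRS weights: risk allele, GWAS odds ratio, ln(OR) weight.

    After risk-allele orientation every odds ratio is >= 1, hence every weight
    is >= 0.  ``table`` is indexed by variant ID with columns ``risk_allele``,
    ``other_allele``, ``odds_ratio``, ``weight``, ``locus_label`` and
    ``categories`` (a frozenset of category names).
    """

    table: pd.DataFrame

    REQUIRED = ("risk_allele", "other_allele", "odds_ratio", "weight")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"weight table missing column {col!r}")
        if "locus_label" not in self.table.columns:
            self.table = self.table.assign(locus_label="")
        if "categories" not in self.table.columns:
            self.table = self.table.assign(categories=[frozenset()] * len(self.table))
        if (self.table["odds_ratio"] <= 0).any():
            bad = self.table.index[self.table["odds_ratio"] <= 0].tolist()
            raise ValueError(f"non-positive odds ratio for variants {bad}")
        if not np.allclose(
            self.table["weight"], np.log(self.table["odds_ratio"]), atol=1e-12
        ):
            raise ValueError("weight column must equal ln(odds_ratio)")
        if (self.table["weight"] < -1e-12).any():
            raise ValueError("negative weight after orientation (OR < 1 not re-oriented?)")

    @property
    def variant_ids(self) -> list[str]:
        return list(self.table.index)

    def weights_for(self, variants: Sequence[str]) -> np.ndarray:
        missing = [v for v in variants if v not in self.table.index]
        if missing:
            raise KeyError(f"variants absent from weight table: {missing}")
        return self.table.loc[list(variants), "weight"].to_numpy(dtype=float)

    def risk_allele(self, variant: str) -> str:
        return str(self.table.loc[variant, "risk_allele"])

    def variants_in_category(self, category: str) -> list[str]:
        mask = self.table["categories"].map(lambda cs: category in cs)
        return list(self.table.index[mask])


@dataclass
class ExpressionMatrix:
    """Genes x individuals matrix of (already normalized) expression values."""

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        g, n = self.values.shape
        if g != len(self.gene_ids) or n != len(self.sample_ids):
            raise ValueError("expression values shape does not match gene/sample ids")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([lookup[s] for s in sample_ids], dtype=int)
        return ExpressionMatrix(
            gene_ids=self.gene_ids.copy(),
            sample_ids=np.asarray(list(sample_ids), dtype=object),
            values=self.values[:, idx],
        )


@dataclass
class Cohort:
    """Genotypes, expression and covariates aligned to one ordered sample set."""

    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    covariates: pd.DataFrame  # indexed by sample id, possibly zero columns

    def __post_init__(self) -> None:
        gs = list(self.genotypes.sample_ids)
        if list(self.expression.sample_ids) != gs or list(self.covariates.index) != gs:
            raise ValueError("cohort components are not sample-aligned")

    @property
    def sample_ids(self) -> np.ndarray:
        return self.genotypes.sample_ids

    @property
    def n_samples(self) -> int:
        return self.genotypes.n_samples


@dataclass
class LoadReport:
    """Counts of variants excluded per filtering rule while loading genotypes."""

    multiallelic: int = 0
    missing: int = 0
    low_maf: int = 0
    retained: int = 0
    reoriented: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "multiallelic": self.multiallelic,
            "missing": self.missing,
            "low_maf": self.low_maf,
            "retained": self.retained,
            "reoriented": list(self.reoriented),
        }


class AssociationRecord(NamedTuple):
    """One (combination, gene) test result from the risk-group regression."""

    combination: str
    gene_id: str
    n_low: int
    n_high: int
    es: float
    se: float
    p: float
    q: float | None = None
    flag: str = ""


#: column order used by all association tables
ASSOCIATION_COLUMNS = [
    "combination",
    "gene_id",
    "n_low",
    "n_high",
    "es",
    "se",
    "p",
    "q",
]
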