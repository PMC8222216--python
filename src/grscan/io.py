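"""Readers and writers for cohort inputs and scan outputs.

Variant filtering on load follows three exclusion rules: multi-allelic
records, variants with any missing genotype call, and variants whose sample
minor allele frequency falls below the configured floor (5% by default).
A :class:`~grscan.datatypes.LoadReport` states how many variants each rule
removed.

Dosages are counted on the risk allele whenever a weight table is supplied
for orientation; for VCF input without one, on the alternate allele.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ASSOCIATION_COLUMNS,
    Cohort,
    ExpressionMatrix,
    GenotypeMatrix,
    LoadReport,
    VariantWeightTable,
    combination_key,
)

__all__ = [
    "read_genotypes",
    "read_weights",
    "read_expression",
    "read_covariates",
    "read_categories",
    "align_cohort",
    "read_associations",
    "write_associations",
    "write_genotypes_vcf",
    "write_genotypes_tsv",
    "write_expression",
    "write_covariates",
    "write_weights",
]

FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(
    path: str | Path,
    fmt: str | None = None,
    maf_floor: float = 0.05,
    weights: VariantWeightTable | None = None,
) -> tuple[GenotypeMatrix, LoadReport]:
    """Load a dosage matrix from VCF or TSV, applying the exclusion rules.

    Returns ``(GenotypeMatrix, LoadReport)``.  Raises if no variant survives.
    """
    path = Path(path)
    if not 0 <= maf_floor < 0.5:
        raise ValueError(f"maf_floor {maf_floor} outside [0, 0.5)")
    if fmt is None:
        fmt = "vcf" if "".join(path.suffixes).lower().endswith((".vcf", ".vcf.gz")) else "tsv"
    if fmt == "vcf":
        gm, report = _read_vcf(path, maf_floor, weights)
    elif fmt == "tsv":
        gm, report = _read_genotype_tsv(path, maf_floor, weights)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    if gm.n_variants == 0:
        raise ValueError(
            f"no variants survive filtering in {path} "
            f"(excluded: {report.as_dict()})"
        )
    return gm, report


def _sample_maf(dosage: np.ndarray) -> float:
    f = float(dosage.mean()) / 2.0
    return min(f, 1.0 - f)


def _read_vcf(
    path: Path, maf_floor: float, weights: VariantWeightTable | None
) -> tuple[GenotypeMatrix, LoadReport]:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = np.array(vcf.samples, dtype=object)
    report = LoadReport()
    kept_ids, kept_dos, meta_rows = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            report.multiallelic += 1
            continue
        gt = np.asarray(var.gt_types)  # 0,1,2 dosage of ALT; 3 = missing
        if (gt == 3).any():
            report.missing += 1
            continue
        dosage = gt.astype(np.int8)
        if _sample_maf(dosage) < maf_floor:
            report.low_maf += 1
            continue
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        risk, other = var.ALT[0], var.REF
        if weights is not None and vid in weights.table.index:
            wanted = weights.risk_allele(vid)
            if wanted == var.REF:
                dosage = (2 - dosage).astype(np.int8)
                risk, other = var.REF, var.ALT[0]
            elif wanted != var.ALT[0]:
                raise ValueError(
                    f"risk allele {wanted!r} for {vid} matches neither "
                    f"REF {var.REF!r} nor ALT {var.ALT[0]!r}"
                )
        kept_ids.append(vid)
        kept_dos.append(dosage)
        meta_rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "risk_allele": risk,
                "other_allele": other,
                "maf": _sample_maf(dosage),
            }
        )
    report.retained = len(kept_ids)
    meta = pd.DataFrame(
        meta_rows,
        index=pd.Index(kept_ids, name="variant_id"),
        columns=["chrom", "pos", "risk_allele", "other_allele", "maf"],
    )
    dosage = (
        np.stack(kept_dos, axis=1) if kept_dos else np.empty((len(samples), 0), np.int8)
    )
    gm = GenotypeMatrix(
        sample_ids=samples,
        variant_ids=np.array(kept_ids, dtype=object),
        dosage=dosage,
        variant_meta=meta,
    )
    return gm, report


def _read_genotype_tsv(
    path: Path, maf_floor: float, weights: VariantWeightTable | None
) -> tuple[GenotypeMatrix, LoadReport]:
    """TSV layout: first column variant ID, remaining columns sample IDs.

    Dosages in a TSV are taken to already count the risk allele (the format
    carries no allele labels); a supplied weight table contributes allele
    metadata only.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ".", ""])
    except Exception as exc:  # pragma: no cover - pandas error path
        raise ValueError(f"malformed genotype TSV {path}: {exc}") from exc
    report = LoadReport()
    samples = np.array(df.columns, dtype=object)
    kept_ids, kept_dos, meta_rows = [], [], []
    for vid, row in df.iterrows():
        vals = row.to_numpy(dtype=float)
        if np.isnan(vals).any():
            report.missing += 1
            continue
        if not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError(f"non-dosage value in genotype TSV {path} at {vid!r}")
        dosage = vals.astype(np.int8)
        if _sample_maf(dosage) < maf_floor:
            report.low_maf += 1
            continue
        if weights is not None and vid in weights.table.index:
            risk = weights.risk_allele(vid)
            other = str(weights.table.loc[vid, "other_allele"])
        else:
            risk, other = ".", "."
        kept_ids.append(str(vid))
        kept_dos.append(dosage)
        meta_rows.append(
            {
                "chrom": ".",
                "pos": 0,
                "risk_allele": risk,
                "other_allele": other,
                "maf": _sample_maf(dosage),
            }
        )
    report.retained = len(kept_ids)
    meta = pd.DataFrame(
        meta_rows,
        index=pd.Index(kept_ids, name="variant_id"),
        columns=["chrom", "pos", "risk_allele", "other_allele", "maf"],
    )
    dosage = (
        np.stack(kept_dos, axis=1) if kept_dos else np.empty((len(samples), 0), np.int8)
    )
    gm = GenotypeMatrix(
        sample_ids=samples,
        variant_ids=np.array(kept_ids, dtype=object),
        dosage=dosage,
        variant_meta=meta,
    )
    return gm, report


def write_genotypes_vcf(
    gm: GenotypeMatrix, path: str | Path, extra_records: Iterable[str] = ()
) -> None:
    """Write a minimal VCF v4.2 with GT genotypes (risk allele as ALT)."""
    gtmap = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in gm.sample_ids)
            + "\n"
        )
        for i, vid in enumerate(gm.variant_ids):
            m = gm.variant_meta.loc[vid]
            gts = "\t".join(gtmap[int(d)] for d in gm.dosage[:, i])
            fh.write(
                f"{m['chrom']}\t{int(m['pos'])}\t{vid}\t{m['other_allele']}\t"
                f"{m['risk_allele']}\t.\tPASS\t.\tGT\t{gts}\n"
            )
        for line in extra_records:
            fh.write(line.rstrip("\n") + "\n")


def write_genotypes_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        gm.dosage.T,
        index=pd.Index(gm.variant_ids, name="variant_id"),
        columns=gm.sample_ids,
    )
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# weights


def read_weights(path: str | Path) -> VariantWeightTable:
    """Load the variant weight table; re-orient rows with OR < 1.

    Odds ratios below 1 mark a protective lead allele: the risk/other alleles
    are swapped and the OR inverted so every stored weight ``ln(OR)`` is
    non-negative.  Re-orientations are logged via :mod:`warnings` and recorded
    in the table's ``reoriented`` attribute.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    required = {"variant_id", "risk_allele", "odds_ratio"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"weight table {path} missing columns {sorted(required - set(df.columns))}"
        )
    if (df["odds_ratio"] <= 0).any():
        bad = df.loc[df["odds_ratio"] <= 0, "variant_id"].tolist()
        raise ValueError(f"non-positive odds ratio for variants {bad}")
    if "other_allele" not in df.columns:
        df["other_allele"] = "."
    if "locus_label" not in df.columns:
        df["locus_label"] = ""
    cats = df["categories"] if "categories" in df.columns else ""
    df = df.set_index("variant_id")

    reoriented = []
    flip = df["odds_ratio"] < 1.0
    for vid in df.index[flip]:
        reoriented.append(vid)
        ra, oa = df.loc[vid, "risk_allele"], df.loc[vid, "other_allele"]
        df.loc[vid, "risk_allele"], df.loc[vid, "other_allele"] = oa, ra
        df.loc[vid, "odds_ratio"] = 1.0 / df.loc[vid, "odds_ratio"]
    if reoriented:
        warnings.warn(
            f"re-oriented {len(reoriented)} variant(s) with OR < 1: {reoriented}",
            stacklevel=2,
        )
    noninformative = df.index[df["odds_ratio"] == 1.0].tolist()
    if noninformative:
        warnings.warn(
            f"variant(s) with OR = 1 carry zero GRS weight: {noninformative}",
            stacklevel=2,
        )

    def _parse_cats(c) -> frozenset:
        if isinstance(c, str) and c.strip():
            return frozenset(x.strip() for x in c.split(",") if x.strip())
        return frozenset()

    if isinstance(cats, pd.Series):
        cat_col = [_parse_cats(c) for c in cats]
    else:
        cat_col = [frozenset()] * len(df)

    table = pd.DataFrame(
        {
            "risk_allele": df["risk_allele"],
            "other_allele": df["other_allele"],
            "odds_ratio": df["odds_ratio"].astype(float),
            "weight": np.log(df["odds_ratio"].astype(float)),
            "locus_label": df["locus_label"],
            "categories": cat_col,
        },
        index=df.index,
    )
    wt = VariantWeightTable(table)
    wt.reoriented = reoriented
    return wt


def write_weights(wt: VariantWeightTable, path: str | Path) -> None:
    df = wt.table.copy()
    df["categories"] = df["categories"].map(lambda cs: ",".join(sorted(cs)))
    out = df.reset_index()[
        ["variant_id", "risk_allele", "other_allele", "odds_ratio", "locus_label", "categories"]
    ]
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# expression / covariates / categories


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        gene_ids=np.array(df.index, dtype=object),
        sample_ids=np.array(df.columns, dtype=object),
        values=df.to_numpy(dtype=float),
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    pd.DataFrame(
        expr.values,
        index=pd.Index(expr.gene_ids, name="gene_id"),
        columns=expr.sample_ids,
    ).to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    return df


def write_covariates(cov: pd.DataFrame, path: str | Path) -> None:
    out = cov.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_categories(
    path: str | Path, weights: VariantWeightTable | None = None
) -> dict[str, set[str]]:
    """Category annotation TSV (columns ``category``, ``variant_id``) into a
    mapping; validates variant IDs against the weight table when given."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"category", "variant_id"}.issubset(df.columns):
        raise ValueError(f"category table {path} needs columns category, variant_id")
    mapping: dict[str, set[str]] = {}
    for cat, vid in zip(df["category"], df["variant_id"]):
        mapping.setdefault(cat, set()).add(vid)
    if weights is not None:
        known = set(weights.table.index)
        unknown = sorted({v for vs in mapping.values() for v in vs} - known)
        if unknown:
            raise ValueError(f"category table references unknown variants {unknown}")
    return mapping


# ---------------------------------------------------------------------------
# cohort alignment


def align_cohort(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    covariates: pd.DataFrame | None = None,
) -> Cohort:
    """Restrict all inputs to their common samples, ordered by sample ID."""
    sets = {
        "genotypes": set(map(str, genotypes.sample_ids)),
        "expression": set(map(str, expression.sample_ids)),
    }
    if covariates is not None and len(covariates.columns) > 0:
        sets["covariates"] = set(map(str, covariates.index))
    common = sorted(set.intersection(*sets.values()))
    if not common:
        counts = {k: len(v) for k, v in sets.items()}
        raise ValueError(f"no samples shared between inputs (sizes: {counts})")
    if covariates is None:
        covariates = pd.DataFrame(index=pd.Index(common, name="sample_id"))
    else:
        covariates = covariates.loc[common]
    return Cohort(
        genotypes=genotypes.subset_samples(common),
        expression=expression.subset_samples(common),
        covariates=covariates,
    )


# ---------------------------------------------------------------------------
# association tables


def write_associations(records: pd.DataFrame, path: str | Path) -> None:
    """Write association records as TSV, 12 significant digits."""
    df = records.copy()
    for col in ASSOCIATION_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col == "q" else None
    df[ASSOCIATION_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT, na_rep="NA"
    )


def read_associations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in ASSOCIATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"association table {path} missing columns {missing}")
    df["combination"] = [
        combination_key(c.split("+")) for c in df["combination"].astype(str)
    ]
    return df[ASSOCIATION_COLUMNS]
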