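"""Aggregation of scan records: eGene summaries, variant-contribution
profiles, combination trees and cross-dataset validation."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import Cohort, VariantWeightTable, combination_key, parse_combination_key
from .scan import fit_group_association
from .grs import compute_grs, stratify

__all__ = [
    "significant_records",
    "summarize_egenes",
    "contribution_profile",
    "build_combination_tree",
    "tree_to_nested_dict",
    "cross_dataset_overlap",
    "replicate_top_combinations",
    "percent_half_up",
]


def percent_half_up(count: int, total: int) -> float:
    """Percentage at 0.1% resolution, rounded half-up (98.7 for 40366/40903)."""
    if total <= 0:
        raise ValueError("total must be positive")
    frac = Decimal(count) * 100 / Decimal(total)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def significant_records(
    records: pd.DataFrame, threshold: float, stat: str = "q"
) -> pd.DataFrame:
    """Records whose ``stat`` ("p" or "q") falls below ``threshold``."""
    if stat not in ("p", "q"):
        raise ValueError("stat must be 'p' or 'q'")
    if stat not in records.columns or records[stat].isna().all() and len(records):
        raise ValueError(f"records do not carry the statistic {stat!r}")
    return records[records[stat] < threshold]


def _combo_size(key: str) -> int:
    return len(parse_combination_key(key))


def summarize_egenes(
    records: pd.DataFrame,
    threshold: float,
    stat: str = "q",
    min_combinations: int = 1,
) -> pd.DataFrame:
    """Per-gene summary over significant records (eGenes).

    Genes with at least ``min_combinations`` significant combinations are
    summarized.  The "strongest" combination maximizes |ES|, ties broken by
    smaller p then canonical combination order.  ``single_variant_sufficient``
    is true iff some size-1 combination is significant for the gene.
    """
    cols = [
        "gene_id",
        "n_significant_combinations",
        "min_combination_size",
        "max_combination_size",
        "strongest_combination",
        "strongest_es",
        "strongest_se",
        "strongest_p",
        "single_variant_sufficient",
    ]
    if len(records) == 0:
        return pd.DataFrame(columns=cols)
    sig = significant_records(records, threshold, stat).copy()
    if len(sig) == 0:
        return pd.DataFrame(columns=cols)
    sig["size"] = sig["combination"].map(_combo_size)
    rows = []
    for gene, grp in sig.groupby("gene_id", sort=True):
        if len(grp) < min_combinations:
            continue
        best = grp.sort_values(
            by=["es", "p", "combination"],
            key=lambda s: -s.abs() if s.name == "es" else s,
        ).iloc[0]
        rows.append(
            {
                "gene_id": gene,
                "n_significant_combinations": int(len(grp)),
                "min_combination_size": int(grp["size"].min()),
                "max_combination_size": int(grp["size"].max()),
                "strongest_combination": best["combination"],
                "strongest_es": float(best["es"]),
                "strongest_se": float(best["se"]),
                "strongest_p": float(best["p"]),
                "single_variant_sufficient": bool((grp["size"] == 1).any()),
            }
        )
    return pd.DataFrame(rows, columns=cols)


def contribution_profile(
    records: pd.DataFrame,
    threshold: float,
    stat: str = "p",
    gene_id: str | None = None,
    all_variants: Sequence[str] | None = None,
) -> pd.DataFrame:
    """How often each variant appears among a gene's significant combinations.

    Returns one row per variant with ``n_combinations`` (significant
    combinations containing it) and ``percent`` (share of the gene's
    significant combinations, 0.1% resolution, half-up).  ``all_variants``
    optionally forces zero-count rows for never-contributing variants.
    """
    recs = records if gene_id is None else records[records["gene_id"] == gene_id]
    sig = significant_records(recs, threshold, stat)
    if len(sig) == 0:
        raise ValueError("no significant records for this gene at the threshold")
    if sig["gene_id"].nunique() > 1:
        raise ValueError("records span multiple genes; pass gene_id")
    combos = sig["combination"].unique()
    total = len(combos)
    counts: dict[str, int] = {}
    for key in combos:
        for v in parse_combination_key(key):
            counts[v] = counts.get(v, 0) + 1
    if all_variants is not None:
        for v in all_variants:
            counts.setdefault(v, 0)
    rows = [
        {
            "variant_id": v,
            "n_combinations": n,
            "fraction": n / total,
            "percent": percent_half_up(n, total),
        }
        for v, n in counts.items()
    ]
    out = pd.DataFrame(rows).sort_values(
        by=["n_combinations", "variant_id"], ascending=[False, True]
    )
    out.attrs["n_significant_combinations"] = total
    return out.reset_index(drop=True)


@dataclass
class CombinationTree:
    """Subset-lattice covering relations among tested combinations.

    Nodes are canonical combination keys; an edge joins a combination to a
    tested superset with exactly one added variant.  Node payloads carry
    (es, p, significant).
    """

    root: str
    nodes: dict  # key -> {"es": float, "p": float, "significant": bool, "size": int}
    edges: list  # (parent_key, child_key)


def build_combination_tree(
    records: pd.DataFrame,
    gene_id: str,
    root_combination: Sequence[str] | str,
    threshold: float = 0.05,
    stat: str = "p",
) -> CombinationTree:
    """Expand the root combination through tested single-variant additions.

    Breadth-first over the records of ``gene_id``: a tested combination is a
    node if it is reachable from the root through a chain of tested
    combinations each adding one variant; edges are all covering relations
    among the reached nodes.
    """
    if isinstance(root_combination, str):
        root = combination_key(parse_combination_key(root_combination))
    else:
        root = combination_key(root_combination)
    recs = records[records["gene_id"] == gene_id]
    tested = {}
    for _, r in recs.iterrows():
        tested[r["combination"]] = r
    if root not in tested:
        raise KeyError(f"root combination {root!r} was not tested for {gene_id!r}")

    by_size: dict[int, list[tuple[frozenset, str]]] = {}
    for key in tested:
        members = frozenset(parse_combination_key(key))
        by_size.setdefault(len(members), []).append((members, key))

    root_set = frozenset(parse_combination_key(root))
    reached = {root}
    frontier = [(root_set, root)]
    edges = []
    while frontier:
        nxt = []
        for members, key in frontier:
            for cand_set, cand_key in by_size.get(len(members) + 1, []):
                if members < cand_set:
                    edges.append((key, cand_key))
                    if cand_key not in reached:
                        reached.add(cand_key)
                        nxt.append((cand_set, cand_key))
        frontier = nxt
    # edges among reached nodes only, deduplicated, deterministic order
    edges = sorted({(p, c) for p, c in edges if p in reached and c in reached})

    nodes = {}
    for key in sorted(reached, key=lambda k: (_combo_size(k), k)):
        r = tested[key]
        stat_val = r[stat] if stat in r else r["p"]
        nodes[key] = {
            "es": float(r["es"]),
            "p": float(r["p"]),
            "significant": bool(stat_val < threshold) if pd.notna(stat_val) else False,
            "size": _combo_size(key),
        }
    return CombinationTree(root=root, nodes=nodes, edges=edges)


def tree_to_nested_dict(tree: CombinationTree) -> dict:
    """Nested-dict form of the tree (JSON/YAML-ready; children recurse).

    A node reachable through several parents is expanded under each of them,
    matching how such charts are drawn.
    """
    children: dict[str, list[str]] = {}
    for p, c in tree.edges:
        children.setdefault(p, []).append(c)

    def build(key: str) -> dict:
        payload = dict(tree.nodes[key])
        return {
            "combination": key,
            **payload,
            "children": [build(c) for c in sorted(children.get(key, []))],
        }

    return build(tree.root)


def cross_dataset_overlap(
    egenes_a: Iterable[str] | pd.DataFrame, egenes_b: Iterable[str] | pd.DataFrame
) -> tuple[set[str], tuple[int, int, int]]:
    """Shared eGenes between two summaries; returns (shared, (n_a, n_b, n_shared))."""

    def genes(x) -> set[str]:
        if isinstance(x, pd.DataFrame):
            return set(x["gene_id"])
        return set(x)

    a, b = genes(egenes_a), genes(egenes_b)
    shared = a & b
    return shared, (len(a), len(b), len(shared))


def replicate_top_combinations(
    records_a: pd.DataFrame,
    cohort_b: Cohort,
    weights: VariantWeightTable,
    top_k: int = 5,
    threshold: float = 1e-7,
    stat: str = "p",
    q_fraction: float = 0.30,
    replication_alpha: float = 0.05,
    covariate_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Re-test each eGene's strongest combinations in a second cohort.

    For every eGene in ``records_a`` the ``top_k`` significant combinations by
    |ES| are re-fit in ``cohort_b``; the result rows report both effect sizes,
    the replication p-value, sign concordance and nominal significance.
    Combinations whose variants are absent from ``cohort_b`` are flagged
    untestable rather than dropped.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    sig = significant_records(records_a, threshold, stat).copy()
    sig["abs_es"] = sig["es"].abs()
    available = set(cohort_b.genotypes.variant_ids) & set(weights.table.index)
    cov = cohort_b.covariates
    if covariate_columns is not None:
        cov = cov[list(covariate_columns)]

    rows = []
    for gene, grp in sig.groupby("gene_id", sort=True):
        top = grp.sort_values(
            by=["abs_es", "p", "combination"], ascending=[False, True, True]
        ).head(top_k)
        gidx = np.flatnonzero(cohort_b.expression.gene_ids == gene)
        for _, r in top.iterrows():
            combo = parse_combination_key(r["combination"])
            testable = set(combo) <= available and gidx.size == 1
            if not testable:
                rows.append(
                    {
                        "gene_id": gene,
                        "combination": r["combination"],
                        "es_a": float(r["es"]),
                        "es_b": np.nan,
                        "p_b": np.nan,
                        "same_sign": False,
                        "significant_b": False,
                        "testable": False,
                    }
                )
                continue
            grs = compute_grs(cohort_b.genotypes, weights, combo)
            assignment = stratify(grs, q_fraction)
            y = cohort_b.expression.values[gidx[0]]
            es_b, _, p_b = fit_group_association(y, assignment.labels, cov)
            rows.append(
                {
                    "gene_id": gene,
                    "combination": r["combination"],
                    "es_a": float(r["es"]),
                    "es_b": es_b,
                    "p_b": p_b,
                    "same_sign": bool(np.sign(es_b) == np.sign(r["es"])),
                    "significant_b": bool(p_b < replication_alpha),
                    "testable": True,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "combination",
            "es_a",
            "es_b",
            "p_b",
            "same_sign",
            "significant_b",
            "testable",
        ],
    )
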