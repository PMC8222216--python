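"""Variant-combination enumeration, GRS computation and risk-group stratification.

The genetic risk score (GRS) of individual :math:`j` for a variant set
:math:`S` is the weighted sum of risk-allele dosages, normalized by the mean
weight of the included variants:

.. math::

    \\mathrm{GRS}_j(S) = \\frac{\\sum_{i \\in S} d_{ji} \\, w_i}
                              {\\tfrac{1}{|S|} \\sum_{i \\in S} w_i},
    \\qquad w_i = \\ln \\mathrm{OR}_i .

The normalization puts every combination's score on a common "effective
risk-allele count" scale: for a single variant the GRS reduces exactly to the
dosage, and rescaling all weights by a positive constant leaves scores
unchanged.  Individuals are then graded into a low-risk group (the lowest
``q``-quantile of scores) and a high-risk group (the highest ``q``-quantile),
each of exactly ``floor(q * n)`` individuals; everyone else is excluded from
that combination's test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations as _itercombinations
from typing import Iterator, Sequence

import numpy as np

from .datatypes import GenotypeMatrix, VariantWeightTable, combination_key

__all__ = [
    "enumerate_combinations",
    "count_combinations",
    "compute_grs",
    "group_size",
    "stratify",
    "GRSVector",
    "RiskAssignment",
]

LOW, EXCLUDED, HIGH = -1, 0, 1  # integer codes used in RiskAssignment.codes


def enumerate_combinations(
    variant_ids: Sequence[str],
    max_size: int | None = None,
    start_after: Sequence[str] | None = None,
) -> Iterator[tuple[str, ...]]:
    """Yield every non-empty subset of ``variant_ids`` up to ``max_size``.

    Subsets are produced in deterministic order — increasing size, then
    lexicographic within a size — so truncated runs are well-defined prefixes
    and an interrupted run can resume from a cursor: ``start_after`` names the
    last combination already processed, and only the strictly following ones
    are yielded.  The iterator streams; nothing is materialized.

    With no size cap, ``m`` variants yield ``2**m - 1`` combinations.
    """
    ids = sorted(set(str(v) for v in variant_ids))
    if len(ids) != len(variant_ids):
        raise ValueError("variant_ids contain duplicates")
    if not ids:
        raise ValueError("need at least one variant")
    cap = len(ids) if max_size is None else int(max_size)
    if cap < 1:
        raise ValueError("max_size must be >= 1")
    cap = min(cap, len(ids))
    cursor = tuple(sorted(start_after)) if start_after is not None else None
    if cursor is not None and not set(cursor) <= set(ids):
        raise ValueError(f"start_after references unknown variants: {cursor}")
    skipping = cursor is not None
    for k in range(1, cap + 1):
        if skipping and k < len(cursor):
            continue
        for combo in _itercombinations(ids, k):
            if skipping:
                if combo == cursor:
                    skipping = False
                continue
            yield combo
    if skipping:
        raise ValueError(f"start_after cursor {cursor} not in the enumeration")


def count_combinations(n_variants: int, max_size: int | None = None) -> int:
    """Exact number of combinations ``enumerate_combinations`` would yield."""
    if n_variants < 1:
        raise ValueError("need at least one variant")
    if max_size is None or max_size >= n_variants:
        return 2**n_variants - 1
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    return sum(math.comb(n_variants, k) for k in range(1, max_size + 1))


@dataclass
class GRSVector:
    """Per-individual normalized GRS for one variant combination."""

    combination: tuple[str, ...]
    scores: np.ndarray
    sample_ids: np.ndarray

    @property
    def key(self) -> str:
        return combination_key(self.combination)


def compute_grs(
    genotypes: GenotypeMatrix,
    weights: VariantWeightTable,
    combination: Sequence[str],
) -> GRSVector:
    """Normalized genetic risk score of every individual for one combination.

    ``score_j = (sum_i dosage_ji * w_i) / mean_i(w_i)`` with ``w_i = ln(OR_i)``.
    Raises if the mean weight is zero (all included ORs equal 1), in which case
    the normalization is undefined.
    """
    members = tuple(sorted(combination))
    if len(members) != len(set(members)) or not members:
        raise ValueError("combination must be a non-empty set of distinct variants")
    w = weights.weights_for(members)
    mean_w = float(np.mean(w))
    if mean_w == 0.0:
        raise ZeroDivisionError(
            f"mean weight of combination {combination_key(members)} is zero "
            "(all odds ratios equal 1); normalized GRS undefined"
        )
    dos = genotypes.dosage_for(members).astype(float)
    scores = dos @ w / mean_w
    return GRSVector(combination=members, scores=scores, sample_ids=genotypes.sample_ids)


def group_size(n_individuals: int, q: float) -> int:
    """Number of individuals in each risk group: ``floor(q * n)``.

    ``q`` must lie in (0, 0.5] so the low and high groups cannot overlap.
    """
    if not 0 < q <= 0.5:
        raise ValueError(f"quantile fraction q={q} outside (0, 0.5]")
    if n_individuals < 1:
        raise ValueError("n_individuals must be positive")
    return int(math.floor(q * n_individuals))


@dataclass
class RiskAssignment:
    """Low/high/excluded labels for one combination at quantile fraction q."""

    combination: tuple[str, ...]
    q: float
    sample_ids: np.ndarray
    codes: np.ndarray  # int8, LOW / EXCLUDED / HIGH per individual
    n_low: int
    n_high: int

    @property
    def key(self) -> str:
        return combination_key(self.combination)

    @property
    def labels(self) -> np.ndarray:
        out = np.empty(len(self.codes), dtype=object)
        out[self.codes == LOW] = "low"
        out[self.codes == EXCLUDED] = "excluded"
        out[self.codes == HIGH] = "high"
        return out

    @property
    def used_mask(self) -> np.ndarray:
        return self.codes != EXCLUDED

    @property
    def high_mask(self) -> np.ndarray:
        return self.codes == HIGH


def stratify(grs: GRSVector, q: float) -> RiskAssignment:
    """Grade individuals into low/high risk groups by their GRS quantile.

    The ``floor(q*n)`` lowest-scoring individuals form the low-risk group and
    the same number of highest-scoring individuals the high-risk group; the
    middle of the distribution is excluded.  Ties at a group boundary are
    broken deterministically by sample ID (stable across input orderings).
    """
    n = len(grs.scores)
    g = group_size(n, q)
    if g < 1 or n < 2 * g:
        raise ValueError(
            f"cannot form two disjoint groups of {g} from {n} individuals at q={q}"
        )
    # lexsort: primary key scores, tie-break on sample id
    order = np.lexsort((np.asarray(grs.sample_ids, dtype=str), grs.scores))
    codes = np.zeros(n, dtype=np.int8)
    codes[order[:g]] = LOW
    codes[order[-g:]] = HIGH
    return RiskAssignment(
        combination=grs.combination,
        q=q,
        sample_ids=grs.sample_ids,
        codes=codes,
        n_low=g,
        n_high=g,
    )
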