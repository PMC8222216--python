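"""Risk-group association scanning: covariate-adjusted OLS per (combination, gene).

For one variant combination the cohort is split into low/high GRS quantile
groups and, for every gene, expression is regressed on

    y ~ intercept + high_indicator + covariates

by ordinary least squares.  The reported effect size (ES) is the
high-vs-low-group coefficient, the standard error (SE) its OLS standard
error, and the P-value the two-sided t-test with residual degrees of freedom
``n_used - n_parameters``.  Excluded (middle-quantile) individuals take no
part in the fit.  Without covariates this reduces exactly to the classical
pooled-variance two-sample t-test.

False-discovery-rate control is Benjamini-Hochberg applied once across an
entire test series (all combinations x all genes of one run).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import Cohort, VariantWeightTable, combination_key
from .grs import compute_grs, count_combinations, enumerate_combinations, group_size, stratify

__all__ = [
    "ScanConfig",
    "fit_group_association",
    "run_scan",
    "run_series",
    "adjust_fdr",
    "qq_data",
    "calibrate_group_size",
    "CalibrationResult",
    "build_covariate_design",
]

P_FLOOR = 1e-300  # underflow floor for vanishing residual variance

DEFAULT_Q_GRID = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35)


@dataclass
class ScanConfig:
    """Configuration of one scan series."""

    q_fraction: float = 0.30
    mode: str = "fdr"  # "fdr" (BH at alpha) or "p_threshold"
    alpha: float = 0.05
    p_threshold: float = 1e-5
    max_size: int | None = None
    covariate_columns: list[str] | None = None  # None = use all columns
    gene_chunk: int = 4096

    def __post_init__(self) -> None:
        if self.mode not in ("fdr", "p_threshold"):
            raise ValueError(f"unknown significance mode {self.mode!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if not 0 < self.q_fraction <= 0.5:
            raise ValueError("q_fraction must lie in (0, 0.5]")


def build_covariate_design(
    covariates: pd.DataFrame, columns: Sequence[str] | None = None
) -> pd.DataFrame:
    """Numeric covariate design: categorical columns expanded to indicator
    columns (first level dropped as reference), numeric columns passed through."""
    if columns is not None:
        missing = [c for c in columns if c not in covariates.columns]
        if missing:
            raise KeyError(f"covariate columns not found: {missing}")
        covariates = covariates[list(columns)]
    if covariates.shape[1] == 0:
        return pd.DataFrame(index=covariates.index)
    parts = []
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float).to_frame(name))
        else:
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            parts.append(dummies)
    return pd.concat(parts, axis=1)


def _ols_indicator_scan(
    X: np.ndarray, Y: np.ndarray, column_names: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """OLS of each column of ``Y`` on ``X``; inference on X's second column.

    Returns ``(es, se, p, flags)`` arrays of length ``Y.shape[1]``.
    ``flags`` is an object array: "" normal, "zero_variance" for a constant
    response within the used samples, "p_underflow" when residual variance
    vanishes with a non-zero effect.
    """
    n, k = X.shape
    if n <= k:
        raise ValueError(f"only {n} samples for {k} parameters")
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(n, k) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    if (diag <= tol).any():
        bad = [column_names[i] for i in np.flatnonzero(diag <= tol)]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear column(s): {bad}"
        )
    beta = np.linalg.solve(R, Q.T @ Y)
    resid = Y - X @ beta
    df = n - k
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df
    # var(beta_1) = sigma2 * [(X'X)^-1]_{11}
    Rinv = np.linalg.solve(R, np.eye(k))
    c = float((Rinv @ Rinv.T)[1, 1])

    es = beta[1].copy()
    se = np.sqrt(np.maximum(sigma2, 0.0) * c)
    flags = np.full(Y.shape[1], "", dtype=object)

    ss_tot = Y.var(axis=0) * n
    zero_var = ss_tot <= 0
    # residuals indistinguishable from zero at machine precision: perfect fit
    underflow = (rss <= 1e-24 * ss_tot) & ~zero_var

    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, es / np.where(se > 0, se, 1.0), np.inf)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.maximum(p, P_FLOOR)

    es[zero_var] = 0.0
    se[zero_var] = 0.0
    p[zero_var] = 1.0
    flags[zero_var] = "zero_variance"
    p[underflow] = P_FLOOR
    flags[underflow] = "p_underflow"
    return es, se, p, flags


def fit_group_association(
    y: np.ndarray,
    labels: Sequence,
    covariates: pd.DataFrame | None = None,
) -> tuple[float, float, float]:
    """ES, SE and two-sided P for one gene's low/high group comparison.

    ``labels`` holds "low"/"high" (anything else is excluded); ``y`` and the
    covariate rows are taken over the same individuals, in the same order.
    """
    labels = np.asarray(labels, dtype=object)
    y = np.asarray(y, dtype=float)
    used = (labels == "low") | (labels == "high")
    if not used.any() or not (labels == "low").any() or not (labels == "high").any():
        raise ValueError("both risk groups must be non-empty")
    high = (labels[used] == "high").astype(float)
    n = int(used.sum())
    if covariates is not None and covariates.shape[1] > 0:
        D = build_covariate_design(covariates).to_numpy(dtype=float)[used]
        names = ["intercept", "high"] + list(build_covariate_design(covariates).columns)
        X = np.column_stack([np.ones(n), high, D])
    else:
        names = ["intercept", "high"]
        X = np.column_stack([np.ones(n), high])
    es, se, p, _ = _ols_indicator_scan(X, y[used, None], names)
    return float(es[0]), float(se[0]), float(p[0])


def run_scan(
    cohort: Cohort,
    weights: VariantWeightTable,
    variant_subset: Sequence[str] | None = None,
    config: ScanConfig | None = None,
    start_after: Sequence[str] | None = None,
) -> Iterator[pd.DataFrame]:
    """Stream association records, one DataFrame per variant combination.

    For every combination from :func:`enumerate_combinations` the cohort is
    stratified at ``config.q_fraction`` and every gene tested; records appear
    in enumeration order.  ``start_after`` resumes an interrupted scan from a
    checkpoint cursor (the last combination already done); resumed output is
    identical to the corresponding tail of an uninterrupted run.  A failing
    combination is logged (warning) and skipped, never silently dropped.
    """
    config = config or ScanConfig()
    variants = (
        list(variant_subset)
        if variant_subset is not None
        else [v for v in cohort.genotypes.variant_ids if v in weights.table.index]
    )
    if not variants:
        raise ValueError("no variants to scan")
    design = build_covariate_design(cohort.covariates, config.covariate_columns)
    D = design.to_numpy(dtype=float)
    names = ["intercept", "high"] + list(design.columns)
    expr_t = cohort.expression.values.T  # samples x genes
    gene_ids = cohort.expression.gene_ids

    for combo in enumerate_combinations(variants, config.max_size, start_after):
        try:
            grs = compute_grs(cohort.genotypes, weights, combo)
            assignment = stratify(grs, config.q_fraction)
            used = assignment.used_mask
            high = assignment.high_mask[used].astype(float)
            n_used = int(used.sum())
            X = np.column_stack([np.ones(n_used), high, D[used]])
            Yu = expr_t[used]
            parts = []
            for start in range(0, len(gene_ids), config.gene_chunk):
                stop = min(start + config.gene_chunk, len(gene_ids))
                es, se, p, flags = _ols_indicator_scan(X, Yu[:, start:stop], names)
                parts.append(
                    pd.DataFrame(
                        {
                            "gene_id": gene_ids[start:stop],
                            "es": es,
                            "se": se,
                            "p": p,
                            "flag": flags,
                        }
                    )
                )
            out = pd.concat(parts, ignore_index=True)
            out.insert(0, "combination", combination_key(combo))
            out.insert(2, "n_low", assignment.n_low)
            out.insert(3, "n_high", assignment.n_high)
            yield out
        except Exception as exc:
            warnings.warn(
                f"combination {combination_key(combo)} failed and was skipped: {exc}",
                stacklevel=2,
            )


def run_series(
    cohort: Cohort,
    weights: VariantWeightTable,
    variant_subset: Sequence[str] | None = None,
    config: ScanConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """One full test series: scan, series-wide multiplicity handling, run log.

    In ``fdr`` mode BH q-values are computed once over the entire series and
    ``significant`` marks records with q < alpha; in ``p_threshold`` mode
    ``significant`` marks raw p below the configured threshold (q left unset).
    """
    config = config or ScanConfig()
    variants = (
        list(variant_subset)
        if variant_subset is not None
        else [v for v in cohort.genotypes.variant_ids if v in weights.table.index]
    )
    chunks = list(run_scan(cohort, weights, variants, config))
    records = (
        pd.concat(chunks, ignore_index=True)
        if chunks
        else pd.DataFrame(
            columns=["combination", "gene_id", "n_low", "n_high", "es", "se", "p", "flag"]
        )
    )
    n_combos = count_combinations(len(variants), config.max_size)
    if config.mode == "fdr" and len(records):
        records["q"] = adjust_fdr(records["p"].to_numpy())
        records["significant"] = records["q"] < config.alpha
    else:
        records["q"] = np.nan
        records["significant"] = (
            records["p"] < config.p_threshold if len(records) else False
        )
    log = {
        "n_variants": len(variants),
        "n_combinations": n_combos,
        "n_genes": int(cohort.expression.n_genes),
        "n_tests_planned": n_combos * int(cohort.expression.n_genes),
        "n_records": int(len(records)),
        "n_skipped_combinations": int(n_combos - records["combination"].nunique())
        if len(records)
        else n_combos,
        "n_significant": int(records["significant"].sum()) if len(records) else 0,
        "q_fraction": config.q_fraction,
        "mode": config.mode,
        "alpha": config.alpha,
        "p_threshold": config.p_threshold,
        "max_size": config.max_size,
    }
    return records, log


def adjust_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for one test series."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def qq_data(p_values: np.ndarray) -> pd.DataFrame:
    """Observed vs expected -log10 p under the uniform null.

    Observed p-values are sorted ascending and paired with the uniform
    order-statistic expectations ``i / (m + 1)``.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    if p.size == 0:
        raise ValueError("no p-values")
    m = p.size
    expected = np.arange(1, m + 1) / (m + 1)
    # rows ascend the -log10 scale: the most significant point comes last
    return pd.DataFrame(
        {"expected": -np.log10(expected)[::-1], "observed": -np.log10(p)[::-1]}
    )


@dataclass
class CalibrationResult:
    """Outcome of the risk-group size sweep."""

    table: pd.DataFrame  # q, n_replicated, replicated (tuple), all_replicated
    selected_q: float | None
    known_egenes: tuple[str, ...] = field(default_factory=tuple)


def calibrate_group_size(
    cohort: Cohort,
    weights: VariantWeightTable,
    variant_set: Sequence[str] | None = None,
    known_egenes: Sequence[str] = (),
    q_grid: Sequence[float] = DEFAULT_Q_GRID,
    alpha: float = 0.05,
    covariate_columns: Sequence[str] | None = None,
) -> CalibrationResult:
    """Pick the smallest quantile fraction replicating all known eGenes.

    For each candidate ``q`` the GRS over the full ``variant_set`` is
    stratified and only the ``known_egenes`` are tested; BH adjustment is
    applied within that small batch.  The selected group size is the smallest
    grid value at which every known eGene reaches q-value < ``alpha``; if no
    grid value does, ``selected_q`` is None and a warning is issued.
    """
    if not known_egenes:
        raise ValueError("known_egenes must be non-empty")
    variants = (
        list(variant_set)
        if variant_set is not None
        else [v for v in cohort.genotypes.variant_ids if v in weights.table.index]
    )
    gene_idx = {g: i for i, g in enumerate(cohort.expression.gene_ids)}
    missing = [g for g in known_egenes if g not in gene_idx]
    if missing:
        raise KeyError(f"known eGenes absent from expression matrix: {missing}")

    design = build_covariate_design(cohort.covariates, covariate_columns)
    D = design.to_numpy(dtype=float)
    names = ["intercept", "high"] + list(design.columns)
    grs = compute_grs(cohort.genotypes, weights, variants)

    rows = []
    selected = None
    for q in sorted(q_grid):
        assignment = stratify(grs, q)
        used = assignment.used_mask
        high = assignment.high_mask[used].astype(float)
        X = np.column_stack([np.ones(int(used.sum())), high, D[used]])
        Y = cohort.expression.values[
            [gene_idx[g] for g in known_egenes]
        ].T[used]
        _, _, p, _ = _ols_indicator_scan(X, Y, names)
        qvals = adjust_fdr(p)
        replicated = tuple(
            g for g, qv in zip(known_egenes, qvals) if qv < alpha
        )
        all_rep = len(replicated) == len(known_egenes)
        rows.append(
            {
                "q": q,
                "n_replicated": len(replicated),
                "replicated": replicated,
                "all_replicated": all_rep,
            }
        )
        if all_rep and selected is None:
            selected = q
    if selected is None:
        warnings.warn(
            "no group size in the grid replicates all known eGenes", stacklevel=2
        )
    return CalibrationResult(
        table=pd.DataFrame(rows),
        selected_q=selected,
        known_egenes=tuple(known_egenes),
    )
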