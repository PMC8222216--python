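"""End-to-end orchestration: load or simulate a cohort, scan one test
series, adjust significance, and emit result tables with a run manifest.

One pipeline invocation is one test series (one FDR scope).  All randomness
flows from a single master seed recorded in the manifest; re-running the
same config and seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as cohort_io
from .datatypes import Cohort, VariantWeightTable
from .grs import count_combinations
from .report import summarize_egenes
from .scan import ScanConfig, calibrate_group_size, run_series
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["run_pipeline", "RunManifest", "load_config"]


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit given its inputs."""

    version: str
    seed: int
    config: dict
    input_digests: dict = field(default_factory=dict)
    n_samples: int = 0
    n_variants: int = 0
    variant_filter_report: dict = field(default_factory=dict)
    n_genes: int = 0
    n_combinations: int = 0
    n_tests: int = 0
    threshold_mode: str = "fdr"
    n_significant: int = 0
    selected_q: float | None = None

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _load_inputs(cfg: dict, manifest: RunManifest):
    inputs = cfg["inputs"]
    wt = cohort_io.read_weights(inputs["weights"])
    gm, report = cohort_io.read_genotypes(
        inputs["genotypes"],
        fmt=inputs.get("format"),
        maf_floor=inputs.get("maf_floor", 0.05),
        weights=wt,
    )
    expr = cohort_io.read_expression(inputs["expression"])
    cov = (
        cohort_io.read_covariates(inputs["covariates"])
        if inputs.get("covariates")
        else None
    )
    cohort = cohort_io.align_cohort(gm, expr, cov)
    manifest.variant_filter_report = report.as_dict()
    for key in ("genotypes", "weights", "expression", "covariates"):
        if inputs.get(key):
            manifest.input_digests[key] = _sha256(Path(inputs[key]))
    truth = None
    return cohort, wt, truth


def _simulate_inputs(cfg: dict, seed: int):
    sim_cfg = SimulationConfig.from_dict({**cfg.get("simulate", {}), "seed": seed})
    cohort, wt, truth = simulate_cohort(sim_cfg)
    return cohort, wt, truth


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> Path:
    """Run one full scan series from a config mapping or YAML path.

    Writes ``results.tsv`` (all association records), ``egenes.tsv``,
    ``truth.tsv`` (simulated cohorts only), ``calibration.tsv`` (when a
    calibration stage is configured) and ``manifest.json`` into the output
    directory, which is returned.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    outdir = Path(output_dir or cfg.get("output_dir", "grscan_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest = RunManifest(version=__version__, seed=seed, config=cfg)

    # --- inputs ------------------------------------------------------------
    try:
        if "inputs" in cfg:
            cohort, weights, truth = _load_inputs(cfg, manifest)
        elif "simulate" in cfg:
            cohort, weights, truth = _simulate_inputs(cfg, seed)
        else:
            raise ValueError("config needs either an 'inputs' or a 'simulate' section")
    except Exception as exc:
        raise StageError("inputs", exc) from exc

    manifest.n_samples = cohort.n_samples
    manifest.n_genes = int(cohort.expression.n_genes)

    # --- variant selection --------------------------------------------------
    try:
        category = cfg.get("category")
        if category:
            variants = [
                v
                for v in weights.variants_in_category(category)
                if v in set(cohort.genotypes.variant_ids)
            ]
            if not variants:
                raise ValueError(f"no genotyped variants in category {category!r}")
        else:
            variants = [
                v for v in cohort.genotypes.variant_ids if v in weights.table.index
            ]
        if not variants:
            raise ValueError("no variants survive filters and weight-table join")
        manifest.n_variants = len(variants)
    except Exception as exc:
        raise StageError("variant_selection", exc) from exc

    scan_cfg = ScanConfig(**cfg.get("scan", {}))
    manifest.threshold_mode = scan_cfg.mode
    manifest.n_combinations = count_combinations(len(variants), scan_cfg.max_size)
    manifest.n_tests = manifest.n_combinations * manifest.n_genes

    # --- optional group-size calibration ------------------------------------
    cal_cfg = cfg.get("calibrate")
    if cal_cfg:
        try:
            result = calibrate_group_size(
                cohort,
                weights,
                variants,
                known_egenes=cal_cfg["known_egenes"],
                q_grid=cal_cfg.get("q_grid", (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35)),
                alpha=cal_cfg.get("alpha", 0.05),
            )
            result.table.assign(
                replicated=result.table["replicated"].map(lambda t: "+".join(t))
            ).to_csv(outdir / "calibration.tsv", sep="\t", index=False)
            manifest.selected_q = result.selected_q
            if cal_cfg.get("use_selected_q", False) and result.selected_q is not None:
                scan_cfg.q_fraction = result.selected_q
        except Exception as exc:
            raise StageError("calibrate", exc) from exc

    # --- scan ----------------------------------------------------------------
    try:
        records, log = run_series(cohort, weights, variants, scan_cfg)
        cohort_io.write_associations(records, outdir / "results.tsv")
        manifest.n_significant = int(log["n_significant"])
    except Exception as exc:
        raise StageError("scan", exc) from exc

    # --- reporting -----------------------------------------------------------
    try:
        rep_cfg = cfg.get("report", {})
        stat = rep_cfg.get("stat", "q" if scan_cfg.mode == "fdr" else "p")
        threshold = rep_cfg.get(
            "threshold", scan_cfg.alpha if stat == "q" else scan_cfg.p_threshold
        )
        egenes = summarize_egenes(
            records,
            threshold=threshold,
            stat=stat,
            min_combinations=rep_cfg.get("min_combinations", 1),
        )
        egenes.to_csv(outdir / "egenes.tsv", sep="\t", index=False)
        if truth is not None:
            truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("report", exc) from exc

    manifest.write(outdir / "manifest.json")
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
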