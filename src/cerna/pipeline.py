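"""End-to-end orchestration: simulate/load -> preprocess -> DE -> axes -> enrichment.

A single config (YAML file or plain dict) drives the run.  Defaults pin
every threshold to the published parameterization: intensity > 100 in >=
25% of arrays, |log2FC| >= 0.5 with BH-adjusted p < 0.001 for DE calling,
Pearson r > 0.5 with correlation FDR < 0.001 for the co-expression gate,
and PPI combined score >= 0.4.  Each stage logs its input/output counts,
writes its artifacts to disk (so any downstream stage can be resumed from
files alone) and contributes to a machine-readable :class:`RunReport`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io_formats import (
    ConsistencyError,
    LNC_MIR,
    MIR_MRNA,
    read_expression_matrix,
    read_gmt,
    read_interaction_table,
    read_lncrna_list,
    read_ppi_table,
    read_sample_metadata,
    write_expression_matrix,
    write_network,
)
from .preprocess import (
    FilterReport,
    adjust_covariates,
    intensity_filter,
    iqr_filter,
    log2_transform,
    quantile_normalize,
)
from .diffexpr import call_degs, moderated_t_test, partition_lnc_mrna
from .axis_builder import (
    assemble_axes,
    axes_to_frame,
    axis_summary,
    build_candidate_triples,
    correlate_pairs,
    filter_interactions,
    overlay_ppi,
)
from .enrichment import enrich
from .synthetic_data import GroundTruth, SimulationConfig, simulate_study, write_study

__all__ = [
    "DEFAULT_THRESHOLDS",
    "ConfigurationError",
    "StageError",
    "RunReport",
    "run_pipeline",
    "score_against_truth",
]

log = logging.getLogger("cerna")

#: The published parameterization; every value can be overridden in config.
DEFAULT_THRESHOLDS = {
    "min_signal": 100.0,
    "min_fraction": 0.25,
    "lfc": 0.5,
    "fdr": 0.001,
    "r_min": 0.5,
    "corr_fdr": 0.001,
    "ppi_min_score": 0.4,
}


class ConfigurationError(ValueError):
    """The run config is unusable; detected before any computation."""


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is the first argument."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunReport:
    """Per-stage counts and settings of one pipeline run.

    ``wall_times`` is the only non-deterministic field; comparisons of
    reports across identically-seeded runs should exclude it (``to_json``
    keeps it in a separate top-level key for that reason).
    """

    config: dict
    seed: int
    version: str = __version__
    counts: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    recovery: dict = field(default_factory=dict)
    wall_times: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        times = payload.pop("wall_times")
        payload["wall_times"] = times  # last key; strip before diffing runs
        Path(path).write_text(json.dumps(payload, indent=1, default=str) + "\n")


def score_against_truth(axes, truth: GroundTruth) -> dict:
    """Sensitivity and decoy count of emitted axes against the planted set."""
    emitted = {(a.lncrna, a.mirna, a.mrna) for a in axes}
    planted = {(a.lncrna, a.mirna, a.mrna) for a in truth.planted_axes}
    recovered = emitted & planted
    return {
        "n_planted_axes": len(planted),
        "n_emitted_axes": len(emitted),
        "n_recovered_axes": len(recovered),
        "n_decoy_axes": len(emitted - planted),
        "sensitivity": (len(recovered) / len(planted)) if planted else None,
    }


def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, (str, Path)):
        try:
            config = yaml.safe_load(Path(config).read_text())
        except (OSError, yaml.YAMLError) as err:
            raise ConfigurationError(f"cannot read config: {err}") from err
    if not isinstance(config, dict):
        raise ConfigurationError("config must be a mapping")
    return dict(config)


def run_pipeline(config: str | Path | dict, out_dir: str | Path | None = None) -> RunReport:
    """Run the whole discovery pipeline from one config.

    Config keys (all optional unless noted):

    - ``simulate``: bool, default True; synthetic mode.
    - ``sim``: mapping of :class:`SimulationConfig` overrides.
    - ``inputs``: real-data mode paths (``expr``, ``meta``, ``lnc_list``,
      ``lnc_mir``, ``mir_mrna``, ``ppi``, ``gmt``); required when
      ``simulate`` is false.
    - ``thresholds``: overrides of :data:`DEFAULT_THRESHOLDS`.
    - ``covariates``: list, default ``[age, gender]``.
    - ``ordinary_t`` / ``strict_lfc``: DE statistic variants.
    - ``seed``: int, default 0.
    - ``out_dir``: output directory (may instead be given as the argument).
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    simulate = bool(cfg.get("simulate", True))
    thresholds = {**DEFAULT_THRESHOLDS, **cfg.get("thresholds", {})}
    covariates = cfg.get("covariates", ["age", "gender"])
    out_dir = Path(out_dir or cfg.get("out_dir", "cerna_run"))
    out_dir.mkdir(parents=True, exist_ok=True)

    unknown = set(thresholds) - set(DEFAULT_THRESHOLDS)
    if unknown:
        raise ConfigurationError(f"unknown threshold(s): {sorted(unknown)}")

    # pre-flight config validation: fail before any computation
    sim_config: SimulationConfig | None = None
    inputs: dict | None = None
    if simulate:
        sim_overrides = dict(cfg.get("sim", {}))
        sim_overrides.setdefault("seed", seed)
        try:
            sim_config = SimulationConfig(**sim_overrides)
        except (TypeError, ValueError) as err:
            raise ConfigurationError(f"invalid simulation config: {err}") from err
    else:
        inputs = cfg.get("inputs")
        if not inputs:
            raise ConfigurationError("real-data mode requires an 'inputs' mapping")
        required = {"expr", "meta", "lnc_list", "lnc_mir", "mir_mrna", "ppi", "gmt"}
        missing = required - set(inputs)
        if missing:
            raise ConfigurationError(f"missing input path(s): {sorted(missing)}")
        for key in sorted(required):
            if not Path(inputs[key]).exists():
                raise ConfigurationError(f"input file not found: {inputs[key]}")

    report = RunReport(config=cfg, seed=seed, thresholds=thresholds)
    truth: GroundTruth | None = None
    timer: dict[str, float] = report.wall_times

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                log.info("stage %s: start", name)
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timer[name] = round(time.perf_counter() - self.t0, 4)
                if exc is not None:
                    raise StageError(name, exc) from exc
                log.info("stage %s: done (%.2fs)", name, timer[name])

        return _Ctx()

    # ---- stage: inputs -----------------------------------------------------
    with _stage("inputs"):
        if simulate:
            study = simulate_study(sim_config)
            write_study(study, out_dir / "inputs")
            expr, meta = study.expression, study.metadata
            lnc_symbols = study.lnc_symbols
            lnc_mir_raw, mir_mrna_raw = study.lnc_mir, study.mir_mrna
            ppi_raw, gene_sets = study.ppi, study.gene_sets
            truth = study.truth
        else:
            expr = read_expression_matrix(inputs["expr"], scale=cfg.get("expr_scale", "linear"))
            meta = read_sample_metadata(inputs["meta"])
            lnc_symbols = read_lncrna_list(inputs["lnc_list"])
            lnc_mir_raw = read_interaction_table(inputs["lnc_mir"], LNC_MIR)
            mir_mrna_raw = read_interaction_table(inputs["mir_mrna"], MIR_MRNA)
            ppi_raw = read_ppi_table(inputs["ppi"], string_scale=cfg.get("string_scale", False))
            gene_sets = read_gmt(inputs["gmt"])
        missing_samples = set(expr.sample_ids) - set(meta["sample_id"])
        if missing_samples:
            raise ConsistencyError(
                f"sample {sorted(missing_samples)[0]!r} has expression but no metadata"
            )
        report.counts["n_samples"] = expr.shape[1]
        report.counts["n_genes_input"] = expr.shape[0]

    # ---- stage: preprocess -------------------------------------------------
    with _stage("preprocess"):
        norm = quantile_normalize(expr)
        filtered_linear, rep_int = intensity_filter(
            norm, thresholds["min_signal"], thresholds["min_fraction"]
        )
        logged = log2_transform(filtered_linear)
        filtered_log2, rep_iqr = iqr_filter(logged)
        filter_report = FilterReport.merge(rep_int, rep_iqr)
        adjusted = adjust_covariates(filtered_log2, meta, list(covariates))
        write_expression_matrix(adjusted, out_dir / "expression_processed.tsv")
        (out_dir / "filter_report.json").write_text(
            json.dumps(filter_report.to_dict(), indent=1) + "\n"
        )
        report.counts["n_after_intensity"] = filter_report.n_after_intensity
        report.counts["n_after_iqr"] = filter_report.n_after_iqr

    # ---- stage: diffexpr ---------------------------------------------------
    with _stage("diffexpr"):
        de = moderated_t_test(adjusted, meta, ordinary=bool(cfg.get("ordinary_t", False)))
        de = call_degs(
            de,
            lfc_cut=thresholds["lfc"],
            fdr_cut=thresholds["fdr"],
            strict_lfc=bool(cfg.get("strict_lfc", False)),
        )
        delnc, demrna = partition_lnc_mrna(de, lnc_symbols)
        de["biotype"] = ["lncRNA" if s in lnc_symbols else "mRNA" for s in de.index]
        de.to_csv(out_dir / "de_table.tsv", sep="\t", float_format="%.6g")
        report.counts["n_delncrna"] = len(delnc)
        report.counts["n_demrna"] = len(demrna)

    # ---- stage: axes -------------------------------------------------------
    with _stage("axes"):
        lnc_mir = filter_interactions(lnc_mir_raw, LNC_MIR)
        mir_mrna = filter_interactions(mir_mrna_raw, MIR_MRNA)
        triples = build_candidate_triples(
            set(delnc.index), set(demrna.index), lnc_mir, mir_mrna
        )
        pairs = sorted({(t.lncrna, t.mrna) for t in triples})
        correlations = correlate_pairs(adjusted, pairs)
        found = set(zip(correlations["lncrna"], correlations["mrna"]))
        dropped = frozenset(p for p in pairs if p not in found)
        axes = assemble_axes(
            triples,
            de,
            correlations,
            r_min=thresholds["r_min"],
            fdr_max=thresholds["corr_fdr"],
            dropped_pairs=dropped,
        )
        ppi_edges = overlay_ppi(axes, ppi_raw, thresholds["ppi_min_score"])
        axes_to_frame(axes).to_csv(out_dir / "axes.tsv", sep="\t", index=False, float_format="%.6g")
        correlations.to_csv(
            out_dir / "correlations.tsv", sep="\t", index=False, float_format="%.6g"
        )
        write_network(axes, ppi_edges, out_dir / "network", de_table=de)
        report.counts["n_candidate_triples"] = len(triples)
        report.counts.update(axis_summary(axes))
        report.counts["n_ppi_edges"] = len(ppi_edges)

    # ---- stage: enrichment -------------------------------------------------
    with _stage("enrichment"):
        axis_mrnas = {a.mrna for a in axes}
        universe = set(adjusted.gene_ids)
        if axis_mrnas and len(gene_sets):
            enr = enrich(axis_mrnas, gene_sets, universe)
            enr.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
            report.counts["n_enriched_sets_fdr05"] = int((enr["adj_p"] < 0.05).sum())
            report.counts["top_enriched_set"] = (
                str(enr.iloc[0]["set_name"]) if len(enr) else None
            )
        else:
            (out_dir / "enrichment.tsv").write_text(
                "set_name\toverlap_k\tset_size_K\tquery_n\tuniverse_N\tp_value\tadj_p\toverlap_genes\n"
            )
            report.counts["n_enriched_sets_fdr05"] = 0
            report.counts["top_enriched_set"] = None

    # ---- stage: report -----------------------------------------------------
    with _stage("report"):
        if truth is not None:
            report.recovery = score_against_truth(axes, truth)
        report.to_json(out_dir / "run_report.json")

    return report
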