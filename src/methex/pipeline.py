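"""Pipeline orchestration: chain simulate -> score -> methionine -> screen ->
survive (-> integrate) from a flat key/value config, writing per-stage
tab-delimited outputs and a JSON run manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import io as mio
from .exceptions import ConfigurationError, StageError
from .integration import cnv_expression_assoc, intersect_driven_genes
from .metabolites import (
    es_metabolite_screen,
    impute_min,
    serum_mta_normalize,
    tumor_nontumor_ratio,
)
from .methionine import bulk_pathway_scores, classify_cells, sc_pathway_difference, tumor_dominance
from .score import ExhaustionScoreModel, cytolytic_score
from .signature import cd3_normalize
from .simulate import CohortConfig, generate_bulk_cohort
from .survival import cox_fit, km_estimate, logrank_test, median_split

__all__ = ["run_pipeline", "DEFAULT_STAGES"]

DEFAULT_STAGES = ["simulate", "score", "methionine", "screen", "survive"]

_COHORT_FIELDS = {
    "n_samples": int,
    "n_signature_genes": int,
    "n_noise_genes": int,
    "exhaustion_effect": float,
    "hazard_log_hr": float,
    "censor_rate": float,
    "metabolite_rho": float,
    "n_null_metabolites": int,
    "salvage_denovo_anticorr": float,
    "noise_sd": float,
    "seed": int,
}


def _cohort_config(cfg: dict[str, str]) -> CohortConfig:
    kwargs = {}
    for name, cast in _COHORT_FIELDS.items():
        if name in cfg:
            try:
                kwargs[name] = cast(cfg[name])
            except ValueError as exc:
                raise ConfigurationError(f"invalid value for '{name}': {cfg[name]}") from exc
    return CohortConfig(**kwargs)


def _require(data: dict, key: str, stage: str):
    if data.get(key) is None:
        raise StageError(f"stage '{stage}' requires missing input '{key}' "
                         f"(provide a path or enable the simulate stage)")
    return data[key]


def run_pipeline(config_path, out_dir=None) -> dict:
    """Execute the configured stages; returns {stage: {name: path}}.

    The config is a flat ``key = value`` file; ``stages`` is a comma list
    (default ``simulate,score,methionine,screen,survive``). Without the
    simulate stage, input tables are read from the paths named by keys
    ``expression``, ``clinical``, ``signature``, ``tumor_metabolome``,
    ``nontumor_metabolome``, ``serum_metabolome``, ``single_cell_dir``,
    ``cnv``, ``peak_table``, ``de_table``.
    """
    cfg = mio.read_config(config_path) if not isinstance(config_path, dict) else dict(config_path)
    out = Path(out_dir if out_dir is not None else cfg.get("out", "methex_out"))
    out.mkdir(parents=True, exist_ok=True)
    stages = [s.strip() for s in cfg.get("stages", ",".join(DEFAULT_STAGES)).split(",") if s.strip()]
    seed = int(cfg.get("seed", 0))
    linear = cfg.get("linear", "false").lower() in ("1", "true", "yes")
    alpha = float(cfg.get("alpha", 0.001))

    data: dict = {k: None for k in (
        "expression", "clinical", "signature", "tumor_metabolome", "nontumor_metabolome",
        "serum_metabolome", "single_cell", "cnv", "scores",
    )}
    # pre-load any explicitly configured inputs
    if cfg.get("expression"):
        data["expression"] = mio.read_expression(cfg["expression"], linear=linear)
    if cfg.get("clinical"):
        data["clinical"] = mio.read_survival(cfg["clinical"])
    if cfg.get("signature"):
        data["signature"] = mio.read_table(cfg["signature"])["gene"].tolist()
    for key in ("tumor_metabolome", "nontumor_metabolome", "serum_metabolome"):
        if cfg.get(key):
            data[key] = mio.read_metabolites(cfg[key])
    if cfg.get("single_cell_dir"):
        scd = Path(cfg["single_cell_dir"])
        data["single_cell"] = mio.read_single_cell(
            scd / "matrix.mtx", scd / "cells.tsv", scd / "genes.tsv"
        )
    if cfg.get("cnv"):
        data["cnv"] = mio.read_expression(cfg["cnv"])
    if cfg.get("scores"):
        data["scores"] = mio.read_table(cfg["scores"]).set_index("sample")

    report: dict = {}
    for stage in stages:
        sdir = out / stage
        sdir.mkdir(exist_ok=True)
        if stage == "simulate":
            cc_cfg = dict(cfg)
            cc_cfg.setdefault("seed", str(seed))
            bundle = generate_bulk_cohort(_cohort_config(cc_cfg))
            paths = bundle.write(sdir)
            data.update(
                expression=bundle.bulk_expression,
                clinical=bundle.clinical,
                signature=bundle.signature_genes,
                tumor_metabolome=bundle.tumor_metabolome,
                nontumor_metabolome=bundle.nontumor_metabolome,
                serum_metabolome=bundle.serum_metabolome,
                single_cell=bundle.single_cell,
                cnv=bundle.cnv,
            )
            report[stage] = {k: str(v) for k, v in paths.items()}
        elif stage == "score":
            expr = _require(data, "expression", stage)
            clin = _require(data, "clinical", stage)
            sig = _require(data, "signature", stage)
            normalized = cd3_normalize(expr, sig)
            model = ExhaustionScoreModel(
                normalized.loc[[g for g in sig if g in normalized.index]], clin, alpha=alpha
            ).fit()
            scores = model.predict(normalized)
            scores["CYT"] = cytolytic_score(expr)
            scores["risk_group"] = median_split(scores["ES"])
            data["scores"] = scores
            mio.write_table(scores, sdir / "scores.tsv", index_label="sample")
            model.to_json(sdir / "model.json")
            report[stage] = {"scores": str(sdir / "scores.tsv"), "model": str(sdir / "model.json")}
        elif stage == "methionine":
            expr = _require(data, "expression", stage)
            pw = bulk_pathway_scores(expr)
            mio.write_table(pw, sdir / "pathway_scores.tsv", index_label="sample")
            report[stage] = {"pathway_scores": str(sdir / "pathway_scores.tsv")}
            if data.get("single_cell") is not None:
                diffs = sc_pathway_difference(data["single_cell"])
                labels = classify_cells(diffs)
                comp = tumor_dominance(labels, diffs["tumor"])
                diffs["program"] = labels
                mio.write_table(diffs, sdir / "sc_differences.tsv", index_label="cell_id")
                mio.write_table(comp, sdir / "tumor_composition.tsv")
                report[stage]["sc_differences"] = str(sdir / "sc_differences.tsv")
                report[stage]["tumor_composition"] = str(sdir / "tumor_composition.tsv")
        elif stage == "screen":
            scores = _require(data, "scores", stage)
            tumor = _require(data, "tumor_metabolome", stage)
            nontumor = _require(data, "nontumor_metabolome", stage)
            ratios = tumor_nontumor_ratio(impute_min(tumor), impute_min(nontumor))
            screen = es_metabolite_screen(scores["ES"], ratios)
            mio.write_table(screen, sdir / "screen.tsv")
            report[stage] = {"screen": str(sdir / "screen.tsv")}
            if data.get("serum_metabolome") is not None:
                serum = serum_mta_normalize(impute_min(data["serum_metabolome"]))
                mio.write_table(serum.to_frame(), sdir / "serum_mta.tsv", index_label="sample")
                report[stage]["serum_mta"] = str(sdir / "serum_mta.tsv")
        elif stage == "survive":
            scores = _require(data, "scores", stage)
            clin = _require(data, "clinical", stage)
            groups = median_split(scores["ES"].astype(float))
            km = km_estimate(clin, groups)
            curves = pd.concat([est.as_frame() for est in km.values()], ignore_index=True)
            mio.write_table(curves, sdir / "km_curves.tsv", index=False)
            stat, p = logrank_test(clin, groups)
            fit = cox_fit(clin, (groups == "high").astype(float).rename("ES_high"))
            payload = {"logrank_statistic": stat, "logrank_p": p, "cox": fit.to_dict()}
            with open(sdir / "survival.json", "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
                fh.write("\n")
            report[stage] = {
                "km_curves": str(sdir / "km_curves.tsv"),
                "survival": str(sdir / "survival.json"),
            }
        elif stage == "integrate":
            report[stage] = {}
            if cfg.get("peak_table") and cfg.get("de_table"):
                peaks = mio.read_table(cfg["peak_table"])
                de = mio.read_table(cfg["de_table"])
                exclusion = ()
                if cfg.get("exclusion_list"):
                    exclusion = mio.read_table(cfg["exclusion_list"])["gene"].tolist()
                driven = intersect_driven_genes(peaks, de, exclusion_list=exclusion)
                mio.write_table(driven, sdir / "driven_genes.tsv", index=False)
                report[stage]["driven_genes"] = str(sdir / "driven_genes.tsv")
            if data.get("cnv") is not None and data.get("expression") is not None:
                summary, calls = cnv_expression_assoc(data["cnv"], data["expression"])
                mio.write_table(summary, sdir / "cnv_assoc.tsv")
                mio.write_table(calls, sdir / "cnv_calls.tsv", index=False)
                report[stage]["cnv_assoc"] = str(sdir / "cnv_assoc.tsv")
            if not report[stage]:
                raise StageError(
                    "stage 'integrate' requires peak_table+de_table and/or cnv+expression inputs"
                )
        else:
            raise ConfigurationError(f"unknown stage '{stage}'")

    params = {k: v for k, v in cfg.items() if k != "out"}  # location is not a parameter
    mio.write_manifest(out / "manifest.json", seed=seed, parameters=params, stages=stages)
    report["manifest"] = str(out / "manifest.json")
    return report
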