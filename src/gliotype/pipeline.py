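"""End-to-end pipeline orchestration for ``tp run``.

One master seed spawns per-stage seeds, so any stage can be rerun in
isolation reproducibly.  Every artifact directory gets a ``run_log.json``
stamped with the configuration hash, the seed, and the counts a consensus
run is judged by: removed iterations, unsupervised-ambiguous samples, and
ensemble-ambiguous samples.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import dbu as dbu_mod
from . import ensemble as ens
from . import signature as sig
from .characterization import concordance, km_logrank, mutation_enrichment, purity_by_group
from .config import config_hash
from .io_preprocess import (
    ExpressionMatrix,
    read_clinical,
    read_expression,
    read_labels,
    read_mutations,
    read_purity,
    standardize,
    write_expression,
)
from .synthetic import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def run_pipeline(cfg: dict) -> dict:
    """Execute simulate/load -> dbu -> signature -> dictionary -> classify -> characterize."""
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg["seed"])
    log: dict = {"config_hash": config_hash(cfg), "seed": cfg["seed"]}
    cohort = None

    stage = "simulate" if "simulate" in cfg else "load"
    try:
        if "simulate" in cfg:
            cohort = generate_cohort(CohortConfig(**{
                **{k: tuple(v) if isinstance(v, list) else v for k, v in cfg["simulate"].items()},
                "seed": seeds[0],
            }))
            expr = cohort.expression
            clinical = cohort.clinical
            mutations = cohort.mutations
            purity = cohort.purity
            write_expression(expr, out / "expression.tsv")
            clinical.to_csv(out / "clinical.tsv", sep="\t")
            cohort.true_subtype.to_frame().rename_axis("sample_id").to_csv(out / "truth.tsv", sep="\t")
        else:
            paths = cfg["input"]
            expr = read_expression(paths["expression"])
            if not expr.standardized:
                expr = standardize(expr)
            clinical = read_clinical(paths["clinical"])
            mutations = read_mutations(paths["mutations"]) if paths.get("mutations") else None
            purity = read_purity(paths["purity"]) if paths.get("purity") else None
    except Exception as err:
        raise PipelineError(stage, err) from err

    stage = "dbu"
    try:
        d = cfg["dbu"]
        params = dbu_mod.DBUParams(
            n_iterations=d["n_iterations"],
            genes_per_iteration=d["genes_per_iteration"],
            n_neighbors=d["n_neighbors"],
            min_dist=d["min_dist"],
            metric=d["metric"],
            min_points=d["min_points"],
            eps=d["eps"] if d["eps"] == "auto" else float(d["eps"]),
            expected_groups=d["expected_groups"],
            ambiguity_threshold=d["ambiguity_threshold"],
            seed=seeds[1],
        )
        if d["subcluster"]:
            labels, calls, subres = dbu_mod.run_dbu_with_subclustering(expr, params)
            log["subclusters_split"] = [g for g, r in subres.items() if r.split]
        else:
            calls, _ = dbu_mod.run_dbu(expr, params)
            labels = calls.labels
        frame = calls.calls.copy()
        frame["consensus_class"] = labels
        frame.to_csv(out / "calls.tsv", sep="\t")
        calls.votes.to_csv(out / "votes.tsv", sep="\t")
        log["dbu_retained_iterations"] = calls.n_retained_iterations
        log["dbu_removed_iterations"] = d["n_iterations"] - calls.n_retained_iterations
        log["dbu_ambiguous"] = int((labels == dbu_mod.AMBIGUOUS).sum())
    except Exception as err:
        raise PipelineError(stage, err) from err

    stage = "signature"
    try:
        s = cfg["signature"]
        curated = s["curated"]
        if isinstance(curated, str):
            curated = [l.strip() for l in Path(curated).read_text().splitlines() if l.strip()]
        signature = sig.build_signature(
            expr,
            labels,
            n_select=s["n_select"],
            curated_genes=curated,
            n_groups=s["n_groups"],
            candidate_pool=s["candidate_pool"],
            step=s["step"],
            seed=seeds[2],
        )
        signature.to_json(out / "signature.json")
    except Exception as err:
        raise PipelineError(stage, err) from err

    stage = "dictionary"
    try:
        dc = cfg["dictionary"]
        dictionary = sig.build_model_dictionary(
            expr, labels, signature, n_models=dc["n_models"], step=dc["step"],
            cv=dc["cv_folds"], seed=seeds[3],
        )
        dictionary = sig.cv_filter_models(
            dictionary, expr, labels, folds=dc["cv_folds"], floor=dc["floor"], seed=seeds[3]
        )
        dictionary.to_json(out / "dictionary.json")
        log["dictionary_entries"] = len(dictionary)
        log["dictionary_mean_accuracy"] = float(np.mean(dictionary.cv_accuracy))
    except Exception as err:
        raise PipelineError(stage, err) from err

    stage = "classify"
    try:
        predictions = ens.crossfit_calls(
            expr, labels, dictionary, n_folds=cfg["ensemble"]["n_folds"], seed=seeds[4]
        )
        predictions.to_csv(out / "predictions.tsv", sep="\t")
        model = ens.fit_final(expr, labels, dictionary, seed=seeds[4])
        model.to_json(out / "model.json")
        log["etc_ambiguous"] = int((predictions["call"] == dbu_mod.AMBIGUOUS).sum())
    except Exception as err:
        raise PipelineError(stage, err) from err

    stage = "characterize"
    try:
        etc_labels = predictions["call"]
        if mutations is not None:
            mutation_enrichment(mutations, etc_labels).to_csv(
                out / "mutation_enrichment.tsv", sep="\t", index=False
            )
        if clinical is not None:
            summary = km_logrank(clinical, etc_labels, reference=cfg["characterize"]["reference_group"])
            summary.hazard_ratios.assign(
                reference=summary.reference,
                logrank_statistic=summary.logrank_statistic,
                logrank_p=summary.logrank_p,
            ).to_csv(out / "survival.tsv", sep="\t", index=False)
        if purity is not None:
            table, f_stat, p = purity_by_group(purity, etc_labels)
            table.assign(anova_F=f_stat, anova_p=p).to_csv(out / "purity.tsv", sep="\t", index=False)
        compare = cfg["characterize"]["compare"]
        if compare == "truth" and cohort is not None:
            other = cohort.true_subtype
        elif compare not in (None, "truth"):
            header = pd.read_csv(compare, sep="\t", nrows=0).columns
            other = read_labels(compare, column=header[1])
        else:
            other = None
        if other is not None:
            result = concordance(etc_labels, other)
            result.table.to_csv(out / "concordance.tsv", sep="\t")
            log["concordance"] = result.agreement
    except Exception as err:
        raise PipelineError(stage, err) from err

    (out / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
    return {"out_dir": str(out), "log": log}
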