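"""End-to-end orchestration of the synthetic signature pipeline.

``run_pipeline`` sequences the stages: simulate a cell-line time course,
compute log2 ratios against untreated controls, run the seven-comparison
differential screen, prune to the strongest probesets (plus an optional
curated list), translate the signature against simulated tumor cohorts,
score a fresh cohort, run survival and association analyses, and emit
TSV artifacts plus a machine-readable JSON run report.

The run report records, for every executed stage, its input/output
counts (so the probeset funnel is always visible), the thresholds used,
orientation signs, test statistics and the seeds — identical config and
seed give an identical report (a ``timestamp`` field aside).  Artifact
files are written atomically (temp-then-rename).
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
import time
from pathlib import Path

import pandas as pd
import yaml

from . import defilter, signature as sigmod, scoring, survival, associations, simulate
from .defilter import FilterConfig, GroupScheme
from .expression import compute_log_ratios, write_expression_matrix

DEFAULT_CONFIG = {
    "seed": 0,
    "thresholds": {
        "fold_threshold_log2": 0.585,
        "strong_fold_threshold_log2": 1.0,
        "strong_p_cutoff": 0.002,
    },
    "min_agree_fraction": 0.5,
    "n_translation_cohorts": 3,
    "horizons_months": [36, 60],
    "simulation": {},   # nested overrides of the SimulationConfig dataclasses
}


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage label."""


def load_config(path_or_dict) -> dict:
    """Merge a YAML config file (or dict) over the defaults."""
    if path_or_dict is None:
        user = {}
    elif isinstance(path_or_dict, dict):
        user = path_or_dict
    else:
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy

    def merge(dst, src):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    merge(cfg, user)
    return cfg


def build_simulation_config(overrides: dict | None = None) -> simulate.SimulationConfig:
    """SimulationConfig with nested dict overrides applied."""
    sim = simulate.SimulationConfig()
    for block, values in (overrides or {}).items():
        if not hasattr(sim, block):
            raise PipelineError(f"unknown simulation block {block!r}")
        sub = getattr(sim, block)
        for k, v in values.items():
            if not hasattr(sub, k):
                raise PipelineError(f"unknown simulation field {block}.{k}")
            if isinstance(v, list):
                v = tuple(v)
            setattr(sub, k, v)
    sim.validate()
    return sim


def _atomic_write(path: Path, writer) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _write_tsv(df: pd.DataFrame, path: Path, index=False) -> None:
    _atomic_write(path, lambda tmp: df.to_csv(tmp, sep="\t", index=index))


def run_pipeline(config=None, out_dir=None, seed: int | None = None) -> dict:
    """Run the full synthetic pipeline; returns the run report dict.

    ``config`` may be a YAML path, a dict of overrides, or None for the
    defaults; ``seed`` overrides the config seed.  When ``out_dir`` is
    given, artifacts (ratio matrix, category table, signature,
    translation report, scores, KM curves, report JSON) are written
    there atomically.
    """
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    seed = int(cfg["seed"])
    out = Path(out_dir) if out_dir is not None else None
    fcfg = FilterConfig(**cfg["thresholds"])
    sim = build_simulation_config(cfg.get("simulation"))

    report = {"seed": seed, "thresholds": dataclasses.asdict(fcfg),
              "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
              "stages": []}

    def stage(name, **info):
        report["stages"].append({"stage": name, **info})

    try:
        matrix, ann, truth = simulate.simulate_cellline_experiment(sim, seed)
        stage("simulate_cellline", n_probesets=matrix.shape[0],
              n_samples=matrix.shape[1])
    except Exception as e:  # noqa: BLE001 - re-raise with stage label
        raise PipelineError(f"simulate_cellline: {e}") from e

    try:
        ratios = compute_log_ratios(matrix, ann)
        stage("log_ratios", n_probesets=ratios.shape[0], n_samples=ratios.shape[1])
    except Exception as e:
        raise PipelineError(f"log_ratios: {e}") from e

    try:
        scheme = GroupScheme.from_annotation(ann)
        stats_by, calls, categories = defilter.run_de_screen(ratios, scheme, fcfg)
        cat_counts = categories["category"].value_counts().to_dict()
        stage("de_screen", n_input=ratios.shape[0], categories=cat_counts)
    except Exception as e:
        raise PipelineError(f"de_screen: {e}") from e

    try:
        selected = sigmod.strongest_filter(categories, stats_by, fcfg)
        curated = pd.DataFrame(columns=["probeset_id", "gene_symbol"])
        sig = sigmod.add_curated(selected, curated, categories,
                                 matrix.gene_symbols, name="synthetic-EMT")
        stage("signature_builder", n_categorized=int(
            (categories["category"] == "EMT-related").sum()),
            n_strongest=len(selected), n_with_curated=len(sig))
    except Exception as e:
        raise PipelineError(f"signature_builder: {e}") from e

    try:
        n_coh = int(cfg["n_translation_cohorts"])
        cohorts = [simulate.simulate_tumor_cohort(sim, sig, seed + 1000 + i)[0]
                   for i in range(n_coh)]
        sig_t, trans_report = sigmod.translation_filter(
            sig, cohorts, float(cfg["min_agree_fraction"]))
        stage("translation", n_input=len(sig), n_cohorts=n_coh,
              n_output=len(sig_t))
    except Exception as e:
        raise PipelineError(f"translation: {e}") from e

    try:
        tumor_m, tumor_ann, tumor_truth = simulate.simulate_tumor_cohort(
            sim, sig_t, seed + 2000)
        scored = scoring.score_cohort(tumor_m, sig_t)
        groups = scoring.median_split(scored.scores)
        stage("scoring", n_samples=len(scored.scores),
              orientation_sign=scored.orientation_sign,
              pct_variance_pc1=scored.pct_variance,
              n_high=int((groups == "high").sum()),
              n_low=int((groups == "low").sum()))
    except Exception as e:
        raise PipelineError(f"scoring: {e}") from e

    try:
        surv_out = {}
        curves = {}
        for endpoint in ("OS", "MFS"):
            recs = survival.build_endpoint(tumor_ann, endpoint)
            recs = recs.merge(groups.rename("group"), left_on="sample_id",
                              right_index=True)
            hi = recs[recs["group"] == "high"]
            lo = recs[recs["group"] == "low"]
            chi2, p = survival.logrank_test(hi, lo)
            entry = {"n": len(recs), "n_high": len(hi), "n_low": len(lo),
                     "chi2": chi2, "p": p, "delta_surv_pct": {}}
            ch, cl = survival.km_estimate(hi), survival.km_estimate(lo)
            curves[endpoint] = (ch, cl)
            for h in cfg["horizons_months"]:
                if h <= min(ch.max_time, cl.max_time):
                    entry["delta_surv_pct"][str(h)] = survival.delta_surv(ch, cl, h)
            surv_out[endpoint] = entry
        stage("survival", **surv_out)
    except Exception as e:
        raise PipelineError(f"survival: {e}") from e

    try:
        colon_m, colon_ann = simulate.simulate_colon_cohort(sim, sig_t, seed + 3000)
        colon_scores = scoring.score_cohort(colon_m, sig_t).scores
        t, p, means = associations.score_group_ttest(
            colon_scores, colon_ann.set_index("sample_id")["met_at_surgery"])
        mut_m, mut_ann, mut_truth = simulate.simulate_mutation_cohort(
            sim, sig_t, seed + 4000)
        km_groups = scoring.kmeans_split(mut_m, sig_t, seed=seed)
        mut_cols = [c for c in mut_ann.columns if c.startswith("mut_")]
        enrich = associations.fisher_enrichment(
            km_groups, mut_ann.set_index("sample_id")[mut_cols])
        stage("associations", colon_t=t, colon_p=p,
              colon_means={str(k): v for k, v in means.items()},
              n_mutation_genes=len(enrich),
              top_enriched_gene=(enrich.iloc[0]["gene"] if len(enrich) else None),
              top_enriched_p=(float(enrich.iloc[0]["p"]) if len(enrich) else None))
    except Exception as e:
        raise PipelineError(f"associations: {e}") from e

    if out is not None:
        _atomic_write(out / "ratios.tsv",
                      lambda tmp: write_expression_matrix(ratios, tmp))
        _write_tsv(categories.rename_axis("probeset_id").reset_index(),
                   out / "categories.tsv")
        _atomic_write(out / "signature.tsv", lambda tmp: sig_t.save(tmp))
        _write_tsv(trans_report.rename_axis("probeset_id").reset_index(),
                   out / "translation_report.tsv")
        scores_df = pd.DataFrame({"sample_id": scored.scores.index,
                                  "score": scored.scores.to_numpy(),
                                  "group": groups.to_numpy(),
                                  "method": "median"})
        _write_tsv(scores_df, out / "scores.tsv")
        for endpoint, (ch, cl) in curves.items():
            for label, c in (("high", ch), ("low", cl)):
                km_df = pd.DataFrame({"time": c.event_times,
                                      "at_risk": c.at_risk,
                                      "events": c.n_events,
                                      "survival": c.survival})
                _write_tsv(km_df, out / f"km_{endpoint.lower()}_{label}.tsv")
        _write_tsv(enrich, out / "mutation_enrichment.tsv")
        _atomic_write(out / "report.json",
                      lambda tmp: Path(tmp).write_text(
                          json.dumps(report, indent=2, default=float)))
        _atomic_write(out / "config_resolved.yaml",
                      lambda tmp: Path(tmp).write_text(yaml.safe_dump(cfg)))
    return report
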