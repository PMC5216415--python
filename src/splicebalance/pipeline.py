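"""End-to-end pipeline: simulate/load -> normalize -> SI -> differential ->
partition -> classification -> enrichment -> survival.

Driven by a flat YAML-style configuration dictionary; every stage that
consumes randomness receives a seed derived deterministically from the
root seed and the stage name, so a re-run with the same configuration is
byte-identical.  Outputs are TSV tables plus a JSON manifest recording
the configuration, derived seeds, package versions and a SHA-256
checksum of every written file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError, DataError
from . import simulate as sim
from . import expression as expr
from . import differential as diff
from . import classify as clf
from . import enrichment as enr
from . import survival as surv

logger = logging.getLogger(__name__)

KNOWN_STAGES = (
    "simulate", "normalize", "si", "diff", "partition", "classify", "enrich", "survival",
)
DEFAULT_STAGES = (
    "simulate", "normalize", "si", "diff", "partition", "classify", "survival",
)


def derive_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(root_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _validate_config(config: dict):
    stages = config.get("stages", list(DEFAULT_STAGES))
    unknown = set(stages) - set(KNOWN_STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stage(s): {sorted(unknown)}")
    if "simulate" not in stages and "dataset" not in config:
        raise ConfigurationError("config needs a 'simulate' stage or a 'dataset' directory")
    thresholds = config.get("thresholds", {})
    for key, default in (("diff_q", 0.001), ("survival_q", 0.1), ("nonde_q", 0.01)):
        val = thresholds.get(key, default)
        if not 0 < val < 1:
            raise ConfigurationError(f"threshold {key} must be in (0, 1)")
    return stages


def _resolve_groups(config: dict, samples: pd.DataFrame | None):
    comparisons = config.get("comparisons")
    if comparisons is None:
        if samples is None:
            raise ConfigurationError("no comparisons configured and no sample table yet")
        groups = list(dict.fromkeys(samples["group"]))
        comparisons = [[groups[0], groups[-1]]]
    if samples is not None:
        known = set(samples["group"])
        for pair in comparisons:
            for g in pair:
                if g not in known:
                    raise ConfigurationError(f"comparison group {g!r} not in sample table")
    return [tuple(pair) for pair in comparisons]


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the configured stages; returns the manifest dictionary."""
    stages = _validate_config(config)
    root_seed = int(config.get("seed", 0))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    thresholds = {
        "diff_q": 0.001, "survival_q": 0.1, "nonde_q": 0.01,
        **config.get("thresholds", {}),
    }
    written: dict[str, Path] = {}

    def save(name: str, frame: pd.DataFrame, index_label=None):
        path = out_dir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")
        written[name] = path
        return path

    # --- obtain the cohort -------------------------------------------------
    if "simulate" in stages:
        sim_conf = dict(config.get("simulate", {}))
        sim_conf.setdefault("seed", derive_seed(root_seed, "simulate"))
        if "exon_count_range" in sim_conf:
            sim_conf["exon_count_range"] = tuple(sim_conf["exon_count_range"])
        cohort = sim.generate_cohort(sim.CohortConfig(**sim_conf))
        paths = sim.write_dataset(
            cohort.matrix, cohort.annotation, cohort.samples, cohort.truth,
            out_dir / "dataset",
        )
        written.update({f"dataset_{k}": v for k, v in paths.items()})
    else:
        cohort = sim.read_dataset(config["dataset"])
    matrix, annotation, samples, truth = cohort
    comparisons = _resolve_groups(config, samples)

    # --- normalize / summarize / SI ---------------------------------------
    if "normalize" in stages:
        matrix = expr.quantile_normalize(matrix)
        save("normalized", matrix, index_label="probe_id")
    summarize_method = config.get("summarize_method", "median_polish")
    gene_matrix = expr.summarize_gene_expression(matrix, annotation, summarize_method)
    si_matrix = expr.compute_splicing_index(matrix, annotation)
    if "si" in stages:
        save("splicing_index", si_matrix, index_label="probe_id")
        save("gene_expression", gene_matrix, index_label="gene_id")

    # SI testing is restricted to multi-probe genes (single-probe SI == 1)
    probe_gene = annotation["gene_id"]
    multi = probe_gene.map(probe_gene.value_counts()) >= 2
    si_testable = si_matrix.loc[multi]

    results: dict[str, dict] = {"comparisons": {}}
    ge_tables: dict[tuple, pd.DataFrame] = {}
    if {"diff", "partition", "classify"} & set(stages):
        for pair in comparisons:
            a, b = pair
            mask = samples["group"].isin(pair)
            sub_samples = samples.loc[mask]
            labels = sub_samples["group"]
            tag = f"{a}_vs_{b}"
            try:
                ge = diff.moderated_t_test(
                    gene_matrix.loc[:, sub_samples.index], labels, level="GE",
                    group_order=(a, b),
                )
                ee = diff.moderated_t_test(
                    matrix.loc[:, sub_samples.index], labels, level="EE",
                    group_order=(a, b),
                )
                si_t = diff.moderated_t_test(
                    si_testable.loc[:, sub_samples.index], labels, level="SI",
                    group_order=(a, b),
                )
            except (DataError, ConfigurationError):
                logger.exception("differential stage failed for %s", tag)
                results["comparisons"][tag] = {"error": "differential stage failed"}
                raise
            ge_tables[pair] = ge
            if "diff" in stages:
                save(f"diff_ge_{tag}", ge, index_label="feature_id")
                ee_out = ee.copy()
                ee_out.insert(0, "gene_id", annotation.loc[ee.index, "gene_id"])
                save(f"diff_ee_{tag}", ee_out, index_label="feature_id")
                si_out = si_t.copy()
                si_out.insert(0, "gene_id", annotation.loc[si_t.index, "gene_id"])
                save(f"diff_si_{tag}", si_out, index_label="feature_id")
            if "partition" in stages:
                calls = diff.call_genes(ge, si_t, annotation, thresholds["diff_q"])
                summary = diff.partition_summary(calls)
                save(f"gene_calls_{tag}", calls, index_label="gene_id")
                save(f"partition_{tag}", summary, index_label="category")
                results["comparisons"][tag] = {
                    "partition": summary["count"].to_dict()
                }

    # --- classification ----------------------------------------------------
    if "classify" in stages:
        cls_conf = dict(config.get("classify", {}))
        pair = comparisons[0]
        mask = samples["group"].isin(pair)
        sub = samples.loc[mask]
        data_type = cls_conf.pop("data_type", "SI")
        cc = clf.ClassificationConfig(
            data_type=data_type,
            positive_label=cls_conf.pop("positive_label", pair[0]),
            seed=cls_conf.pop("seed", derive_seed(root_seed, "classify")),
            **cls_conf,
        )
        if data_type == "GE":
            feats = gene_matrix
        elif data_type == "EE":
            feats = matrix
        elif data_type == "SI":
            feats = si_testable
        else:
            feats = clf.build_si_nonDE_features(
                si_testable, ge_tables[pair], annotation, thresholds["nonde_q"]
            )
        summary = clf.run_classification_experiment(
            feats.loc[:, sub.index], sub["group"], cc
        )
        save("classification", summary.set_index("n_features"), index_label="n_features")
        results["classification"] = summary.to_dict("records")

    # --- enrichment ---------------------------------------------------------
    if "enrich" in stages:
        enrich_conf = config.get("enrich", {})
        if "gmt" not in enrich_conf:
            raise ConfigurationError("enrich stage requires a 'gmt' path")
        collection = enr.read_gmt(enrich_conf["gmt"])
        universe = set(annotation["gene_id"])
        pair = comparisons[0]
        calls = diff.call_genes(
            ge_tables[pair], diff.moderated_t_test(
                si_testable.loc[:, samples.index[samples["group"].isin(pair)]],
                samples.loc[samples["group"].isin(pair), "group"], level="SI",
                group_order=pair,
            ),
            annotation, thresholds["diff_q"],
        )
        query = calls.index[calls["category"] == "SI_only"]
        table = enr.fisher_enrichment(query, collection, universe)
        save("enrichment", table.set_index("set_name"), index_label="set_name")

    # --- survival -----------------------------------------------------------
    if "survival" in stages:
        surv_conf = config.get("survival", {})
        levels = surv_conf.get("levels", ["GE", "SI"])
        models = surv_conf.get("models", ["univariate"])
        screens: dict[tuple, pd.DataFrame] = {}
        for level in levels:
            feats = {"GE": gene_matrix, "EE": matrix, "SI": si_testable}[level]
            annot = None if level == "GE" else annotation
            for model in models:
                table = surv.survival_screen(
                    feats, samples, level=level, model=model, annotation=annot
                )
                screens[(level, model)] = table
                save(f"survival_{level.lower()}_{model}", table, index_label="feature_id")
        if ("GE", "univariate") in screens and ("SI", "univariate") in screens:
            counts = surv.categorize_survival_genes(
                screens[("GE", "univariate")], screens[("SI", "univariate")],
                annotation, thresholds["survival_q"],
            )
            results["survival_categories"] = counts.as_dict()
            save(
                "survival_categories",
                pd.DataFrame([counts.as_dict()]).T.rename(columns={0: "count"}),
                index_label="category",
            )

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": _jsonable(config),
        "root_seed": root_seed,
        "derived_seeds": {s: derive_seed(root_seed, s) for s in ("simulate", "classify")},
        "stages": list(stages),
        "results": results,
        "files": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in written.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
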