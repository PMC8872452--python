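"""End-to-end orchestration: label -> train -> score -> ensemble -> adjust -> enrich.

A single declarative YAML config drives the run; every run writes a manifest
(config snapshot, seeds, input digests, output paths, version) beside its
outputs so any summary cell can be regenerated exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import fisher_enrichment, read_gmt
from .features import read_feature_matrix
from .labels import read_candidates, select_training_labels, write_labels
from .prediction import ModelConfig, ensemble_score, train_and_score
from .weighting import (
    bh_rejections,
    ihw,
    read_hypothesis_table,
    shuffled_covariate_control,
    stratified_pvalue_histogram,
)

__all__ = ["run_pipeline", "compare_methods_report", "DEFAULT_ALPHAS"]

logger = logging.getLogger(__name__)

DEFAULT_ALPHAS = (0.05, 0.1, 0.2, 0.3)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def compare_methods_report(summary: pd.DataFrame) -> pd.DataFrame:
    """Percent change of each weighting method over plain BH, per alpha.

    ``summary`` has one row per method (index) including a ``BH`` row, one
    column per alpha. Cells are 100 * (method - BH) / BH rounded to integer
    percent; alphas where BH rejects nothing are reported as NaN (undefined).
    """
    if "BH" not in summary.index:
        raise ValueError("summary has no BH row")
    bh = summary.loc["BH"].astype(float)
    others = summary.drop(index="BH").astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (others - bh) / bh
    pct.loc[:, bh == 0] = np.nan  # undefined where BH rejects nothing
    return pct.round(0)


def run_pipeline(config, outdir=None) -> dict:
    """Execute the full pipeline from a config dict or YAML path.

    Config keys: ``seed``; ``output_dir``; ``inputs`` (``candidates``,
    ``features`` mapping source -> path, ``hypotheses``, optional
    ``p_column``/``from_qvalues``/``gene_sets``); ``model`` (forest
    parameters); ``ihw`` (``n_bins``, ``n_folds``); ``alphas``;
    ``n_shuffles``; ``enrich`` (``n_top``).

    Returns the run manifest (also written as ``manifest.json``).
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    seed = int(config.get("seed", 0))
    outdir = Path(outdir or config.get("output_dir", "rvprior_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = config["inputs"]
    for key in ("candidates", "features", "hypotheses"):
        if key not in inputs:
            raise ValueError(f"config inputs missing {key!r}")
    for path in [inputs["candidates"], inputs["hypotheses"], *inputs["features"].values()]:
        if not Path(path).exists():
            raise FileNotFoundError(f"mandatory input missing: {path}")

    alphas = [float(a) for a in config.get("alphas", DEFAULT_ALPHAS)]
    model_cfg = ModelConfig(seed=seed, **config.get("model", {}))
    ihw_cfg = config.get("ihw", {})
    n_bins = ihw_cfg.get("n_bins", "auto")
    n_folds = int(ihw_cfg.get("n_folds", 5))
    n_shuffles = int(config.get("n_shuffles", 1))

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {},
        "outputs": {},
    }
    for name, path in [("candidates", inputs["candidates"]), ("hypotheses", inputs["hypotheses"])] + [
        (f"features:{s}", p) for s, p in inputs["features"].items()
    ]:
        manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    # stage 1: training labels
    candidates = read_candidates(inputs["candidates"])
    labels = select_training_labels(candidates)
    labels_path = outdir / "labels.tsv"
    write_labels(labels, labels_path)
    manifest["outputs"]["labels"] = str(labels_path)
    logger.info("labels: %d positives, %d negatives (median posterior %.3f)",
                len(labels.positives), len(labels.negatives), labels.median_posterior)

    # stage 2: per-source training and genome-wide scoring
    score_cols = {}
    auc_rows = []
    for source, path in inputs["features"].items():
        fm = read_feature_matrix(path, source=source)
        scores, repeat_aucs = train_and_score(fm, labels, model_cfg)
        score_cols[source] = scores
        for r, a in enumerate(repeat_aucs):
            auc_rows.append((source, r, a))
    per_source = pd.DataFrame(score_cols)
    auc_report = pd.DataFrame(auc_rows, columns=["source", "repeat", "mean_cv_auc"])
    auc_path = outdir / "auc_report.tsv"
    auc_report.to_csv(auc_path, sep="\t", index=False)
    manifest["outputs"]["auc_report"] = str(auc_path)

    # stage 3: ensemble score
    scored = ensemble_score(per_source)
    scores_path = outdir / "scores.tsv"
    scored.rename(columns=lambda c: c if c == "ensemble" else f"score_{c}").to_csv(
        scores_path, sep="\t", index_label="gene_id"
    )
    manifest["outputs"]["scores"] = str(scores_path)

    # stage 4: join hypotheses with covariates
    hyp = read_hypothesis_table(
        inputs["hypotheses"],
        p_column=inputs.get("p_column", "p"),
        from_qvalues=bool(inputs.get("from_qvalues", False)),
    )
    n_in = len(hyp)
    hyp = hyp.dropna(subset=["p"])
    merged = hyp.merge(scored.reset_index(names="gene_id"), on="gene_id", how="inner")
    merged = merged.dropna(subset=["ensemble"])
    logger.info("hypotheses: %d in, %d with covariate (%d dropped)",
                n_in, len(merged), n_in - len(merged))
    p = merged["p"].to_numpy()

    # stage 5: multiple-testing adjustment, all methods x alphas
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    covariate_methods = [(f"IHW-{s}", s) for s in inputs["features"]] + [("IHW-ensemble", "ensemble")]
    summary = {}
    for method, col in covariate_methods:
        x = merged[col].to_numpy(dtype=float)
        counts = []
        for alpha in alphas:
            res = ihw(p, x, alpha=alpha, n_bins=n_bins, n_folds=n_folds,
                      seed=int(rng.integers(0, 2**31 - 1)))
            counts.append(res.n_rejected_)
            if method == "IHW-ensemble":
                res_df = res.result_frame(merged["gene_id"], p, x)
                res_df.to_csv(outdir / f"ihw_ensemble_alpha{alpha}.tsv", sep="\t", index=False)
        summary[method] = counts
    shuffle_counts = []
    for alpha in alphas:
        cs = shuffled_covariate_control(
            p, merged["ensemble"].to_numpy(dtype=float), n_shuffles=n_shuffles,
            alpha=alpha, seed=int(rng.integers(0, 2**31 - 1)),
            n_bins=n_bins, n_folds=n_folds,
        )
        shuffle_counts.append(int(np.median(cs)) if len(cs) else 0)
    summary["IHW-shuffled ensemble"] = shuffle_counts
    summary["BH"] = [int(bh_rejections(p, alpha)[1].sum()) for alpha in alphas]
    summary_df = pd.DataFrame(summary, index=[str(a) for a in alphas]).T
    summary_path = outdir / "rejections_summary.tsv"
    summary_df.to_csv(summary_path, sep="\t", index_label="method")
    manifest["outputs"]["rejections_summary"] = str(summary_path)

    pct = compare_methods_report(summary_df)
    pct_path = outdir / "percent_change_vs_bh.tsv"
    pct.to_csv(pct_path, sep="\t", index_label="method")
    manifest["outputs"]["percent_change"] = str(pct_path)

    # diagnostics: stratified p-value histogram on the ensemble covariate
    counts, first_bin = stratified_pvalue_histogram(p, merged["ensemble"].to_numpy(dtype=float))
    hist_path = outdir / "stratified_histogram.tsv"
    counts.to_csv(hist_path, sep="\t", index_label="group")
    manifest["outputs"]["stratified_histogram"] = str(hist_path)

    # stage 6 (optional): gene-set enrichment of the top-ranked genes
    if inputs.get("gene_sets"):
        n_top = int(config.get("enrich", {}).get("n_top", 1000))
        ranked = scored["ensemble"].dropna().sort_values(ascending=False)
        gene_sets = read_gmt(inputs["gene_sets"])
        enr = fisher_enrichment(list(ranked.index), gene_sets, list(ranked.index), n_top=n_top)
        enr_path = outdir / "enrichment.tsv"
        enr.to_csv(enr_path, sep="\t", index=False)
        manifest["outputs"]["enrichment"] = str(enr_path)
        manifest["inputs"]["gene_sets"] = {
            "path": str(inputs["gene_sets"]), "sha256": _sha256(inputs["gene_sets"])
        }

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
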