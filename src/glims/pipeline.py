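"""End-to-end orchestration: simulate/load -> train -> optimize -> evaluate.

Each run writes its intermediate artifacts (scores, networks, metrics)
plus a run manifest into the output directory. A stage failure aborts
the run naming the stage; artifacts written before the failure are moved
under ``out_dir/partial``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import shutil
import time

import numpy as np
import pandas as pd

from . import __version__
from .config import load_config, stage_seed
from .core_io import (
    LabelSet,
    load_edge_list,
    load_gene_list,
    load_omics_matrix,
    load_psi_matrix,
    max_connected_subnetwork,
    pca_reduce,
)
from .evaluation import RankedGeneList, aucn_curve, binary_metrics
from .himgcn import HIMGCNConfig, sample_negatives, select_candidates, train
from .splice_opt import (
    ASFilterConfig,
    build_coregulation_network,
    build_cosplicing_network,
    filter_as_events,
    reprioritize,
)
from .synthetic import PRESETS, SyntheticConfig, generate_dataset

logger = logging.getLogger("glims")

_OMICS_FILE_KEYS = {"exp": "expression", "mut": "mutation",
                    "meth": "methylation", "cnv": "cnv"}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(cfg: dict, out_dir: str):
    """Return (network, omics dict, labels, psi_tumor, psi_normal, checksums)."""
    data = cfg["data"]
    sim = cfg["simulate"]
    if sim.get("preset"):
        base = PRESETS[sim["preset"]]
        overrides = dict(sim.get("overrides") or {})
        overrides.setdefault("seed", stage_seed(cfg["seed"], "simulate"))
        scfg = dataclasses.replace(base, **overrides)
        ds = generate_dataset(scfg, out_dir=os.path.join(out_dir, "data"))
        return ds.network, ds.omics, ds.labels, ds.psi_tumor, ds.psi_normal, {}
    required = ["network", "exp", "mut", "meth", "cnv", "pos", "neg"]
    missing = [k for k in required if not data.get(k)]
    if missing:
        raise ValueError(f"config.data is missing required inputs: {missing} "
                         "(or set simulate.preset)")
    checksums = {k: _sha256(data[k]) for k in data if data.get(k)}
    net = load_edge_list(data["network"])
    omics = {kind: load_omics_matrix(data[key], kind=kind)
             for key, kind in _OMICS_FILE_KEYS.items()}
    positives = load_gene_list(data["pos"])
    negatives = load_gene_list(data["neg"])
    labels = LabelSet(frozenset(positives), frozenset(negatives - positives))
    psi_t = load_psi_matrix(data["psi_tumor"], "tumor") if data.get("psi_tumor") else None
    psi_n = load_psi_matrix(data["psi_normal"], "normal") if data.get("psi_normal") else None
    return net, omics, labels, psi_t, psi_n, checksums


def prepare_features(net, omics, pca_variance: dict):
    """Restrict to the maximum connected subnetwork over genes with omics
    data, then PCA-reduce each omics matrix aligned to the node order."""
    covered = set()
    for m in omics.values():
        covered |= set(m.genes)
    sub = max_connected_subnetwork(net, covered & set(net.nodes))
    features = {
        "exp": pca_reduce(omics["expression"], pca_variance["expression"], sub),
        "mut": pca_reduce(omics["mutation"], pca_variance["mutation"], sub),
        "meth": pca_reduce(omics["methylation"], pca_variance["methylation"], sub),
        "cnv": pca_reduce(omics["cnv"], pca_variance["cnv"], sub),
    }
    return sub, features


def run_stage1(net, omics, labels, cfg: dict, seed: int, out_dir: str):
    h = cfg["himgcn"]
    sub, features = prepare_features(net, omics, h["pca_variance"])
    labels = labels.restrict(sub.nodes)
    if h.get("negative_sampling") == "specific":
        negs = sample_negatives(labels.negatives, labels.positives, "specific", seed=seed)
        labels = LabelSet(labels.positives, negs)
    mcfg = HIMGCNConfig(
        per_omics_out_dim=h["per_omics_out_dim"], hidden_dim=h["hidden_dim"],
        out_dim=h["out_dim"], learning_rate=h["learning_rate"], epochs=h["epochs"],
        lambda1=h["lambda1"], lambda2=h["lambda2"], n_folds=h["n_folds"],
        seed=seed, score_mode=h["score_mode"])
    result = train(sub, features, labels, mcfg)
    result.scores.rename("probability").rename_axis("gene").reset_index().to_csv(
        os.path.join(out_dir, "scores_stage1.tsv"), sep="\t", index=False)
    result.fold_metrics.to_csv(os.path.join(out_dir, "fold_metrics.tsv"),
                               sep="\t", index=False)
    np.savez(os.path.join(out_dir, "model_final.npz"), **result.final_model.weights)
    return sub, features, labels, result


def run_stage2(scores: pd.Series, expr, psi_tumor, psi_normal, cfg: dict,
               seed: int, out_dir: str):
    s = cfg["splice_opt"]
    candidates = select_candidates(scores, s["candidate_cutoff"])
    if len(candidates) < 2:
        logger.warning("stage2: only %d candidates above cutoff %.2f; skipping",
                       len(candidates), s["candidate_cutoff"])
        return None
    events = filter_as_events(psi_tumor, psi_normal, ASFilterConfig(**s["filter"]))
    if events.psi.shape[0] == 0:
        logger.warning("stage2: no AS events survive filtering; skipping")
        return None
    cosplice = build_cosplicing_network(candidates, expr, events,
                                        n_perm=s["n_perm"], fdr_level=s["fdr_level"],
                                        seed=seed)
    cosplice.edges.to_csv(os.path.join(out_dir, "cosplicing_edges.tsv"),
                          sep="\t", index=False)
    coreg = build_coregulation_network(cosplice, s["coreg_threshold"])
    coreg.edges.to_csv(os.path.join(out_dir, "coregulation_edges.tsv"),
                       sep="\t", index=False)
    final = reprioritize(scores, coreg, alpha=s["alpha"])
    final.rename("probability").rename_axis("gene").reset_index().to_csv(
        os.path.join(out_dir, "scores_stage2.tsv"), sep="\t", index=False)
    return {"cosplice": cosplice, "coreg": coreg, "scores": final}


def _final_table(stage1: pd.Series, stage2: pd.Series | None, out_dir: str) -> pd.DataFrame:
    final = stage2 if stage2 is not None else stage1
    order = sorted(final.index, key=lambda g: (-final[g], g))
    table = pd.DataFrame({
        "gene": order,
        "stage1_prob": stage1.loc[order].to_numpy(),
        "stage2_prob": final.loc[order].to_numpy(),
        "rank": np.arange(1, len(order) + 1),
    })
    table.to_csv(os.path.join(out_dir, "ranked_genes.tsv"), sep="\t", index=False,
                 float_format="%.10g")
    return table


def _evaluate(stage1, stage2, labels, cfg):
    report = {"stage1": binary_metrics(stage1, labels, cfg["evaluation"]["threshold"]).to_dict()}
    n_neg_scored = len(set(stage1.index) & labels.negatives)
    ns = [n for n in cfg["evaluation"]["aucn"] if n <= n_neg_scored]
    if ns:
        report["stage1"]["aucn"] = aucn_curve(
            RankedGeneList.from_scores(stage1, labels), ns)
    if stage2 is not None:
        report["stage2"] = binary_metrics(stage2, labels, cfg["evaluation"]["threshold"]).to_dict()
        if ns:
            report["stage2"]["aucn"] = aucn_curve(
                RankedGeneList.from_scores(stage2, labels), ns)
    return report


def run_pipeline(config=None, out_dir: str = "glims_run", overrides: dict | None = None
                 ) -> dict:
    """Execute Stage I then Stage II from a YAML path / config dict and
    write all artifacts plus the run manifest under ``out_dir``."""
    if isinstance(config, dict):
        cfg = load_config(None, _merge_dicts(config, overrides))
    else:
        cfg = load_config(config, overrides)
    os.makedirs(out_dir, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config": cfg,
        "seeds": {s: stage_seed(cfg["seed"], s) for s in ("stage1", "stage2")},
        "stages": {},
        "timings_sec": {},
    }
    stage = "inputs"
    try:
        t0 = time.perf_counter()
        net, omics, labels, psi_t, psi_n, checksums = _load_inputs(cfg, out_dir)
        manifest["input_checksums"] = checksums
        manifest["timings_sec"]["inputs"] = round(time.perf_counter() - t0, 3)

        stage = "stage1"
        t0 = time.perf_counter()
        sub, features, labels, result = run_stage1(
            net, omics, labels, cfg, manifest["seeds"]["stage1"], out_dir)
        stage1_scores = result.scores
        manifest["stages"]["stage1"] = {
            "status": "complete",
            "n_genes": len(sub.nodes),
            "n_edges": len(sub.edges),
            "fold_auroc_mean": float(result.fold_metrics["auroc"].mean()),
        }
        manifest["timings_sec"]["stage1"] = round(time.perf_counter() - t0, 3)

        stage = "stage2"
        t0 = time.perf_counter()
        if psi_t is None or psi_n is None:
            logger.warning("PSI inputs missing; stage2 skipped")
            manifest["stages"]["stage2"] = {"status": "skipped",
                                            "reason": "missing PSI inputs"}
            stage2 = None
        else:
            expr = omics["expression"]
            stage2 = run_stage2(stage1_scores, expr, psi_t, psi_n, cfg,
                                manifest["seeds"]["stage2"], out_dir)
            if stage2 is None:
                manifest["stages"]["stage2"] = {"status": "skipped",
                                                "reason": "no candidates or no events"}
            else:
                manifest["stages"]["stage2"] = {
                    "status": "complete",
                    "n_candidates": len(stage2["cosplice"].candidates),
                    "fdr_cutoff": stage2["cosplice"].cutoff,
                    "n_cosplicing_edges": int(len(stage2["cosplice"].edges)),
                    "n_coregulation_edges": int(len(stage2["coreg"].edges)),
                }
        manifest["timings_sec"]["stage2"] = round(time.perf_counter() - t0, 3)

        stage = "evaluate"
        stage2_scores = stage2["scores"] if stage2 else None
        _final_table(stage1_scores, stage2_scores, out_dir)
        if labels.positives and labels.negatives:
            manifest["metrics"] = _evaluate(stage1_scores, stage2_scores, labels, cfg)
    except Exception as exc:  # noqa: BLE001 - rewrap with the failing stage name
        _quarantine_partial(out_dir)
        raise StageError(stage, exc) from exc

    tmp = os.path.join(out_dir, "manifest.json.tmp")
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
    os.replace(tmp, os.path.join(out_dir, "manifest.json"))
    return manifest


def _merge_dicts(a: dict, b: dict | None) -> dict:
    if not b:
        return a
    out = dict(a)
    for k, v in b.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge_dicts(out[k], v)
        else:
            out[k] = v
    return out


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, frozenset):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _quarantine_partial(out_dir: str) -> None:
    partial = os.path.join(out_dir, "partial")
    os.makedirs(partial, exist_ok=True)
    for name in os.listdir(out_dir):
        if name == "partial":
            continue
        shutil.move(os.path.join(out_dir, name), os.path.join(partial, name))
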