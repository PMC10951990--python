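"""YAML configuration schema with defaults and deterministic seed fan-out.

A single file with sections ``data``, ``himgcn``, ``splice_opt``,
``evaluation``, ``simulate``; CLI flags override YAML values. All
randomness flows from one top-level ``seed``, fanned out per stage so
stages stay reproducible independently of each other.
"""

from __future__ import annotations

import copy

import numpy as np
import yaml

DEFAULTS: dict = {
    "seed": 0,
    "data": {
        # paths; all None means "simulate instead"
        "network": None, "exp": None, "mut": None, "meth": None, "cnv": None,
        "pos": None, "neg": None, "psi_tumor": None, "psi_normal": None,
    },
    "simulate": {
        "preset": None,  # "easy" | "hard"; overrides below are SyntheticConfig fields
        "overrides": {},
    },
    "himgcn": {
        "per_omics_out_dim": 50,
        "hidden_dim": 100,
        "out_dim": 1,
        "learning_rate": 0.001,
        "epochs": 500,  # desk-scale default; cancer-dataset presets go to 6000/2000/3000/1500
        "lambda1": 5e-4,
        "lambda2": 5e-4,
        "n_folds": 3,
        "score_mode": "full",
        # PCA explained-variance thresholds per omics
        "pca_variance": {"expression": 0.98, "methylation": 0.98,
                         "mutation": 0.7, "cnv": 0.7},
        "negative_sampling": "pan_cancer",  # or "specific" (tenfold rule)
    },
    "splice_opt": {
        "candidate_cutoff": 0.7,
        "n_perm": 5,
        "fdr_level": 0.05,
        "coreg_threshold": 0.3,
        "alpha": 0.5,
        "filter": {
            "min_mean_psi": 0.1,
            "min_abs_log2fc": 1.5,
            "min_tumor_fraction_expressed": 0.5,
            "require_in_normal": True,
            "min_psi_variance": 0.0,
        },
    },
    "evaluation": {"threshold": 0.5, "aucn": [10, 50, 100]},
}

STAGE_NAMES = ("simulate", "stage1", "stage2", "evaluate")


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Resolve defaults <- YAML file <- programmatic overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: top level must be a mapping")
        unknown = set(user) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"{path}: unknown config sections {sorted(unknown)}")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    idx = STAGE_NAMES.index(stage)
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % 2**31)
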