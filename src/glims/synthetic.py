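"""Seeded generator of complete synthetic datasets.

Real inputs for this kind of analysis (TCGA omics joined to a PPI
network, curated driver-gene labels, SUPPA2 PSI tables) need large
downloads, so the generator plants the statistical structure the two
stages exploit into a dataset of desk scale:

* a stochastic-block-model gene network whose driver communities
  concentrate the positive labels (label-informative topology);
* four omics matrices whose positive-gene rows are mean-shifted
  (class-informative features), with value ranges respecting each
  omics' semantics;
* tumor/normal PSI matrices in which a planted subset of positive
  genes ("splicing factors") co-regulates shared AS events through a
  logistic link on their expression, while unregulated events are pure
  Beta noise with equal tumor/normal means (so default differential
  filters remove them).

Everything is reproducible bit-for-bit from (config, seed), and the
planted gene-to-event map is returned for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .core_io import (
    AS_EVENT_CLASSES,
    GeneNetwork,
    LabelSet,
    OmicsMatrix,
    PSIMatrix,
    write_edge_list,
    write_gene_list,
    write_omics_matrix,
    write_psi_matrix,
)


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 1000
    n_samples_tumor: int = 100
    n_samples_normal: int = 100
    n_communities: int = 10
    p_in: float = 0.15
    p_out: float = 0.005
    frac_positive: float = 0.10
    omics_effect_size: float = 3.0  # mean shift (in noise SDs) of positive-gene features
    n_events: int = 250
    frac_regulated_events: float = 0.6
    regulation_strength: float = 2.0  # logistic-scale coefficient, regulator z-score -> PSI
    noise_sd: float = 0.1
    seed: int = 17
    # Structure knobs beyond the headline parameters
    label_concentration: float = 1000.0  # sampling-weight ratio, driver vs other communities
    n_regulators_per_event: int = 4
    frac_splicing_factors: float = 1.0  # fraction of positives acting as regulators
    regulator_module_size: int = 4  # co-regulation module size among splicing factors
    neg_per_pos: int = 3  # labeled negatives per positive; the rest stay unlabeled

    def __post_init__(self):
        for name in ("p_in", "p_out", "frac_positive", "frac_regulated_events",
                     "frac_splicing_factors"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_in <= self.p_out:
            raise ValueError("p_in must exceed p_out (planted assortativity)")
        for name in ("n_genes", "n_samples_tumor", "n_samples_normal",
                     "n_communities", "n_events"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: Named study conditions. "easy" carries strong planted signal and is the
#: default for end-to-end checks; "hard" weakens every effect for power
#: exploration.
PRESETS: dict[str, SyntheticConfig] = {
    "easy": SyntheticConfig(),
    # Stage-II study condition: deeper tumor sampling tightens the null
    # distribution of chance gene-PSI correlations.
    "coreg": SyntheticConfig(n_samples_tumor=200),
    "hard": SyntheticConfig(omics_effect_size=0.5, regulation_strength=0.5,
                            noise_sd=0.3, p_in=0.06, p_out=0.02,
                            label_concentration=5.0),
}


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_network(cfg: SyntheticConfig) -> tuple[GeneNetwork, dict[str, int]]:
    """Stochastic-block-model graph with near-equal communities.

    Returns the network and the gene -> community assignment (needed to
    concentrate positive labels in designated communities).
    """
    base = cfg.n_genes // cfg.n_communities
    sizes = [base + (1 if i < cfg.n_genes % cfg.n_communities else 0)
             for i in range(cfg.n_communities)]
    probs = [[cfg.p_in if i == j else cfg.p_out for j in range(cfg.n_communities)]
             for i in range(cfg.n_communities)]
    g = nx.stochastic_block_model(sizes, probs, seed=cfg.seed)
    names = _gene_names(cfg.n_genes)
    community = {}
    start = 0
    for c, size in enumerate(sizes):
        for i in range(start, start + size):
            community[names[i]] = c
        start += size
    edges = [(names[a], names[b]) for a, b in g.edges()]
    return GeneNetwork(names, edges), community


def generate_labels(net: GeneNetwork, community: dict[str, int],
                    cfg: SyntheticConfig) -> LabelSet:
    """Imbalanced labels with positives concentrated in driver communities."""
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    genes = list(net.nodes)
    n_pos = max(1, round(cfg.frac_positive * len(genes)))
    n_driver = max(1, round(2 * cfg.frac_positive * cfg.n_communities))
    w = cfg.label_concentration
    weights = np.array([w if community[g] < n_driver else 1.0 for g in genes])
    weights /= weights.sum()
    positives = set(rng.choice(genes, size=n_pos, replace=False, p=weights).tolist())
    pool = sorted(set(genes) - positives)
    n_neg = min(len(pool), cfg.neg_per_pos * n_pos)
    anti = np.array([1.0 if community[g] < n_driver else w for g in pool])
    anti /= anti.sum()
    negatives = set(rng.choice(pool, size=n_neg, replace=False, p=anti).tolist())
    return LabelSet(frozenset(positives), frozenset(negatives))


def generate_omics(net: GeneNetwork, labels: LabelSet, cfg: SyntheticConfig
                   ) -> dict[str, OmicsMatrix]:
    """Four tumor gene-by-sample matrices with class-informative rows."""
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2)))
    genes = list(net.nodes)
    n, s = len(genes), cfg.n_samples_tumor
    samples = [f"T{i:03d}" for i in range(s)]
    pos = np.array([g in labels.positives for g in genes], dtype=float)
    eff = cfg.omics_effect_size

    mu_expr = rng.normal(4.0, 1.0, n) + eff * pos
    expr = np.clip(mu_expr[:, None] + rng.normal(0.0, 1.0, (n, s)), 0.0, None)

    mu_meth = 0.4 + 0.08 * eff * pos + rng.normal(0.0, 0.05, n)
    meth = np.clip(mu_meth[:, None] + rng.normal(0.0, 0.1, (n, s)), 0.0, 1.0)

    rate_mut = 0.02 + 0.02 * eff * pos
    mut = np.clip(rate_mut[:, None] + rng.normal(0.0, 0.02, (n, s)), 0.0, 1.0)

    cnv = 0.25 * eff * pos[:, None] + rng.normal(0.0, 1.0, (n, s))

    def make(values, kind):
        return OmicsMatrix(pd.DataFrame(values, index=genes, columns=samples), kind=kind)

    return {
        "expression": make(expr, "expression"),
        "mutation": make(mut, "mutation"),
        "methylation": make(meth, "methylation"),
        "cnv": make(cnv, "cnv"),
    }


def generate_splicing(net: GeneNetwork, labels: LabelSet, expr: OmicsMatrix,
                      cfg: SyntheticConfig) -> tuple[PSIMatrix, PSIMatrix, pd.DataFrame]:
    """Tumor + normal PSI matrices and the planted regulator -> event map.

    Regulated events: tumor PSI = logistic(strength·mean regulator z-score
    + 0.5·host z-score + noise), so tumor means sit near 0.5; their normal
    PSI is Beta with mean ~0.08, so the default differential filters keep
    them. Unregulated events are Beta noise with equal tumor/normal means.

    Splicing factors (the positives, by default) are partitioned into
    small modules; events are assigned to modules round-robin and each
    event's regulators cycle over the within-module subsets, so factors
    in a module share AS targets evenly (the structure the co-regulation
    Dice weight detects) while factors in different modules do not.
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 3)))
    genes = list(net.nodes)
    tumor_samples = list(expr.samples)
    normal_samples = [f"N{i:03d}" for i in range(cfg.n_samples_normal)]
    x = expr.data.loc[genes, tumor_samples].to_numpy()
    sd = x.std(axis=1, ddof=0)
    z = (x - x.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)[:, None]
    row_of = {g: i for i, g in enumerate(genes)}

    positives = sorted(labels.positives)
    n_sf = max(cfg.n_regulators_per_event, round(cfg.frac_splicing_factors * len(positives)))
    factors = rng.choice(positives, size=min(n_sf, len(positives)), replace=False).tolist()
    rng.shuffle(factors)  # decorrelate module membership from gene/community order
    msize = max(2, cfg.regulator_module_size)
    modules = [factors[i:i + msize] for i in range(0, len(factors), msize)]
    if len(modules) > 1 and len(modules[-1]) < 2:  # fold a stub module into the previous one
        modules[-2].extend(modules.pop())
    from itertools import combinations

    subsets = [list(combinations(m, min(cfg.n_regulators_per_event, len(m))))
               for m in modules]
    subset_pos = [0] * len(modules)

    n_reg = round(cfg.frac_regulated_events * cfg.n_events)
    event_ids, tumor_rows, normal_rows, truth = [], [], [], []
    for k in range(cfg.n_events):
        cls = AS_EVENT_CLASSES[k % len(AS_EVENT_CLASSES)]
        regulated = k < n_reg
        if regulated:
            m = k % len(modules)
            regs = list(subsets[m][subset_pos[m] % len(subsets[m])])
            subset_pos[m] += 1
            host = genes[rng.integers(len(genes))]
            while host in regs:
                host = genes[rng.integers(len(genes))]
        else:
            regs, host = [], genes[rng.integers(len(genes))]
        ev = f"{host};{cls};chr1:{1000 + 10 * k}-{1005 + 10 * k}"
        event_ids.append(ev)
        if regulated:
            drive = z[[row_of[r] for r in regs]].mean(axis=0) * np.sqrt(len(regs))
            logit = (cfg.regulation_strength * drive
                     + 0.5 * z[row_of[host]]
                     + rng.normal(0.0, cfg.noise_sd, len(tumor_samples)))
            tumor_rows.append(1.0 / (1.0 + np.exp(-logit)))
            normal_rows.append(rng.beta(2.0, 23.0, cfg.n_samples_normal))
            truth.extend((r, ev) for r in regs)
        else:
            tumor_rows.append(rng.beta(6.0, 14.0, len(tumor_samples)))
            normal_rows.append(rng.beta(6.0, 14.0, cfg.n_samples_normal))

    hosts = pd.Series([e.split(";")[0] for e in event_ids], index=event_ids, name="host")
    classes = pd.Series([e.split(";")[1] for e in event_ids], index=event_ids,
                        name="event_class")
    tumor = PSIMatrix(pd.DataFrame(tumor_rows, index=event_ids, columns=tumor_samples),
                      hosts, classes, condition="tumor")
    normal = PSIMatrix(pd.DataFrame(normal_rows, index=event_ids, columns=normal_samples),
                       hosts.copy(), classes.copy(), condition="normal")
    truth_df = pd.DataFrame(truth, columns=["regulator", "event"])
    return tumor, normal, truth_df


@dataclass
class SyntheticDataset:
    """In-memory bundle of one generated dataset plus its ground truth."""

    config: SyntheticConfig
    network: GeneNetwork
    community: dict[str, int]
    labels: LabelSet
    omics: dict[str, OmicsMatrix]
    psi_tumor: PSIMatrix
    psi_normal: PSIMatrix
    truth_edges: pd.DataFrame  # planted (regulator, event) pairs

    def splicing_factors(self) -> frozenset[str]:
        return frozenset(self.truth_edges["regulator"])


def generate_dataset(cfg: SyntheticConfig, out_dir: str | os.PathLike | None = None
                     ) -> SyntheticDataset:
    """Generate a self-consistent dataset; optionally write it to disk in
    the package's file formats plus a manifest recording config and truth."""
    net, community = generate_network(cfg)
    labels = generate_labels(net, community, cfg)
    omics = generate_omics(net, labels, cfg)
    tumor, normal, truth = generate_splicing(net, labels, omics["expression"], cfg)
    ds = SyntheticDataset(cfg, net, community, labels, omics, tumor, normal, truth)
    if out_dir is not None:
        write_dataset(ds, out_dir)
    return ds


def write_dataset(ds: SyntheticDataset, out_dir) -> dict[str, str]:
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    def p(name):
        paths[name.split(".")[0]] = os.path.join(out_dir, name)
        return paths[name.split(".")[0]]

    write_edge_list(ds.network, p("network.tsv"))
    write_omics_matrix(ds.omics["expression"], p("exp.tsv"))
    write_omics_matrix(ds.omics["mutation"], p("mut.tsv"))
    write_omics_matrix(ds.omics["methylation"], p("meth.tsv"))
    write_omics_matrix(ds.omics["cnv"], p("cnv.tsv"))
    write_gene_list(ds.labels.positives, p("pos.txt"))
    write_gene_list(ds.labels.negatives, p("neg.txt"))
    write_psi_matrix(ds.psi_tumor, p("psi_tumor.tsv"))
    write_psi_matrix(ds.psi_normal, p("psi_normal.tsv"))
    ds.truth_edges.to_csv(p("truth_edges.tsv"), sep="\t", index=False)
    manifest = {
        "config": dataclasses.asdict(ds.config),
        "files": {k: os.path.basename(v) for k, v in paths.items()},
        "n_positive": len(ds.labels.positives),
        "n_negative": len(ds.labels.negatives),
        "n_planted_edges": int(len(ds.truth_edges)),
        "splicing_factors": sorted(ds.splicing_factors()),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return paths
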