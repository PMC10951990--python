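"""Stage II: refine candidate scores with alternative-splicing regulation.

Informative AS events are selected by differential-PSI filters; a
bipartite gene-event co-splicing network is built from first-order
partial correlations (conditioning each event on its host gene's
expression) thresholded at a permutation-FDR cutoff; genes sharing AS
targets are linked by a Dice-weighted co-regulation network; and the
Stage-I probabilities are re-propagated over that network with a
random-walk-with-restart (PageRank) iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import OmicsMatrix, PSIMatrix

logger = logging.getLogger("glims")

_PSEUDOCOUNT = 1e-3  # added to both mean PSIs before the fold-change ratio
_DEGENERATE_R = 1.0 - 1e-12


@dataclass(frozen=True)
class ASFilterConfig:
    """Thresholds for selecting cancer-informative AS events.

    Defaults: tumor mean PSI > 0.1, |log2 fold-change| vs normal > 1.5,
    non-missing PSI on more than half the tumor samples, and the event
    must occur in normal samples. ``min_psi_variance`` enables the
    variance-based variant (> 0.02 with |log2FC| > 0) when set.
    """

    min_mean_psi: float = 0.1
    min_abs_log2fc: float = 1.5
    min_tumor_fraction_expressed: float = 0.5
    require_in_normal: bool = True
    min_psi_variance: float = 0.0

    def __post_init__(self):
        for name in ("min_mean_psi", "min_abs_log2fc",
                     "min_tumor_fraction_expressed", "min_psi_variance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def filter_as_events(tumor: PSIMatrix, normal: PSIMatrix,
                     cfg: ASFilterConfig = ASFilterConfig()) -> PSIMatrix:
    """Keep tumor events that are expressed, abundant and differential."""
    if tumor.psi.shape[0] == 0:
        raise ValueError("empty tumor PSI matrix")
    t = tumor.psi
    frac_expressed = t.notna().mean(axis=1)
    mean_t = t.mean(axis=1, skipna=True)
    var_t = t.var(axis=1, skipna=True, ddof=1)

    keep = []
    for ev in t.index:
        if not frac_expressed[ev] > cfg.min_tumor_fraction_expressed:
            continue
        in_normal = ev in normal.psi.index and normal.psi.loc[ev].notna().any()
        if cfg.require_in_normal and not in_normal:
            continue
        if not mean_t[ev] > cfg.min_mean_psi:
            continue
        mean_n = normal.psi.loc[ev].mean(skipna=True) if in_normal else 0.0
        log2fc = np.log2((mean_t[ev] + _PSEUDOCOUNT) / (mean_n + _PSEUDOCOUNT))
        if not abs(log2fc) > cfg.min_abs_log2fc:
            continue
        if cfg.min_psi_variance > 0 and not var_t[ev] > cfg.min_psi_variance:
            continue
        keep.append(ev)
    logger.info("filter_as_events: kept %d / %d events", len(keep), t.shape[0])
    return tumor.subset(keep)


# ---------------------------------------------------------------------------
# Correlations


def partial_correlation(r_ge: float, r_he: float, r_gh: float) -> float:
    """First-order partial correlation of gene and event given the host:
    (r_ge − r_he·r_gh) / sqrt((1−r_he²)(1−r_gh²))."""
    for name, r in (("r_ge", r_ge), ("r_he", r_he), ("r_gh", r_gh)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name}={r} outside [-1, 1]")
    if abs(r_he) >= _DEGENERATE_R or abs(r_gh) >= _DEGENERATE_R:
        raise ValueError("degenerate conditioning: |r_he| or |r_gh| is 1")
    return (r_ge - r_he * r_gh) / np.sqrt((1 - r_he ** 2) * (1 - r_gh ** 2))


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlation matrix between x (a x n) and y (b x n).

    Pairs are computed over pairwise-complete samples; entries with fewer
    than 3 complete observations or zero variance come back NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isnan(x).any() or np.isnan(y).any()):
        n = x.shape[1]
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        xs = np.sqrt((xc ** 2).sum(axis=1))
        ys = np.sqrt((yc ** 2).sum(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (xc @ yc.T) / np.outer(xs, ys)
        r[~np.isfinite(r)] = np.nan
        return np.clip(r, -1.0, 1.0)
    out = np.full((x.shape[0], y.shape[0]), np.nan)
    for i in range(x.shape[0]):
        for j in range(y.shape[0]):
            ok = ~(np.isnan(x[i]) | np.isnan(y[j]))
            if ok.sum() < 3:
                continue
            xi, yj = x[i, ok], y[j, ok]
            if xi.std() == 0 or yj.std() == 0:
                continue
            out[i, j] = np.clip(np.corrcoef(xi, yj)[0, 1], -1.0, 1.0)
    return out


def gene_event_correlations(candidates, expr: OmicsMatrix, events: PSIMatrix
                            ) -> pd.DataFrame:
    """Raw and partial correlations for every candidate-gene x AS-event pair.

    For candidate g_i and event e_j hosted by g_j != g_i: Pearson r of
    g_i expression vs event PSI over shared samples, then the partial
    correlation conditioning on the host gene's expression. Events hosted
    by g_i itself, degenerate conditionings, and undefined correlations
    are skipped (counts logged).
    """
    candidates = sorted(set(candidates) & set(expr.genes))
    shared = expr.samples.intersection(events.samples)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need at least 3")
    hosts_known = [ev for ev in events.events if events.host[ev] in set(expr.genes)]
    n_no_host = events.psi.shape[0] - len(hosts_known)
    if n_no_host:
        logger.info("gene_event_correlations: %d events lack host expression", n_no_host)
    ev_ids = hosts_known
    if not candidates or not ev_ids:
        return pd.DataFrame(columns=["gene", "event", "host",
                                     "r_ge", "r_he", "r_gh", "partial_r"])

    cand_x = expr.data.loc[candidates, shared].to_numpy()
    psi = events.psi.loc[ev_ids, shared].to_numpy()
    hosts = [events.host[ev] for ev in ev_ids]
    uniq_hosts = sorted(set(hosts))
    host_idx = {h: i for i, h in enumerate(uniq_hosts)}
    host_x = expr.data.loc[uniq_hosts, shared].to_numpy()

    r_ge = _pearson_rows(cand_x, psi)                       # C x E
    r_he_u = _pearson_rows(host_x, psi)                     # H x E
    r_he = np.array([r_he_u[host_idx[h], j] for j, h in enumerate(hosts)])
    r_gh_u = _pearson_rows(cand_x, host_x)                  # C x H
    r_gh = r_gh_u[:, [host_idx[h] for h in hosts]]          # C x E

    rows = []
    n_skipped = 0
    for i, g in enumerate(candidates):
        for j, ev in enumerate(ev_ids):
            h = hosts[j]
            if g == h:
                continue
            rge, rhe, rgh = r_ge[i, j], r_he[j], r_gh[i, j]
            if np.isnan(rge) or np.isnan(rhe) or np.isnan(rgh):
                n_skipped += 1
                continue
            if abs(rhe) >= _DEGENERATE_R or abs(rgh) >= _DEGENERATE_R:
                n_skipped += 1
                continue
            rows.append((g, ev, h, rge, rhe, rgh,
                         partial_correlation(rge, rhe, rgh)))
    if n_skipped:
        logger.info("gene_event_correlations: skipped %d undefined/degenerate pairs",
                    n_skipped)
    return pd.DataFrame(rows, columns=["gene", "event", "host",
                                       "r_ge", "r_he", "r_gh", "partial_r"])


def fdr_scan_cutoff(observed, nulls, fdr_level: float = 0.05) -> float:
    """Smallest observed |r| at which the permutation FDR drops below the
    target level.

    FDR(c) = mean over null sets of #{null >= c}, divided by
    #{observed >= c}; candidate cutoffs are the observed values themselves
    (the FDR curve is a step function between them). Returns +inf if no
    cutoff qualifies.
    """
    observed = np.abs(np.asarray(observed, dtype=float))
    if observed.size == 0:
        raise ValueError("no observed values")
    obs_sorted = np.sort(observed)
    null_counts = np.zeros(observed.size)
    for null in nulls:
        null_sorted = np.sort(np.abs(np.asarray(null, dtype=float)))
        null_counts += null_sorted.size - np.searchsorted(null_sorted, obs_sorted,
                                                          side="left")
    mean_null_ge = null_counts / max(1, len(nulls))
    n_obs_ge = observed.size - np.arange(observed.size)
    fdr = mean_null_ge / np.maximum(1, n_obs_ge)
    qualifying = obs_sorted[fdr < fdr_level]
    return float(qualifying.min()) if qualifying.size else float("inf")


def permutation_fdr_cutoff(observed, expr: OmicsMatrix, events: PSIMatrix,
                           candidates, n_perm: int = 5, fdr_level: float = 0.05,
                           seed: int = 0) -> float:
    """Permutation-based |partial r| cutoff controlling the FDR.

    Sample labels of expression and PSI columns are shuffled independently
    ``n_perm`` times and the full |partial r| distribution recomputed.
    FDR(c) = mean over permutations of #null >= c, divided by #observed >= c;
    the cutoff is the smallest observed value with FDR < ``fdr_level``
    (+inf if none qualifies).
    """
    observed = np.abs(np.asarray(observed, dtype=float))
    if observed.size == 0:
        raise ValueError("no observed partial correlations")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0.0 < fdr_level < 1.0:
        raise ValueError("fdr_level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    shared = expr.samples.intersection(events.samples)
    nulls = []
    for _ in range(n_perm):
        e_perm = expr.data[shared].to_numpy()[:, rng.permutation(len(shared))]
        p_perm = events.psi[shared].to_numpy()[:, rng.permutation(len(shared))]
        expr_shuf = OmicsMatrix(
            pd.DataFrame(e_perm, index=expr.data.index, columns=shared), kind=expr.kind)
        events_shuf = PSIMatrix(
            pd.DataFrame(p_perm, index=events.psi.index, columns=shared),
            events.host, events.event_class, events.condition)
        nulls.append(np.abs(gene_event_correlations(candidates, expr_shuf,
                                                    events_shuf)["partial_r"].to_numpy()))
    return fdr_scan_cutoff(observed, nulls, fdr_level)


# ---------------------------------------------------------------------------
# Networks


@dataclass
class CoSplicingNetwork:
    """Bipartite candidate-gene <-> AS-event network above the FDR cutoff."""

    edges: pd.DataFrame  # columns gene, event, host, partial_r
    cutoff: float
    seed: int
    candidates: tuple[str, ...] = ()

    def targets(self, gene: str) -> frozenset[str]:
        """AS target set T(g): events linked to ``gene``."""
        return frozenset(self.edges.loc[self.edges["gene"] == gene, "event"])

    def target_map(self) -> dict[str, frozenset[str]]:
        grouped = self.edges.groupby("gene")["event"].agg(frozenset)
        return {g: grouped.get(g, frozenset()) for g in self.candidates}


def build_cosplicing_network(candidates, expr: OmicsMatrix, events: PSIMatrix,
                             n_perm: int = 5, fdr_level: float = 0.05,
                             seed: int = 0) -> CoSplicingNetwork:
    """Partial-correlation network between Stage-I candidates and filtered
    AS events, thresholded at the permutation-FDR cutoff."""
    table = gene_event_correlations(candidates, expr, events)
    if table.empty:
        return CoSplicingNetwork(table.assign(), float("inf"), seed,
                                 tuple(sorted(set(candidates))))
    cutoff = permutation_fdr_cutoff(table["partial_r"].to_numpy(), expr, events,
                                    candidates, n_perm, fdr_level, seed)
    kept = table[np.abs(table["partial_r"]) >= cutoff].reset_index(drop=True)
    logger.info("co-splicing network: cutoff |r| >= %.4g keeps %d / %d edges",
                cutoff, len(kept), len(table))
    return CoSplicingNetwork(kept, cutoff, seed, tuple(sorted(set(candidates))))


def coregulation_weight(t_i, t_j) -> float:
    """Dice coefficient of two AS target sets: 2|Ti ∩ Tj| / (|Ti| + |Tj|)."""
    t_i, t_j = set(t_i), set(t_j)
    if not t_i and not t_j:
        raise ValueError("both target sets are empty")
    return 2.0 * len(t_i & t_j) / (len(t_i) + len(t_j))


@dataclass
class CoRegulationNetwork:
    """Candidate genes linked by shared AS targets (Dice weight)."""

    nodes: tuple[str, ...]
    edges: pd.DataFrame  # columns gene_a, gene_b, weight
    threshold: float

    def degree(self) -> pd.Series:
        d = pd.Series(0.0, index=list(self.nodes))
        for _, row in self.edges.iterrows():
            d[row["gene_a"]] += 1
            d[row["gene_b"]] += 1
        return d


def build_coregulation_network(cosplice: CoSplicingNetwork,
                               weight_threshold: float = 0.3) -> CoRegulationNetwork:
    """All-pairs Dice weights among candidates; edges kept when the weight
    reaches the threshold (inclusive). Isolated candidates stay as nodes."""
    if not 0.0 <= weight_threshold <= 1.0:
        raise ValueError("weight_threshold must be in [0, 1]")
    targets = cosplice.target_map()
    genes = sorted(targets)
    rows = []
    for i, gi in enumerate(genes):
        for gj in genes[i + 1:]:
            if not targets[gi] and not targets[gj]:
                continue
            w = coregulation_weight(targets[gi], targets[gj])
            if w >= weight_threshold:
                rows.append((gi, gj, w))
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])
    return CoRegulationNetwork(tuple(genes), edges, weight_threshold)


# ---------------------------------------------------------------------------
# PageRank re-prioritization


def pagerank(network: CoRegulationNetwork, prior: pd.Series, alpha: float = 0.5,
             tol: float = 1e-10, max_iter: int = 1000) -> pd.Series:
    """Random walk with restart: p_{k+1} = α·p0 + (1−α)·W·p_k, W = A·D⁻¹.

    Undirected edges count in both directions and propagate in proportion
    to their co-regulation weight (A is the weighted adjacency, D the
    weighted out-degree). Dangling (degree-0) nodes redistribute their
    mass to the prior, so the iterate keeps summing to 1.
    """
    nodes = list(network.nodes)
    if not nodes:
        raise ValueError("empty network")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    p0 = prior.reindex(nodes).to_numpy(dtype=float)
    if np.isnan(p0).any() or (p0 < 0).any():
        raise ValueError("prior must be nonnegative and cover all network nodes")
    if abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError(f"prior must sum to 1 (got {p0.sum()!r})")
    n = len(nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    adj = np.zeros((n, n))
    for _, row in network.edges.iterrows():
        i, j = idx[row["gene_a"]], idx[row["gene_b"]]
        adj[i, j] = adj[j, i] = float(row.get("weight", 1.0))
    deg = adj.sum(axis=0)
    dangling = deg == 0
    with np.errstate(divide="ignore"):
        w = adj / np.where(dangling, 1.0, deg)
    p = p0.copy()
    for _ in range(max_iter):
        p_next = alpha * p0 + (1 - alpha) * (w @ p + p[dangling].sum() * p0)
        if np.abs(p_next - p).sum() < tol:
            p = p_next
            break
        p = p_next
    return pd.Series(p, index=nodes, name="pagerank")


def reprioritize(candidates: pd.Series, coreg: CoRegulationNetwork,
                 alpha: float = 0.5) -> pd.Series:
    """Replace scores of co-regulation-network genes with the PageRank
    vector (prior = their Stage-I probabilities normalized to sum 1),
    max-rescaled to [0, 1]; all other genes keep their Stage-I score."""
    missing = [g for g in coreg.nodes if g not in candidates.index]
    if missing:
        raise ValueError(f"scores missing for network genes: {missing[:5]}")
    out = candidates.astype(float).copy()
    if not coreg.nodes:
        return out
    prior = candidates.reindex(list(coreg.nodes)).astype(float)
    total = prior.sum()
    if total <= 0:
        prior = pd.Series(1.0 / len(prior), index=prior.index)
    else:
        prior = prior / total
    pr = pagerank(coreg, prior, alpha=alpha)
    peak = pr.max()
    if peak > 0:
        pr = pr / peak
    out.loc[pr.index] = pr
    out.name = "probability"
    return out
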