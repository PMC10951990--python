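"""Data model, file readers/writers, and network/feature preprocessing.

All matrices downstream use the :class:`GeneNetwork` node order as the
canonical row order; files may list genes in any order and are realigned
on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA

logger = logging.getLogger("glims")

#: Alternative-splicing event classes emitted by SUPPA2-style pipelines.
AS_EVENT_CLASSES = ("SE", "MX", "A5", "A3", "RI", "AF", "AL")

OMICS_KINDS = ("expression", "mutation", "methylation", "cnv")


class GeneNetwork:
    """A simple undirected graph over gene identifiers.

    The node order is stable and explicit: it defines the row order of
    every matrix built against this network (adjacency, feature sets,
    score vectors).
    """

    def __init__(self, nodes, edges):
        self.nodes: tuple[str, ...] = tuple(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            dupes = sorted({n for n in self.nodes if list(self.nodes).count(n) > 1})
            raise ValueError(f"duplicate node identifiers: {dupes}")
        index = {n: i for i, n in enumerate(self.nodes)}
        canon = set()
        for a, b in edges:
            if a == b:
                continue
            if a not in index or b not in index:
                raise ValueError(f"edge endpoint not a node: {(a, b)}")
            canon.add((a, b) if a < b else (b, a))
        self.edges: frozenset[tuple[str, str]] = frozenset(canon)
        self._index = index

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def degree(self) -> np.ndarray:
        d = np.zeros(len(self.nodes), dtype=float)
        for a, b in self.edges:
            d[self._index[a]] += 1
            d[self._index[b]] += 1
        return d

    def adjacency(self) -> sp.csr_matrix:
        """Binary symmetric adjacency A in node order (no self-loops)."""
        n = len(self.nodes)
        rows, cols = [], []
        for a, b in self.edges:
            i, j = self._index[a], self._index[b]
            rows += [i, j]
            cols += [j, i]
        data = np.ones(len(rows), dtype=float)
        return sp.csr_matrix((data, (rows, cols)), shape=(n, n))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "GeneNetwork":
        nodes = sorted(g.nodes())
        return cls(nodes, [tuple(e) for e in g.edges()])


@dataclass
class OmicsMatrix:
    """Raw gene-by-sample omics values before PCA reduction.

    Values are omics-specific: log2(FPKM+1) expression, beta-value
    methylation in [0, 1], per-sample mutation frequency in [0, 1],
    copy-number score. Missing values are NaN, never silently zero.
    """

    data: pd.DataFrame  # rows = genes, columns = samples
    kind: str = "expression"

    def __post_init__(self):
        if self.data.index.duplicated().any():
            dupes = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise ValueError(f"duplicate gene IDs: {dupes}")
        if self.data.columns.duplicated().any():
            dupes = sorted(self.data.columns[self.data.columns.duplicated()].unique())
            raise ValueError(f"duplicate sample IDs: {dupes}")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns


@dataclass
class OmicsFeatureSet:
    """PCA-reduced gene-by-feature matrix aligned to a network node order."""

    genes: tuple[str, ...]
    values: np.ndarray  # shape (n_genes, n_components)
    zero_filled: tuple[str, ...] = ()  # genes lacking omics data, rows zeroed

    def __post_init__(self):
        if self.values.shape[0] != len(self.genes):
            raise ValueError(
                f"feature rows ({self.values.shape[0]}) != genes ({len(self.genes)})"
            )


@dataclass(frozen=True)
class LabelSet:
    """Positive / negative gene labels; everything else is unlabeled."""

    positives: frozenset[str]
    negatives: frozenset[str]

    def __post_init__(self):
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"genes labeled both positive and negative: {sorted(overlap)}")

    def restrict(self, genes) -> "LabelSet":
        genes = set(genes)
        return LabelSet(frozenset(self.positives & genes), frozenset(self.negatives & genes))

    def to_arrays(self, node_order) -> tuple[np.ndarray, np.ndarray]:
        """Return (y, labeled_mask) aligned to ``node_order``."""
        y = np.zeros(len(node_order), dtype=float)
        mask = np.zeros(len(node_order), dtype=bool)
        for i, g in enumerate(node_order):
            if g in self.positives:
                y[i], mask[i] = 1.0, True
            elif g in self.negatives:
                mask[i] = True
        return y, mask


@dataclass
class PSIMatrix:
    """Percent-spliced-in values per AS event per sample.

    Event IDs follow the SUPPA2 convention ``GENE;CLASS;coords``: the host
    gene and event class are parsed out, the coordinates stay opaque.
    """

    psi: pd.DataFrame  # rows = event IDs, columns = samples
    host: pd.Series  # event ID -> host gene
    event_class: pd.Series  # event ID -> one of AS_EVENT_CLASSES
    condition: str = "tumor"  # "tumor" | "normal"

    def __post_init__(self):
        vals = self.psi.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("PSI values must lie in [0, 1] or be missing")
        if not self.host.index.equals(self.psi.index):
            raise ValueError("host gene map must cover exactly the event index")

    @property
    def events(self) -> pd.Index:
        return self.psi.index

    @property
    def samples(self) -> pd.Index:
        return self.psi.columns

    def subset(self, event_ids) -> "PSIMatrix":
        idx = pd.Index(event_ids)
        return PSIMatrix(
            self.psi.loc[idx], self.host.loc[idx], self.event_class.loc[idx], self.condition
        )


# ---------------------------------------------------------------------------
# Readers / writers


def _read_table(path, **kwargs) -> pd.DataFrame:
    # Delimiter auto-detected among tab/comma; tab is the written default.
    return pd.read_csv(path, sep=None, engine="python", index_col=0,
                       na_values=["NA", "NaN", "nan", ""], keep_default_na=True, **kwargs)


def load_omics_matrix(path, kind: str = "expression") -> OmicsMatrix:
    """Read a delimited gene-by-sample table (first column = gene IDs)."""
    df = _read_table(path)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicate gene IDs: {dupes}")
    for col in df.columns:
        bad = df[col].map(lambda v: isinstance(v, str))
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(f"{path}: non-numeric cell at gene {row!r}, sample {col!r}")
    return OmicsMatrix(df.astype(float), kind=kind)


def write_omics_matrix(m: OmicsMatrix, path) -> None:
    m.data.to_csv(path, sep="\t", na_rep="NA", index_label="gene")


def load_edge_list(path) -> GeneNetwork:
    """Read a 2- or 3-column edge list (weight column ignored).

    Reciprocal duplicates and self-loops are collapsed/dropped with a
    logged count.
    """
    edges = set()
    nodes = []
    seen = set()
    n_self, n_dup, n_lines = 0, 0, 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) < 2:
                raise ValueError(f"{path}: edge line has fewer than 2 columns: {line!r}")
            a, b = parts[0], parts[1]
            n_lines += 1
            for g in (a, b):
                if g not in seen:
                    seen.add(g)
                    nodes.append(g)
            if a == b:
                n_self += 1
                continue
            key = (a, b) if a < b else (b, a)
            if key in edges:
                n_dup += 1
            edges.add(key)
    if n_lines == 0:
        raise ValueError(f"{path}: no edges")
    if n_self or n_dup:
        logger.info("load_edge_list: dropped %d self-loops, collapsed %d duplicate edges",
                    n_self, n_dup)
    return GeneNetwork(sorted(nodes), edges)


def write_edge_list(net: GeneNetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")


def load_gene_list(path) -> frozenset[str]:
    """One gene per line."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def load_psi_matrix(path, condition: str = "tumor") -> PSIMatrix:
    """Read a PSI table whose index is ``GENE;CLASS;coords`` event IDs."""
    df = _read_table(path)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    df.index = df.index.astype(str)
    hosts, classes = [], []
    for ev in df.index:
        fields = ev.split(";")
        if len(fields) < 2:
            raise ValueError(f"{path}: event ID {ev!r} is not 'GENE;CLASS;coords'")
        hosts.append(fields[0])
        classes.append(fields[1])
    host = pd.Series(hosts, index=df.index, name="host")
    event_class = pd.Series(classes, index=df.index, name="event_class")
    return PSIMatrix(df.astype(float), host, event_class, condition=condition)


def write_psi_matrix(m: PSIMatrix, path) -> None:
    m.psi.to_csv(path, sep="\t", na_rep="NA", index_label="event")


def load_scores(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str),
                     name="probability")


def write_scores(scores: pd.Series, path) -> None:
    out = scores.rename("probability").rename_axis("gene").reset_index()
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Preprocessing


def max_connected_subnetwork(net: GeneNetwork, keep) -> GeneNetwork:
    """Induced subgraph on ``keep``, restricted to its largest connected
    component (ties broken by the component containing the smallest
    lexicographic gene ID)."""
    keep = set(keep)
    present = keep & set(net.nodes)
    if not present:
        raise ValueError("keep set is disjoint from network nodes")
    g = net.to_networkx().subgraph(present)
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: (-len(c), c[0]))
    winner = components[0]
    sub = g.subgraph(winner)
    return GeneNetwork(winner, [tuple(e) for e in sub.edges()])


def impute_column_means(m: OmicsMatrix) -> OmicsMatrix:
    """Replace missing values with per-sample (column) means."""
    df = m.data.copy()
    means = df.mean(axis=0, skipna=True).fillna(0.0)
    df = df.fillna(means)
    return OmicsMatrix(df, kind=m.kind)


def pca_reduce(m: OmicsMatrix, variance_ratio: float, net: GeneNetwork | None = None
               ) -> OmicsFeatureSet:
    """PCA-reduce a gene-by-sample matrix, keeping the smallest number of
    leading components whose cumulative explained-variance ratio strictly
    exceeds ``variance_ratio``.

    If a network is given, rows are realigned to its node order; genes
    present in the network but absent from the matrix get zero feature
    vectors and are flagged in ``zero_filled``.
    """
    if not (0.0 < variance_ratio <= 1.0):
        raise ValueError(f"variance_ratio must be in (0, 1], got {variance_ratio}")
    if m.data.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    df = m.data
    if df.isna().any().any():
        df = impute_column_means(m).data
    X = df.to_numpy(dtype=float)
    # Full SVD so the component count matches the exact cumulative rule.
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_ratio, side="right")) + 1
    k = min(k, scores.shape[1])
    scores = scores[:, :k]
    if net is None:
        return OmicsFeatureSet(tuple(df.index), scores)
    out = np.zeros((len(net.nodes), k), dtype=float)
    missing = []
    row_of = {g: i for i, g in enumerate(df.index)}
    for i, g in enumerate(net.nodes):
        j = row_of.get(g)
        if j is None:
            missing.append(g)
        else:
            out[i] = scores[j]
    if missing:
        logger.info("pca_reduce(%s): %d network genes lack omics data, rows zero-filled",
                    m.kind, len(missing))
    return OmicsFeatureSet(tuple(net.nodes), out, zero_filled=tuple(missing))


def normalize_adjacency(net: GeneNetwork) -> sp.csr_matrix:
    """Symmetrically normalized adjacency with self-connections,
    D̃^(−1/2) (A + I) D̃^(−1/2)."""
    if len(net.nodes) == 0:
        raise ValueError("empty network")
    a_tilde = net.adjacency() + sp.identity(len(net.nodes), format="csr")
    deg = np.asarray(a_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    return (d_inv_sqrt @ a_tilde @ d_inv_sqrt).tocsr()
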