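"""Stage I: hierarchical multi-omics graph convolutional model (HIM-GCN).

Four one-layer GCNs learn per-omics gene representations on the shared
interaction network; their outputs are concatenated and refined by a
two-layer integrative GCN that emits a per-gene cancer-gene probability.
Training is semi-supervised (labels on a small gene subset, propagation
over the whole graph) with a class-imbalance-weighted cross-entropy loss,
optimized full-batch with Adam. The model is small enough that forward,
backward and the optimizer are written directly against numpy/scipy;
gradients are exercised against finite differences in the test suite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import GeneNetwork, LabelSet, OmicsFeatureSet, normalize_adjacency
from .evaluation import binary_metrics

logger = logging.getLogger("glims")

OMICS_ORDER = ("exp", "mut", "meth", "cnv")

#: Training epochs used for each cancer dataset.
EPOCH_PRESETS = {"pan_cancer": 6000, "BRCA": 2000, "GBM": 3000, "LUAD": 1500}


@dataclass(frozen=True)
class HIMGCNConfig:
    per_omics_out_dim: int = 50
    hidden_dim: int = 100
    out_dim: int = 1
    learning_rate: float = 0.001
    epochs: int = 6000
    lambda1: float = 5e-4  # L1 weight penalty
    lambda2: float = 5e-4  # squared-L2 weight penalty
    n_folds: int = 3
    seed: int = 0
    score_mode: str = "full"  # "full": predict with the all-label model; "fold_mean": average folds

    @property
    def concat_dim(self) -> int:
        return 4 * self.per_omics_out_dim

    def __post_init__(self):
        for name in ("per_omics_out_dim", "hidden_dim", "out_dim", "n_folds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


def _relu(x):
    return np.maximum(x, 0.0)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


_ACTIVATIONS = {"relu": _relu, "identity": lambda x: x, "output": _sigmoid}


def gcn_layer(a_hat, h: np.ndarray, w: np.ndarray, activation: str = "relu") -> np.ndarray:
    """One spectral graph-convolution step: activation(Â · H · W)."""
    h = np.asarray(h, dtype=float)
    w = np.asarray(w, dtype=float)
    if h.shape[1] != w.shape[0]:
        raise ValueError(f"shape mismatch: features {h.shape} vs weights {w.shape}")
    try:
        act = _ACTIVATIONS[activation]
    except KeyError:
        raise ValueError(f"unknown activation {activation!r}") from None
    return act(a_hat @ (h @ w))


@dataclass
class HIMGCNModel:
    """Weights of the hierarchical GCN plus the fixed normalized adjacency."""

    weights: dict[str, np.ndarray]  # W_exp, W_mut, W_meth, W_cnv, W_int0, W_int1
    a_hat: sp.csr_matrix
    nodes: tuple[str, ...]
    config: HIMGCNConfig

    WEIGHT_KEYS = ("W_exp", "W_mut", "W_meth", "W_cnv", "W_int0", "W_int1")

    @classmethod
    def initialize(cls, net: GeneNetwork, input_dims, cfg: HIMGCNConfig,
                   seed: int | None = None) -> "HIMGCNModel":
        """Glorot-uniform initialization, seeded."""
        rng = np.random.default_rng(cfg.seed if seed is None else seed)

        def glorot(fan_in, fan_out):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=(fan_in, fan_out))

        d = cfg.per_omics_out_dim
        weights = {}
        for tag, d_in in zip(OMICS_ORDER, input_dims):
            weights[f"W_{tag}"] = glorot(d_in, d)
        weights["W_int0"] = glorot(cfg.concat_dim, cfg.hidden_dim)
        weights["W_int1"] = glorot(cfg.hidden_dim, cfg.out_dim)
        return cls(weights, normalize_adjacency(net), tuple(net.nodes), cfg)

    def weight_norms(self) -> tuple[float, float]:
        """(Σ‖W‖₁, Σ‖W‖₂²) over all six weight matrices."""
        l1 = sum(np.abs(w).sum() for w in self.weights.values())
        l2 = sum((w ** 2).sum() for w in self.weights.values())
        return float(l1), float(l2)


def _check_alignment(model: HIMGCNModel, features: dict[str, OmicsFeatureSet]) -> None:
    for tag in OMICS_ORDER:
        fs = features[tag]
        if tuple(fs.genes) != model.nodes:
            raise ValueError(f"feature set {tag!r} is not aligned to the model's network")
        d_in = model.weights[f"W_{tag}"].shape[0]
        if fs.values.shape[1] != d_in:
            raise ValueError(
                f"feature set {tag!r} has {fs.values.shape[1]} columns, model expects {d_in}")


def _forward_cached(model: HIMGCNModel, ax: dict[str, np.ndarray]) -> dict:
    """Forward pass given precomputed Â·X_t products; returns all caches."""
    w = model.weights
    s_t, z_t = {}, {}
    for tag in OMICS_ORDER:
        s_t[tag] = ax[tag] @ w[f"W_{tag}"]
        z_t[tag] = _relu(s_t[tag])
    x_int = np.hstack([z_t[tag] for tag in OMICS_ORDER])
    ax_int = model.a_hat @ x_int
    s1 = ax_int @ w["W_int0"]
    h1 = _relu(s1)
    ah1 = model.a_hat @ h1
    logits = (ah1 @ w["W_int1"]).ravel()
    return {"s_t": s_t, "ax_int": ax_int, "s1": s1, "ah1": ah1, "logits": logits}


def _precompute_ax(model: HIMGCNModel, features: dict[str, OmicsFeatureSet]
                   ) -> dict[str, np.ndarray]:
    return {tag: model.a_hat @ features[tag].values for tag in OMICS_ORDER}


def forward(model: HIMGCNModel, features: dict[str, OmicsFeatureSet]) -> pd.Series:
    """Per-gene probability of being a cancer gene.

    ``features`` maps the omics tags ``exp, mut, meth, cnv`` to feature
    sets aligned to the model's network; concatenation order is fixed.
    """
    _check_alignment(model, features)
    cache = _forward_cached(model, _precompute_ax(model, features))
    return pd.Series(_sigmoid(cache["logits"]), index=list(model.nodes), name="probability")


def weighted_loss(scores: pd.Series, labels: LabelSet, model: HIMGCNModel | None = None,
                  lambda1: float = 0.0, lambda2: float = 0.0,
                  alpha: tuple[float, float] | None = None) -> float:
    """Imbalance-weighted cross-entropy over labeled genes plus weight penalties.

    L = −(1/N) Σ_labeled [α1·y·log p + α2·(1−y)·log(1−p)] + λ1Σ‖W‖₁ + λ2Σ‖W‖₂²
    with α1 = N/N_pos, α2 = N/N_neg by default. Unlabeled genes contribute
    nothing.
    """
    y, mask = _labels_on(scores.index, labels)
    n_pos, n_neg = int(y[mask].sum()), int(mask.sum() - y[mask].sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    n = n_pos + n_neg
    a1, a2 = (n / n_pos, n / n_neg) if alpha is None else alpha
    p = np.clip(scores.to_numpy(dtype=float), 1e-12, 1 - 1e-12)
    terms = a1 * y * np.log(p) + a2 * (1 - y) * np.log(1 - p)
    loss = -terms[mask].sum() / n
    if model is not None:
        l1, l2 = model.weight_norms()
        loss += lambda1 * l1 + lambda2 * l2
    return float(loss)


def _labels_on(index, labels: LabelSet):
    y = np.array([1.0 if g in labels.positives else 0.0 for g in index])
    mask = np.array([g in labels.positives or g in labels.negatives for g in index])
    return y, mask


# ---------------------------------------------------------------------------
# Training


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1 ** self.t)
            v_hat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _loss_and_grads(model: HIMGCNModel, ax: dict[str, np.ndarray],
                    features: dict[str, OmicsFeatureSet],
                    y: np.ndarray, mask: np.ndarray,
                    a1: float, a2: float, lam1: float, lam2: float):
    """Stable logit-space loss and exact gradients for all six weights."""
    w = model.weights
    cache = _forward_cached(model, ax)
    z = cache["logits"]
    p = _sigmoid(z)
    n = int(mask.sum())
    # softplus(x) = log(1 + e^x), computed stably
    sp_pos = np.logaddexp(0.0, z)   # softplus(z)  = -log(1-p)
    sp_neg = np.logaddexp(0.0, -z)  # softplus(-z) = -log p
    data_loss = (a1 * y * sp_neg + a2 * (1 - y) * sp_pos)[mask].sum() / n
    l1, l2 = model.weight_norms()
    loss = data_loss + lam1 * l1 + lam2 * l2

    dz = np.zeros_like(z)
    dz[mask] = (-a1 * y * (1 - p) + a2 * (1 - y) * p)[mask] / n

    grads = {}
    a_hat = model.a_hat
    grads["W_int1"] = cache["ah1"].T @ dz[:, None]
    d_ah1 = dz[:, None] @ w["W_int1"].T
    d_s1 = (a_hat @ d_ah1) * (cache["s1"] > 0)
    grads["W_int0"] = cache["ax_int"].T @ d_s1
    d_x_int = a_hat @ (d_s1 @ w["W_int0"].T)
    d = model.config.per_omics_out_dim
    for i, tag in enumerate(OMICS_ORDER):
        d_z_t = d_x_int[:, i * d:(i + 1) * d]
        d_s_t = d_z_t * (cache["s_t"][tag] > 0)
        grads[f"W_{tag}"] = ax[tag].T @ d_s_t
    for k in grads:
        grads[k] += lam1 * np.sign(w[k]) + 2.0 * lam2 * w[k]
    return loss, grads


def _train_single(model: HIMGCNModel, features: dict[str, OmicsFeatureSet],
                  y: np.ndarray, mask: np.ndarray, cfg: HIMGCNConfig) -> list[float]:
    n_pos = int(y[mask].sum())
    n_neg = int(mask.sum()) - n_pos
    n = n_pos + n_neg
    a1, a2 = n / n_pos, n / n_neg
    ax = _precompute_ax(model, features)
    opt = _Adam(model.weights, cfg.learning_rate)
    history = []
    for _ in range(cfg.epochs):
        loss, grads = _loss_and_grads(model, ax, features, y, mask,
                                      a1, a2, cfg.lambda1, cfg.lambda2)
        opt.step(model.weights, grads)
        history.append(loss)
    return history


def stratified_folds(positives, negatives, n_folds: int, seed: int) -> list[frozenset[str]]:
    """Seeded stratified split of labeled genes into ``n_folds`` folds."""
    rng = np.random.default_rng(seed)
    folds = [set() for _ in range(n_folds)]
    for group in (sorted(positives), sorted(negatives)):
        order = rng.permutation(len(group))
        for slot, idx in enumerate(order):
            folds[slot % n_folds].add(group[idx])
    return [frozenset(f) for f in folds]


@dataclass
class TrainResult:
    fold_models: list[HIMGCNModel]
    fold_metrics: pd.DataFrame  # one row per fold: accuracy, auroc, auprc, f1, ...
    final_model: HIMGCNModel
    scores: pd.Series  # per-gene probability from the configured score_mode
    loss_history: list[float] = field(default_factory=list)


def train(net: GeneNetwork, features: dict[str, OmicsFeatureSet], labels: LabelSet,
          cfg: HIMGCNConfig) -> TrainResult:
    """Train under stratified k-fold cross-validation plus a final
    all-label model used for prediction.

    Each fold trains on the other folds' labels for ``cfg.epochs`` Adam
    steps and is evaluated on its own held-out labels. All randomness
    (fold assignment, weight initialization) derives from ``cfg.seed``.
    """
    labels = labels.restrict(net.nodes)
    if len(labels.positives) < cfg.n_folds or len(labels.negatives) < cfg.n_folds:
        raise ValueError(
            f"need at least {cfg.n_folds} genes per class, got "
            f"{len(labels.positives)} positives / {len(labels.negatives)} negatives")
    input_dims = [features[tag].values.shape[1] for tag in OMICS_ORDER]
    ss = np.random.SeedSequence(cfg.seed)
    fold_seed, *model_seeds = [int(s.generate_state(1)[0] % 2**31)
                               for s in ss.spawn(cfg.n_folds + 2)]
    folds = stratified_folds(labels.positives, labels.negatives, cfg.n_folds, fold_seed)

    fold_models, rows = [], []
    y_all, _ = _labels_on(net.nodes, labels)
    for k, held_out in enumerate(folds):
        train_labels = LabelSet(labels.positives - held_out, labels.negatives - held_out)
        y, mask = _labels_on(net.nodes, train_labels)
        model = HIMGCNModel.initialize(net, input_dims, cfg, seed=model_seeds[k])
        _train_single(model, features, y, mask, cfg)
        scores_k = forward(model, features)
        test_labels = LabelSet(labels.positives & held_out, labels.negatives & held_out)
        report = binary_metrics(scores_k.loc[sorted(held_out)], test_labels)
        rows.append({"fold": k, **report.to_dict()})
        fold_models.append(model)

    final_seed = model_seeds[cfg.n_folds]
    final_model = HIMGCNModel.initialize(net, input_dims, cfg, seed=final_seed)
    y, mask = _labels_on(net.nodes, labels)
    history = _train_single(final_model, features, y, mask, cfg)

    if cfg.score_mode == "fold_mean":
        scores = sum(forward(m, features) for m in fold_models) / len(fold_models)
        scores.name = "probability"
    else:
        scores = forward(final_model, features)
    return TrainResult(fold_models, pd.DataFrame(rows), final_model, scores, history)


# ---------------------------------------------------------------------------
# Label and candidate helpers


def sample_negatives(negative_pool, positives, mode: str = "pan_cancer",
                     seed: int = 0) -> frozenset[str]:
    """Pan-cancer analyses use the whole curated negative pool; cancer-
    specific analyses sample negatives at ten times the positive count."""
    pool = set(negative_pool)
    if not pool:
        raise ValueError("empty negative pool")
    if pool & set(positives):
        raise ValueError("negative pool overlaps positives")
    if mode == "pan_cancer":
        return frozenset(pool)
    if mode != "specific":
        raise ValueError(f"unknown mode {mode!r}")
    want = 10 * len(set(positives))
    if len(pool) <= want:
        warnings.warn(
            f"negative pool ({len(pool)}) smaller than 10x positives ({want}); using all")
        return frozenset(pool)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(sorted(pool), size=want, replace=False)
    return frozenset(chosen.tolist())


def select_candidates(scores: pd.Series, cutoff: float = 0.7) -> frozenset[str]:
    """Genes whose probability strictly exceeds the cutoff."""
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError("cutoff must be in [0, 1]")
    return frozenset(scores.index[scores > cutoff].tolist())
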