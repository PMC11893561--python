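"""Cross-attention multimodal fusion and bag-level classification.

A bag is a quadruplet of row-aligned feature matrices — patch ``F_p``,
cell ``F_c``, text ``F_t`` and reconstruction ``F_r`` — and the classifier
aggregates them with a cascade of single-head cross-attention blocks
(``Attention(Q, K, V) = softmax(Q K^T / sqrt(d_k)) V``):

    H1 = Attn(F_t, F_c, F_c)      # text queries contextualize cell features
    H2 = Attn(H1, F_p, F_p)       # then patch features
    H3 = Attn(F_r, H2, H2)        # reconstruction features guide the final pass

The instance axis is preserved through the cascade; the bag representation
is the mean over the rows of ``H3``, followed by a linear head.  When a
modality is absent (feature-ablation variants) the cascade simply skips
its block; with patch features alone the chain degenerates to
``Attn(F_r, F_p, F_p)``.

Because the native dims differ across modalities (512/1280/512), every
block learns linear projections of Q, K and V into a common model
dimension.  In unimodal mode a fixed-size learnable latent array attends
to the (F_r-queried) representation, Perceiver-IO style, so the cost of
the readout is independent of the bag size.

Class imbalance is handled by weighted cross-entropy with
``w_c = N_total / (C * N_c)``, which makes rare classes count more while
conserving ``sum_c N_c w_c = N_total``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .anomaly import GMVAEModel, reconstruct
from .autodiff import Tensor, log_softmax, mean_, softmax, sum_
from .bags import BagDataset, EmbeddingBag
from .nn import Adam, Linear
from .selection import SelectionConfig, apply_selection, select

logger = logging.getLogger(__name__)

#: native embedding dims per modality (patch, cell, text, reconstruction)
DEFAULT_DIMS = {"p": 512, "c": 1280, "t": 512, "r": 512}


# ---------------------------------------------------------------------------
# Attention primitives
# ---------------------------------------------------------------------------

def scaled_dot_attention(Q, K, V):
    """Single-head attention ``softmax(Q K^T / sqrt(d_k)) V``.

    Rows of the output are convex combinations of the rows of ``V``.
    Generic over numpy arrays and autodiff Tensors.
    """
    k_shape = K.data.shape if isinstance(K, Tensor) else np.shape(K)
    if k_shape[0] == 0:
        raise ValueError("attention needs at least one key/value row")
    d_k = k_shape[1]
    scores = (Q @ K.T) * (1.0 / math.sqrt(d_k))
    return softmax(scores, axis=-1) @ V


class CrossAttentionBlock:
    """Projects Q/K/V into a common model dim, attends, projects the output."""

    def __init__(self, d_query: int, d_context: int, d_model: int,
                 rng: np.random.Generator):
        self.d_model = d_model
        self.q_proj = Linear(d_query, d_model, rng)
        self.k_proj = Linear(d_context, d_model, rng)
        self.v_proj = Linear(d_context, d_model, rng)
        self.out_proj = Linear(d_model, d_model, rng)

    @classmethod
    def identity(cls, d: int) -> "CrossAttentionBlock":
        """All projections set to the identity (for d_query = d_context = d_model)."""
        block = cls(d, d, d, np.random.default_rng(0))
        for lin in (block.q_proj, block.k_proj, block.v_proj, block.out_proj):
            lin.W.data = np.eye(d, dtype=lin.W.data.dtype)
            lin.b.data[:] = 0.0
        return block

    def __call__(self, query_feats, context_feats):
        Q = self.q_proj(query_feats)
        K = self.k_proj(context_feats)
        V = self.v_proj(context_feats)
        return self.out_proj(scaled_dot_attention(Q, K, V))

    def parameters(self):
        return [p for lin in (self.q_proj, self.k_proj, self.v_proj, self.out_proj)
                for p in lin.parameters()]


def cross_attention_block(query_feats, context_feats,
                          params: CrossAttentionBlock):
    """Functional form of :class:`CrossAttentionBlock`."""
    return params(query_feats, context_feats)


# ---------------------------------------------------------------------------
# Fusion model
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Classifier training hyperparameters (per-bag gradient steps)."""

    learning_rate: float = 3e-5
    epochs: int = 20
    weight_decay: float = 1e-3
    d_model: int = 512
    n_latents: int = 32
    n_classes: int = 2
    class_weights: Optional[np.ndarray] = None  # computed from data if None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate < 0 or self.epochs < 1:
            raise ValueError("invalid learning_rate/epochs")


class FusionModel:
    """Cross-attention cascade (or Perceiver-style unimodal block) + linear head.

    ``modalities`` lists the feature matrices the model consumes, out of
    ``p`` (patch, always required), ``c`` (cell), ``t`` (text) and ``r``
    (reconstruction).  The cascade wiring follows the fixed order
    text -> cell -> patch -> reconstruction, skipping absent modalities.
    """

    def __init__(self, modalities: Sequence[str] = ("p", "c", "t", "r"),
                 mode: str = "multimodal", d_model: int = 512,
                 n_classes: int = 2, n_latents: int = 32, seed: int = 0,
                 dims: Optional[dict] = None):
        if mode not in ("multimodal", "unimodal"):
            raise ValueError(f"unknown mode {mode!r}")
        if "p" not in modalities:
            raise ValueError("patch features 'p' are required")
        self.mode = mode
        self.modalities = tuple(modalities)
        self.dims = dict(DEFAULT_DIMS, **(dims or {}))
        self.d_model = d_model
        self.n_classes = n_classes
        self.n_latents = n_latents
        self.seed = seed
        self.frozen = False
        self.loss_history: list[float] = []
        rng = np.random.default_rng(seed)

        if mode == "unimodal":
            if "r" not in self.modalities:
                raise ValueError("unimodal mode uses ('p', 'r')")
            self.input_proj = Linear(self.dims["r"], d_model, rng)
            self.p_block = CrossAttentionBlock(d_model, self.dims["p"], d_model, rng)
            self.latents = Tensor(
                rng.normal(0.0, 1.0 / math.sqrt(d_model),
                           (n_latents, d_model)).astype(np.float32),
                requires_grad=True)
            self.latent_block = CrossAttentionBlock(d_model, d_model, d_model, rng)
            self._ctx_names: list[str] = []
        else:
            ctxs = [m for m in ("c", "p") if m in self.modalities]
            self._q0 = "t" if "t" in self.modalities else ctxs.pop(0)
            self._ctx_names = ctxs
            self.input_proj = Linear(self.dims[self._q0], d_model, rng)
            self.blocks = {name: CrossAttentionBlock(d_model, self.dims[name],
                                                     d_model, rng)
                           for name in ctxs}
            if "r" in self.modalities:
                self.r_block = CrossAttentionBlock(self.dims["r"], d_model,
                                                   d_model, rng)
        head_rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(7,)))
        self.head = Linear(d_model, n_classes, head_rng)

    # -- forward -------------------------------------------------------------
    def fuse(self, feats: dict):
        """Run the cascade; returns ``(H3, pooled)`` with pooled of shape (1, d_model)."""
        missing = [m for m in self.modalities if m not in feats]
        if missing:
            raise ValueError(f"bag is missing modalities {missing}")
        if self.mode == "unimodal":
            Hq = self.input_proj(feats["r"])
            H = self.p_block(Hq, feats["p"])
            Z = self.latent_block(self.latents, H)
            return Z, mean_(Z, axis=0, keepdims=True)
        H = self.input_proj(feats[self._q0])
        for name in self._ctx_names:
            H = self.blocks[name](H, feats[name])
        if "r" in self.modalities:
            H = self.r_block(feats["r"], H)
        return H, mean_(H, axis=0, keepdims=True)

    def logits(self, feats: dict):
        _, pooled = self.fuse(feats)
        return self.head(pooled)

    def parameters(self):
        params = self.input_proj.parameters()
        if self.mode == "unimodal":
            params += self.p_block.parameters()
            params.append(self.latents)
            params += self.latent_block.parameters()
        else:
            for name in self._ctx_names:
                params += self.blocks[name].parameters()
            if "r" in self.modalities:
                params += self.r_block.parameters()
        return params + self.head.parameters()

    def freeze(self) -> "FusionModel":
        self.frozen = True
        return self

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        import json
        from pathlib import Path
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        with open(path, "wb") as f:
            np.savez(f, **arrays)
        meta = {"mode": self.mode, "modalities": list(self.modalities),
                "d_model": self.d_model, "n_classes": self.n_classes,
                "n_latents": self.n_latents, "seed": self.seed,
                "dims": self.dims, "frozen": self.frozen,
                "loss_history": self.loss_history}
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "FusionModel":
        import json
        from pathlib import Path
        meta = json.loads(Path(str(path) + ".json").read_text())
        model = cls(modalities=meta["modalities"], mode=meta["mode"],
                    d_model=meta["d_model"], n_classes=meta["n_classes"],
                    n_latents=meta["n_latents"], seed=meta["seed"],
                    dims={k: int(v) for k, v in meta["dims"].items()})
        with np.load(path) as data:
            for i, p in enumerate(model.parameters()):
                p.data = data[f"param_{i}"]
        model.loss_history = list(meta["loss_history"])
        if meta["frozen"]:
            model.freeze()
        return model


def fuse(F_p, F_c, F_t, F_r, model: FusionModel):
    """Cascade over the full quadruplet; returns ``(H3, H3_bar)``.

    ``H3`` keeps one row per instance; ``H3_bar`` is their mean (the bag
    representation fed to the linear head).
    """
    feats = {"p": F_p, "c": F_c, "t": F_t, "r": F_r}
    feats = {k: v for k, v in feats.items() if v is not None}
    H, pooled = model.fuse(feats)
    pooled = pooled.data if isinstance(pooled, Tensor) else pooled
    H = H.data if isinstance(H, Tensor) else H
    return H, pooled[0]


def perceiver_fuse_unimodal(F_p, F_r, model: FusionModel):
    """Latent-bottleneck readout of (F_p, F_r); returns the pooled d_model vector."""
    if model.mode != "unimodal":
        raise ValueError("model must be in unimodal mode")
    _, pooled = model.fuse({"p": F_p, "r": F_r})
    pooled = pooled.data if isinstance(pooled, Tensor) else pooled
    return pooled[0]


# ---------------------------------------------------------------------------
# Baseline aggregators and losses
# ---------------------------------------------------------------------------

def mean_pool_baseline(H: np.ndarray) -> np.ndarray:
    """Column mean over instances (bag-level average embedding)."""
    H = np.asarray(H)
    if H.shape[0] == 0:
        raise ValueError("empty bag")
    return H.mean(axis=0)


def max_pool_baseline(H: np.ndarray) -> np.ndarray:
    """Elementwise column max over instances (most salient activations)."""
    H = np.asarray(H)
    if H.shape[0] == 0:
        raise ValueError("empty bag")
    return H.max(axis=0)


def concat_modalities(feats: dict[str, np.ndarray]) -> np.ndarray:
    """Feature-axis concatenation of row-aligned modalities (baseline fusion)."""
    mats = [feats[k] for k in sorted(feats)]
    return np.concatenate(mats, axis=1)


def class_weights(labels, n_classes: int) -> np.ndarray:
    """Inverse-frequency weights ``w_c = N_total / (C * N_c)``.

    Conserves ``sum_c N_c w_c = N_total``; errors if a class is empty.
    """
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=n_classes)
    if np.any(counts == 0):
        raise ValueError(f"every class must be present; counts={counts.tolist()}")
    return len(labels) / (n_classes * counts.astype(float))


def _one_hot(labels, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.ndim == 2:
        return labels.astype(float)
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels.astype(int)] = 1.0
    return out


def weighted_ce(logits, labels, w):
    """Weighted cross-entropy over softmax probabilities.

    ``L = -(1/b) sum_i sum_c w_c Y_ic log(softmax(logits)_ic)``.
    ``labels`` may be one-hot rows or integer class indices.  Generic over
    numpy arrays and Tensors (for the training graph).
    """
    shape = logits.data.shape if isinstance(logits, Tensor) else np.shape(logits)
    b, C = shape
    Y = _one_hot(labels, C)
    if Y.shape != (b, C):
        raise ValueError("labels shape does not match logits")
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("class weights must be positive")
    logp = log_softmax(logits, axis=-1)
    dtype = logits.data.dtype if isinstance(logits, Tensor) else np.asarray(logits).dtype
    weighted = (Y * w).astype(dtype, copy=False)  # keep the graph in the logits dtype
    return -(1.0 / b) * sum_(logp * weighted)


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------

@dataclass
class BagPrediction:
    """Logits, softmax probabilities and the arg-max label for one bag."""

    logits: np.ndarray
    probabilities: np.ndarray
    label: int


def _bag_feats(bag: EmbeddingBag, modalities, dtype=np.float32) -> dict:
    feats = bag.modalities()
    missing = [m for m in modalities if m not in feats]
    if missing:
        raise ValueError(f"bag {bag.bag_id} is missing modalities {missing}")
    return {k: feats[k].astype(dtype) for k in modalities}


def train_classifier(dataset: BagDataset, model: FusionModel,
                     config: TrainConfig) -> FusionModel:
    """Train the fusion classifier on (already selected) bags.

    One gradient step per bag (bags have variable instance counts), Adam,
    weighted cross-entropy with Eq.-style inverse-frequency class weights
    computed from the training labels unless supplied.
    """
    labels = dataset.labels
    w = (np.asarray(config.class_weights, dtype=float)
         if config.class_weights is not None
         else class_weights(labels, config.n_classes))
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(3,)))
    opt = Adam(model.parameters(), lr=config.learning_rate,
               weight_decay=config.weight_decay)
    cached = [_bag_feats(b, model.modalities) for b in dataset]
    for epoch in range(config.epochs):
        order = rng.permutation(len(dataset))
        losses = []
        for i in order:
            feats = {k: Tensor(v) for k, v in cached[i].items()}
            logits = model.logits(feats)
            loss = weighted_ce(logits, np.array([labels[i]]), w)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        epoch_loss = float(np.mean(losses))
        model.loss_history.append(epoch_loss)
        logger.info("fusion epoch %d/%d loss=%.4f",
                    epoch + 1, config.epochs, epoch_loss)
    return model.freeze()


def predict_bag(bag: EmbeddingBag, ad_model: GMVAEModel,
                fusion_model: FusionModel,
                selection: SelectionConfig) -> BagPrediction:
    """Deterministic pipeline: reconstruct -> select -> fuse -> linear head.

    Scores the bag with the frozen anomaly detector, keeps the top-k
    instances, runs the fusion cascade on the kept rows and returns softmax
    probabilities.
    """
    if not fusion_model.frozen:
        raise ValueError("fusion model must be frozen before prediction")
    rec = reconstruct(ad_model, bag.F_p)
    bag = bag.with_(F_r=rec.F_r, errors=rec.errors)
    result = select(rec.errors, selection)
    if result.n_selected == 0:
        raise ValueError("selection produced an empty bag")
    kept = apply_selection(bag, result)
    feats = _bag_feats(kept, fusion_model.modalities)
    logits = fusion_model.logits(feats)
    logits = logits.data if isinstance(logits, Tensor) else logits
    logits = np.asarray(logits, dtype=float)[0]
    p = np.exp(logits - logits.max())
    p /= p.sum()
    return BagPrediction(logits=logits, probabilities=p, label=int(np.argmax(p)))
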