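"""The multimodal fusion network for herb-symptom association prediction.

Architecture (mirrors the four blocks of the predictor): a main feature
processor (MLP over the concatenated semantic embeddings and proximity
scalars), two bidirectional LSTM target encoders over the herb's target
genes and the symptom's gene set, cross-modal scaled dot-product attention
applied in both directions (herb targets attending over symptom genes and
vice versa, each mean-pooled over valid query positions), and a sigmoid
classifier over the fused representation.

Gene tokens enter through a learned embedding table trained end-to-end;
the PPI graph's contribution arrives through the proximity scalars.  All
parameters are float64 tensors from :mod:`tcmspred.autograd`; optimization
is mini-batch Adam on mean binary cross-entropy with early stopping on a
held-out validation AUC.  Every source of randomness (initialization,
shuffling, dropout) flows from the one config seed, and prediction is
deterministic (dropout off).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .network import PairFeatures

__all__ = ["ModelConfig", "TrainedModel", "PairScore", "EncoderState",
           "AttentionOutput", "FusionNetwork", "encode_targets",
           "cross_attend", "forward", "train", "predict", "bce_loss",
           "save_model", "load_model"]

MODALITIES = ("semantic", "proximity", "sequence")
_EPS = 1e-12


@dataclass
class ModelConfig:
    gene_dim: int = 32              # learned gene-token embedding size d_g
    hidden: int = 64                # LSTM hidden units per direction
    proc_hidden: tuple[int, ...] = (128,)
    cls_hidden: tuple[int, ...] = (64,)
    dropout: float = 0.1
    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 5
    val_fraction: float = 0.1
    modalities: tuple[str, ...] = MODALITIES
    seed: int = 0

    def validate(self) -> None:
        if self.gene_dim < 1 or self.hidden < 1:
            raise ValueError("sizes must be >= 1")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if not self.modalities or any(m not in MODALITIES for m in self.modalities):
            raise ValueError(f"modalities must be a subset of {MODALITIES}")

    @property
    def attn_dim(self) -> int:
        return 2 * self.hidden


@dataclass
class EncoderState:
    """Per-position bidirectional hidden vectors [fwd; bwd] plus the mask."""

    hidden: Tensor          # (B, L, 2h)
    mask: np.ndarray        # (B, L) bool


@dataclass
class AttentionOutput:
    weights: Tensor         # (B, Lq, Lk); rows over valid keys sum to 1
    context: Tensor         # (B, Lq, 2h)


@dataclass
class PairScore:
    herb: str
    symptom: str
    probability: float


@dataclass
class TrainedModel:
    params: dict[str, np.ndarray]
    config: ModelConfig
    n_genes: int
    semantic_dim: int
    prox_mean: np.ndarray
    prox_std: np.ndarray
    feature_digest: str
    history: dict = field(default_factory=dict)


class FusionNetwork:
    """Parameter container + forward pass; differentiable via autograd."""

    def __init__(self, config: ModelConfig, n_genes: int, semantic_dim: int,
                 rng: np.random.Generator):
        config.validate()
        self.config = config
        self.n_genes = n_genes
        self.semantic_dim = semantic_dim
        self.params: dict[str, Tensor] = {}
        c = config

        def glorot(shape):
            bound = np.sqrt(6.0 / (shape[0] + shape[-1]))
            return Tensor(rng.uniform(-bound, bound, shape), requires_grad=True)

        if "sequence" in c.modalities:
            self.params["gene_emb"] = Tensor(
                rng.normal(0, 0.1, (n_genes, c.gene_dim)), requires_grad=True)
            for enc in ("herb", "sym"):
                for direction in ("f", "b"):
                    p = f"lstm_{enc}_{direction}"
                    self.params[f"{p}_W"] = glorot((c.gene_dim, 4 * c.hidden))
                    self.params[f"{p}_U"] = glorot((c.hidden, 4 * c.hidden))
                    b = np.zeros(4 * c.hidden)
                    b[c.hidden:2 * c.hidden] = 1.0   # forget-gate bias
                    self.params[f"{p}_b"] = Tensor(b, requires_grad=True)

        proc_in = 0
        if "semantic" in c.modalities:
            proc_in += 2 * semantic_dim
        if "proximity" in c.modalities:
            proc_in += 4
        if proc_in == 0:
            raise ValueError("at least one scalar modality or sequence required")
        sizes = [proc_in, *c.proc_hidden]
        for i in range(len(sizes) - 1):
            self.params[f"proc_{i}_W"] = glorot((sizes[i], sizes[i + 1]))
            self.params[f"proc_{i}_b"] = Tensor(np.zeros(sizes[i + 1]),
                                                requires_grad=True)
        fused = sizes[-1] + (2 * c.attn_dim if "sequence" in c.modalities else 0)
        sizes = [fused, *c.cls_hidden, 1]
        for i in range(len(sizes) - 1):
            self.params[f"cls_{i}_W"] = glorot((sizes[i], sizes[i + 1]))
            self.params[f"cls_{i}_b"] = Tensor(np.zeros(sizes[i + 1]),
                                               requires_grad=True)

    # ---- building blocks -------------------------------------------
    def _lstm_direction(self, x: Tensor, prefix: str) -> list[Tensor]:
        """Run one LSTM direction over (B, L, d) input; returns h_t list."""
        c_cfg = self.config
        B, L = x.shape[0], x.shape[1]
        W, U, b = (self.params[f"{prefix}_W"], self.params[f"{prefix}_U"],
                   self.params[f"{prefix}_b"])
        h = Tensor(np.zeros((B, c_cfg.hidden)))
        cell = Tensor(np.zeros((B, c_cfg.hidden)))
        H = c_cfg.hidden
        outs = []
        for t in range(L):
            xt = x.slice((slice(None), t))
            gates = xt @ W + h @ U + b
            i = ag.sigmoid(gates.slice((slice(None), slice(0, H))))
            f = ag.sigmoid(gates.slice((slice(None), slice(H, 2 * H))))
            g = ag.tanh(gates.slice((slice(None), slice(2 * H, 3 * H))))
            o = ag.sigmoid(gates.slice((slice(None), slice(3 * H, 4 * H))))
            cell = f * cell + i * g
            h = o * ag.tanh(cell)
            outs.append(h)
        return outs

    def encode(self, seq: np.ndarray, mask: np.ndarray, which: str) -> EncoderState:
        """Bidirectional encoding of a (B, L) gene-index batch."""
        if not mask.any(axis=1).all():
            raise ValueError("all-pad sequence in batch (empty entity)")
        x = ag.embedding_lookup(self.params["gene_emb"], seq)
        fwd = self._lstm_direction(x, f"lstm_{which}_f")
        x_rev = ag.embedding_lookup(self.params["gene_emb"], seq[:, ::-1])
        bwd_rev = self._lstm_direction(x_rev, f"lstm_{which}_b")
        L = seq.shape[1]
        per_pos = [ag.concat([fwd[t], bwd_rev[L - 1 - t]], axis=-1)
                   for t in range(L)]
        return EncoderState(hidden=ag.stack_rows(per_pos, axis=1), mask=mask)

    def attend(self, query: EncoderState, key: EncoderState) -> AttentionOutput:
        """Scaled dot-product cross attention, A = softmax(Q K^T / sqrt(d_a))."""
        d_a = self.config.attn_dim
        logits = (query.hidden @ key.hidden.transpose_last()) * (1.0 / np.sqrt(d_a))
        A = ag.masked_softmax(logits, key.mask[:, None, :])
        return AttentionOutput(weights=A, context=A @ key.hidden)

    @staticmethod
    def _masked_mean(x: Tensor, mask: np.ndarray) -> Tensor:
        w = mask.astype(float)
        denom = w.sum(axis=1, keepdims=True)
        return (x * Tensor(w[:, :, None])).sum(axis=1) * Tensor(1.0 / denom)

    def _mlp(self, x: Tensor, prefix: str, n_layers: int, final_linear: bool,
             dropout_rng: np.random.Generator | None) -> Tensor:
        p = self.config.dropout
        for i in range(n_layers):
            x = x @ self.params[f"{prefix}_{i}_W"] + self.params[f"{prefix}_{i}_b"]
            last = i == n_layers - 1
            if not (final_linear and last):
                x = ag.relu(x)
                if dropout_rng is not None and p > 0:
                    keep = (dropout_rng.random(x.shape) >= p) / (1.0 - p)
                    x = x * Tensor(keep)
        return x

    def forward_batch(
        self,
        sem_h: np.ndarray, sem_s: np.ndarray, prox: np.ndarray,
        herb_seq: np.ndarray, herb_mask: np.ndarray,
        sym_seq: np.ndarray, sym_mask: np.ndarray,
        dropout_rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Probabilities (B,) for a standardized feature batch."""
        c = self.config
        scalar_parts = []
        if "semantic" in c.modalities:
            scalar_parts += [Tensor(sem_h), Tensor(sem_s)]
        if "proximity" in c.modalities:
            scalar_parts.append(Tensor(prox))
        z = self._mlp(ag.concat(scalar_parts, axis=-1), "proc",
                      len(c.proc_hidden), final_linear=False,
                      dropout_rng=dropout_rng)
        fused = [z]
        if "sequence" in c.modalities:
            Hh = self.encode(herb_seq, herb_mask, "herb")
            Hs = self.encode(sym_seq, sym_mask, "sym")
            ctx_hs = self.attend(Hh, Hs).context    # herb queries over symptom keys
            ctx_sh = self.attend(Hs, Hh).context
            fused.append(self._masked_mean(ctx_hs, herb_mask))
            fused.append(self._masked_mean(ctx_sh, sym_mask))
        logit = self._mlp(ag.concat(fused, axis=-1), "cls",
                          len(c.cls_hidden) + 1, final_linear=True,
                          dropout_rng=dropout_rng)
        return ag.sigmoid(logit.reshape(-1))

    def parameter_vector(self) -> np.ndarray:
        return np.concatenate([self.params[k].data.ravel()
                               for k in sorted(self.params)])


# ---- functional surface ---------------------------------------------

def encode_targets(network: FusionNetwork, token_seq: np.ndarray,
                   mask: np.ndarray, which: str = "herb") -> EncoderState:
    """Encode one (L,) sequence; see :meth:`FusionNetwork.encode`."""
    return network.encode(token_seq[None, :], mask[None, :], which)


def cross_attend(network: FusionNetwork, query: EncoderState,
                 key: EncoderState) -> AttentionOutput:
    return network.attend(query, key)


def bce_loss(probs: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy -[y log p + (1-y) log(1-p)]."""
    y = np.asarray(labels, dtype=float)
    p = probs
    one = Tensor(np.ones_like(y))
    return -(Tensor(y) * (p + _EPS).log()
             + (one - Tensor(y)) * (one - p + _EPS).log()).mean()


def _standardize(prox: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    return (prox - mean) / std


def _batch_arrays(features: list[PairFeatures], model_mean, model_std):
    sem_h = np.stack([f.semantic_herb for f in features])
    sem_s = np.stack([f.semantic_symptom for f in features])
    prox = _standardize(np.array([f.proximity for f in features], dtype=float),
                        model_mean, model_std)
    h_seq = np.stack([f.herb_token_seq for f in features])
    h_mask = np.stack([f.herb_mask for f in features])
    s_seq = np.stack([f.symptom_token_seq for f in features])
    s_mask = np.stack([f.symptom_mask for f in features])
    return sem_h, sem_s, prox, h_seq, h_mask, s_seq, s_mask


def _rebuild(model: TrainedModel) -> FusionNetwork:
    net = FusionNetwork(model.config, model.n_genes, model.semantic_dim,
                        np.random.default_rng(0))
    for k, v in model.params.items():
        net.params[k].data = v.copy()
    return net


def forward(features: PairFeatures, model: TrainedModel) -> PairScore:
    """Deterministic single-pair prediction (evaluation mode)."""
    return predict(model, [features])[0]


def predict(model: TrainedModel, features_list: list[PairFeatures]) -> list[PairScore]:
    """Order-preserving batched prediction with dropout off."""
    if not features_list:
        return []
    for f in features_list:
        if f.config_digest and model.feature_digest and \
                f.config_digest != model.feature_digest:
            raise ValueError(
                "feature configuration digest does not match the model "
                f"({f.config_digest} != {model.feature_digest})")
    net = _rebuild(model)
    out: list[PairScore] = []
    B = model.config.batch_size
    for lo in range(0, len(features_list), B):
        chunk = features_list[lo:lo + B]
        arrays = _batch_arrays(chunk, model.prox_mean, model.prox_std)
        probs = net.forward_batch(*arrays, dropout_rng=None)
        out.extend(PairScore(f.herb, f.symptom, float(p))
                   for f, p in zip(chunk, probs.data))
    return out


class _Adam:
    def __init__(self, params: dict[str, Tensor], lr: float):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def train(dataset: list[tuple[PairFeatures, int]],
          config: ModelConfig) -> TrainedModel:
    """Fit the fusion network; early-stops on a held-out validation AUC.

    The validation split is a seeded stratified 10% of the training data.
    Raises on a single-class dataset and aborts on non-finite loss.
    """
    from .evaluation import roc_auc  # local import to avoid a cycle

    config.validate()
    labels = np.array([y for _, y in dataset], dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("training dataset must contain both classes")
    feats = [f for f, _ in dataset]
    n_genes = 1 + max(int(f.herb_token_seq.max(initial=-1)) for f in feats + feats)
    n_genes = max(n_genes, 1 + max(
        int(f.symptom_token_seq.max(initial=-1)) for f in feats))
    semantic_dim = feats[0].semantic_herb.shape[0]

    prox_raw = np.array([f.proximity for f in feats], dtype=float)
    prox_mean = prox_raw.mean(axis=0)
    prox_std = prox_raw.std(axis=0)
    prox_std[prox_std == 0] = 1.0

    rng = np.random.default_rng(config.seed)
    # stratified validation split
    val_idx: list[int] = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        n_val = max(1, int(round(config.val_fraction * len(idx))))
        val_idx.extend(idx[:n_val].tolist())
    val_mask = np.zeros(len(dataset), dtype=bool)
    val_mask[val_idx] = True
    train_idx = np.flatnonzero(~val_mask)
    val_idx = np.flatnonzero(val_mask)

    net = FusionNetwork(config, n_genes, semantic_dim, rng)
    opt = _Adam(net.params, config.lr)
    digest = feats[0].config_digest

    def batch_of(idx: np.ndarray):
        chunk = [feats[i] for i in idx]
        return _batch_arrays(chunk, prox_mean, prox_std), labels[idx]

    def val_auc() -> float:
        probs = []
        for lo in range(0, len(val_idx), config.batch_size):
            arrays, _ = batch_of(val_idx[lo:lo + config.batch_size])
            probs.extend(net.forward_batch(*arrays, dropout_rng=None).data)
        return roc_auc(np.array(probs), labels[val_idx])

    best_auc, best_params, best_epoch = -np.inf, None, -1
    stall = 0
    history = {"train_loss": [], "val_auc": []}
    for epoch in range(config.max_epochs):
        order = train_idx[rng.permutation(len(train_idx))]
        epoch_loss = 0.0
        for lo in range(0, len(order), config.batch_size):
            arrays, y = batch_of(order[lo:lo + config.batch_size])
            opt.zero_grad()
            probs = net.forward_batch(*arrays, dropout_rng=rng)
            loss = bce_loss(probs, y)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(y)
        epoch_loss /= len(order)
        auc = val_auc()
        history["train_loss"].append(epoch_loss)
        history["val_auc"].append(auc)
        if auc > best_auc:
            best_auc, best_epoch, stall = auc, epoch, 0
            best_params = {k: p.data.copy() for k, p in net.params.items()}
        else:
            stall += 1
            if stall >= config.patience:
                break

    assert best_params is not None
    history["best_epoch"] = best_epoch
    history["best_val_auc"] = float(best_auc)
    return TrainedModel(
        params=best_params, config=copy.deepcopy(config), n_genes=n_genes,
        semantic_dim=semantic_dim, prox_mean=prox_mean, prox_std=prox_std,
        feature_digest=digest, history=history)


# ---- checkpoint I/O -------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write <path>.json (metadata) and <path>.bin (raw float64 blob)."""
    path = Path(path)
    keys = sorted(model.params)
    meta = {
        "config": {**model.config.__dict__,
                   "proc_hidden": list(model.config.proc_hidden),
                   "cls_hidden": list(model.config.cls_hidden),
                   "modalities": list(model.config.modalities)},
        "n_genes": model.n_genes,
        "semantic_dim": model.semantic_dim,
        "prox_mean": model.prox_mean.tolist(),
        "prox_std": model.prox_std.tolist(),
        "feature_digest": model.feature_digest,
        "param_shapes": {k: list(model.params[k].shape) for k in keys},
    }
    path.with_suffix(".json").write_text(
        json.dumps(meta, indent=1, sort_keys=True), encoding="utf-8")
    blob = np.concatenate([model.params[k].ravel() for k in keys])
    path.with_suffix(".bin").write_bytes(blob.astype("<f8").tobytes())


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
    cfg_d = dict(meta["config"])
    cfg_d["proc_hidden"] = tuple(cfg_d["proc_hidden"])
    cfg_d["cls_hidden"] = tuple(cfg_d["cls_hidden"])
    cfg_d["modalities"] = tuple(cfg_d["modalities"])
    config = ModelConfig(**cfg_d)
    blob = np.frombuffer(path.with_suffix(".bin").read_bytes(), dtype="<f8")
    params: dict[str, np.ndarray] = {}
    off = 0
    for k in sorted(meta["param_shapes"]):
        shape = tuple(meta["param_shapes"][k])
        size = int(np.prod(shape))
        params[k] = blob[off:off + size].reshape(shape).copy()
        off += size
    return TrainedModel(
        params=params, config=config, n_genes=meta["n_genes"],
        semantic_dim=meta["semantic_dim"],
        prox_mean=np.array(meta["prox_mean"]),
        prox_std=np.array(meta["prox_std"]),
        feature_digest=meta["feature_digest"])
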