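"""The confidence-conditioned ROI adjudication network.

A convolutional backbone maps a cropped ROI patch to an embedding, which is
L2-normalized and concatenated with the detector confidence ``s``; a
two-layer perceptron head with ReLU and a sigmoid output produces the
adjudicator probability

    y_hat = sigmoid(W2 relu(W1 [psi; s] + b1) + b2),   psi = f(patch)/||f(patch)||.

Training minimizes focal loss (cross-entropy with a ``(1-p)**gamma``
modulating factor that down-weights easy examples) by mini-batch Adam,
with early stopping on validation F1 and an optional per-epoch
hard-negative-mining hook that may enlarge the training pool.

The backbone is a 4-block strided CNN sized for 64 x 64 patches.  The
contract is backbone-agnostic: anything exposing the same block/embedding
interface can stand behind ``AdjudicatorModel``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import nn
from .metrics import f1_score
from .roidata import AugmentConfig, RoiRecord, assert_patient_disjoint, augment

EMBED_EPS = 1e-12
FOCAL_EPS = 1e-7


class AdjudicatorModel:
    """Backbone f(.) + L2 normalization + confidence-conditioned MLP head.

    ``channels`` defines the strided conv blocks (stride 2 each, 3x3
    kernels, ReLU); the embedding dimension equals the last channel count
    and the head input dimension is that plus one (for ``s``).
    """

    def __init__(
        self,
        patch_size: int = 64,
        in_channels: int = 1,
        channels: Sequence[int] = (8, 16, 32, 32),
        hidden: int = 64,
        seed: int = 0,
        dtype=np.float64,
    ):
        rng = np.random.default_rng(seed)
        self.patch_size = patch_size
        self.in_channels = in_channels
        self.channels = tuple(channels)
        self.hidden = hidden
        self.seed = seed
        self.dtype = np.dtype(dtype)
        self.convs: list[nn.Conv2d] = []
        self.relus: list[nn.ReLU] = []
        c_in = in_channels
        for c_out in channels:
            self.convs.append(nn.Conv2d(c_in, c_out, k=3, stride=2, rng=rng, dtype=dtype))
            self.relus.append(nn.ReLU())
            c_in = c_out
        self.gap = nn.GlobalAvgPool()
        self.embed_dim = c_in
        self.fc1 = nn.Dense(self.embed_dim + 1, hidden, rng=rng, dtype=dtype)
        self.head_relu = nn.ReLU()
        self.fc2 = nn.Dense(hidden, 1, rng=rng, dtype=dtype)
        self._cache: dict = {}

    # -- parameter plumbing -------------------------------------------------
    @property
    def params(self):
        out = []
        for layer in (*self.convs, self.fc1, self.fc2):
            out.extend(layer.params)
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for (p, _), w in zip(self.params, weights):
            p[...] = w

    # -- forward / backward -------------------------------------------------
    def backbone_forward(self, x: np.ndarray) -> list[np.ndarray]:
        """Post-ReLU activations of every block for a NCHW batch."""
        acts = []
        h = x
        for conv, relu in zip(self.convs, self.relus):
            h = relu.forward(conv.forward(h))
            acts.append(h)
        return acts

    def forward(self, patches: np.ndarray, s: np.ndarray) -> np.ndarray:
        """Adjudicator probabilities for a batch.

        ``patches``: (N, H, W) or (N, C, H, W); ``s``: (N,) confidences.
        """
        x = np.asarray(patches, dtype=self.dtype)
        if x.ndim == 3:
            x = x[:, None]
        s = np.asarray(s, dtype=self.dtype).reshape(-1)
        acts = self.backbone_forward(x)
        v = self.gap.forward(acts[-1])
        psi = nn.l2_normalize(v, EMBED_EPS)
        z = np.concatenate([psi, s[:, None]], axis=1)
        h1 = self.head_relu.forward(self.fc1.forward(z))
        logit = self.fc2.forward(h1).reshape(-1)
        self._cache = {"acts": acts, "v": v, "psi": psi}
        return nn.sigmoid(logit)

    def backward(
        self, dlogit: np.ndarray, collect_activation_grads: bool = False
    ) -> Optional[list[np.ndarray]]:
        """Backpropagate d(loss)/d(logit); accumulates parameter gradients.

        With ``collect_activation_grads`` the gradients with respect to each
        block's post-ReLU activation are returned (index-aligned with
        :meth:`backbone_forward`) — the quantity Grad-CAM needs.
        """
        dh1 = self.fc2.backward(dlogit.reshape(-1, 1))
        dz = self.fc1.backward(self.head_relu.backward(dh1))
        dpsi = dz[:, : self.embed_dim]
        dv = nn.l2_normalize_backward(self._cache["v"], self._cache["psi"], dpsi)
        dx = self.gap.backward(dv)
        block_grads: list[np.ndarray] = [None] * len(self.convs)
        for k in range(len(self.convs) - 1, -1, -1):
            if collect_activation_grads:
                block_grads[k] = dx
            dx = self.convs[k].backward(self.relus[k].backward(dx))
        return block_grads if collect_activation_grads else None

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0


# ---------------------------------------------------------------------------
# single-record operations


def embed(model: AdjudicatorModel, patch: np.ndarray) -> np.ndarray:
    """Unit-norm embedding psi = f(patch)/||f(patch)||_2 of one patch."""
    x = np.asarray(patch, dtype=model.dtype)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[None]
    acts = model.backbone_forward(x)
    v = model.gap.forward(acts[-1])
    return nn.l2_normalize(v, EMBED_EPS)[0]


def adjudicate(model: AdjudicatorModel, patch: np.ndarray, s: float) -> float:
    """Adjudicator probability for one (patch, confidence) pair."""
    if not 0.0 <= s <= 1.0:
        raise ValueError("detector confidence s must lie in [0, 1]")
    x = np.asarray(patch, dtype=float)
    if x.ndim == 2:
        x = x[None]
    return float(model.forward(x, np.array([s]))[0])


# ---------------------------------------------------------------------------
# focal loss


def focal_loss(y_hat: np.ndarray, y: np.ndarray, gamma: float) -> float:
    """Mean focal loss; reduces to binary cross-entropy at gamma = 0.

    Probabilities at exactly 0 or 1 are clamped to [eps, 1-eps] with
    eps = 1e-7 before the logarithm.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    p = np.clip(np.asarray(y_hat, dtype=float), FOCAL_EPS, 1.0 - FOCAL_EPS)
    y = np.asarray(y, dtype=float)
    per = -(
        (1.0 - p) ** gamma * y * np.log(p)
        + p**gamma * (1.0 - y) * np.log(1.0 - p)
    )
    return float(per.mean())


def focal_loss_grad_logit(y_hat: np.ndarray, y: np.ndarray, gamma: float) -> np.ndarray:
    """d(mean focal loss)/d(logit) for a batch (sigmoid output)."""
    p = np.clip(np.asarray(y_hat, dtype=float), FOCAL_EPS, 1.0 - FOCAL_EPS)
    y = np.asarray(y, dtype=float)
    logp = np.log(p)
    log1p = np.log(1.0 - p)
    dldp = y * (gamma * (1.0 - p) ** (gamma - 1.0) * logp - (1.0 - p) ** gamma / p) + (
        1.0 - y
    ) * (p**gamma / (1.0 - p) - gamma * p ** (gamma - 1.0) * log1p)
    return dldp * p * (1.0 - p) / p.shape[0]


# ---------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.  Defaults follow the reference configuration
    (Adam, lr 1e-4, batch 32, 50 epochs, focal gamma 2, early stopping on
    validation F1); desk-scale profiles override epochs and learning rate."""

    max_epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    gamma: float = 2.0
    patience: int = 10
    seed: int = 0
    augment_config: Optional[AugmentConfig] = None

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class TrainHistory:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_f1: list[float] = field(default_factory=list)
    n_pos: list[int] = field(default_factory=list)
    n_neg0: list[int] = field(default_factory=list)
    n_hard: list[int] = field(default_factory=list)
    selected_epoch: int = -1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": self.epochs,
                "train_loss": self.train_loss,
                "val_f1": self.val_f1,
                "n_pos": self.n_pos,
                "n_neg0": self.n_neg0,
                "n_hard": self.n_hard,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def predict_proba(
    model: AdjudicatorModel,
    records: Sequence[RoiRecord],
    batch_size: int = 256,
) -> np.ndarray:
    """Adjudicator probabilities for a list of ROI records."""
    out = np.empty(len(records))
    for i in range(0, len(records), batch_size):
        chunk = records[i : i + batch_size]
        x = np.stack([r.patch for r in chunk])
        s = np.array([r.s for r in chunk])
        out[i : i + len(chunk)] = model.forward(x, s)
    return out


def _as_pool(train_records):
    from .mining import MiningPool  # local import avoids a cycle

    if isinstance(train_records, MiningPool):
        return train_records
    return MiningPool.from_records(list(train_records))


def train(
    model: AdjudicatorModel,
    train_records,
    val_records: Sequence[RoiRecord],
    config: TrainConfig,
    mining_hook: Optional[Callable] = None,
) -> tuple[AdjudicatorModel, TrainHistory]:
    """Fit the adjudicator by mini-batch focal-loss descent.

    ``train_records`` may be a plain record list or a
    :class:`roiadj.mining.MiningPool`.  After each epoch ``mining_hook
    (model, epoch, pool)`` may enlarge the pool (hard-negative mining);
    validation F1 (threshold 0.5 on y_hat) drives early stopping, and the
    parameters of the best-validation-F1 epoch are restored on return.
    """
    pool = _as_pool(train_records)
    if not pool.records():
        raise ValueError("empty training set")
    if not val_records:
        raise ValueError("empty validation set")
    assert_patient_disjoint(pool.all_known_records(), list(val_records))

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.params, lr=config.learning_rate)
    history = TrainHistory()
    y_val = np.array([r.y for r in val_records])
    best_f1, best_weights, best_epoch, stale = -1.0, model.get_weights(), 0, 0

    for epoch in range(config.max_epochs):
        records = pool.records()
        idx = rng.permutation(len(records))
        losses = []
        for start in range(0, len(idx), config.batch_size):
            batch = [records[i] for i in idx[start : start + config.batch_size]]
            if config.augment_config is not None:
                seeds = rng.integers(0, 2**31 - 1, size=len(batch))
                x = np.stack(
                    [
                        augment(r.patch, config.augment_config, int(sd))
                        for r, sd in zip(batch, seeds)
                    ]
                )
            else:
                x = np.stack([r.patch for r in batch])
            s = np.array([r.s for r in batch])
            y = np.array([r.y for r in batch])
            p = model.forward(x, s)
            loss = focal_loss(p, y, config.gamma)
            if not np.isfinite(loss):
                raise FloatingPointError("training diverged: non-finite loss")
            losses.append(loss)
            model.zero_grad()
            model.backward(focal_loss_grad_logit(p, y, config.gamma))
            opt.step()

        p_val = predict_proba(model, val_records)
        f1 = f1_score(y_val, p_val >= 0.5)
        sizes = pool.sizes()
        history.epochs.append(epoch)
        history.train_loss.append(float(np.mean(losses)))
        history.val_f1.append(float(f1))
        history.n_pos.append(sizes[0])
        history.n_neg0.append(sizes[1])
        history.n_hard.append(sizes[2])

        if f1 > best_f1:
            best_f1, best_weights, best_epoch, stale = f1, model.get_weights(), epoch, 0
        else:
            stale += 1
            if stale >= config.patience:
                break

        if mining_hook is not None:
            updated = mining_hook(model, epoch, pool)
            if updated is not None:
                pool = updated

    model.set_weights(best_weights)
    history.selected_epoch = best_epoch
    return model, history


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(
    model: AdjudicatorModel, path, metadata: Optional[dict] = None
) -> None:
    """Weights + architecture + metadata (config/seed/pool state) as .npz."""
    meta = {
        "patch_size": model.patch_size,
        "in_channels": model.in_channels,
        "channels": list(model.channels),
        "hidden": model.hidden,
        "seed": model.seed,
        "dtype": model.dtype.name,
        "extra": metadata or {},
    }
    arrays = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> tuple[AdjudicatorModel, dict]:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    model = AdjudicatorModel(
        patch_size=meta["patch_size"],
        in_channels=meta["in_channels"],
        channels=meta["channels"],
        hidden=meta["hidden"],
        seed=meta["seed"],
        dtype=np.dtype(meta.get("dtype", "float64")),
    )
    n = len(model.get_weights())
    model.set_weights([data[f"w{i}"] for i in range(n)])
    return model, meta["extra"]
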