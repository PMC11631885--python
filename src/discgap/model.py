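"""Large-kernel 1D-CNN labeling each profile position as
no-disc-space / normal / narrowed, with its combined cross-entropy +
focal loss, a deterministic Adam training loop, and per-gap decision
post-processing.

The network sees the bare 0/1 profile as a single input channel.  A stem
convolution lifts it to 64 channels; five residual blocks (conv k=151 ->
batch norm -> ReLU, identity skip) follow; a width-1 convolution maps to
3 logits per position and a softmax yields per-position class
probabilities.  With six k=151 convolutions the receptive field of one
output position spans 1 + 6*(151-1) = 901 input positions, so each gap
is judged relative to its neighbours.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .nn import Adam, BatchNorm1d, Conv1d, ConvMethod, ReLU, softmax
from .phantom import CLASS_NARROWED, CLASS_NORMAL
from .quantify import VECTOR_LEN, GapRecord


@dataclass(frozen=True)
class ModelConfig:
    kernel_size: int = 151
    channels: int = 64
    stride: int = 1
    n_intermediate_layers: int = 5
    n_classes: int = 3
    input_length: int = VECTOR_LEN

    def __post_init__(self) -> None:
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd (length-preserving padding)")
        if self.stride != 1:
            raise ValueError("stride must be 1 to retain dimensionality")


@dataclass(frozen=True)
class LossConfig:
    alpha: float = 0.25
    gamma: float = 2.0
    n_classes: int = 3
    clip_eps: float = 1e-7

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-5
    epochs: int = 50
    batch_size: int = 16
    seed: int = 0
    validation_fraction: float = 0.2
    patience: int = 10

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")


@dataclass(frozen=True)
class PositionLabels:
    """Per-position 3-class labeling of one length-1024 profile."""

    values: np.ndarray  # (1024,) in {0, 1, 2}
    probs: np.ndarray | None = None  # (1024, 3), rows sum to 1

    def __post_init__(self) -> None:
        if self.values.shape != (VECTOR_LEN,):
            raise ValueError(f"values must have shape ({VECTOR_LEN},)")


class NarrowingNet:
    """Stem conv -> 5 residual (conv->BN->ReLU) blocks -> 1x1 head."""

    def __init__(
        self,
        config: ModelConfig,
        rng: np.random.Generator,
        method: ConvMethod = "fft",
        dtype: np.dtype = np.float32,
    ) -> None:
        self.config = config
        self.dtype = np.dtype(dtype)
        c = config.channels
        k = config.kernel_size
        self.stem = Conv1d(1, c, k, rng, method, dtype)
        self.stem_bn = BatchNorm1d(c, dtype=dtype)
        self.stem_relu = ReLU()
        self.blocks: list[tuple[Conv1d, BatchNorm1d, ReLU]] = [
            (Conv1d(c, c, k, rng, method, dtype), BatchNorm1d(c, dtype=dtype), ReLU())
            for _ in range(config.n_intermediate_layers)
        ]
        self.head = Conv1d(c, config.n_classes, 1, rng, method, dtype)

    @property
    def layers(self) -> list:
        out = [self.stem, self.stem_bn]
        for conv, bn, _ in self.blocks:
            out.extend([conv, bn])
        out.append(self.head)
        return out

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits of shape (batch, n_classes, length) for (batch, 1, length) input."""
        h = self.stem_relu.forward(self.stem_bn.forward(self.stem.forward(x), training))
        self._res_inputs = []
        for conv, bn, relu in self.blocks:
            self._res_inputs.append(h)
            h = h + relu.forward(bn.forward(conv.forward(h), training))
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dh = self.head.backward(dlogits)
        for conv, bn, relu in reversed(self.blocks):
            dbranch = conv.backward(bn.backward(relu.backward(dh)))
            dh = dh + dbranch
        dx = self.stem.backward(self.stem_bn.backward(self.stem_relu.backward(dh)))
        return dx

    def predict_proba(self, vectors: np.ndarray) -> np.ndarray:
        """(batch, length, n_classes) probabilities in evaluation mode."""
        x = np.asarray(vectors, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        logits = self.forward(x[:, None, :], training=False)
        return np.moveaxis(softmax(logits, axis=1), 1, 2)

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                state[f"layer{i}_p{j}"] = p.copy()
            if isinstance(layer, BatchNorm1d):
                state[f"layer{i}_rmean"] = layer.running_mean.copy()
                state[f"layer{i}_rvar"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                p[...] = state[f"layer{i}_p{j}"]
            if isinstance(layer, BatchNorm1d):
                layer.running_mean[...] = state[f"layer{i}_rmean"]
                layer.running_var[...] = state[f"layer{i}_rvar"]


def build_model(
    config: ModelConfig,
    seed: int = 0,
    method: ConvMethod = "fft",
    dtype: np.dtype = np.float32,
) -> NarrowingNet:
    """Freshly initialized network; identical seed gives identical weights."""
    return NarrowingNet(config, np.random.default_rng(seed), method=method, dtype=dtype)


def _clip(p: np.ndarray, eps: float) -> np.ndarray:
    return np.clip(p, eps, 1.0 - eps)


def combined_loss(
    y_true: np.ndarray, y_pred: np.ndarray, cfg: LossConfig | None = None
) -> float:
    """Combined cross-entropy + focal loss, averaged over positions.

    Per position and class, ``L_cc = -y_true_c * log(y_pred_c)``; the
    combined term is ``sum_c [alpha_c * (1 - y_pred_c)**gamma * L_cc + L_cc]``.
    The batch value is the mean over all positions and items.
    ``y_true`` is one-hot over the trailing axis; ``y_pred`` holds valid
    probability triples (clipped before the logarithm).
    """
    if cfg is None:
        cfg = LossConfig()
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape:
        raise ValueError(f"shape mismatch: {yt.shape} vs {yp.shape}")
    p = _clip(yp, cfg.clip_eps)
    lcc = -yt * np.log(p)
    combined = cfg.alpha * (1.0 - p) ** cfg.gamma * lcc + lcc
    per_position = combined.sum(axis=-1)
    return float(per_position.mean())


def _loss_and_dlogits(
    logits: np.ndarray, labels: np.ndarray, cfg: LossConfig, grad: bool = True
) -> tuple[float, np.ndarray | None]:
    """Mean combined loss and its gradient w.r.t. logits.

    ``logits``: (B, C, L); ``labels``: (B, L) integer classes.
    """
    B, C, L = logits.shape
    p = softmax(logits, axis=1)
    pc = _clip(p, cfg.clip_eps)
    onehot = np.zeros_like(p)
    idx_b, idx_l = np.meshgrid(np.arange(B), np.arange(L), indexing="ij")
    onehot[idx_b, labels, idx_l] = 1.0
    lcc = -onehot * np.log(pc)
    combined = cfg.alpha * (1.0 - pc) ** cfg.gamma * lcc + lcc
    loss = float(combined.sum(axis=1).mean())
    if not grad:
        return loss, None
    # dL/dp, nonzero only at the true class (chain rule through the clip is
    # dropped outside [eps, 1-eps], where the loss is flat by construction)
    focal = cfg.alpha * (1.0 - pc) ** cfg.gamma
    dldp = onehot * (
        -(1.0 + focal) / pc
        + cfg.alpha * cfg.gamma * (1.0 - pc) ** (cfg.gamma - 1.0) * np.log(pc)
    )
    inside = (p > cfg.clip_eps) & (p < 1.0 - cfg.clip_eps)
    dldp = np.where(inside, dldp, 0.0)
    # softmax backward: dL/dz_j = p_j * (dldp_j - sum_c dldp_c * p_c)
    dot = (dldp * p).sum(axis=1, keepdims=True)
    dlogits = p * (dldp - dot) / (B * L)
    return loss, dlogits


@dataclass
class TrainResult:
    model: NarrowingNet
    history: list[dict[str, float]]
    best_epoch: int
    best_val_loss: float


def train(
    vectors: Sequence[np.ndarray],
    labels: Sequence[np.ndarray],
    mcfg: ModelConfig | None = None,
    tcfg: TrainConfig | None = None,
    lcfg: LossConfig | None = None,
) -> TrainResult:
    """Train the narrowing detector on (profile, per-position label) pairs.

    The dataset is split by image into train/validation (default 80:20,
    random but seeded); per-epoch train and validation losses are
    recorded and the parameters of the best-validation-loss epoch are
    restored at the end.  Training stops early when the validation loss
    has not improved for ``patience`` epochs.  Fixed seed reproduces the
    loss history exactly.
    """
    if mcfg is None:
        mcfg = ModelConfig()
    if tcfg is None:
        tcfg = TrainConfig()
    if lcfg is None:
        lcfg = LossConfig(n_classes=mcfg.n_classes)
    n = len(vectors)
    if n < 1:
        raise ValueError("empty dataset")
    X = np.stack([np.asarray(v, dtype=float) for v in vectors])
    Y = np.stack([np.asarray(l, dtype=np.int64) for l in labels])
    if X.shape[1] != mcfg.input_length or Y.shape != X.shape:
        raise ValueError("vectors/labels must all have the configured input length")

    rng = np.random.default_rng(tcfg.seed)
    perm = rng.permutation(n)
    n_val = int(round(tcfg.validation_fraction * n)) if n > 1 else 0
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0:
        tr_idx, val_idx = perm, perm[:0]

    model = NarrowingNet(mcfg, rng)
    opt = Adam(model.params, model.grads, lr=tcfg.learning_rate)

    def eval_loss(idx: np.ndarray) -> float:
        total, count = 0.0, 0
        for s in range(0, idx.size, tcfg.batch_size):
            b = idx[s : s + tcfg.batch_size]
            logits = model.forward(X[b][:, None, :], training=False)
            loss, _ = _loss_and_dlogits(logits, Y[b], lcfg, grad=False)
            total += loss * b.size
            count += b.size
        return total / max(count, 1)

    history: list[dict[str, float]] = []
    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = 0
    stale = 0
    for epoch in range(1, tcfg.epochs + 1):
        order = rng.permutation(tr_idx)
        total, count = 0.0, 0
        for s in range(0, order.size, tcfg.batch_size):
            b = order[s : s + tcfg.batch_size]
            logits = model.forward(X[b][:, None, :], training=True)
            loss, dlogits = _loss_and_dlogits(logits, Y[b], lcfg)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} (batch start {s})"
                )
            model.backward(dlogits)
            opt.step()
            total += loss * b.size
            count += b.size
        train_loss = total / max(count, 1)
        val_loss = eval_loss(val_idx) if val_idx.size else train_loss
        history.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss}
        )
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= tcfg.patience:
                break
    model.load_state_dict(best_state)
    return TrainResult(
        model=model, history=history, best_epoch=best_epoch, best_val_loss=float(best_val)
    )


def classify_vector(model: NarrowingNet, vector: np.ndarray) -> PositionLabels:
    """Per-position argmax labels; ties break toward the lower class index."""
    v = np.asarray(vector, dtype=float)
    if v.shape != (model.config.input_length,):
        raise ValueError(f"vector must have length {model.config.input_length}")
    probs = model.predict_proba(v)[0]
    values = np.argmax(probs, axis=1).astype(np.int64)  # first max = lowest index
    return PositionLabels(values=values, probs=probs)


def detect_narrowed(
    labels: PositionLabels, gaps: Iterable[GapRecord]
) -> list[GapRecord]:
    """Per-gap decision: majority vote of normal/narrowed position labels.

    Votes of the no-disc-space class are ignored; an exact tie counts as
    narrowed (conservative for screening); a gap whose rows carry no
    normal/narrowed votes at all stays unassigned.
    """
    out: list[GapRecord] = []
    for gap in gaps:
        rows = labels.values[gap.start_row : gap.end_row]
        n_normal = int(np.sum(rows == CLASS_NORMAL))
        n_narrow = int(np.sum(rows == CLASS_NARROWED))
        if n_normal == 0 and n_narrow == 0:
            label = "unassigned"
        elif n_narrow >= n_normal:
            label = "narrowed"
        else:
            label = "normal"
        out.append(replace(gap, label=label))
    return out


def save_checkpoint(path, model: NarrowingNet) -> None:
    """NPZ checkpoint with the ModelConfig embedded as JSON."""
    state = model.state_dict()
    np.savez(
        path,
        __config__=np.frombuffer(
            json.dumps(asdict(model.config)).encode(), dtype=np.uint8
        ),
        **state,
    )


def load_checkpoint(path, expected: ModelConfig | None = None) -> NarrowingNet:
    """Restore a checkpoint; a mismatching expected config is a hard error."""
    with np.load(path) as data:
        cfg = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
        if expected is not None and cfg != expected:
            raise ValueError(
                f"checkpoint ModelConfig {cfg} does not match expected {expected}"
            )
        model = build_model(cfg, seed=0)
        state = {k: data[k] for k in data.files if k != "__config__"}
    model.load_state_dict(state)
    return model
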