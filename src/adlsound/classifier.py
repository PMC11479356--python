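"""Small residual CNN over 48x32 log-Mel inputs.

The deployment target is a microcontroller, so the model is deliberately
tiny: a 3x3 stem (8 channels), three residual stages of widths 8/16/32
(one identity block each, stride-2 at stage entry), global average pooling
and a softmax head — a few tens of thousands of parameters. Training uses
Adam with early stopping on validation loss. Quantized inference emulates
the deployed 8-bit path: batch norms folded into convolutions, per-tensor
symmetric int8 weights, per-tensor affine int8 activations calibrated on a
held-out min/max sweep.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import features as F
from .nn import ResidualCNN, Adam, _im2col, softmax, cross_entropy


@dataclass
class ModelConfig:
    n_classes: int = 12
    widths: tuple[int, ...] = (8, 16, 32)
    stem_channels: int = 8
    lr: float = 1e-3
    epochs: int = 30
    batch_size: int = 64
    val_fraction: float = 0.1
    patience: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


def build_model(config: ModelConfig) -> ResidualCNN:
    return ResidualCNN(
        n_classes=config.n_classes,
        widths=config.widths,
        stem_channels=config.stem_channels,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# metrics (computed from the confusion matrix)
# ---------------------------------------------------------------------------


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (np.asarray(y_true), np.asarray(y_pred)), 1)
    return cm


def metrics_from_confusion(cm: np.ndarray) -> dict:
    total = cm.sum()
    diag = np.diag(cm).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(cm.sum(0) > 0, diag / cm.sum(0), 0.0)
        recall = np.where(cm.sum(1) > 0, diag / cm.sum(1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    return {
        "accuracy": float(diag.sum() / total) if total else 0.0,
        "macro_f1": float(f1.mean()),
        "per_class_f1": f1,
    }


def evaluate(model, X: np.ndarray, y: np.ndarray) -> dict:
    """Accuracy, cross-entropy loss, macro F1 and confusion matrix on a test set."""
    if len(X) == 0:
        raise ValueError("test set is empty")
    probs = model.predict_proba(X)
    cm = confusion_matrix(y, probs.argmax(axis=1), probs.shape[1])
    out = metrics_from_confusion(cm)
    out["loss"] = cross_entropy(probs, np.asarray(y))
    out["confusion"] = cm
    return out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train(
    model: ResidualCNN,
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    verbose: bool = False,
) -> dict:
    """Train with Adam + early stopping; returns the per-epoch history.

    If no validation split is supplied, a stratified ``val_fraction`` slice
    is held out (augmented rows should be confined to the training side by
    the caller — see ``dataset.split_pool``).
    """
    y = np.asarray(y)
    present = np.unique(y)
    if len(present) < model.n_classes:
        missing = sorted(set(range(model.n_classes)) - set(present.tolist()))
        raise ValueError(f"classes absent from training data: {missing}")
    rng = np.random.default_rng(config.seed)
    if X_val is None:
        tr_idx, va_idx = _stratified_split(y, config.val_fraction, rng)
        X, X_val, y, y_val = X[tr_idx], X[va_idx], y[tr_idx], y[va_idx]

    opt = Adam(model, lr=config.lr)
    history: dict[str, list] = {k: [] for k in ("train_loss", "train_acc", "val_loss", "val_acc", "val_macro_f1")}
    best_loss, best_state, since_best = np.inf, None, 0
    n = len(X)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for a in range(0, n, config.batch_size):
            idx = order[a : a + config.batch_size]
            xb, yb = X[idx], y[idx]
            probs = softmax(model.forward(xb, train=True))
            ep_loss += cross_entropy(probs, yb) * len(idx)
            ep_correct += int((probs.argmax(1) == yb).sum())
            d = probs
            d[np.arange(len(yb)), yb] -= 1.0
            model.backward((d / len(yb)).astype(np.float32))
            opt.step()
        val = evaluate(model, X_val, y_val)
        history["train_loss"].append(ep_loss / n)
        history["train_acc"].append(ep_correct / n)
        history["val_loss"].append(val["loss"])
        history["val_acc"].append(val["accuracy"])
        history["val_macro_f1"].append(val["macro_f1"])
        if verbose:
            print(
                f"epoch {epoch + 1}/{config.epochs} "
                f"train_loss={ep_loss / n:.4f} val_loss={val['loss']:.4f} val_acc={val['accuracy']:.3f}",
                flush=True,
            )
        if val["loss"] < best_loss - 1e-5:
            best_loss, best_state, since_best = val["loss"], model.get_weights(), 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_state is not None:
        model.set_weights(best_state)
    return history


def _stratified_split(y: np.ndarray, fraction: float, rng: np.random.Generator):
    tr, va = [], []
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        k = max(1, int(round(len(idx) * fraction)))
        va.append(idx[:k])
        tr.append(idx[k:])
    return np.concatenate(tr), np.concatenate(va)


# ---------------------------------------------------------------------------
# emulated int8 inference
# ---------------------------------------------------------------------------


def _quantize_weight(w: np.ndarray) -> tuple[np.ndarray, float]:
    scale = max(float(np.abs(w).max()) / 127.0, 1e-12)
    return np.clip(np.round(w / scale), -127, 127).astype(np.int8), scale


def _fake_quant(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    scale = (hi - lo) / 255.0
    if scale <= 0:
        return x
    zp = np.clip(round(-128 - lo / scale), -128, 127)
    q = np.clip(np.round(x / scale) + zp, -128, 127)
    return ((q - zp) * scale).astype(np.float32)


@dataclass
class _QConv:
    wq: np.ndarray  # int8 (cout, cin*k*k)
    w_scale: float
    bias: np.ndarray
    k: int
    stride: int

    def __call__(self, x: np.ndarray) -> np.ndarray:
        w = self.wq.astype(np.float32) * self.w_scale
        cols, (b, _, _, _, ho, wo) = _im2col(x, self.k, self.stride, self.k // 2)
        y = cols @ w.T + self.bias
        return y.reshape(b, ho, wo, -1).transpose(0, 3, 1, 2)


class QuantizedModel:
    """8-bit inference twin of a trained :class:`~adlsound.nn.ResidualCNN`.

    Weights are folded (conv+BN) and stored as per-tensor symmetric int8;
    activations pass through an affine int8 quantize/dequantize at every
    stage boundary, with ranges calibrated on a representative feature set.
    Inputs may be float features or :class:`~adlsound.features.QuantizedFeature`.
    """

    def __init__(self, model: ResidualCNN, calibration: np.ndarray):
        calibration = np.asarray(calibration, dtype=np.float32)
        if len(calibration) == 0:
            raise ValueError("calibration set must be nonempty")
        self.n_classes = model.n_classes
        self._stem = _fold_quant(model.stem)
        self._blocks = []
        for blk in model.blocks:
            self._blocks.append(
                (
                    _fold_quant(blk.main1),
                    _fold_quant(blk.main2),
                    _fold_quant(blk.proj) if blk.proj is not None else None,
                )
            )
        wq, ws = _quantize_weight(model.head.weight)
        self._head = (wq, ws, model.head.bias.copy())
        self.weight_scales = [self._stem.w_scale] + [c.w_scale for trio in self._blocks for c in trio if c] + [ws]
        self._ranges = self._calibrate(calibration)
        self.input_scale, self.input_zero_point = F.calibrate_quantization([calibration])

    def _stages(self, x: np.ndarray, record: list | None):
        def tap(i: int, h: np.ndarray) -> np.ndarray:
            if record is not None:
                record[i] = (min(record[i][0], float(h.min())), max(record[i][1], float(h.max())))
                return h
            return _fake_quant(h, *self._ranges[i])

        h = tap(0, np.maximum(self._stem(x), 0.0))
        i = 1
        for main1, main2, proj in self._blocks:
            h1 = tap(i, np.maximum(main1(h), 0.0))
            short = proj(h) if proj is not None else h
            h = tap(i + 1, np.maximum(main2(h1) + short, 0.0))
            i += 2
        pooled = tap(i, h.mean(axis=(2, 3)))
        wq, ws, bias = self._head
        return pooled @ (wq.astype(np.float32) * ws) + bias

    def _calibrate(self, calibration: np.ndarray) -> list[tuple[float, float]]:
        n_taps = 1 + 2 * len(self._blocks) + 1
        record = [(np.inf, -np.inf)] * n_taps
        for a in range(0, len(calibration), 256):
            xb = calibration[a : a + 256]
            self._ranges = None
            self._stages(xb[:, None, :, :], record)
        return record

    def predict_proba(self, X, batch_size: int = 256) -> np.ndarray:
        if isinstance(X, F.QuantizedFeature):
            X = F.dequantize(X)[None]
        elif isinstance(X, (list, tuple)) and X and isinstance(X[0], F.QuantizedFeature):
            X = np.stack([F.dequantize(q) for q in X])
        X = np.asarray(X, dtype=np.float32)
        # input consumed through the int8 feature representation
        X = _fake_quant(
            X,
            -(self.input_zero_point + 128) * self.input_scale,
            (127 - self.input_zero_point) * self.input_scale,
        )
        out = []
        for a in range(0, len(X), batch_size):
            logits = self._stages(X[a : a + batch_size, None, :, :], None)
            out.append(softmax(logits))
        return np.concatenate(out, axis=0)


def _fold_quant(convbn) -> _QConv:
    w, b = convbn.folded_weight()
    wq, ws = _quantize_weight(w)
    return _QConv(wq, ws, b.astype(np.float32), convbn.conv.k, convbn.conv.stride)


def quantize_model(model: ResidualCNN, calibration: np.ndarray) -> QuantizedModel:
    """Emulated int8 deployment path for a trained model."""
    return QuantizedModel(model, calibration)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_model(model: ResidualCNN, config: ModelConfig, path: str) -> None:
    weights = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    np.savez(path, _config=np.frombuffer(json.dumps(asdict(config)).encode(), dtype=np.uint8), **weights)


def load_model(path: str) -> tuple[ResidualCNN, ModelConfig]:
    z = np.load(path)
    cfg_dict = json.loads(bytes(z["_config"]).decode())
    cfg_dict["widths"] = tuple(cfg_dict["widths"])
    config = ModelConfig(**cfg_dict)
    model = build_model(config)
    model.set_weights([z[f"w{i}"] for i in range(len(z.files) - 1)])
    return model, config
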