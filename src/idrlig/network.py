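"""Encoder/decoder/predictor network and its stepwise transfer-learning harness.

The model maps a 20 x 20 x 20 pair-separation tensor to

* a 20-dimensional encoding vector (sequence classification space),
* a decoded 20 x 20 x 20 tensor fd representing interaction sites, and
* a softmax vector over the protogroup vocabulary.

The encoder is one convolutional layer (filters spanning the full
20 x 20 amino-acid plane, sliding along the separation axis) followed by
two dense layers, tanh at the 20-unit encoding layer; the decoder expands
the encoding through two dense layers to the 8000-cell decoded tensor;
the predictor mirrors the input convolution over fd and ends in a softmax.
ReLU is used everywhere else.

Training proceeds in three steps with earlier parts frozen: (1) the
encoder+decoder as an autoencoder under the loss 1 - |Pearson r| with
Adam; (2) the decoder alone against site-restricted target tensors;
(3) the predictor alone with categorical cross-entropy under Adamax.
A full simultaneous retrain is available as a control.

Everything runs on a small self-contained numpy engine with explicit
backpropagation, so training is deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import h5py
import numpy as np

from .sequences import (
    PairTensor,
    ResidueScores,
    Sequence,
    TENSOR_SHAPE,
    encode_pair_tensor,
    featurize,
    normalize_scores,
    residue_scores,
    smooth_tensor,
)

logger = logging.getLogger(__name__)

PARTS = ("encoder", "decoder", "predictor")

#: Fixed gain applied to tensors entering the convolutional trunks.  Pair
#: tensors are globally normalized, so individual entries are O(1e-4) and
#: would otherwise leave the first layers operating in a near-constant
#: regime; the gain is pure numerical conditioning (the Pearson losses are
#: scale-free) and is part of the architecture, not a tunable.
INPUT_GAIN = 1000.0

#: Weight counts reported for the original full-scale model of this
#: architecture (encoder, decoder, predictor, encoder+decoder, total).
#: They are not derivable from the stated layer dimensions under standard
#: padding/bias conventions, so builds log their own counts next to these
#: reference figures and assert nothing.
REFERENCE_FULL_SCALE_COUNTS = {
    "encoder": 7_689_220,
    "decoder": 10_162_860,
    "predictor": 7_750_573,
    "encoder+decoder": 17_852_080,
    "total": 25_602_653,
}


@dataclass(frozen=True)
class NetworkConfig:
    """Layer sizes and per-step training schedule.

    The full profile follows the reference architecture: 800 convolution
    filters of size 20 x 20 x 3 with stride 20 x 20 x 1, encoder dense
    sizes 400 and 20 (the encoding dimension), decoder dense sizes 75 and
    1200 ahead of the 8000-cell decoded tensor, predictor dense size 400
    ahead of the 87-class softmax, and learning rates 1e-3 / 7e-5 / 1e-7
    with epoch caps 350 / 260 / 700 (50 for the full retrain).
    """

    conv_filters: int = 800
    conv_kernel: tuple[int, int, int] = (20, 20, 3)
    conv_stride: tuple[int, int, int] = (20, 20, 1)
    conv_padding: str = "valid"
    encoder_dense: tuple[int, int] = (400, 20)
    decoder_dense: tuple[int, int] = (75, 1200)
    predictor_dense: tuple[int, ...] = (400,)
    output_classes: int = 87
    learning_rates: dict[str, float] = field(
        default_factory=lambda: {"step1": 1e-3, "step2": 7e-5, "step3": 1e-7, "full": 1e-7}
    )
    epochs: dict[str, int] = field(
        default_factory=lambda: {"step1": 350, "step2": 260, "step3": 700, "full": 50}
    )
    batch_size: int = 32

    def __post_init__(self) -> None:
        if self.encoder_dense[-1] != 20:
            raise ValueError(f"encoding dimension must be 20, got {self.encoder_dense[-1]}")
        if self.conv_padding not in ("valid", "same"):
            raise ValueError(f"conv_padding must be 'valid' or 'same', got {self.conv_padding!r}")
        if self.output_classes < 1:
            raise ValueError("output_classes must be >= 1")

    @property
    def conv_positions(self) -> int:
        depth = TENSOR_SHAPE[2]
        return depth if self.conv_padding == "same" else depth - self.conv_kernel[2] + 1

    @classmethod
    def reduced(cls, output_classes: int = 87) -> "NetworkConfig":
        """Desk-scale profile: 16 filters, hidden widths /10, practical
        learning rates and epoch caps so training completes in minutes on
        one CPU.  Eight filters proved too few for the autoencoder to
        converge reliably across random inits; sixteen is the smallest
        width that did."""
        return cls(
            conv_filters=16,
            encoder_dense=(40, 20),
            decoder_dense=(8, 120),
            predictor_dense=(40,),
            output_classes=output_classes,
            learning_rates={"step1": 1e-3, "step2": 1e-3, "step3": 1e-3, "full": 1e-3},
            epochs={"step1": 60, "step2": 80, "step3": 150, "full": 50},
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


# ---------------------------------------------------------------------------
# Parameter bundle


@dataclass
class NetworkBundle:
    """Weights for the three network parts plus freeze bookkeeping."""

    cfg: NetworkConfig
    params: dict[str, np.ndarray]
    freeze: dict[str, bool] = field(
        default_factory=lambda: {p: False for p in PARTS}
    )
    step: str = "init"
    seed: int | None = None

    def part_keys(self, part: str) -> list[str]:
        return sorted(k for k in self.params if k.startswith(part + "/"))

    def parameter_counts(self) -> dict[str, int]:
        counts = {p: sum(self.params[k].size for k in self.part_keys(p)) for p in PARTS}
        counts["encoder+decoder"] = counts["encoder"] + counts["decoder"]
        counts["total"] = sum(counts[p] for p in PARTS)
        return counts

    def checksum(self, part: str) -> str:
        """SHA-256 over the part's weights (exact freeze-contract witness)."""
        digest = hashlib.sha256()
        for key in self.part_keys(part):
            digest.update(key.encode())
            digest.update(np.ascontiguousarray(self.params[key]).tobytes())
        return digest.hexdigest()

    def save(self, path: str | Path, extra: dict | None = None) -> None:
        with h5py.File(path, "w") as fh:
            fh.attrs["config"] = self.cfg.to_json()
            fh.attrs["step"] = self.step
            fh.attrs["seed"] = -1 if self.seed is None else self.seed
            fh.attrs["config_hash"] = hashlib.sha256(self.cfg.to_json().encode()).hexdigest()
            for key, value in (extra or {}).items():
                fh.attrs[key] = value
            for part in PARTS:
                grp = fh.create_group(part)
                grp.attrs["frozen"] = self.freeze[part]
                for key in self.part_keys(part):
                    grp.create_dataset(key.split("/", 1)[1], data=self.params[key])

    @classmethod
    def load(cls, path: str | Path) -> "NetworkBundle":
        with h5py.File(path, "r") as fh:
            raw = json.loads(fh.attrs["config"])
            raw["conv_kernel"] = tuple(raw["conv_kernel"])
            raw["conv_stride"] = tuple(raw["conv_stride"])
            raw["encoder_dense"] = tuple(raw["encoder_dense"])
            raw["decoder_dense"] = tuple(raw["decoder_dense"])
            raw["predictor_dense"] = tuple(raw["predictor_dense"])
            cfg = NetworkConfig(**raw)
            params = {}
            freeze = {}
            for part in PARTS:
                grp = fh[part]
                freeze[part] = bool(grp.attrs["frozen"])
                for name in grp:
                    params[f"{part}/{name}"] = grp[name][()]
            seed = int(fh.attrs["seed"])
            return cls(
                cfg=cfg,
                params=params,
                freeze=freeze,
                step=str(fh.attrs["step"]),
                seed=None if seed < 0 else seed,
            )


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def build_network(cfg: NetworkConfig, rng_seed: int = 0) -> NetworkBundle:
    """Initialize all three parts (Glorot-uniform weights, seeded).

    Per-part parameter counts are logged next to the reference full-scale
    figures; the decoded-tensor layer's biases start slightly positive so
    its ReLU output is not dead at initialization.
    """
    rng = np.random.default_rng(rng_seed)
    window = cfg.conv_kernel[0] * cfg.conv_kernel[1] * cfg.conv_kernel[2]
    conv_out = cfg.conv_positions * cfg.conv_filters
    d1, d_enc = cfg.encoder_dense
    d3, d4 = cfg.decoder_dense
    cells = int(np.prod(TENSOR_SHAPE))
    params: dict[str, np.ndarray] = {
        "encoder/conv_W": _glorot(rng, (window, cfg.conv_filters)),
        "encoder/conv_b": np.zeros(cfg.conv_filters),
        "encoder/dense1_W": _glorot(rng, (conv_out, d1)),
        "encoder/dense1_b": np.zeros(d1),
        "encoder/dense2_W": _glorot(rng, (d1, d_enc)),
        "encoder/dense2_b": np.zeros(d_enc),
        "decoder/dense1_W": _glorot(rng, (d_enc, d3)),
        "decoder/dense1_b": np.zeros(d3),
        "decoder/dense2_W": _glorot(rng, (d3, d4)),
        "decoder/dense2_b": np.zeros(d4),
        "decoder/out_W": _glorot(rng, (d4, cells)),
        "decoder/out_b": np.full(cells, 0.01),
        "predictor/conv_W": _glorot(rng, (window, cfg.conv_filters)),
        "predictor/conv_b": np.zeros(cfg.conv_filters),
        "predictor/dense1_W": _glorot(rng, (conv_out, cfg.predictor_dense[0])),
        "predictor/dense1_b": np.zeros(cfg.predictor_dense[0]),
        "predictor/out_W": _glorot(rng, (cfg.predictor_dense[0], cfg.output_classes)),
        "predictor/out_b": np.zeros(cfg.output_classes),
    }
    bundle = NetworkBundle(cfg=cfg, params=params, seed=rng_seed)
    counts = bundle.parameter_counts()
    for name, count in counts.items():
        logger.info(
            "built %s: %d parameters (reference full-scale: %s)",
            name, count, REFERENCE_FULL_SCALE_COUNTS.get(name, "n/a"),
        )
    return bundle


# ---------------------------------------------------------------------------
# Forward / backward passes


def _windows(x: np.ndarray, cfg: NetworkConfig) -> np.ndarray:
    """(B, 20, 20, 20) -> (B, P, window) separation-axis convolution windows."""
    depth = TENSOR_SHAPE[2]
    kd = cfg.conv_kernel[2]
    if cfg.conv_padding == "same":
        pad = (kd - 1) // 2
        x = np.pad(x, ((0, 0), (0, 0), (0, 0), (pad, kd - 1 - pad)))
    batch = x.shape[0]
    out = np.empty((batch, cfg.conv_positions, TENSOR_SHAPE[0] * TENSOR_SHAPE[1] * kd))
    for p in range(cfg.conv_positions):
        out[:, p, :] = x[:, :, :, p : p + kd].reshape(batch, -1)
    return out


def _windows_backward(dwin: np.ndarray, cfg: NetworkConfig) -> np.ndarray:
    """Scatter window gradients back onto the (B, 20, 20, 20) input."""
    depth = TENSOR_SHAPE[2]
    kd = cfg.conv_kernel[2]
    pad = (kd - 1) // 2 if cfg.conv_padding == "same" else 0
    batch = dwin.shape[0]
    dx = np.zeros((batch, TENSOR_SHAPE[0], TENSOR_SHAPE[1], depth + (kd - 1 if pad else 0)))
    for p in range(cfg.conv_positions):
        dx[:, :, :, p : p + kd] += dwin[:, p, :].reshape(
            batch, TENSOR_SHAPE[0], TENSOR_SHAPE[1], kd
        )
    if pad:
        dx = dx[:, :, :, pad : pad + depth]
    return dx


def _conv_dense_forward(
    x: np.ndarray, params: dict[str, np.ndarray], part: str, cfg: NetworkConfig
) -> tuple[np.ndarray, dict]:
    """Shared encoder/predictor trunk: conv -> ReLU -> flatten -> dense -> ReLU."""
    win = _windows(x, cfg)
    pre_conv = win @ params[f"{part}/conv_W"] + params[f"{part}/conv_b"]
    act_conv = np.maximum(pre_conv, 0.0)
    flat = act_conv.reshape(x.shape[0], -1)
    pre1 = flat @ params[f"{part}/dense1_W"] + params[f"{part}/dense1_b"]
    act1 = np.maximum(pre1, 0.0)
    cache = {"win": win, "pre_conv": pre_conv, "flat": flat, "pre1": pre1, "act1": act1}
    return act1, cache


def _conv_dense_backward(
    dact1: np.ndarray,
    cache: dict,
    params: dict[str, np.ndarray],
    grads: dict[str, np.ndarray],
    part: str,
    cfg: NetworkConfig,
) -> np.ndarray:
    dpre1 = dact1 * (cache["pre1"] > 0)
    grads[f"{part}/dense1_W"] = cache["flat"].T @ dpre1
    grads[f"{part}/dense1_b"] = dpre1.sum(axis=0)
    dflat = dpre1 @ params[f"{part}/dense1_W"].T
    dact_conv = dflat.reshape(cache["pre_conv"].shape)
    dpre_conv = dact_conv * (cache["pre_conv"] > 0)
    grads[f"{part}/conv_W"] = np.einsum("bpi,bpf->if", cache["win"], dpre_conv)
    grads[f"{part}/conv_b"] = dpre_conv.sum(axis=(0, 1))
    dwin = dpre_conv @ params[f"{part}/conv_W"].T
    return _windows_backward(dwin, cfg)


def encoder_forward(
    x: np.ndarray, bundle: NetworkBundle
) -> tuple[np.ndarray, dict]:
    act1, cache = _conv_dense_forward(x * INPUT_GAIN, bundle.params, "encoder", bundle.cfg)
    pre2 = act1 @ bundle.params["encoder/dense2_W"] + bundle.params["encoder/dense2_b"]
    encoding = np.tanh(pre2)
    cache["encoding"] = encoding
    return encoding, cache


def encoder_backward(
    dencoding: np.ndarray, cache: dict, bundle: NetworkBundle, grads: dict
) -> np.ndarray:
    dpre2 = dencoding * (1.0 - cache["encoding"] ** 2)
    grads["encoder/dense2_W"] = cache["act1"].T @ dpre2
    grads["encoder/dense2_b"] = dpre2.sum(axis=0)
    dact1 = dpre2 @ bundle.params["encoder/dense2_W"].T
    return _conv_dense_backward(dact1, cache, bundle.params, grads, "encoder", bundle.cfg)


def decoder_forward(
    encoding: np.ndarray, bundle: NetworkBundle
) -> tuple[np.ndarray, dict]:
    p = bundle.params
    pre1 = encoding @ p["decoder/dense1_W"] + p["decoder/dense1_b"]
    act1 = np.maximum(pre1, 0.0)
    pre2 = act1 @ p["decoder/dense2_W"] + p["decoder/dense2_b"]
    act2 = np.maximum(pre2, 0.0)
    pre_out = act2 @ p["decoder/out_W"] + p["decoder/out_b"]
    decoded = np.maximum(pre_out, 0.0)
    cache = {
        "encoding": encoding, "pre1": pre1, "act1": act1,
        "pre2": pre2, "act2": act2, "pre_out": pre_out,
    }
    return decoded, cache


def decoder_backward(
    ddecoded: np.ndarray, cache: dict, bundle: NetworkBundle, grads: dict
) -> np.ndarray:
    p = bundle.params
    dpre_out = ddecoded * (cache["pre_out"] > 0)
    grads["decoder/out_W"] = cache["act2"].T @ dpre_out
    grads["decoder/out_b"] = dpre_out.sum(axis=0)
    dact2 = dpre_out @ p["decoder/out_W"].T
    dpre2 = dact2 * (cache["pre2"] > 0)
    grads["decoder/dense2_W"] = cache["act1"].T @ dpre2
    grads["decoder/dense2_b"] = dpre2.sum(axis=0)
    dact1 = dpre2 @ p["decoder/dense2_W"].T
    dpre1 = dact1 * (cache["pre1"] > 0)
    grads["decoder/dense1_W"] = cache["encoding"].T @ dpre1
    grads["decoder/dense1_b"] = dpre1.sum(axis=0)
    return dpre1 @ p["decoder/dense1_W"].T


def predictor_forward(
    decoded: np.ndarray, bundle: NetworkBundle
) -> tuple[np.ndarray, dict]:
    x = decoded.reshape(-1, *TENSOR_SHAPE) * INPUT_GAIN
    act1, cache = _conv_dense_forward(x, bundle.params, "predictor", bundle.cfg)
    logits = act1 @ bundle.params["predictor/out_W"] + bundle.params["predictor/out_b"]
    shifted = logits - logits.max(axis=1, keepdims=True)
    expd = np.exp(shifted)
    probs = expd / expd.sum(axis=1, keepdims=True)
    cache["probs"] = probs
    return probs, cache


def predictor_backward(
    dlogits: np.ndarray, cache: dict, bundle: NetworkBundle, grads: dict
) -> np.ndarray:
    grads["predictor/out_W"] = cache["act1"].T @ dlogits
    grads["predictor/out_b"] = dlogits.sum(axis=0)
    dact1 = dlogits @ bundle.params["predictor/out_W"].T
    dx = _conv_dense_backward(dact1, cache, bundle.params, grads, "predictor", bundle.cfg)
    return dx.reshape(dlogits.shape[0], -1) * INPUT_GAIN


# ---------------------------------------------------------------------------
# Losses


def pearson_loss(x: np.ndarray, y: np.ndarray) -> float:
    """1 - |Pearson r| over the flattened inputs; 1 when either is constant."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    return 1.0 - abs(_pearson_r(x.ravel(), y.ravel()))


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def _pearson_batch_loss(
    pred: np.ndarray, target: np.ndarray
) -> tuple[float, np.ndarray, float]:
    """Mean 1 - |r| over the batch, its gradient wrt pred, and mean signed r."""
    batch = pred.shape[0]
    grad = np.zeros_like(pred)
    losses = np.empty(batch)
    rs = np.empty(batch)
    for b in range(batch):
        x = target[b].ravel()
        y = pred[b].ravel()
        xc = x - x.mean()
        yc = y - y.mean()
        sx = np.sqrt(xc @ xc)
        sy = np.sqrt(yc @ yc)
        if sx == 0.0 or sy == 0.0:
            losses[b] = 1.0
            rs[b] = 0.0
            continue
        r = float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))
        losses[b] = 1.0 - abs(r)
        rs[b] = r
        dr_dy = xc / (sx * sy) - r * yc / (sy * sy)
        g = -np.sign(r) * dr_dy if r != 0 else np.zeros_like(yc)
        g = g - g.mean()  # gradient through the mean-centering of yc
        grad[b] = (g / batch).reshape(pred.shape[1:])
    return float(losses.mean()), grad, float(rs.mean())


def _cross_entropy(
    probs: np.ndarray, onehot: np.ndarray
) -> tuple[float, np.ndarray, float]:
    """Mean categorical CE, gradient wrt logits, and categorical accuracy."""
    batch = probs.shape[0]
    eps = 1e-12
    loss = float(-(onehot * np.log(probs + eps)).sum(axis=1).mean())
    dlogits = (probs - onehot) / batch
    accuracy = float((probs.argmax(axis=1) == onehot.argmax(axis=1)).mean())
    return loss, dlogits, accuracy


# ---------------------------------------------------------------------------
# Optimizers


class _MomentOptimizer:
    """Adam / Adamax with per-parameter state over the trainable key set."""

    def __init__(self, keys: Iterable[str], lr: float, variant: str = "adam",
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if variant not in ("adam", "adamax"):
            raise ValueError(f"unknown optimizer variant {variant!r}")
        self.keys = sorted(keys)
        self.lr = lr
        self.variant = variant
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for key in self.keys:
            g = grads[key]
            m = self.m.setdefault(key, np.zeros_like(g))
            v = self.v.setdefault(key, np.zeros_like(g))
            m *= self.beta1
            m += (1 - self.beta1) * g
            mhat = m / (1 - self.beta1 ** self.t)
            if self.variant == "adam":
                v *= self.beta2
                v += (1 - self.beta2) * g * g
                vhat = v / (1 - self.beta2 ** self.t)
                params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            else:  # adamax: infinity-norm second moment, no bias correction on u
                np.maximum(self.beta2 * v, np.abs(g), out=v)
                params[key] -= self.lr * mhat / (v + self.eps)


# ---------------------------------------------------------------------------
# Training harness


def _as_array(tensors: TypingSequence[PairTensor | np.ndarray]) -> np.ndarray:
    rows = [t.values if isinstance(t, PairTensor) else np.asarray(t) for t in tensors]
    return np.stack(rows).astype(np.float64)


def _split(n: int, rng: np.random.Generator, test_fraction: float = 0.5):
    order = rng.permutation(n)
    n_test = int(round(n * test_fraction))
    return order[n_test:], order[:n_test]


def _check_finite(loss: float, context: str) -> None:
    if not np.isfinite(loss):
        raise RuntimeError(f"training diverged ({context}): loss={loss}")


def _frozen_keys(bundle: NetworkBundle) -> set[str]:
    return {
        key for part in PARTS if bundle.freeze[part] for key in bundle.part_keys(part)
    }


def _autoencoder_pass(
    bundle: NetworkBundle, x: np.ndarray, target: np.ndarray, train_keys: set[str]
) -> tuple[float, float, dict[str, np.ndarray]]:
    encoding, enc_cache = encoder_forward(x, bundle)
    decoded, dec_cache = decoder_forward(encoding, bundle)
    loss, ddecoded, mean_r = _pearson_batch_loss(
        decoded, target.reshape(target.shape[0], -1)
    )
    grads: dict[str, np.ndarray] = {}
    dencoding = decoder_backward(ddecoded, dec_cache, bundle, grads)
    if any(k.startswith("encoder/") for k in train_keys):
        encoder_backward(dencoding, enc_cache, bundle, grads)
    return loss, mean_r, grads


def _reconstruction_stats(bundle: NetworkBundle, x: np.ndarray, target: np.ndarray):
    encoding, _ = encoder_forward(x, bundle)
    decoded, _ = decoder_forward(encoding, bundle)
    flat_t = target.reshape(target.shape[0], -1)
    losses = [pearson_loss(decoded[b], flat_t[b]) for b in range(x.shape[0])]
    rs = [_pearson_r(decoded[b], flat_t[b]) for b in range(x.shape[0])]
    return float(np.mean(losses)), float(np.mean(rs))


def _run_epochs(
    bundle: NetworkBundle,
    x: np.ndarray,
    target: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    epochs: int,
    optimizer: _MomentOptimizer,
    rng: np.random.Generator,
    pass_fn,
    eval_fn,
    context: str,
) -> list[dict]:
    history: list[dict] = []
    train_keys = set(optimizer.keys)
    batch = bundle.cfg.batch_size
    for epoch in range(epochs):
        order = rng.permutation(len(train_idx))
        epoch_losses = []
        for start in range(0, len(order), batch):
            take = train_idx[order[start : start + batch]]
            loss, _, grads = pass_fn(bundle, x[take], target[take], train_keys)
            _check_finite(loss, f"{context} epoch {epoch}")
            optimizer.step(bundle.params, {k: grads[k] for k in train_keys})
            epoch_losses.append(loss)
        entry = {"epoch": epoch + 1, "train_loss": float(np.mean(epoch_losses))}
        entry.update(eval_fn(bundle, x, target, train_idx, test_idx))
        history.append(entry)
    return history


def train_autoencoder(
    tensors: TypingSequence[PairTensor | np.ndarray],
    cfg: NetworkConfig,
    rng_seed: int,
    bundle: NetworkBundle | None = None,
) -> tuple[NetworkBundle, list[dict]]:
    """Step 1: train encoder+decoder to reconstruct the input tensors.

    Half of the data is held out as the test split (seeded).  Loss is
    1 - |Pearson r| between decoded and input tensors, optimized with Adam
    at the step-1 learning rate.
    """
    x = _as_array(tensors)
    if x.shape[0] == 0:
        raise ValueError("empty training set")
    fresh = bundle is None
    if bundle is None:
        bundle = build_network(cfg, rng_seed=rng_seed)
    bundle.freeze = {"encoder": False, "decoder": False, "predictor": True}
    rng = np.random.default_rng([rng_seed, 10])
    train_idx, test_idx = _split(x.shape[0], rng)
    if len(train_idx) == 0 or len(test_idx) == 0:
        train_idx = test_idx = np.arange(x.shape[0])
    if fresh:
        # Start the decoded layer at the mean training target: standard
        # output-bias initialization, which also pins the sign-invariant
        # 1 - |r| loss to its positive-correlation branch.
        bundle.params["decoder/out_b"] = (
            x[train_idx].reshape(len(train_idx), -1).mean(axis=0).copy()
        )
    keys = bundle.part_keys("encoder") + bundle.part_keys("decoder")
    optimizer = _MomentOptimizer(keys, lr=cfg.learning_rates["step1"], variant="adam")

    def evaluate(bundle, x, target, train_idx, test_idx):
        test_loss, test_r = _reconstruction_stats(bundle, x[test_idx], target[test_idx])
        return {"test_loss": test_loss, "test_corr": test_r}

    history = _run_epochs(
        bundle, x, x, train_idx, test_idx, cfg.epochs["step1"], optimizer, rng,
        _autoencoder_pass, evaluate, "step1",
    )
    bundle.step = "step1"
    bundle.seed = rng_seed
    return bundle, history


def build_site_target(
    seq: Sequence, sites: set[int], mode: str = "either"
) -> PairTensor:
    """Target tensor for interaction-site training.

    Runs the standard encode + attenuate + smooth pipeline but counts only
    pairs touching an interacting site ("either": at least one member;
    "both": both members) and k = 0 entries for site residues only.  An
    empty site set yields the all-zero tensor.
    """
    if not sites:
        return PairTensor(
            np.zeros(TENSOR_SHAPE), normalized=True, smoothed=True, id=seq.id
        )
    return smooth_tensor(encode_pair_tensor(seq, site_positions=sites, site_mode=mode))


def train_site_decoder(
    bundle: NetworkBundle,
    pairs: TypingSequence[tuple[PairTensor | np.ndarray, PairTensor | np.ndarray]],
    cfg: NetworkConfig,
    rng_seed: int,
) -> tuple[NetworkBundle, list[dict]]:
    """Step 2: retrain the decoder against site-restricted targets.

    The encoder is frozen (its weights are checksummed before and after;
    drift raises).  Loss and optimizer as in step 1, at the step-2
    learning rate.
    """
    if bundle.step not in ("step1", "step2"):
        logger.warning("site-decoder training from stage %r (expected step1)", bundle.step)
    x = _as_array([p[0] for p in pairs])
    target = _as_array([p[1] for p in pairs])
    bundle.freeze = {"encoder": True, "decoder": False, "predictor": True}
    before = bundle.checksum("encoder")
    rng = np.random.default_rng([rng_seed, 20])
    train_idx, test_idx = _split(x.shape[0], rng)
    if len(train_idx) == 0 or len(test_idx) == 0:
        train_idx = test_idx = np.arange(x.shape[0])
    optimizer = _MomentOptimizer(
        bundle.part_keys("decoder"), lr=cfg.learning_rates["step2"], variant="adam"
    )

    def evaluate(bundle, x, target, train_idx, test_idx):
        test_loss, test_r = _reconstruction_stats(bundle, x[test_idx], target[test_idx])
        return {"test_loss": test_loss, "test_corr": test_r}

    history = _run_epochs(
        bundle, x, target, train_idx, test_idx, cfg.epochs["step2"], optimizer, rng,
        _autoencoder_pass, evaluate, "step2",
    )
    if bundle.checksum("encoder") != before:
        raise RuntimeError("freeze contract violated: encoder weights drifted in step 2")
    bundle.step = "step2"
    return bundle, history


def _predictor_pass(
    bundle: NetworkBundle, x: np.ndarray, onehot: np.ndarray, train_keys: set[str]
) -> tuple[float, float, dict[str, np.ndarray]]:
    encoding, enc_cache = encoder_forward(x, bundle)
    decoded, dec_cache = decoder_forward(encoding, bundle)
    probs, pred_cache = predictor_forward(decoded, bundle)
    loss, dlogits, accuracy = _cross_entropy(probs, onehot)
    grads: dict[str, np.ndarray] = {}
    ddecoded = predictor_backward(dlogits, pred_cache, bundle, grads)
    if any(k.startswith(("encoder/", "decoder/")) for k in train_keys):
        dencoding = decoder_backward(ddecoded, dec_cache, bundle, grads)
        encoder_backward(dencoding, enc_cache, bundle, grads)
    return loss, accuracy, grads


def _predictor_eval(bundle: NetworkBundle, x: np.ndarray, onehot: np.ndarray):
    encoding, _ = encoder_forward(x, bundle)
    decoded, _ = decoder_forward(encoding, bundle)
    probs, _ = predictor_forward(decoded, bundle)
    loss, _, accuracy = _cross_entropy(probs, onehot)
    return loss, accuracy


def _train_classifier(
    bundle: NetworkBundle,
    dataset: TypingSequence[tuple[PairTensor | np.ndarray, np.ndarray]],
    cfg: NetworkConfig,
    rng_seed: int,
    step: str,
    freeze: dict[str, bool],
    rng_key: int,
) -> tuple[NetworkBundle, list[dict]]:
    x = _as_array([d[0] for d in dataset])
    onehot = np.stack([np.asarray(d[1], dtype=np.float64) for d in dataset])
    if onehot.shape[1] != cfg.output_classes:
        raise ValueError(
            f"one-hot width {onehot.shape[1]} != output_classes {cfg.output_classes}"
        )
    bundle.freeze = freeze
    before = {p: bundle.checksum(p) for p in PARTS if freeze[p]}
    rng = np.random.default_rng([rng_seed, rng_key])
    train_idx, test_idx = _split(x.shape[0], rng)
    if len(train_idx) == 0 or len(test_idx) == 0:
        train_idx = test_idx = np.arange(x.shape[0])
    keys = [k for p in PARTS if not freeze[p] for k in bundle.part_keys(p)]
    optimizer = _MomentOptimizer(keys, lr=cfg.learning_rates[step], variant="adamax")

    def pass_fn(bundle, xb, tb, train_keys):
        return _predictor_pass(bundle, xb, tb, train_keys)

    def evaluate(bundle, x, target, train_idx, test_idx):
        test_loss, test_acc = _predictor_eval(bundle, x[test_idx], target[test_idx])
        return {"test_loss": test_loss, "test_accuracy": test_acc}

    history = _run_epochs(
        bundle, x, onehot, train_idx, test_idx, cfg.epochs[step], optimizer, rng,
        pass_fn, evaluate, step,
    )
    for part, checksum in before.items():
        if bundle.checksum(part) != checksum:
            raise RuntimeError(
                f"freeze contract violated: {part} weights drifted in {step}"
            )
    bundle.step = step if step != "full" else "full_retrain"
    return bundle, history


def train_protogroup_predictor(
    bundle: NetworkBundle,
    dataset: TypingSequence[tuple[PairTensor | np.ndarray, np.ndarray]],
    cfg: NetworkConfig,
    rng_seed: int,
) -> tuple[NetworkBundle, list[dict]]:
    """Step 3: train the predictor; encoder and decoder stay frozen.

    Targets are one-hot vectors over the protogroup vocabulary (one example
    per sequence/protogroup pairing); categorical cross-entropy under the
    Adamax optimizer at the step-3 learning rate.
    """
    return _train_classifier(
        bundle, dataset, cfg, rng_seed, "step3",
        {"encoder": True, "decoder": True, "predictor": False}, 30,
    )


def train_full(
    bundle: NetworkBundle,
    dataset: TypingSequence[tuple[PairTensor | np.ndarray, np.ndarray]],
    cfg: NetworkConfig,
    rng_seed: int,
) -> tuple[NetworkBundle, list[dict]]:
    """Control run: all parts trainable on the step-3 data pathway (cap 50 epochs)."""
    return _train_classifier(
        bundle, dataset, cfg, rng_seed, "full",
        {"encoder": False, "decoder": False, "predictor": False}, 40,
    )


def make_predictor_examples(
    records, vocab_size: int
) -> list[tuple[PairTensor, np.ndarray]]:
    """Expand interaction records to (input tensor, one-hot) training pairs.

    A record interacting with several protogroups contributes one example
    per protogroup.
    """
    examples = []
    for rec in records:
        seq = Sequence(id=rec.segment.segment_id, residues=rec.segment.residues)
        tensor = featurize(seq)
        for group in sorted(rec.protogroup_ids):
            if not 1 <= group <= vocab_size:
                raise ValueError(f"protogroup index {group} outside 1..{vocab_size}")
            onehot = np.zeros(vocab_size)
            onehot[group - 1] = 1.0
            examples.append((tensor, onehot))
    return examples


# ---------------------------------------------------------------------------
# Inference


@dataclass(frozen=True)
class ProtogroupScores:
    """Raw softmax vp over the vocabulary and max-normalized tn."""

    raw: np.ndarray
    normalized: np.ndarray


def predict(
    bundle: NetworkBundle, seq: Sequence
) -> tuple[np.ndarray, ResidueScores, ProtogroupScores]:
    """Run the full pipeline on one sequence.

    Returns the encoding vector, per-residue site scores (raw s and
    normalized sn), and protogroup scores (softmax vp and tn = vp / max vp).
    """
    x = featurize(seq).values[None]
    encoding, _ = encoder_forward(x, bundle)
    decoded, _ = decoder_forward(encoding, bundle)
    fd = decoded.reshape(TENSOR_SHAPE)
    scores = normalize_scores(residue_scores(fd, seq))
    probs, _ = predictor_forward(decoded, bundle)
    vp = probs[0]
    top = vp.max()
    tn = vp / top if top > 0 else np.zeros_like(vp)
    return encoding[0], scores, ProtogroupScores(raw=vp, normalized=tn)
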