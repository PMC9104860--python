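"""Context aggregation network (CAN) for image-to-image phase regression.

The architecture is a ten-level fully-convolutional network: nine 3x3
convolutions whose dilation doubles from 1 to 128 and then resets to 1,
each followed by adaptive normalization and a leaky ReLU (slope 0.2,
0.01 at the last hidden level), closed by a 1x1 convolution to a single
output channel trained with a mean-squared-error regression loss.
Padding equals dilation everywhere so the spatial size is preserved at
every level, and after the dilation-128 level the theoretical receptive
field (1 + 2*sum(dilations) = 511) covers a 256x256 input.

Adaptive normalization is a learnable mix of the identity and a
normalized branch:  AN(x) = a*x + m*(gamma*IN(x) + beta)  with scalars
a, m per level and per-channel gamma/beta; IN uses instance statistics
(the minibatch size is one).

Implementation: dilated convolutions are evaluated by im2col + matmul in
numpy and trained with hand-written reverse-mode gradients and the Adam
optimizer.  This keeps the scaled-down profile (64x64 inputs, M = 8
features) comfortably trainable on a single CPU; the full-size profile
(256x256, M up to 512) uses the identical code path.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

__all__ = ["CANConfig", "TrainConfig", "CAN", "build_can", "train",
           "predict", "ablate_channel"]

_DILATIONS = (1, 2, 4, 8, 16, 32, 64, 128, 1)
_LRELU = (0.2,) * 8 + (0.01,)
_EPS = 1e-5


@dataclass(frozen=True)
class CANConfig:
    """Architecture hyperparameters.

    ``input_size`` documents the nominal training resolution; the network
    is fully convolutional and accepts any spatial size at prediction.
    """

    input_channels: int = 1
    features: int = 64
    input_size: int = 256
    dilations: tuple[int, ...] = _DILATIONS
    lrelu_scales: tuple[float, ...] = _LRELU

    def __post_init__(self) -> None:
        if self.input_channels < 1 or self.features < 1:
            raise ValueError("input_channels and features must be >= 1")
        if len(self.dilations) != len(self.lrelu_scales):
            raise ValueError("dilations and lrelu_scales must align")

    @property
    def receptive_field(self) -> int:
        return 1 + 2 * sum(self.dilations)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam, minibatch 1, MSE loss).

    ``lr_schedule`` is "constant" or "cosine"; the cosine option anneals
    the learning rate to zero over the epoch budget.
    """

    learning_rate: float = 1e-4
    minibatch: int = 1
    epochs: int = 100
    seed: int = 0
    lr_schedule: str = "constant"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 1:
            raise ValueError("learning_rate and epochs must be positive")
        if self.minibatch != 1:
            raise ValueError("only minibatch size 1 is supported")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")

    def lr_at(self, epoch: int) -> float:
        if self.lr_schedule == "cosine":
            return self.learning_rate * 0.5 * (
                1.0 + np.cos(np.pi * epoch / self.epochs))
        return self.learning_rate


# ---------------------------------------------------------------- conv ops

def _im2col(x: np.ndarray, d: int) -> np.ndarray:
    """(C, H, W) -> (9C, H*W) patch matrix for a 3x3 dilated conv."""
    C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (d, d), (d, d)))
    cols = np.empty((3, 3, C, H, W), dtype=x.dtype)
    for i in range(3):
        for j in range(3):
            cols[i, j] = xp[:, i * d:i * d + H, j * d:j * d + W]
    return cols.reshape(9 * C, H * W)


def _col2im(dcols: np.ndarray, d: int, shape: tuple[int, int, int]) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    C, H, W = shape
    dcols = dcols.reshape(3, 3, C, H, W)
    dxp = np.zeros((C, H + 2 * d, W + 2 * d), dtype=dcols.dtype)
    for i in range(3):
        for j in range(3):
            dxp[:, i * d:i * d + H, j * d:j * d + W] += dcols[i, j]
    return dxp[:, d:d + H, d:d + W]


class CAN:
    """Trainable context aggregation network (numpy parameters).

    Parameters live in ``self.params`` keyed per level:
    ``W{l}/b{l}`` convolution weights (M, C_in, 3, 3) and bias, ``a{l}``
    identity-mix scalar, ``m{l}`` normalized-branch mix scalar, ``g{l}``
    and ``c{l}`` per-channel scale/offset of the normalized branch, plus
    ``Wf/bf`` for the final 1x1 convolution.
    """

    def __init__(self, config: CANConfig, seed: int = 0) -> None:
        self.config = config
        self.history: dict[str, list[float]] = {}
        rng = np.random.default_rng(seed)
        M = config.features
        self.params: dict[str, np.ndarray] = {}
        c_in = config.input_channels
        for l in range(len(config.dilations)):
            fan_in = 9 * c_in
            self.params[f"W{l}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), (M, c_in, 3, 3)).astype(np.float32)
            self.params[f"b{l}"] = np.zeros(M, dtype=np.float32)
            self.params[f"a{l}"] = np.float32(1.0)   # identity branch on
            self.params[f"m{l}"] = np.float32(0.0)   # normalized branch learns in
            self.params[f"g{l}"] = np.ones(M, dtype=np.float32)
            self.params[f"c{l}"] = np.zeros(M, dtype=np.float32)
            c_in = M
        self.params["Wf"] = rng.normal(0.0, np.sqrt(2.0 / M), (1, M)).astype(np.float32)
        self.params["bf"] = np.zeros(1, dtype=np.float32)
        self._adam: dict[str, tuple[np.ndarray, np.ndarray]] | None = None
        self._adam_t = 0

    # ------------------------------------------------------------ forward

    @property
    def n_params(self) -> int:
        return int(sum(np.size(v) for v in self.params.values()))

    @property
    def receptive_field(self) -> int:
        return self.config.receptive_field

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Run the network on one (C, H, W) input; returns (H, W) output."""
        cfg = self.config
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 3 or x.shape[0] != cfg.input_channels:
            raise ValueError(
                f"expected ({cfg.input_channels}, H, W) input, got {x.shape}")
        H, W = x.shape[1:]
        cache: list[dict] = []
        act = x
        for l, (d, s) in enumerate(zip(cfg.dilations, cfg.lrelu_scales)):
            p = self.params
            Wl = p[f"W{l}"]
            M, C = Wl.shape[:2]
            cols = _im2col(act, d)
            wmat = Wl.transpose(0, 2, 3, 1).reshape(M, 9 * C)
            y = wmat @ cols + p[f"b{l}"][:, None]
            mu = y.mean(axis=1, keepdims=True)
            var = y.var(axis=1, keepdims=True)
            istd = 1.0 / np.sqrt(var + _EPS)
            xhat = (y - mu) * istd
            h = p[f"a{l}"] * y + p[f"m{l}"] * (
                p[f"g{l}"][:, None] * xhat + p[f"c{l}"][:, None])
            neg = h < 0
            out = np.where(neg, s * h, h)
            if want_cache:
                cache.append({"cols": cols, "y": y, "xhat": xhat, "istd": istd,
                              "neg": neg, "in_shape": act.shape, "d": d, "s": s})
            act = out.reshape(M, H, W)
        flat = act.reshape(act.shape[0], H * W)
        pred = (self.params["Wf"] @ flat + self.params["bf"][:, None]).reshape(H, W)
        if want_cache:
            return pred, {"levels": cache, "last": flat, "hw": (H, W)}
        return pred

    # ----------------------------------------------------------- backward

    def loss_and_grads(self, x: np.ndarray, label: np.ndarray):
        """MSE loss and gradients for one input/label pair."""
        pred, cache = self.forward(x, want_cache=True)
        label = np.asarray(label, dtype=np.float32)
        if label.shape != pred.shape:
            raise ValueError("label shape mismatch")
        resid = pred - label
        n_pix = resid.size
        loss = float(np.mean(resid.astype(np.float64) ** 2))
        grads: dict[str, np.ndarray] = {}
        dpred = (2.0 / n_pix) * resid.reshape(1, -1).astype(np.float32)

        flat = cache["last"]
        grads["Wf"] = dpred @ flat.T
        grads["bf"] = dpred.sum(axis=1)
        dact = self.params["Wf"].T @ dpred  # (M, HW)

        for l in range(len(self.config.dilations) - 1, -1, -1):
            c = cache["levels"][l]
            p = self.params
            dh = np.where(c["neg"], np.float32(c["s"]), np.float32(1.0)) * dact
            gah = p[f"g{l}"][:, None] * c["xhat"] + p[f"c{l}"][:, None]
            grads[f"a{l}"] = np.float32((dh * c["y"]).sum())
            grads[f"m{l}"] = np.float32((dh * gah).sum())
            grads[f"g{l}"] = p[f"m{l}"] * (dh * c["xhat"]).sum(axis=1)
            grads[f"c{l}"] = p[f"m{l}"] * dh.sum(axis=1)
            dxhat = (p[f"m{l}"] * p[f"g{l}"][:, None]) * dh
            dy = c["istd"] * (
                dxhat - dxhat.mean(axis=1, keepdims=True)
                - c["xhat"] * (dxhat * c["xhat"]).mean(axis=1, keepdims=True))
            dy = dy + p[f"a{l}"] * dh
            Wl = p[f"W{l}"]
            M, C = Wl.shape[:2]
            wmat = Wl.transpose(0, 2, 3, 1).reshape(M, 9 * C)
            dwmat = dy @ c["cols"].T
            grads[f"W{l}"] = dwmat.reshape(M, 3, 3, C).transpose(0, 3, 1, 2)
            grads[f"b{l}"] = dy.sum(axis=1)
            if l > 0:
                dcols = wmat.T @ dy
                dact = _col2im(dcols, c["d"], c["in_shape"]).reshape(C, -1)
        return loss, grads

    def adam_step(self, grads: dict[str, np.ndarray], lr: float,
                  beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        if self._adam is None:
            self._adam = {k: (np.zeros_like(np.asarray(v, dtype=np.float32)),
                              np.zeros_like(np.asarray(v, dtype=np.float32)))
                          for k, v in self.params.items()}
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m, v = self._adam[k]
            m = beta1 * m + (1 - beta1) * g
            v = beta2 * v + (1 - beta2) * g * g
            self._adam[k] = (m, v)
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            self.params[k] = (self.params[k]
                              - lr * mhat / (np.sqrt(vhat) + eps)).astype(np.float32)

    # -------------------------------------------------------- persistence

    def save(self, path) -> None:
        """Single-file weight archive + JSON architecture sidecar."""
        np.savez(path, **self.params)
        with open(f"{path}.json", "w") as fh:
            json.dump(asdict(self.config), fh)

    @classmethod
    def load(cls, path) -> "CAN":
        with open(f"{path}.json") as fh:
            d = json.load(fh)
        d["dilations"] = tuple(d["dilations"])
        d["lrelu_scales"] = tuple(d["lrelu_scales"])
        model = cls(CANConfig(**d))
        archive = np.load(f"{path}.npz" if not str(path).endswith(".npz") else path)
        for k in model.params:
            model.params[k] = archive[k]
        return model


def build_can(config: CANConfig, seed: int = 0) -> CAN:
    """Untrained network with fan-in-scaled random initialization."""
    return CAN(config, seed=seed)


def _record_arrays(rec):
    x = np.asarray(rec.inputs, dtype=np.float32)
    y = np.asarray(rec.label, dtype=np.float32)
    return x, y


def train(model: CAN, split, tc: TrainConfig, verbose: bool = False) -> CAN:
    """Train in place on a dataset split; returns the model with history.

    ``split`` needs ``train`` and ``validation`` sequences of records with
    ``inputs`` (C, H, W) and ``label`` (H, W) arrays.
    """
    if not split.train:
        raise ValueError("empty training set")
    c0 = np.asarray(split.train[0].inputs).shape[0]
    if c0 != model.config.input_channels:
        raise ValueError(
            f"records have {c0} channels, model expects {model.config.input_channels}")
    rng = np.random.default_rng(tc.seed)
    hist_train: list[float] = []
    hist_val: list[float] = []
    for epoch in range(tc.epochs):
        lr = tc.lr_at(epoch)
        order = rng.permutation(len(split.train))
        losses = []
        for i in order:
            x, y = _record_arrays(split.train[i])
            loss, grads = model.loss_and_grads(x, y)
            model.adam_step(grads, lr)
            losses.append(loss)
        hist_train.append(float(np.mean(losses)))
        if split.validation:
            vloss = [float(np.mean((model.forward(*_record_arrays(r)[:1])
                                    - r.label) ** 2))
                     for r in split.validation]
            hist_val.append(float(np.mean(vloss)))
        if verbose:
            msg = f"epoch {epoch + 1}/{tc.epochs}  train {hist_train[-1]:.5f}"
            if hist_val:
                msg += f"  val {hist_val[-1]:.5f}"
            print(msg)
    model.history = {"train_loss": hist_train, "val_loss": hist_val}
    return model


def predict(model: CAN, inputs: np.ndarray | Sequence[np.ndarray]) -> np.ndarray:
    """Raw (unwrapped) regression output for one input or a batch."""
    arr = np.asarray(inputs, dtype=np.float32)
    if arr.ndim == 3:
        return model.forward(arr)
    if arr.ndim == 4:
        return np.stack([model.forward(a) for a in arr])
    raise ValueError(f"expected (C,H,W) or (B,C,H,W) input, got {arr.shape}")


def ablate_channel(inputs: np.ndarray, channel_index: int) -> np.ndarray:
    """Copy of ``inputs`` with one channel zeroed (post-normalization)."""
    arr = np.array(inputs, copy=True)
    axis = 0 if arr.ndim == 3 else 1
    n_ch = arr.shape[axis]
    if not 0 <= channel_index < n_ch:
        raise IndexError(f"channel {channel_index} out of range ({n_ch} channels)")
    if arr.ndim == 3:
        arr[channel_index] = 0.0
    elif arr.ndim == 4:
        arr[:, channel_index] = 0.0
    else:
        raise ValueError("expected (C,H,W) or (B,C,H,W)")
    return arr
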