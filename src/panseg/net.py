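"""Compact 3D encoder-decoder segmentation network with probability fusion.

A U-shaped fully convolutional network (3x3x3 convolutions, average-pool
down-sampling, nearest-neighbour up-sampling, skip concatenation, 1x1x1
classification head) produces a per-voxel probability map Y over the
three subregions.  In every training epoch Y is fused with the Bayes
anatomical soft-label map X into the joint map

    Yhat_c  ∝  Y_c * X_c      (renormalized so channels sum to 1),

and the Dice + focal loss (1:1 weighting) is computed on Yhat, so the
network learns to complement the anatomical prior rather than re-derive
it.  At inference the same fusion precedes the final argmax.

The network, its backward pass and the Adam optimizer are implemented in
numpy: at the volume sizes this package targets the model is small enough
that explicit im2col convolutions train in seconds per epoch on one CPU,
and a pure-numpy pipeline is bit-for-bit reproducible given a seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------

@dataclass
class NetConfig:
    """Architecture and optimization settings.

    Defaults follow the reference training recipe (three down/up-sampling
    steps, Adam with lr 1e-4, batch size 2, up to 500 epochs, Dice and
    focal losses weighted 1:1).  ``desk_test`` is a small preset that
    trains on ~32^3 phantoms in seconds on one CPU.
    """

    depth: int = 3
    base_channels: int = 8
    use_bayes_input: bool = True   # concatenate the 3 Bayes channels to the image
    fuse: bool = True              # multiply Y with X before loss / argmax
    n_classes: int = 3
    lr: float = 1e-4
    batch_size: int = 2
    max_epochs: int = 500
    dice_weight: float = 1.0
    focal_weight: float = 1.0
    focal_gamma: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_classes != 3:
            raise ValueError("the subregion problem has exactly 3 classes")
        if self.dice_weight <= 0 or self.focal_weight <= 0:
            raise ValueError("loss weights must be > 0")

    @property
    def in_channels(self) -> int:
        return 1 + (3 if self.use_bayes_input else 0)

    @classmethod
    def desk_test(cls, **overrides) -> "NetConfig":
        """CPU-friendly preset: shallow net, few epochs, larger lr."""
        base = dict(depth=2, base_channels=8, max_epochs=15, lr=1e-3, seed=0)
        base.update(overrides)
        return cls(**base)


@dataclass
class TrainState:
    """Per-epoch training history and best-checkpoint bookkeeping."""

    losses: list = field(default_factory=list)
    dsc_history: list = field(default_factory=list)  # per-epoch (H, B, T) train DSC
    best_epoch: int = -1
    best_dsc: float = -1.0

    @property
    def epochs_completed(self) -> int:
        return len(self.losses)


# ----------------------------------------------------------------------
# fusion
# ----------------------------------------------------------------------

def fuse_probability_maps(Y, X, mask=None):
    """Joint probability map: per voxel, per class, Yhat ∝ Y*X, channel sums 1.

    Where every class product is 0 (both maps reject the voxel) the result
    falls back to uniform (1/3) to avoid NaNs.  With a ``mask``, voxels
    outside it are zeroed instead.
    """
    Y = np.asarray(Y, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    if Y.shape != X.shape:
        raise ValueError(f"shape mismatch {Y.shape} vs {X.shape}")
    prod = Y * X
    tot = prod.sum(axis=0, keepdims=True)
    out = np.where(tot > 0, prod / np.where(tot > 0, tot, 1.0), 1.0 / 3.0)
    if mask is not None:
        out = np.where(np.asarray(mask)[None], out, 0.0)
    return out


def _fusion_backward(gYhat, Y, X, Yhat):
    """d loss / d Y given d loss / d Yhat, for Yhat = Y*X / sum(Y*X)."""
    tot = (Y * X).sum(axis=0, keepdims=True)
    safe = tot > 0
    inner = (gYhat * Yhat).sum(axis=0, keepdims=True)
    gY = X * (gYhat - inner) / np.where(safe, tot, 1.0)
    return np.where(safe, gY, 0.0)


# ----------------------------------------------------------------------
# losses
# ----------------------------------------------------------------------

def one_hot(labels, n_classes=3):
    """(C, *shape) one-hot encoding of labels 1..C; background rows are all 0."""
    labels = np.asarray(labels)
    return np.stack([(labels == c + 1).astype(np.float64) for c in range(n_classes)])


def dice_focal_loss(pred, target, mask=None, gamma=2.0,
                    dice_weight=1.0, focal_weight=1.0, return_grad=False):
    """Mean soft-Dice loss plus focal loss, weighted ``dice:focal``.

    Parameters
    ----------
    pred : (C, *shape) probability map (channels sum to 1 on the mask)
    target : label volume (0..C) or (C, *shape) one-hot grid
    mask : bool grid, optional
        Voxels the loss is computed over; defaults to target > 0.

    The Dice term averages ``1 - 2|P∩T|/(|P|+|T|)`` over classes (soft,
    using probabilities); the focal term is ``mean (1-p_t)^gamma (-log p_t)``
    over mask voxels with p_t the probability of the true class.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target)
    if target.ndim == pred.ndim - 1:
        t_onehot = one_hot(target, pred.shape[0])
        default_mask = target > 0
    else:
        if target.shape != pred.shape:
            raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
        t_onehot = target.astype(np.float64)
        default_mask = t_onehot.sum(axis=0) > 0
    mask = default_mask if mask is None else np.asarray(mask).astype(bool)
    if mask.shape != pred.shape[1:]:
        raise ValueError("mask shape mismatch")

    pm = pred[:, mask]      # (C, N)
    tm = t_onehot[:, mask]
    n_vox = pm.shape[1]
    eps = 1e-7

    inter = (pm * tm).sum(axis=1)
    denom = pm.sum(axis=1) + tm.sum(axis=1) + eps
    dice = (2.0 * inter + eps) / denom
    dice_loss = float(np.mean(1.0 - dice))

    pt = np.clip((pm * tm).sum(axis=0), eps, 1.0)
    focal = (1.0 - pt) ** gamma * (-np.log(pt))
    focal_loss = float(focal.mean())

    loss = dice_weight * dice_loss + focal_weight * focal_loss
    if not return_grad:
        return loss

    # d(dice_loss)/dp = -(2 t - dice) / denom / C
    g_dice = -(2.0 * tm - dice[:, None]) / denom[:, None] / pred.shape[0]
    dpt = (gamma * (1.0 - pt) ** (gamma - 1.0) * np.log(pt)
           - (1.0 - pt) ** gamma / pt) / n_vox
    g_focal = tm * dpt[None, :]
    grad = np.zeros_like(pred)
    grad[:, mask] = dice_weight * g_dice + focal_weight * g_focal
    return loss, grad


# ----------------------------------------------------------------------
# layers (forward + backward)
# ----------------------------------------------------------------------

def _conv3d_forward(x, W, b):
    # x: (Cin, D, H, W); W: (Cout, Cin, 3, 3, 3); 'same' padding
    cin, d, h, w = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3, 3), axis=(1, 2, 3))  # (Cin,D,H,W,3,3,3)
    cols = np.ascontiguousarray(win.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(
        d * h * w, cin * 27
    )
    out = cols @ W.reshape(W.shape[0], -1).T + b
    y = out.reshape(d, h, w, W.shape[0]).transpose(3, 0, 1, 2)
    return y, cols


def _conv3d_backward(gy, cols, W, x_shape):
    cout = gy.shape[0]
    cin, d, h, w = x_shape
    gy_mat = gy.reshape(cout, -1).T                      # (N, Cout)
    gW = (gy_mat.T @ cols).reshape(W.shape)
    gb = gy_mat.sum(axis=0)
    gcols = gy_mat @ W.reshape(cout, -1)                 # (N, Cin*27)
    gwin = gcols.reshape(d, h, w, cin, 3, 3, 3)
    gxp = np.zeros((cin, d + 2, h + 2, w + 2))
    for i in range(3):
        for j in range(3):
            for k in range(3):
                gxp[:, i:i + d, j:j + h, k:k + w] += gwin[..., i, j, k].transpose(3, 0, 1, 2)
    return gxp[:, 1:-1, 1:-1, 1:-1], gW, gb


def _relu_forward(x):
    return np.maximum(x, 0.0), x > 0


def _avgpool_forward(x):
    c, d, h, w = x.shape
    return x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(2, 4, 6))


def _avgpool_backward(gy):
    return gy.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3) / 8.0


def _upsample_forward(x):
    return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)


def _upsample_backward(gy):
    c, d, h, w = gy.shape
    return gy.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(2, 4, 6))


def softmax_channels(z):
    z = z - z.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


# ----------------------------------------------------------------------
# the network
# ----------------------------------------------------------------------

class UNet3D:
    """U-shaped 3D fully convolutional network in numpy.

    Encoder: ``depth`` levels of (conv3 + ReLU, avg-pool /2); bottleneck
    conv; decoder: ``depth`` levels of (nearest upsample x2, skip concat,
    conv3 + ReLU); 1x1x1 head to class logits.  Channel widths double per
    level starting from ``base_channels``.  Input spatial dims must be
    multiples of ``2**depth`` (see :func:`pad_to_multiple`).
    """

    def __init__(self, config: NetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = [config.base_channels * 2 ** i for i in range(config.depth + 1)]
        self.params = {}
        cin = config.in_channels
        for i in range(config.depth):
            self._init_conv(rng, f"enc{i}", cin, ch[i])
            cin = ch[i]
        self._init_conv(rng, "bottleneck", cin, ch[config.depth])
        cup = ch[config.depth]
        for i in reversed(range(config.depth)):
            self._init_conv(rng, f"dec{i}", cup + ch[i], ch[i])
            cup = ch[i]
        # 1x1x1 classification head
        self.params["head_W"] = rng.normal(
            0.0, np.sqrt(2.0 / cup), size=(config.n_classes, cup)
        )
        self.params["head_b"] = np.zeros(config.n_classes)

    def _init_conv(self, rng, name, cin, cout):
        std = np.sqrt(2.0 / (cin * 27))
        self.params[f"{name}_W"] = rng.normal(0.0, std, size=(cout, cin, 3, 3, 3))
        self.params[f"{name}_b"] = np.zeros(cout)

    # -- forward / backward -------------------------------------------------

    def forward(self, x):
        """Input (Cin, D, H, W) -> (logits (C, D, H, W), cache)."""
        cfg, p = self.config, self.params
        cache = {"x_shapes": {}, "cols": {}, "relu": {}, "skips": []}
        h = np.asarray(x, dtype=np.float64)
        for i in range(cfg.depth):
            cache["x_shapes"][f"enc{i}"] = h.shape
            h, cols = _conv3d_forward(h, p[f"enc{i}_W"], p[f"enc{i}_b"])
            cache["cols"][f"enc{i}"] = cols
            h, m = _relu_forward(h)
            cache["relu"][f"enc{i}"] = m
            cache["skips"].append(h)
            h = _avgpool_forward(h)
        cache["x_shapes"]["bottleneck"] = h.shape
        h, cols = _conv3d_forward(h, p["bottleneck_W"], p["bottleneck_b"])
        cache["cols"]["bottleneck"] = cols
        h, m = _relu_forward(h)
        cache["relu"]["bottleneck"] = m
        for i in reversed(range(cfg.depth)):
            h = _upsample_forward(h)
            h = np.concatenate([h, cache["skips"][i]], axis=0)
            cache["x_shapes"][f"dec{i}"] = h.shape
            h, cols = _conv3d_forward(h, p[f"dec{i}_W"], p[f"dec{i}_b"])
            cache["cols"][f"dec{i}"] = cols
            h, m = _relu_forward(h)
            cache["relu"][f"dec{i}"] = m
        cache["head_in"] = h
        c, d, hh, w = h.shape
        logits = (p["head_W"] @ h.reshape(c, -1) + p["head_b"][:, None]).reshape(
            cfg.n_classes, d, hh, w
        )
        return logits, cache

    def backward(self, glogits, cache):
        cfg, p = self.config, self.params
        grads = {}
        hin = cache["head_in"]
        c = hin.shape[0]
        g_mat = glogits.reshape(cfg.n_classes, -1)
        grads["head_W"] = g_mat @ hin.reshape(c, -1).T
        grads["head_b"] = g_mat.sum(axis=1)
        gh = (p["head_W"].T @ g_mat).reshape(hin.shape)
        gskips = {}
        for i in range(cfg.depth):
            gh = gh * cache["relu"][f"dec{i}"]
            gh, gW, gb = _conv3d_backward(
                gh, cache["cols"][f"dec{i}"], p[f"dec{i}_W"], cache["x_shapes"][f"dec{i}"]
            )
            grads[f"dec{i}_W"], grads[f"dec{i}_b"] = gW, gb
            n_up = cache["x_shapes"][f"dec{i}"][0] - cache["skips"][i].shape[0]
            gskips[i] = gh[n_up:]
            gh = _upsample_backward(gh[:n_up])
        gh = gh * cache["relu"]["bottleneck"]
        gh, gW, gb = _conv3d_backward(
            gh, cache["cols"]["bottleneck"], p["bottleneck_W"],
            cache["x_shapes"]["bottleneck"]
        )
        grads["bottleneck_W"], grads["bottleneck_b"] = gW, gb
        for i in reversed(range(cfg.depth)):
            gh = _avgpool_backward(gh) + gskips[i]
            gh = gh * cache["relu"][f"enc{i}"]
            gh, gW, gb = _conv3d_backward(
                gh, cache["cols"][f"enc{i}"], p[f"enc{i}_W"], cache["x_shapes"][f"enc{i}"]
            )
            grads[f"enc{i}_W"], grads[f"enc{i}_b"] = gW, gb
        return grads, gh

    def predict_probs(self, x):
        logits, _ = self.forward(x)
        return softmax_channels(logits)

    # -- serialization ------------------------------------------------------

    def state_dict(self):
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state):
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float64).copy()

    def save(self, path):
        np.savez(path, __config__=json.dumps(asdict(self.config)), **self.params)

    @classmethod
    def load(cls, path):
        with np.load(path, allow_pickle=False) as data:
            config = NetConfig(**json.loads(str(data["__config__"])))
            model = cls(config)
            model.load_state_dict({k: data[k] for k in model.params})
        return model


# ----------------------------------------------------------------------
# training
# ----------------------------------------------------------------------

def pad_to_multiple(arrays, multiple):
    """Zero-pad trailing spatial dims of each array to a common multiple.

    Accepts (C, D, H, W) and (D, H, W) arrays mixed; returns padded copies
    plus the original spatial shape for unpadding.
    """
    spatial = arrays[0].shape[-3:]
    target = tuple(-(-s // multiple) * multiple for s in spatial)
    out = []
    for a in arrays:
        pad = [(0, t - s) for s, t in zip(a.shape[-3:], target)]
        if a.ndim == 4:
            pad = [(0, 0)] + pad
        out.append(np.pad(a, pad))
    return out, spatial


def _build_input(vol, bayes_probs, config):
    x = vol.intensities[None].astype(np.float64)
    if config.use_bayes_input:
        if bayes_probs is None:
            raise ValueError("config.use_bayes_input=True but no Bayes map given")
        x = np.concatenate([x, np.asarray(bayes_probs, dtype=np.float64)], axis=0)
    return x


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads, beta1=0.9, beta2=0.999, eps=1e-8):
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = beta1 * self.m[k] + (1 - beta1) * g
            self.v[k] = beta2 * self.v[k] + (1 - beta2) * g * g
            mhat = self.m[k] / (1 - beta1 ** self.t)
            vhat = self.v[k] / (1 - beta2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _forward_fused(model, x, bayes_padded, mask, config):
    logits, cache = model.forward(x)
    Y = softmax_channels(logits)
    if config.fuse:
        if bayes_padded is None:
            raise ValueError("config.fuse=True but no Bayes map given")
        Yhat = fuse_probability_maps(Y, bayes_padded)
    else:
        Yhat = Y
    return logits, cache, Y, Yhat


def train(dataset, config: NetConfig):
    """Train the network on (PancreasVolume, labels, bayes_probs) triples.

    Per epoch and per sample: forward -> Y, fuse with the case's Bayes map
    X -> Yhat, Dice+focal loss on Yhat over pancreas voxels, backprop
    through fusion and softmax, Adam update per mini-batch.  The checkpoint
    with the best mean training DSC is restored at the end.  Fully
    deterministic given ``config.seed``.
    """
    if len(dataset) < 2:
        raise ValueError("need at least 2 training cases")
    mult = 2 ** config.depth
    prepared = []
    for vol, labels, bayes_probs in dataset:
        x = _build_input(vol, bayes_probs, config)
        arrays = [x, np.asarray(labels), vol.mask.astype(bool)]
        if bayes_probs is not None:
            arrays.append(np.asarray(bayes_probs, dtype=np.float64))
        padded, _ = pad_to_multiple(arrays, mult)
        xp, lp, mp = padded[:3]
        bp = padded[3] if bayes_probs is not None else None
        prepared.append((xp, lp.astype(np.uint8), mp.astype(bool), bp))

    model = UNet3D(config)
    opt = _Adam(model.params, config.lr)
    rng = np.random.default_rng(config.seed)
    state = TrainState()
    best_state = model.state_dict()

    from .evaluation import dsc  # local import to avoid a cycle

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(prepared))
        epoch_losses = []
        epoch_preds = [None] * len(prepared)
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            grads_sum = None
            batch_loss = 0.0
            for idx in batch:
                xp, lp, mp, bp = prepared[idx]
                logits, cache, Y, Yhat = _forward_fused(model, xp, bp, mp, config)
                loss, gYhat = dice_focal_loss(
                    Yhat, lp, mask=mp, gamma=config.focal_gamma,
                    dice_weight=config.dice_weight,
                    focal_weight=config.focal_weight, return_grad=True,
                )
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, case {idx}"
                    )
                gY = _fusion_backward(gYhat, Y, np.asarray(prepared[idx][3]), Yhat) \
                    if config.fuse else gYhat
                glogits = Y * (gY - (gY * Y).sum(axis=0, keepdims=True))
                grads, _ = model.backward(glogits, cache)
                grads_sum = grads if grads_sum is None else {
                    k: grads_sum[k] + grads[k] for k in grads
                }
                batch_loss += loss
                labels_pred = np.zeros(mp.shape, dtype=np.uint8)
                labels_pred[mp] = np.argmax(Yhat[:, mp], axis=0).astype(np.uint8) + 1
                epoch_preds[idx] = labels_pred
            n_b = len(batch)
            opt.step(model.params, {k: v / n_b for k, v in grads_sum.items()})
            epoch_losses.append(batch_loss / n_b)
        state.losses.append(float(np.mean(epoch_losses)))
        class_dsc = np.array([
            np.mean([dsc(epoch_preds[i], prepared[i][1], c + 1, prepared[i][2])
                     for i in range(len(prepared))])
            for c in range(3)
        ])
        state.dsc_history.append(class_dsc.tolist())
        mean_dsc = float(class_dsc.mean())
        if mean_dsc > state.best_dsc:
            state.best_dsc = mean_dsc
            state.best_epoch = epoch
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return model, state


def predict(model: UNet3D, vol, bayes_probs=None, fuse=None):
    """Segment one case: returns (fused probability map, hard labels).

    The probability map and labels have the volume's original shape;
    voxels outside the pancreas mask are background (0).  With ``fuse``
    unset the model config decides; ``fuse=False`` gives the plain-network
    path (ablation baseline).
    """
    config = model.config
    fuse = config.fuse if fuse is None else fuse
    x = _build_input(vol, bayes_probs, config)
    arrays = [x] + ([np.asarray(bayes_probs, dtype=np.float64)]
                    if bayes_probs is not None else [])
    padded, spatial = pad_to_multiple(arrays, 2 ** config.depth)
    Y = model.predict_probs(padded[0])
    if fuse:
        if bayes_probs is None:
            raise ValueError("fusion requested but no Bayes map given")
        Yhat = fuse_probability_maps(Y, padded[1])
    else:
        Yhat = Y
    sl = tuple(slice(0, s) for s in spatial)
    Yhat = Yhat[(slice(None),) + sl]
    mask = vol.mask.astype(bool)
    probs = np.where(mask[None], Yhat, 0.0)
    labels = np.zeros(mask.shape, dtype=np.uint8)
    labels[mask] = np.argmax(Yhat[:, mask], axis=0).astype(np.uint8) + 1
    return probs, labels
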