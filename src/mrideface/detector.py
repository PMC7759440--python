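"""Attention-gated 3D U-net facial-feature detector.

The network is an encoder-decoder with skip connections.  Each encoder
level applies two 3x3x3 convolutions with ReLU and halves the resolution by
2x average pooling; the decoder mirrors it with nearest-neighbour
upsampling.  Skip connections pass through additive attention gates: the
skip features x and the upsampled decoder features u are projected to a
common width, summed, passed through ReLU and a per-voxel sigmoid to give
an attention map that rescales x before concatenation.  A final 1x1x1
convolution and softmax produce per-voxel probabilities over the four
classes {background, eye, nose, ear}.

Training minimizes (1 - soft Dice) + 0.1 x categorical cross-entropy with
Adam, monitors mean validation Dice over the feature classes each epoch,
keeps the best parameters, and stops after ``patience`` epochs without
improvement.

The implementation is pure NumPy with hand-written backward passes (see
:mod:`mrideface.nn`), which is entirely adequate at the desk scales this
package targets and keeps the dependency footprint to the scientific stack.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import nn
from .augmentation import AugmentSpec, epoch_size, make_epoch_stream
from .defacer import DetectionRegions
from .io_formats import Volume
from .metrics_loss import CCE_WEIGHT, DICE_EPS, dice_multiclass, one_hot
from .phantom import LabelMap


class ConfigError(ValueError):
    pass


class TrainingError(RuntimeError):
    """Raised when the loss diverges; carries the history collected so far."""

    def __init__(self, message: str, history: "TrainHistory"):
        super().__init__(message)
        self.history = history


@dataclass
class DetectorConfig:
    depth: int = 4                 # encoder levels
    base_channels: int = 16        # channels at full resolution, doubling per level
    n_classes: int = 4
    attention_gates: bool = True
    input_patch: tuple[int, int, int] = (64, 64, 64)
    learning_rate: float = 1e-3
    batch_size: int = 2
    min_component_voxels: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes != 4:
            raise ConfigError("the detector is defined for 4 classes")
        if self.depth < 2:
            raise ConfigError("depth must be >= 2")
        for n in self.input_patch:
            if n % (2 ** self.depth) != 0:
                raise ConfigError(
                    f"input_patch {self.input_patch} not divisible by 2^depth"
                )

    @classmethod
    def small(cls, **kw) -> "DetectorConfig":
        """Desk-scale detector: depth 3, base 8 channels, 32-voxel patches."""
        kw.setdefault("depth", 3)
        kw.setdefault("base_channels", 8)
        kw.setdefault("input_patch", (32, 32, 32))
        return cls(**kw)


@dataclass
class TrainConfig:
    max_epochs: int = 50
    patience: int = 5
    k_augment_train: int = 3
    k_augment_val: int = 1
    dice_weight: float = 1.0
    cce_weight: float = CCE_WEIGHT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ConfigError("patience must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    best_epoch: int = 0            # 1-based
    stopped_epoch: int = 0

    def as_rows(self) -> list[dict]:
        return [
            {"epoch": i + 1, "train_loss": l, "val_dice": d}
            for i, (l, d) in enumerate(zip(self.train_loss, self.val_dice))
        ]


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class AttentionUNet3D:
    """Parameter container plus forward/backward for the U-net."""

    def __init__(self, config: DetectorConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        C = [config.base_channels * 2 ** i for i in range(config.depth)]
        self.channels = C
        p = self.params

        def conv3(name: str, ci: int, co: int) -> None:
            p[f"{name}.w"] = nn.he_init(rng, 27 * ci, (27, ci, co))
            p[f"{name}.b"] = np.zeros(co, dtype=np.float32)

        def conv1(name: str, ci: int, co: int) -> None:
            p[f"{name}.w"] = nn.he_init(rng, ci, (ci, co))
            p[f"{name}.b"] = np.zeros(co, dtype=np.float32)

        prev = 1
        for i, c in enumerate(C):
            conv3(f"enc{i}a", prev, c)
            conv3(f"enc{i}b", c, c)
            prev = c
        for i in range(config.depth - 2, -1, -1):
            c, cd = C[i], C[i + 1]
            conv1(f"up{i}", cd, c)
            if config.attention_gates:
                ca = max(c // 2, 4)
                conv1(f"att{i}.x", c, ca)
                conv1(f"att{i}.g", c, ca)
                conv1(f"att{i}.psi", ca, 1)
            conv3(f"dec{i}a", 2 * c, c)
            conv3(f"dec{i}b", c, c)
        conv1("head", C[0], config.n_classes)

    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    # -- forward -----------------------------------------------------------

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (D,H,W,1) float32 in [0,1] -> per-voxel class probabilities."""
        cfg = self.config
        p = self.params
        cache: dict = {}
        skips = []
        h = x
        for i in range(cfg.depth):
            h, cache[f"enc{i}a"] = nn.conv3_forward(h, p[f"enc{i}a.w"], p[f"enc{i}a.b"])
            h, cache[f"enc{i}a.r"] = nn.relu_forward(h)
            h, cache[f"enc{i}b"] = nn.conv3_forward(h, p[f"enc{i}b.w"], p[f"enc{i}b.b"])
            h, cache[f"enc{i}b.r"] = nn.relu_forward(h)
            if i < cfg.depth - 1:
                skips.append(h)
                h, cache[f"pool{i}"] = nn.avgpool2_forward(h)
        for i in range(cfg.depth - 2, -1, -1):
            h, cache[f"ups{i}"] = nn.upsample2_forward(h)
            h, cache[f"up{i}"] = nn.conv1_forward(h, p[f"up{i}.w"], p[f"up{i}.b"])
            h, cache[f"up{i}.r"] = nn.relu_forward(h)
            s = skips[i]
            if cfg.attention_gates:
                qx, cache[f"att{i}.x"] = nn.conv1_forward(
                    s, p[f"att{i}.x.w"], p[f"att{i}.x.b"])
                qg, cache[f"att{i}.g"] = nn.conv1_forward(
                    h, p[f"att{i}.g.w"], p[f"att{i}.g.b"])
                q, cache[f"att{i}.r"] = nn.relu_forward(qx + qg)
                a, cache[f"att{i}.psi"] = nn.conv1_forward(
                    q, p[f"att{i}.psi.w"], p[f"att{i}.psi.b"])
                alpha, cache[f"att{i}.s"] = nn.sigmoid_forward(a)
                cache[f"att{i}.alpha"] = alpha
                cache[f"att{i}.skip"] = s
                s = s * alpha
            h = np.concatenate([s, h], axis=-1)
            h, cache[f"dec{i}a"] = nn.conv3_forward(h, p[f"dec{i}a.w"], p[f"dec{i}a.b"])
            h, cache[f"dec{i}a.r"] = nn.relu_forward(h)
            h, cache[f"dec{i}b"] = nn.conv3_forward(h, p[f"dec{i}b.w"], p[f"dec{i}b.b"])
            h, cache[f"dec{i}b.r"] = nn.relu_forward(h)
        logits, cache["head"] = nn.conv1_forward(h, p["head.w"], p["head.b"])
        probs = nn.softmax(logits.astype(np.float64))
        if want_cache:
            return probs, cache
        return probs

    # -- backward ----------------------------------------------------------

    def backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        cfg = self.config
        grads: dict[str, np.ndarray] = {}
        dh = dlogits.astype(np.float32)
        dh, grads["head.w"], grads["head.b"] = nn.conv1_backward(dh, cache["head"])
        dskips: dict[int, np.ndarray] = {}
        for i in range(0, cfg.depth - 1):
            dh = nn.relu_backward(dh, cache[f"dec{i}b.r"])
            dh, grads[f"dec{i}b.w"], grads[f"dec{i}b.b"] = nn.conv3_backward(
                dh, cache[f"dec{i}b"])
            dh = nn.relu_backward(dh, cache[f"dec{i}a.r"])
            dh, grads[f"dec{i}a.w"], grads[f"dec{i}a.b"] = nn.conv3_backward(
                dh, cache[f"dec{i}a"])
            c = self.channels[i]
            ds, du = dh[..., :c], dh[..., c:]
            if cfg.attention_gates:
                alpha = cache[f"att{i}.alpha"]
                skip = cache[f"att{i}.skip"]
                dalpha = (ds * skip).sum(axis=-1, keepdims=True)
                ds = ds * alpha
                da = nn.sigmoid_backward(dalpha, cache[f"att{i}.s"])
                dq, grads[f"att{i}.psi.w"], grads[f"att{i}.psi.b"] = nn.conv1_backward(
                    da, cache[f"att{i}.psi"])
                dq = nn.relu_backward(dq, cache[f"att{i}.r"])
                dqx, grads[f"att{i}.x.w"], grads[f"att{i}.x.b"] = nn.conv1_backward(
                    dq, cache[f"att{i}.x"])
                dqg, grads[f"att{i}.g.w"], grads[f"att{i}.g.b"] = nn.conv1_backward(
                    dq, cache[f"att{i}.g"])
                ds = ds + dqx
                du = du + dqg
            dskips[i] = ds
            du = nn.relu_backward(du, cache[f"up{i}.r"])
            du, grads[f"up{i}.w"], grads[f"up{i}.b"] = nn.conv1_backward(
                du, cache[f"up{i}"])
            dh = nn.upsample2_backward(du, cache[f"ups{i}"])
        for i in range(cfg.depth - 1, -1, -1):
            if i < cfg.depth - 1:
                dh = nn.avgpool2_backward(dh, cache[f"pool{i}"])
                dh = dh + dskips[i]
            dh = nn.relu_backward(dh, cache[f"enc{i}b.r"])
            dh, grads[f"enc{i}b.w"], grads[f"enc{i}b.b"] = nn.conv3_backward(
                dh, cache[f"enc{i}b"])
            dh = nn.relu_backward(dh, cache[f"enc{i}a.r"])
            dh, grads[f"enc{i}a.w"], grads[f"enc{i}a.b"] = nn.conv3_backward(
                dh, cache[f"enc{i}a"])
        return grads

    def state_copy(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()


def build_detector(config: DetectorConfig | None = None) -> AttentionUNet3D:
    """Construct an attention-gated 3D U-net with seeded initialization."""
    return AttentionUNet3D(config or DetectorConfig())


# ---------------------------------------------------------------------------
# Intensity normalization
# ---------------------------------------------------------------------------

def normalize_intensity(data: np.ndarray) -> np.ndarray:
    """Per-volume robust rescale of intensities to [0, 1] (1st-99th pct)."""
    lo, hi = np.percentile(data, [1, 99])
    if hi <= lo:
        hi = lo + 1.0
    return np.clip((data - lo) / (hi - lo), 0.0, 1.0).astype(np.float32)


# ---------------------------------------------------------------------------
# Loss gradient
# ---------------------------------------------------------------------------

def _loss_and_grad(probs: np.ndarray, onehot: np.ndarray,
                   cce_weight: float) -> tuple[float, np.ndarray]:
    """Composite loss and its gradient with respect to the logits."""
    axes = tuple(range(probs.ndim - 1))
    s_pq = (probs * onehot).sum(axis=axes)
    s_p = probs.sum(axis=axes)
    s_y = onehot.sum(axis=axes)
    den = s_p + s_y + DICE_EPS
    d_c = (2.0 * s_pq + DICE_EPS) / den
    n_classes = probs.shape[-1]
    n_vox = probs.size // n_classes
    p_clip = np.clip(probs, 1e-12, 1.0)
    cce = float(-(onehot * np.log(p_clip)).sum() / n_vox)
    loss = (1.0 - float(np.mean(d_c))) + cce_weight * cce
    # d(1 - mean Dice)/dp
    dp = -(2.0 * onehot - d_c) / den / n_classes
    dlogits = nn.softmax_chain(dp, probs)
    dlogits += cce_weight * (probs - onehot) / n_vox
    return loss, dlogits


# ---------------------------------------------------------------------------
# Early stopping
# ---------------------------------------------------------------------------

def early_stop_epoch(scores: list[float], patience: int) -> tuple[int, int]:
    """Apply the stopping rule to a validation-metric sequence.

    Epochs are 1-based.  The best epoch is the first occurrence of the
    maximum; training stops at the epoch where ``patience`` epochs have
    passed since the best (e.g. best at 23 -> stop at 28 with patience 5),
    or at the end of the sequence if improvement never ceases long enough.
    Returns ``(best_epoch, stopped_epoch)``.
    """
    best, best_epoch = -np.inf, 0
    for e, score in enumerate(scores, start=1):
        if score > best:
            best, best_epoch = score, e
        if e - best_epoch >= patience:
            return best_epoch, e
    return best_epoch, len(scores)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_detector(
    model: AttentionUNet3D,
    train_cohort,
    val_cohort,
    tconf: TrainConfig | None = None,
    aug: AugmentSpec | None = None,
    log=None,
) -> tuple[AttentionUNet3D, TrainHistory]:
    """Train with per-epoch augmentation streams and Dice-monitored stopping.

    Each epoch streams ``epoch_size(n_train, k_augment_train)`` volume/label
    pairs (originals plus fresh random augments) for optimization and
    ``epoch_size(n_val, k_augment_val)`` pairs for validation.  The model
    with the best mean validation Dice is kept and returned.
    """
    if tconf is None:
        tconf = TrainConfig()
    if aug is None:
        aug = AugmentSpec()
    if not len(train_cohort) or not len(val_cohort):
        raise ValueError("cohorts must be non-empty")
    cfg = model.config
    opt = nn.Adam(lr=cfg.learning_rate)
    history = TrainHistory()
    best_state = model.state_copy()
    n_classes = cfg.n_classes

    for epoch in range(1, tconf.max_epochs + 1):
        losses = []
        batch_grads: dict[str, np.ndarray] | None = None
        in_batch = 0
        stream = make_epoch_stream(
            train_cohort, aug, tconf.k_augment_train,
            epoch_seed=tconf.seed * 100003 + epoch,
        )
        for vol, labels in stream:
            x = normalize_intensity(vol.data)[..., None]
            y = one_hot(labels.data, n_classes)
            probs, cache = model.forward(x, want_cache=True)
            loss, dlogits = _loss_and_grad(probs, y, tconf.cce_weight)
            if not np.isfinite(loss):
                history.stopped_epoch = epoch
                raise TrainingError(f"loss diverged at epoch {epoch}", history)
            losses.append(loss)
            grads = model.backward(dlogits, cache)
            if batch_grads is None:
                batch_grads = grads
            else:
                for k in batch_grads:
                    batch_grads[k] += grads[k]
            in_batch += 1
            if in_batch == cfg.batch_size:
                for k in batch_grads:
                    batch_grads[k] /= in_batch
                opt.step(model.params, batch_grads)
                batch_grads, in_batch = None, 0
        if batch_grads is not None:
            for k in batch_grads:
                batch_grads[k] /= in_batch
            opt.step(model.params, batch_grads)

        val_scores = []
        val_stream = make_epoch_stream(
            val_cohort, aug, tconf.k_augment_val,
            epoch_seed=(tconf.seed * 100003 + epoch) ^ 0x5EED,
        )
        for vol, labels in val_stream:
            pred = predict_labels(model, vol)
            _, mean = dice_multiclass(pred, labels)
            val_scores.append(mean)
        mean_dice = float(np.mean(val_scores))
        history.train_loss.append(float(np.mean(losses)))
        history.val_dice.append(mean_dice)
        if log is not None:
            log(epoch, history.train_loss[-1], mean_dice)

        best_epoch, stopped = early_stop_epoch(history.val_dice, tconf.patience)
        if best_epoch == epoch:
            best_state = model.state_copy()
        history.best_epoch = best_epoch
        if stopped < len(history.val_dice) or (
                stopped == len(history.val_dice)
                and stopped - best_epoch >= tconf.patience):
            history.stopped_epoch = stopped
            break
    else:
        history.stopped_epoch = tconf.max_epochs

    model.load_state(best_state)
    return model, history


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_labels(model: AttentionUNet3D, vol: Volume) -> LabelMap:
    """Per-voxel argmax class prediction on the volume's own lattice.

    Volumes whose shape is not divisible by ``2^depth`` are zero-padded to
    the next multiple for the forward pass and cropped back.
    """
    factor = 2 ** model.config.depth
    data = normalize_intensity(np.asarray(vol.data, dtype=np.float64))
    shape = data.shape
    padded = [int(np.ceil(s / factor) * factor) for s in shape]
    if padded != list(shape):
        pad = [(0, p - s) for p, s in zip(padded, shape)]
        data = np.pad(data, pad)
    probs = model.forward(data[..., None])
    labels = np.argmax(probs, axis=-1).astype(np.int16)
    labels = labels[: shape[0], : shape[1], : shape[2]]
    return LabelMap(labels)


def separate_instances(
    labels: LabelMap, min_voxels: int = 10
) -> DetectionRegions:
    """Split a label map into the five facial-feature instance masks.

    Connected components are extracted per class; components smaller than
    ``min_voxels`` are discarded as speckle.  The two largest eye (and ear)
    components are assigned left/right by centroid position along the
    lateral axis; the largest nose component is kept.  Absent features get
    empty masks and a ``present`` flag of False.
    """
    lab = np.asarray(labels.data)
    shape = lab.shape
    empty = np.zeros(shape, dtype=bool)
    masks = {f: empty.copy() for f in DetectionRegions.FEATURES}
    present = {f: False for f in DetectionRegions.FEATURES}

    def components(cls: int) -> list[np.ndarray]:
        cc, n = ndimage.label(lab == cls)
        sizes = ndimage.sum_labels(np.ones_like(cc), cc, index=range(1, n + 1))
        keep = [i + 1 for i, s in enumerate(sizes) if s >= min_voxels]
        keep.sort(key=lambda i: -sizes[i - 1])
        return [cc == i for i in keep]

    def assign_lr(comps: list[np.ndarray], name: str) -> None:
        comps = comps[:2]
        if not comps:
            return
        centroids = [float(np.mean(np.nonzero(c)[0])) for c in comps]
        if len(comps) == 1:
            side = "left" if centroids[0] < shape[0] / 2 else "right"
            masks[f"{name}_{side}"] = comps[0]
            present[f"{name}_{side}"] = True
            return
        order = np.argsort(centroids)  # lower lateral index = subject's left
        masks[f"{name}_left"] = comps[order[0]]
        masks[f"{name}_right"] = comps[order[1]]
        present[f"{name}_left"] = present[f"{name}_right"] = True

    assign_lr(components(1), "eye")
    assign_lr(components(3), "ear")
    nose_comps = components(2)
    if nose_comps:
        masks["nose"] = nose_comps[0]
        present["nose"] = True

    return DetectionRegions(
        masks["eye_left"], masks["eye_right"], masks["nose"],
        masks["ear_left"], masks["ear_right"], present,
    )


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: AttentionUNet3D, path: str | Path) -> None:
    """Write parameters as .npz with a JSON sidecar holding the config."""
    path = Path(path)
    np.savez(path, **model.params)
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in vars(model.config).items()}
    path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))


def load_checkpoint(path: str | Path) -> AttentionUNet3D:
    path = Path(path)
    cfg = json.loads(path.with_suffix(".json").read_text())
    cfg["input_patch"] = tuple(cfg["input_patch"])
    model = AttentionUNet3D(DetectorConfig(**cfg))
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        model.load_state({k: z[k] for k in z.files})
    return model
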