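"""UNW: a U-shaped encoder-decoder with normalization/whitening alignment.

The network is a compact U-Net-style backbone (configurable stage widths,
2x2 max pooling, bilinear upsampling, skip concatenation) with a
pre-segmentation branch — a 1x1 softmax classifier over the bottleneck
features whose probability maps M guide the FCA block and whose weight
matrix w drives FDA channel grouping.  By default FCA then FDA act on the
bottleneck feature map; both are plug-and-play and can be disabled to
recover the plain backbone (the ablation baseline).

Training minimises

    L = lambda_seg * CE(final prediction, labels)
      + lambda_fca * [CE(M, labels) + ||F_bar - FC||_1]
      + lambda_fda * L_FDA

with SGD (momentum + weight decay).  Labels are nearest-neighbour
downsampled to the bottleneck resolution for the class-region statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Module, DoubleConv, Conv1x1, SGD
from .fca import FCA, DEFAULT_THRESHOLD
from .fda import rank_channels, build_groups, fda_loss
from .primitives import DEFAULT_BETA
from .metrics import aggregate

__all__ = ["ModelConfig", "TrainConfig", "UNW", "build_unw", "total_loss",
           "train", "predict", "evaluate", "save_checkpoint",
           "load_checkpoint"]

_INSERTION_POINTS = ("bottleneck", "all")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and loss configuration."""

    n_classes: int = 2
    widths: tuple = (16, 32, 64, 128)  # encoder stage widths; last = bottleneck
    n_convs: int = 2                   # convs per stage
    skip_connections: bool = True      # raw skips bypass the alignment blocks
    preseg_on_normalized: bool = True  # classify IN(F), not raw F (see doc)
    use_fca: bool = True
    use_fda: bool = True
    insertion: str = "bottleneck"
    lambda_seg: float = 1.0
    lambda_fca: float = 1.0
    lambda_fda: float = 1.0
    beta: float = DEFAULT_BETA
    threshold: float = DEFAULT_THRESHOLD
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.insertion not in _INSERTION_POINTS:
            raise ValueError(f"unknown insertion point {self.insertion!r}; "
                             f"available: {_INSERTION_POINTS}")
        if min(self.lambda_seg, self.lambda_fca, self.lambda_fda) < 0:
            raise ValueError("loss weights must be nonnegative")

    @property
    def stride(self):
        return 2 ** (len(self.widths) - 1)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings (defaults: SGD, lr 5e-4, momentum 0.9,
    weight decay 5e-4, batch 6, 200 epochs, 512x512 input)."""

    optimizer: str = "sgd"
    lr: float = 5e-4
    momentum: float = 0.9
    weight_decay: float = 5e-4
    epochs: int = 200
    batch_size: int = 6
    input_size: int = 512
    augment: bool = True
    clip_norm: float = 5.0  # global gradient-norm clip; None disables
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("lr, epochs and batch size must be positive")


class UNW(Module):
    """The segmentation network; see the module docstring."""

    def __init__(self, config=None):
        config = config or ModelConfig()
        self.config = config
        rng = np.random.default_rng(config.seed)
        widths = list(config.widths)
        self.enc = []
        cin = 3
        for wd in widths[:-1]:
            self.enc.append(DoubleConv(cin, wd, rng, config.n_convs))
            cin = wd
        self.bottleneck = DoubleConv(cin, widths[-1], rng, config.n_convs)
        self.preseg = Conv1x1(widths[-1], config.n_classes, rng)
        self.fca = FCA(config.n_classes, widths[-1], rng,
                       t=config.threshold, beta=config.beta) \
            if config.use_fca else None
        # per-stage insertion: an FCA block on every skip connection, fed by
        # the (upsampled) pre-segmentation map; without these, raw
        # style-sensitive encoder features reach the decoder unaligned
        self.fca_skips = None
        if config.use_fca and config.insertion == "all":
            self.fca_skips = [FCA(config.n_classes, wd, rng,
                                  t=config.threshold, beta=config.beta)
                              for wd in widths[:-1]]
        self.dec = []
        up_c = widths[-1]
        for wd in reversed(widths[:-1]):
            cin = up_c + wd if config.skip_connections else up_c
            self.dec.append(DoubleConv(cin, wd, rng, config.n_convs))
            up_c = wd
        self.head = Conv1x1(widths[0], config.n_classes, rng)

    # -- forward ------------------------------------------------------------
    def forward(self, images, labels=None):
        """Run the network.

        images: (N, 3, H, W) float in [0, 1] or (N, H, W, 3) uint8.
        Returns (probs, M_full, losses) where probs is the final per-pixel
        class probability map (N, C, H, W), M_full the upsampled
        pre-segmentation map, and losses a dict with 'seg', 'fca', 'fda'
        tensors when labels were given (else None).
        """
        x = _as_batch(images)
        cfg = self.config
        n, _, h, w = x.shape
        if h % cfg.stride or w % cfg.stride:
            raise ValueError(f"spatial dims must be multiples of "
                             f"{cfg.stride}, got {h}x{w}")
        lab = None
        if labels is not None:
            lab = np.asarray(labels)
            if lab.shape != (n, h, w):
                raise ValueError("label/image shape mismatch")

        t = Tensor(x)
        skips = []
        for stage in self.enc:
            t = stage(t)
            skips.append(t)
            t = ad.maxpool2x(t)
        F = self.bottleneck(t)

        # pre-segmentation branch: 1x1 classifier over bottleneck features.
        # The classifier sees the instance-normalized features by default:
        # its class maps steer the whole FCA pipeline, so it must itself be
        # robust to appearance shift, and IN is the style remover the
        # architecture is built on.  Its weights w still drive FDA grouping.
        from .primitives import instance_normalize
        pre_in = instance_normalize(F, cfg.beta, validate=False) \
            if cfg.preseg_on_normalized else F
        pre_logits = self.preseg(pre_in)
        M = ad.softmax(pre_logits, axis=1)
        M_full = M
        for _ in range(len(self.enc)):
            M_full = ad.upsample2x(M_full)

        losses = None
        lab_down = None
        if lab is not None:
            s = cfg.stride
            lab_down = lab[:, ::s, ::s]
            losses = {}

        F_bar = F
        if self.fca is not None:
            if lab is not None:
                F_bar, FC, l_fca = self.fca(F, M, lab_down)
                losses["fca"] = l_fca
            else:
                F_bar, _, _ = self.fca(F, M)
            if self.fca_skips is not None:
                M_stage = M
                aligned = []
                for level in range(len(skips) - 1, -1, -1):
                    M_stage = ad.upsample2x(M_stage)
                    s_lab = lab[:, ::2 ** level, ::2 ** level] \
                        if lab is not None else None
                    out = self.fca_skips[level](skips[level], M_stage,
                                                s_lab)
                    aligned.append(out)
                    if s_lab is not None:
                        losses["fca"] = losses["fca"] + out[2]
                skips = [a[0] for a in reversed(aligned)]
        elif lab is not None and cfg.use_fda:
            # FDA without FCA still needs a meaningful classifier: supervise
            # the pre-segmentation branch with its cross-entropy alone
            losses["fca"] = ad.cross_entropy(pre_logits, lab_down)

        if cfg.use_fda and lab is not None:
            grouping = build_groups(rank_channels(self.preseg.weight.data),
                                    K=F.shape[1], C=cfg.n_classes)
            losses["fda"] = fda_loss(F_bar, self.preseg.weight, grouping)

        t = F_bar
        for stage, skip in zip(self.dec, reversed(skips)):
            t = ad.upsample2x(t)
            if cfg.skip_connections:
                t = ad.concat([t, skip], axis=1)
            t = stage(t)
        logits = self.head(t)
        probs = ad.softmax(logits, axis=1)
        if lab is not None:
            losses["seg"] = ad.cross_entropy(logits, lab)
        return probs, M_full, losses

    __call__ = forward

    @property
    def classifier_weights(self):
        """The (C, K) pre-segmentation weight matrix w."""
        return self.preseg.weight


def build_unw(config=None):
    """Build a UNW model; same seed and config give identical parameters."""
    model = UNW(config)
    model_log = {"n_params": model.n_params(),
                 "config": asdict(model.config)}
    model.build_log = model_log
    return model


def _as_batch(images):
    """Accept (N, 3, H, W) float or (N, H, W, 3) uint8; return float32."""
    x = np.asarray(images)
    if x.ndim != 4:
        raise ValueError("expected a 4-D image batch")
    if x.shape[-1] == 3 and x.shape[1] != 3:
        x = x.transpose(0, 3, 1, 2)
    if x.dtype == np.uint8:
        x = x.astype(np.float32) / 255.0
    return np.ascontiguousarray(x, dtype=np.float32)


def total_loss(losses, config):
    """Weighted sum of the loss terms returned by forward()."""
    total = config.lambda_seg * losses["seg"]
    if "fca" in losses:
        total = total + config.lambda_fca * losses["fca"]
    if "fda" in losses:
        total = total + config.lambda_fda * losses["fda"]
    return total


def predict(model, images):
    """Argmax class map; exact ties resolve to the lower class index."""
    probs, _, _ = model(images)
    return np.argmax(probs.data, axis=1)


def evaluate(model, dataset, batch_size=8):
    """Confusion-based metrics over a dataset of SegSample-likes.

    Returns (pooled, per_image, mean, std) as in
    :func:`unwseg.metrics.aggregate`.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty dataset")
    pairs = []
    for i in range(0, len(dataset), batch_size):
        chunk = dataset[i:i + batch_size]
        imgs = np.stack([s.image for s in chunk])
        preds = predict(model, imgs)
        pairs.extend((preds[j], chunk[j].mask) for j in range(len(chunk)))
    return aggregate(pairs)


def train(model, train_set, val_set=None, tcfg=None, log_path=None,
          keep_best=True, augment_fn=None):
    """Seeded SGD training loop.

    Records one history entry per epoch (loss terms plus validation
    metrics), retains the parameters of the best validation-DSC epoch when
    ``keep_best`` (restored into the model at the end), aborts on
    non-finite loss, and optionally appends JSON-lines records to
    ``log_path``.
    """
    from .synthetic import random_augment

    tcfg = tcfg or TrainConfig()
    train_set = list(train_set)
    if not train_set:
        raise ValueError("empty training set")
    if tcfg.optimizer != "sgd":
        raise ValueError("only SGD is supported")
    opt = SGD(model.parameters(), lr=tcfg.lr, momentum=tcfg.momentum,
              weight_decay=tcfg.weight_decay, clip_norm=tcfg.clip_norm)
    rng = np.random.default_rng(tcfg.seed)
    cfg = model.config
    history = []
    best = (-1.0, None)
    log_f = open(log_path, "w") if log_path else None
    try:
        for epoch in range(tcfg.epochs):
            order = rng.permutation(len(train_set))
            sums = {"seg": 0.0, "fca": 0.0, "fda": 0.0, "total": 0.0}
            nb = 0
            for i in range(0, len(order), tcfg.batch_size):
                chunk = [train_set[j] for j in order[i:i + tcfg.batch_size]]
                if tcfg.augment:
                    fn = augment_fn or random_augment
                    chunk = [fn(s, rng) for s in chunk]
                imgs = np.stack([s.image for s in chunk])
                labs = np.stack([s.mask for s in chunk])
                _, _, losses = model(imgs, labs)
                loss = total_loss(losses, cfg)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}: {loss.data!r}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                for k in ("seg", "fca", "fda"):
                    if k in losses:
                        sums[k] += float(losses[k].data)
                sums["total"] += float(loss.data)
                nb += 1
            rec = {"epoch": epoch,
                   "seg_ce": sums["seg"] / nb,
                   "l_fca": sums["fca"] / nb,
                   "l_fda": sums["fda"] / nb,
                   "total": sums["total"] / nb}
            if val_set:
                _, _, vmean, _ = evaluate(model, val_set)
                rec.update({f"val_{k}": v for k, v in vmean.items()})
                if keep_best and vmean["dsc"] >= best[0]:
                    best = (vmean["dsc"], model.state_dict())
            history.append(rec)
            if log_f:
                log_f.write(json.dumps(rec) + "\n")
    finally:
        if log_f:
            log_f.close()
    if keep_best and best[1] is not None:
        model.load_state_dict(best[1])
    return history


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model, optimizer=None, epoch=None, rng_state=None):
    """Single-file .npz checkpoint with config, parameters and state."""
    payload = {f"param_{i}": p for i, p in model.state_dict().items()}
    payload["config_json"] = np.array(json.dumps(asdict(model.config)))
    if epoch is not None:
        payload["epoch"] = np.array(epoch)
    if optimizer is not None:
        st = optimizer.state_dict()
        payload["opt_json"] = np.array(json.dumps(
            {k: st[k] for k in ("lr", "momentum", "weight_decay")}))
        for i, v in enumerate(st["velocity"]):
            payload[f"vel_{i}"] = v
    if rng_state is not None:
        payload["rng_json"] = np.array(json.dumps(rng_state))
    np.savez(path, **payload)


def load_checkpoint(path):
    """Rebuild a model (and optimizer state, if present) from a checkpoint."""
    with np.load(path, allow_pickle=False) as z:
        cfg = ModelConfig(**json.loads(str(z["config_json"])))
        model = UNW(cfg)
        n = len(model.parameters())
        model.load_state_dict({i: z[f"param_{i}"] for i in range(n)})
        extras = {}
        if "opt_json" in z:
            extras["optimizer"] = json.loads(str(z["opt_json"]))
            extras["velocity"] = [z[f"vel_{i}"] for i in range(n)]
        if "epoch" in z:
            extras["epoch"] = int(z["epoch"])
        if "rng_json" in z:
            extras["rng"] = json.loads(str(z["rng_json"]))
    return model, extras
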