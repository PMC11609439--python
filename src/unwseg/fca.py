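"""Feature Center Alignment (FCA).

FCA aligns the *centres* of per-class feature distributions.  During
training, ground-truth labels define the class regions and the encoder
feature map is standardised per class region (class-region instance
normalization).  At inference no labels exist, so a pre-segmentation branch
supplies soft class-probability maps M; the feature map is highlighted per
class (Hadamard product with M^c), refined by a small attention module (FR),
restricted to a learnable region mask (sigmoid response thresholded at t),
and region-normalised.  An L1 penalty pulls the label-free pipeline's output
F-bar toward the label-guided normalization FC, and a cross-entropy term
trains the pre-segmentation branch.

Class regions and region masks enter the statistics as non-differentiable
constants; gradients flow through the feature values and the affine
parameters.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Module, Parameter, Conv3x3
from .primitives import DEFAULT_BETA

__all__ = ["ClassAffine", "class_region_normalize", "highlight_class",
           "FeatureRefine", "RegionMaskHead", "region_normalize",
           "fca_loss", "FCA", "DEFAULT_THRESHOLD"]

#: region-mask threshold t on the sigmoid response
DEFAULT_THRESHOLD = 0.8


def _raw(x):
    return x.data if isinstance(x, Tensor) else np.asarray(x)


class ClassAffine(Module):
    """Learnable per-class, per-channel scale alpha and shift epsilon.

    Initialised to the identity transform (scale 1, shift 0).
    """

    def __init__(self, n_classes, n_channels):
        self.scale = Parameter(np.ones((n_classes, n_channels)))
        self.shift = Parameter(np.zeros((n_classes, n_channels)))

    def for_class(self, c):
        return self.scale[c], self.shift[c]


def _masked_standardize(F, mask, beta):
    """Standardise F over the spatial region selected by binary ``mask``.

    mask: constant ndarray broadcastable to (N, 1, H, W).  Returns the
    standardised field (defined everywhere; callers restrict it to the
    region) plus the per-sample pixel counts.  Empty regions use a guarded
    denominator so the (unused) values stay finite.
    """
    mask = np.asarray(_raw(mask), dtype=_raw(F).dtype)
    cnt = mask.sum(axis=(2, 3), keepdims=True)
    safe = np.maximum(cnt, 1.0)
    mu = (F * mask).sum(axis=(2, 3), keepdims=True) / safe
    var = (((F - mu) ** 2) * mask).sum(axis=(2, 3), keepdims=True) / safe
    if beta == 0 and np.any((_raw(var) == 0) & (cnt > 0)):
        raise ZeroDivisionError(
            "constant region with beta = 0: variance vanishes")
    return (F - mu) / (var + beta) ** 0.5, cnt


def class_region_normalize(F, labels, affine=None, beta=DEFAULT_BETA):
    """Class-region instance normalization of F guided by integer labels.

    For each sample n, channel m and class c, the feature values at the
    positions labelled c are standardised by the mean and population
    deviation over that region only, then scaled by alpha[c, m] and shifted
    by epsilon[c, m].  A class with no pixels in a sample contributes
    nothing (its branch passes through).
    """
    raw = _raw(F)
    if raw.ndim != 4:
        raise ValueError("F must be (N, K, H, W)")
    lab = np.asarray(_raw(labels))
    if lab.shape != (raw.shape[0],) + raw.shape[2:]:
        raise ValueError(f"labels shape {lab.shape} does not match feature "
                         f"map spatial shape {raw.shape}")
    if lab.size == 0:
        raise ValueError("empty label mask")
    n_classes = int(lab.max()) + 1
    if affine is not None:
        n_classes = max(n_classes, _raw(affine.scale).shape[0])
    out = None
    for c in range(n_classes):
        mask = (lab == c)[:, None].astype(raw.dtype)
        normed, _ = _masked_standardize(F, mask, beta)
        if affine is not None:
            a, e = affine.for_class(c)
            if not isinstance(F, Tensor):  # keep plain-array calls plain
                a, e = _raw(a), _raw(e)
            normed = normed * _vec(a) + _vec(e)
        term = normed * mask
        out = term if out is None else out + term
    return out


def _vec(v):
    """(K,) class-affine vector -> broadcastable (1, K, 1, 1)."""
    if isinstance(v, Tensor):
        return v.reshape(1, -1, 1, 1)
    return np.asarray(v).reshape(1, -1, 1, 1)


def highlight_class(F, M):
    """Hadamard class highlighting: F^c = F * M^c for each class c.

    Returns a list of C feature maps, each (N, K, H, W).
    """
    raw_f, raw_m = _raw(F), _raw(M)
    if raw_f.shape[0] != raw_m.shape[0] or raw_f.shape[2:] != raw_m.shape[2:]:
        raise ValueError("F and M are not spatially aligned")
    C = raw_m.shape[1]
    return [F * M[:, c:c + 1] for c in range(C)]


class FeatureRefine(Module):
    """FR attention: channel-pooled descriptors -> 3x3 conv -> sigmoid gate.

    The class-highlighted map F^c is max-pooled and mean-pooled over the
    channel axis (two (N, 1, H, W) descriptors), concatenated with the class
    probability map M^c, convolved 3x3 to one channel and squashed to an
    attention field A in (0, 1).  Output is the gated residual
    F''c = F^c + A * F^c.
    """

    def __init__(self, rng):
        self.conv = Conv3x3(3, 1, rng)

    def __call__(self, Fc, Mc):
        Fc, Mc = ad.astensor(Fc), ad.astensor(Mc)
        if Mc.shape != (Fc.shape[0], 1) + Fc.shape[2:]:
            raise ValueError("Mc must be (N, 1, H, W) aligned with Fc")
        pooled = ad.concat([ad.channel_max(Fc),
                            Fc.mean(axis=1, keepdims=True), Mc], axis=1)
        A = ad.sigmoid(self.conv(pooled))
        return Fc + A * Fc


class RegionMaskHead(Module):
    """LRN mask head: pooled descriptors -> 3x3 conv -> sigmoid -> threshold.

    Produces the binary region mask Phi by comparing the sigmoid response
    against t (mask = 1 where response >= t).  The thresholded mask is a
    constant with respect to gradients.
    """

    def __init__(self, rng, t=DEFAULT_THRESHOLD):
        if not 0 < t < 1:
            raise ValueError("threshold t must lie in (0, 1)")
        self.conv = Conv3x3(2, 1, rng)
        # bias starts at the threshold logit so the mask opens where the
        # pooled descriptors push the response above its resting point;
        # a zero bias would leave the mask empty (sigmoid 0.5 < t) forever
        # since thresholding passes no gradient back to this head
        self.conv.bias.data[:] = np.log(t / (1.0 - t))
        self.t = float(t)

    def __call__(self, Fc):
        Fc = ad.astensor(Fc)
        pooled = ad.concat([ad.channel_max(Fc),
                            Fc.mean(axis=1, keepdims=True)], axis=1)
        resp = ad.sigmoid(self.conv(pooled))
        return (resp.data >= self.t).astype(np.uint8)


def make_region_mask(Fc, head, t=None):
    """Functional wrapper over :class:`RegionMaskHead`."""
    if t is not None:
        head.t = float(t)
    return head(Fc)


def region_normalize(Fc_refined, mask, affine=None, class_id=0,
                     beta=DEFAULT_BETA):
    """Learnable region normalization (LRN) of one class branch.

    Features at masked-in positions are standardised by the statistics of
    the masked region (per sample, per channel) and affine-transformed with
    the branch's class parameters; masked-out positions pass through
    bit-identically.  An empty mask passes the whole sample through.
    """
    m = np.asarray(_raw(mask))
    raw = _raw(Fc_refined)
    if m.ndim == 3:
        m = m[:, None]
    if m.shape != (raw.shape[0], 1) + raw.shape[2:]:
        raise ValueError("mask must be (N, 1, H, W) aligned with features")
    if not np.isin(m, (0, 1)).all():
        raise ValueError("region mask must be binary")
    normed, _ = _masked_standardize(Fc_refined, m.astype(raw.dtype), beta)
    if affine is not None:
        a, e = affine.for_class(class_id)
        if not isinstance(Fc_refined, Tensor):
            a, e = _raw(a), _raw(e)
        normed = normed * _vec(a) + _vec(e)
    if isinstance(Fc_refined, Tensor) or isinstance(normed, Tensor):
        return ad.where_const(m.astype(bool), normed, Fc_refined)
    return np.where(m.astype(bool), normed, raw)


def fca_loss(M, labels, F_bar, FC):
    """FCA objective: CE(M, L) + mean L1 distance between F-bar and FC.

    The cross-entropy is averaged over pixels; the alignment term is the
    entrywise L1 distance normalised by the element count, so both terms are
    resolution-independent.
    """
    raw_m = _raw(M)
    if raw_m.min() < -1e-6 or raw_m.max() > 1 + 1e-6:
        raise ValueError("class probabilities must lie in [0, 1]")
    lab = np.asarray(_raw(labels))
    C = raw_m.shape[1]
    onehot = np.moveaxis(np.eye(C, dtype=raw_m.dtype)[lab], -1, 1)
    # log of the true-class probability only: p*onehot + (1-onehot) is 1 at
    # every non-selected entry, so its log contributes nothing there
    if isinstance(M, Tensor):
        sel = M * onehot + (1.0 - onehot)
        # clamp away float32 softmax underflow; gradient is zero at the clamp
        floor = 1e-8
        sel = ad.where_const(sel.data > floor, sel,
                             np.full_like(sel.data, floor))
        ce = -(sel.log()).sum() / lab.size
    else:
        with np.errstate(divide="ignore"):
            ce = -np.log(raw_m * onehot + (1.0 - onehot)).sum() / lab.size
    l1 = abs(F_bar - FC).mean()
    return ce + l1


class FCA(Module):
    """The full FCA block: highlight -> FR -> region mask -> LRN -> sum.

    Holds the class-affine parameters (shared between the label-guided
    normalization FC and the region normalization), one FR module and one
    mask head per class.  In training mode (labels given) it also returns FC
    and the two loss terms of the FCA objective.
    """

    def __init__(self, n_classes, n_channels, rng, t=DEFAULT_THRESHOLD,
                 beta=DEFAULT_BETA):
        self.n_classes = int(n_classes)
        self.affine = ClassAffine(n_classes, n_channels)
        self.refiners = [FeatureRefine(rng) for _ in range(n_classes)]
        self.mask_heads = [RegionMaskHead(rng, t=t) for _ in range(n_classes)]
        self.beta = float(beta)

    def __call__(self, F, M, labels=None):
        F = ad.astensor(F)
        M = ad.astensor(M)
        if M.shape[1] != self.n_classes:
            raise ValueError("M class count mismatch")
        branches = highlight_class(F, M)
        F_bar = None
        for c, Fc in enumerate(branches):
            Fcc = self.refiners[c](Fc, M[:, c:c + 1])
            mask = self.mask_heads[c](Fcc)
            lrn = region_normalize(Fcc, mask, affine=self.affine,
                                   class_id=c, beta=self.beta)
            F_bar = lrn if F_bar is None else F_bar + lrn
        if labels is None:
            return F_bar, None, None
        lab = np.asarray(_raw(labels))
        if lab.shape != (F.shape[0],) + F.shape[2:]:
            raise ValueError("labels misaligned with feature map")
        FC = class_region_normalize(F, lab, affine=self.affine,
                                    beta=self.beta)
        return F_bar, FC, fca_loss(M, lab, F_bar, FC)
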