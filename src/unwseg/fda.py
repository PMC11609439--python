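"""Feature Distribution Alignment (FDA).

Where FCA aligns class feature *centres*, FDA aligns their *distributions*:
it ranks the feature channels by their weight in the pre-segmentation
classifier (how strongly each channel votes for each class), assembles
floor(K/C) disjoint groups mixing one channel per class, and penalises the
deviation of each group's (weight-scaled) channel covariance from the
identity — grouped instance whitening that decorrelates channels belonging
to different classes while leaving within-class structure alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .primitives import batched_channel_covariance

__all__ = ["ChannelGrouping", "rank_channels", "build_groups", "fda_loss"]


def _raw(x):
    return x.data if isinstance(x, Tensor) else np.asarray(x)


@dataclass
class ChannelGrouping:
    """A disjoint partition of channels into groups of one channel per class.

    ``groups[m][c]`` is the channel that represents class ``c`` in group
    ``m``; ``ranking[c]`` lists all channels in descending relevance to
    class ``c``; ``excluded`` are leftover channels (K not divisible by C)
    that take no part in the loss.
    """

    groups: list
    ranking: np.ndarray
    excluded: list = field(default_factory=list)

    @property
    def n_groups(self):
        return len(self.groups)


def rank_channels(w):
    """Rank channels by descending classifier weight per class.

    Returns rho of shape (C, K): rho[c] is the channel order for class c,
    ties broken by ascending channel index.
    """
    w = np.asarray(_raw(w), dtype=np.float64)
    if w.ndim != 2:
        raise ValueError("classifier weights must be (C, K)")
    if not np.all(np.isfinite(w)):
        raise ValueError("classifier weights must be finite")
    # stable sort on the negated weights keeps ascending index among ties
    return np.argsort(-w, axis=1, kind="stable")


def build_groups(rho, K, C):
    """Greedy disjoint grouping: one not-yet-assigned top channel per class.

    For m = 1..floor(K/C), group m takes, for each class c in order, that
    class's highest-ranked channel not already assigned.  Channels left over
    when C does not divide K are excluded from the loss.
    """
    rho = np.asarray(rho)
    if K < C:
        raise ValueError(f"need at least C={C} channels, got K={K}")
    if rho.shape != (C, K):
        raise ValueError("ranking shape must be (C, K)")
    n_groups = K // C
    taken = np.zeros(K, dtype=bool)
    cursors = [0] * C
    groups = []
    for _ in range(n_groups):
        grp = []
        for c in range(C):
            i = cursors[c]
            while taken[rho[c, i]]:
                i += 1
            ch = int(rho[c, i])
            taken[ch] = True
            cursors[c] = i + 1
            grp.append(ch)
        groups.append(grp)
    excluded = [int(k) for k in range(K) if not taken[k]]
    return ChannelGrouping(groups=groups, ranking=rho, excluded=excluded)


def fda_loss(F_bar, w, grouping=None):
    """Grouped whitening loss over classifier-weight-guided channel groups.

    For each sample n and group m, the group's C channels are each scaled by
    their classifier weight w[c, rho(c, m)], stacked, and their C x C
    channel covariance Sigma computed (population rule); the loss is
    (1/N) * sum_n sum_m ||Sigma - I||_1 with the entrywise L1 norm.

    Differentiable in both F_bar and w when given as tensors.  If
    ``grouping`` is omitted it is rebuilt from the current weights.
    """
    raw_f = _raw(F_bar)
    if raw_f.ndim != 4:
        raise ValueError("F_bar must be (N, K, H, W)")
    N, K = raw_f.shape[:2]
    C = _raw(w).shape[0]
    if grouping is None:
        grouping = build_groups(rank_channels(w), K, C)
    eye = np.eye(C, dtype=raw_f.dtype)
    total = None
    for grp in grouping.groups:
        idx = np.asarray(grp)
        if idx.max() >= K:
            raise ValueError("grouping references channel beyond K")
        wvec = w[(np.arange(C), idx)]
        sub = F_bar[:, idx] * _broadcast_w(wvec)
        cov = batched_channel_covariance(sub)
        term = abs(cov - eye).sum()
        total = term if total is None else total + term
    if total is None:
        raise ValueError("grouping has no groups")
    return total * (1.0 / N)


def _broadcast_w(wvec):
    """(C,) weights -> (1, C, 1, 1) for scaling stacked group channels."""
    if isinstance(wvec, Tensor):
        return wvec.reshape(1, -1, 1, 1)
    return np.asarray(wvec).reshape(1, -1, 1, 1)
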