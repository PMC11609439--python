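"""Image, mask and manifest I/O.

Masks are single-channel PNGs holding integer class ids (not colours) and
round-trip bit-exactly.  RGB images load as 8-bit; 16-bit TIFFs are accepted
and rescaled to 8-bit with a logged warning.  Manifests are CSV files with
one row per sample (image path, mask path, split, style id).
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = ["read_image", "write_image", "read_mask", "write_mask",
           "write_manifest", "read_manifest", "save_samples"]

log = logging.getLogger("unwseg")

MANIFEST_COLUMNS = ["image", "mask", "split", "style"]
_SPLITS = {"train", "val", "test"}


def read_image(path):
    """Load an RGB image as (H, W, 3) uint8."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype == np.uint16:
        log.warning("rescaling 16-bit image %s to 8-bit", path)
        arr = (arr.astype(np.float64) / 257.0).round().astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise ValueError(f"unsupported image dtype {arr.dtype} in {path}")
    return arr


def write_image(path, image):
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise ValueError("images are written as 8-bit")
    iio.imwrite(path, image)


def read_mask(path, n_classes=None):
    """Load an integer class mask; validate ids against ``n_classes``."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim != 2:
        raise ValueError(f"mask {path} is not single-channel")
    arr = arr.astype(np.int64)
    if n_classes is not None and arr.max() >= n_classes:
        bad = int(arr.max())
        raise ValueError(f"mask {path} contains class id {bad} >= "
                         f"C={n_classes}")
    return arr


def write_mask(path, mask):
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() > 255:
        raise ValueError("mask ids must fit in one byte")
    iio.imwrite(path, mask.astype(np.uint8))


def write_manifest(path, rows):
    """rows: iterable of dicts with the manifest columns."""
    df = pd.DataFrame(list(rows))
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest rows missing columns {sorted(missing)}")
    bad = set(df["split"]) - _SPLITS
    if bad:
        raise ValueError(f"unknown splits {sorted(bad)}")
    df[MANIFEST_COLUMNS + [c for c in df.columns
                           if c not in MANIFEST_COLUMNS]].to_csv(
        path, index=False)


def read_manifest(path, check_exists=True):
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    if check_exists:
        root = Path(path).parent
        for col in ("image", "mask"):
            for p in df[col]:
                q = Path(p)
                if not q.is_absolute():
                    q = root / q
                if not q.exists():
                    raise FileNotFoundError(f"manifest references missing "
                                            f"file {q}")
    return df


def save_samples(samples, out_dir, split="train", prefix="sample"):
    """Write image/mask PNG pairs plus manifest rows; returns the rows."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        img_p = out / f"{prefix}_{i:04d}.png"
        msk_p = out / f"{prefix}_{i:04d}_mask.png"
        write_image(img_p, s.image)
        write_mask(msk_p, s.mask)
        rows.append({"image": img_p.name, "mask": msk_p.name,
                     "split": split, "style": s.meta.get("style", ""),
                     "seed": s.meta.get("seed", "")})
    return rows


def load_samples(manifest_path, split=None, n_classes=2):
    """Read samples referenced by a manifest back into SegSample objects."""
    from .synthetic import SegSample

    df = read_manifest(manifest_path)
    if split is not None:
        df = df[df["split"] == split]
    root = Path(manifest_path).parent
    out = []
    for _, row in df.iterrows():
        img = read_image(root / row["image"])
        msk = read_mask(root / row["mask"], n_classes=n_classes)
        out.append(SegSample(image=img, mask=msk,
                             meta={"style": row.get("style", "")}))
    return out
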