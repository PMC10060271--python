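"""File-format plumbing: TIFF stacks, label masks, CSV tables.

Well image stacks are single multi-page TIFFs ordered frame-major,
channel-minor (channel order BF, blue, green). Label masks are 16-bit
TIFFs, one page per frame. Tables are comma-separated UTF-8 CSV with a
header row and '.' decimals.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .config import ValidationError
from .segmentation import LabeledMask
from .synthetic import WellImageSet

CHANNEL_ORDER = ("bf", "blue", "green")


def write_well_tiff(images: WellImageSet, path: str | Path) -> None:
    """Write a WellImageSet as one multi-page float32 TIFF."""
    pages = []
    for t in range(images.n_frames):
        for name in CHANNEL_ORDER:
            ch = getattr(images, name)
            if ch is not None:
                pages.append(ch[t].astype(np.float32))
    meta = {
        "well_id": images.well_id,
        "times_h": list(map(float, images.times_h)),
        "um_per_px": images.um_per_px,
        "channels": [c for c in CHANNEL_ORDER if getattr(images, c) is not None],
    }
    tifffile.imwrite(str(path), np.stack(pages), metadata=meta)


def read_well_tiff(path: str | Path) -> WellImageSet:
    """Read a stack written by :func:`write_well_tiff`."""
    path = Path(path)
    try:
        with tifffile.TiffFile(str(path)) as tf:
            data = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    except Exception as exc:
        raise ValidationError(f"{path}: TIFF parse error: {exc}") from exc
    channels = meta.get("channels", list(CHANNEL_ORDER))
    n_ch = len(channels)
    if data.shape[0] % n_ch:
        raise ValidationError(
            f"{path}: page count {data.shape[0]} not a multiple of {n_ch} channels"
        )
    n_frames = data.shape[0] // n_ch
    stacks = {name: data[i::n_ch] for i, name in enumerate(channels)}
    return WellImageSet(
        well_id=meta.get("well_id", path.stem),
        times_h=meta.get("times_h", list(range(n_frames))),
        bf=stacks["bf"],
        blue=stacks.get("blue"),
        green=stacks.get("green"),
        um_per_px=float(meta.get("um_per_px", 1.0)),
    )


def write_label_tiff(masks: list[LabeledMask], path: str | Path) -> None:
    """Write per-frame label masks as a 16-bit multi-page TIFF."""
    pages = []
    for m in masks:
        if m.labels.max() > np.iinfo(np.uint16).max:
            raise ValidationError("labels: object id exceeds 16-bit range")
        pages.append(m.labels.astype(np.uint16))
    tifffile.imwrite(str(path), np.stack(pages))


def read_label_tiff(path: str | Path, provenance: str = "truth") -> list[LabeledMask]:
    try:
        data = tifffile.imread(str(path))
    except Exception as exc:
        raise ValidationError(f"{path}: TIFF parse error: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    return [
        LabeledMask(labels=page.astype(np.int32), frame=t, provenance=provenance)
        for t, page in enumerate(data)
    ]


def write_overlay_png(bf: np.ndarray, mask: LabeledMask, path: str | Path) -> None:
    """Colored object overlay on the brightfield image, for QC at a glance."""
    from matplotlib import colormaps
    import imageio.v3 as iio

    base = np.clip(bf, 0, 1)
    rgb = np.stack([base] * 3, axis=-1)
    ids = mask.label_ids
    if len(ids):
        colors = colormaps["tab20"](np.linspace(0, 1, len(ids)))[:, :3]
        for color, k in zip(colors, ids):
            sel = mask.labels == k
            rgb[sel] = 0.5 * rgb[sel] + 0.5 * color
    iio.imwrite(str(path), (rgb * 255).astype(np.uint8))
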