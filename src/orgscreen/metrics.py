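"""Per-well kinetic metrics from masks and fluorescence channels.

Reduces each (frame, mask, channels) triple to the well-level metric
vector used downstream: object count, mean and total mask area (µm²),
green-overlap area and background-subtracted green intensity (RFU), the
intra-well normalized ratios green_area_ratio and green_intensity_ratio,
the viable area (total mask area − green area), and per-well fold changes
from the first frame (T0).

Undefined ratios (empty wells, zero denominators) are flagged, never
silently zeroed; downstream fits drop flagged points.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ValidationError
from .segmentation import LabeledMask
from .synthetic import WellImageSet

GREEN_THRESHOLD = 0.3  # intensity cut for green-positive pixels


def compute_well_metrics(
    images: WellImageSet,
    masks: list[LabeledMask],
    green_threshold: float = GREEN_THRESHOLD,
) -> pd.DataFrame:
    """Per-frame well metrics for one well.

    Returns a DataFrame with one row per frame. Green metrics are
    0-filled with ``green_missing=True`` when the image set has no green
    channel. Green intensity is background-subtracted using the median of
    out-of-mask pixels before summation.
    """
    if len(masks) != images.n_frames:
        raise ValidationError(
            f"masks: {len(masks)} frames but images have {images.n_frames}"
        )
    scale = images.um_per_px**2
    rows = []
    for t, mask in enumerate(masks):
        if mask.labels.shape != images.bf.shape[1:]:
            raise ValidationError(
                f"masks: frame {t} shape {mask.labels.shape} != image {images.bf.shape[1:]}"
            )
        fg = mask.foreground()
        count = mask.n_objects
        total_area = float(fg.sum()) * scale
        mean_area = total_area / count if count else 0.0

        green_missing = images.green is None
        if green_missing:
            green_area = 0.0
            green_intensity = 0.0
        else:
            g = images.green[t]
            gpos = (g > green_threshold) & fg
            green_area = float(gpos.sum()) * scale
            bg = float(np.median(g[~fg])) if (~fg).any() else 0.0
            green_intensity = float(np.clip(g[fg] - bg, 0.0, None).sum())

        undefined = total_area <= 0
        rows.append(
            {
                "well_id": images.well_id,
                "frame": t,
                "time_h": images.times_h[t],
                "count": count,
                "mean_mask_area_um2": mean_area,
                "total_mask_area_um2": total_area,
                "total_green_area_um2": green_area,
                "total_green_intensity_rfu": green_intensity,
                "green_area_ratio": green_area / total_area if not undefined else np.nan,
                "green_intensity_ratio": green_intensity / total_area
                if not undefined
                else np.nan,
                "viable_area_um2": max(total_area - green_area, 0.0),
                "undefined_ratio": undefined,
                "green_missing": green_missing,
            }
        )
    df = pd.DataFrame(rows)
    return df


def fold_change(ts: pd.DataFrame, metric: str) -> pd.Series:
    """Per-well fold change of a metric column relative to the first frame.

    NaN where the T0 value is not positive (flagged, not zero-filled).
    """
    if metric not in ts.columns:
        raise ValidationError(f"metric: unknown column {metric!r}")
    out = []
    for _, grp in ts.groupby("well_id", sort=False):
        grp = grp.sort_values("frame")
        t0 = grp[metric].iloc[0]
        fc = grp[metric] / t0 if t0 > 0 else pd.Series(np.nan, index=grp.index)
        out.append(fc)
    return pd.concat(out).reindex(ts.index)


def growth_rate_series(ts: pd.DataFrame, metric: str = "total_mask_area_um2") -> dict:
    """Per-interval log2 growth rates of one well's metric series.

    Returns per-interval log2 fold changes (log2 units/frame), the same
    rates per hour, and their averages. The series is undefined-flagged
    when the metric is not positive at T0.
    """
    if metric not in ts.columns:
        raise ValidationError(f"metric: unknown column {metric!r}")
    grp = ts.sort_values("frame")
    values = grp[metric].to_numpy(dtype=float)
    times = grp["time_h"].to_numpy(dtype=float)
    if values[0] <= 0:
        return {"undefined": True, "per_interval_log2": [], "per_hour": [],
                "mean_log2_per_interval": np.nan, "mean_log2_per_hour": np.nan}
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = values[1:] / values[:-1]
        per_interval = np.log2(ratios)
    dt = np.diff(times)
    per_hour = per_interval / dt
    return {
        "undefined": False,
        "per_interval_log2": per_interval.tolist(),
        "per_hour": per_hour.tolist(),
        "mean_log2_per_interval": float(np.nanmean(per_interval)),
        "mean_log2_per_hour": float(np.nanmean(per_hour)),
    }


def to_long_format(ts: pd.DataFrame) -> pd.DataFrame:
    """Wide per-frame metrics -> long (well, frame, time_h, metric, value)."""
    value_cols = [
        c for c in ts.columns if c not in ("well_id", "frame", "time_h")
        and ts[c].dtype != bool
    ]
    return ts.melt(
        id_vars=["well_id", "frame", "time_h"],
        value_vars=value_cols,
        var_name="metric",
        value_name="value",
    )
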