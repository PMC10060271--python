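"""End-to-end pipeline: simulate → segment → track → metrics → response.

Each stage writes its outputs before the next begins, so a failure
retains partial results; stage failures surface as :class:`StageError`
naming the stage. Re-running with an identical config reproduces
byte-identical CSV outputs (classical backend).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PlateMap, RunConfig, ValidationError
from .fcn import SegModel, segment_fcn, train_seg_model
from .io import write_label_tiff, write_well_tiff
from .metrics import compute_well_metrics, fold_change, to_long_format
from .response import (
    FitError,
    classify_response,
    fit_4pl,
    gr_metric,
    ndr_metric,
    normalize_viability,
    z_factor,
)
from .segmentation import fluorescence_ground_truth, segment_classical
from .synthetic import render_well_stack, simulate_plate
from .tracking import track_objects

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _geomean(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values) & (values > 0)]
    if values.size == 0:
        return float("nan")
    return float(np.exp(np.mean(np.log(values))))


def run_pipeline(config: RunConfig, write_images: bool = False) -> dict:
    """Execute the full pipeline and write the result bundle.

    Returns a dict with the key tables (metrics, fits, response) and the
    paths written. The simulation stage runs whenever ``images_dir`` is
    not set; with ``write_images=True`` the rendered stacks and truth
    masks are also saved as TIFFs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    # ---- plate map (validated before any computation)
    try:
        if config.plate_map_path is None:
            raise ValidationError("plate_map_path: plate map is required")
        pmap = PlateMap.read_csv(config.plate_map_path)
        pmap.validate_for_format(config.simulation.plate_format)
    except Exception as exc:
        raise StageError("plate_map", exc) from exc

    manifest = {
        "seed": config.seed,
        "simulation_seed": config.simulation.seed,
        "backend": config.backend,
        "metric": config.metric,
        "config_echo": config.simulation.to_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    # ---- simulate + render
    try:
        truth = simulate_plate(config.simulation, pmap)
        truth.per_well_expected.to_csv(out / "truth_per_well.csv", index=False)
        truth.states.to_csv(out / "truth_states.csv", index=False)
        stacks = {}
        for well in pmap.wells:
            images, tmasks = render_well_stack(truth, well)
            stacks[well] = (images, tmasks)
            if write_images:
                write_well_tiff(images, out / f"{well}.tif")
                write_label_tiff(
                    [m for m in _as_masks(tmasks)], out / f"{well}_truth_labels.tif"
                )
    except Exception as exc:
        raise StageError("simulate", exc) from exc

    # ---- segment
    try:
        model: SegModel | None = None
        if config.backend == "fcn":
            pairs = []
            for well in pmap.wells[: max(4, len(pmap.wells) // 4)]:
                images, _ = stacks[well]
                for t in range(images.n_frames):
                    gt = fluorescence_ground_truth(images.blue[t], images.green[t])
                    pairs.append((images.bf[t], gt))
            model = train_seg_model(pairs, seed=config.seed)
        masks_by_well = {}
        for well in pmap.wells:
            images, _ = stacks[well]
            frames = []
            for t in range(images.n_frames):
                if config.backend == "fcn":
                    frames.append(
                        segment_fcn(images.bf[t], model, frame=t,
                                    params=config.segmentation_params)
                    )
                else:
                    frames.append(
                        segment_classical(images.bf[t], config.segmentation_params,
                                          frame=t)
                    )
            masks_by_well[well] = frames
    except Exception as exc:
        raise StageError("segment", exc) from exc

    # ---- track
    try:
        for well in pmap.wells:
            graph = track_objects(masks_by_well[well])
            graph.to_json(out / f"{well}_tracks.json")
    except Exception as exc:
        raise StageError("track", exc) from exc

    # ---- metrics
    try:
        tables = []
        for well in pmap.wells:
            images, _ = stacks[well]
            tables.append(compute_well_metrics(images, masks_by_well[well]))
        metrics = pd.concat(tables, ignore_index=True)
        to_long_format(metrics).to_csv(out / "metrics.csv", index=False)
    except Exception as exc:
        raise StageError("metrics", exc) from exc

    # ---- response
    try:
        fits_df, response_df, quality = analyze_response(
            metrics, pmap, metric=config.metric, endpoint_time_h=config.endpoint_time_h
        )
        fits_df.to_csv(out / "fits.csv", index=False)
        response_df.to_csv(out / "response.csv", index=False)
        (out / "quality.json").write_text(json.dumps(quality, indent=2))
    except Exception as exc:
        raise StageError("response", exc) from exc

    return {
        "metrics": metrics,
        "fits": fits_df,
        "response": response_df,
        "quality": quality,
        "output_dir": str(out),
        "truth": truth,
    }


def _as_masks(label_arrays):
    from .segmentation import LabeledMask

    return [
        LabeledMask(labels=a.astype(np.int32), frame=t, provenance="truth")
        for t, a in enumerate(label_arrays)
    ]


def analyze_response(
    metrics: pd.DataFrame,
    pmap: PlateMap,
    metric: str = "viable_area_um2",
    endpoint_time_h: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Drug-response tables from well metrics and the plate map.

    Per-well fold changes of ``metric`` from T0 to the endpoint feed the
    GR/NDR metrics (control replicates pooled by geometric mean); raw
    endpoint values normalized to vehicle (100%) / positive (0%) feed one
    4PL fit per drug. Returns (fits, per-well response, quality) where
    quality carries the plate Z-factor on the endpoint metric.
    """
    if endpoint_time_h is None:
        endpoint_time_h = metrics["time_h"].max()
    times = metrics["time_h"].unique()
    endpoint = times[np.argmin(np.abs(times - endpoint_time_h))]

    fc = fold_change(metrics, metric)
    metrics = metrics.assign(_fc=fc)
    end = metrics[metrics["time_h"] == endpoint].set_index("well_id")
    roles = pmap.table.set_index("well_id")

    def wells_of(role):
        return [w for w in roles.index[roles["role"] == role] if w in end.index]

    veh_wells = wells_of("vehicle")
    pos_wells = wells_of("positive")
    fc_vehicle = _geomean(end.loc[veh_wells, "_fc"].to_numpy()) if veh_wells else np.nan
    fc_positive = _geomean(end.loc[pos_wells, "_fc"].to_numpy()) if pos_wells else np.nan

    response_rows = []
    for well, row in roles.iterrows():
        if row["role"] not in ("treated",) or well not in end.index:
            continue
        fc_t = float(end.loc[well, "_fc"])
        rec = {
            "well_id": well, "drug": row["drug"], "concentration": row["concentration"],
            "endpoint_time_h": endpoint, "fc_treated": fc_t,
            "fc_vehicle": fc_vehicle, "fc_positive": fc_positive,
            "gr": np.nan, "ndr": np.nan, "classification": None,
        }
        try:
            rec["gr"] = gr_metric(fc_t, fc_vehicle)
            rec["classification"] = classify_response(rec["gr"])
        except ValidationError:
            pass
        try:
            rec["ndr"] = ndr_metric(fc_t, fc_vehicle, fc_positive)
            rec["classification"] = classify_response(rec["ndr"])
        except ValidationError:
            pass
        response_rows.append(rec)
    response_df = pd.DataFrame(response_rows)

    # per-well fold change from T0 is the intra-well normalization: it
    # cancels seeding differences before any cross-well comparison
    veh_vals = end.loc[veh_wells, "_fc"].to_numpy() if veh_wells else np.array([])
    pos_vals = end.loc[pos_wells, "_fc"].to_numpy() if pos_wells else np.array([])

    fit_rows = []
    if len(response_df):
        for drug, grp in response_df.groupby("drug"):
            conc = grp["concentration"].to_numpy(dtype=float)
            raw = grp["fc_treated"].to_numpy(dtype=float)
            if len(veh_vals) and len(pos_vals):
                resp = normalize_viability(raw, veh_vals, pos_vals, "vehicle+baseline")
            elif len(veh_vals):
                resp = normalize_viability(raw, veh_vals, mode="vehicle-only")
            else:
                continue
            try:
                fit = fit_4pl(conc, resp, direction="inhibitory")
            except FitError as exc:
                logger.warning("4PL fit skipped for %s: %s", drug, exc)
                continue
            fit_rows.append(
                {"drug": drug, "top": fit.top, "bottom": fit.bottom, "hill": fit.hill,
                 "log_ic50": fit.log_ic50, "ic50_molar": fit.ic50,
                 "ic50_um": fit.ic50 * 1e6, "rss": fit.rss, "df": fit.df,
                 "n_points": fit.n_points, "degenerate": fit.degenerate}
            )
    fits_df = pd.DataFrame(
        fit_rows,
        columns=["drug", "top", "bottom", "hill", "log_ic50", "ic50_molar", "ic50_um",
                 "rss", "df", "n_points", "degenerate"],
    )

    quality = {"endpoint_time_h": float(endpoint), "metric": f"{metric} fold change"}
    if len(veh_vals) >= 2 and len(pos_vals) >= 2:
        try:
            quality["z_factor"] = z_factor(veh_vals, pos_vals)
        except ValidationError:
            quality["z_factor"] = None
    return fits_df, response_df, quality
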