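"""End-to-end convenience: detections → sync → locate → QC → swim → summary."""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import box

from . import behaviorstats, clocksync, multilat, swimvec, trackqc
from .hydrofield import VelocityField
from .synthgen import ScenarioConfig


def default_region(config: ScenarioConfig, array: pd.DataFrame, pad: float = 40.0):
    """Rectangular analysis region spanning the receiver array plus a pad."""
    return box(
        array["x"].min() - pad,
        0.0,
        array["x"].max() + pad,
        config.channel.width_m,
    )


def run_pipeline(
    scenario: dict,
    config: ScenarioConfig,
    knot_interval: float = 3600.0,
    vranges=("top1m", "top2m", "full"),
    qc: trackqc.QCConfig | None = None,
    n_boot: int = 500,
    seed: int = 0,
) -> dict:
    """Run the full analysis on one generated scenario.

    Returns a dict with the sync solutions, fixes, kept fixes, swim
    records (weighted), and per-vertical-range summaries.
    """
    array = scenario["array"]
    detections = scenario["detections"]
    field: VelocityField = scenario["field"]

    sols = clocksync.solve_sync(
        detections,
        array,
        knot_interval=knot_interval,
        sound_speed=config.sound_speed_ms,
    )
    model = clocksync.merge_models(sols)
    corrected = clocksync.apply_sync(detections, model)

    loc_cfg = multilat.LocateConfig(
        sound_speed=config.sound_speed_ms,
        tag_depth=config.tag_depth_m,
        noise_floor_s=max(config.arrival_noise_sd_s, 1e-6),
    )
    fixes = multilat.locate_all(corrected, array, loc_cfg)

    if qc is None:
        qc = trackqc.QCConfig(region=default_region(config, array))
    kept, rejections = trackqc.apply_qc(fixes, qc)

    records = swimvec.track_swim_records(
        kept, field, vranges=vranges, max_gap=4 * config.pri_s
    )
    predator_tags = []
    if not records.empty:
        for tag, g in records[records["vrange"] == "top2m"].groupby("tag_id"):
            ok, spd = trackqc.flag_predator_by_speed(g, qc)
            if not ok:
                predator_tags.append(tag)
        records = records[~records["tag_id"].isin(predator_tags)]
        records = behaviorstats.segment_weights(records)
    summaries = (
        behaviorstats.summarize_records(records, n_boot=n_boot, seed=seed)
        if not records.empty
        else []
    )
    return {
        "sync_solutions": sols,
        "clock_model": model,
        "fixes": fixes,
        "kept_fixes": kept,
        "qc_rejections": rejections,
        "predator_tags": predator_tags,
        "records": records,
        "summaries": summaries,
    }
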