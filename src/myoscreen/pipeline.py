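"""Stage composition: images -> per-field rows -> per-well indices -> scores.

The pipeline mirrors the screen's flow: quantify every field (muscle area,
puncta area, index), aggregate fields to wells, normalize wells per plate
against the lacZ median, score amplicons by UMVUE SSMD and call genes.
Composition here equals stage-by-stage invocation; no hidden state.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .imaging import (
    GranularityParams,
    ImageField,
    MuscleSegParams,
    autophagy_index,
    detect_puncta_granularity,
    segment_muscle,
)
from .screen import HitThresholds, call_genes, normalize_plate, score_amplicons
from .simulate import FieldSimConfig, ScreenSimConfig, simulate_field, simulate_screen

logger = logging.getLogger(__name__)

__all__ = [
    "quantify_field",
    "quantify_fields",
    "aggregate_wells",
    "score_well_table",
    "simulate_quantified_screen",
]

FIELD_ROW_COLUMNS = [
    "field_id", "plate_id", "well", "n_muscles",
    "muscle_area", "puncta_area", "index", "n_puncta",
]


def quantify_field(
    field: ImageField,
    seg_params: MuscleSegParams | None = None,
    gran_params: GranularityParams | None = None,
) -> dict:
    """One field -> muscle area, puncta area and autophagy index.

    Fields without any detected muscle get ``index = NaN`` and are excluded
    at aggregation (logged there).
    """
    muscle = segment_muscle(field, seg_params)
    if muscle.total_area == 0:
        return {
            "field_id": field.field_id, "plate_id": field.plate_id,
            "well": field.well_id, "n_muscles": 0, "muscle_area": 0,
            "puncta_area": 0, "index": np.nan, "n_puncta": 0,
        }
    puncta = detect_puncta_granularity(field, muscle, gran_params)
    return {
        "field_id": field.field_id,
        "plate_id": field.plate_id,
        "well": field.well_id,
        "n_muscles": muscle.n_muscles,
        "muscle_area": muscle.total_area,
        "puncta_area": puncta.total_area,
        "index": autophagy_index(puncta, muscle),
        "n_puncta": len(puncta),
    }


def quantify_fields(fields, seg_params=None, gran_params=None) -> pd.DataFrame:
    rows = [quantify_field(f, seg_params, gran_params) for f in fields]
    return pd.DataFrame.from_records(rows, columns=FIELD_ROW_COLUMNS)


def aggregate_wells(field_rows: pd.DataFrame, mode: str = "pooled") -> pd.DataFrame:
    """Combine a well's fields into one autophagy index.

    ``pooled`` (default): sum of puncta areas / sum of muscle areas across
    the well's fields — robust to fields with little muscle.  ``mean``:
    unweighted mean of per-field indices.  Fields with zero muscle are
    excluded (logged).
    """
    if mode not in ("pooled", "mean"):
        raise ValueError("mode must be 'pooled' or 'mean'")
    usable = field_rows[field_rows.muscle_area > 0]
    dropped = len(field_rows) - len(usable)
    if dropped:
        logger.info("excluding %d fields with zero muscle area", dropped)
    records = []
    for (plate_id, well), grp in usable.groupby(["plate_id", "well"], sort=False):
        if mode == "pooled":
            idx = grp.puncta_area.sum() / grp.muscle_area.sum()
        else:
            idx = grp["index"].mean()
        records.append(
            {
                "plate_id": plate_id,
                "well": well,
                "n_fields": len(grp),
                "muscle_area": int(grp.muscle_area.sum()),
                "puncta_area": int(grp.puncta_area.sum()),
                "index": float(idx),
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=["plate_id", "well", "n_fields", "muscle_area", "puncta_area", "index"],
    )


def score_well_table(
    wells: pd.DataFrame,
    thresholds: HitThresholds | None = None,
    min_neg_wells: int = 4,
    zero_policy: str = "epsilon",
    min_replicates: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Well table -> (normalized wells, amplicon scores, gene calls)."""
    wells_d = normalize_plate(wells, min_neg_wells=min_neg_wells, zero_policy=zero_policy)
    scores = score_amplicons(wells_d, min_replicates=min_replicates)
    calls = call_genes(scores, thresholds)
    return wells_d, scores, calls


def simulate_quantified_screen(
    screen_config: ScreenSimConfig,
    field_config: FieldSimConfig | None = None,
    fields_per_well: int = 1,
    base_autophagy_level: float = 1.0,
    seg_params: MuscleSegParams | None = None,
    gran_params: GranularityParams | None = None,
) -> pd.DataFrame:
    """Image-level end-to-end simulation of a screen.

    For every non-empty well a field image is rendered with
    ``autophagy_level = base_autophagy_level * theta_g * pi_r * eps`` (the
    well's multiplicative truth from :func:`simulate_screen`), quantified
    with the imaging stage, and aggregated to a measured per-well index.
    Returns a well table whose ``index`` column is the *measured* index,
    ready for :func:`score_well_table`.
    """
    field_config = field_config or FieldSimConfig()
    layout, _truth = simulate_screen(screen_config)
    seed_root = np.random.SeedSequence([screen_config.seed, 0x51534E]).generate_state(1)[0]

    records = []
    for i, row in enumerate(layout.itertuples()):
        if row.role == "empty":
            continue
        level = base_autophagy_level * row.true_level
        cfg = replace(
            field_config,
            autophagy_level=level,
            seed=int((seed_root + i) % np.iinfo(np.int32).max),
        )
        frames = []
        for j in range(fields_per_well):
            fcfg = cfg if j == 0 else replace(cfg, seed=cfg.seed + 7919 * j)
            field, _ = simulate_field(fcfg)
            field.field_id = f"{row.plate_id}_{row.well}_f{j}"
            field.plate_id, field.well_id = row.plate_id, row.well
            frames.append(quantify_field(field, seg_params, gran_params))
        field_rows = pd.DataFrame.from_records(frames, columns=FIELD_ROW_COLUMNS)
        agg = aggregate_wells(field_rows)
        if len(agg) == 0:
            logger.warning(
                "well %s/%s had no usable fields; excluded", row.plate_id, row.well
            )
            continue
        records.append(
            {
                "plate_id": row.plate_id,
                "well": row.well,
                "amplicon_id": row.amplicon_id,
                "gene": row.gene,
                "role": row.role,
                "index": float(agg["index"].iloc[0]),
                "true_level": row.true_level,
            }
        )
    return pd.DataFrame.from_records(records)
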