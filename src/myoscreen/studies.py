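"""Repeated-simulation studies of the scoring pipeline's operating behavior.

These drive the simulators through the full scoring stack many times to
measure control calibration (how null lacZ-like and strong-suppressor
Atg18-like amplicons score) and hit recovery (sensitivity / false-positive
rate of the two-tier gene calls), the quantities a screener would check
before trusting a screen.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .pipeline import simulate_quantified_screen
from .screen import HitThresholds, call_genes, normalize_plate, score_amplicons
from .simulate import FieldSimConfig, ScreenSimConfig, simulate_screen

__all__ = ["control_score_study", "endtoend_recovery_study"]


def control_score_study(
    n_runs: int = 100,
    base_seed: int = 0,
    n_null_genes: int = 150,
    config: ScreenSimConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Score simulated screens repeatedly; return control and null scores.

    Each run simulates a fresh screen (3 replicate 384-well plates by
    default, theta = 1 for every scored sample amplicon, a strong-suppressor
    positive-control amplicon, lognormal plate and well noise), normalizes
    per plate against the negative-control median and scores every amplicon
    with the UMVUE SSMD.

    Returns
    -------
    pos_scores : (n_runs,) array
        The positive-control amplicon's score in each run.
    null_scores : flat array
        Scores of every theta = 1 sample amplicon, pooled over runs.
    """
    base = config or ScreenSimConfig(
        gene_effect_map={f"null{i:03d}": 1.0 for i in range(n_null_genes)},
        n_plates=3,
        sigma_plate=0.1,
        sigma_well=0.2,
        n_neg_wells=16,
        n_pos_wells=8,
        pos_control_theta=0.1,
    )
    seeds = np.random.SeedSequence(base_seed).generate_state(n_runs) % np.int64(2**31)
    pos_scores, null_scores = [], []
    for seed in seeds:
        wells, _ = simulate_screen(replace(base, seed=int(seed)))
        scores = score_amplicons(normalize_plate(wells))
        pos_scores.append(float(scores.loc[scores.role == "pos_ctrl", "ssmd"].iloc[0]))
        null_scores.append(scores.loc[scores.role == "sample", "ssmd"].to_numpy())
    return np.asarray(pos_scores), np.concatenate(null_scores)


def endtoend_recovery_study(
    n_seeds: int = 20,
    base_seed: int = 0,
    theta_suppressor: float = 0.3,
    theta_enhancer: float = 3.0,
    n_planted_each: int = 4,
    n_null_genes: int = 12,
    field_config: FieldSimConfig | None = None,
    base_autophagy_level: float = 2.0,
    thresholds: HitThresholds | None = None,
) -> dict:
    """Image-level parameter recovery of planted suppressors and enhancers.

    For each seed a full screen is simulated down to the pixel level: every
    well's field image is rendered at its true autophagy level, quantified
    (segmentation + puncta detection), aggregated, normalized and scored,
    and genes are called with the two-tier rule.  Sensitivity counts
    planted genes recovered in the correct direction (either tier);
    the false-positive rate counts null genes called in any direction.
    """
    effects = {f"sup{i:02d}": theta_suppressor for i in range(n_planted_each)}
    effects |= {f"enh{i:02d}": theta_enhancer for i in range(n_planted_each)}
    effects |= {f"null{i:02d}": 1.0 for i in range(n_null_genes)}
    field_config = field_config or FieldSimConfig(
        canvas_size=(176, 176),
        n_muscles=2,
        muscle_length_range=(60.0, 100.0),
        n_nonmuscle_cells=10,
    )
    screen_base = ScreenSimConfig(
        gene_effect_map=effects,
        wells_per_plate=96,
        n_neg_wells=8,
        n_pos_wells=4,
        n_plates=3,
        sigma_plate=0.1,
        sigma_well=0.15,
    )
    seeds = np.random.SeedSequence(base_seed).generate_state(n_seeds) % np.int64(2**31)

    tp = fn = fp = tn = 0
    wrong_direction = 0
    for seed in seeds:
        wells = simulate_quantified_screen(
            replace(screen_base, seed=int(seed)),
            field_config,
            base_autophagy_level=base_autophagy_level,
        )
        scores = score_amplicons(normalize_plate(wells))
        calls = call_genes(scores, thresholds).set_index("gene")
        for gene in effects:
            direction = calls.loc[gene, "direction"] if gene in calls.index else "none"
            if gene.startswith("sup"):
                tp += direction == "positive_regulator"
                fn += direction != "positive_regulator"
                wrong_direction += direction == "negative_regulator"
            elif gene.startswith("enh"):
                tp += direction == "negative_regulator"
                fn += direction != "negative_regulator"
                wrong_direction += direction == "positive_regulator"
            else:
                fp += direction != "none"
                tn += direction == "none"
    return {
        "sensitivity": tp / (tp + fn),
        "false_positive_rate": fp / (fp + tn),
        "wrong_direction": wrong_direction,
        "n_planted": tp + fn,
        "n_null": fp + tn,
    }
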