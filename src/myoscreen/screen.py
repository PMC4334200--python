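"""Per-amplicon SSMD scoring and two-tier gene hit calling.

The scoring follows the screen's scheme: per-well autophagy indices are
log-transformed and referenced to the median of the plate's negative-control
(lacZ-like) wells, giving a per-well log fold change ``d``.  Each amplicon's
replicate ``d`` values (one per plate; duplicate wells within a plate are
averaged on the log scale first) are summarized by the UMVUE of the strictly
standardized mean difference,

    SSMD = c(n) * mean(d) / sd(d),
    c(n) = Gamma((n-1)/2) / Gamma((n-2)/2) * sqrt(2 / (n-1)),

with the sample standard deviation (n-1 denominator).  A *negative* score
means knockdown suppressed puncta formation, i.e. the gene is a positive
autophagy regulator.

Gene calls use two tiers: "multi" when two or more amplicons pass |SSMD| >=
0.5 in the same direction, "single" when exactly one amplicon passes
|SSMD| >= 1.0 and no other amplicon passes 0.5 in the opposite direction.
Threshold ties count as passing.  No multiple-testing correction is applied;
hits are called by SSMD thresholds alone.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "WELL_COLUMNS",
    "HitThresholds",
    "CallSummary",
    "normalize_plate",
    "ssmd_umvue",
    "ssmd_correction_factor",
    "score_amplicons",
    "call_genes",
    "summarize_calls",
    "compare_groups",
    "control_qc",
]

WELL_COLUMNS = ["plate_id", "well", "amplicon_id", "gene", "role", "index"]

DIRECTION_POSITIVE = "positive_regulator"
DIRECTION_NEGATIVE = "negative_regulator"
DIRECTION_NONE = "none"


@dataclass(frozen=True)
class HitThresholds:
    """|SSMD| cutoffs of the two evidence tiers (inclusive)."""

    multi_amplicon: float = 0.5
    single_amplicon: float = 1.0

    def validate(self) -> None:
        if not (self.single_amplicon >= self.multi_amplicon > 0):
            raise ValueError("thresholds must satisfy single >= multi > 0")


class CallSummary(NamedTuple):
    positive_regulators: int
    negative_regulators: int
    uncalled: int


def normalize_plate(
    wells: pd.DataFrame,
    min_neg_wells: int = 4,
    zero_policy: str = "epsilon",
) -> pd.DataFrame:
    """Per-well normalized log differences against the plate's lacZ median.

    Adds a column ``d = log(index) - median(log(index) over neg_ctrl)`` per
    plate.  Negative-control wells get their own ``d``.  Wells with a zero
    index are offset by ``eps = (smallest positive index on the plate) *
    1e-3`` (``zero_policy='epsilon'``) or dropped (``'drop'``); either way
    the event is logged.  Plates with fewer than ``min_neg_wells`` positive
    negative-control wells are rejected with a logged message; if every
    plate is rejected a ValueError is raised.  Empty wells are excluded.
    """
    missing = [c for c in WELL_COLUMNS if c not in wells.columns]
    if missing:
        raise ValueError(f"well table lacks columns {missing}")
    if zero_policy not in ("epsilon", "drop"):
        raise ValueError("zero_policy must be 'epsilon' or 'drop'")
    wells = wells[wells.role != "empty"].copy()
    if (wells["index"] < 0).any():
        raise ValueError("autophagy indices must be >= 0")

    out_frames = []
    for plate_id, plate in wells.groupby("plate_id", sort=False):
        neg = plate[(plate.role == "neg_ctrl") & (plate["index"] > 0)]
        if len(neg) < min_neg_wells:
            logger.warning(
                "plate %s rejected: %d usable negative-control wells (< %d)",
                plate_id, len(neg), min_neg_wells,
            )
            continue
        positive = plate.loc[plate["index"] > 0, "index"]
        zeros = plate["index"] == 0
        if zeros.any():
            if zero_policy == "drop":
                logger.info(
                    "plate %s: dropping %d zero-index wells", plate_id, int(zeros.sum())
                )
                plate = plate[~zeros].copy()
            else:
                eps = float(positive.min()) * 1e-3
                logger.info(
                    "plate %s: offsetting %d zero-index wells by eps=%.3g",
                    plate_id, int(zeros.sum()), eps,
                )
                plate = plate.copy()
                plate.loc[zeros, "index"] = plate.loc[zeros, "index"] + eps
        neg_median = float(np.median(np.log(neg["index"].to_numpy())))
        plate = plate.copy()
        plate["d"] = np.log(plate["index"].to_numpy()) - neg_median
        out_frames.append(plate)
    if not out_frames:
        raise ValueError("no plate has enough usable negative-control wells")
    return pd.concat(out_frames, ignore_index=True)


def ssmd_correction_factor(n: int) -> float:
    """UMVUE correction c(n) = Gamma((n-1)/2)/Gamma((n-2)/2) * sqrt(2/(n-1))."""
    if n < 3:
        raise ValueError("correction factor defined for n >= 3")
    return math.exp(gammaln((n - 1) / 2.0) - gammaln((n - 2) / 2.0)) * math.sqrt(
        2.0 / (n - 1)
    )


def ssmd_umvue(d: Sequence[float] | np.ndarray) -> float:
    """UMVUE of the SSMD from per-replicate normalized differences.

    Unbiased for the population mean/sd ratio under normality; requires at
    least three replicates and non-degenerate spread.
    """
    d = np.asarray(d, dtype=float)
    n = d.size
    if n < 3:
        raise ValueError(f"insufficient replicates for SSMD: n={n} < 3")
    s = float(d.std(ddof=1))
    m = float(d.mean())
    if s == 0.0:
        raise ValueError(
            f"zero replicate standard deviation (sign(mean) = {int(np.sign(m))})"
        )
    return ssmd_correction_factor(n) * m / s


def score_amplicons(
    wells_d: pd.DataFrame,
    min_replicates: int = 3,
    include_controls: bool = True,
) -> pd.DataFrame:
    """Per-amplicon SSMD over replicate plates.

    Expects the output of :func:`normalize_plate` (a ``d`` column).
    Duplicate wells of one amplicon within a plate are averaged on the log
    scale first; amplicons present on fewer than ``min_replicates`` plates
    are excluded with a logged message.
    """
    if "d" not in wells_d.columns:
        raise ValueError("wells table lacks 'd'; run normalize_plate first")
    df = wells_d[wells_d.role != "empty"]
    if not include_controls:
        df = df[df.role == "sample"]

    records = []
    for amp, grp in df.groupby("amplicon_id", sort=False):
        per_plate = grp.groupby("plate_id")["d"].mean()
        n = len(per_plate)
        if n < min_replicates:
            logger.warning(
                "amplicon %s excluded: %d replicate plates (< %d)", amp, n, min_replicates
            )
            continue
        d = per_plate.to_numpy()
        records.append(
            {
                "amplicon_id": amp,
                "gene": grp.gene.iloc[0],
                "role": grp.role.iloc[0],
                "n": n,
                "mean_d": float(d.mean()),
                "ssmd": ssmd_umvue(d),
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["amplicon_id", "gene", "role", "n", "mean_d", "ssmd"]
    )


def _call_one_gene(
    amps: Sequence[str], scores: np.ndarray, th: HitThresholds
) -> tuple[str, str, list[str], bool]:
    """Direction, tier, supporting amplicons and ambiguity flag for one gene."""
    scores = np.asarray(scores, dtype=float)
    neg_q = scores <= -th.multi_amplicon
    pos_q = scores >= th.multi_amplicon
    supporting: list[str] = []

    if neg_q.sum() >= 2 and pos_q.sum() >= 2:
        return DIRECTION_NONE, "none", supporting, True
    if neg_q.sum() >= 2:
        supporting = [a for a, q in zip(amps, neg_q) if q]
        return DIRECTION_POSITIVE, "multi", supporting, False
    if pos_q.sum() >= 2:
        supporting = [a for a, q in zip(amps, pos_q) if q]
        return DIRECTION_NEGATIVE, "multi", supporting, False

    strong = np.abs(scores) >= th.single_amplicon
    if strong.sum() == 1:
        i = int(np.flatnonzero(strong)[0])
        sign = np.sign(scores[i])
        opposite = (np.abs(scores) >= th.multi_amplicon) & (np.sign(scores) == -sign)
        opposite[i] = False
        if not opposite.any():
            direction = DIRECTION_POSITIVE if sign < 0 else DIRECTION_NEGATIVE
            return direction, "single", [amps[i]], False
        return DIRECTION_NONE, "none", [], False
    # zero strong scores, or several strong scores in opposite directions
    ambiguous = strong.sum() >= 2
    return DIRECTION_NONE, "none", [], ambiguous


def call_genes(
    scores: pd.DataFrame,
    thresholds: HitThresholds | None = None,
    include_controls: bool = False,
) -> pd.DataFrame:
    """Two-tier per-gene hit calls from an amplicon score table.

    The call depends only on the *set* of a gene's scores, never on their
    order, and making a qualifying score more extreme never removes a hit.
    Genes qualifying "multi" in both directions simultaneously are called
    ``none`` and flagged ambiguous.
    """
    thresholds = thresholds or HitThresholds()
    thresholds.validate()
    for col in ("amplicon_id", "gene", "ssmd"):
        if col not in scores.columns:
            raise ValueError(f"score table lacks column {col!r}")
    df = scores
    if not include_controls and "role" in df.columns:
        df = df[df.role == "sample"]

    records = []
    for gene, grp in df.groupby("gene", sort=False):
        direction, tier, supporting, ambiguous = _call_one_gene(
            list(grp.amplicon_id), grp.ssmd.to_numpy(), thresholds
        )
        records.append(
            {
                "gene": gene,
                "direction": direction,
                "tier": tier,
                "n_amplicons": len(grp),
                "supporting_amplicons": ";".join(supporting),
                "ambiguous": ambiguous,
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=["gene", "direction", "tier", "n_amplicons",
                 "supporting_amplicons", "ambiguous"],
    )


def summarize_calls(calls: pd.DataFrame) -> CallSummary:
    """Counts of positive regulators, negative regulators and uncalled genes."""
    if len(calls) == 0:
        return CallSummary(0, 0, 0)
    counts = calls.direction.value_counts()
    return CallSummary(
        positive_regulators=int(counts.get(DIRECTION_POSITIVE, 0)),
        negative_regulators=int(counts.get(DIRECTION_NEGATIVE, 0)),
        uncalled=int(counts.get(DIRECTION_NONE, 0)),
    )


def compare_groups(a: Iterable[float], b: Iterable[float]) -> float:
    """Two-sided p-value of the classical equal-variance Student t-test."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if a.var(ddof=1) + b.var(ddof=1) == 0.0:
        raise ValueError("zero pooled variance: p-value undefined")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.pvalue)


def control_qc(scores: pd.DataFrame, wells_d: pd.DataFrame | None = None) -> pd.DataFrame:
    """Control-well QC: score summary per role, and per-plate d summaries.

    Returns a tidy table of negative/positive control behavior; on a healthy
    screen the negative-control scores sit near zero and the positive
    control scores are strongly negative.
    """
    frames = []
    ctrl = scores[scores.role.isin(["neg_ctrl", "pos_ctrl"])]
    if len(ctrl):
        agg = ctrl.groupby("role")["ssmd"].agg(["count", "mean", "min", "max"])
        agg = agg.reset_index().rename(columns={"count": "n"})
        agg.insert(0, "level", "amplicon_score")
        agg.insert(1, "plate_id", "all")
        frames.append(agg)
    if wells_d is not None and "d" in wells_d.columns:
        ctrl_wells = wells_d[wells_d.role.isin(["neg_ctrl", "pos_ctrl"])]
        agg = (
            ctrl_wells.groupby(["plate_id", "role"])["d"]
            .agg(["count", "mean", "min", "max"])
            .reset_index()
            .rename(columns={"count": "n"})
        )
        agg.insert(0, "level", "well_d")
        frames.append(agg)
    if not frames:
        return pd.DataFrame(
            columns=["level", "plate_id", "role", "n", "mean", "min", "max"]
        )
    return pd.concat(frames, ignore_index=True)
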