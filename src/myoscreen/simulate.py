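"""Ground-truthed synthetic data for the screen analysis.

Two generators mirror the two stages of the assay:

``simulate_field``
    Renders one microscope field: elongated muscle cells (capsules) among
    small, weakly stained non-muscle cells, a diffuse cytoplasmic+nuclear
    GFP reporter inside muscles, and bright GFP puncta whose expected count
    scales with an ``autophagy_level``.  Emits the exact masks used for
    rendering, so the true puncta-area / muscle-area index is known.

``simulate_screen``
    Draws replicate 384-well plates of autophagy indices with gene-level
    multiplicative effects, a shared lognormal plate effect and lognormal
    well noise:  y = A0 * theta_g * pi_r * eps.  Control wells emulate the
    screen's lacZ (null) and Atg18 (strong suppressor) dsRNAs.

Both are deterministic under their integer seed; each stage draws from its
own named substream so field and screen simulations are independently
reproducible.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field as dataclass_field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .imaging import ImageField

__all__ = [
    "FieldSimConfig",
    "ScreenSimConfig",
    "GroundTruth",
    "simulate_field",
    "simulate_flux_field",
    "field_from_masks",
    "simulate_screen",
    "plate_layout",
]

# substream tags so the two generators never share a random stream
_FIELD_STREAM = 0x46494C44  # "FILD"
_SCREEN_STREAM = 0x53435245  # "SCRE"

ROLE_SAMPLE = "sample"
ROLE_NEG = "neg_ctrl"
ROLE_POS = "pos_ctrl"
ROLE_EMPTY = "empty"


@dataclass(frozen=True)
class FieldSimConfig:
    """Geometry, intensity and noise model of one synthetic field.

    Intensities are arbitrary fluorescence units on a 16-bit-like scale.
    ``puncta_density`` is the expected number of puncta per muscle pixel per
    unit ``autophagy_level``; the punctum count is Poisson with mean
    ``autophagy_level * muscle_area * puncta_density``.
    """

    canvas_size: tuple[int, int] = (512, 512)  # rows, cols
    n_muscles: int = 4
    muscle_length_range: tuple[float, float] = (120.0, 240.0)
    muscle_width_range: tuple[float, float] = (24.0, 36.0)
    n_nonmuscle_cells: int = 40
    nonmuscle_radius_range: tuple[float, float] = (5.0, 9.0)
    n_nuclei_per_muscle: tuple[int, int] = (2, 6)
    nucleus_radius: float = 10.0
    autophagy_level: float = 1.0
    puncta_density: float = 2.0e-3
    puncta_radius_mean: float = 3.0
    puncta_radius_sd: float = 0.8
    puncta_profile: str = "disk"  # or "gaussian"
    diffuse_gfp_level: float = 60.0
    nuclear_gfp_level: float = 90.0
    puncta_gfp_level: float = 160.0
    actin_level: float = 120.0
    nonmuscle_actin_level: float = 25.0
    striation_amplitude: float = 0.0  # optional sinusoidal actin texture
    striation_period: float = 8.0
    noise_sd: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.canvas_size
        if h < 16 or w < 16:
            raise ValueError("canvas_size must be at least 16x16")
        if self.n_muscles < 1:
            raise ValueError("need at least one muscle")
        lo, hi = self.muscle_length_range
        wlo, whi = self.muscle_width_range
        if not (0 < lo <= hi) or not (0 < wlo <= whi):
            raise ValueError("muscle size ranges must be positive and ordered")
        if min(h, w) <= wlo:
            raise ValueError("canvas too small to hold one muscle")
        if self.autophagy_level < 0:
            raise ValueError("autophagy_level must be >= 0")
        if self.puncta_density < 0:
            raise ValueError("puncta_density must be >= 0")
        if self.puncta_radius_mean <= 0 or self.puncta_radius_sd < 0:
            raise ValueError("puncta radius parameters must be positive")
        if self.puncta_profile not in ("disk", "gaussian"):
            raise ValueError("puncta_profile must be 'disk' or 'gaussian'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.nucleus_radius <= 0:
            raise ValueError("nucleus_radius must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Exact rendering masks and the true autophagy index of one field."""

    muscle_mask: np.ndarray
    puncta_mask: np.ndarray
    nuclei_mask: np.ndarray
    true_index: float

    def __post_init__(self) -> None:
        if (self.puncta_mask & ~self.muscle_mask).any():
            raise ValueError("puncta_mask must be contained in muscle_mask")


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    h, w = shape
    cy, cx = center
    r = int(np.ceil(radius))
    y0, y1 = max(0, int(cy) - r - 1), min(h, int(cy) + r + 2)
    x0, x1 = max(0, int(cx) - r - 1), min(w, int(cx) + r + 2)
    out = np.zeros(shape, dtype=bool)
    if y0 >= y1 or x0 >= x1:
        return out
    yy, xx = np.mgrid[y0:y1, x0:x1]
    out[y0:y1, x0:x1] = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    return out


def _capsule_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    angle: float,
    length: float,
    width: float,
) -> np.ndarray:
    """Rotated capsule: a segment of given length dilated by width/2."""
    h, w = shape
    cy, cx = center
    dy, dx = np.sin(angle), np.cos(angle)
    half = max(length - width, 0.0) / 2.0  # segment between the cap centers
    radius = width / 2.0
    p0 = np.array([cy - dy * half, cx - dx * half])
    p1 = np.array([cy + dy * half, cx + dx * half])
    pad = radius + 1
    y0 = max(0, int(np.floor(min(p0[0], p1[0]) - pad)))
    y1 = min(h, int(np.ceil(max(p0[0], p1[0]) + pad)) + 1)
    x0 = max(0, int(np.floor(min(p0[1], p1[1]) - pad)))
    x1 = min(w, int(np.ceil(max(p0[1], p1[1]) + pad)) + 1)
    out = np.zeros(shape, dtype=bool)
    if y0 >= y1 or x0 >= x1:
        return out
    yy, xx = np.mgrid[y0:y1, x0:x1]
    pts = np.stack([yy - p0[0], xx - p0[1]], axis=-1).astype(float)
    seg = p1 - p0
    seg_len2 = float(seg @ seg)
    if seg_len2 == 0.0:
        d2 = pts[..., 0] ** 2 + pts[..., 1] ** 2
    else:
        t = np.clip((pts[..., 0] * seg[0] + pts[..., 1] * seg[1]) / seg_len2, 0.0, 1.0)
        d2 = (pts[..., 0] - t * seg[0]) ** 2 + (pts[..., 1] - t * seg[1]) ** 2
    out[y0:y1, x0:x1] = d2 <= radius**2
    return out


def _render_puncta_channel(
    config: FieldSimConfig, puncta: list[tuple[float, float, float]], shape
) -> np.ndarray:
    """Additive puncta intensity layer (before muscle clipping)."""
    layer = np.zeros(shape, dtype=np.float64)
    for cy, cx, r in puncta:
        if config.puncta_profile == "disk":
            layer[_disk_mask(shape, (cy, cx), r)] += config.puncta_gfp_level
        else:
            spot = np.zeros(shape)
            iy, ix = int(round(cy)), int(round(cx))
            if 0 <= iy < shape[0] and 0 <= ix < shape[1]:
                spot[iy, ix] = 1.0
                spot = gaussian_filter(spot, sigma=r / 2.0)
                peak = spot.max()
                if peak > 0:
                    layer += spot * (config.puncta_gfp_level / peak)
    return layer


def field_from_masks(
    muscle_mask: np.ndarray,
    puncta_mask: np.ndarray | None = None,
    nuclei_mask: np.ndarray | None = None,
    nonmuscle_mask: np.ndarray | None = None,
    config: FieldSimConfig | None = None,
    rng: np.random.Generator | None = None,
    field_id: str = "",
) -> tuple[ImageField, GroundTruth]:
    """Render channels from explicitly given masks.

    Useful for constructing fields with exactly known geometry (areas are
    then exact integers by construction).  Puncta and nuclei are clipped to
    the muscle mask.
    """
    config = config or FieldSimConfig()
    muscle = np.asarray(muscle_mask, dtype=bool)
    shape = muscle.shape
    puncta = (
        np.zeros(shape, dtype=bool)
        if puncta_mask is None
        else np.asarray(puncta_mask, dtype=bool) & muscle
    )
    nuclei = (
        np.zeros(shape, dtype=bool)
        if nuclei_mask is None
        else np.asarray(nuclei_mask, dtype=bool) & muscle
    )
    nonmuscle = (
        np.zeros(shape, dtype=bool)
        if nonmuscle_mask is None
        else np.asarray(nonmuscle_mask, dtype=bool)
    )

    actin = np.where(muscle, config.actin_level, 0.0)
    actin = np.maximum(actin, np.where(nonmuscle, config.nonmuscle_actin_level, 0.0))
    gfp = np.where(muscle, config.diffuse_gfp_level, 0.0)
    gfp[nuclei] += config.nuclear_gfp_level
    gfp[puncta] += config.puncta_gfp_level
    nuclear = np.where(nuclei, 200.0, 0.0)

    channels = {"gfp": gfp, "actin": actin, "nuclear": nuclear}
    if config.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng([config.seed, _FIELD_STREAM])
        for role in channels:
            channels[role] = np.clip(
                channels[role] + rng.normal(0.0, config.noise_sd, shape), 0.0, None
            )

    area = int(muscle.sum())
    truth = GroundTruth(
        muscle_mask=muscle,
        puncta_mask=puncta,
        nuclei_mask=nuclei,
        true_index=(int(puncta.sum()) / area) if area else 0.0,
    )
    return ImageField(channels=channels, field_id=field_id), truth


def simulate_field(config: FieldSimConfig | None = None) -> tuple[ImageField, GroundTruth]:
    """Simulate one field image with known ground truth."""
    config = config or FieldSimConfig()
    config.validate()
    rng = np.random.default_rng([config.seed, _FIELD_STREAM])
    shape = config.canvas_size
    h, w = shape

    muscle = np.zeros(shape, dtype=bool)
    muscle_parts: list[np.ndarray] = []
    striation = np.ones(shape, dtype=np.float64)
    for _ in range(config.n_muscles):
        length = rng.uniform(*config.muscle_length_range)
        width = rng.uniform(*config.muscle_width_range)
        angle = rng.uniform(0.0, np.pi)
        margin = width / 2.0 + 1.0
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        part = _capsule_mask(shape, (cy, cx), angle, length, width)
        muscle_parts.append(part)
        muscle |= part
        if config.striation_amplitude > 0:
            yy, xx = np.nonzero(part)
            axis = (yy - cy) * np.sin(angle) + (xx - cx) * np.cos(angle)
            striation[yy, xx] = 1.0 + config.striation_amplitude * np.sin(
                2.0 * np.pi * axis / config.striation_period
            )

    # nuclei centers drawn from the eroded muscle interior so each nucleus
    # disk lies wholly inside its muscle (thin clipped slivers would defeat
    # the size separation the puncta detector relies on)
    nuclei = np.zeros(shape, dtype=bool)
    lo, hi = config.n_nuclei_per_muscle
    for part in muscle_parts:
        interior = distance_transform_edt(part) > config.nucleus_radius
        coords = np.argwhere(interior)
        if len(coords) == 0:
            continue
        for _ in range(int(rng.integers(lo, hi + 1))):
            cy, cx = coords[rng.integers(len(coords))]
            nuclei |= _disk_mask(shape, (float(cy), float(cx)), config.nucleus_radius)
    nuclei &= muscle

    nonmuscle = np.zeros(shape, dtype=bool)
    nm_nuclei = np.zeros(shape, dtype=bool)
    for _ in range(config.n_nonmuscle_cells):
        r = rng.uniform(*config.nonmuscle_radius_range)
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        nonmuscle |= _disk_mask(shape, (cy, cx), r)
        nm_nuclei |= _disk_mask(shape, (cy, cx), r * 0.5)
    nonmuscle &= ~muscle

    area = int(muscle.sum())
    mean_count = config.autophagy_level * area * config.puncta_density
    n_puncta = int(rng.poisson(mean_count)) if mean_count > 0 else 0
    coords = np.argwhere(muscle)
    puncta_mask = np.zeros(shape, dtype=bool)
    puncta_spots: list[tuple[float, float, float]] = []
    for _ in range(n_puncta):
        cy, cx = coords[rng.integers(len(coords))]
        r = max(1.0, rng.normal(config.puncta_radius_mean, config.puncta_radius_sd))
        puncta_spots.append((float(cy), float(cx), r))
        puncta_mask |= _disk_mask(shape, (float(cy), float(cx)), r)
    puncta_mask &= muscle

    actin = np.where(muscle, config.actin_level, 0.0) * striation
    actin = np.maximum(actin, np.where(nonmuscle, config.nonmuscle_actin_level, 0.0))
    gfp = np.where(muscle, config.diffuse_gfp_level, 0.0)
    gfp[nuclei] += config.nuclear_gfp_level
    if config.puncta_profile == "disk":
        gfp[puncta_mask] += config.puncta_gfp_level
    else:
        gfp += _render_puncta_channel(config, puncta_spots, shape) * muscle
    nuclear = np.where(nuclei | nm_nuclei, 200.0, 0.0)

    channels = {"gfp": gfp, "actin": actin, "nuclear": nuclear}
    if config.noise_sd > 0:
        for role in channels:
            channels[role] = np.clip(
                channels[role] + rng.normal(0.0, config.noise_sd, shape), 0.0, None
            )

    truth = GroundTruth(
        muscle_mask=muscle,
        puncta_mask=puncta_mask,
        nuclei_mask=nuclei,
        true_index=(int(puncta_mask.sum()) / area) if area else 0.0,
    )
    return ImageField(channels=channels), truth


def simulate_flux_field(
    config: FieldSimConfig | None = None, acidified_fraction: float = 0.0
) -> tuple[ImageField, GroundTruth, int]:
    """Simulate a dual-reporter (GFP + mCherry) field for flux measurement.

    All puncta appear in the red channel; a fraction ``acidified_fraction``
    of them (autolysosomes, where GFP is quenched) are omitted from the
    green channel.  Returns the field, the ground truth of the *red* puncta
    set, and the number of acidified (red-only) puncta.
    """
    config = config or FieldSimConfig()
    config.validate()
    if not 0.0 <= acidified_fraction < 1.0:
        raise ValueError("acidified_fraction must be in [0, 1)")
    field, truth = simulate_field(config)
    rng = np.random.default_rng([config.seed, _FIELD_STREAM, 0xF1])

    from skimage import measure  # local import to avoid cycle at module load

    labels = measure.label(truth.puncta_mask, connectivity=1)
    n = int(labels.max())
    acidified = rng.random(n) < acidified_fraction
    green_puncta = truth.puncta_mask.copy()
    for lab in np.nonzero(acidified)[0] + 1:
        green_puncta[labels == lab] = False

    base = np.where(truth.muscle_mask, config.diffuse_gfp_level, 0.0)
    base[truth.nuclei_mask] += config.nuclear_gfp_level
    gfp = base.copy()
    gfp[green_puncta] += config.puncta_gfp_level
    red = base.copy()
    red[truth.puncta_mask] += config.puncta_gfp_level
    if config.noise_sd > 0:
        gfp = np.clip(gfp + rng.normal(0, config.noise_sd, gfp.shape), 0, None)
        red = np.clip(red + rng.normal(0, config.noise_sd, red.shape), 0, None)

    channels = dict(field.channels)
    channels["gfp"] = gfp
    channels["red"] = red
    return ImageField(channels=channels), truth, int(acidified.sum())


# ---------------------------------------------------------------------------
# screen simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenSimConfig:
    """Statistical model of a replicate 384-well screen.

    Each well's autophagy index is ``y = A0 * theta_g * pi_r * eps`` with a
    per-plate lognormal factor ``pi_r`` (scale ``sigma_plate``) shared by
    all wells of a plate and i.i.d. lognormal well noise ``eps`` (scale
    ``sigma_well``).  ``gene_effect_map`` maps gene name to its multiplier
    theta (1 = null, <1 suppressor of puncta, >1 enhancer).  Control wells
    emulate lacZ (theta = 1) and Atg18 (theta = ``pos_control_theta``).
    """

    gene_effect_map: Mapping[str, float] = dataclass_field(default_factory=dict)
    n_plates: int = 3
    wells_per_plate: int = 384
    amplicons_per_gene: int = 2
    baseline_index: float = 0.02
    sigma_plate: float = 0.1
    sigma_well: float = 0.2
    neg_control_label: str = "lacZ"
    pos_control_label: str = "Atg18"
    n_neg_wells: int = 16
    n_pos_wells: int = 8
    pos_control_theta: float = 0.1
    off_target_map: Mapping[str, float] = dataclass_field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if not self.gene_effect_map:
            raise ValueError("gene_effect_map must not be empty")
        if self.n_plates < 3:
            raise ValueError("SSMD scoring needs at least 3 replicate plates")
        if any(t <= 0 for t in self.gene_effect_map.values()):
            raise ValueError("all gene effects theta must be > 0")
        if self.pos_control_theta <= 0:
            raise ValueError("pos_control_theta must be > 0")
        if self.sigma_plate < 0 or self.sigma_well < 0:
            raise ValueError("sigma parameters must be >= 0")
        if self.amplicons_per_gene < 1:
            raise ValueError("amplicons_per_gene must be >= 1")
        if self.baseline_index <= 0:
            raise ValueError("baseline_index must be > 0")
        n_sample = len(self.gene_effect_map) * self.amplicons_per_gene
        capacity = self.wells_per_plate - self.n_neg_wells - self.n_pos_wells
        if n_sample > capacity:
            raise ValueError(
                f"{n_sample} sample amplicons exceed plate capacity {capacity}"
            )


def plate_layout(wells_per_plate: int) -> list[str]:
    """Well names in row-major order (A01..P24 for a 384-well plate)."""
    shapes = {384: (16, 24), 96: (8, 12), 24: (4, 6)}
    if wells_per_plate in shapes:
        rows, cols = shapes[wells_per_plate]
    else:
        rows = int(np.floor(np.sqrt(wells_per_plate / 1.5)))
        rows = max(rows, 1)
        cols = int(np.ceil(wells_per_plate / rows))
    names = [
        f"{string.ascii_uppercase[r]}{c + 1:02d}" for r in range(rows) for c in range(cols)
    ]
    return names[:wells_per_plate]


def _assign_wells(config: ScreenSimConfig) -> pd.DataFrame:
    """Deterministic single-plate layout replicated across plates."""
    wells = plate_layout(config.wells_per_plate)
    n = len(wells)
    n_ctrl = config.n_neg_wells + config.n_pos_wells
    # controls spread evenly across the plate, as on real screening plates
    ctrl_pos = np.unique(np.linspace(0, n - 1, n_ctrl).round().astype(int)) if n_ctrl else []
    ctrl_pos = list(ctrl_pos)
    neg_pos = set(ctrl_pos[:: 2][: config.n_neg_wells])
    remaining = [p for p in ctrl_pos if p not in neg_pos]
    while len(neg_pos) < config.n_neg_wells and remaining:
        neg_pos.add(remaining.pop(0))
    pos_pos = set(p for p in ctrl_pos if p not in neg_pos)

    records = []
    sample_iter = iter(
        (gene, f"{gene}_amp{i + 1}")
        for gene in config.gene_effect_map
        for i in range(config.amplicons_per_gene)
    )
    for idx, well in enumerate(wells):
        if idx in neg_pos:
            records.append((well, f"{config.neg_control_label}_ctrl",
                            config.neg_control_label, ROLE_NEG))
        elif idx in pos_pos:
            records.append((well, f"{config.pos_control_label}_ctrl",
                            config.pos_control_label, ROLE_POS))
        else:
            nxt = next(sample_iter, None)
            if nxt is None:
                records.append((well, "", "", ROLE_EMPTY))
            else:
                gene, amp = nxt
                records.append((well, amp, gene, ROLE_SAMPLE))
    return pd.DataFrame(records, columns=["well", "amplicon_id", "gene", "role"])


def simulate_screen(
    config: ScreenSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a replicate-plate screen of autophagy indices.

    Returns
    -------
    wells : DataFrame
        One row per plate x well: ``plate_id, well, amplicon_id, gene,
        role, index, true_level`` where ``true_level = theta * pi_r * eps``
        is the multiplicative truth (index = baseline * true_level).
    truth : DataFrame
        Per-amplicon true effect sizes: ``amplicon_id, gene, role, theta``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _SCREEN_STREAM])
    layout = _assign_wells(config)

    def theta_of(row) -> float:
        if row.role == ROLE_NEG:
            return 1.0
        if row.role == ROLE_POS:
            return config.pos_control_theta
        if row.role == ROLE_EMPTY:
            return 0.0
        if row.amplicon_id in config.off_target_map:
            return float(config.off_target_map[row.amplicon_id])
        return float(config.gene_effect_map[row.gene])

    thetas = np.array([theta_of(r) for r in layout.itertuples()])
    frames = []
    for r in range(config.n_plates):
        plate_id = f"P{r + 1:02d}"
        pi_r = float(np.exp(rng.normal(0.0, config.sigma_plate)))
        eps = np.exp(rng.normal(0.0, config.sigma_well, size=len(layout)))
        level = thetas * pi_r * eps
        level[layout.role.values == ROLE_EMPTY] = 0.0
        df = layout.copy()
        df.insert(0, "plate_id", plate_id)
        df["index"] = config.baseline_index * level
        df["true_level"] = level
        frames.append(df)
    wells = pd.concat(frames, ignore_index=True)

    truth = (
        layout[layout.role != ROLE_EMPTY][["amplicon_id", "gene", "role"]]
        .drop_duplicates("amplicon_id")
        .reset_index(drop=True)
    )
    truth["theta"] = [
        1.0 if role == ROLE_NEG
        else config.pos_control_theta if role == ROLE_POS
        else float(config.off_target_map.get(amp, config.gene_effect_map[gene]))
        for amp, gene, role in zip(truth.amplicon_id, truth.gene, truth.role)
    ]
    return wells, truth
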