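"""Robust Automatic Threshold Selection (RATS).

RATS computes a *local* threshold surface from gradient-weighted mean
intensities over a quadtree decomposition of the image.  Pixels near edges
(large gradient) dominate each region's threshold estimate

    T(region) = sum(w * I) / sum(w),    w = g**lambda  for g > noise_threshold,

where ``g`` is the gradient magnitude.  Regions without enough edge evidence
are "invalid" and inherit the threshold of their nearest valid ancestor in
the quadtree, so a flat background area far from any structure yields no
foreground at all.

The estimator is deliberately simple and fully deterministic; every constant
is surfaced through :class:`RatsParams`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = ["RatsParams", "RatsResult", "rats_threshold"]


@dataclass(frozen=True)
class RatsParams:
    """Parameters of the RATS threshold estimator.

    Attributes
    ----------
    noise_threshold:
        Gradient magnitudes at or below this value carry no weight.  Keeps
        flat, noisy background from contributing edge evidence.
    lambda_factor:
        Exponent applied to the gradient when forming weights; larger values
        concentrate the estimate on the strongest edges.
    min_leaf_size:
        Minimum area (pixels) of a quadtree leaf.  A node is split only if
        all four children would stay at or above this area.
    validity_fraction:
        A leaf is valid when ``sum(w) > noise_threshold**lambda * area *
        validity_fraction``; i.e. it must hold clearly super-noise edge
        evidence over a fraction of its area.
    """

    noise_threshold: float = 20.0
    lambda_factor: float = 3.0
    min_leaf_size: int = 100
    validity_fraction: float = 0.01

    def validate(self) -> None:
        if self.noise_threshold < 0:
            raise ValueError("noise_threshold must be >= 0")
        if self.lambda_factor <= 0:
            raise ValueError("lambda_factor must be > 0")
        if self.min_leaf_size < 4:
            raise ValueError("min_leaf_size must be >= 4")
        if self.validity_fraction <= 0:
            raise ValueError("validity_fraction must be > 0")


class RatsResult(NamedTuple):
    mask: np.ndarray
    """Boolean foreground mask, ``image > threshold``."""
    threshold: np.ndarray
    """Per-pixel threshold surface (``+inf`` where no threshold applies)."""
    no_foreground: bool
    """True when no region anywhere held enough edge evidence."""


def _integral(a: np.ndarray) -> np.ndarray:
    out = np.zeros((a.shape[0] + 1, a.shape[1] + 1), dtype=np.float64)
    np.cumsum(np.cumsum(a, axis=0), axis=1, out=out[1:, 1:])
    return out


def _rect_sum(s: np.ndarray, r0: int, r1: int, c0: int, c1: int) -> float:
    return s[r1, c1] - s[r0, c1] - s[r1, c0] + s[r0, c0]


def gradient_weights(image: np.ndarray, params: RatsParams) -> np.ndarray:
    """Edge weights ``g**lambda`` (zero at or below the noise threshold).

    The gradient magnitude is the max of the absolute horizontal and
    vertical central differences (one-sided at the borders).
    """
    gy, gx = np.gradient(image.astype(np.float64, copy=False))
    g = np.maximum(np.abs(gx), np.abs(gy))
    w = np.zeros_like(g)
    above = g > params.noise_threshold
    w[above] = g[above] ** params.lambda_factor
    return w


def rats_threshold(image: np.ndarray, params: RatsParams | None = None) -> RatsResult:
    """Threshold ``image`` with the RATS quadtree estimator.

    Images smaller than any allowed 4-way split are treated as a single
    leaf, in which case the threshold is the global gradient-weighted mean
    intensity.

    Returns
    -------
    RatsResult
        Foreground mask, the per-pixel threshold surface and a flag that is
        set when the image contains no valid region at all (e.g. a constant
        image), in which case the mask is empty.
    """
    params = params or RatsParams()
    params.validate()
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("rats_threshold expects a 2-D raster")

    w = gradient_weights(img, params)
    sw = _integral(w)
    swi = _integral(w * img)

    surface = np.full(img.shape, np.inf, dtype=np.float64)
    floor = params.noise_threshold ** params.lambda_factor * params.validity_fraction
    any_valid = False

    # iterative DFS; each entry carries the nearest valid ancestor threshold
    stack: list[tuple[int, int, int, int, float, bool]] = [
        (0, img.shape[0], 0, img.shape[1], np.inf, False)
    ]
    while stack:
        r0, r1, c0, c1, inh_t, inh_valid = stack.pop()
        area = (r1 - r0) * (c1 - c0)
        s = _rect_sum(sw, r0, r1, c0, c1)
        valid = s > floor * area and s > 0.0
        if valid:
            t = _rect_sum(swi, r0, r1, c0, c1) / s
            any_valid = True
        else:
            t, valid = inh_t, inh_valid

        rm, cm = (r0 + r1) // 2, (c0 + c1) // 2
        # split only if the smallest child stays at or above min_leaf_size
        if (rm - r0) * (cm - c0) >= params.min_leaf_size:
            stack.extend(
                (
                    (r0, rm, c0, cm, t, valid),
                    (r0, rm, cm, c1, t, valid),
                    (rm, r1, c0, cm, t, valid),
                    (rm, r1, cm, c1, t, valid),
                )
            )
        else:
            surface[r0:r1, c0:c1] = t if valid else np.inf

    with np.errstate(invalid="ignore"):
        mask = img > surface
    return RatsResult(mask=mask, threshold=surface, no_foreground=not any_valid)
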