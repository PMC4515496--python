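"""Fuzzy-stretching brightness-contrast enhancement.

Abdominal B-mode ultrasound frames are dominated by low intensities; the
bright landmarks the ROI extractor needs (fascia, limiting membrane, kidney
fat) sit in a thin upper tail.  Plain min-max stretching wastes dynamic range
on outliers, so the stretch bounds are instead chosen through a triangular
fuzzy membership over intensity: the triangle is centred on an adjusted
image mean, an alpha-cut selects the intensity values considered "typical",
and the lowest/highest surviving values become the stretch bounds
``gamma``/``beta``.  The final mapping is the affine rescale of
``[gamma, beta]`` onto ``[0, 255]``.

All bound computations keep the image mean at full float precision; rounding
happens only when producing the output 8-bit image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "StretchParams",
    "compute_mean_brightness",
    "compute_stretch_bounds",
    "membership",
    "compute_alpha_cut",
    "compute_gamma_beta",
    "apply_stretch",
    "fuzzy_stretch",
]


@dataclass
class StretchParams:
    """State of the fuzzy-stretching computation.

    ``x_m``, ``x_h``, ``x_l`` are the image mean / max / min intensities;
    ``d_max``/``d_min`` the distances from the mean to the extremes; ``ad``
    the adjustment distance that sets the triangle support
    ``[I_min, I_max]`` with peak ``I_mid``.  ``alpha_cut`` is the membership
    threshold and ``gamma``/``beta`` the resulting stretch bounds.
    """

    x_m: float = 0.0
    x_h: float = 0.0
    x_l: float = 0.0
    d_max: float = 0.0
    d_min: float = 0.0
    ad: float = 0.0
    I_max: float = 0.0
    I_min: float = 0.0
    I_mid: float = 0.0
    alpha_cut: float = 0.0
    gamma: float = 0.0
    beta: float = 0.0
    fallback_used: bool = field(default=False)

    def to_dict(self) -> dict:
        """JSON-serialisable record for run reports."""
        d = asdict(self)
        return {k: (bool(v) if isinstance(v, bool) else float(v)) for k, v in d.items()}


def _as_image(img) -> np.ndarray:
    a = np.asarray(img)
    if a.ndim != 2 or a.size == 0:
        raise ValueError("expected a nonempty 2-D grayscale image")
    return a


def compute_mean_brightness(img) -> float:
    """Arithmetic mean intensity over all M*N pixels, unrounded."""
    return float(_as_image(img).mean(dtype=np.float64))


def compute_stretch_bounds(img) -> StretchParams:
    """Derive the triangular membership support from the image statistics.

    The adjustment distance ``ad`` follows a cascade on the mean ``x_m``:
    a bright image (``x_m > 128``) keeps headroom to 255; otherwise ``ad``
    is the larger applicable of the two mean-to-extreme distances, falling
    back to ``x_m`` itself.  ``I_max = x_m + ad`` and ``I_min = x_m - ad``
    are clamped to [0, 255] before the peak ``I_mid`` is taken, since the
    alpha-cut ratio presupposes in-range bounds.
    """
    a = _as_image(img)
    x_m = compute_mean_brightness(a)
    x_h = float(a.max())
    x_l = float(a.min())
    d_max = x_h - x_m
    d_min = x_m - x_l

    if x_m > 128:
        ad = 255.0 - x_m
    elif x_m <= d_min:
        ad = d_min
    elif x_m <= d_max:
        ad = d_max
    else:
        ad = x_m

    I_max = min(255.0, x_m + ad)
    I_min = max(0.0, x_m - ad)
    I_mid = (I_max + I_min) / 2.0

    return StretchParams(
        x_m=x_m, x_h=x_h, x_l=x_l,
        d_max=d_max, d_min=d_min, ad=ad,
        I_max=I_max, I_min=I_min, I_mid=I_mid,
    )


def membership(x: float, p: StretchParams) -> float:
    """Triangular membership degree of intensity ``x`` on [I_min, I_max].

    Zero outside the support, 1 exactly at the peak ``I_mid``, linear on
    both flanks.  A degenerate flank (``I_mid == I_min`` or
    ``I_mid == I_max``) contributes 0 except at the peak itself, which
    avoids the division by zero without inventing a plateau.
    """
    if x == p.I_mid:
        return 1.0
    if x <= p.I_min or x >= p.I_max:
        return 0.0
    if x > p.I_mid:
        if p.I_max == p.I_mid:
            return 0.0
        return (p.I_max - x) / (p.I_max - p.I_mid)
    if p.I_mid == p.I_min:
        return 0.0
    return (x - p.I_min) / (p.I_mid - p.I_min)


def compute_alpha_cut(p: StretchParams) -> float:
    """Membership threshold: I_min/I_max when I_min is nonzero, else 0.5."""
    if p.I_min != 0:
        assert p.I_max != 0, "I_max = 0 with I_min != 0 violates bound invariants"
        return p.I_min / p.I_max
    return 0.5


def compute_gamma_beta(img, p: StretchParams) -> tuple[float, float]:
    """Stretch bounds: min/max intensity present with membership >= alpha-cut.

    Scanned over the 256-bin histogram of values actually present (identical
    to a per-pixel scan, cheaper).  Membership exactly equal to the alpha-cut
    is included.  An empty qualifying set degrades to plain min-max bounds
    ``(x_l, x_h)`` with a logged warning.
    """
    a = _as_image(img)
    alpha = p.alpha_cut if p.alpha_cut else compute_alpha_cut(p)
    present = np.unique(a)
    qualifying = [int(v) for v in present if membership(float(v), p) >= alpha]
    if not qualifying:
        logger.warning(
            "fuzzy stretch: no intensity reaches alpha-cut %.4f; "
            "falling back to min-max bounds (%g, %g)", alpha, p.x_l, p.x_h,
        )
        p.fallback_used = True
        return float(p.x_l), float(p.x_h)
    return float(min(qualifying)), float(max(qualifying))


def apply_stretch(img, gamma: float, beta: float) -> np.ndarray:
    """Affine rescale of [gamma, beta] onto [0, 255], rounded and clamped.

    ``gamma == beta`` means there is no contrast to stretch; the input is
    returned unchanged (degenerate passthrough, logged).
    """
    a = _as_image(img)
    if gamma == beta:
        logger.warning("fuzzy stretch: gamma == beta == %g; image passed through", gamma)
        return a.astype(np.uint8, copy=True)
    out = np.rint(255.0 * (a.astype(np.float64) - gamma) / (beta - gamma))
    return np.clip(out, 0, 255).astype(np.uint8)


def fuzzy_stretch(img) -> tuple[np.ndarray, StretchParams]:
    """Full enhancement chain; returns the stretched image and its parameters."""
    a = _as_image(img)
    p = compute_stretch_bounds(a)
    p.alpha_cut = compute_alpha_cut(p)
    p.gamma, p.beta = compute_gamma_beta(a, p)
    return apply_stretch(a, p.gamma, p.beta), p
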