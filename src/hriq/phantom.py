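"""Synthetic right-subcostal ultrasound phantoms with known ground truth.

A phantom emulates the fixed anatomical layout the ROI extractor assumes on
a right-subcostal scan: a bright horizontal fascia band near the top, a
darker liver-parenchyma field beneath it, a bright curved limiting membrane
separating liver from kidney, and below that kidney-level tissue containing
a bright perirenal-fat annulus that encloses the renal-cortex field.
Speckle is modelled as multiplicative Gaussian noise
(``value = mean * (1 + cv * N(0, 1))``), clipped to [0, 255] and rounded —
the simplest model that exercises thresholding; it is not an acoustic
simulation (no attenuation, shadowing or refraction).

Ground truth records the liver and kidney parenchyma masks and the true
liver-minus-kidney intensity difference, so the pipeline's recovered
hepatorenal index can be scored against a known answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "REFERENCE_CLASS_MEANS",
    "generate_phantom",
    "generate_cohort",
    "save_phantom",
]

#: Representative liver/kidney parenchyma mean intensities for the three
#: severity classes the pipeline grades (normal, mild, moderate fatty liver).
#: A normal liver is nearly isoechoic with the renal cortex; echogenicity of
#: the liver — and hence the hepatorenal difference — rises with steatosis.
REFERENCE_CLASS_MEANS: dict[str, tuple[float, float]] = {
    "normal": (43.500, 41.709),
    "mild": (52.159, 43.724),
    "moderate": (68.729, 46.704),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic scan.

    Bright structures (fascia, membrane, kidney fat) must all exceed both
    parenchyma means, otherwise the landmark layout is unextractable and the
    phantom would not represent a valid scan.
    """

    width: int = 512
    height: int = 384
    liver_mean: float = 43.5
    kidney_mean: float = 41.709
    fascia_mean: float = 200.0
    membrane_mean: float = 200.0
    kidneyfat_mean: float = 200.0
    background: float = 10.0
    noise_cv: float = 0.1
    seed: int = 0
    membrane_gap_px: int = 0  # >0 draws the membrane dashed (for restoration tests)

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("phantom dimensions must be positive")
        for name in ("liver_mean", "kidney_mean", "fascia_mean",
                     "membrane_mean", "kidneyfat_mean", "background"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValueError(f"{name}={v} outside [0, 255]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        bright = min(self.fascia_mean, self.membrane_mean, self.kidneyfat_mean)
        if bright <= max(self.liver_mean, self.kidney_mean):
            raise ValueError("bright structures must exceed both parenchyma means")


@dataclass
class PhantomTruth:
    """A generated phantom image with its ground-truth annotation."""

    image: np.ndarray
    liver_mask: np.ndarray
    kidney_mask: np.ndarray
    true_hri_diff: float
    spec: PhantomSpec
    label: str | None = None
    meta: dict = field(default_factory=dict)


def _geometry(spec: PhantomSpec):
    """Index masks for each anatomical structure (noise-free layout)."""
    H, W = spec.height, spec.width
    rows = np.arange(H)[:, None]
    cols = np.arange(W)[None, :]

    fascia_top = round(0.06 * H)
    fascia_bot = round(0.12 * H)  # inclusive
    fascia = np.zeros((H, W), dtype=bool)
    fascia[fascia_top:fascia_bot + 1, :] = True

    # Limiting membrane: downward-bowed parabolic band of ~8 px thickness.
    c = np.arange(W, dtype=np.float64)
    mid = (c - W / 2.0) / (W / 2.0)
    centre_row = 0.50 * H + 0.10 * H * mid**2
    half_t = max(3, round(0.01 * H))
    membrane_band = np.abs(rows - centre_row[None, :]) <= half_t
    if spec.membrane_gap_px > 0:
        # dash the membrane: alternate kept/removed column runs
        period = 3 * spec.membrane_gap_px
        keep = (np.arange(W) % period) < (period - spec.membrane_gap_px)
        membrane_band &= keep[None, :]

    liver = (rows > fascia_bot) & (rows < (centre_row[None, :] - half_t))

    below = rows > (centre_row[None, :] + half_t)

    # Perirenal fat annulus enclosing the renal cortex, lower right.
    cy, cx = 0.80 * H, 0.64 * W
    a_out, b_out = 0.14 * H, 0.21 * W
    thick = 0.032 * H
    a_in, b_in = a_out - thick, b_out - thick
    r_out = ((rows - cy) / a_out) ** 2 + ((cols - cx) / b_out) ** 2
    r_in = ((rows - cy) / a_in) ** 2 + ((cols - cx) / b_in) ** 2
    annulus = (r_out <= 1.0) & (r_in > 1.0) & below
    cortex = (r_in <= 1.0) & below

    return fascia, liver, membrane_band, below, annulus, cortex


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Render one phantom; deterministic for a fixed ``spec.seed``."""
    fascia, liver, membrane, below, annulus, cortex = _geometry(spec)

    means = np.full((spec.height, spec.width), spec.background, dtype=np.float64)
    means[liver] = spec.liver_mean
    means[below] = spec.kidney_mean        # perirenal tissue and cortex alike
    means[fascia] = spec.fascia_mean
    means[membrane] = spec.membrane_mean
    means[annulus] = spec.kidneyfat_mean

    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        means = means * (1.0 + spec.noise_cv * rng.standard_normal(means.shape))
    image = np.clip(np.rint(means), 0, 255).astype(np.uint8)

    kidney_mask = cortex & ~annulus
    return PhantomTruth(
        image=image,
        liver_mask=liver.copy(),
        kidney_mask=kidney_mask,
        true_hri_diff=float(spec.liver_mean - spec.kidney_mean),
        spec=spec,
        meta={"seed": spec.seed, "noise_cv": spec.noise_cv},
    )


def generate_cohort(
    n_per_class: int,
    class_means: list[tuple[float, float]],
    base_seed: int = 0,
    *,
    noise_cv: float = 0.1,
    labels: list[str] | None = None,
    **spec_kwargs,
) -> list[PhantomTruth]:
    """Generate ``n_per_class`` phantoms per (liver_mean, kidney_mean) class.

    Phantom ``i`` (global index, class-major order) uses seed
    ``base_seed + i`` so every cohort member is distinct yet reproducible.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if not class_means:
        raise ValueError("class_means must be nonempty")
    if labels is not None and len(labels) != len(class_means):
        raise ValueError("labels must match class_means in length")

    out: list[PhantomTruth] = []
    idx = 0
    for ci, (lm, km) in enumerate(class_means):
        for _ in range(n_per_class):
            spec = PhantomSpec(
                liver_mean=lm, kidney_mean=km, noise_cv=noise_cv,
                seed=base_seed + idx, **spec_kwargs,
            )
            ph = generate_phantom(spec)
            ph.label = labels[ci] if labels is not None else f"class{ci}"
            out.append(ph)
            idx += 1
    return out


def save_phantom(ph: PhantomTruth, out_dir, stem: str) -> Path:
    """Write image + masks as PNG and truth metadata as JSON; returns the JSON path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out / f"{stem}.png", ph.image)
    iio.imwrite(out / f"{stem}_liver_mask.png", (ph.liver_mask * np.uint8(255)))
    iio.imwrite(out / f"{stem}_kidney_mask.png", (ph.kidney_mask * np.uint8(255)))
    meta = {
        "true_hri_diff": ph.true_hri_diff,
        "label": ph.label,
        "spec": asdict(ph.spec),
        **ph.meta,
    }
    path = out / f"{stem}.json"
    path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path
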