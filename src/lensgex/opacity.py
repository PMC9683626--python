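"""Lens-opacity quantification from top-view grayscale photographs.

The cortical equatorial opacity of a cultured lens — the clouding of the
outer ring seen from above — is scored as the mean 8-bit brightness over the
outer 20% of the lens radius.  A lens is detected as the largest bright
connected component on the darker background; its annulus mask is taken at
``0.8·r < d ≤ r`` for the default fraction 0.2.  Treatment effect is the
paired difference: opacity after treatment minus opacity before, with the
geometry detected on the *before* image and reused for the after image so the
pair stays comparable.

The "weighted average" of the brightness measurement is interpreted as the
pixel-area-weighted mean, i.e. a plain mean over the annulus; a pluggable
``weights`` hook on :func:`opacity_score` allows other weightings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from skimage import color, measure
from skimage.filters import threshold_otsu
from statsmodels.iolib.table import SimpleTable

from .errors import DataError


@dataclass
class LensGeometry:
    """Detected lens disk: center (x, y) and radius, in pixels."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise DataError("lens radius must be positive")


@dataclass
class OpacityMeasurement:
    """Mean annulus brightness of one lens image."""

    image_id: str
    geometry: LensGeometry
    annulus_fraction: float
    mean_brightness: float
    n_pixels: int

    def __post_init__(self) -> None:
        if not 0 <= self.mean_brightness <= 255:
            raise DataError("mean brightness outside [0, 255]")
        if self.n_pixels <= 0:
            raise DataError("empty annulus mask")


def as_grayscale(image: np.ndarray) -> np.ndarray:
    """Coerce an input image to 8-bit grayscale (luma transform for colour)."""
    img = np.asarray(image)
    if img.ndim == 3:
        img = color.rgb2gray(img[..., :3]) * 255.0
    if img.dtype != np.uint8:
        img = np.clip(np.rint(img.astype(float)), 0, 255).astype(np.uint8)
    return img


def detect_lens_disk(image: np.ndarray, min_area: int = 64) -> LensGeometry:
    """Locate the lens as the largest bright connected foreground component.

    The center is the intensity-weighted centroid of that component and the
    radius is the equivalent-disk radius sqrt(area / pi).  Two disks in the
    frame select the larger one.
    """
    img = as_grayscale(image)
    if img.max() == img.min():
        raise DataError("no foreground: image is uniform")
    thresh = threshold_otsu(img)
    fg = img > thresh
    labels = measure.label(fg)
    props = [p for p in measure.regionprops(labels, intensity_image=img) if p.area >= min_area]
    if not props:
        raise DataError(f"no foreground component of area >= {min_area}")
    props.sort(key=lambda p: p.area, reverse=True)
    if len(props) > 1:
        import logging

        logging.getLogger(__name__).warning(
            "detect_lens_disk: %d foreground components, using the largest", len(props)
        )
    best = props[0]
    cy, cx = best.centroid_weighted
    radius = float(np.sqrt(best.area / np.pi))
    return LensGeometry(center=(float(cx), float(cy)), radius=radius)


def cortical_annulus_mask(
    geometry: LensGeometry,
    shape: tuple[int, int],
    annulus_fraction: float = 0.20,
) -> np.ndarray:
    """Boolean mask of the outer ``annulus_fraction`` of the lens radius.

    For the default fraction 0.2 the mask covers pixels with
    ``0.8·r < distance-from-center ≤ r``.
    """
    if not 0 < annulus_fraction <= 1:
        raise ValueError("annulus_fraction must lie in (0, 1]")
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dist = np.hypot(yy - geometry.center[1], xx - geometry.center[0])
    inner = (1.0 - annulus_fraction) * geometry.radius
    mask = (dist > inner) & (dist <= geometry.radius)
    if not mask.any():
        raise ValueError("annulus mask is empty")
    return mask


def opacity_score(
    image: np.ndarray,
    mask: np.ndarray,
    weights: Callable[[np.ndarray], np.ndarray] | None = None,
) -> float:
    """Mean brightness (0–255) of the image under the mask.

    ``weights`` maps the masked pixel values to non-negative weights for a
    weighted mean; the default is the uniform (pixel-area) weighting.
    """
    img = as_grayscale(image)
    if mask.shape != img.shape:
        raise ValueError("mask shape differs from image shape")
    if not mask.any():
        raise ValueError("empty mask")
    vals = img[mask].astype(float)
    if weights is None:
        return float(vals.mean())
    w = np.asarray(weights(vals), dtype=float)
    if (w < 0).any() or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    return float(np.average(vals, weights=w))


def measure_lens(
    image: np.ndarray,
    image_id: str = "",
    annulus_fraction: float = 0.20,
    geometry: LensGeometry | None = None,
) -> OpacityMeasurement:
    """Detect (or reuse) the lens geometry and score its cortical annulus."""
    img = as_grayscale(image)
    geom = geometry if geometry is not None else detect_lens_disk(img)
    mask = cortical_annulus_mask(geom, img.shape, annulus_fraction)
    return OpacityMeasurement(
        image_id=image_id,
        geometry=geom,
        annulus_fraction=annulus_fraction,
        mean_brightness=opacity_score(img, mask),
        n_pixels=int(mask.sum()),
    )


def delta_opacity(before: OpacityMeasurement, after: OpacityMeasurement) -> float:
    """Signed brightness change of one lens: after minus before."""
    if before.annulus_fraction != after.annulus_fraction:
        raise ValueError("before/after measurements use different annulus fractions")
    return after.mean_brightness - before.mean_brightness


class OpacityAssay:
    """Paired before/after opacity measurement over groups of lenses.

    ``pairs`` maps a group label (e.g. ``vehicle``, ``TH1834``) to a sequence
    of ``(before_image, after_image)`` pairs.  Geometry is detected on each
    *before* image and reused for its partner.
    """

    def __init__(self, pairs: dict[str, Sequence[tuple[np.ndarray, np.ndarray]]],
                 annulus_fraction: float = 0.20):
        self.pairs = pairs
        self.annulus_fraction = annulus_fraction

    def fit(self) -> "OpacityResults":
        deltas: dict[str, list[float]] = {}
        measurements: dict[str, list[tuple[OpacityMeasurement, OpacityMeasurement]]] = {}
        for group, lens_pairs in self.pairs.items():
            deltas[group] = []
            measurements[group] = []
            for i, (before_img, after_img) in enumerate(lens_pairs):
                before = measure_lens(before_img, f"{group}_{i}_before", self.annulus_fraction)
                after = measure_lens(
                    after_img, f"{group}_{i}_after", self.annulus_fraction,
                    geometry=before.geometry,
                )
                measurements[group].append((before, after))
                deltas[group].append(delta_opacity(before, after))
        return OpacityResults(self, deltas, measurements)


@dataclass
class OpacityResults:
    model: OpacityAssay
    deltas: dict[str, list[float]]
    measurements: dict[str, list]

    def group_summary(self) -> dict[str, tuple[float, float]]:
        """Per-group mean ± standard error of the paired opacity change."""
        out = {}
        for group, d in self.deltas.items():
            arr = np.asarray(d, dtype=float)
            se = arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else float("nan")
            out[group] = (float(arr.mean()), float(se))
        return out

    def summary(self) -> SimpleTable:
        rows = [
            [g, f"{m:.2f}", f"{se:.2f}", str(len(self.deltas[g]))]
            for g, (m, se) in self.group_summary().items()
        ]
        return SimpleTable(
            rows,
            headers=["group", "delta mean", "SE", "n"],
            title=f"Cortical opacity change (annulus fraction {self.model.annulus_fraction:g})",
        )
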