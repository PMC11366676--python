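"""Pixel-class quantification of stained valve slides.

Movat pentachrome renders collagen-rich fibrotic tissue red and
mineralised (calcific) tissue yellow; quantitative histology reduces a
slide to the fraction of tissue pixels in each of those two classes.
Here pixels are classified by maximum likelihood under class-conditional
Gaussian colour models in CIELAB (a perceptually uniform space, so
Euclidean-ish covariances are meaningful); everything best explained by
the pooled "other" class (ground substance, elastin, background) or
darker than a luminance bound is non-tissue.  Per-slide fibrotic
percentages are averaged, unweighted, across the nine slices of a valve
(three per cusp) to give the per-valve composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.color import rgb2lab

__all__ = [
    "SlideImage",
    "ClassColorReference",
    "SlideComposition",
    "ValveComposition",
    "classify_pixels",
    "slide_composition",
    "valve_composition",
]

#: Label codes of the pixel classifier.
PIXEL_OTHER, PIXEL_FIBROTIC, PIXEL_CALCIFIC = 0, 1, 2


@dataclass(frozen=True)
class SlideImage:
    """One stained slide raster with its cusp/slice position in the valve."""

    rgb: np.ndarray  # (H, W, 3) uint8
    cusp_id: int = 1
    slice_id: int = 1

    def __post_init__(self) -> None:
        arr = np.asarray(self.rgb)
        if arr.ndim != 3 or arr.shape[2] != 3 or arr.size == 0:
            raise ValueError("rgb must be a nonempty (H, W, 3) raster")
        if not (1 <= self.cusp_id <= 3 and 1 <= self.slice_id <= 3):
            raise ValueError("cusp_id and slice_id must be in 1..3")
        object.__setattr__(self, "rgb", arr.astype(np.uint8))


@dataclass(frozen=True)
class ClassColorReference:
    """Gaussian colour models for fibrotic / calcific / other pixels.

    ``class_rgb`` holds the nominal 8-bit RGB class colours (also used by
    the slide generator); ``lab_means``/``lab_covs`` are the corresponding
    CIELAB class models the classifier evaluates.  ``min_luminance`` (L*)
    excludes near-black pixels (dust, tears) from tissue.
    """

    class_rgb: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "fibrotic": (178.0, 34.0, 34.0),   # Movat collagen red
            "calcific": (218.0, 165.0, 32.0),  # mineral yellow
            "other": (245.0, 245.0, 245.0),    # background / unstained
        }
    )
    lab_cov_diag: tuple[float, float, float] = (30.0, 30.0, 30.0)
    min_luminance: float = 8.0

    def __post_init__(self) -> None:
        names = set(self.class_rgb)
        if names != {"fibrotic", "calcific", "other"}:
            raise ValueError("class_rgb must define fibrotic, calcific and other")
        if any(c <= 0 for c in self.lab_cov_diag):
            raise ValueError("covariance diagonal must be positive definite")
        rgbs = [tuple(v) for v in self.class_rgb.values()]
        if len(set(rgbs)) != 3:
            raise ValueError("class colours must be pairwise distinct")

    @classmethod
    def movat_default(cls) -> "ClassColorReference":
        return cls()

    def lab_means(self) -> dict[str, np.ndarray]:
        out = {}
        for name, rgb in self.class_rgb.items():
            arr = np.asarray(rgb, dtype=float).reshape(1, 1, 3) / 255.0
            out[name] = rgb2lab(arr).reshape(3)
        return out


def classify_pixels(slide: SlideImage, ref: ClassColorReference) -> np.ndarray:
    """Assign each pixel the colour class with the highest Gaussian likelihood.

    Returns an (H, W) uint8 raster of {0 other/non-tissue, 1 fibrotic,
    2 calcific}.  Deterministic: ties break toward the lower class code.
    """
    lab = rgb2lab(np.asarray(slide.rgb, dtype=float) / 255.0)
    means = ref.lab_means()
    inv = 1.0 / np.asarray(ref.lab_cov_diag, dtype=float)
    scores = np.stack(
        [
            -0.5 * np.sum((lab - means[name]) ** 2 * inv, axis=2)
            for name in ("other", "fibrotic", "calcific")
        ],
        axis=0,
    )  # diagonal covariances share the same normalising constant
    labels = np.argmax(scores, axis=0).astype(np.uint8)
    labels[lab[..., 0] < ref.min_luminance] = PIXEL_OTHER
    return labels


@dataclass(frozen=True)
class SlideComposition:
    """Pixel counts of one slide and its fibrotic share of tissue pixels."""

    n_fibrotic: int
    n_calcific: int
    n_other: int
    fibrotic_pct: float
    defined: bool
    cusp_id: int = 1
    slice_id: int = 1


def slide_composition(
    labels: np.ndarray, cusp_id: int = 1, slice_id: int = 1
) -> SlideComposition:
    """Fibrotic percentage of tissue pixels; "other" is excluded from the denominator."""
    labels = np.asarray(labels)
    n_fib = int((labels == PIXEL_FIBROTIC).sum())
    n_cal = int((labels == PIXEL_CALCIFIC).sum())
    n_other = int(labels.size - n_fib - n_cal)
    tissue = n_fib + n_cal
    if tissue == 0:
        return SlideComposition(0, 0, n_other, float("nan"), False, cusp_id, slice_id)
    return SlideComposition(
        n_fib, n_cal, n_other, 100.0 * n_fib / tissue, True, cusp_id, slice_id
    )


@dataclass(frozen=True)
class ValveComposition:
    """Per-valve composition: unweighted mean over defined slide values."""

    slides: tuple[SlideComposition, ...]
    cusp_means: dict[int, float]
    valve_fibrotic_pct: float
    n_undefined: int

    @property
    def valve_calcific_pct(self) -> float:
        return 100.0 - self.valve_fibrotic_pct


def valve_composition(slides: Sequence[SlideComposition]) -> ValveComposition:
    """Aggregate slide compositions to the valve level.

    The valve value is the plain arithmetic mean of the defined slide
    percentages (slides are not weighted by pixel count); undefined slides
    are dropped and counted.  Per-cusp means are reported alongside.
    """
    defined = [s for s in slides if s.defined]
    if not defined:
        raise ValueError("all slide compositions undefined; no tissue to aggregate")
    cusp_vals: dict[int, list[float]] = {}
    for s in defined:
        cusp_vals.setdefault(s.cusp_id, []).append(s.fibrotic_pct)
    return ValveComposition(
        slides=tuple(slides),
        cusp_means={c: float(np.mean(v)) for c, v in sorted(cusp_vals.items())},
        valve_fibrotic_pct=float(np.mean([s.fibrotic_pct for s in defined])),
        n_undefined=len(slides) - len(defined),
    )
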