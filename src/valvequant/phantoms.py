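"""Synthetic phantoms with known ground truth.

No imaging or histology data accompany the study design this package
implements, so every downstream stage is exercised on simulated inputs:

* CT phantoms — a roughly spherical valve ROI whose voxels are partitioned
  into contiguous fibrotic and calcific blobs embedded in contrast-bright
  blood pool, with per-class Gaussian HU noise;
* second-reader ROI variants — seeded boundary perturbations emulating two
  readers contouring the same valve;
* pseudo-histology — stained-slide rasters (nine per valve, three per cusp)
  whose fibrotic/calcific pixel fractions equal the valve composition plus
  truncated-Gaussian noise;
* cohorts — paired CTA-vs-histology composition and reader1-vs-reader2
  volume tables with a controlled intermodality bias (CTA shifted below
  histology) for the agreement statistics.

Default class HU parameters — fibrotic N(90, 35), blood N(420, 45),
calcific N(850, 120) — give the separable populations expected on
contrast CT angiography; default cohort medians and group sizes follow
the stenosis-severity strata of the validation study design
(19 severe / 5 moderate / 5 control).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .ct import CTVolume, ROIMask, TissueLabel
from .histology import ClassColorReference, SlideImage

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "CohortSpec",
    "generate_ct_phantom",
    "generate_reader_variant",
    "generate_histology_set",
    "generate_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one CT valve phantom.

    ``class_params`` maps class name -> (mean HU, SD HU) and must respect
    the contrast-CT ordering fibrotic < blood < calcific.  ``target_volumes``
    are the requested fibrotic and calcific volumes in cm^3; the realized
    voxel counts are the nearest integers.  ``blood_fraction`` is the share
    of ROI voxels assigned to the blood pool.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    class_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "fibrotic": (90.0, 35.0),
            "blood": (420.0, 45.0),
            "calcific": (850.0, 120.0),
        }
    )
    target_volumes: dict[str, float] = field(
        default_factory=lambda: {"fibrotic": 1.18, "calcific": 0.79}
    )
    blood_fraction: float = 0.35
    background_hu: float = -1024.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(g) < 1 for g in self.grid_shape):
            raise ValueError("grid_shape must be a positive integer triple")
        if any(float(s) <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be strictly positive")
        for name in ("fibrotic", "blood", "calcific"):
            if name not in self.class_params:
                raise ValueError(f"class_params missing {name!r}")
            if self.class_params[name][1] <= 0:
                raise ValueError(f"{name} SD must be > 0")
        mf, mb, mc = (self.class_params[n][0] for n in ("fibrotic", "blood", "calcific"))
        if not (mf < mb < mc):
            raise ValueError("class means must satisfy fibrotic < blood < calcific")
        if self.background_hu >= mf:
            raise ValueError("background HU must lie below all class means")
        if any(self.target_volumes.get(n, 0.0) < 0 for n in ("fibrotic", "calcific")):
            raise ValueError("target volumes must be >= 0")
        if not (0.0 <= self.blood_fraction < 1.0):
            raise ValueError("blood_fraction must be in [0, 1)")

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.voxel_spacing)) / 1000.0

    def voxel_counts(self) -> dict[str, int]:
        """Requested per-class voxel counts, including derived blood count."""
        n_fib = round(self.target_volumes.get("fibrotic", 0.0) / self.voxel_volume_cm3)
        n_cal = round(self.target_volumes.get("calcific", 0.0) / self.voxel_volume_cm3)
        n_tissue = n_fib + n_cal
        if n_tissue == 0:
            raise ValueError("phantom needs at least one tissue voxel")
        n_roi = math.ceil(n_tissue / (1.0 - self.blood_fraction))
        return {
            "fibrotic": n_fib,
            "calcific": n_cal,
            "blood": n_roi - n_tissue,
            "roi": n_roi,
        }


@dataclass(frozen=True)
class GroundTruth:
    """Realized per-voxel labels and the exact volumes/composition they imply."""

    label_mask: np.ndarray
    true_volumes: dict[str, float]
    true_composition: float  # fibrotic % of (fibrotic + calcific)

    def __post_init__(self) -> None:
        if not (0.0 <= self.true_composition <= 100.0):
            raise ValueError("true_composition must lie in [0, 100]")


def _nearest_voxels(dist: np.ndarray, candidates: np.ndarray, n: int) -> np.ndarray:
    """Flat indices of the n candidates with smallest distance (stable ties)."""
    order = np.lexsort((candidates, dist))
    return candidates[order[:n]]


def generate_ct_phantom(spec: PhantomSpec) -> tuple[CTVolume, ROIMask, GroundTruth]:
    """Simulate one CT valve phantom.

    The ROI is the set of voxels physically nearest the grid centre, sized
    to hold the requested tissue plus blood pool.  Calcific then fibrotic
    voxels are carved out of the ROI as unions of balls around seeded
    random centres, which keeps blobs contiguous and boundary statistics
    nontrivial; the remainder is blood.  HU values are drawn per voxel
    from the class Gaussians; everything outside the ROI is flat
    background below all class means.
    """
    counts = spec.voxel_counts()
    shape = tuple(int(g) for g in spec.grid_shape)
    total = int(np.prod(shape))
    if counts["roi"] > total:
        raise ValueError(
            f"requested ROI of {counts['roi']} voxels exceeds grid capacity {total}"
        )
    rng = np.random.default_rng(spec.seed)

    # physical distance of every voxel from the grid centre
    axes = [
        (np.arange(shape[i]) - (shape[i] - 1) / 2.0) * spec.voxel_spacing[i]
        for i in range(3)
    ]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    centre_dist = np.sqrt(gx**2 + gy**2 + gz**2).ravel()
    roi_flat = _nearest_voxels(centre_dist, np.arange(total), counts["roi"])

    labels = np.full(total, TissueLabel.BACKGROUND, dtype=np.uint8)
    coords = np.column_stack(np.unravel_index(roi_flat, shape)).astype(float)
    coords *= np.asarray(spec.voxel_spacing)

    remaining = np.arange(roi_flat.size)  # positions within roi_flat
    for name, lab in (("calcific", TissueLabel.CALCIFIC), ("fibrotic", TissueLabel.FIBROTIC)):
        n = counts[name]
        if n == 0:
            continue
        n_centres = max(1, n // 3000)
        centre_pos = rng.choice(remaining, size=min(n_centres, remaining.size), replace=False)
        d = np.min(
            np.linalg.norm(
                coords[remaining][:, None, :] - coords[centre_pos][None, :, :], axis=2
            ),
            axis=1,
        )
        pick = _nearest_voxels(d, remaining, n)
        labels[roi_flat[pick]] = lab
        remaining = np.setdiff1d(remaining, pick, assume_unique=True)
    labels[roi_flat[remaining]] = TissueLabel.BLOOD

    labels = labels.reshape(shape)
    hu = np.full(shape, spec.background_hu, dtype=np.float32)
    for name, lab in (
        ("fibrotic", TissueLabel.FIBROTIC),
        ("blood", TissueLabel.BLOOD),
        ("calcific", TissueLabel.CALCIFIC),
    ):
        sel = labels == lab
        mean, sd = spec.class_params[name]
        hu[sel] = rng.normal(mean, sd, size=int(sel.sum())).astype(np.float32)

    vox = spec.voxel_volume_cm3
    v_fib = counts["fibrotic"] * vox
    v_cal = counts["calcific"] * vox
    truth = GroundTruth(
        label_mask=labels,
        true_volumes={
            "fibrotic": v_fib,
            "calcific": v_cal,
            "blood": counts["blood"] * vox,
        },
        true_composition=100.0 * v_fib / (v_fib + v_cal),
    )
    volume = CTVolume(intensities=hu, voxel_spacing=spec.voxel_spacing)
    mask = ROIMask(mask=labels != TissueLabel.BACKGROUND, reader="reader1")
    return volume, mask, truth


def generate_reader_variant(
    mask: ROIMask, boundary_jitter: int, seed: int, flip_prob: float = 0.3
) -> ROIMask:
    """Perturb an ROI within ``boundary_jitter`` voxels of its boundary.

    Emulates a second reader contouring the same valve: each voxel in the
    band within ``boundary_jitter`` of the original boundary flips its
    membership independently with probability ``flip_prob``.  Jitter 0
    returns the mask unchanged (new reader id only).
    """
    if boundary_jitter < 0:
        raise ValueError("boundary_jitter must be >= 0")
    if mask.n_voxels == 0:
        raise ValueError("cannot perturb an empty mask")
    m = mask.mask
    if boundary_jitter == 0:
        return ROIMask(mask=m.copy(), reader="reader2")
    inner = ndimage.binary_erosion(m, iterations=boundary_jitter)
    outer = ndimage.binary_dilation(m, iterations=boundary_jitter)
    band = outer & ~inner
    rng = np.random.default_rng(seed)
    flips = band & (rng.random(m.shape) < flip_prob)
    out = m ^ flips
    if not out.any():
        raise ValueError("perturbation emptied the mask")
    return ROIMask(mask=out, reader="reader2")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    """One truncated-Gaussian draw by rejection (sd 0 returns the mean)."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(10_000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))  # pathological sd >> range


def generate_histology_set(
    truth: GroundTruth,
    n_slices: int = 9,
    composition_noise_sd: float = 0.0,
    seed: int = 0,
    slide_shape: tuple[int, int] = (128, 128),
    color_reference: ClassColorReference | None = None,
    color_noise_sd: float = 6.0,
) -> list[tuple[SlideImage, float]]:
    """Render stained-slide rasters whose pixel fractions carry the valve composition.

    Each slide's target fibrotic fraction is the valve's true composition
    plus independent truncated-Gaussian noise on the percentage scale.
    Tissue occupies a central disc; the fibrotic share fills the disc from
    its centre outwards with the calcific remainder as an outer rim, and
    pixel colours are drawn around the class reference colours.  Slides are
    grouped three per cusp (cusp_id cycles 1..ceil(n/3)).
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if composition_noise_sd < 0:
        raise ValueError("composition noise SD must be >= 0")
    ref = color_reference if color_reference is not None else ClassColorReference.movat_default()
    rng = np.random.default_rng(seed)
    h, w = slide_shape

    yy, xx = np.mgrid[0:h, 0:w]
    r = np.sqrt((yy - (h - 1) / 2) ** 2 + (xx - (w - 1) / 2) ** 2)
    tissue = r <= 0.45 * min(h, w)
    tissue_idx = np.flatnonzero(tissue.ravel())
    # fill fibrotic from the disc centre outwards -> contiguous regions
    order = np.lexsort((tissue_idx, r.ravel()[tissue_idx]))
    tissue_sorted = tissue_idx[order]
    n_tissue = tissue_sorted.size

    out: list[tuple[SlideImage, float]] = []
    for i in range(n_slices):
        comp = _truncated_normal(rng, truth.true_composition, composition_noise_sd, 0.0, 100.0)
        n_fib = round(comp / 100.0 * n_tissue)
        rgb = np.empty((h * w, 3), dtype=float)
        rgb[:] = ref.class_rgb["other"]
        rgb[tissue_sorted[:n_fib]] = ref.class_rgb["fibrotic"]
        rgb[tissue_sorted[n_fib:]] = ref.class_rgb["calcific"]
        rgb += rng.normal(0.0, color_noise_sd, size=rgb.shape)
        img = np.clip(rgb, 0, 255).astype(np.uint8).reshape(h, w, 3)
        out.append(
            (SlideImage(rgb=img, cusp_id=i // 3 + 1, slice_id=i % 3 + 1), comp)
        )
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated study cohort.

    ``group_medians`` maps group -> (median fibrotic cm^3, median calcific
    cm^3); per-participant volumes are lognormal around those medians with
    ``lognormal_sigmas`` (fibrotic, calcific) log-scale spreads.
    ``intermodality_bias`` is the number of percentage points by which the
    CTA fibrotic composition sits below histology.
    """

    n_severe: int = 19
    n_moderate: int = 5
    n_control: int = 5
    group_medians: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "severe": (1.18, 0.79),
            "moderate": (1.36, 0.11),
            "control": (0.71, 0.04),
        }
    )
    lognormal_sigmas: tuple[float, float] = (0.5, 1.0)
    intermodality_bias: float = 5.0
    composition_noise_sd: float = 3.0
    reader_noise_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_severe, self.n_moderate, self.n_control) < 0:
            raise ValueError("group sizes must be >= 0")
        if self.composition_noise_sd < 0 or self.reader_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")


def generate_cohort(cohort: CohortSpec) -> pd.DataFrame:
    """Simulate paired per-participant measurements for the agreement analyses.

    Returns one row per participant with true fibrotic/calcific volumes and
    composition, the CTA composition (true minus the intermodality bias plus
    noise), the histology composition (true plus noise), and two-reader
    volume measurements; compositions are truncated to [0, 100] and volumes
    to be nonnegative.
    """
    rng = np.random.default_rng(cohort.seed)
    sf, sc = cohort.lognormal_sigmas
    rows = []
    pid = 0
    for group, n in (
        ("severe", cohort.n_severe),
        ("moderate", cohort.n_moderate),
        ("control", cohort.n_control),
    ):
        med_f, med_c = cohort.group_medians[group]
        for _ in range(n):
            pid += 1
            v_f = med_f * math.exp(rng.normal(0.0, sf))
            v_c = med_c * math.exp(rng.normal(0.0, sc))
            comp = 100.0 * v_f / (v_f + v_c)
            cta = _truncated_normal(
                rng, comp - cohort.intermodality_bias, cohort.composition_noise_sd, 0.0, 100.0
            )
            histo = _truncated_normal(rng, comp, cohort.composition_noise_sd, 0.0, 100.0)
            r_noise = rng.normal(0.0, cohort.reader_noise_sd, size=4) \
                if cohort.reader_noise_sd > 0 else np.zeros(4)
            rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "true_fibrotic_cm3": v_f,
                    "true_calcific_cm3": v_c,
                    "true_fibrotic_pct": comp,
                    "cta_fibrotic_pct": cta,
                    "histo_fibrotic_pct": histo,
                    "fibrotic_cm3_reader1": max(0.0, v_f + r_noise[0]),
                    "fibrotic_cm3_reader2": max(0.0, v_f + r_noise[1]),
                    "calcific_cm3_reader1": max(0.0, v_c + r_noise[2]),
                    "calcific_cm3_reader2": max(0.0, v_c + r_noise[3]),
                }
            )
    return pd.DataFrame(rows)
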