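"""Scan-specific Gaussian-mixture thresholding of contrast-CT valve tissue.

On contrast-enhanced CT angiography the aortic valve region of interest
contains three intensity populations, ordered in Hounsfield units:
soft fibrotic tissue < contrast-enhanced blood pool < calcium.  Because
contrast opacification varies between scans, fixed HU cut-offs are
unreliable; instead a three-component 1-D Gaussian mixture is fitted to
the ROI intensity histogram of *each* scan and the two class boundaries
are derived from the fitted mixture.  Voxels are then hard-classified by
those thresholds and tissue volumes, composition percentages and the
fibrocalcific ratio are computed from the label counts.

The blood pool is excluded from "total tissue volume", so fibrotic and
calcific composition percentages sum to 100 by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Sequence

import numpy as np

__all__ = [
    "TissueLabel",
    "CTVolume",
    "ROIMask",
    "IntensityMixture",
    "TissueThresholds",
    "TissueQuantification",
    "extract_roi_intensities",
    "fit_intensity_mixture",
    "derive_thresholds",
    "classify_voxels",
    "quantify_tissue",
]

#: Default HU floor below which ROI voxels are excluded as non-tissue
#: (air / epicardial fat); tissue of interest attenuates well above this.
DEFAULT_TISSUE_FLOOR_HU = -30.0

#: Lower bound on fitted component SDs (HU), preventing EM collapse onto
#: a single repeated value.
SD_FLOOR_HU = 1.0


class TissueLabel(IntEnum):
    """Per-voxel class labels shared by the phantom generator and classifier."""

    BACKGROUND = 0
    EXCLUDED = 1
    FIBROTIC = 2
    BLOOD = 3
    CALCIFIC = 4


@dataclass(frozen=True)
class CTVolume:
    """A 3-D grid of Hounsfield-unit intensities with physical voxel spacing.

    Parameters
    ----------
    intensities
        3-D array of HU values.
    voxel_spacing
        Voxel edge lengths in mm, one per axis; strictly positive.
    """

    intensities: np.ndarray
    voxel_spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3 or arr.size == 0:
            raise ValueError("intensities must be a nonempty 3-D array")
        sp = tuple(float(s) for s in self.voxel_spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError("voxel_spacing must be three strictly positive mm values")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "voxel_spacing", sp)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing))


@dataclass(frozen=True)
class ROIMask:
    """Boolean valve region of interest, congruent with its CT volume."""

    mask: np.ndarray
    reader: str = "reader1"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 3:
            raise ValueError("mask must be a 3-D array")
        object.__setattr__(self, "mask", m.astype(bool))

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class IntensityMixture:
    """A fitted 1-D Gaussian mixture, components sorted by ascending mean."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool
    log_likelihood_path: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        m = np.asarray(self.means, dtype=float)
        s = np.asarray(self.sds, dtype=float)
        if not (w.shape == m.shape == s.shape) or w.ndim != 1:
            raise ValueError("weights, means, sds must be 1-D arrays of equal length")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(s < SD_FLOOR_HU - 1e-12):
            raise ValueError(f"component SDs must be >= {SD_FLOOR_HU} HU")
        if np.any(np.diff(m) < 0):
            raise ValueError("components must be sorted by ascending mean")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "sds", s)

    @property
    def K(self) -> int:
        return int(self.weights.size)

    def component_log_density(self, x: np.ndarray) -> np.ndarray:
        """Weighted per-component log density, shape ``(len(x), K)``."""
        x = np.asarray(x, dtype=float)[:, None]
        w, mu, sd = self.weights[None, :], self.means[None, :], self.sds[None, :]
        return (
            np.log(w)
            - 0.5 * math.log(2.0 * math.pi)
            - np.log(sd)
            - 0.5 * ((x - mu) / sd) ** 2
        )

    def posterior_argmax(self, x: np.ndarray) -> np.ndarray:
        """Index of the component with the highest posterior at each value."""
        return np.argmax(self.component_log_density(x), axis=1)


@dataclass(frozen=True)
class TissueThresholds:
    """HU partition of the ROI: floor < t_low (fibrotic/blood) < t_high (blood/calcific)."""

    t_low: float
    t_high: float
    floor: float = DEFAULT_TISSUE_FLOOR_HU
    fallback_used: bool = False

    def __post_init__(self) -> None:
        if not (self.floor < self.t_low < self.t_high):
            raise ValueError(
                f"require floor < t_low < t_high, got "
                f"{self.floor} / {self.t_low} / {self.t_high}"
            )


@dataclass(frozen=True)
class TissueQuantification:
    """Tissue volumes (cm^3), composition (%), and the fibrocalcific ratio.

    ``fibrotic_pct`` and ``calcific_pct`` are percentages of the
    fibrocalcific (fibrotic + calcific) volume; blood-pool and excluded
    voxels are not part of the denominator, so the two percentages sum
    to 100 whenever any fibrocalcific tissue is present.
    """

    v_fibrotic: float
    v_calcific: float
    v_blood: float
    v_excluded: float
    fibrotic_pct: float
    calcific_pct: float
    fibrocalcific_ratio: float
    composition_defined: bool
    ratio_defined: bool

    @property
    def v_fibrocalcific(self) -> float:
        return self.v_fibrotic + self.v_calcific


def extract_roi_intensities(volume: CTVolume, mask: ROIMask) -> np.ndarray:
    """Return the multiset of HU values at ROI voxels (count preserved)."""
    if volume.intensities.shape != mask.mask.shape:
        raise ValueError(
            f"volume shape {volume.intensities.shape} != mask shape {mask.mask.shape}"
        )
    if mask.n_voxels == 0:
        raise ValueError("ROI mask is empty")
    return np.asarray(volume.intensities, dtype=float)[mask.mask]


def _em_init_means(sample: np.ndarray, k: int) -> np.ndarray:
    # 10th/50th/90th percentiles for the canonical three-class case spread
    # the initial means across the fibrotic / blood / calcific modes.
    if k == 3:
        q = [10.0, 50.0, 90.0]
    else:
        q = list(100.0 * (np.arange(1, k + 1)) / (k + 1))
    return np.percentile(sample, q)


def _run_em(
    x: np.ndarray,
    weights: np.ndarray,
    means: np.ndarray,
    sds: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], bool, int]:
    """EM iterations from one starting point; returns the final state and LL path."""
    n = x.size
    xc = x[:, None]
    ll_path: list[float] = []
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step: responsibilities via log-sum-exp
        logp = (
            np.log(weights)[None, :]
            - 0.5 * math.log(2 * math.pi)
            - np.log(sds)[None, :]
            - 0.5 * ((xc - means[None, :]) / sds[None, :]) ** 2
        )
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        ll_path.append(ll)
        resp = np.exp(logp - lse[:, None])

        if np.isfinite(prev_ll):
            rel = abs(ll - prev_ll) / max(abs(prev_ll), 1.0)
            if rel < tol:
                converged = True
                break
        prev_ll = ll

        # M step
        nk = np.maximum(resp.sum(axis=0), 1e-300)
        weights = nk / n
        means = (resp * xc).sum(axis=0) / nk
        var = (resp * (xc - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.maximum(np.sqrt(var), SD_FLOOR_HU)
    return weights, means, sds, ll_path, converged, it


def fit_intensity_mixture(
    sample: Sequence[float] | np.ndarray,
    K: int = 3,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_init: int = 5,
) -> IntensityMixture:
    """Fit a K-component 1-D Gaussian mixture to HU values by EM.

    EM is run from ``n_init`` starting points and the fit with the highest
    final log likelihood is kept (a single start can lock onto a local
    optimum that merges two tissue populations).  The first start is
    deterministic — equal weights, means at spread sample percentiles
    (10/50/90 for K=3), all SDs at the pooled sample SD; the remaining
    starts place the means at randomly chosen data values using ``seed``,
    so the whole procedure is reproducible.  Convergence is declared when
    the relative change in total log likelihood drops below ``tol``;
    otherwise the fit is returned with ``converged=False``.

    Raises
    ------
    ValueError
        If the sample is too small (``< 10*K``) or is constant while K > 1.
    """
    x = np.asarray(sample, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    if K < 1:
        raise ValueError("K must be >= 1")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    n = x.size
    if n < 10 * K:
        raise ValueError(f"sample size {n} < 10*K = {10 * K}")

    if K == 1:
        mu = float(x.mean())
        sd = max(float(x.std()), SD_FLOOR_HU)  # population SD, closed form
        ll = float(
            np.sum(-0.5 * math.log(2 * math.pi) - math.log(sd) - 0.5 * ((x - mu) / sd) ** 2)
        )
        return IntensityMixture(
            weights=np.array([1.0]),
            means=np.array([mu]),
            sds=np.array([sd]),
            log_likelihood=ll,
            n_iterations=0,
            converged=True,
            log_likelihood_path=np.array([ll]),
        )

    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: all values identical with K > 1")

    rng = np.random.default_rng(seed)
    spread = max(float(x.std()), SD_FLOOR_HU)

    starts: list[np.ndarray] = []
    means0 = _em_init_means(x, K).astype(float)
    if np.any(np.diff(means0) <= 0):
        means0 = np.sort(means0 + rng.normal(0.0, 0.01 * spread, size=K))
    starts.append(means0)
    for _ in range(n_init - 1):
        starts.append(np.sort(rng.choice(x, size=K, replace=False)))

    best: tuple | None = None
    for init_means in starts:
        w, mu, sd, ll_path, converged, it = _run_em(
            x,
            np.full(K, 1.0 / K),
            init_means.copy(),
            np.full(K, spread),
            tol,
            max_iter,
        )
        if best is None or ll_path[-1] > best[3][-1]:
            best = (w, mu, sd, ll_path, converged, it)

    weights, means, sds, ll_path, converged, it = best
    order = np.argsort(means, kind="stable")
    return IntensityMixture(
        weights=weights[order] / weights.sum(),
        means=means[order],
        sds=sds[order],
        log_likelihood=ll_path[-1],
        n_iterations=it,
        converged=converged,
        log_likelihood_path=np.asarray(ll_path),
    )


def _weighted_density_crossing(
    w1: float, m1: float, s1: float, w2: float, m2: float, s2: float
) -> float | None:
    """Smallest x in the open interval (m1, m2) where w1*N(m1,s1) = w2*N(m2,s2).

    The equality of two weighted Gaussian densities is a quadratic in x;
    with equal SDs it degenerates to a linear equation.  Returns None when
    no real root falls strictly between the two means.
    """
    a = 0.5 / s2**2 - 0.5 / s1**2
    b = m1 / s1**2 - m2 / s2**2
    c = 0.5 * m2**2 / s2**2 - 0.5 * m1**2 / s1**2 + math.log((w1 * s2) / (w2 * s1))
    if abs(a) < 1e-15:
        if abs(b) < 1e-15:
            return None
        roots = np.array([-c / b])
    else:
        disc = b * b - 4 * a * c
        if disc < 0:
            return None
        sq = math.sqrt(disc)
        roots = np.array([(-b - sq) / (2 * a), (-b + sq) / (2 * a)])
    inside = roots[(roots > m1) & (roots < m2)]
    if inside.size == 0:
        return None
    return float(inside.min())


def derive_thresholds(
    mixture: IntensityMixture, floor: float = DEFAULT_TISSUE_FLOOR_HU
) -> TissueThresholds:
    """Derive scan-specific HU class boundaries from a fitted K=3 mixture.

    Each boundary is the smallest HU value strictly between two adjacent
    component means at which their weighted densities are equal (the point
    where the posterior flips between the two classes).  If the components
    overlap so pathologically that no crossing lies between the means, the
    midpoint of the means is used and ``fallback_used`` is flagged.
    """
    if mixture.K != 3:
        raise ValueError(f"threshold derivation requires K=3 components, got K={mixture.K}")
    w, mu, sd = mixture.weights, mixture.means, mixture.sds
    bounds: list[float] = []
    fallback = False
    for i in (0, 1):
        x = _weighted_density_crossing(w[i], mu[i], sd[i], w[i + 1], mu[i + 1], sd[i + 1])
        if x is None:
            x = 0.5 * (mu[i] + mu[i + 1])
            fallback = True
        bounds.append(x)
    return TissueThresholds(
        t_low=bounds[0], t_high=bounds[1], floor=float(floor), fallback_used=fallback
    )


def classify_voxels(
    volume: CTVolume, mask: ROIMask, thresholds: TissueThresholds
) -> np.ndarray:
    """Label every voxel by the half-open HU partition.

    ROI voxels: HU < floor -> EXCLUDED; [floor, t_low) -> FIBROTIC;
    [t_low, t_high) -> BLOOD; >= t_high -> CALCIFIC (the upper class wins
    at each boundary).  Non-ROI voxels -> BACKGROUND.
    """
    if volume.intensities.shape != mask.mask.shape:
        raise ValueError("volume and mask shapes differ")
    hu = np.asarray(volume.intensities, dtype=float)
    labels = np.full(hu.shape, TissueLabel.BACKGROUND, dtype=np.uint8)
    roi = mask.mask
    roi_hu = hu[roi]
    roi_labels = np.empty(roi_hu.shape, dtype=np.uint8)
    roi_labels[roi_hu < thresholds.floor] = TissueLabel.EXCLUDED
    roi_labels[(roi_hu >= thresholds.floor) & (roi_hu < thresholds.t_low)] = TissueLabel.FIBROTIC
    roi_labels[(roi_hu >= thresholds.t_low) & (roi_hu < thresholds.t_high)] = TissueLabel.BLOOD
    roi_labels[roi_hu >= thresholds.t_high] = TissueLabel.CALCIFIC
    labels[roi] = roi_labels
    return labels


def quantify_tissue(
    labels: np.ndarray, voxel_spacing: Sequence[float]
) -> TissueQuantification:
    """Turn a label mask into tissue volumes, composition, and ratio.

    Volumes are label counts times the voxel volume, in cm^3.  Composition
    is each component's share of the fibrocalcific volume, as a percentage;
    the fibrocalcific ratio is fibrotic/calcific volume.  Both are flagged
    undefined when their denominators vanish.
    """
    labels = np.asarray(labels)
    vox_cm3 = float(np.prod([float(s) for s in voxel_spacing])) / 1000.0
    counts = np.bincount(labels.ravel(), minlength=5)
    v_fib = counts[TissueLabel.FIBROTIC] * vox_cm3
    v_cal = counts[TissueLabel.CALCIFIC] * vox_cm3
    v_blood = counts[TissueLabel.BLOOD] * vox_cm3
    v_excl = counts[TissueLabel.EXCLUDED] * vox_cm3
    total = v_fib + v_cal
    if total > 0:
        fib_pct = 100.0 * v_fib / total
        cal_pct = 100.0 * v_cal / total
        comp_defined = True
    else:
        fib_pct = cal_pct = float("nan")
        comp_defined = False
    if v_cal > 0:
        ratio = v_fib / v_cal
        ratio_defined = True
    else:
        ratio = float("nan")
        ratio_defined = False
    return TissueQuantification(
        v_fibrotic=v_fib,
        v_calcific=v_cal,
        v_blood=v_blood,
        v_excluded=v_excl,
        fibrotic_pct=fib_pct,
        calcific_pct=cal_pct,
        fibrocalcific_ratio=ratio,
        composition_defined=comp_defined,
        ratio_defined=ratio_defined,
    )
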