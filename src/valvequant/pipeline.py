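"""End-to-end runner: simulation -> quantification -> agreement.

``run_pipeline`` executes the full simulated study in one call: generate a
CT phantom and a second-reader ROI, quantify both by mixture thresholding,
render and quantify the pseudo-histology, simulate a paired cohort, and
compute the agreement statistics for CTA-vs-histology composition and
reader1-vs-reader2 volumes.  Every artifact is written to the output
directory together with a manifest (config echo, seed, version, record
counts, sha256 of each file) so that identical config+seed reruns are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as vio
from .agreement import (
    PairedMeasurements,
    bland_altman,
    icc,
    spearman,
    wilcoxon_paired,
)
from .ct import (
    DEFAULT_TISSUE_FLOOR_HU,
    classify_voxels,
    derive_thresholds,
    extract_roi_intensities,
    fit_intensity_mixture,
    quantify_tissue,
)
from .histology import (
    ClassColorReference,
    classify_pixels,
    slide_composition,
    valve_composition,
)
from .phantoms import (
    CohortSpec,
    PhantomSpec,
    generate_cohort,
    generate_ct_phantom,
    generate_histology_set,
    generate_reader_variant,
)

log = logging.getLogger("valvequant")

__all__ = ["RunConfig", "run_pipeline", "quantify_ct_pair", "agreement_block"]


@dataclass
class RunConfig:
    """Configuration of one simulated pipeline run."""

    out_dir: str = "valvequant_run"
    seed: int = 0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    n_slices: int = 9
    histology_noise_sd: float = 3.0
    reader_jitter: int = 1
    mixture_k: int = 3
    tissue_floor: float = DEFAULT_TISSUE_FLOOR_HU
    em_tol: float = 1e-6
    em_max_iter: int = 500

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        phantom = PhantomSpec(**raw.pop("phantom", {}))
        cohort = CohortSpec(**raw.pop("cohort", {}))
        cfg = cls(phantom=phantom, cohort=cohort, **raw)
        if seed is not None:
            cfg = dataclasses.replace(
                cfg,
                seed=seed,
                phantom=dataclasses.replace(phantom, seed=seed),
                cohort=dataclasses.replace(cohort, seed=seed),
            )
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("phantom", "cohort"):
            d[key] = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d[key].items()}
        return d

    def param_hash(self) -> str:
        """Hash of the scientific parameters only (paths excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def quantify_ct_pair(volume, mask, k=3, floor=DEFAULT_TISSUE_FLOOR_HU,
                     seed=0, tol=1e-6, max_iter=500):
    """Fit the scan-specific mixture and quantify one (volume, mask) pair.

    Voxels below the tissue floor (air/fat picked up by an imprecise ROI)
    are excluded from the mixture sample as well as from the tissue labels.
    """
    sample = extract_roi_intensities(volume, mask)
    sample = sample[sample >= floor]
    mixture = fit_intensity_mixture(sample, K=k, seed=seed, tol=tol, max_iter=max_iter)
    thresholds = derive_thresholds(mixture, floor=floor)
    labels = classify_voxels(volume, mask, thresholds)
    return quantify_tissue(labels, volume.voxel_spacing), mixture, thresholds, labels


def agreement_block(pairs: PairedMeasurements) -> dict:
    """Spearman + both ICC forms + Bland-Altman + paired Wilcoxon, as JSON-ready dict."""
    sp = spearman(pairs)
    icc_a = icc(pairs, form="absolute")
    icc_c = icc(pairs, form="consistency")
    ba = bland_altman(pairs)
    try:
        wx = wilcoxon_paired(pairs)
        wilcox = {
            "w_plus": wx.w_plus,
            "n_effective": wx.n_effective,
            "p_value": wx.p_value,
            "method": wx.method,
            "degenerate": wx.degenerate,
        }
    except ValueError as exc:
        wilcox = {"error": str(exc)}
    return {
        "labels": [pairs.label_a, pairs.label_b],
        "unit": pairs.unit,
        "n": pairs.n,
        "spearman": {"rho": sp.rho, "p_value": sp.p_value, "band": sp.band,
                     "defined": sp.defined},
        "icc_absolute": {"estimate": icc_a.estimate, "ci95": list(icc_a.ci95),
                         "band": icc_a.band, "degenerate": icc_a.degenerate},
        "icc_consistency": {"estimate": icc_c.estimate, "ci95": list(icc_c.ci95),
                            "band": icc_c.band, "degenerate": icc_c.degenerate},
        "bland_altman": {"bias": ba.bias, "sd_diff": ba.sd_diff,
                         "loa_lower": ba.loa_lower, "loa_upper": ba.loa_upper,
                         "cor": ba.cor},
        "wilcoxon_paired": wilcox,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the full simulated study and write all artifacts under ``config.out_dir``.

    Returns the report dictionary (also written as ``report.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "param_hash": config.param_hash(),
        "stages": {},
        "files": {},
    }
    phash = config.param_hash()

    # --- stage 1: CT phantom + two readers --------------------------------
    log.info("stage ct_phantom: generating phantom (seed=%d)", config.phantom.seed)
    volume, mask1, truth = generate_ct_phantom(config.phantom)
    mask2 = generate_reader_variant(mask1, config.reader_jitter, seed=config.seed + 1)
    vio.write_volume(volume, out / "phantom_hu.nii")
    vio.write_mask(mask1, volume.voxel_spacing, out / "roi_reader1.nii")
    vio.write_mask(mask2, volume.voxel_spacing, out / "roi_reader2.nii")
    vio.write_json(
        {
            "true_volumes_cm3": truth.true_volumes,
            "true_fibrotic_pct": truth.true_composition,
        },
        out / "ground_truth.json",
    )

    rows = []
    for mask in (mask1, mask2):
        q, mixture, thresholds, _ = quantify_ct_pair(
            volume, mask, k=config.mixture_k, floor=config.tissue_floor,
            seed=config.seed, tol=config.em_tol, max_iter=config.em_max_iter,
        )
        row = vio.quantification_row(q, "phantom", mask.reader, config.seed, phash)
        row.update(
            t_low=thresholds.t_low, t_high=thresholds.t_high,
            em_converged=mixture.converged,
        )
        rows.append(row)
    ct_df = pd.DataFrame(rows)
    vio.write_table(ct_df, out / "ct_quantification.csv")
    manifest["stages"]["ct_quant"] = {"records": len(ct_df)}

    # --- stage 2: pseudo-histology ----------------------------------------
    log.info("stage histology: %d slides", config.n_slices)
    ref = ClassColorReference.movat_default()
    slides = generate_histology_set(
        truth, n_slices=config.n_slices,
        composition_noise_sd=config.histology_noise_sd, seed=config.seed + 2,
    )
    slide_rows = []
    comps = []
    for slide, true_comp in slides:
        vio.write_slide(slide, out / f"slide_c{slide.cusp_id}_s{slide.slice_id}.png")
        sc = slide_composition(classify_pixels(slide, ref), slide.cusp_id, slide.slice_id)
        comps.append(sc)
        slide_rows.append(
            {
                "cusp_id": slide.cusp_id,
                "slice_id": slide.slice_id,
                "true_fibrotic_pct": true_comp,
                "measured_fibrotic_pct": sc.fibrotic_pct,
                "n_fibrotic_px": sc.n_fibrotic,
                "n_calcific_px": sc.n_calcific,
                "seed": config.seed,
                "param_hash": phash,
            }
        )
    valve = valve_composition(comps)
    vio.write_table(pd.DataFrame(slide_rows), out / "histology_slides.csv")
    manifest["stages"]["histo_quant"] = {
        "records": len(slide_rows),
        "undefined_slides": valve.n_undefined,
    }

    # --- stage 3: cohort + agreement --------------------------------------
    log.info("stage cohort: n=%d participants",
             config.cohort.n_severe + config.cohort.n_moderate + config.cohort.n_control)
    cohort_df = generate_cohort(config.cohort)
    vio.write_table(cohort_df, out / "cohort.csv")
    blocks = {
        "cta_vs_histology_fibrotic_pct": agreement_block(
            PairedMeasurements(
                cohort_df["cta_fibrotic_pct"], cohort_df["histo_fibrotic_pct"],
                "CTA", "histology", "%",
            )
        ),
        "reader1_vs_reader2_fibrotic_cm3": agreement_block(
            PairedMeasurements(
                cohort_df["fibrotic_cm3_reader1"], cohort_df["fibrotic_cm3_reader2"],
                "reader1", "reader2", "cm3",
            )
        ),
        "reader1_vs_reader2_calcific_cm3": agreement_block(
            PairedMeasurements(
                cohort_df["calcific_cm3_reader1"], cohort_df["calcific_cm3_reader2"],
                "reader1", "reader2", "cm3",
            )
        ),
    }
    manifest["stages"]["agreement"] = {"records": len(cohort_df)}

    report = {
        "ct_quantification": rows,
        "histology_valve": {
            "valve_fibrotic_pct": valve.valve_fibrotic_pct,
            "valve_calcific_pct": valve.valve_calcific_pct,
            "cusp_means": {str(k): v for k, v in valve.cusp_means.items()},
        },
        "ground_truth": {
            "true_volumes_cm3": truth.true_volumes,
            "true_fibrotic_pct": truth.true_composition,
        },
        "agreement": blocks,
    }
    vio.write_json(report, out / "report.json")

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = vio.sha256_file(f)
    vio.write_json(manifest, out / "manifest.json")
    return report
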