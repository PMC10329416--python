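"""End-to-end validation experiments on the synthetic phantom.

These drive the whole pipeline -- phantom rendering, ROI extraction,
radiomic features, correlation statistics -- under controlled ground truth,
and are used both by the test suite and by the reproduction script.

Simulation scale: calibration cohorts use 512-px phantoms with a 32-px
tumor (the geometry scales with image size; a 512-px frame holds the full
A/B/C/D layout), 50 patients per cohort and 20 cohort replicates, which
gives stable flagged-fraction and detection-rate estimates on a single CPU.

The *null* condition zeroes both the texture field and the tumor contrast:
region A straddles the tumor disc, so a visible blob alone is a genuine
region effect and would not be a null for the region-association test.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd

from .fieldstats import cross_modality_association, pearson, region_association
from .io_roi import extract_roi
from .phantom import PhantomCase, PhantomConfig, generate_cohort, powerlaw_noise
from .radiomics import FEATURE_NAMES, extract_feature_table, powerlaw_betas

__all__ = [
    "calibration_config",
    "cohort_feature_table",
    "null_flagged_fraction",
    "field_detection_rate",
    "crossmodal_noise_sweep",
    "beta_recovery",
]


def calibration_config(**overrides) -> PhantomConfig:
    """The phantom configuration used by the calibration experiments."""
    base = dict(
        image_size=512,
        tumor_radius=32,
        tumor_contrast=600.0,
        clutter_sd=300.0,
        field_amplitude=1.0,
        field_range=80.0,
        specimen_noise_sd=20.0,
    )
    base.update(overrides)
    return PhantomConfig(**base)


def _case_rois(case: PhantomCase, modality: str):
    img = case.mammogram if modality == "mammo" else case.specimen
    depth = case.truth.bit_depth
    return [
        extract_roi(img, x, y, bit_depth=depth, patient_id=case.patient_id,
                    modality=modality, region=region)
        for region, (x, y) in case.roi_coords[modality].items()
    ]


def cohort_feature_table(cases: list[PhantomCase]) -> pd.DataFrame:
    """Radiomic feature table (long format) for every ROI of every case."""
    patches = []
    for case in cases:
        patches.extend(_case_rois(case, "mammo"))
        if case.specimen is not None:
            patches.extend(_case_rois(case, "specimen"))
    return extract_feature_table(patches)


def _tau_table(cfg: PhantomConfig, n_patients: int, seed: int, fdr: float):
    cases, _ = generate_cohort(cfg, n_patients=n_patients, matched_fraction=0.0, seed=seed)
    feats = cohort_feature_table(cases)
    return region_association(
        feats[list(FEATURE_NAMES)], feats["region"], family="radiomic",
        modality="mammo", fdr=fdr,
    )


def null_flagged_fraction(
    n_patients: int = 50, n_replicates: int = 20, seed: int = 0, fdr: float = 0.05
) -> float:
    """Mean fraction of BH-flagged radiomic features over replicate null
    cohorts (no field, no tumor contrast).  Should not exceed ~2x the FDR."""
    cfg = calibration_config(field_amplitude=0.0, tumor_contrast=0.0)
    fracs = []
    for rep in range(n_replicates):
        tab = _tau_table(cfg, n_patients, seed + 1000 * rep, fdr)
        t = tab.table
        tested = t["p"].notna()
        fracs.append(t.loc[tested, "sig"].mean() if tested.any() else 0.0)
    return float(np.mean(fracs))


def field_detection_rate(
    n_patients: int = 50, n_replicates: int = 20, seed: int = 0, fdr: float = 0.05,
    feature: str = "Histogram average",
) -> float:
    """Fraction of replicate strong-field cohorts in which ``feature`` is
    BH-flagged by the region-association test (statistical power check)."""
    cfg = calibration_config()
    hits = 0
    for rep in range(n_replicates):
        tab = _tau_table(cfg, n_patients, seed + 1000 * rep, fdr)
        if bool(tab.table.loc[feature, "sig"]):
            hits += 1
    return hits / n_replicates


def crossmodal_noise_sweep(
    noise_sds=(20.0, 200.0, 2000.0),
    n_patients: int = 30,
    seed: int = 0,
    feature: str = "Histogram average",
) -> dict[float, float]:
    """Pearson rho between mammogram and specimen values of ``feature`` over
    matched ROIs, at several specimen read-noise levels.  Rho should rise
    monotonically as the noise falls.

    The default levels are decade-spaced and all sit above one quantization
    step (1 gray level): read noise below the quantization floor is not
    resolvable in the rendered integers, so sub-step levels would compare
    rounding jitter rather than the programmed noise.  All levels share one
    latent cohort per seed (same tissue, same placement, same standardized
    noise draw), isolating the noise scale as the only moving part."""
    out = {}
    for sd in noise_sds:
        cfg = calibration_config(specimen_noise_sd=float(sd))
        cases, _ = generate_cohort(cfg, n_patients=n_patients, matched_fraction=1.0, seed=seed)
        feats = cohort_feature_table(cases)
        mam = feats[feats["modality"] == "mammo"].set_index(["patient_id", "region"])
        spc = feats[feats["modality"] == "specimen"].set_index(["patient_id", "region"])
        common = mam.index.intersection(spc.index)
        rho, _p = pearson(mam.loc[common, feature].to_numpy(),
                          spc.loc[common, feature].to_numpy())
        out[float(sd)] = rho
    return out


def beta_recovery(
    betas=(1.0, 2.0, 3.0), n_seeds: int = 20, size: int = 128, seed: int = 0
) -> dict[float, float]:
    """Mean estimated beta_1 over seeds of 1/f^beta noise patches -- the
    generator/estimator round-trip for the power-law spectral exponent."""
    out = {}
    for beta in betas:
        ests = [
            powerlaw_betas(powerlaw_noise((size, size), beta, seed + 7919 * s + int(beta * 100)))[0]
            for s in range(n_seeds)
        ]
        out[float(beta)] = float(np.mean(ests))
    return out
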