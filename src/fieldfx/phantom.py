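"""Synthetic paired mammogram / specimen-radiograph phantoms.

The phantom emulates the acquisition geometry of a screening study of the
breast-cancer *field effect*: a bright tumor blob embedded in 1/f^beta
parenchymal clutter, imaged twice -- once as a 12-bit "mammogram" and once
as a finer-pitch, re-rendered "specimen radiograph" of the same latent
tissue.  A radially decaying texture field around the tumor provides a
programmable ground-truth gradient, so the downstream feature extractors
and correlation statistics can be validated against a known effect.

Region-of-interest protocol: four 128x128 patches per case -- A inside the
tumor, B in adjacent parenchyma, C and D far from the tumor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

ROI_SIZE = 128
REGIONS = ("A", "B", "C", "D")

__all__ = [
    "PhantomConfig",
    "PhantomCase",
    "powerlaw_noise",
    "render_case",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Ground-truth parameters of one synthetic case.

    ``field_amplitude`` is the peak fractional perturbation (at the tumor
    edge) applied both to an intensity offset (as a fraction of
    ``tumor_contrast``) and to the local spectral exponent; it decays as
    exp(-d/field_range) with d the distance from the tumor edge.
    ``specimen_resolution_scale`` is the mammo-to-specimen pixel-pitch ratio
    (70 um / 50 um = 1.4 for the systems emulated here).
    """

    image_size: int = 1024
    bit_depth: int = 12
    clutter_beta_background: float = 2.8
    clutter_sd: float = 300.0
    baseline: float = 1024.0
    tumor_center: Optional[tuple[int, int]] = None  # (x, y); None = image center
    tumor_radius: int = 64
    tumor_contrast: float = 600.0
    field_amplitude: float = 0.5
    field_beta_shift: float = 0.8
    field_range: float = 200.0
    specimen_noise_sd: float = 20.0
    specimen_resolution_scale: float = 1.4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 3 * ROI_SIZE:
            raise ValueError(f"image_size must be >= {3 * ROI_SIZE}, got {self.image_size}")
        if self.tumor_radius < 16:
            raise ValueError("tumor_radius must be >= 16")
        if self.field_amplitude < 0:
            raise ValueError("field_amplitude must be >= 0")
        if self.clutter_beta_background < 0:
            raise ValueError("clutter_beta_background must be >= 0")
        if self.specimen_resolution_scale <= 0:
            raise ValueError("specimen_resolution_scale must be > 0")
        if self.bit_depth < 8 or self.bit_depth > 16:
            raise ValueError("bit_depth must be in [8, 16]")

    @property
    def max_gray(self) -> int:
        return 2 ** self.bit_depth - 1

    def center_xy(self) -> tuple[int, int]:
        if self.tumor_center is not None:
            return tuple(self.tumor_center)  # type: ignore[return-value]
        return (self.image_size // 2, self.image_size // 2)


@dataclass
class PhantomCase:
    """A rendered case: paired images, per-modality ROI coordinates, truth."""

    patient_id: str
    mammogram: np.ndarray
    specimen: Optional[np.ndarray]
    roi_coords: dict  # {"mammo": {"A": (x, y), ...}, "specimen": {...} or absent}
    truth: PhantomConfig = field(repr=False)


def powerlaw_noise(shape: tuple[int, int], beta: float, seed: int) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian field with P(f) ~ f^(-beta).

    Synthesized in the Fourier domain: white complex Gaussian spectrum
    shaped by f^(-beta/2), DC removed.  beta=0 reduces to white noise.
    Deterministic per seed.
    """
    if beta < 0:
        raise ValueError(f"spectral exponent beta must be >= 0, got {beta}")
    h, w = shape
    if h < 8 or w < 8:
        raise ValueError(f"shape dims must be >= 8, got {shape}")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((h, w))
    spec = np.fft.fft2(white)
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = np.inf  # kills DC
    spec *= f ** (-beta / 2.0)
    out = np.fft.ifft2(spec).real
    out -= out.mean()
    sd = out.std()
    if sd > 0:
        out /= sd
    return out


def _tumor_blob(size: int, center_xy: tuple[int, int], radius: int) -> np.ndarray:
    """Unit-height disc with a ~4-pixel soft sigmoid edge."""
    cx, cy = center_xy
    yy, xx = np.mgrid[0:size, 0:size]
    d = np.hypot(yy - cy, xx - cx)
    return 1.0 / (1.0 + np.exp((d - radius) / 2.0))


def _edge_distance(size: int, center_xy: tuple[int, int], radius: int) -> np.ndarray:
    cx, cy = center_xy
    yy, xx = np.mgrid[0:size, 0:size]
    return np.maximum(np.hypot(yy - cy, xx - cx) - radius, 0.0)


def _latent_tissue(cfg: PhantomConfig) -> np.ndarray:
    """Continuous (unquantized) tissue field shared by both modalities."""
    n = cfg.image_size
    base = powerlaw_noise((n, n), cfg.clutter_beta_background, cfg.rng_seed)
    latent = cfg.baseline + cfg.clutter_sd * base
    cxy = cfg.center_xy()
    if cfg.field_amplitude > 0:
        w = cfg.field_amplitude * np.exp(-_edge_distance(n, cxy, cfg.tumor_radius) / cfg.field_range)
        # local-beta perturbation: blend toward a smoother clutter realization
        smooth = powerlaw_noise(
            (n, n), cfg.clutter_beta_background + cfg.field_beta_shift, cfg.rng_seed + 1
        )
        latent = cfg.baseline + cfg.clutter_sd * ((1.0 - w) * base + w * smooth)
        latent += cfg.tumor_contrast * w  # intensity offset decaying from the edge
    latent += cfg.tumor_contrast * _tumor_blob(n, cxy, cfg.tumor_radius)
    return latent


def _quantize(img: np.ndarray, bit_depth: int) -> np.ndarray:
    return np.clip(np.rint(img), 0, 2 ** bit_depth - 1).astype(np.uint16)


def _boxes_overlap(a: tuple[int, int], b: tuple[int, int], size: int = ROI_SIZE) -> bool:
    return abs(a[0] - b[0]) < size and abs(a[1] - b[1]) < size


def _place_rois(cfg: PhantomConfig, rng: np.random.Generator) -> dict[str, tuple[int, int]]:
    """Top-left ROI coordinates for A/B/C/D on the mammogram grid.

    A is centered on the tumor.  B sits at max(2.5*r, 136) px from the tumor
    center (1.5 tumor radii beyond the edge for typical radii).  C and D sit
    at least image_size/3 away, with d(A,C) <= d(A,D) and no pairwise patch
    overlap.  Angles are drawn with rejection sampling from ``rng``.
    """
    n, half = cfg.image_size, ROI_SIZE // 2
    cx, cy = cfg.center_xy()
    a = (cx - half, cy - half)
    lo, hi = 0, n - ROI_SIZE

    def center_to_tl(px: float, py: float) -> tuple[int, int]:
        return (int(round(px)) - half, int(round(py)) - half)

    def inside(tl: tuple[int, int]) -> bool:
        return lo <= tl[0] <= hi and lo <= tl[1] <= hi

    d_ab = max(2.5 * cfg.tumor_radius, 136.0)
    d_far_min = n / 3.0
    if d_ab >= d_far_min:
        raise ValueError(
            "ROIs cannot be placed without overlap: near-ROI distance "
            f"{d_ab:.0f} px >= far-ROI minimum {d_far_min:.0f} px; "
            "reduce tumor_radius or enlarge image_size"
        )

    b_tl = None
    for _ in range(500):
        th = rng.uniform(0, 2 * np.pi)
        tl = center_to_tl(cx + d_ab * np.cos(th), cy + d_ab * np.sin(th))
        if inside(tl) and not _boxes_overlap(tl, a):
            b_tl = tl
            break
    if b_tl is None:
        raise ValueError("ROIs cannot be placed without overlap: no valid near-ROI position")

    placed = {"A": a, "B": b_tl}
    d_far_max = n / 2.0 - half - 2
    for name in ("C", "D"):
        ok = None
        for _ in range(1000):
            d = rng.uniform(d_far_min, max(d_far_min + 1, d_far_max))
            th = rng.uniform(0, 2 * np.pi)
            tl = center_to_tl(cx + d * np.cos(th), cy + d * np.sin(th))
            if not inside(tl):
                continue
            if any(_boxes_overlap(tl, p) for p in placed.values()):
                continue
            ok = tl
            break
        if ok is None:
            raise ValueError(f"ROIs cannot be placed without overlap: region {name}")
        placed[name] = ok

    def dist(p, q):
        return float(np.hypot(p[0] - q[0], p[1] - q[1]))

    if dist(a, placed["C"]) > dist(a, placed["D"]):
        placed["C"], placed["D"] = placed["D"], placed["C"]
    return placed


def render_case(config: PhantomConfig, patient_id: str = "P000", with_specimen: bool = True) -> PhantomCase:
    """Render one paired case from a config.

    The specimen is a re-rendering of the same latent tissue at
    ``specimen_resolution_scale`` finer pixel pitch with additive Gaussian
    read noise, so the statistical mammo-specimen correlation is tunable
    via ``specimen_noise_sd`` without any geometric registration step.
    """
    from scipy.ndimage import zoom

    rng = np.random.default_rng(config.rng_seed)
    latent = _latent_tissue(config)
    mammo = _quantize(latent, config.bit_depth)
    coords = {"mammo": _place_rois(config, rng)}

    specimen = None
    if with_specimen:
        s = config.specimen_resolution_scale
        lat_s = zoom(latent, s, order=1, grid_mode=True, mode="nearest")
        lat_s = lat_s + rng.normal(0.0, config.specimen_noise_sd, lat_s.shape)
        specimen = _quantize(lat_s, config.bit_depth)
        half = ROI_SIZE // 2
        hi = specimen.shape[0] - ROI_SIZE
        spec_coords = {}
        for name, (x, y) in coords["mammo"].items():
            sx = int(np.clip(round((x + half) * s) - half, 0, hi))
            sy = int(np.clip(round((y + half) * s) - half, 0, hi))
            spec_coords[name] = (sx, sy)
        coords["specimen"] = spec_coords

    return PhantomCase(patient_id=patient_id, mammogram=mammo, specimen=specimen,
                       roi_coords=coords, truth=config)


def generate_cohort(
    config: PhantomConfig,
    n_patients: int,
    matched_fraction: float,
    seed: int,
) -> tuple[list[PhantomCase], pd.DataFrame]:
    """Render a cohort and its ROI manifest.

    The first ``round(matched_fraction * n_patients)`` patients carry a
    specimen image (the "matched" subset).  Per-patient configs differ only
    in ``rng_seed``, drawn from a child stream of ``seed``, so the same
    (config, seed) pair always reproduces the cohort bit for bit.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if not 0 <= matched_fraction <= 1:
        raise ValueError("matched_fraction must be in [0, 1]")
    n_matched = int(round(matched_fraction * n_patients))
    seeds = np.random.SeedSequence(seed).generate_state(n_patients) % (2**31)

    cases, rows = [], []
    for i in range(n_patients):
        pid = f"P{i:03d}"
        cfg_i = PhantomConfig(**{**asdict(config), "rng_seed": int(seeds[i])})
        case = render_case(cfg_i, patient_id=pid, with_specimen=(i < n_matched))
        cases.append(case)
        for modality, coord_map in case.roi_coords.items():
            for region, (x, y) in coord_map.items():
                rows.append({"patient_id": pid, "modality": modality,
                             "region": region, "x": x, "y": y})
    manifest = pd.DataFrame(rows, columns=["patient_id", "modality", "region", "x", "y"])
    return cases, manifest


def write_cohort(cases: list[PhantomCase], manifest: pd.DataFrame, out_dir: str | Path) -> Path:
    """Write images as 16-bit PNG plus the manifest CSV and truth JSON."""
    from .io_roi import write_image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for case in cases:
        write_image(out / f"{case.patient_id}_mammo.png", case.mammogram)
        if case.specimen is not None:
            write_image(out / f"{case.patient_id}_specimen.png", case.specimen)
    manifest.to_csv(out / "manifest.csv", index=False)
    truth = {c.patient_id: {**asdict(c.truth)} for c in cases}
    (out / "truth.json").write_text(json.dumps(truth, indent=2, default=str))
    return out / "manifest.csv"
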