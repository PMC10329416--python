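"""The 45 radiomic texture features, in a frozen canonical order.

Feature families (canonical order):

(a) fractal analysis -- box-counting dimension plus five percentile-threshold
    variants, and the Minkowski (blanket) dimension of the intensity surface;
(b) edge-frequency analysis -- statistics of the Sobel gradient magnitude;
(c) gray-level histogram analysis -- mean, empirical-CDF thresholds, balance
    ratios and skewness;
(d) Fourier analysis -- RMS spectral variation and the first moment of the
    power spectrum;
(e) neighborhood gray-tone difference matrix (Amadasun-King) coarseness and
    contrast;
(f) power-law spectral exponents beta over eight nested frequency bands;
(g) fourteen Haralick-family statistics of the gray-level co-occurrence
    matrix.

Degenerate inputs (e.g. a constant patch) yield NaN for the features whose
definition breaks down, with a warning, never an exception: cohort-level
extraction must not abort on a single flat patch, and NaN rows are dropped
pairwise by the correlation stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_roi import ROIPatch

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "GLCM",
    "histogram_features",
    "edge_frequency_features",
    "fourier_features",
    "powerlaw_betas",
    "radial_power_spectrum",
    "ngtdm_features",
    "glcm_compute",
    "glcm_features",
    "boxcounting_dimensions",
    "minkowski_dimension",
    "extract_all",
    "extract_feature_table",
]

#: canonical feature order; any reorder is an API break
FEATURE_NAMES: tuple[str, ...] = (
    # (a) fractal analysis
    "Boxcounting dimension",
    "Boxcounting dimension 1",
    "Boxcounting dimension 2",
    "Boxcounting dimension 3",
    "Boxcounting dimension 4",
    "Boxcounting dimension 5",
    "Minkod global MD",
    # (b) edge-frequency analysis
    "Edge frequency: mean gradient",
    "Edge frequency: max gradient",
    "Edge frequency: minimum gradient",
    "Edge frequency: standard deviation gradient",
    # (c) gray-level histogram analysis
    "Histogram average",
    "Histogram maximum CDF",
    "Histogram minimum CDF",
    "Histogram balance",
    "Histogram seventy CDF",
    "Histogram thirty CDF",
    "Histogram quasi balance",
    "Histogram skewness",
    # (d) Fourier transform analysis
    "Fourier root mean square (FRMS)",
    "Fourier first moment of power spectrum (FFMP)",
    # (e) neighborhood gray-tone difference matrix
    "Coarseness",
    "Contrast",
    # (f) power-law spectral analysis
    "Powerlaw beta 1",
    "Powerlaw beta 2",
    "Powerlaw beta 3",
    "Powerlaw beta 4",
    "Powerlaw beta 5",
    "Powerlaw beta 6",
    "Powerlaw beta 7",
    "Powerlaw beta 8",
    # (g) gray-level co-occurrence matrix
    "GLCM contrast",
    "GLCM correlation",
    "GLCM difference entropy",
    "GLCM difference variance",
    "GLCM energy",
    "GLCM entropy",
    "GLCM homogeneity",
    "GLCM information measure of correlation 1 (IMC1)",
    "GLCM information measure of correlation 2 (IMC2)",
    "GLCM maximum correlation coefficient",
    "GLCM sum average",
    "GLCM sum entropy",
    "GLCM sum variance",
    "GLCM variance",
)

COARSENESS_CAP = 1e6  # division guard for perfectly uniform neighborhoods

_DEFAULT_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


@dataclass(frozen=True)
class FeatureVector:
    """Ordered 45-element radiomic feature vector."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError(f"expected {len(self.names)} values, got {len(self.values)}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


@dataclass(frozen=True)
class GLCM:
    """Symmetric, normalized gray-level co-occurrence matrix."""

    matrix: np.ndarray
    levels: int
    distance: int
    angles: tuple[float, ...]


def _pixels(roi) -> np.ndarray:
    px = roi.pixels if isinstance(roi, ROIPatch) else roi
    return np.asarray(px, dtype=np.float64)


def _warn(msg: str) -> None:
    warnings.warn(msg, RuntimeWarning, stacklevel=3)


# ---------------------------------------------------------------------------
# (c) histogram family
# ---------------------------------------------------------------------------

def histogram_features(roi) -> np.ndarray:
    """(average, maxCDF, minCDF, balance, seventyCDF, thirtyCDF,
    quasi_balance, skewness).

    maxCDF is the smallest gray level g whose empirical CDF reaches 0.95
    (analogously 0.05 / 0.70 / 0.30); balance = (maxCDF-avg)/(avg-minCDF);
    quasi_balance = (seventyCDF-avg)/(avg-thirtyCDF); skewness is the third
    standardized central moment.
    """
    x = _pixels(roi).ravel()
    n = x.size
    srt = np.sort(x)

    def cdf_level(q: float) -> float:
        # smallest present gray level g with #{x <= g}/n >= q
        idx = int(np.ceil(q * n)) - 1
        return float(srt[max(idx, 0)])

    avg = float(x.mean())
    max_cdf, min_cdf = cdf_level(0.95), cdf_level(0.05)
    seventy, thirty = cdf_level(0.70), cdf_level(0.30)

    def ratio(hi: float, lo: float, label: str) -> float:
        denom = avg - lo
        if denom == 0:
            _warn(f"histogram {label}: zero denominator, returning NaN")
            return np.nan
        return (hi - avg) / denom

    balance = ratio(max_cdf, min_cdf, "balance")
    quasi = ratio(seventy, thirty, "quasi balance")

    sd = x.std()
    if sd == 0:
        _warn("histogram skewness undefined for zero-variance ROI")
        skew = np.nan
    else:
        skew = float(np.mean(((x - avg) / sd) ** 3))

    return np.array([avg, max_cdf, min_cdf, balance, seventy, thirty, quasi, skew])


# ---------------------------------------------------------------------------
# (b) edge-frequency family
# ---------------------------------------------------------------------------

def edge_frequency_features(roi) -> np.ndarray:
    """(mean, max, min, sd) of the Sobel gradient magnitude over the ROI
    interior (border pixels excluded to avoid boundary-extension artifacts)."""
    x = _pixels(roi)
    gx = ndimage.sobel(x, axis=1, mode="reflect")
    gy = ndimage.sobel(x, axis=0, mode="reflect")
    mag = np.hypot(gx, gy)[1:-1, 1:-1]
    return np.array([mag.mean(), mag.max(), mag.min(), mag.std()])


# ---------------------------------------------------------------------------
# (d) Fourier family
# ---------------------------------------------------------------------------

def fourier_features(roi) -> np.ndarray:
    """(FRMS, FFMP) of the mean-subtracted patch.

    FRMS = sqrt(sum P / Npix^2) over non-DC frequencies (by Parseval this
    equals the spatial standard deviation).  FFMP = sum(|f| P) / sum(P) with
    |f| the radial frequency in cycles/pixel.
    """
    x = _pixels(roi)
    x = x - x.mean()
    h, w = x.shape
    P = np.abs(np.fft.fft2(x)) ** 2
    P[0, 0] = 0.0
    total = P.sum()
    n_pix = h * w
    frms = float(np.sqrt(total) / n_pix)
    if total == 0:
        _warn("FFMP undefined for zero-variance ROI")
        return np.array([0.0, np.nan])
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.hypot(fy, fx)
    ffmp = float((f * P).sum() / total)
    return np.array([frms, ffmp])


# ---------------------------------------------------------------------------
# (f) power-law spectral exponents
# ---------------------------------------------------------------------------

def radial_power_spectrum(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged power spectrum of the mean-subtracted image.

    Returns (f, P) with f the ring frequencies in cycles/pixel for integer
    radial wavenumbers 1..min(h,w)//2 and P the mean power in each ring.
    """
    x = np.asarray(image, dtype=np.float64)
    x = x - x.mean()
    h, w = x.shape
    P = np.abs(np.fft.fft2(x)) ** 2
    ky = np.fft.fftfreq(h) * h
    kx = np.fft.fftfreq(w) * w
    # radial wavenumber on the common integer grid of the smaller dimension
    scale = min(h, w)
    r = np.rint(np.hypot((ky[:, None] / h) * scale, (kx[None, :] / w) * scale)).astype(int)
    r_max = scale // 2
    counts = np.bincount(r.ravel(), minlength=r_max + 1)[1 : r_max + 1]
    sums = np.bincount(r.ravel(), weights=P.ravel(), minlength=r_max + 1)[1 : r_max + 1]
    with np.errstate(invalid="ignore"):
        prof = sums / counts
    f = np.arange(1, r_max + 1) / scale
    good = counts > 0
    return f[good], prof[good]


def _beta_band_edges(r_max: int, n_bands: int = 8, r_top_min: int = 4) -> list[int]:
    """Upper radial-wavenumber limit of each nested band (band 1 = full range,
    successive bands shrink geometrically from the high-frequency end)."""
    edges = np.exp(np.linspace(np.log(r_max), np.log(r_top_min), n_bands))
    return [int(round(e)) for e in edges]


def powerlaw_betas(roi) -> np.ndarray:
    """Eight spectral exponents beta_k: the negative log-log slope of the
    radially averaged power spectrum over nested frequency bands.

    Band 1 spans the full resolvable range (wavenumbers 1..min(h,w)//2);
    each following band drops more of the high-frequency end, so the later
    betas characterize progressively coarser structure.  DC is excluded, so
    all betas are invariant to adding a constant.
    """
    x = _pixels(roi)
    if x.std() == 0:
        _warn("powerlaw betas undefined for zero-variance ROI")
        return np.full(8, np.nan)
    f, prof = radial_power_spectrum(x)
    r = np.rint(f * min(x.shape)).astype(int)
    log_f, log_p = np.log(f), np.log(np.maximum(prof, 1e-300))
    betas = np.empty(8)
    for k, r_hi in enumerate(_beta_band_edges(int(r.max()))):
        m = r <= r_hi
        if m.sum() < 3:
            betas[k] = np.nan
            continue
        slope = np.polyfit(log_f[m], log_p[m], 1)[0]
        betas[k] = -slope
    return betas


# ---------------------------------------------------------------------------
# (e) NGTDM family
# ---------------------------------------------------------------------------

def _requantize(x: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width requantization over [min, max] to integer levels 0..levels-1."""
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x, dtype=np.int64)
    q = np.floor((x - lo) / (hi - lo) * levels).astype(np.int64)
    return np.minimum(q, levels - 1)


def ngtdm_features(roi, levels: int = 64) -> np.ndarray:
    """Amadasun-King (coarseness, contrast) from the neighborhood gray-tone
    difference matrix: 3x3 neighborhood with the center excluded, gray levels
    requantized to ``levels``, border pixels excluded from the tally.

    A perfectly uniform patch has no tone differences: contrast is 0 and
    coarseness (a reciprocal) is capped at ``COARSENESS_CAP``.
    """
    x = _pixels(roi)
    q = _requantize(x, levels)
    nb_sum = ndimage.uniform_filter(q.astype(np.float64), size=3, mode="nearest") * 9.0
    nb_mean = (nb_sum - q) / 8.0
    inner = (slice(1, -1), slice(1, -1))
    qi = q[inner].ravel()
    diff = np.abs(qi - nb_mean[inner].ravel())
    n = qi.size
    s = np.bincount(qi, weights=diff, minlength=levels)
    counts = np.bincount(qi, minlength=levels)
    p = counts / n
    present = counts > 0
    ng = int(present.sum())

    denom = float((p * s).sum())
    coarseness = COARSENESS_CAP if denom < 1e-12 else min(1.0 / denom, COARSENESS_CAP)

    if ng <= 1:
        contrast = 0.0
    else:
        i = np.arange(levels)[present]
        pi = p[present]
        pair_term = float(((pi[:, None] * pi[None, :]) * (i[:, None] - i[None, :]) ** 2).sum())
        contrast = pair_term / (ng * (ng - 1)) * (float(s.sum()) / n)
    return np.array([coarseness, contrast])


# ---------------------------------------------------------------------------
# (g) GLCM family
# ---------------------------------------------------------------------------

def glcm_compute(
    roi,
    levels: int = 64,
    distance: int = 1,
    angles: tuple[float, ...] = _DEFAULT_ANGLES,
) -> GLCM:
    """Co-occurrence counts accumulated over the given angles, symmetrized
    and normalized to sum 1.  Input is requantized to ``levels`` equal-width
    bins over the patch's [min, max] range."""
    from skimage.feature import graycomatrix

    if levels < 2:
        raise ValueError("levels must be >= 2")
    q = _requantize(_pixels(roi), levels).astype(np.uint8 if levels <= 256 else np.uint16)
    counts = graycomatrix(q, distances=[distance], angles=list(angles),
                          levels=levels, symmetric=True, normed=False)
    mat = counts[:, :, 0, :].sum(axis=2).astype(np.float64)
    total = mat.sum()
    if total > 0:
        mat /= total
    return GLCM(matrix=mat, levels=levels, distance=distance, angles=tuple(angles))


def _entropy2(p: np.ndarray) -> float:
    """Shannon entropy in bits with the 0*log0 := 0 convention."""
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def glcm_features(glcm: GLCM) -> np.ndarray:
    """The 14 Haralick-family statistics, canonical order:
    contrast, correlation, difference entropy, difference variance, energy,
    entropy, homogeneity, IMC1, IMC2, maximum correlation coefficient,
    sum average, sum entropy, sum variance, variance.

    Logs are base 2.  For a single-occupied-level matrix the correlation
    family (correlation, IMC1/2, MCC) is undefined and returns NaN.
    """
    p = glcm.matrix
    L = glcm.levels
    i = np.arange(L, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)  # == py for a symmetric matrix
    mu = float((i * px).sum())
    var_marg = float(((i - mu) ** 2 * px).sum())

    # diagonal-band distributions p_{x-y} and p_{x+y}
    k_diff = np.arange(L)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(0, 2 * L - 1)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])

    contrast = float(((ii - jj) ** 2 * p).sum())
    energy = float((p**2).sum())
    entropy = _entropy2(p.ravel())
    homogeneity = float((p / (1.0 + (ii - jj) ** 2)).sum())

    diff_avg = float((k_diff * p_diff).sum())
    diff_var = float(((k_diff - diff_avg) ** 2 * p_diff).sum())
    diff_entropy = _entropy2(p_diff)

    sum_avg = float((k_sum * p_sum).sum())
    sum_var = float(((k_sum - sum_avg) ** 2 * p_sum).sum())
    sum_entropy = _entropy2(p_sum)

    present = px > 0
    if present.sum() <= 1 or var_marg == 0:
        _warn("GLCM correlation family undefined for a single-level matrix")
        correlation = imc1 = imc2 = mcc = np.nan
    else:
        correlation = float((((ii - mu) * (jj - mu) * p).sum()) / var_marg)
        hx = _entropy2(px)
        pxy_outer = px[:, None] * px[None, :]
        nz = p > 0
        hxy1 = float(-(p[nz] * np.log2(pxy_outer[nz])).sum())
        nz2 = pxy_outer > 0
        hxy2 = float(-(pxy_outer[nz2] * np.log2(pxy_outer[nz2])).sum())
        imc1 = (entropy - hxy1) / hx  # max(HX, HY) = HX by symmetry
        arg = 1.0 - np.exp(-2.0 * (hxy2 - entropy))
        imc2 = float(np.sqrt(max(arg, 0.0)))
        # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k)), restricted to present levels
        ps = p[np.ix_(present, present)]
        pxs = px[present]
        Q = (ps / pxs[:, None]) @ (ps / pxs[None, :]).T
        eig = np.sort(np.real(np.linalg.eigvals(Q)))[::-1]
        mcc = float(np.sqrt(max(eig[1], 0.0))) if eig.size > 1 else np.nan

    return np.array([
        contrast, correlation, diff_entropy, diff_var, energy, entropy,
        homogeneity, imc1, imc2, mcc, sum_avg, sum_entropy, sum_var, var_marg,
    ])


# ---------------------------------------------------------------------------
# (a) fractal family
# ---------------------------------------------------------------------------

BOXCOUNT_PERCENTILES = (50.0, 30.0, 40.0, 50.0, 60.0, 70.0)  # base + variants 1..5


def _boxcount_dimension(mask: np.ndarray) -> float:
    """Box-counting dimension of a binary mask; NaN for empty or full masks
    (the threshold carries no information there)."""
    if not mask.any() or mask.all():
        _warn("box-counting mask empty or full at this threshold; NaN")
        return np.nan
    n = mask.shape[0]
    # box sizes stay <= n/4: counts at box sizes comparable to the image
    # are dominated by finite-size/alignment effects and bias the slope
    sizes = [s for s in (2, 4, 8, 16, 32) if s <= n // 4 and n % s == 0]
    counts = []
    for s in sizes:
        blocks = mask.reshape(n // s, s, n // s, s).any(axis=(1, 3))
        counts.append(blocks.sum())
    slope = np.polyfit(np.log(sizes), np.log(counts), 1)[0]
    return float(-slope)


def boxcounting_dimensions(roi) -> np.ndarray:
    """Six box-counting dimensions from rank-based binarizations: the base
    feature thresholds at the median, the five variants at the 30/40/50/60/70th
    intensity percentiles (mask = pixels strictly above the threshold).
    Rank-based thresholds make all six invariant to affine gray rescaling."""
    x = _pixels(roi)
    out = np.empty(len(BOXCOUNT_PERCENTILES))
    for k, pct in enumerate(BOXCOUNT_PERCENTILES):
        out[k] = _boxcount_dimension(x > np.percentile(x, pct))
    return out


def minkowski_dimension(roi, max_radius: int = 5) -> float:
    """Minkowski (blanket) dimension of the gray-level intensity surface.

    Upper and lower blankets are grown by iterated 3x3 gray dilation/erosion;
    the surface area A(r) = volume(r) / (2r) scales as r^(2-D), so D = 2 minus
    the log-log slope of A against r.  A flat surface gives exactly 2.
    """
    x = _pixels(roi)
    upper, lower = x.copy(), x.copy()
    size = (3, 3)
    areas = []
    for _ in range(max_radius):
        upper = np.maximum(upper + 1.0, ndimage.grey_dilation(upper, size=size, mode="nearest"))
        lower = np.minimum(lower - 1.0, ndimage.grey_erosion(lower, size=size, mode="nearest"))
        areas.append((upper - lower).sum())
    r = np.arange(1, max_radius + 1, dtype=np.float64)
    area = np.asarray(areas) / (2.0 * r)
    slope = np.polyfit(np.log(r), np.log(area), 1)[0]
    return float(2.0 - slope)


# ---------------------------------------------------------------------------
# full vector
# ---------------------------------------------------------------------------

def extract_all(roi, glcm_levels: int = 64, glcm_distance: int = 1) -> FeatureVector:
    """All 45 features in canonical order: (a)7 + (b)4 + (c)8 + (d)2 +
    (e)2 + (f)8 + (g)14.  Never raises on a valid ROI; degenerate families
    surface as NaN (see the per-family docstrings)."""
    values = np.concatenate([
        boxcounting_dimensions(roi),
        [minkowski_dimension(roi)],
        edge_frequency_features(roi),
        histogram_features(roi),
        fourier_features(roi),
        ngtdm_features(roi),
        powerlaw_betas(roi),
        glcm_features(glcm_compute(roi, levels=glcm_levels, distance=glcm_distance)),
    ])
    return FeatureVector(values=values)


def extract_feature_table(patches) -> "pd.DataFrame":
    """Extract the 45-feature vector for every ROIPatch; returns a DataFrame
    with provenance columns (patient_id, modality, region) then the canonical
    feature columns."""
    import pandas as pd

    rows = []
    for patch in patches:
        row = {"patient_id": patch.patient_id, "modality": patch.modality,
               "region": patch.region}
        row.update(extract_all(patch).as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=["patient_id", "modality", "region", *FEATURE_NAMES])
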