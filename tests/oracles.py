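"""Independent brute-force oracles used to validate the package's
implementations.  Everything here is written from the defining formulas with
plain loops -- deliberately slow, deliberately sharing no code with the
package."""

import numpy as np


def glcm_counts_bruteforce(q: np.ndarray, levels: int, distance: int, angles) -> np.ndarray:
    """Directed pair enumeration over every pixel and angle, symmetrized."""
    h, w = q.shape
    mat = np.zeros((levels, levels))
    for theta in angles:
        # angle convention: offset (row, col) = (d*sin(theta), d*cos(theta))
        dr = int(round(np.sin(theta) * distance))
        dc = int(round(np.cos(theta) * distance))
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    mat[q[r, c], q[r2, c2]] += 1
                    mat[q[r2, c2], q[r, c]] += 1  # symmetric
    return mat


def haralick_bruteforce(p: np.ndarray) -> dict:
    """The 14 co-occurrence statistics from literal double/triple loops.
    Logs base 2, 0*log0 = 0.  Returns NaN for the correlation family when
    only one gray level is occupied."""
    L = p.shape[0]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = sum(i * px[i] for i in range(L))
    mu_y = sum(j * py[j] for j in range(L))
    var_x = sum((i - mu_x) ** 2 * px[i] for i in range(L))
    var_y = sum((j - mu_y) ** 2 * py[j] for j in range(L))

    def log2z(v):
        return np.log2(v) if v > 0 else 0.0

    contrast = sum((i - j) ** 2 * p[i, j] for i in range(L) for j in range(L))
    energy = sum(p[i, j] ** 2 for i in range(L) for j in range(L))
    entropy = -sum(p[i, j] * log2z(p[i, j]) for i in range(L) for j in range(L))
    homogeneity = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))
    variance = sum((i - mu_x) ** 2 * p[i, j] for i in range(L) for j in range(L))

    p_diff = np.zeros(L)
    for i in range(L):
        for j in range(L):
            p_diff[abs(i - j)] += p[i, j]
    diff_avg = sum(k * p_diff[k] for k in range(L))
    diff_var = sum((k - diff_avg) ** 2 * p_diff[k] for k in range(L))
    diff_entropy = -sum(p_diff[k] * log2z(p_diff[k]) for k in range(L))

    p_sum = np.zeros(2 * L - 1)
    for i in range(L):
        for j in range(L):
            p_sum[i + j] += p[i, j]
    sum_avg = sum(k * p_sum[k] for k in range(2 * L - 1))
    sum_var = sum((k - sum_avg) ** 2 * p_sum[k] for k in range(2 * L - 1))
    sum_entropy = -sum(p_sum[k] * log2z(p_sum[k]) for k in range(2 * L - 1))

    present = [i for i in range(L) if px[i] > 0]
    if len(present) <= 1 or var_x == 0 or var_y == 0:
        correlation = imc1 = imc2 = mcc = np.nan
    else:
        correlation = sum(
            (i - mu_x) * (j - mu_y) * p[i, j] for i in range(L) for j in range(L)
        ) / np.sqrt(var_x * var_y)
        hx = -sum(px[i] * log2z(px[i]) for i in range(L))
        hy = -sum(py[j] * log2z(py[j]) for j in range(L))
        hxy1 = -sum(
            p[i, j] * log2z(px[i] * py[j]) for i in range(L) for j in range(L)
            if p[i, j] > 0
        )
        hxy2 = -sum(
            px[i] * py[j] * log2z(px[i] * py[j]) for i in range(L) for j in range(L)
            if px[i] * py[j] > 0
        )
        imc1 = (entropy - hxy1) / max(hx, hy)
        imc2 = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy))))
        n = len(present)
        Q = np.zeros((n, n))
        for a, i in enumerate(present):
            for b, j in enumerate(present):
                Q[a, b] = sum(
                    p[i, k] * p[j, k] / (px[i] * py[k]) for k in present
                )
        eig = sorted(np.real(np.linalg.eigvals(Q)), reverse=True)
        mcc = np.sqrt(max(eig[1], 0.0)) if n > 1 else np.nan

    return {
        "contrast": contrast, "correlation": correlation,
        "diff_entropy": diff_entropy, "diff_var": diff_var,
        "energy": energy, "entropy": entropy, "homogeneity": homogeneity,
        "imc1": imc1, "imc2": imc2, "mcc": mcc,
        "sum_avg": sum_avg, "sum_entropy": sum_entropy, "sum_var": sum_var,
        "variance": variance,
    }


def ngtdm_bruteforce(q: np.ndarray, levels: int):
    """Per-pixel Amadasun-King tally: 3x3 neighborhood mean excluding the
    center, border pixels excluded."""
    h, w = q.shape
    s = np.zeros(levels)
    counts = np.zeros(levels)
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            total = 0.0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    total += q[r + dr, c + dc]
            i = q[r, c]
            s[i] += abs(i - total / 8.0)
            counts[i] += 1
    n = counts.sum()
    p = counts / n
    present = counts > 0
    ng = int(present.sum())
    denom = float((p * s).sum())
    coarseness = 1e6 if denom < 1e-12 else min(1.0 / denom, 1e6)
    if ng <= 1:
        contrast = 0.0
    else:
        pair = 0.0
        for i in range(levels):
            for j in range(levels):
                if present[i] and present[j]:
                    pair += p[i] * p[j] * (i - j) ** 2
        contrast = pair / (ng * (ng - 1)) * (s.sum() / n)
    return coarseness, contrast


def tau_b_bruteforce(x, y):
    """O(n^2) concordant/discordant pair counting with tie correction."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    P = Q = tx = ty = txy = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                txy += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                P += 1
            else:
                Q += 1
    n0 = n * (n - 1) // 2
    n1 = tx + txy
    n2 = ty + txy
    denom = np.sqrt((n0 - n1) * (n0 - n2))
    return (P - Q) / denom if denom > 0 else np.nan


def pearson_bruteforce(x, y):
    """Direct covariance-formula product-moment correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cx, cy = x - x.mean(), y - y.mean()
    return float((cx * cy).sum() / np.sqrt((cx**2).sum() * (cy**2).sum()))


def bh_stepup_bruteforce(p_values, m, fdr):
    """Literal step-up: largest k with p_(k) <= k/m * fdr; flag p <= p_(k)."""
    p = np.asarray(p_values, float)
    order = np.argsort(p)
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank / m * fdr:
            k_star = rank
    flags = np.zeros(len(p), bool)
    if k_star > 0:
        thresh = p[order[k_star - 1]]
        flags = p <= thresh
    return flags


def radial_slope_bruteforce(img):
    """Independent log-log spectral slope: floor-binned radial average of the
    periodogram, simple least squares."""
    x = np.asarray(img, float)
    x = x - x.mean()
    n = x.shape[0]
    P = np.abs(np.fft.fft2(x)) ** 2
    k = np.fft.fftfreq(n) * n
    kr = np.sqrt(k[:, None] ** 2 + k[None, :] ** 2)
    fs, ps = [], []
    for r in range(1, n // 2):
        ring = (kr >= r) & (kr < r + 1)
        if ring.any():
            fs.append(r + 0.5)
            ps.append(P[ring].mean())
    A = np.vstack([np.log(fs), np.ones(len(fs))]).T
    slope, _ = np.linalg.lstsq(A, np.log(ps), rcond=None)[0]
    return slope
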