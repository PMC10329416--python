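"""Stage-pooled deep features from a VGG19-topology backbone + PCA reduction.

Each 128x128 ROI is replicated to three channels, pushed through the 16
convolutional layers / 5 max-pooling stages of the VGG19 feature extractor,
and the output of every pooling stage is spatially pooled per channel
(average by default).  Concatenating the five stage vectors gives
64 + 128 + 256 + 512 + 512 = 1472 raw deep features per ROI.

The raw matrix is then filtered (zero-variance columns and columns that are
zero in more than half the rows are dropped) and reduced per modality to 20
principal-component scores -- the "pseudo-features" used by the correlation
stage.

The backbone is a pure-numpy forward pass (im2col convolution, ReLU, 2x2
max pooling).  Weights are He-initialized from a seed by default, which is
sufficient for every structural and statistical contract in this package; a
pretrained weight file exported as .npz (keys ``conv{i}_w``/``conv{i}_b``)
can be supplied to reproduce a transfer-learning setting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_roi import ROIPatch

#: conv channel widths between pools -- the VGG19 feature topology
VGG19_CFG: tuple[tuple[int, ...], ...] = (
    (64, 64),
    (128, 128),
    (256, 256, 256, 256),
    (512, 512, 512, 512),
    (512, 512, 512, 512),
)
STAGE_CHANNELS: tuple[int, ...] = tuple(stage[-1] for stage in VGG19_CFG)
N_DEEP_FEATURES: int = sum(STAGE_CHANNELS)  # 1472

__all__ = [
    "VGG19Backbone",
    "VGG19_CFG",
    "STAGE_CHANNELS",
    "N_DEEP_FEATURES",
    "DeepFeatureMatrix",
    "PseudoFeatureSet",
    "preprocess_roi",
    "stage_features",
    "extract_deep_matrix",
    "filter_columns",
    "pca_pseudofeatures",
]


def _conv2d_same(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3 'same' convolution via im2col + BLAS matmul.

    x: (Cin, H, W); w: (Cout, Cin, 3, 3); b: (Cout,) -> (Cout, H, W).
    """
    cin, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    # patches: (H, W, Cin, 3, 3) without copying via stride tricks
    s = xp.strides
    patches = np.lib.stride_tricks.as_strided(
        xp, shape=(h, wd, cin, 3, 3), strides=(s[1], s[2], s[0], s[1], s[2]),
        writeable=False,
    )
    cols = patches.reshape(h * wd, cin * 9)
    out = cols @ w.reshape(w.shape[0], cin * 9).T + b
    return np.ascontiguousarray(out.T.reshape(w.shape[0], h, wd))


def _maxpool2(x: np.ndarray) -> np.ndarray:
    c, h, w = x.shape
    return x[:, : h - h % 2, : w - w % 2].reshape(c, h // 2, 2, w // 2, 2).max(axis=(2, 4))


class VGG19Backbone:
    """Numpy forward pass of the VGG19 convolutional feature extractor.

    Parameters
    ----------
    weights : "random" or path to an .npz file
        "random" draws He-normal weights from ``seed``.  An .npz file must
        hold ``conv{i}_w`` with shape (Cout, Cin, 3, 3) and ``conv{i}_b``
        for i = 0..15 in network order.
    relu : bool
        Disable to obtain a linear network (used by closed-form tests).
    """

    def __init__(self, weights: str | Path = "random", seed: int = 0, relu: bool = True):
        self.relu = relu
        self.layers: list[tuple[np.ndarray, np.ndarray]] = []
        shapes = []
        cin = 3
        for stage in VGG19_CFG:
            for cout in stage:
                shapes.append((cout, cin))
                cin = cout
        if weights == "random":
            rng = np.random.default_rng(seed)
            for cout, cin_ in shapes:
                fan_in = cin_ * 9
                w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin_, 3, 3))
                self.layers.append((w.astype(np.float32), np.zeros(cout, np.float32)))
        elif weights == "imagenet":
            raise ValueError(
                "pretrained weights are not bundled; export them to .npz "
                "(keys conv{i}_w / conv{i}_b) and pass the file path"
            )
        else:
            data = np.load(weights)
            for i, (cout, cin_) in enumerate(shapes):
                w = np.asarray(data[f"conv{i}_w"], np.float32)
                b = np.asarray(data[f"conv{i}_b"], np.float32)
                if w.shape != (cout, cin_, 3, 3):
                    raise ValueError(
                        f"conv{i}_w has shape {w.shape}, expected {(cout, cin_, 3, 3)}"
                    )
                self.layers.append((w, b))

    def set_constant_weights(self, weight: float, bias: float) -> None:
        """Overwrite every kernel/bias with constants (closed-form tests)."""
        self.layers = [
            (np.full_like(w, weight), np.full_like(b, bias)) for w, b in self.layers
        ]

    def stage_outputs(self, x: np.ndarray) -> list[np.ndarray]:
        """Feature maps after each of the 5 max-pooling stages."""
        x = np.asarray(x, np.float32)
        if x.ndim != 3 or x.shape[0] != 3:
            raise ValueError(f"expected (3, H, W) input, got {x.shape}")
        outs = []
        li = 0
        for stage in VGG19_CFG:
            for _ in stage:
                w, b = self.layers[li]
                x = _conv2d_same(x, w, b)
                if self.relu:
                    np.maximum(x, 0.0, out=x)
                li += 1
            x = _maxpool2(x)
            outs.append(x)
        return outs


def preprocess_roi(roi) -> np.ndarray:
    """Rescale gray values to [0, 1] (per-ROI min/max) and replicate to three
    channels; spatial size is preserved.  A constant ROI maps to zeros."""
    px = np.asarray(roi.pixels if isinstance(roi, ROIPatch) else roi, np.float64)
    lo, hi = px.min(), px.max()
    scaled = np.zeros_like(px) if hi == lo else (px - lo) / (hi - lo)
    return np.broadcast_to(scaled, (3, *scaled.shape)).astype(np.float32).copy()


def stage_features(inp: np.ndarray, backbone: VGG19Backbone, pooling: str = "avg") -> np.ndarray:
    """Concatenated per-channel spatial pooling of the 5 stage outputs
    (1472 values, network order)."""
    if pooling not in ("avg", "max"):
        raise ValueError("pooling must be 'avg' or 'max'")
    parts = []
    for fm in backbone.stage_outputs(inp):
        pooled = fm.mean(axis=(1, 2)) if pooling == "avg" else fm.max(axis=(1, 2))
        parts.append(pooled.astype(np.float64))
    return np.concatenate(parts)


@dataclass
class DeepFeatureMatrix:
    """Raw deep features: one row per ROI, 1472 columns, with the pooling
    stage index of every column."""

    values: np.ndarray
    column_stage: np.ndarray
    index: "pd.DataFrame"  # provenance columns (patient_id, modality, region)

    def __post_init__(self) -> None:
        if self.values.shape[1] != N_DEEP_FEATURES:
            raise ValueError(f"expected {N_DEEP_FEATURES} columns, got {self.values.shape[1]}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("deep feature matrix contains non-finite values")


def extract_deep_matrix(patches, backbone: VGG19Backbone, pooling: str = "avg") -> DeepFeatureMatrix:
    import pandas as pd

    vals = np.stack([stage_features(preprocess_roi(p), backbone, pooling) for p in patches])
    col_stage = np.repeat(np.arange(5), STAGE_CHANNELS)
    idx = pd.DataFrame(
        [{"patient_id": p.patient_id, "modality": p.modality, "region": p.region} for p in patches]
    )
    return DeepFeatureMatrix(values=vals, column_stage=col_stage, index=idx)


def filter_columns(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop zero-variance columns and columns with > 50% exactly-zero entries
    (strictly greater than half).  Returns (filtered matrix, survivor mask).
    Idempotent: re-filtering a filtered matrix keeps every column."""
    X = matrix.values if isinstance(matrix, DeepFeatureMatrix) else np.asarray(matrix, np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2D matrix with >= 2 rows")
    nonconstant = X.min(axis=0) != X.max(axis=0)
    zero_frac = (X == 0).mean(axis=0)
    mask = nonconstant & (zero_frac <= 0.5)
    if not mask.any():
        raise ValueError("all deep-feature columns were removed by the variance/zero filter")
    return X[:, mask], mask


@dataclass
class PseudoFeatureSet:
    """PCA scores (k per ROI) with the fitted filter + projection for reuse."""

    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    fitted_filter_mask: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray  # (k, n_filtered_columns)

    def transform(self, raw: np.ndarray) -> np.ndarray:
        """Project new raw 1472-column rows with the stored filter + PCA."""
        X = np.asarray(raw, np.float64)[:, self.fitted_filter_mask]
        return (X - self.mean) / self.scale @ self.components.T


def pca_pseudofeatures(matrix, k: int = 20) -> PseudoFeatureSet:
    """Standardize the filtered columns and project onto the top-k principal
    components.  The fit is intended to be performed once per modality and
    applied to every region of that modality.

    Component signs are fixed by forcing each component's largest-magnitude
    loading positive, so downstream signed correlations are reproducible.
    """
    from sklearn.decomposition import PCA

    if isinstance(matrix, DeepFeatureMatrix):
        X, mask = filter_columns(matrix.values)
    else:
        X = np.asarray(matrix, np.float64)
        mask = np.ones(X.shape[1], bool)
    n, p = X.shape
    if n <= k:
        raise ValueError(f"need more than k={k} rows to fit PCA, got {n}")
    if p < k:
        raise ValueError(f"need at least k={k} columns after filtering, got {p}")
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    scale[scale == 0] = 1.0  # filter should have removed these already
    Z = (X - mean) / scale
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Z)
    comps = pca.components_
    flip = np.sign(comps[np.arange(k), np.argmax(np.abs(comps), axis=1)])
    flip[flip == 0] = 1.0
    comps = comps * flip[:, None]
    scores = scores * flip[None, :]
    return PseudoFeatureSet(
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        fitted_filter_mask=mask,
        mean=mean,
        scale=scale,
        components=comps,
    )
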