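"""Encoding models and model-based receptive-field inference.

The model of a unit's per-fixation response is a linear readout (ridge
regression) of a fixed feature representation of the image patch at a given
retinotopic offset from the fixation point.  Fitting a separate readout at
every offset of a fixation-anchored grid (-7..7 dva, 1-dva steps, 15 x 15)
and measuring cross-validated performance yields a spatial map whose peak
marks the receptive field (RF).  A second, regularized stage shares the
readout weights from the peak offset across all offsets and correlates the
resulting scalar "preference" with held-out responses, a computation
analogous to reverse correlation.  Elliptical-Gaussian fits summarize the
maps; cross-split consistency of the fits quantifies RF evidence.

Feature extractors are deterministic built-ins (a Gabor energy bank and a
seeded random projection of patch pixels); any callable mapping patch
pixels to a fixed-length vector can be registered behind the same
interface (e.g., a pretrained-network adapter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.model_selection import GroupKFold

__all__ = [
    "GridSpec",
    "FIXATION_GRID",
    "RF_GRID",
    "FeatureExtractor",
    "GaborBankExtractor",
    "RandomProjectionExtractor",
    "get_extractor",
    "FeatureGrid",
    "extract_patch_features",
    "RFModelConfig",
    "RFMap",
    "GaussianRF",
    "offset_grid",
    "offset_feature_stack",
    "fit_response_model",
    "normalize_performance",
    "map_rf",
    "fit_gaussian_rf",
    "rf_consistency",
    "saccade_rf_timecourse",
    "normalized_saccade_map",
    "adjust_match_fit",
]

GRAY = 0.5  # padding value for patches extending beyond the image


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r with a zero-variance guard (returns nan instead of warning)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# Grid specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Sampling grid for cached patch features.

    patch_dva: side of the square patch; step_dva: grid spacing;
    margin_dva: how far the grid extends beyond the image edge (gray-padded),
    so fixation-anchored offsets up to the margin stay on the grid.
    """

    patch_dva: float
    step_dva: float
    margin_dva: float = 7.0


FIXATION_GRID = GridSpec(patch_dva=4.0, step_dva=1.0)  # fixation-centered models
RF_GRID = GridSpec(patch_dva=2.0, step_dva=0.5)  # RF mapping / simulation


# ---------------------------------------------------------------------------
# Feature extractors
# ---------------------------------------------------------------------------

class FeatureExtractor:
    """Deterministic map from patch pixels to a fixed-length feature vector."""

    name: str = "base"
    deterministic: bool = True

    def dim(self, patch_px: int) -> int:
        raise NotImplementedError

    def transform(self, patches: np.ndarray) -> np.ndarray:
        """patches: (n, P, P) float in [0, 1] -> (n, D) float32."""
        raise NotImplementedError


class GaborBankExtractor(FeatureExtractor):
    """Multi-scale, multi-orientation Gabor bank plus local luminance structure.

    Per patch: mean luminance, pixel s.d. (contrast), a coarse
    ``lum_grid`` x ``lum_grid`` grid of block-mean luminances (local
    luminance layout, as in the earliest stages of any visual feature
    hierarchy), and for each of ``n_scales`` x ``n_orientations`` Gabor
    kernels the linear cosine and sine responses (on the mean-subtracted
    patch) and their quadrature energy.
    D = 2 + lum_grid**2 + 3 * n_scales * n_orientations.
    """

    name = "gabor-bank"

    def __init__(self, n_scales: int = 3, n_orientations: int = 4, lum_grid: int = 4):
        self.n_scales = n_scales
        self.n_orientations = n_orientations
        self.lum_grid = lum_grid
        self._kernels: dict[int, np.ndarray] = {}

    def dim(self, patch_px: int) -> int:
        return 2 + self.lum_grid**2 + 3 * self.n_scales * self.n_orientations

    def _bank(self, P: int) -> np.ndarray:
        if P not in self._kernels:
            yy, xx = np.mgrid[0:P, 0:P].astype(float) - (P - 1) / 2.0
            cols = []
            for s in range(self.n_scales):
                lam = P / (2.0 * 2**s)  # wavelengths P/2, P/4, P/8 px
                sigma = 0.6 * lam
                env = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
                for o in range(self.n_orientations):
                    th = math.pi * o / self.n_orientations
                    u = xx * math.cos(th) + yy * math.sin(th)
                    c = env * np.cos(2 * math.pi * u / lam)
                    s_ = env * np.sin(2 * math.pi * u / lam)
                    c -= c.mean()  # zero-mean so responses ignore patch luminance
                    norm = math.sqrt((c**2).sum()) or 1.0
                    cols.append(c.ravel() / norm)
                    norm = math.sqrt((s_**2).sum()) or 1.0
                    cols.append(s_.ravel() / norm)
            self._kernels[P] = np.stack(cols, axis=1).astype(np.float32)
        return self._kernels[P]

    def transform(self, patches: np.ndarray) -> np.ndarray:
        n, P, _ = patches.shape
        flat = patches.reshape(n, P * P).astype(np.float32)
        mean = flat.mean(axis=1)
        std = flat.std(axis=1)
        g = self.lum_grid
        if P % g == 0:
            k = P // g
            blocks = patches.reshape(n, g, k, g, k).mean(axis=(2, 4)).reshape(n, g * g)
        else:
            idx = np.linspace(0, P - 1, g).round().astype(int)
            blocks = patches[:, idx][:, :, idx].reshape(n, g * g)
        K = self._bank(P)
        lin = (flat - mean[:, None]) @ K  # (n, 2 * n_pairs)
        cosr = lin[:, 0::2]
        sinr = lin[:, 1::2]
        energy = np.sqrt(cosr**2 + sinr**2)
        return np.concatenate(
            [mean[:, None], std[:, None], blocks.astype(np.float32),
             cosr, sinr, energy], axis=1
        ).astype(np.float32)


class RandomProjectionExtractor(FeatureExtractor):
    """Seeded fixed random projection of the downsampled patch pixels.

    Projection weights are made point-symmetric within the patch
    (w(u) = w(-u)), so each channel's spatial weighting is centered on
    the patch: a channel then probes image content *at* the patch
    location rather than at a random sub-patch offset.
    """

    name = "random-projection"

    def __init__(self, n_features: int = 32, down: int = 8, seed: int = 12345):
        self.n_features = n_features
        self.down = down
        self.seed = seed
        self._proj: dict[int, np.ndarray] = {}

    def dim(self, patch_px: int) -> int:
        return self.n_features

    def _matrix(self) -> np.ndarray:
        key = self.down * self.down
        if key not in self._proj:
            rng = np.random.default_rng(self.seed)
            R = rng.standard_normal((self.down, self.down, self.n_features))
            R = (R + R[::-1, ::-1]) / 2.0  # center each channel's weight mass
            self._proj[key] = (
                R.reshape(key, self.n_features) / math.sqrt(key)
            ).astype(np.float32)
        return self._proj[key]

    def transform(self, patches: np.ndarray) -> np.ndarray:
        n, P, _ = patches.shape
        d = self.down
        if P % d == 0:
            k = P // d
            small = patches.reshape(n, d, k, d, k).mean(axis=(2, 4))
        else:
            idx = np.linspace(0, P - 1, d).round().astype(int)
            small = patches[:, idx][:, :, idx]
        return (small.reshape(n, d * d).astype(np.float32) @ self._matrix())


_EXTRACTORS = {
    "gabor-bank": GaborBankExtractor,
    "random-projection": RandomProjectionExtractor,
}


def get_extractor(name: str, **kwargs) -> FeatureExtractor:
    if name not in _EXTRACTORS:
        raise KeyError(f"unknown feature extractor: {name!r} (have {sorted(_EXTRACTORS)})")
    return _EXTRACTORS[name](**kwargs)


# ---------------------------------------------------------------------------
# Cached feature grids
# ---------------------------------------------------------------------------

@dataclass
class FeatureGrid:
    """Cached patch features for one image on a regular grid (image coords)."""

    image_id: str
    spec: GridSpec
    x_centers: np.ndarray  # (nx,) dva, ascending
    y_centers: np.ndarray  # (ny,) dva, ascending
    features: np.ndarray  # (ny, nx, D) float32
    extractor: str

    @property
    def dim(self) -> int:
        return self.features.shape[2]

    def nearest_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Indices of the grid cell closest to image-coordinate point(s)."""
        step = self.spec.step_dva
        ix = np.clip(
            np.rint((np.asarray(x, float) - self.x_centers[0]) / step).astype(int),
            0,
            len(self.x_centers) - 1,
        )
        iy = np.clip(
            np.rint((np.asarray(y, float) - self.y_centers[0]) / step).astype(int),
            0,
            len(self.y_centers) - 1,
        )
        return iy, ix

    def features_at(self, x, y) -> np.ndarray:
        iy, ix = self.nearest_index(x, y)
        return self.features[iy, ix]

    def channel_bilinear(self, x, y, channel: int) -> np.ndarray:
        """Bilinear interpolation of one feature channel at image points.

        Makes the feature field continuous in position (the cached grid is
        a discrete sampling of a continuous patch transform).
        """
        step = self.spec.step_dva
        gx = np.clip((np.asarray(x, float) - self.x_centers[0]) / step,
                     0, len(self.x_centers) - 1 - 1e-9)
        gy = np.clip((np.asarray(y, float) - self.y_centers[0]) / step,
                     0, len(self.y_centers) - 1 - 1e-9)
        ix0 = gx.astype(int)
        iy0 = gy.astype(int)
        fx = gx - ix0
        fy = gy - iy0
        F = self.features[..., channel]
        return ((1 - fy) * ((1 - fx) * F[iy0, ix0] + fx * F[iy0, ix0 + 1])
                + fy * ((1 - fx) * F[iy0 + 1, ix0] + fx * F[iy0 + 1, ix0 + 1]))


def extract_patch_features(
    images: dict[str, np.ndarray],
    spec: GridSpec,
    extractor: FeatureExtractor | str,
    pixels_per_dva: float = 8.0,
) -> dict[str, FeatureGrid]:
    """Precompute patch features on a regular grid per image.

    Grid cells beyond the image use gray-padded patches; the grid covers
    the image plus ``spec.margin_dva`` on every side.  A fixation (or any
    image-coordinate point) indexes the closest cell.
    """
    if isinstance(extractor, str):
        extractor = get_extractor(extractor)
    ppd = pixels_per_dva
    P = int(round(spec.patch_dva * ppd))
    grids: dict[str, FeatureGrid] = {}
    for image_id, img in images.items():
        img = np.asarray(img, np.float32)
        h_px, w_px = img.shape
        w_dva, h_dva = w_px / ppd, h_px / ppd
        ex = w_dva / 2 + spec.margin_dva
        ey = h_dva / 2 + spec.margin_dva
        nx = int(math.floor(ex / spec.step_dva + 1e-9)) * 2 + 1
        ny = int(math.floor(ey / spec.step_dva + 1e-9)) * 2 + 1
        x_centers = (np.arange(nx) - nx // 2) * spec.step_dva
        y_centers = (np.arange(ny) - ny // 2) * spec.step_dva
        pad = int(math.ceil((max(ex, ey) + spec.patch_dva) * ppd)) + 2
        padded = np.full((h_px + 2 * pad, w_px + 2 * pad), GRAY, np.float32)
        padded[pad : pad + h_px, pad : pad + w_px] = img
        # pixel column of patch left edge per x center; row of top edge per y center
        c0 = np.rint((x_centers + w_dva / 2) * ppd - P / 2).astype(int) + pad
        # y up in dva, rows increase downward
        r0 = np.rint((h_dva / 2 - y_centers) * ppd - P / 2).astype(int) + pad
        rows = r0[:, None, None, None] + np.arange(P)[None, None, :, None]
        cols = c0[None, :, None, None] + np.arange(P)[None, None, None, :]
        patches = padded[rows, cols]  # (ny, nx, P, P)
        feats = extractor.transform(patches.reshape(ny * nx, P, P))
        grids[image_id] = FeatureGrid(
            image_id=image_id,
            spec=spec,
            x_centers=x_centers,
            y_centers=y_centers,
            features=feats.reshape(ny, nx, -1),
            extractor=extractor.name,
        )
    return grids


def offset_grid(extent: float = 7.0, step: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Offset axes for RF mapping; default 15 x 15 from -7 to 7 dva."""
    ax = np.arange(-extent, extent + step / 2, step)
    return ax, ax


def offset_feature_stack(
    grids: dict[str, FeatureGrid],
    image_ids: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    offsets_x: np.ndarray,
    offsets_y: np.ndarray,
) -> np.ndarray:
    """Features at (point + offset) for every point and offset.

    Returns (n_points, n_offsets, D) float32 with offsets enumerated as
    (oy, ox) row-major over the offset grid.
    """
    image_ids = np.asarray(image_ids)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    any_grid = next(iter(grids.values()))
    D = any_grid.dim
    n_off = len(offsets_x) * len(offsets_y)
    out = np.empty((len(x), n_off, D), np.float32)
    ox_flat = np.tile(offsets_x, len(offsets_y))
    oy_flat = np.repeat(offsets_y, len(offsets_x))
    for image_id in np.unique(image_ids):
        sel = np.flatnonzero(image_ids == image_id)
        g = grids[image_id]
        px = x[sel][:, None] + ox_flat[None, :]
        py = y[sel][:, None] + oy_flat[None, :]
        iy, ix = g.nearest_index(px, py)
        out[sel] = g.features[iy, ix]
    return out


# ---------------------------------------------------------------------------
# Ridge models with grouped CV
# ---------------------------------------------------------------------------

@dataclass
class RFModelConfig:
    """Configuration shared by all encoding-model fits."""

    alpha: float = 1e5
    n_folds: int = 5
    offset_extent: float = 7.0
    offset_step: float = 1.0
    eps: float = 1e-12

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("ridge alpha must be > 0")


def _image_folds(image_ids: np.ndarray, n_folds: int):
    """Fold index per sample; folds partition *images* (grouped CV)."""
    image_ids = np.asarray(image_ids)
    if len(np.unique(image_ids)) < n_folds:
        raise ValueError(
            f"need >= {n_folds} distinct images for {n_folds}-fold grouped CV"
        )
    folds = np.empty(len(image_ids), int)
    gkf = GroupKFold(n_splits=n_folds)
    for k, (_, test) in enumerate(gkf.split(image_ids, groups=image_ids)):
        folds[test] = k
    return folds


def _ridge_batch(X: np.ndarray, y: np.ndarray, alpha: float, eps: float):
    """Solve standardized ridge for a batch of offsets.

    X: (n, n_off, D); y: (n,).  Returns (weights (n_off, D), mu, sd, ymean)
    where weights act on standardized features and predict y - ymean.
    """
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < eps, 1.0, sd)
    Xs = (X - mu[None]) / sd[None]
    ymean = float(y.mean())
    yc = (y - ymean).astype(np.float32)
    Xt = np.ascontiguousarray(Xs.transpose(1, 2, 0))  # (o, d, n)
    G = (Xt @ Xt.transpose(0, 2, 1)).astype(np.float64)  # batched BLAS
    D = X.shape[2]
    G[:, np.arange(D), np.arange(D)] += alpha
    b = (Xt @ yc).astype(np.float64)  # (o, d)
    w = np.linalg.solve(G, b[..., None])[..., 0]
    return w, mu, sd, ymean


def _predict_batch(X, w, mu, sd, ymean):
    Xs = (X - mu[None]) / sd[None]
    return np.einsum("nod,od->no", Xs, w, optimize=True) + ymean


def fit_response_model(
    features: np.ndarray,
    responses: np.ndarray,
    image_ids: np.ndarray,
    config: RFModelConfig | None = None,
) -> dict:
    """Fit the fixation-centered encoding model with grouped CV.

    features: (n, D) patch features at the fixations; responses: (n,).
    Folds partition images, so no return-fixation pair straddles train and
    test.  Performance is the Pearson r between predicted and actual
    held-out responses, averaged over folds (per-fold correlation avoids
    the bias that image-level rate differences between folds induce in a
    pooled correlation at small sample sizes).
    """
    config = config or RFModelConfig()
    X = np.asarray(features, np.float32)[:, None, :]
    y = np.asarray(responses, float)
    folds = _image_folds(image_ids, config.n_folds)
    preds = np.full(len(y), np.nan)
    fold_r = np.full(config.n_folds, np.nan)
    for k in range(config.n_folds):
        tr = folds != k
        te = ~tr
        w, mu, sd, ymean = _ridge_batch(X[tr], y[tr], config.alpha, config.eps)
        preds[te] = _predict_batch(X[te], w, mu, sd, ymean)[:, 0]
        fold_r[k] = pearson(preds[te], y[te])
    return {
        "predictions": preds,
        "performance": float(np.nanmean(fold_r)),
        "fold_performance": fold_r,
        "folds": folds,
    }


def normalize_performance(r_model: float, r_sc: float) -> tuple[float, bool]:
    """Ceiling-normalize model performance by self-consistency.

    Returns (value, excluded).  Excluded when the self-consistency ceiling
    is <= 0; otherwise the ratio clipped to [0, 1], then squared (fraction
    of explainable variance captured up to a linear transform).
    """
    if not np.isfinite(r_sc) or r_sc <= 0:
        return float("nan"), True
    return float(np.clip(r_model / r_sc, 0.0, 1.0) ** 2), False


# ---------------------------------------------------------------------------
# Offset-grid RF maps
# ---------------------------------------------------------------------------

@dataclass
class RFMap:
    """Model-based RF map on a fixation-anchored offset grid.

    ``performance``: stage-1 held-out model performance per offset per CV
    split; ``map``: stage-2 reverse-correlation-style map per split.
    Shapes (ny, nx, n_splits) with y ascending (row 0 = most negative
    offset).
    """

    offsets_x: np.ndarray
    offsets_y: np.ndarray
    performance: np.ndarray
    map: np.ndarray
    valid: bool = True

    @property
    def n_splits(self) -> int:
        return self.map.shape[2]

    def mean_map(self) -> np.ndarray:
        return np.nanmean(self.map, axis=2)

    def peak_performance(self) -> float:
        return float(np.nanmax(np.nanmean(self.performance, axis=2)))


def map_rf(
    stack: np.ndarray,
    responses: np.ndarray,
    image_ids: np.ndarray,
    config: RFModelConfig | None = None,
    offsets_x: np.ndarray | None = None,
    offsets_y: np.ndarray | None = None,
) -> RFMap:
    """Two-stage model-based RF mapping on a fixation-anchored offset grid.

    stack: (n, n_off, D) features per event per offset (see
    :func:`offset_feature_stack`); responses: (n,) rates in the analysis
    window.  Stage 1 fits an independent ridge readout per offset per CV
    split and records held-out performance.  Stage 2 regularizes the map:
    per split, the readout weights from the peak-performance offset (peak
    of that split's training-set performance) project every offset's
    features to a scalar preference per held-out event, and the map value
    is the correlation of that scalar with the held-out responses.
    """
    config = config or RFModelConfig()
    if offsets_x is None or offsets_y is None:
        offsets_x, offsets_y = offset_grid(config.offset_extent, config.offset_step)
    ny, nx = len(offsets_y), len(offsets_x)
    X = np.asarray(stack, np.float32)
    y = np.asarray(responses, float)
    image_ids = np.asarray(image_ids)
    finite = np.isfinite(y)
    X, y, image_ids = X[finite], y[finite], image_ids[finite]
    n, n_off, _ = X.shape
    assert n_off == ny * nx
    if len(y) < config.n_folds + 1 or np.std(y) == 0:
        empty = np.full((ny, nx, config.n_folds), np.nan)
        return RFMap(offsets_x, offsets_y, empty, empty.copy(), valid=False)
    folds = _image_folds(image_ids, config.n_folds)
    perf = np.full((n_off, config.n_folds), np.nan)
    rmap = np.full((n_off, config.n_folds), np.nan)
    for k in range(config.n_folds):
        tr = folds != k
        te = ~tr
        if te.sum() < 3 or np.std(y[tr]) == 0 or np.std(y[te]) == 0:
            continue
        Xtr, Xte = X[tr], X[te]
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd = np.where(sd < config.eps, 1.0, sd).astype(np.float32)
        mu = mu.astype(np.float32)
        Xs_tr = (Xtr - mu[None]) / sd[None]
        Xs_te = (Xte - mu[None]) / sd[None]
        ymean = float(y[tr].mean())
        yc = (y[tr] - ymean).astype(np.float32)
        Xt = np.ascontiguousarray(Xs_tr.transpose(1, 2, 0))  # (o, d, n)
        G = (Xt @ Xt.transpose(0, 2, 1)).astype(np.float64)
        D = X.shape[2]
        G[:, np.arange(D), np.arange(D)] += config.alpha
        b = (Xt @ yc).astype(np.float64)
        w = np.linalg.solve(G, b[..., None])[..., 0]
        w32 = w.astype(np.float32)
        pr_te = np.einsum("nod,od->no", Xs_te, w32, optimize=True)
        pr_tr = np.einsum("nod,od->no", Xs_tr, w32, optimize=True)
        yte_c = y[te] - y[te].mean()
        perf[:, k] = _corr_cols(pr_te, yte_c)
        train_perf = _corr_cols(pr_tr, yc.astype(float))
        o_star = int(np.nanargmax(train_perf))
        scalar = Xs_te @ w32[o_star]  # (n_te, n_off) preference per offset
        rmap[:, k] = _corr_cols(scalar, yte_c)
    valid = bool(np.isfinite(rmap).any())
    return RFMap(
        offsets_x,
        offsets_y,
        perf.reshape(ny, nx, -1),
        rmap.reshape(ny, nx, -1),
        valid=valid,
    )


def _corr_cols(M: np.ndarray, yc: np.ndarray) -> np.ndarray:
    """Pearson r between each column of M (n, m) and centered y (n,)."""
    Mc = M - M.mean(axis=0, keepdims=True)
    denom = np.sqrt((Mc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Mc * yc[:, None]).sum(axis=0) / denom
    return np.where(denom > 0, r, np.nan)


# ---------------------------------------------------------------------------
# Gaussian RF fits
# ---------------------------------------------------------------------------

@dataclass
class GaussianRF:
    """Elliptical 2-D Gaussian summary of an RF map.

    a, b are the s.d. along the major and minor axes (a >= b);
    FWHM = 2.355 * sqrt(a * b); coverage is the integral of the fitted
    Gaussian density inside the mapping window (-extent..extent dva).
    """

    center_x: float
    center_y: float
    a: float
    b: float
    orientation: float
    amplitude: float
    baseline: float
    fwhm: float
    gof: float
    coverage: float
    valid: bool = True
    peak_performance: float = float("nan")

    def surface(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        ct, st = math.cos(self.orientation), math.sin(self.orientation)
        u = (X - self.center_x) * ct + (Y - self.center_y) * st
        v = -(X - self.center_x) * st + (Y - self.center_y) * ct
        return self.baseline + self.amplitude * np.exp(
            -(u**2 / (2 * self.a**2) + v**2 / (2 * self.b**2))
        )

    def density_coverage(self, extent: float, n: int = 141) -> float:
        """Probability mass of the *normalized* Gaussian inside the window."""
        ax = np.linspace(-extent, extent, n)
        X, Y = np.meshgrid(ax, ax)
        ct, st = math.cos(self.orientation), math.sin(self.orientation)
        u = (X - self.center_x) * ct + (Y - self.center_y) * st
        v = -(X - self.center_x) * st + (Y - self.center_y) * ct
        dens = np.exp(-(u**2 / (2 * self.a**2) + v**2 / (2 * self.b**2)))
        dens /= 2 * math.pi * self.a * self.b
        cell = (ax[1] - ax[0]) ** 2
        return float(min(dens.sum() * cell, 1.0))

    def passes_selection(
        self, min_peak: float = 0.2, min_gof: float = 0.7, min_coverage: float = 0.5
    ) -> bool:
        return (
            self.valid
            and self.peak_performance >= min_peak
            and self.gof >= min_gof
            and self.coverage >= min_coverage
        )


def process_map(map2d: np.ndarray) -> np.ndarray:
    """Clip an RF map at 0 (negative correlations reflect overfitting), then square."""
    return np.clip(np.nan_to_num(np.asarray(map2d, float)), 0.0, None) ** 2


def _gauss_model(p, X, Y):
    x0, y0, sa, sb, th, amp, off = p
    ct, st = math.cos(th), math.sin(th)
    u = (X - x0) * ct + (Y - y0) * st
    v = -(X - x0) * st + (Y - y0) * ct
    return off + amp * np.exp(-(u**2 / (2 * sa**2) + v**2 / (2 * sb**2)))


def _gauss_jac(p, X, Y):
    x0, y0, sa, sb, th, amp, off = p
    ct, st = math.cos(th), math.sin(th)
    u = (X - x0) * ct + (Y - y0) * st
    v = -(X - x0) * st + (Y - y0) * ct
    E = np.exp(-(u**2 / (2 * sa**2) + v**2 / (2 * sb**2)))
    aE = amp * E
    J = np.empty(X.size * 7).reshape(X.shape + (7,))
    J[..., 0] = aE * (u * ct / sa**2 - v * st / sb**2)
    J[..., 1] = aE * (u * st / sa**2 + v * ct / sb**2)
    J[..., 2] = aE * u**2 / sa**3
    J[..., 3] = aE * v**2 / sb**3
    J[..., 4] = aE * u * v * (1.0 / sb**2 - 1.0 / sa**2)
    J[..., 5] = E
    J[..., 6] = 1.0
    return J.reshape(-1, 7)


def fit_gaussian_rf(
    map2d: np.ndarray,
    offsets_x: np.ndarray | None = None,
    offsets_y: np.ndarray | None = None,
    peak_performance: float = float("nan"),
    preprocess: bool = True,
) -> GaussianRF:
    """Least-squares elliptical-Gaussian fit to an RF map.

    The map is clipped at 0 and squared before fitting (skip with
    ``preprocess=False`` if already processed).  Multi-start: center
    initialized at the map peak and at the grid center; the lower-residual
    solution wins.  Axes are reported with a >= b.
    """
    if offsets_x is None or offsets_y is None:
        offsets_x, offsets_y = offset_grid()
    Z = process_map(map2d) if preprocess else np.nan_to_num(np.asarray(map2d, float))
    X, Y = np.meshgrid(offsets_x, offsets_y)
    extent = float(offsets_x[-1])
    zmax = Z.max()
    if not np.isfinite(zmax) or zmax <= 0:
        return GaussianRF(0, 0, 1, 1, 0, 0, 0, 2.355, float("nan"), 0.0, valid=False,
                          peak_performance=peak_performance)
    iy, ix = np.unravel_index(np.argmax(Z), Z.shape)
    # moment-based width initialization around the peak
    W = np.clip(Z - np.median(Z), 0, None)
    tot = W.sum()
    if tot > 0:
        mx = float((W * X).sum() / tot)
        my = float((W * Y).sum() / tot)
        sx = math.sqrt(max(float((W * (X - mx) ** 2).sum() / tot), 0.04))
        sy = math.sqrt(max(float((W * (Y - my) ** 2).sum() / tot), 0.04))
    else:
        sx = sy = 1.5
    starts = [
        (float(offsets_x[ix]), float(offsets_y[iy]), sx, sy),
        (0.0, 0.0, 1.5, 1.5),
    ]
    span = extent * 2
    best = None
    for x0, y0, s0x, s0y in starts:
        p0 = [x0, y0, s0x, s0y, 0.0, zmax, float(np.median(Z))]
        lb = [-span, -span, 0.05, 0.05, -math.pi, 0.0, -zmax]
        ub = [span, span, span, span, math.pi, 4 * zmax + 1e-12, zmax]
        p0 = np.clip(p0, lb, ub)
        try:
            res = least_squares(
                lambda p: (_gauss_model(p, X, Y) - Z).ravel(),
                p0,
                jac=lambda p: _gauss_jac(p, X, Y),
                bounds=(lb, ub),
                max_nfev=400,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return GaussianRF(0, 0, 1, 1, 0, 0, 0, 2.355, float("nan"), 0.0, valid=False,
                          peak_performance=peak_performance)
    x0, y0, sa, sb, th, amp, off = best.x
    if sb > sa:  # enforce a >= b, rotating by 90 degrees
        sa, sb = sb, sa
        th += math.pi / 2
    th = (th + math.pi / 2) % math.pi - math.pi / 2
    fit = GaussianRF(
        center_x=float(x0),
        center_y=float(y0),
        a=float(sa),
        b=float(sb),
        orientation=float(th),
        amplitude=float(amp),
        baseline=float(off),
        fwhm=float(2.355 * math.sqrt(sa * sb)),
        gof=float("nan"),
        coverage=0.0,
        valid=True,
        peak_performance=peak_performance,
    )
    fit.gof = pearson(fit.surface(X, Y).ravel(), Z.ravel())
    fit.coverage = fit.density_coverage(extent)
    return fit


def rf_consistency(rfmap: RFMap) -> float:
    """Cross-split RF evidence.

    Per split, fit a Gaussian to that split's processed map and evaluate
    its surface against every *other* split's processed map (Pearson r);
    average over all directed split pairs.  NaN when fewer than 2 splits
    have usable maps.
    """
    S = rfmap.n_splits
    X, Y = np.meshgrid(rfmap.offsets_x, rfmap.offsets_y)
    processed = [process_map(rfmap.map[:, :, s]) for s in range(S)]
    usable = [s for s in range(S) if np.isfinite(rfmap.map[:, :, s]).any()]
    if len(usable) < 2:
        return float("nan")
    scores = []
    for i in usable:
        g = fit_gaussian_rf(processed[i], rfmap.offsets_x, rfmap.offsets_y,
                            preprocess=False)
        if not g.valid:
            continue
        surf = g.surface(X, Y).ravel()
        for j in usable:
            if j == i:
                continue
            scores.append(pearson(surf, processed[j].ravel()))
    return float(np.nanmean(scores)) if scores else float("nan")


# ---------------------------------------------------------------------------
# Saccade-aligned RF time courses and normalized-saccade joint maps
# ---------------------------------------------------------------------------

def saccade_rf_timecourse(
    grids: dict[str, FeatureGrid],
    saccades: pd.DataFrame,
    binned_responses: np.ndarray,
    config: RFModelConfig | None = None,
    anchors: tuple[str, ...] = ("fp1", "fp2", "midpoint"),
) -> dict[str, np.ndarray]:
    """RF evidence per anchor per saccade-aligned time bin.

    ``saccades`` needs columns image_id, x1, y1, x2, y2 (image coords
    of the pre-/postsaccadic fixation points); ``binned_responses``
    is (n_saccades, n_bins) rates aligned to saccade onsets.  Each bin is
    modeled independently with the full map -> Gaussian fit -> cross-split
    consistency chain.  ``midpoint`` anchors to the Euclidean midpoint of
    the two fixation points.
    """
    config = config or RFModelConfig()
    offsets_x, offsets_y = offset_grid(config.offset_extent, config.offset_step)
    R = np.asarray(binned_responses, float)
    n_bins = R.shape[1]
    image_ids = saccades["image_id"].to_numpy()
    out: dict[str, np.ndarray] = {}
    for anchor in anchors:
        if anchor == "fp1":
            ax, ay = saccades["x1"].to_numpy(), saccades["y1"].to_numpy()
        elif anchor == "fp2":
            ax, ay = saccades["x2"].to_numpy(), saccades["y2"].to_numpy()
        elif anchor == "midpoint":
            ax = (saccades["x1"].to_numpy() + saccades["x2"].to_numpy()) / 2
            ay = (saccades["y1"].to_numpy() + saccades["y2"].to_numpy()) / 2
        else:
            raise ValueError(f"unknown anchor: {anchor!r}")
        stack = offset_feature_stack(grids, image_ids, ax, ay, offsets_x, offsets_y)
        ev = np.full(n_bins, np.nan)
        for b in range(n_bins):
            y = R[:, b]
            ok = np.isfinite(y)
            if ok.sum() < 5 * config.n_folds:
                continue
            m = map_rf(stack[ok], y[ok], image_ids[ok], config, offsets_x, offsets_y)
            if m.valid:
                ev[b] = rf_consistency(m)
        out[anchor] = ev
    return out


def normalized_saccade_map(
    grids: dict[str, FeatureGrid],
    saccades: pd.DataFrame,
    binned_responses: np.ndarray,
    config: RFModelConfig | None = None,
    rel_positions: np.ndarray | None = None,
    min_amplitude: float = 2.0,
    feature_saccades: pd.DataFrame | None = None,
    rf_center: tuple[float, float] = (0.0, 0.0),
) -> dict:
    """Joint (relative position along saccade) x (time) model-performance map.

    Relative positions (default -0.5..1.5 in 0.25 steps; 0 = presaccadic
    RF 1, 1 = postsaccadic RF 2, 0.5 = midpoint) are converted to actual
    image locations per saccade and modeled with the stage-1 ridge +
    grouped CV.  ``rf_center`` is the unit's retinotopic RF-center offset
    (dva): relative position 0 then sits on RF 1 (not the fixation point)
    and 1 on RF 2.  Saccades below ``min_amplitude`` are dropped so
    relative positions stay well defined.  For match-saccade controls
    pass ``feature_saccades``: stimulus features are taken along those
    (template) saccades while responses remain the given ones.
    """
    config = config or RFModelConfig()
    if rel_positions is None:
        rel_positions = np.arange(-0.5, 1.5 + 0.125, 0.25)
    fs = feature_saccades if feature_saccades is not None else saccades
    if len(fs) != len(saccades):
        raise ValueError("feature_saccades must align row-wise with saccades")
    dx = fs["x2"].to_numpy() - fs["x1"].to_numpy()
    dy = fs["y2"].to_numpy() - fs["y1"].to_numpy()
    amp = np.hypot(dx, dy)
    keep = amp >= min_amplitude
    if keep.sum() < 5 * config.n_folds:
        return {"performance": None, "rel_positions": rel_positions, "valid": False}
    fs = fs.loc[keep]
    R = np.asarray(binned_responses, float)[keep]
    image_ids = fs["image_id"].to_numpy()
    px = fs["x1"].to_numpy()[:, None] + rf_center[0] + dx[keep][:, None] * rel_positions[None, :]
    py = fs["y1"].to_numpy()[:, None] + rf_center[1] + dy[keep][:, None] * rel_positions[None, :]
    # build a (n, n_pos, D) stack by treating positions like offsets
    any_grid = next(iter(grids.values()))
    X = np.empty((len(fs), len(rel_positions), any_grid.dim), np.float32)
    for image_id in np.unique(image_ids):
        sel = np.flatnonzero(image_ids == image_id)
        g = grids[image_id]
        iy, ix = g.nearest_index(px[sel], py[sel])
        X[sel] = g.features[iy, ix]
    n_bins = R.shape[1]
    perf = np.full((len(rel_positions), n_bins), np.nan)
    folds = _image_folds(image_ids, config.n_folds)
    for b in range(n_bins):
        y = R[:, b]
        ok = np.isfinite(y)
        if ok.sum() < 5 * config.n_folds or np.std(y[ok]) == 0:
            continue
        Xo, yo, fo = X[ok], y[ok], folds[ok]
        fold_r = np.full((config.n_folds, len(rel_positions)), np.nan)
        for k in range(config.n_folds):
            tr = fo != k
            te = ~tr
            if te.sum() < 3 or np.std(yo[tr]) == 0 or np.std(yo[te]) == 0:
                continue
            w, mu, sd, ymean = _ridge_batch(Xo[tr], yo[tr], config.alpha, config.eps)
            preds = _predict_batch(Xo[te], w, mu, sd, ymean)
            fold_r[k] = _corr_cols(preds, yo[te] - yo[te].mean())
        perf[:, b] = np.nanmean(fold_r, axis=0)
    return {"performance": perf, "rel_positions": rel_positions, "valid": True}


def adjust_match_fit(
    orig_rf1: np.ndarray, match_rf1: np.ndarray, match_rf2: np.ndarray
) -> dict:
    """First-order correction of match-saccade model fits.

    Matching saccades at a 1-dva start threshold does not perfectly
    reproduce the presaccadic stimulus, so match-saccade RF 1 performance
    runs slightly below the original.  Fit slope + intercept mapping the
    match RF 1 time course onto the original RF 1 (grand averages), apply
    the same transform to the match RF 2 curve, and report diagnostics.
    """
    m1 = np.asarray(match_rf1, float)
    o1 = np.asarray(orig_rf1, float)
    m2 = np.asarray(match_rf2, float)
    ok = np.isfinite(m1) & np.isfinite(o1)
    if ok.sum() < 2 or np.std(m1[ok]) == 0:
        raise ValueError("degenerate fit: match RF1 curve has no variance")
    slope, intercept = np.polyfit(m1[ok], o1[ok], 1)
    fitted = slope * m1 + intercept
    ss_res = np.nansum((o1 - fitted) ** 2)
    ss_tot = np.nansum((o1 - np.nanmean(o1[ok])) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel_dev = np.where(np.abs(o1) > 1e-12, np.abs(fitted - o1) / np.abs(o1), np.nan)
    return {
        "adjusted_rf2": slope * m2 + intercept,
        "slope": float(slope),
        "intercept": float(intercept),
        "r2": float(1 - ss_res / ss_tot) if ss_tot > 0 else float("nan"),
        "relative_deviation_mean": float(np.nanmean(rel_dev)),
        "relative_deviation_sd": float(np.nanstd(rel_dev)),
    }
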