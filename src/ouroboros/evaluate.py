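"""Quantitative evaluation of generated images and expression predictions.

Covers central-spot cropping, Frechet-distance image quality with a
noise baseline, classical nucleus detection (colour deconvolution, Otsu,
watershed), the 63-feature nuclear morphometry profile with a paired
distance test, per-marker correlation metrics and a prediction-only CNN
baseline.

FID caveat: values are only comparable within one embedding. The default
embedding is a seeded fixed random convolutional network, so no pretrained
weights are needed; requesting ``external_pretrained`` raises with an
explanation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats
from skimage.color import rgb2hed
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import disk, opening
from skimage.segmentation import watershed
from scipy import ndimage as ndi

from . import _nn as nn
from .data import images_to_float

log = logging.getLogger(__name__)

N_MORPH_FEATURES = 63

_SHAPE_NAMES = ("area", "perimeter", "equivalent_diameter", "major_axis",
                "minor_axis", "eccentricity", "solidity", "extent",
                "circularity")
_CHANNEL_NAMES = ("red", "green", "blue", "hematoxylin", "eosin", "od")
_STAT_NAMES = ("mean", "std", "min", "max", "median", "p10", "p90",
               "skewness", "kurtosis")

MORPH_FEATURE_NAMES = tuple(_SHAPE_NAMES) + tuple(
    f"{ch}_{st}" for ch in _CHANNEL_NAMES for st in _STAT_NAMES)


# ---------------------------------------------------------------------------
# cropping
# ---------------------------------------------------------------------------

def center_crop(img: np.ndarray, size: int) -> np.ndarray:
    """Axis-centred crop with half-open bounds: rows/cols [(d-size)//2, ...+size)."""
    h, w = img.shape[:2]
    if size > h or size > w:
        raise ValueError(f"crop size {size} exceeds image dims {(h, w)}")
    y0 = (h - size) // 2
    x0 = (w - size) // 2
    return img[y0:y0 + size, x0:x0 + size]


# ---------------------------------------------------------------------------
# image embeddings + FID
# ---------------------------------------------------------------------------

def _to_unit(images: np.ndarray) -> np.ndarray:
    """Any image stack -> float32 in [0, 1]."""
    arr = np.asarray(images)
    if arr.dtype == np.uint8:
        return arr.astype(np.float32) / 255.0
    arr = arr.astype(np.float32)
    if arr.min() < -0.01:  # [-1, 1] convention
        arr = (arr + 1.0) / 2.0
    return np.clip(arr, 0.0, 1.0)


def _random_conv_embed(images: np.ndarray, seed: int) -> np.ndarray:
    """Fixed random 3-layer conv net; embedding = spatial mean+std, 64-D."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF1D]))
    x = _to_unit(images) - 0.5
    widths = [(3, 16), (16, 32), (32, 32)]
    ws = [nn.Tensor(rng.normal(0, np.sqrt(2.0 / (9 * ci)), (3, 3, ci, co))
                    .astype(np.float32)) for ci, co in widths]
    out = []
    with nn.no_grad():
        for i in range(0, len(x), 64):
            h = nn.Tensor(x[i:i + 64])
            for w in ws:
                h = nn.avgpool2x(nn.relu(nn.conv3x3(h, w)))
            d = h.data
            mu = d.mean(axis=(1, 2))
            sd = d.std(axis=(1, 2))
            out.append(np.concatenate([mu, sd], axis=1))
    return np.concatenate(out, axis=0).astype(np.float64)


def _handcrafted_embed(images: np.ndarray) -> np.ndarray:
    """Deterministic 64-D descriptor: per-channel moments, histograms, gradients.

    On a constant-colour image the channel means equal the colour, all stds
    and gradient features are zero and each 8-bin histogram is one-hot at the
    colour's bin.
    """
    x = _to_unit(images)
    n = len(x)
    feats = np.zeros((n, 64))
    for i in range(n):
        img = x[i]
        col = 0
        for c in range(3):
            ch = img[..., c]
            feats[i, col:col + 2] = (ch.mean(), ch.std())
            col += 2
        for c in range(3):  # 8-bin histograms (24 dims)
            hist, _ = np.histogram(img[..., c], bins=8, range=(0, 1))
            feats[i, col:col + 8] = hist / img[..., c].size
            col += 8
        gray = img.mean(axis=2)
        gy, gx = np.gradient(gray)
        gm = np.hypot(gx, gy)
        feats[i, col:col + 4] = (gm.mean(), gm.std(), np.percentile(gm, 90), gm.max())
        col += 4
        hed = rgb2hed(img)
        for c in range(3):  # H, E, D channel moments (6 dims)
            feats[i, col:col + 2] = (hed[..., c].mean(), hed[..., c].std())
            col += 2
        # coarse 2x2 block means of gray (4 dims) for layout sensitivity
        hh, wwp = gray.shape
        blocks = gray[:hh // 2 * 2, :wwp // 2 * 2].reshape(2, hh // 2, 2, wwp // 2)
        feats[i, col:col + 4] = blocks.mean(axis=(1, 3)).ravel()
        col += 4
    return feats


def embed_images(images: np.ndarray, method: str = "seeded_random_conv",
                 seed: int = 0) -> np.ndarray:
    """Embed a stack of patches into fixed-dimension vectors for FID."""
    if method == "seeded_random_conv":
        return _random_conv_embed(images, seed)
    if method == "handcrafted":
        return _handcrafted_embed(images)
    if method == "external_pretrained":
        raise RuntimeError(
            "external_pretrained embedding requires downloading pretrained "
            "Inception weights; use 'seeded_random_conv' or 'handcrafted' "
            "for self-contained runs")
    raise ValueError(f"unknown embedding method {method!r}")


def compute_fid(emb_a: np.ndarray, emb_b: np.ndarray, eps: float = 1e-6) -> float:
    """Frechet distance between Gaussian fits of two embedding sets.

    ``||mu_a - mu_b||^2 + Tr(S_a + S_b - 2 (S_a S_b)^(1/2))``. Singular
    covariances get a small logged diagonal regularizer.
    """
    a = np.asarray(emb_a, dtype=np.float64)
    b = np.asarray(emb_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per side")
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    s_a = np.atleast_2d(np.cov(a, rowvar=False))
    s_b = np.atleast_2d(np.cov(b, rowvar=False))
    diff = mu_a - mu_b
    covmean = np.asarray(linalg.sqrtm(s_a @ s_b))
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    if not np.isfinite(covmean).all():
        log.warning("singular covariance product; regularizing with %g * I", eps)
        off = eps * np.eye(s_a.shape[0])
        covmean = np.asarray(linalg.sqrtm((s_a + off) @ (s_b + off))).real
    fid = diff @ diff + np.trace(s_a) + np.trace(s_b) - 2.0 * np.trace(covmean)
    return float(max(fid, 0.0))


# ---------------------------------------------------------------------------
# nucleus detection + morphometry
# ---------------------------------------------------------------------------

def detect_nuclei(img: np.ndarray, min_area: int = 6, max_area: int | None = None,
                  smooth_sigma: float = 1.0, split_touching: bool = True):
    """Detect nuclei in an RGB patch with a classical pipeline.

    Colour deconvolution (fixed H&E matrix) -> hematoxylin channel ->
    Gaussian smoothing -> Otsu threshold -> morphological opening ->
    connected components -> size filter -> optional distance-transform
    watershed split of touching blobs. Returns a list of boolean masks.
    """
    img = np.asarray(img)
    if img.dtype != np.uint8:
        img = np.clip((_to_unit(img) * 255), 0, 255).astype(np.uint8)
    if max_area is None:
        max_area = img.shape[0] * img.shape[1] // 4
    hema = rgb2hed(img)[..., 0]
    hema = gaussian(hema, sigma=smooth_sigma)
    lo, hi = hema.min(), hema.max()
    if hi - lo < 1e-3:  # blank/flat image
        return []
    thr = threshold_otsu(hema)
    # guard against Otsu splitting pure background texture: require real contrast
    fg = hema > max(thr, lo + 0.25 * (hi - lo))
    fg = opening(fg, disk(1))
    if not fg.any():
        return []
    lab = cc_label(fg)
    if split_touching:
        # split only components well above the median size: merged blobs,
        # not ordinary single nuclei
        areas = np.bincount(lab.ravel())[1:]
        median_area = np.median(areas[areas >= min_area]) if (areas >= min_area).any() else 0
        next_label = lab.max() + 1
        for r in regionprops(lab):
            if median_area and r.area > 1.8 * median_area:
                sub = np.zeros_like(fg)
                sub[r.slice] = r.image
                dist = ndi.distance_transform_edt(sub)
                peaks = _local_peaks(dist, min_distance=3)
                if peaks.sum() > 1:
                    markers = cc_label(peaks)
                    split = watershed(-dist, markers=markers, mask=sub)
                    lab[sub] = split[sub] + next_label
                    next_label += int(split.max()) + 1
    masks = []
    for r in regionprops(lab):
        if min_area <= r.area <= max_area:
            masks.append(lab == r.label)
    return masks


def _local_peaks(dist: np.ndarray, min_distance: int = 3) -> np.ndarray:
    """Boolean map of local maxima of the distance transform."""
    mx = ndi.maximum_filter(dist, size=2 * min_distance + 1)
    return (dist == mx) & (dist > 1.0)


def _intensity_stats(vals: np.ndarray) -> list[float]:
    """mean, std, min, max, median, p10, p90, skewness, excess kurtosis."""
    mu = vals.mean()
    d = vals - mu
    m2 = np.mean(d * d)
    sd = np.sqrt(m2)
    p10, med, p90 = np.quantile(vals, (0.1, 0.5, 0.9))
    if m2 > 1e-12 and vals.size > 3:
        skew = np.mean(d ** 3) / m2 ** 1.5
        kurt = np.mean(d ** 4) / (m2 * m2) - 3.0
    else:
        skew = kurt = 0.0
    return [mu, sd, vals.min(), vals.max(), med, p10, p90, skew, kurt]


def morph_features(img: np.ndarray, masks=None):
    """63-feature nuclear morphometry vector, averaged over detected nuclei.

    Nine shape descriptors plus 9 statistics of 6 intensity channels (R, G,
    B, hematoxylin, eosin, optical density) over each nucleus' pixels,
    averaged across nuclei. Returns ``(vector, n_nuclei)``; with no detected
    nucleus the vector is ``None`` (flagged patch, excluded from distances).
    """
    img = np.asarray(img)
    if masks is None:
        masks = detect_nuclei(img)
    if len(masks) == 0:
        return None, 0
    # single label image so regionprops works per-bbox, not per-full-frame
    lab = np.zeros(img.shape[:2], dtype=np.int32)
    for i, mask in enumerate(masks):
        lab[mask] = i + 1
    unit = _to_unit(img)
    hed = rgb2hed(np.clip(unit * 255, 0, 255).astype(np.uint8))
    od = -np.log10(np.maximum(unit.mean(axis=2), 1e-3))
    channels = [unit[..., 0], unit[..., 1], unit[..., 2],
                hed[..., 0], hed[..., 1], od]
    per_nucleus = []
    for props in regionprops(lab):
        perim = props.perimeter if props.perimeter > 0 else 1.0
        shape_feats = [
            props.area, props.perimeter, props.equivalent_diameter_area,
            props.axis_major_length, props.axis_minor_length,
            props.eccentricity, props.solidity, props.extent,
            4.0 * np.pi * props.area / perim ** 2,
        ]
        sl, inner = props.slice, props.image
        inten_feats = []
        for ch in channels:
            vals = ch[sl][inner]
            inten_feats.extend(_intensity_stats(vals))
        per_nucleus.append(np.array(shape_feats + inten_feats, dtype=np.float64))
    vec = np.mean(per_nucleus, axis=0)
    vec = np.nan_to_num(vec, nan=0.0, posinf=0.0, neginf=0.0)
    assert vec.shape == (N_MORPH_FEATURES,)
    return vec, len(masks)


def morph_feature_matrix(images: np.ndarray, crop: int | None = None):
    """Morphometry for a stack of patches.

    Returns ``(features (n, 63) with NaN rows for flagged patches,
    n_nuclei (n,))``.
    """
    n = len(images)
    feats = np.full((n, N_MORPH_FEATURES), np.nan)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        img = images[i]
        if crop is not None:
            img = center_crop(img, crop)
        v, k = morph_features(img)
        counts[i] = k
        if v is not None:
            feats[i] = v
    return feats, counts


@dataclass
class MorphScaler:
    """Per-feature standard deviations fitted on a real reference set."""

    scale: np.ndarray

    @classmethod
    def fit(cls, reference: np.ndarray) -> "MorphScaler":
        ref = np.asarray(reference, dtype=np.float64)
        ref = ref[~np.isnan(ref).any(axis=1)]
        if len(ref) < 2:
            raise ValueError("need >= 2 reference feature vectors")
        sd = ref.std(axis=0)
        return cls(scale=np.where(sd > 0, sd, 1.0))


def morph_distance(f1: np.ndarray, f2: np.ndarray, scaler: MorphScaler) -> float:
    """Euclidean distance between per-feature standardized morphometry vectors."""
    d = (np.asarray(f1, dtype=np.float64) - np.asarray(f2, dtype=np.float64)) / scaler.scale
    return float(np.sqrt((d * d).sum()))


def paired_morph_test(real_feats: np.ndarray, synth_feats: np.ndarray,
                      wsi_ids, n_random: int = 100, seed: int = 0,
                      scaler: MorphScaler | None = None):
    """Matched vs within-WSI baseline morphometry distances, Wilcoxon one-sided.

    For each real patch: the distance to its own synthetic counterpart is
    compared with the mean distance to ``n_random`` other real patches of the
    same WSI (without replacement when the pool allows, else with; logged).
    Returns ``(mean_matched, mean_baseline, p_value)`` for the one-sided
    Wilcoxon signed-rank alternative "matched < baseline".
    """
    real_feats = np.asarray(real_feats, dtype=np.float64)
    synth_feats = np.asarray(synth_feats, dtype=np.float64)
    wsi_ids = np.asarray(wsi_ids)
    ok = ~(np.isnan(real_feats).any(axis=1) | np.isnan(synth_feats).any(axis=1))
    n_flagged = int((~ok).sum())
    if n_flagged:
        log.info("paired_morph_test: excluding %d flagged pair(s)", n_flagged)
    real_feats, synth_feats, wsi_ids = real_feats[ok], synth_feats[ok], wsi_ids[ok]
    n = len(real_feats)
    if n < 10:
        raise ValueError(f"need >= 10 usable pairs, have {n}")
    if scaler is None:
        scaler = MorphScaler.fit(real_feats)
    rng = np.random.default_rng(seed)
    rf = real_feats / scaler.scale
    sf = synth_feats / scaler.scale
    d_matched = np.sqrt(((rf - sf) ** 2).sum(axis=1))
    d_base = np.zeros(n)
    for i in range(n):
        pool = np.flatnonzero((wsi_ids == wsi_ids[i]) & (np.arange(n) != i))
        if len(pool) == 0:
            raise ValueError(f"no same-WSI pool for patch {i}")
        replace = len(pool) < n_random
        if replace:
            log.info("pool of %d < n_random=%d; sampling with replacement",
                     len(pool), n_random)
        sel = rng.choice(pool, size=n_random, replace=replace)
        d_base[i] = np.sqrt(((rf[sel] - rf[i]) ** 2).sum(axis=1)).mean()
    diffs = d_matched - d_base
    if np.all(diffs == 0):
        warnings.warn("all paired distances tied; p = 1")
        return float(d_matched.mean()), float(d_base.mean()), 1.0
    res = stats.wilcoxon(d_matched, d_base, alternative="less")
    return float(d_matched.mean()), float(d_base.mean()), float(res.pvalue)


# ---------------------------------------------------------------------------
# prediction metrics
# ---------------------------------------------------------------------------

def prediction_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                       marker_names=None) -> dict:
    """Per-marker Pearson/Spearman correlations between true and predicted.

    Constant columns give undefined correlations; they are recorded as NaN
    and excluded from the means (count reported).
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted matrices must have equal shape")
    if y_true.shape[0] < 3:
        raise ValueError("need at least 3 spots")
    m = y_true.shape[1]
    pearson = np.full(m, np.nan)
    pearson_p = np.full(m, np.nan)
    spearman = np.full(m, np.nan)
    spearman_p = np.full(m, np.nan)
    for j in range(m):
        if np.std(y_true[:, j]) == 0 or np.std(y_pred[:, j]) == 0:
            continue
        pearson[j], pearson_p[j] = stats.pearsonr(y_true[:, j], y_pred[:, j])
        spearman[j], spearman_p[j] = stats.spearmanr(y_true[:, j], y_pred[:, j])
    valid = ~np.isnan(pearson)
    return {
        "pearson": pearson, "pearson_p": pearson_p,
        "spearman": spearman, "spearman_p": spearman_p,
        "mean_pearson": float(np.nanmean(pearson)) if valid.any() else float("nan"),
        "std_pearson": float(np.nanstd(pearson)) if valid.any() else float("nan"),
        "mean_spearman": float(np.nanmean(spearman)) if valid.any() else float("nan"),
        "n_undefined": int((~valid).sum()),
        "marker_names": list(marker_names) if marker_names is not None else None,
    }


# ---------------------------------------------------------------------------
# prediction-only baseline CNN
# ---------------------------------------------------------------------------

class BaselineRegressor:
    """Prediction-only residual CNN mapping patches to expression vectors.

    A generic size-configurable residual down-sampling network trained with
    mean squared error — deliberately *not* the adversarial discriminator —
    serving as the prediction-only comparison under the same CV protocol.
    """

    def __init__(self, patch_size_px: int, n_markers: int, seed: int = 0,
                 base_width: int = 64, min_width: int = 8):
        from .model import ArchDescriptor, DiscriminatorParams

        arch = ArchDescriptor(patch_size_px=patch_size_px, n_markers=n_markers,
                              base_width=base_width, min_width=min_width,
                              attention=False)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBA5E]))
        self._net = DiscriminatorParams(arch, rng)
        self.arch = arch

    def fit(self, images: np.ndarray, expression: np.ndarray,
            steps: int = 500, batch_size: int = 16, lr: float = 1e-4,
            seed: int = 0) -> list[float]:
        """Minimize MSE over (patch, expression) pairs; returns the loss trace."""
        from .train import _mse_t

        imgs = images_to_float(images) if images.dtype == np.uint8 else images
        expr = np.asarray(expression, dtype=np.float32)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF17]))
        opt = nn.Adam(self._net.parameters(), lr=lr, beta1=0.5)
        n = len(imgs)
        losses = []
        done = 0
        while done < steps:
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                if len(idx) < 2:
                    continue
                _, pred = self._net.forward(nn.Tensor(imgs[idx]))
                loss = _mse_t(pred, nn.Tensor(expr[idx]))
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(loss.item())
                done += 1
                if done >= steps:
                    break
        return losses

    def predict(self, images: np.ndarray, batch: int = 32) -> np.ndarray:
        imgs = images_to_float(images) if images.dtype == np.uint8 else images
        out = []
        with nn.no_grad():
            for i in range(0, len(imgs), batch):
                _, pred = self._net.forward(nn.Tensor(imgs[i:i + batch]))
                out.append(pred.data)
        return np.concatenate(out, axis=0)
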