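"""Spot-level preprocessing: grid geometry, expression transform, batch correction.

The expression transform log-transforms non-zero counts and z-scores them
per marker; zero counts are mapped through the same affine map after
substituting a pseudo-count 1000x smaller than the marker's smallest
observed positive value, so zeros land strictly below every positive
expression value and remain a separate "not expressed" category.

Batch (patient) harmonisation is a self-contained parametric empirical-Bayes
location/scale adjustment: per-marker standardisation against the pooled
data, per-batch additive and multiplicative effect estimates, shrinkage of
those estimates toward batch-level priors, and removal.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

#: transformed value assigned to markers that are zero in every spot
ALL_ZERO_FLOOR = -10.0


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpotGeometry:
    """Pixel geometry of one spot and its centred context patch.

    Bounds are half-open ``(y0, x0, h, w)`` in 0-based, row-major pixel
    coordinates. The spot is always centred within its patch.
    """

    row: int
    col: int
    spot_bounds: tuple[int, int, int, int]
    patch_bounds: tuple[int, int, int, int]
    clamped: bool = False


def grid_partition(wsi_width: int, wsi_height: int, spot_size: int,
                   patch_size: int, border: str = "drop") -> list[SpotGeometry]:
    """Partition a WSI into non-overlapping spot tiles with context patches.

    Spots tile the largest inscribed grid of ``spot_size`` squares; each
    context patch is the spot expanded by ``(patch_size - spot_size) / 2``
    on every side. Spots whose patch exits the image are dropped
    (``border="drop"``, default) or have their patch clamped to the image
    (``border="clamp"``).
    """
    if spot_size % 2 or patch_size % 2:
        raise ValueError("spot_size and patch_size must be even")
    if patch_size < spot_size:
        raise ValueError("patch_size must be >= spot_size")
    if border not in ("drop", "clamp"):
        raise ValueError("border must be 'drop' or 'clamp'")
    n_rows = wsi_height // spot_size
    n_cols = wsi_width // spot_size
    if n_rows == 0 or n_cols == 0 or wsi_height < patch_size or wsi_width < patch_size:
        if border == "drop" or n_rows == 0 or n_cols == 0:
            warnings.warn("WSI smaller than one patch; no spots produced")
            if n_rows == 0 or n_cols == 0:
                return []
    margin = (patch_size - spot_size) // 2
    out: list[SpotGeometry] = []
    for r in range(n_rows):
        for c in range(n_cols):
            sy, sx = r * spot_size, c * spot_size
            py, px = sy - margin, sx - margin
            inside = (py >= 0 and px >= 0 and py + patch_size <= wsi_height
                      and px + patch_size <= wsi_width)
            if inside:
                out.append(SpotGeometry(r, c, (sy, sx, spot_size, spot_size),
                                        (py, px, patch_size, patch_size)))
            elif border == "clamp":
                cy = min(max(py, 0), wsi_height - patch_size)
                cx = min(max(px, 0), wsi_width - patch_size)
                out.append(SpotGeometry(r, c, (sy, sx, spot_size, spot_size),
                                        (cy, cx, patch_size, patch_size),
                                        clamped=True))
    return out


def aggregate_spot(cell_counts: np.ndarray, n_markers: int | None = None) -> np.ndarray:
    """Mean per-marker expression over the cells of one spot.

    ``cell_counts`` is an ``(n_cells, n_markers)`` array. An empty spot
    yields an all-zero vector (logged); pass ``n_markers`` so the width is
    known in that case.
    """
    cell_counts = np.asarray(cell_counts, dtype=np.float64)
    if cell_counts.size == 0:
        if n_markers is None:
            if cell_counts.ndim == 2:
                n_markers = cell_counts.shape[1]
            else:
                raise ValueError("empty spot: n_markers must be given")
        log.warning("aggregate_spot: empty spot, returning all-zero vector")
        return np.zeros(n_markers)
    return cell_counts.mean(axis=0)


# ---------------------------------------------------------------------------
# expression transform
# ---------------------------------------------------------------------------

@dataclass
class TransformState:
    """Fitted per-marker statistics of the log-z expression transform."""

    mu: np.ndarray
    sigma: np.ndarray
    min_positive: np.ndarray
    sentinel_factor: float = 1000.0
    marker_names: tuple[str, ...] | None = None

    def to_json(self, path) -> None:
        obj = {
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "min_positive": [None if not np.isfinite(v) else v
                             for v in self.min_positive],
            "sentinel_factor": self.sentinel_factor,
            "marker_names": list(self.marker_names) if self.marker_names else None,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TransformState":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            mu=np.asarray(obj["mu"], dtype=np.float64),
            sigma=np.asarray(obj["sigma"], dtype=np.float64),
            min_positive=np.asarray(
                [np.nan if v is None else v for v in obj["min_positive"]],
                dtype=np.float64),
            sentinel_factor=obj["sentinel_factor"],
            marker_names=tuple(obj["marker_names"]) if obj["marker_names"] else None,
        )


def fit_transform_expression(raw: np.ndarray, marker_names=None,
                             sentinel_factor: float = 1000.0):
    """Fit and apply the per-marker log-z transform with zero sentinels.

    Returns ``(transformed, state)``. Per marker, positive entries map to
    ``(log x - mu) / sigma`` with the statistics taken over that marker's
    positive log values; zeros map through the same affine map after
    substituting ``min_positive / sentinel_factor``, guaranteeing they fall
    strictly below every transformed positive value.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 2:
        raise ValueError("raw must be a (spots, markers) matrix")
    if (raw < 0).any():
        raise ValueError("raw expression must be non-negative")
    n, m = raw.shape
    mu = np.zeros(m)
    sigma = np.ones(m)
    min_pos = np.full(m, np.nan)
    for j in range(m):
        pos = raw[:, j][raw[:, j] > 0]
        if pos.size == 0:
            name = marker_names[j] if marker_names else j
            log.warning("marker %s is zero everywhere; transformed to floor %.1f",
                        name, ALL_ZERO_FLOOR)
            continue
        lv = np.log(pos)
        mu[j] = lv.mean()
        s = lv.std()
        if s == 0.0:
            name = marker_names[j] if marker_names else j
            log.warning("marker %s has a single distinct positive value; "
                        "sigma fallback to 1", name)
            s = 1.0
        sigma[j] = s
        min_pos[j] = pos.min()
    state = TransformState(mu=mu, sigma=sigma, min_positive=min_pos,
                           sentinel_factor=sentinel_factor,
                           marker_names=tuple(marker_names) if marker_names else None)
    return apply_transform(raw, state), state


def apply_transform(raw: np.ndarray, state: TransformState,
                    marker_names=None) -> np.ndarray:
    """Apply a fitted :class:`TransformState` to a raw count matrix."""
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 2 or raw.shape[1] != len(state.mu):
        raise ValueError(
            f"raw matrix width {raw.shape[-1]} does not match fitted state "
            f"({len(state.mu)} markers)")
    if marker_names is not None and state.marker_names is not None:
        if tuple(marker_names) != tuple(state.marker_names):
            raise ValueError("marker name mismatch between data and TransformState")
    out = np.empty_like(raw)
    for j in range(raw.shape[1]):
        col = raw[:, j]
        if not np.isfinite(state.min_positive[j]):
            out[:, j] = np.where(col > 0,
                                 (np.log(np.maximum(col, 1e-300)) - state.mu[j]) / state.sigma[j],
                                 ALL_ZERO_FLOOR)
            continue
        sentinel_raw = state.min_positive[j] / state.sentinel_factor
        vals = np.where(col > 0, col, sentinel_raw)
        out[:, j] = (np.log(vals) - state.mu[j]) / state.sigma[j]
    return out


# ---------------------------------------------------------------------------
# batch correction
# ---------------------------------------------------------------------------

def _eb_priors(gamma_hat: np.ndarray, delta_hat: np.ndarray):
    """Method-of-moments hyperpriors for one batch across markers."""
    gbar = gamma_hat.mean()
    t2 = gamma_hat.var()
    dmean = delta_hat.mean()
    dvar = delta_hat.var()
    if dvar <= 0:
        aprior, bprior = 2.0, dmean  # flat-ish prior when no spread
    else:
        aprior = (2 * dvar + dmean ** 2) / dvar
        bprior = (dmean * dvar + dmean ** 3) / dvar
    return gbar, t2, aprior, bprior


def _eb_iterate(z: np.ndarray, gamma_hat, delta_hat, gbar, t2, aprior, bprior,
                shrink_location: bool = True,
                conv: float = 1e-4, max_iter: int = 200):
    """Parametric empirical-Bayes iteration for one batch.

    ``z`` is the standardized (n_batch, m) data of the batch. Returns
    (gamma_star, delta_star): the location and scale effects with the scale
    (and optionally the location) shrunk toward the cross-marker priors.
    """
    n = z.shape[0]
    g_new = gamma_hat.copy()
    d_new = delta_hat.copy()
    for _ in range(max_iter):
        g_old, d_old = g_new, d_new
        if not shrink_location:
            g_new = gamma_hat
        elif t2 > 0:
            g_new = (n * t2 * gamma_hat + d_old * gbar) / (n * t2 + d_old)
        else:
            g_new = np.full_like(gamma_hat, gbar)
        sse = ((z - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sse + bprior) / (n / 2.0 + aprior - 1.0)
        d_new = np.maximum(d_new, 1e-8)
        change = max(np.abs(g_new - g_old).max(), np.abs(d_new - d_old).max())
        if change < conv:
            break
    return g_new, d_new


@dataclass
class BatchCorrector:
    """Empirical-Bayes location/scale batch-effect removal (fit/apply split).

    ``fit`` estimates the pooled reference location and scale on training
    batches; ``apply`` standardizes new data against that reference,
    estimates the batch effects of the (possibly unseen) batches present in
    the new data with the same EB shrinkage, and removes them. This keeps
    held-out patients from influencing the reference frame in
    cross-validation.

    Location effects are removed unshrunk by default so per-batch means
    align exactly after correction; scale effects, which are estimated with
    more noise, get the parametric EB shrinkage toward the cross-marker
    prior. Set ``shrink_location=True`` for shrinkage on both.
    """

    stand_mean: np.ndarray | None = None
    var_pooled: np.ndarray | None = None
    shrink: bool = True
    shrink_location: bool = False

    def fit(self, X: np.ndarray, batches) -> "BatchCorrector":
        X = np.asarray(X, dtype=np.float64)
        batches = np.asarray(batches)
        ids = _batch_ids(batches)
        if len(ids) < 1:
            raise ValueError("at least one batch required")
        nb = np.array([np.sum(batches == b) for b in ids], dtype=float)
        if (nb < 2).any():
            raise ValueError("every batch needs at least 2 spots")
        # reference location: sample-size weighted batch means; pooled
        # variance is the within-batch residual variance (batch means removed)
        bm = np.stack([X[batches == b].mean(axis=0) for b in ids])
        self.stand_mean = (nb[:, None] * bm).sum(axis=0) / nb.sum()
        resid = X - bm[[ids.index(b) for b in batches]]
        self.var_pooled = (resid ** 2).mean(axis=0)
        self.var_pooled = np.maximum(self.var_pooled, 1e-12)
        return self

    def apply(self, X: np.ndarray, batches) -> np.ndarray:
        if self.stand_mean is None:
            raise RuntimeError("BatchCorrector must be fitted first")
        X = np.asarray(X, dtype=np.float64)
        batches = np.asarray(batches)
        ids = _batch_ids(batches)
        sd = np.sqrt(self.var_pooled)
        Z = (X - self.stand_mean) / sd
        out = np.empty_like(Z)
        for b in ids:
            sel = batches == b
            zb = Z[sel]
            if zb.shape[0] < 2:
                warnings.warn(f"batch {b!r} has <2 spots; passed through uncorrected")
                out[sel] = zb
                continue
            gamma_hat = zb.mean(axis=0)
            delta_hat = zb.var(axis=0, ddof=1)
            flat = delta_hat <= 0
            if flat.any():
                warnings.warn(f"batch {b!r}: zero variance for "
                              f"{int(flat.sum())} marker(s); scale fallback to 1")
                delta_hat = np.where(flat, 1.0, delta_hat)
            if self.shrink and zb.shape[1] >= 2:
                gbar, t2, ap, bp = _eb_priors(gamma_hat, delta_hat)
                g_star, d_star = _eb_iterate(zb, gamma_hat, delta_hat,
                                             gbar, t2, ap, bp,
                                             shrink_location=self.shrink_location)
                d_star = np.where(flat, 1.0, d_star)
            else:
                g_star, d_star = gamma_hat, delta_hat
            out[sel] = (zb - g_star[None, :]) / np.sqrt(d_star)[None, :]
        return out * sd + self.stand_mean

    def fit_apply(self, X: np.ndarray, batches) -> np.ndarray:
        return self.fit(X, batches).apply(X, batches)


def _batch_ids(batches):
    seen: dict = {}
    for b in batches:
        seen.setdefault(b, None)
    return list(seen)


def correct_batches(X: np.ndarray, batches) -> np.ndarray:
    """Remove per-batch location/scale effects from a transformed matrix.

    A single batch is returned unchanged (nothing to correct). Otherwise the
    parametric empirical-Bayes adjustment described in the module docstring
    is fitted and applied; the per-marker grand mean is preserved.
    """
    X = np.asarray(X, dtype=np.float64)
    batches = np.asarray(batches)
    if len(batches) != len(X):
        raise ValueError("one batch label per spot required")
    if len(_batch_ids(batches)) == 1:
        return X.copy()
    out = BatchCorrector().fit_apply(X, batches)
    # exact restoration of the per-marker grand mean (shrinkage leaves a
    # negligible residue otherwise)
    return out - out.mean(axis=0) + X.mean(axis=0)
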