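"""Expression interpolation/perturbation and CCA + mixture subspace alignment.

Interpolation walks a straight line in transformed expression space between
two spots and generates a patch at every step with the noise vector held
fixed, so image changes reflect expression changes alone. The alignment
analysis projects the expression space and the morphology space of the
*generated* patches onto paired 2-D canonical axes, clusters the morphology
projection with a Gaussian mixture, and quantifies concordance as the
adjusted Rand index against an independent mixture fit on the expression
projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

from .evaluate import detect_nuclei
from .model import GeneratorParams, generate

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# interpolation / perturbation
# ---------------------------------------------------------------------------

def interpolate(p_a: np.ndarray, p_b: np.ndarray, steps: int = 10) -> np.ndarray:
    """Linear interpolation including both endpoints.

    Returns ``steps`` vectors ``v_i = (1 - t_i) p_a + t_i p_b`` with
    ``t_i = i / (steps - 1)``.
    """
    p_a = np.asarray(p_a, dtype=np.float64)
    p_b = np.asarray(p_b, dtype=np.float64)
    if p_a.shape != p_b.shape:
        raise ValueError("endpoints must have equal length")
    if steps < 2:
        raise ValueError("steps must be >= 2")
    t = np.linspace(0.0, 1.0, steps)
    return (1.0 - t)[:, None] * p_a[None, :] + t[:, None] * p_b[None, :]


def perturb(p: np.ndarray, marker: str, delta: float, marker_names) -> np.ndarray:
    """Shift one marker by ``delta`` in transformed space; others unchanged."""
    marker_names = list(marker_names)
    if marker not in marker_names:
        raise ValueError(f"marker {marker!r} not in panel")
    out = np.array(p, dtype=np.float64, copy=True)
    out[marker_names.index(marker)] += delta
    return out


@dataclass
class InterpolationResult:
    """Vectors, generated patches and per-step morphology of one interpolation."""

    vectors: np.ndarray          # (steps, m)
    patches: np.ndarray          # (steps, P, P, 3) float in [-1, 1]
    nucleus_counts: np.ndarray   # (steps,) detected nuclei per patch
    mean_areas: np.ndarray       # (steps,) mean detected nucleus area (NaN if none)


def run_interpolation_experiment(generator: GeneratorParams,
                                 p_a: np.ndarray, p_b: np.ndarray,
                                 steps: int = 10, seed: int = 0,
                                 fixed_z: bool = True) -> InterpolationResult:
    """Generate patches along an expression interpolation path.

    The noise vector is drawn once from the seed and reused at every step by
    default (``fixed_z=True``); per-step morphology is summarized by the
    detected nucleus count and mean nucleus area.
    """
    vectors = interpolate(p_a, p_b, steps)
    rng = np.random.default_rng(seed)
    if fixed_z:
        z = np.tile(rng.standard_normal(generator.arch.noise_dim), (steps, 1))
    else:
        z = rng.standard_normal((steps, generator.arch.noise_dim))
    patches = generate(generator, vectors.astype(np.float32), z.astype(np.float32))
    counts = np.zeros(steps, dtype=int)
    areas = np.full(steps, np.nan)
    for i in range(steps):
        masks = detect_nuclei(patches[i])
        counts[i] = len(masks)
        if masks:
            areas[i] = float(np.mean([m.sum() for m in masks]))
    return InterpolationResult(vectors=vectors, patches=patches,
                               nucleus_counts=counts, mean_areas=areas)


# ---------------------------------------------------------------------------
# CCA + mixture alignment
# ---------------------------------------------------------------------------

def cca_project(X: np.ndarray, Y: np.ndarray, dims: int = 2,
                reg: float = 1e-3):
    """Regularized canonical correlation analysis between two views.

    Columns are standardized internally; within-view covariances get a ridge
    ``reg * I`` to stabilize near-singular problems. Returns
    ``(psi, phi, correlations)`` where ``psi``/``phi`` are the (n, dims)
    projections of X and Y onto paired canonical directions and
    ``correlations`` are the canonical correlations (non-increasing, in
    [0, 1]).
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("X and Y must have one row per spot, aligned")
    if n <= dims:
        raise ValueError(f"need more than dims={dims} spots, have {n}")

    def _standardize(A):
        mu = A.mean(axis=0)
        sd = A.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return (A - mu) / sd

    Xs, Ys = _standardize(X), _standardize(Y)
    cxx = Xs.T @ Xs / n + reg * np.eye(Xs.shape[1])
    cyy = Ys.T @ Ys / n + reg * np.eye(Ys.shape[1])
    cxy = Xs.T @ Ys / n
    # whiten each view, then SVD of the cross-covariance
    ix = _inv_sqrt_psd(cxx)
    iy = _inv_sqrt_psd(cyy)
    k = ix @ cxy @ iy
    u, s, vt = np.linalg.svd(k)
    corrs = np.clip(s[:dims], 0.0, 1.0)
    wx = ix @ u[:, :dims]
    wy = iy @ vt.T[:, :dims]
    return Xs @ wx, Ys @ wy, corrs


def _inv_sqrt_psd(a: np.ndarray) -> np.ndarray:
    vals, vecs = linalg.eigh(a)
    vals = np.maximum(vals, 1e-12)
    return vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T


def gmm_cluster(phi: np.ndarray, k: int = 8, seed: int = 0,
                max_retries: int = 3) -> np.ndarray:
    """Hard labels from a k-component full-covariance Gaussian mixture (EM).

    Seeded k-means++-style initialization makes the labels deterministic for
    a given seed; a degenerate/unconverged fit triggers a bounded number of
    re-seeded restarts (logged).
    """
    phi = np.asarray(phi, dtype=np.float64)
    if len(phi) < k:
        raise ValueError(f"need at least k={k} points, have {len(phi)}")
    for attempt in range(max_retries + 1):
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             random_state=seed + attempt, n_init=1,
                             init_params="k-means++", reg_covar=1e-6)
        labels = gm.fit_predict(phi)
        if gm.converged_ or attempt == max_retries:
            if not gm.converged_:
                log.warning("GMM did not converge after %d restarts", max_retries)
            elif attempt > 0:
                log.info("GMM converged after %d restart(s)", attempt)
            return labels
    raise AssertionError("unreachable")


def alignment_concordance(psi: np.ndarray, phi_labels: np.ndarray,
                          k: int, seed: int = 0) -> float:
    """Adjusted Rand index between mixture clusterings of the two projections.

    Fits an independent k-component mixture on the expression projection
    ``psi`` and scores its labels against the supplied morphology-space
    labels. 1 means identical partitions, approximately 0 means chance-level
    agreement.
    """
    psi = np.asarray(psi, dtype=np.float64)
    phi_labels = np.asarray(phi_labels)
    if len(psi) != len(phi_labels):
        raise ValueError("psi and phi_labels must be aligned one-to-one")
    psi_labels = gmm_cluster(psi, k=k, seed=seed)
    return float(adjusted_rand_score(phi_labels, psi_labels))


@dataclass
class AlignmentResult:
    """Paired 2-D projections, canonical correlations and concordance."""

    psi: np.ndarray
    phi: np.ndarray
    correlations: np.ndarray
    labels: np.ndarray
    concordance: float


def run_alignment(expression: np.ndarray, morphology: np.ndarray,
                  dims: int = 2, k: int = 8, seed: int = 0,
                  reg: float = 1e-3) -> AlignmentResult:
    """CCA projection + mixture clustering + concordance in one call.

    Rows of ``morphology`` containing NaN (patches without detected nuclei)
    are dropped from both views to keep the one-to-one correspondence.
    """
    expression = np.asarray(expression, dtype=np.float64)
    morphology = np.asarray(morphology, dtype=np.float64)
    ok = ~np.isnan(morphology).any(axis=1)
    if (~ok).any():
        log.info("alignment: dropping %d flagged spot(s)", int((~ok).sum()))
    psi, phi, corrs = cca_project(expression[ok], morphology[ok], dims=dims, reg=reg)
    labels = gmm_cluster(phi, k=k, seed=seed)
    score = alignment_concordance(psi, labels, k=k, seed=seed)
    return AlignmentResult(psi=psi, phi=phi, correlations=corrs,
                           labels=labels, concordance=score)
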