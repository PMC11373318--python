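"""Synthetic multi-patient cohorts: Hyperion-like counts paired with H&E-like patches.

The simulator provides a fully specified forward model so the whole
generative-predictive pipeline can be exercised and validated without real
tissue data. Four designated "driver" markers causally control the rendered
morphology of each patch:

* ``density`` — number of nuclei drawn in the patch,
* ``size`` — mean nuclear radius,
* ``hema`` — nuclear darkness (hematoxylin-like blue-purple),
* ``eos`` — background pink intensity (eosin-like stroma).

Per-spot driver values are standard normal; the remaining markers are fixed
linear mixtures of the drivers plus independent noise, giving realistic
marker correlation. Raw counts are overdispersed (gamma-Poisson) around
``exp(latent + patient_shift)``, so zeros occur naturally at low means and
each pseudo-patient carries a reproducible additive batch effect on the log
scale. Rendering uses fixed hematoxylin/eosin RGB anchors and per-nucleus
darkness/size jitter, so nuclear pixel statistics carry information about
all four drivers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import ellipse

from .config import ConfigError
from .data import SpotDataset
from .preprocess import aggregate_spot

log = logging.getLogger(__name__)

#: fixed rendering palette (RGB anchors)
HEMATOXYLIN_RGB = np.array([60.0, 35.0, 110.0])
EOSIN_RGB = np.array([238.0, 150.0, 180.0])

DRIVER_NAMES = ("density", "size", "hema", "eos")


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator."""

    n_patients: int = 4
    spots_per_patient: int = 400
    patch_size_px: int = 64
    n_markers: int = 38
    driver_map: dict = field(default_factory=lambda: {
        "density": 0, "size": 1, "hema": 2, "eos": 3})
    batch_shift_scale: float = 0.6
    count_dispersion: float = 0.5
    seed: int = 0
    # rendering knobs (defaults sized for 64 px patches)
    k_min: int = 5
    k_max: int = 28
    base_radius: float = 3.2

    def __post_init__(self):
        idx = [self.driver_map[k] for k in DRIVER_NAMES]
        if len(set(idx)) != 4 or any(i >= self.n_markers or i < 0 for i in idx):
            raise ConfigError("driver_map indices must be 4 distinct markers "
                              "within the panel")
        if self.spots_per_patient < 1:
            raise ConfigError("spots_per_patient must be >= 1")
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.batch_shift_scale < 0:
            raise ConfigError("batch_shift_scale must be >= 0")
        if self.count_dispersion <= 0:
            raise ConfigError("count_dispersion must be > 0")
        if self.patch_size_px < int(8 * self.base_radius):
            raise ConfigError("patch too small to place a nucleus: "
                              f"patch_size_px={self.patch_size_px}")

    @property
    def driver_indices(self) -> np.ndarray:
        return np.array([self.driver_map[k] for k in DRIVER_NAMES])


@dataclass
class CellRecord:
    """One simulated cell: centroid (x, y) in patch pixels + marker counts."""

    centroid: tuple[float, float]
    counts: np.ndarray | None = None


@dataclass
class SpotSample:
    """Latents and raw counts of one simulated spot."""

    drivers: np.ndarray       # (4,) standard-normal driver values
    log_means: np.ndarray     # (m,) per-marker latent log-mean incl. batch shift
    cell_counts: np.ndarray   # (n_cells, m) integer counts
    spot_counts: np.ndarray   # (m,) mean over cells


def _panel_constants(config: SimConfig):
    """Cohort-level constants fixed by the simulation seed.

    Returns (base log-means, marker<-driver mixing matrix, per-patient
    per-marker additive log shifts).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0F0]))
    m = config.n_markers
    base = rng.uniform(np.log(1.5), np.log(15.0), size=m)
    W = rng.normal(0.0, 0.5, size=(m, 4))
    for k, name in enumerate(DRIVER_NAMES):
        j = config.driver_map[name]
        W[j] = 0.0
        W[j, k] = 1.0
    shifts = rng.normal(0.0, 1.0, size=(config.n_patients, m)) * config.batch_shift_scale
    return base, W, shifts


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def n_nuclei(density: float, config: SimConfig) -> int:
    """Deterministic nucleus count from the density driver (logistic ramp)."""
    return int(round(config.k_min + _sigmoid(density) * (config.k_max - config.k_min)))


def sample_spot_expression(config: SimConfig, patient: int,
                           rng: np.random.Generator,
                           drivers: np.ndarray | None = None) -> SpotSample:
    """Draw one spot's latent drivers and batch-shifted raw cell counts.

    The number of cells equals the nucleus count implied by the density
    driver, so per-cell tables stay consistent with the rendered patch.
    """
    base, W, shifts = _panel_constants(config)
    if drivers is None:
        drivers = rng.standard_normal(4)
    drivers = np.asarray(drivers, dtype=np.float64)
    noise = rng.normal(0.0, 0.4, size=config.n_markers)
    noise[config.driver_indices] = 0.0  # driver markers are exact readouts
    log_mean = base + W @ drivers + noise + shifts[patient % config.n_patients]
    k_cells = n_nuclei(drivers[DRIVER_NAMES.index("density")], config)
    mu = np.exp(log_mean)
    disp = config.count_dispersion
    lam = rng.gamma(shape=1.0 / disp, scale=mu * disp, size=(k_cells, config.n_markers))
    cell_counts = rng.poisson(lam).astype(np.float64)
    return SpotSample(drivers=drivers, log_means=log_mean,
                      cell_counts=cell_counts,
                      spot_counts=aggregate_spot(cell_counts, config.n_markers))


def render_patch(drivers: np.ndarray, config: SimConfig,
                 rng: np.random.Generator,
                 cell_counts: np.ndarray | None = None):
    """Render an H&E-like RGB patch from the four driver values.

    Returns ``(image uint8 (P, P, 3), cells)`` where ``cells`` is the
    ground-truth :class:`CellRecord` list (counts attached when
    ``cell_counts`` is given).
    """
    drivers = np.asarray(drivers, dtype=np.float64)
    if drivers.shape[-1] == config.n_markers:
        drivers = drivers[config.driver_indices]
    if drivers.shape != (4,):
        raise ValueError("drivers must be the 4 driver values or a full panel vector")
    P = config.patch_size_px
    density, size, hema, eos = drivers

    # eosin background: white -> pink ramp plus smooth fibrillary texture
    w = 0.30 + 0.55 * _sigmoid(eos)
    bg = (1.0 - w) * 255.0 + w * EOSIN_RGB
    img = np.empty((P, P, 3), dtype=np.float64)
    img[:] = bg
    fib = ndi.gaussian_filter(rng.normal(0.0, 1.0, size=(P, P)), sigma=2.0)
    img += (fib * 14.0)[:, :, None]
    img += rng.normal(0.0, 4.0, size=(P, P, 3))

    # nuclei
    k = n_nuclei(density, config)
    r_mean = float(np.clip(config.base_radius * np.exp(0.25 * size), 1.5, P / 6.0))
    dk_patch = 0.35 + 0.55 * _sigmoid(hema)
    centers: list[tuple[float, float]] = []
    cells: list[CellRecord] = []
    min_d2 = (2.1 * r_mean) ** 2
    for i in range(k):
        for _attempt in range(40):
            cy = rng.uniform(r_mean, P - r_mean)
            cx = rng.uniform(r_mean, P - r_mean)
            if all((cy - y0) ** 2 + (cx - x0) ** 2 >= min_d2 for y0, x0 in centers):
                break
        centers.append((cy, cx))
        r = r_mean * rng.lognormal(0.0, 0.12)
        # crowding compresses nuclei: dense patches have more elongated,
        # spindle-like nuclei (independent of the size driver)
        u = rng.uniform(1.0, 1.4) + 0.45 * _sigmoid(density)
        angle = rng.uniform(0.0, np.pi)
        dk = float(np.clip(dk_patch + rng.normal(0.0, 0.07), 0.15, 1.0))
        color = (1.0 - dk) * 255.0 + dk * HEMATOXYLIN_RGB
        rr, cc = ellipse(cy, cx, r * u, r / u, shape=(P, P), rotation=angle)
        tex = rng.normal(0.0, 5.0, size=(rr.size, 3))
        img[rr, cc] = color + tex
        counts = None if cell_counts is None else np.asarray(cell_counts[i])
        cells.append(CellRecord(centroid=(float(cx), float(cy)), counts=counts))
    return np.clip(img, 0, 255).astype(np.uint8), cells


def simulate_cohort(config: SimConfig):
    """Simulate a full multi-patient cohort.

    Returns ``(dataset, cells_table)``: a :class:`SpotDataset` with raw
    spot-level mean counts, rendered patches, patient labels and the
    ground-truth driver latents, plus a per-cell pandas table
    (patient, spot, cell, x, y, one column per marker).
    """
    import pandas as pd

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_total = config.n_patients * config.spots_per_patient
    m = config.n_markers
    P = config.patch_size_px
    expression = np.zeros((n_total, m))
    latents = np.zeros((n_total, 4))
    images = np.zeros((n_total, P, P, 3), dtype=np.uint8)
    patients = np.empty(n_total, dtype=object)
    rows = []
    i = 0
    for pat in range(config.n_patients):
        pid = f"patient{pat}"
        for s in range(config.spots_per_patient):
            sample = sample_spot_expression(config, pat, rng)
            img, cells = render_patch(sample.drivers, config, rng,
                                      cell_counts=sample.cell_counts)
            expression[i] = sample.spot_counts
            latents[i] = sample.drivers
            images[i] = img
            patients[i] = pid
            for ci, cell in enumerate(cells):
                rows.append((pid, i, ci, cell.centroid[0], cell.centroid[1],
                             *cell.counts))
            i += 1
    marker_names = tuple(f"M{j:02d}" for j in range(m))
    # name driver markers by their role for readability
    names = list(marker_names)
    for role, j in config.driver_map.items():
        names[j] = f"DRV_{role}"
    cells_table = pd.DataFrame(
        rows, columns=["patient", "spot", "cell", "x", "y", *names])
    dataset = SpotDataset(expression=expression, images=images,
                          patients=patients, marker_names=tuple(names),
                          transformed=False, latents=latents)
    return dataset, cells_table
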