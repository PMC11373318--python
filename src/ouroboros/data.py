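"""In-memory containers for paired expression/image datasets.

An expression vector is a 1-D float array ordered by the marker panel; a
patch is an ``(H, W, 3)`` uint8 RGB array. A :class:`SpotDataset` holds the
paired collections W_j = {(p_ij, I_ij)} for every patient j, with the
patient id doubling as the batch label for harmonisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SpotDataset:
    """Paired spot-level expression vectors and image patches.

    Attributes
    ----------
    expression : (n_spots, n_markers) float array
        Raw mean counts or transformed values, per :attr:`transformed`.
    images : (n_spots, H, W, 3) uint8 array
    patients : (n_spots,) array of patient/batch identifiers
    marker_names : ordered marker panel
    transformed : whether ``expression`` is in transformed (log-z) space
    latents : optional (n_spots, k) simulator ground-truth driver values
    """

    expression: np.ndarray
    images: np.ndarray
    patients: np.ndarray
    marker_names: tuple[str, ...]
    transformed: bool = False
    latents: np.ndarray | None = None
    spot_ids: np.ndarray | None = None

    def __post_init__(self):
        self.expression = np.asarray(self.expression, dtype=np.float64)
        self.patients = np.asarray(self.patients)
        self.marker_names = tuple(self.marker_names)
        n = len(self.expression)
        if self.images is not None and len(self.images) != n:
            raise ValueError("expression and images must have equal length")
        if len(self.patients) != n:
            raise ValueError("patients must have one label per spot")
        if self.expression.shape[1] != len(self.marker_names):
            raise ValueError("expression width must match marker panel size")
        if self.spot_ids is None:
            self.spot_ids = np.arange(n)

    @property
    def n_spots(self) -> int:
        return len(self.expression)

    @property
    def patient_ids(self) -> list:
        seen: dict = {}
        for p in self.patients:
            seen.setdefault(p, None)
        return list(seen)

    def subset(self, mask) -> "SpotDataset":
        mask = np.asarray(mask)
        return SpotDataset(
            expression=self.expression[mask],
            images=self.images[mask] if self.images is not None else None,
            patients=self.patients[mask],
            marker_names=self.marker_names,
            transformed=self.transformed,
            latents=self.latents[mask] if self.latents is not None else None,
            spot_ids=self.spot_ids[mask],
        )

    def by_patient(self):
        """Yield (patient_id, SpotDataset) groups in first-seen order."""
        for pid in self.patient_ids:
            yield pid, self.subset(self.patients == pid)

    def with_expression(self, expression: np.ndarray, transformed: bool) -> "SpotDataset":
        out = SpotDataset(
            expression=expression,
            images=self.images,
            patients=self.patients,
            marker_names=self.marker_names,
            transformed=transformed,
            latents=self.latents,
            spot_ids=self.spot_ids,
        )
        return out


def images_to_float(images: np.ndarray) -> np.ndarray:
    """uint8 RGB -> float32 in [-1, 1]."""
    return (np.asarray(images, dtype=np.float32) / 127.5) - 1.0


def images_to_uint8(images: np.ndarray) -> np.ndarray:
    """float in [-1, 1] -> uint8 RGB."""
    x = (np.clip(images, -1.0, 1.0) + 1.0) * 127.5
    return np.round(x).astype(np.uint8)
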