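"""Plant/background segmentation by a normalized-difference index + Otsu.

VNIR cubes use the red-edge NDVI (RENDVI, bands nearest 750 and 705 nm);
SWIR cubes use a water-band index from the bands nearest 1141 and 1375 nm,
oriented so vegetation (high 1141 nm reflectance, strong 1375 nm water
absorption) scores positive.  The index image is thresholded with Otsu's
method; pixels above the threshold are plant.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .exceptions import DegenerateInputError, InvalidInputError
from .hsi_io import Hypercube

__all__ = ["PlantMask", "normalized_difference", "otsu_threshold", "segment_plant"]

# (index name, numerator wavelength a, denominator partner b) per sensor;
# the index is (R_a - R_b) / (R_a + R_b)
_SENSOR_INDEX = {
    "VNIR": ("RENDVI", 750.0, 705.0),
    "SWIR": ("SWIR-ND", 1141.0, 1375.0),
}


@dataclass
class PlantMask:
    """Binary plant mask with the index and threshold that produced it."""

    mask: np.ndarray  # rows x cols, bool; True = plant
    source_index: str
    threshold: float

    def iou(self, other: np.ndarray) -> float:
        """Intersection-over-union against another binary mask."""
        a, b = self.mask.astype(bool), np.asarray(other, dtype=bool)
        union = np.logical_or(a, b).sum()
        return float(np.logical_and(a, b).sum() / union) if union else 1.0

    def to_json_sidecar(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"source_index": self.source_index, "threshold": self.threshold}, fh
            )


def normalized_difference(
    cube: Hypercube, lam_a: float, lam_b: float
) -> np.ndarray:
    """Pixelwise ``(R_a - R_b) / (R_a + R_b)`` using the nearest bands.

    Pixels whose denominator is zero are flagged NaN (excluded from Otsu).
    """
    ia, ib = cube.band_index(lam_a), cube.band_index(lam_b)
    ra = cube.data[:, :, ia].astype(np.float64)
    rb = cube.data[:, :, ib].astype(np.float64)
    denom = ra + rb
    with np.errstate(divide="ignore", invalid="ignore"):
        index = (ra - rb) / denom
    index[denom == 0] = np.nan
    return index


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Threshold maximising between-class variance of the binned histogram."""
    v = np.asarray(values, dtype=np.float64).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2 or np.unique(v).size < 2:
        raise DegenerateInputError(
            "Otsu thresholding requires at least two distinct finite values"
        )
    return float(threshold_otsu(v, nbins=n_bins))


def segment_plant(cube: Hypercube, n_bins: int = 256) -> PlantMask:
    """Binary plant mask from the sensor-appropriate index + Otsu threshold.

    All-background scenes (near-constant index) raise
    :class:`DegenerateInputError`; callers may catch it and treat the scene as
    an empty mask.
    """
    if cube.sensor not in _SENSOR_INDEX:
        raise InvalidInputError(
            f"no segmentation index defined for sensor {cube.sensor!r}"
        )
    name, lam_a, lam_b = _SENSOR_INDEX[cube.sensor]
    index = normalized_difference(cube, lam_a, lam_b)
    if np.isnan(index).any():
        warnings.warn(
            f"{int(np.isnan(index).sum())} pixels with zero denominator "
            "excluded from Otsu",
            stacklevel=2,
        )
    thr = otsu_threshold(index, n_bins=n_bins)
    mask = np.where(np.isnan(index), False, index > thr)
    return PlantMask(mask, name, thr)
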