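"""Patch spectral library: quadrant tiling, extraction, splits, augmentation.

The classifier consumes fixed-size spatial windows ("patches", default
15 x 15 pixels through all bands) sampled from the plant canopy.  Each scene
is tiled into four quadrants and a fixed number of patches is drawn per
quadrant from the grid of non-overlapping positions whose plant-pixel
fraction meets a threshold; when the non-overlapping supply is too small the
caller may relax to overlapping positions (logged).

Splits follow the 3:1 train-test, then 80:20 train-validation convention,
stratified by treatment; rotation and flip augmentation enlarge the
training pool without touching held-out data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    InsufficientCanopyError,
    InvalidInputError,
    InvalidParameterError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PatchSet",
    "SplitSpec",
    "quadrant_split",
    "quadrant_split_array",
    "extract_patches",
    "split_dataset",
    "augment_rotate",
    "augment_flip",
]


@dataclass
class PatchSet:
    """Fixed-size labelled patches with provenance.

    ``data`` is (N, m, n, k) float32; ``labels`` is an (N,) array of
    treatment labels; ``provenance`` records one
    ``(scene_id, quadrant, row, col, note)`` tuple per patch.
    """

    data: np.ndarray
    labels: np.ndarray
    provenance: list = field(default_factory=list)
    wavelengths: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.labels = np.asarray(self.labels)
        if self.data.shape[0] != self.labels.shape[0]:
            raise InvalidInputError("labels length must match patch count")
        if not self.provenance:
            self.provenance = [("?", -1, -1, -1, "") for _ in range(len(self))]

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def class_names(self) -> list:
        return sorted(set(self.labels.tolist()))

    def class_counts(self) -> dict:
        names, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(names.tolist(), counts.tolist()))

    def subset(self, idx) -> "PatchSet":
        idx = np.asarray(idx)
        return PatchSet(
            self.data[idx],
            self.labels[idx],
            [self.provenance[i] for i in idx],
            self.wavelengths,
        )

    def select_bands(self, band_indices) -> "PatchSet":
        band_indices = np.asarray(band_indices, dtype=int)
        wl = None if self.wavelengths is None else self.wavelengths[band_indices]
        return PatchSet(
            self.data[..., band_indices], self.labels, list(self.provenance), wl
        )

    @classmethod
    def concatenate(cls, sets: list) -> "PatchSet":
        if not sets:
            raise InvalidInputError("nothing to concatenate")
        data = np.concatenate([s.data for s in sets], axis=0)
        labels = np.concatenate([s.labels for s in sets], axis=0)
        prov = [p for s in sets for p in s.provenance]
        return cls(data, labels, prov, sets[0].wavelengths)

    def to_hdf5(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("patches", data=self.data)
            fh.create_dataset(
                "labels", data=np.asarray(self.labels, dtype="S16")
            )
            fh.create_dataset(
                "provenance",
                data=np.asarray(
                    ["|".join(map(str, p)) for p in self.provenance], dtype="S64"
                ),
            )
            if self.wavelengths is not None:
                fh.create_dataset("wavelengths", data=self.wavelengths)


@dataclass
class SplitSpec:
    """Stratified 3:1 train-test then 80:20 train-validation split."""

    test_fraction: float = 0.25
    val_fraction_of_train: float = 0.2
    stratified: bool = True
    group_by_scene: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("test_fraction", "val_fraction_of_train"):
            f = getattr(self, name)
            if not 0.0 < f < 1.0:
                raise InvalidParameterError(f"{name}={f} outside (0, 1)")
        if self.test_fraction + (1 - self.test_fraction) * self.val_fraction_of_train >= 1:
            raise InvalidParameterError("split fractions leave no training data")


def _split_points(n: int) -> tuple:
    # odd dimensions: the first quadrant takes the extra row/col
    return (n + 1) // 2, n


def quadrant_split_array(arr: np.ndarray) -> list:
    """Split the two leading (spatial) axes into four tiles: TL, TR, BL, BR."""
    h, w = arr.shape[:2]
    if h < 2 or w < 2:
        raise InvalidInputError("need at least 2 rows and 2 cols to split")
    hm, _ = _split_points(h)
    wm, _ = _split_points(w)
    return [arr[:hm, :wm], arr[:hm, wm:], arr[hm:, :wm], arr[hm:, wm:]]


def quadrant_split(cube) -> list:
    """Quadrant tiling of a Hypercube (returns four sub-cubes)."""
    from .hsi_io import Hypercube

    if isinstance(cube, Hypercube):
        return [
            Hypercube(tile, cube.wavelengths.copy(), cube.sensor, dict(cube.meta))
            for tile in quadrant_split_array(cube.data)
        ]
    return quadrant_split_array(np.asarray(cube))


def _candidate_positions(
    mask: np.ndarray, patch_size: int, min_plant_fraction: float, stride: int
) -> list:
    h, w = mask.shape
    positions = []
    m = mask.astype(np.float64)
    # summed-area table for O(1) window fractions
    sat = np.zeros((h + 1, w + 1))
    sat[1:, 1:] = m.cumsum(0).cumsum(1)
    area = patch_size * patch_size
    for r in range(0, h - patch_size + 1, stride):
        for c in range(0, w - patch_size + 1, stride):
            s = (
                sat[r + patch_size, c + patch_size]
                - sat[r, c + patch_size]
                - sat[r + patch_size, c]
                + sat[r, c]
            )
            if s / area >= min_plant_fraction:
                positions.append((r, c))
    return positions


def extract_patches(
    segment: np.ndarray,
    mask: np.ndarray,
    patch_size: int = 15,
    n_patches: int = 20,
    min_plant_fraction: float = 0.9,
    rng: np.random.Generator | None = None,
    relax_overlap: bool = False,
    scene_id: str = "?",
    quadrant: int = -1,
) -> PatchSet:
    """Sample ``n_patches`` canopy patches from one quadrant segment.

    Candidates are the non-overlapping grid of ``patch_size`` windows whose
    plant fraction is at least ``min_plant_fraction``; sampling is without
    replacement.  With fewer candidates than requested an
    :class:`InsufficientCanopyError` is raised unless ``relax_overlap`` is
    set, in which case unit-stride (overlapping) positions are used and the
    relaxation is logged.
    """
    segment = np.asarray(segment)
    mask = np.asarray(mask, dtype=bool)
    if segment.shape[:2] != mask.shape:
        raise InvalidInputError("segment and mask spatial shapes differ")
    if min(segment.shape[:2]) < patch_size:
        raise InvalidInputError(
            f"segment {segment.shape[:2]} smaller than patch size {patch_size}"
        )
    rng = np.random.default_rng(rng)

    positions = _candidate_positions(mask, patch_size, min_plant_fraction, patch_size)
    note = ""
    if len(positions) < n_patches:
        if not relax_overlap:
            raise InsufficientCanopyError(len(positions), n_patches)
        positions = _candidate_positions(mask, patch_size, min_plant_fraction, 1)
        note = "overlap-relaxed"
        logger.info(
            "scene %s quadrant %d: relaxed to overlapping positions "
            "(%d candidates)",
            scene_id,
            quadrant,
            len(positions),
        )
        if len(positions) < n_patches:
            raise InsufficientCanopyError(len(positions), n_patches)

    chosen = rng.choice(len(positions), size=n_patches, replace=False)
    data = np.stack(
        [
            segment[positions[i][0] : positions[i][0] + patch_size,
                    positions[i][1] : positions[i][1] + patch_size]
            for i in chosen
        ]
    )
    prov = [(scene_id, quadrant, positions[i][0], positions[i][1], note) for i in chosen]
    labels = np.array(["?"] * n_patches)
    return PatchSet(data, labels, prov)


def split_dataset(patchset: PatchSet, spec: SplitSpec) -> tuple:
    """Stratified (train, val, test) split.

    Per class: ``floor(n * test_fraction)`` test patches, then
    ``floor(remaining * val_fraction_of_train)`` validation patches, remainder
    to train (2800 per class -> 1680/420/700).  With ``group_by_scene`` all
    patches of one scene land in the same fold (leakage-safe option).
    """
    rng = np.random.default_rng(spec.seed)
    labels = patchset.labels
    idx_train, idx_val, idx_test = [], [], []

    classes = np.unique(labels) if spec.stratified else np.array(["__all__"])
    for c in classes:
        cls_idx = (
            np.flatnonzero(labels == c)
            if spec.stratified
            else np.arange(len(patchset))
        )
        if spec.group_by_scene:
            scenes = np.array([patchset.provenance[i][0] for i in cls_idx])
            uniq = np.unique(scenes)
            uniq = uniq[rng.permutation(len(uniq))]
            n_test = int(np.floor(len(uniq) * spec.test_fraction))
            n_val = int(np.floor((len(uniq) - n_test) * spec.val_fraction_of_train))
            test_scenes = set(uniq[:n_test])
            val_scenes = set(uniq[n_test : n_test + n_val])
            for i, s in zip(cls_idx, scenes):
                if s in test_scenes:
                    idx_test.append(i)
                elif s in val_scenes:
                    idx_val.append(i)
                else:
                    idx_train.append(i)
        else:
            perm = cls_idx[rng.permutation(len(cls_idx))]
            n_test = int(np.floor(len(perm) * spec.test_fraction))
            n_val = int(np.floor((len(perm) - n_test) * spec.val_fraction_of_train))
            idx_test.extend(perm[:n_test])
            idx_val.extend(perm[n_test : n_test + n_val])
            idx_train.extend(perm[n_test + n_val :])

    return (
        patchset.subset(sorted(idx_train)),
        patchset.subset(sorted(idx_val)),
        patchset.subset(sorted(idx_test)),
    )


def _rotate_patch(patch: np.ndarray, angle_deg: float) -> np.ndarray:
    """In-plane rotation of all bands by one angle, nearest-neighbour.

    Out-of-frame samples are filled with the per-band median of the patch
    border ring so the fill is spectrally consistent with the patch's own
    background.
    """
    m, n = patch.shape[:2]
    theta = np.deg2rad(angle_deg)
    cy, cx = (m - 1) / 2.0, (n - 1) / 2.0
    rr, cc = np.mgrid[0:m, 0:n]
    dy, dx = rr - cy, cc - cx
    # inverse mapping: output pixel samples from the input at -theta
    src_r = np.round(cy + np.cos(theta) * dy - np.sin(theta) * dx).astype(int)
    src_c = np.round(cx + np.sin(theta) * dy + np.cos(theta) * dx).astype(int)
    valid = (src_r >= 0) & (src_r < m) & (src_c >= 0) & (src_c < n)
    out = np.empty_like(patch)
    border = np.concatenate(
        [patch[0, :], patch[-1, :], patch[1:-1, 0], patch[1:-1, -1]], axis=0
    )
    fill = np.median(border, axis=0)
    out[~valid] = fill
    out[valid] = patch[src_r[valid], src_c[valid]]
    return out


def augment_rotate(
    patchset: PatchSet,
    fraction: float = 0.4,
    angle_range: tuple = (-20.0, 20.0),
    rng: np.random.Generator | None = None,
) -> PatchSet:
    """Duplicate a random fraction of patches with a random in-plane rotation.

    Each selected patch gains one rotated copy (uniform angle in
    ``angle_range``, applied identically to every band); originals are kept,
    labels preserved.  ``fraction=0.4`` on 1000 patches yields 1400.
    """
    if not 0.0 <= fraction <= 1.0:
        raise InvalidParameterError(f"fraction={fraction} outside [0, 1]")
    if fraction == 0.0 or len(patchset) == 0:
        return patchset
    rng = np.random.default_rng(rng)
    n_aug = int(round(fraction * len(patchset)))
    chosen = rng.choice(len(patchset), size=n_aug, replace=False)
    angles = rng.uniform(angle_range[0], angle_range[1], size=n_aug)
    aug = np.stack(
        [_rotate_patch(patchset.data[i], a) for i, a in zip(chosen, angles)]
    )
    prov = [
        patchset.provenance[i][:4] + (f"rot{a:+.1f}",) for i, a in zip(chosen, angles)
    ]
    extra = PatchSet(aug, patchset.labels[chosen], prov, patchset.wavelengths)
    return PatchSet.concatenate([patchset, extra])


def augment_flip(
    patchset: PatchSet,
    fraction: float = 1.0,
    direction: str = "both",
    rng: np.random.Generator | None = None,
) -> PatchSet:
    """Enlarge the set with horizontal/vertical mirror copies.

    ``direction`` in {"horizontal", "vertical", "both"}; "both" adds two
    copies per selected patch.  Flips act identically on every band, so each
    band's pixel multiset is preserved.
    """
    if direction not in ("horizontal", "vertical", "both"):
        raise InvalidParameterError(f"unknown flip direction {direction!r}")
    if not 0.0 <= fraction <= 1.0:
        raise InvalidParameterError(f"fraction={fraction} outside [0, 1]")
    if fraction == 0.0 or len(patchset) == 0:
        return patchset
    rng = np.random.default_rng(rng)
    n_sel = int(round(fraction * len(patchset)))
    chosen = rng.choice(len(patchset), size=n_sel, replace=False)
    pieces = [patchset]
    axes = {"horizontal": [1], "vertical": [0], "both": [1, 0]}[direction]
    tag = {0: "flipV", 1: "flipH"}
    for ax in axes:
        flipped = np.flip(patchset.data[chosen], axis=ax + 1)  # +1 for batch axis
        prov = [patchset.provenance[i][:4] + (tag[ax],) for i in chosen]
        pieces.append(
            PatchSet(flipped, patchset.labels[chosen], prov, patchset.wavelengths)
        )
    return PatchSet.concatenate(pieces)
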