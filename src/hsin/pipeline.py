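"""End-to-end experiment orchestration on synthetic scenes.

simulate -> calibrate -> segment -> transform -> patchify -> train/evaluate
-> select wavebands -> retrain per growth stage.

The spectral transforms (SNV, second derivative) act on individual pixel
spectra, so applying them to extracted patches is numerically identical to
applying them to the calibrated cube before extraction; the LDA projection
is supervised and is therefore always fitted on training patches only and
then applied to validation/test data.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .exceptions import InvalidInputError, InvalidParameterError
from .hsi_io import Hypercube, calibrate, smooth_savgol
from .patches import (
    PatchSet,
    SplitSpec,
    augment_flip,
    augment_rotate,
    extract_patches,
    quadrant_split_array,
    split_dataset,
)
from .segmentation import segment_plant
from .synth import Scene, SceneSpec, default_profiles, generate_dataset
from .transforms import LdaModel, apply_lda_to_cube, lda_fit, second_derivative, snv
from .band_selection import BandSelectionResult, greedy_stepwise_select
from .evaluation import confusion_matrix, metrics_report
from .models import ARCHITECTURES, TrainConfig, predict, train

__all__ = [
    "PipelineConfig",
    "calibrate_scene",
    "scene_to_patches",
    "build_patch_library",
    "apply_transform",
    "select_bands",
    "run_full_spectrum_experiment",
    "run_stagewise_experiment",
    "profiles_at_stage",
]


@dataclass
class PipelineConfig:
    """Resolved configuration for the experiment pipeline."""

    n_scenes_per_treatment: int = 10
    scene: SceneSpec = field(default_factory=SceneSpec)
    seed: int = 0
    # preprocessing
    smooth: bool = False
    sg_window: int = 13
    sg_polyorder: int = 2
    # patches
    patch_size: int = 15
    patches_per_quadrant: int = 5
    min_plant_fraction: float = 0.9
    relax_overlap: bool = True
    # splits
    split: SplitSpec = field(default_factory=SplitSpec)
    # experiment grid
    transforms: tuple = ("raw", "snv", "sderi", "lda")
    architectures: tuple = ("hybrid", "hybridsn", "cnn3d", "cnn2d")
    train: TrainConfig = field(default_factory=TrainConfig)
    # augmentation (stagewise retraining)
    rotate_fraction: float = 0.4
    rotate_range: tuple = (-20.0, 20.0)
    flip_fraction: float = 1.0
    # band selection
    max_bands: int = 20
    # growth stages
    stages: tuple = ("I", "II", "III", "IV", "V")
    stage_min_contrast: float = 0.6

    def __post_init__(self):
        if self.n_scenes_per_treatment < 1:
            raise InvalidParameterError("n_scenes_per_treatment must be >= 1")
        unknown = set(self.architectures) - set(ARCHITECTURES)
        if unknown:
            raise InvalidParameterError(f"unknown architectures {sorted(unknown)}")
        unknown = set(self.transforms) - {"raw", "snv", "sderi", "lda"}
        if unknown:
            raise InvalidParameterError(f"unknown transforms {sorted(unknown)}")

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["scene"]["vnir_wavelengths"] = self.scene.vnir_wavelengths.tolist()
        d["scene"]["swir_wavelengths"] = self.scene.swir_wavelengths.tolist()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "scene" in d:
            d["scene"] = SceneSpec(**d["scene"])
        if "split" in d:
            d["split"] = SplitSpec(**d["split"])
        if "train" in d:
            d["train"] = TrainConfig(**d["train"])
        for key in ("transforms", "architectures", "stages", "rotate_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def calibrate_scene(scene: Scene, config: PipelineConfig | None = None):
    """Calibrated (and optionally smoothed) VNIR and SWIR cubes of a scene."""
    config = config or PipelineConfig()
    out = []
    for cap in (scene.vnir, scene.swir):
        cube = calibrate(cap.raw, cap.refs)
        if config.smooth and cube.n_bands >= config.sg_window:
            cube = smooth_savgol(cube, config.sg_window, config.sg_polyorder)
        out.append(cube)
    return tuple(out)


def scene_to_patches(
    scene: Scene,
    config: PipelineConfig,
    rng: np.random.Generator,
) -> PatchSet:
    """Calibrate, segment and patchify one scene (labels from the scene)."""
    vnir, swir = calibrate_scene(scene, config)
    mask = segment_plant(vnir).mask
    data = np.concatenate([vnir.data, swir.data], axis=2).astype(np.float32)
    wavelengths = np.concatenate([vnir.wavelengths, swir.wavelengths])

    sets = []
    for q, (seg, mseg) in enumerate(
        zip(quadrant_split_array(data), quadrant_split_array(mask))
    ):
        ps = extract_patches(
            seg,
            mseg,
            patch_size=config.patch_size,
            n_patches=config.patches_per_quadrant,
            min_plant_fraction=config.min_plant_fraction,
            rng=rng,
            relax_overlap=config.relax_overlap,
            scene_id=scene.scene_id,
            quadrant=q,
        )
        ps.labels = np.array([scene.label] * len(ps))
        ps.wavelengths = wavelengths
        sets.append(ps)
    return PatchSet.concatenate(sets)


def build_patch_library(
    scenes: list, config: PipelineConfig, seed: int | None = None
) -> PatchSet:
    """Patch spectral library over all scenes (calibrated reflectance)."""
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    children = ss.spawn(len(scenes))
    return PatchSet.concatenate(
        [
            scene_to_patches(scene, config, np.random.default_rng(child))
            for scene, child in zip(scenes, children)
        ]
    )


def _sensor_boundary(wavelengths: np.ndarray) -> int:
    """Index of the first SWIR band (largest gap in the concatenated grid)."""
    return int(np.argmax(np.diff(wavelengths))) + 1


def _sderi_patches(data: np.ndarray, wavelengths: np.ndarray, window: int,
                   polyorder: int) -> np.ndarray:
    nv = _sensor_boundary(wavelengths)
    pieces = []
    for sl in (slice(0, nv), slice(nv, None)):
        w = wavelengths[sl]
        win = min(window, w.size if w.size % 2 == 1 else w.size - 1)
        pieces.append(
            second_derivative(data[..., sl], w, window=win, polyorder=polyorder)
        )
    return np.concatenate(pieces, axis=-1)


def _snv_patches(data: np.ndarray) -> np.ndarray:
    out = snv(data, on_constant="nan")
    bad = ~np.isfinite(out)
    if bad.any():
        out = np.where(bad, 0.0, out)  # flagged constant spectra zeroed explicitly
    return out


def apply_transform(
    train_set: PatchSet,
    val_set: PatchSet,
    test_set: PatchSet,
    transform: str,
    config: PipelineConfig,
):
    """Apply one spectral representation to the three splits.

    Returns ``(train, val, test, lda_model_or_None)``.  LDA is fitted on
    training patch pixels only.
    """
    wavelengths = train_set.wavelengths
    if transform == "raw":
        return train_set, val_set, test_set, None

    if transform in ("snv", "sderi"):
        fn = (
            _snv_patches
            if transform == "snv"
            else lambda d: _sderi_patches(
                d, wavelengths, config.sg_window, config.sg_polyorder
            )
        )
        out = []
        for s in (train_set, val_set, test_set):
            out.append(
                PatchSet(fn(s.data.astype(np.float64)), s.labels,
                         list(s.provenance), s.wavelengths)
            )
        return (*out, None)

    if transform == "lda":
        n, m, p, k = train_set.data.shape
        pixels = train_set.data.reshape(-1, k).astype(np.float64)
        labels = np.repeat(train_set.labels, m * p)
        # subsample pixels for the scatter estimate (deterministic)
        rng = np.random.default_rng(config.seed)
        if pixels.shape[0] > 50000:
            keep = rng.choice(pixels.shape[0], 50000, replace=False)
            pixels, labels = pixels[keep], labels[keep]
        model = lda_fit(pixels, labels, shrinkage="auto")
        out = []
        for s in (train_set, val_set, test_set):
            flat = s.data.reshape(len(s), m, p, k).astype(np.float64)
            proj = np.stack([apply_lda_to_cube(model, cube) for cube in flat])
            out.append(PatchSet(proj, s.labels, list(s.provenance), None))
        return (*out, model)

    raise InvalidParameterError(f"unknown transform {transform!r}")


def _build_spec(arch: str, sample_shape: tuple, n_classes: int):
    builder = ARCHITECTURES[arch]
    if arch == "cnn2d":
        return builder(tuple(sample_shape), n_classes)
    return builder(tuple(sample_shape) + (1,), n_classes)


def _train_eval(arch, tr, va, te, config, seed_offset=0):
    cfg = TrainConfig(**{**asdict(config.train), "seed": config.train.seed + seed_offset})
    spec = _build_spec(arch, tr.data.shape[1:], len(tr.class_names))
    t0 = time.perf_counter()
    model = train(spec, tr.data, tr.labels, va.data, va.labels, cfg)
    elapsed = time.perf_counter() - t0
    _, pred = predict(model, te.data)
    cm = confusion_matrix(te.labels, pred, class_names=tr.class_names)
    return model, metrics_report(cm), cm, elapsed


def run_full_spectrum_experiment(config: PipelineConfig | None = None):
    """The architecture x transform grid on one synthetic dataset.

    All cells share the same scenes, patch library and split membership.
    Returns ``(results_df, context)`` where ``context`` carries the library,
    split indices and fitted models for further inspection.
    """
    config = config or PipelineConfig()
    scenes = generate_dataset(
        config.n_scenes_per_treatment, config.scene, seed=config.seed
    )
    library = build_patch_library(scenes, config)
    tr0, va0, te0 = split_dataset(library, config.split)

    rows, models = [], {}
    for transform in config.transforms:
        tr, va, te, _ = apply_transform(tr0, va0, te0, transform, config)
        for arch in config.architectures:
            model, rep, cm, elapsed = _train_eval(arch, tr, va, te, config)
            models[(arch, transform)] = model
            rows.append(
                {
                    "architecture": arch,
                    "transform": transform,
                    "overall_accuracy": rep.overall_accuracy,
                    "f_score": rep.f_score,
                    "kappa": rep.kappa,
                    "n_test": rep.n_samples,
                    "train_seconds": elapsed,
                }
            )
    results = pd.DataFrame(rows)
    context = {
        "library": library,
        "splits": (tr0, va0, te0),
        "models": models,
        "scenes": scenes,
    }
    return results, context


def select_bands(
    train_set: PatchSet, max_bands: int = 20, min_gain: float = 0.0
) -> BandSelectionResult:
    """Greedy CFS on patch-mean spectra of the training split."""
    X = train_set.data.reshape(len(train_set), -1, train_set.data.shape[-1]).mean(axis=1)
    return greedy_stepwise_select(
        X,
        train_set.labels,
        max_bands=max_bands,
        min_gain=min_gain,
        wavelengths=train_set.wavelengths,
    )


def profiles_at_stage(
    profiles: dict, stage_index: int, n_stages: int, min_contrast: float = 0.6
) -> dict:
    """Per-stage treatment profiles: spectral contrast between treatments
    grows linearly from ``min_contrast`` (stage 0) to 1 (final stage),
    emulating the divergence of canopy spectra as deficiency develops."""
    from dataclasses import replace

    f = (
        1.0
        if n_stages == 1
        else min_contrast + (1.0 - min_contrast) * stage_index / (n_stages - 1)
    )
    fields_ = ("green_peak_height", "red_level", "nir_plateau", "swir_absorption_depth")
    means = {
        name: float(np.mean([getattr(p, name) for p in profiles.values()]))
        for name in fields_
    }
    out = {}
    for label, p in profiles.items():
        out[label] = replace(
            p,
            **{
                name: means[name] + f * (getattr(p, name) - means[name])
                for name in fields_
            },
        )
    return out


def run_stagewise_experiment(
    config: PipelineConfig,
    selection: BandSelectionResult,
    architectures: tuple | None = None,
):
    """Retrain on selected wavebands (second-derivative data) per growth stage.

    Training data are augmented with rotations and flips.  Returns
    ``(metrics_df, per_class_df)`` shaped like per-stage model reports.
    """
    if not len(selection):
        raise InvalidInputError("empty band selection")
    architectures = architectures or config.architectures
    profiles = default_profiles()
    n_stages = len(config.stages)
    sel = np.asarray(selection.selected_indices, dtype=int)

    rows, per_class_rows = [], []
    for s_idx, stage in enumerate(config.stages):
        stage_profiles = profiles_at_stage(
            profiles, s_idx, n_stages, config.stage_min_contrast
        )
        scenes = generate_dataset(
            config.n_scenes_per_treatment,
            config.scene,
            profiles=stage_profiles,
            seed=config.seed + 1000 * (s_idx + 1),
        )
        library = build_patch_library(scenes, config, seed=config.seed + 77 * (s_idx + 1))
        tr0, va0, te0 = split_dataset(library, config.split)
        tr, va, te, _ = apply_transform(tr0, va0, te0, "sderi", config)
        if sel.max() >= tr.data.shape[-1]:
            raise InvalidInputError(
                f"selection references band {sel.max()} outside the cube "
                f"({tr.data.shape[-1]} bands)"
            )
        tr, va, te = (s.select_bands(sel) for s in (tr, va, te))
        rng = np.random.default_rng(config.seed + 13 * (s_idx + 1))
        tr_aug = augment_rotate(tr, config.rotate_fraction, config.rotate_range, rng)
        tr_aug = augment_flip(tr_aug, config.flip_fraction, rng=rng)

        for arch in architectures:
            model, rep, cm, elapsed = _train_eval(
                arch, tr_aug, va, te, config, seed_offset=s_idx
            )
            rows.append(
                {
                    "stage": stage,
                    "architecture": arch,
                    "overall_accuracy": rep.overall_accuracy,
                    "f_score": rep.f_score,
                    "kappa": rep.kappa,
                    "n_test": rep.n_samples,
                    "train_seconds": elapsed,
                }
            )
            for cls, acc in rep.per_class_accuracy.items():
                per_class_rows.append(
                    {
                        "stage": stage,
                        "architecture": arch,
                        "treatment": cls,
                        "accuracy": acc,
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(per_class_rows)
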