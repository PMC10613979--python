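"""Synthetic hyperspectral scenes for four N x P nutrient treatments.

The generator emulates canopy reflectance of plants grown under crossed
high/low nitrogen and phosphorus supply.  Each treatment's spectrum is a sum
of parameterised primitives -- a Gaussian chlorophyll peak near 550 nm, a
logistic red edge rising to a near-infrared plateau, and Gaussian water
absorption dips near 1450/1940 nm with a gradual short-wave-infrared
decline -- chosen so the qualitative orderings seen in nutrient trials hold:
nitrogen-starved plants reflect more in the red (600-700 nm), well-fed plants
reflect most on the NIR plateau (750-1100 nm).

Scenes are rendered as plant-shaped masks (a union of ellipses) over a flat
background, converted to raw sensor counts by inverting the radiometric
calibration (``raw = dark + reflectance * (white - dark)``), so the
calibration stage downstream is testable as an exact round trip.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import InvalidInputError
from .hsi_io import Hypercube, ReferencePair, write_envi

__all__ = [
    "TreatmentProfile",
    "SceneSpec",
    "SceneCapture",
    "Scene",
    "TREATMENTS",
    "default_profiles",
    "default_vnir_wavelengths",
    "default_swir_wavelengths",
    "base_curve",
    "generate_spectrum",
    "generate_scene",
    "generate_dataset",
    "write_scene",
]

TREATMENTS = ("HNHP", "HNLP", "LNHP", "LNLP")


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class TreatmentProfile:
    """Spectral parameters of one nutrient treatment.

    Reflectance parameters are unitless in [0, 1]; wavelength-independent
    noise terms are standard deviations on the reflectance scale.
    """

    label: str
    green_peak_height: float  # reflectance at the ~550 nm chlorophyll peak
    red_level: float  # mean reflectance over 600-700 nm
    nir_plateau: float  # mean reflectance over 750-1100 nm
    swir_absorption_depth: float  # depth of the ~1450 nm water dip
    baseline_drift_sd: float = 0.005  # per-scene additive offset sd
    noise_sd: float = 0.01  # per-pixel, per-band additive noise sd
    gain_range: tuple = (0.9, 1.1)  # per-scene multiplicative illumination

    def __post_init__(self):
        for name in (
            "green_peak_height",
            "red_level",
            "nir_plateau",
            "swir_absorption_depth",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name}={v} outside [0, 1]")

    def quiet(self) -> "TreatmentProfile":
        """Noise-free copy (no pixel noise, no drift, unit gain)."""
        return replace(self, noise_sd=0.0, baseline_drift_sd=0.0, gain_range=(1.0, 1.0))


def default_profiles() -> dict:
    """Default four-treatment profiles.

    Orderings encoded: NIR plateau HNHP > HNLP and LNHP > LNLP (healthy
    canopies reflect most in the NIR); red reflectance higher under low N
    (chlorosis); the green peak follows the red ordering; the water-dip depth
    is deeper under high P.
    """
    return {
        "HNHP": TreatmentProfile("HNHP", 0.12, 0.06, 0.65, 0.35),
        "HNLP": TreatmentProfile("HNLP", 0.10, 0.05, 0.55, 0.24),
        "LNHP": TreatmentProfile("LNHP", 0.18, 0.12, 0.50, 0.30),
        "LNLP": TreatmentProfile("LNLP", 0.20, 0.15, 0.42, 0.20),
    }


def default_vnir_wavelengths() -> np.ndarray:
    """155 VNIR bands, 398-1014 nm at 4 nm (covers the 705/750 nm red edge)."""
    return 398.0 + 4.0 * np.arange(155)


def default_swir_wavelengths() -> np.ndarray:
    """68 SWIR bands spanning 1040-2500 nm."""
    return np.linspace(1040.0, 2500.0, 68)


@dataclass
class SceneSpec:
    """Geometry and grid of a synthetic scene (both sensors share the mask)."""

    height: int = 64
    width: int = 64
    vnir_wavelengths: np.ndarray = field(default_factory=default_vnir_wavelengths)
    swir_wavelengths: np.ndarray = field(default_factory=default_swir_wavelengths)
    n_blobs: int = 4
    background_reflectance: float = 0.15

    def __post_init__(self):
        self.vnir_wavelengths = np.asarray(self.vnir_wavelengths, dtype=float)
        self.swir_wavelengths = np.asarray(self.swir_wavelengths, dtype=float)
        for name in ("vnir_wavelengths", "swir_wavelengths"):
            w = getattr(self, name)
            if w.size and np.any(np.diff(w) <= 0):
                raise InvalidInputError(f"{name} must be strictly increasing")
        if (
            self.vnir_wavelengths.size
            and self.swir_wavelengths.size
            and self.vnir_wavelengths[-1] >= self.swir_wavelengths[0]
        ):
            raise InvalidInputError("VNIR grid must end below the SWIR grid")


def base_curve(profile: TreatmentProfile, wavelengths: np.ndarray) -> np.ndarray:
    """Closed-form noise-free reflectance of a treatment on a wavelength grid."""
    w = np.asarray(wavelengths, dtype=float)
    if w.size == 0:
        raise InvalidInputError("empty wavelength grid")
    if np.any(w < 390.0) or np.any(w > 2500.0):
        raise InvalidInputError("wavelengths must lie within 390-2500 nm")
    if np.any(np.diff(w) <= 0):
        raise InvalidInputError("wavelengths must be strictly increasing")

    p = profile
    r = np.full_like(w, p.red_level)
    # chlorophyll reflectance peak in the green
    r += (p.green_peak_height - p.red_level) * np.exp(-0.5 * ((w - 552.0) / 22.0) ** 2)
    # red edge rising to the NIR plateau
    r += (p.nir_plateau - p.red_level) * _sigmoid((w - 715.0) / 12.0)
    # water absorption dips at ~1450 and ~1940 nm
    r -= p.swir_absorption_depth * (
        np.exp(-0.5 * ((w - 1450.0) / 60.0) ** 2)
        + 0.85 * np.exp(-0.5 * ((w - 1940.0) / 80.0) ** 2)
    )
    # broad SWIR decline and slight upturn past 2200 nm, tied to the dip depth
    r -= 1.2 * p.swir_absorption_depth * _sigmoid((w - 1700.0) / 350.0)
    r += 0.3 * p.swir_absorption_depth * _sigmoid((w - 2250.0) / 120.0)
    return np.clip(r, 0.0, 1.0)


def generate_spectrum(
    profile: TreatmentProfile,
    wavelengths: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One canopy pixel spectrum: gain * base curve + drift + noise, in [0, 1]."""
    rng = np.random.default_rng(rng)
    base = base_curve(profile, wavelengths)
    gain = rng.uniform(*profile.gain_range)
    drift = rng.normal(0.0, profile.baseline_drift_sd) if profile.baseline_drift_sd else 0.0
    noise = (
        rng.normal(0.0, profile.noise_sd, size=base.shape)
        if profile.noise_sd
        else 0.0
    )
    return np.clip(gain * base + drift + noise, 0.0, 1.0)


def make_plant_mask(
    height: int, width: int, n_blobs: int, rng: np.random.Generator
) -> np.ndarray:
    """Plant canopy mask: one large central ellipse plus smaller blobs."""
    rr, cc = np.mgrid[0:height, 0:width]
    mask = np.zeros((height, width), dtype=bool)

    def add_ellipse(cy, cx, ay, ax, theta):
        dy, dx = rr - cy, cc - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        mask[(u / ay) ** 2 + (v / ax) ** 2 <= 1.0] = True

    # central canopy covering the scene middle so every quadrant holds plant
    add_ellipse(
        height / 2 + rng.uniform(-1, 1),
        width / 2 + rng.uniform(-1, 1),
        rng.uniform(0.34, 0.42) * height,
        rng.uniform(0.34, 0.42) * width,
        rng.uniform(0, np.pi),
    )
    for _ in range(max(n_blobs - 1, 0)):
        add_ellipse(
            rng.uniform(0.3, 0.7) * height,
            rng.uniform(0.3, 0.7) * width,
            rng.uniform(0.10, 0.22) * height,
            rng.uniform(0.10, 0.22) * width,
            rng.uniform(0, np.pi),
        )
    return mask


@dataclass
class SceneCapture:
    """Raw counts plus reference captures for one sensor."""

    raw: Hypercube
    refs: ReferencePair

    @property
    def wavelengths(self) -> np.ndarray:
        return self.raw.wavelengths


@dataclass
class Scene:
    """A labelled synthetic scene: VNIR + SWIR captures sharing one mask."""

    scene_id: str
    label: str
    vnir: SceneCapture
    swir: SceneCapture
    mask: np.ndarray
    seed: int | None = None


def _render_capture(
    reflectance: np.ndarray,
    wavelengths: np.ndarray,
    sensor: str,
    white_level,
    dark_level,
) -> SceneCapture:
    white = np.broadcast_to(np.asarray(white_level, dtype=float), wavelengths.shape)
    dark = np.broadcast_to(np.asarray(dark_level, dtype=float), wavelengths.shape)
    if np.any(white <= dark):
        raise InvalidInputError("white reference must exceed dark reference everywhere")
    raw = dark + reflectance * (white - dark)
    cube = Hypercube(raw, wavelengths, sensor=sensor)
    return SceneCapture(cube, ReferencePair(white.copy(), dark.copy()))


def _reflectance_field(
    spec: SceneSpec,
    profile: TreatmentProfile,
    wavelengths: np.ndarray,
    mask: np.ndarray,
    gain: float,
    drift: float,
    rng: np.random.Generator,
) -> np.ndarray:
    base = base_curve(profile, wavelengths)
    field3 = np.full(
        (spec.height, spec.width, wavelengths.size), spec.background_reflectance
    )
    field3[mask] = base
    field3 *= gain
    field3 += drift
    if profile.noise_sd:
        field3 += rng.normal(0.0, profile.noise_sd, size=field3.shape)
    return np.clip(field3, 0.0, 1.0)


def generate_scene(
    spec: SceneSpec,
    profile: TreatmentProfile,
    white_level: float = 10000.0,
    dark_level: float = 100.0,
    rng: np.random.Generator | None = None,
    scene_id: str = "scene-0",
) -> Scene:
    """Render one labelled scene as raw counts + references + truth mask.

    The scene-level illumination gain and baseline drift are drawn once and
    applied to both sensors; per-pixel noise is independent per band.
    """
    rng = np.random.default_rng(rng)
    mask = make_plant_mask(spec.height, spec.width, spec.n_blobs, rng)
    gain = rng.uniform(*profile.gain_range)
    drift = rng.normal(0.0, profile.baseline_drift_sd) if profile.baseline_drift_sd else 0.0

    captures = {}
    for sensor, w in (("VNIR", spec.vnir_wavelengths), ("SWIR", spec.swir_wavelengths)):
        refl = _reflectance_field(spec, profile, w, mask, gain, drift, rng)
        captures[sensor] = _render_capture(refl, w, sensor, white_level, dark_level)
    return Scene(scene_id, profile.label, captures["VNIR"], captures["SWIR"], mask)


def generate_dataset(
    n_scenes_per_treatment: int,
    spec: SceneSpec | None = None,
    profiles: dict | None = None,
    seed: int = 0,
    white_level: float = 10000.0,
    dark_level: float = 100.0,
) -> list:
    """Balanced labelled scene collection, reproducible under ``seed``.

    Returns ``4 * n_scenes_per_treatment`` scenes (for the default four
    treatments), interleaved so every consecutive block of four holds one
    scene per treatment.
    """
    if n_scenes_per_treatment < 1:
        raise InvalidInputError("n_scenes_per_treatment must be >= 1")
    spec = spec or SceneSpec()
    profiles = profiles or default_profiles()
    labels = list(profiles)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_scenes_per_treatment * len(labels))
    scenes = []
    k = 0
    for rep in range(n_scenes_per_treatment):
        for label in labels:
            rng = np.random.default_rng(children[k])
            scenes.append(
                generate_scene(
                    spec,
                    profiles[label],
                    white_level,
                    dark_level,
                    rng,
                    scene_id=f"{label}-{rep:03d}",
                )
            )
            scenes[-1].seed = k
            k += 1
    return scenes


def write_scene(scene: Scene, out_dir: str) -> None:
    """Persist a scene: ENVI rasters per sensor, PNG mask, manifest row."""
    import imageio.v3 as iio

    os.makedirs(out_dir, exist_ok=True)
    for sensor, cap in (("vnir", scene.vnir), ("swir", scene.swir)):
        write_envi(cap.raw, os.path.join(out_dir, f"{scene.scene_id}_{sensor}"))
        np.savetxt(
            os.path.join(out_dir, f"{scene.scene_id}_{sensor}_white.txt"),
            np.atleast_1d(cap.refs.white),
        )
        np.savetxt(
            os.path.join(out_dir, f"{scene.scene_id}_{sensor}_dark.txt"),
            np.atleast_1d(cap.refs.dark),
        )
    iio.imwrite(
        os.path.join(out_dir, f"{scene.scene_id}_mask.png"),
        (scene.mask.astype(np.uint8) * 255),
    )
    manifest = os.path.join(out_dir, "manifest.csv")
    new = not os.path.exists(manifest)
    with open(manifest, "a", newline="") as fh:
        w = csv.writer(fh)
        if new:
            w.writerow(["scene_id", "label", "seed"])
        w.writerow([scene.scene_id, scene.label, scene.seed])
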