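"""Hypercube container, ENVI raster I/O and radiometric preprocessing.

A hypercube is stored as a ``rows x cols x bands`` array together with the
per-band centre wavelengths in nanometres.  Preprocessing follows the usual
push-broom imaging-spectrometer chain: radiometric calibration against
white/dark reference captures, spectral down-sampling with an averaging
window, and Savitzky-Golay smoothing of each pixel spectrum.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import (
    CalibrationError,
    FormatError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "Hypercube",
    "ReferencePair",
    "read_envi",
    "write_envi",
    "calibrate",
    "downsample",
    "smooth_savgol",
]

# ENVI "data type" codes <-> numpy dtypes (the subset we support)
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class Hypercube:
    """Calibrated or raw hyperspectral raster with its wavelength grid.

    Parameters
    ----------
    data : ndarray, shape (rows, cols, bands)
        Reflectance or raw counts.  Finite values required.
    wavelengths : ndarray, shape (bands,)
        Strictly increasing band-centre wavelengths in nm.
    sensor : str
        Sensor tag, ``"VNIR"`` or ``"SWIR"`` (free-form tags are allowed for
        derived products such as concatenated cubes).
    meta : dict
        Free-form provenance.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    sensor: str = "VNIR"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise InvalidInputError(
                f"hypercube data must be 3-D (rows, cols, bands), got {self.data.ndim}-D"
            )
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise InvalidInputError(
                f"wavelength list length {self.wavelengths.size} does not match "
                f"band count {self.data.shape[2]}"
            )
        if self.wavelengths.size and np.any(np.diff(self.wavelengths) <= 0):
            raise InvalidInputError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise InvalidInputError("hypercube data must be finite")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band nearest ``wavelength_nm``.

        Raises :class:`WavelengthLookupError` when the nearest band is farther
        away than half the local band spacing.
        """
        from .exceptions import WavelengthLookupError

        w = self.wavelengths
        idx = int(np.argmin(np.abs(w - wavelength_nm)))
        if w.size > 1:
            diffs = np.diff(w)
            lo = diffs[max(idx - 1, 0)]
            hi = diffs[min(idx, diffs.size - 1)]
            tol = 0.5 * max(lo, hi) + 1e-9
        else:
            tol = np.inf
        if abs(w[idx] - wavelength_nm) > tol:
            raise WavelengthLookupError(
                f"no band within {tol:.2f} nm of {wavelength_nm} nm "
                f"(nearest is {w[idx]:.2f} nm)"
            )
        return idx


@dataclass
class ReferencePair:
    """White/dark reference captures used by :func:`calibrate`.

    Each reference may be a full cube matching the raw data, a per-band
    spectrum (the common case for a dark capture taken with the lens capped),
    or a scalar.
    """

    white: Union[np.ndarray, float]
    dark: Union[np.ndarray, float]

    def __post_init__(self):
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)


# ---------------------------------------------------------------------------
# ENVI raster + ASCII header


def write_envi(cube: Hypercube, path: str, interleave: str = "bil") -> None:
    """Write ``cube`` as an ENVI raster (``<path>.img``) + header (``<path>.hdr``).

    ``path`` is the base name without extension.  The header records samples,
    lines, bands, interleave, data type, byte order and the wavelength list.
    """
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise FormatError(f"unsupported interleave {interleave!r}")
    data = cube.data
    dtype = np.dtype(data.dtype)
    if dtype not in _DTYPE_CODES:
        data = data.astype(np.float64)
        dtype = np.dtype(np.float64)
    lines, samples, bands = data.shape
    if interleave == "bip":
        arr = data  # (lines, samples, bands)
    elif interleave == "bil":
        arr = np.transpose(data, (0, 2, 1))  # (lines, bands, samples)
    else:  # bsq
        arr = np.transpose(data, (2, 0, 1))  # (bands, lines, samples)
    np.ascontiguousarray(arr).tofile(path + ".img")

    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths)
    hdr = (
        "ENVI\n"
        f"description = {{hsin hypercube, sensor {cube.sensor}}}\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"sensor type = {cube.sensor}\n"
        f"wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    with open(path + ".hdr", "w") as fh:
        fh.write(hdr)


def _parse_envi_header(text: str) -> dict:
    fields: dict = {}
    key, buf, in_braces = None, "", False
    for line in text.splitlines():
        line = line.strip()
        if not line or line.upper() == "ENVI":
            continue
        if not in_braces:
            if "=" not in line:
                continue
            key, _, value = line.partition("=")
            key = key.strip().lower()
            value = value.strip()
            if value.startswith("{") and not value.endswith("}"):
                in_braces, buf = True, value[1:]
            elif value.startswith("{"):
                fields[key] = value[1:-1].strip()
            else:
                fields[key] = value
        else:
            if line.endswith("}"):
                buf += " " + line[:-1]
                fields[key] = buf.strip()
                in_braces = False
            else:
                buf += " " + line
    return fields


def read_envi(path: str) -> Hypercube:
    """Read an ENVI raster written by :func:`write_envi` (or compatible).

    ``path`` is the base name; ``<path>.hdr`` and ``<path>.img`` must exist.
    """
    hdr_path = path + ".hdr"
    img_path = path + ".img"
    if not os.path.exists(hdr_path):
        raise FormatError(f"missing ENVI header {hdr_path}")
    with open(hdr_path) as fh:
        fields = _parse_envi_header(fh.read())

    for required in ("samples", "lines", "bands", "interleave", "data type"):
        if required not in fields:
            raise FormatError(f"ENVI header missing required field {required!r}")
    if "wavelength" not in fields:
        raise FormatError("ENVI header has no 'wavelength' field")

    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = fields["interleave"].lower()
    code = int(fields["data type"])
    if code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type code {code}")
    dtype = np.dtype(_ENVI_DTYPES[code])
    if int(fields.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")

    raw = np.fromfile(img_path, dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise FormatError(
            f"ENVI raster size {raw.size} does not match header "
            f"({lines}x{samples}x{bands}={expected}); interleave/shape mismatch?"
        )
    if interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    else:
        raise FormatError(f"unsupported interleave {interleave!r}")

    wavelengths = np.array(
        [float(tok) for tok in fields["wavelength"].replace(",", " ").split()]
    )
    sensor = fields.get("sensor type", "VNIR")
    return Hypercube(np.ascontiguousarray(data), wavelengths, sensor=sensor)


# ---------------------------------------------------------------------------
# Preprocessing


def calibrate(raw: Hypercube, refs: ReferencePair) -> Hypercube:
    """Radiometric calibration ``(raw - dark) / (white - dark)``.

    References broadcast against the cube: full cubes, per-band spectra or
    scalars are all accepted.  A zero denominator at any band raises
    :class:`CalibrationError` naming the offending band.
    """
    white = np.broadcast_to(refs.white, raw.data.shape)
    dark = np.broadcast_to(refs.dark, raw.data.shape)
    denom = white - dark
    bad = ~(np.abs(denom) > 0)
    if np.any(bad):
        band = int(np.argwhere(bad.any(axis=(0, 1)))[0][0])
        raise CalibrationError(
            f"white - dark is zero at band {band} "
            f"({raw.wavelengths[band]:.2f} nm)"
        )
    data = (raw.data.astype(np.float64) - dark) / denom
    meta = dict(raw.meta, calibrated=True)
    return Hypercube(data, raw.wavelengths.copy(), sensor=raw.sensor, meta=meta)


def downsample(cube: Hypercube, step_nm: float) -> Hypercube:
    """Spectral down-sampling with a ``step_nm``-wide averaging window.

    Windows are half-open, anchored at the first wavelength:
    band *b* of the output is the unweighted mean of the input bands whose
    wavelength lies in ``[w0 + b*step, w0 + (b+1)*step)``; its wavelength is
    the window centre.  Empty windows are dropped.
    """
    w = cube.wavelengths
    native = float(np.min(np.diff(w))) if w.size > 1 else 0.0
    if step_nm <= native:
        raise InvalidParameterError(
            f"down-sampling step {step_nm} nm must exceed the native spacing "
            f"({native:.4g} nm)"
        )
    bins = np.floor((w - w[0]) / step_nm).astype(int)
    out_bands, out_w = [], []
    for b in np.unique(bins):
        members = bins == b
        out_bands.append(cube.data[:, :, members].mean(axis=2))
        out_w.append(w[0] + (b + 0.5) * step_nm)
    data = np.stack(out_bands, axis=2)
    meta = dict(cube.meta, downsampled_step_nm=step_nm)
    return Hypercube(data, np.array(out_w), sensor=cube.sensor, meta=meta)


def smooth_savgol(cube: Hypercube, window: int = 13, polyorder: int = 2) -> Hypercube:
    """Savitzky-Golay smoothing of every pixel spectrum.

    Each spectrum is replaced by the value of a local least-squares polynomial
    fit (window 13, order 2 by default).  Spectrum ends use a polynomial fit on
    the truncated edge window, which preserves exact reproduction of
    polynomials up to ``polyorder``.
    """
    if window % 2 == 0:
        raise InvalidParameterError(f"window must be odd, got {window}")
    if window <= polyorder:
        raise InvalidParameterError(
            f"window ({window}) must exceed polyorder ({polyorder})"
        )
    if cube.n_bands < window:
        raise InvalidInputError(
            f"cube has {cube.n_bands} bands, fewer than window {window}"
        )
    data = savgol_filter(
        cube.data.astype(np.float64), window, polyorder, axis=2, mode="interp"
    )
    meta = dict(cube.meta, sg_window=window, sg_polyorder=polyorder)
    return Hypercube(data, cube.wavelengths.copy(), sensor=cube.sensor, meta=meta)
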