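"""Spectral representations fed to the classifiers.

Four model-input representations are supported: raw reflectance, standard
normal variate (SNV), Savitzky-Golay second derivative (SDeri), and a linear
discriminant analysis (LDA) projection to at most C-1 channels.

SNV centres each spectrum and scales it to unit *sample* variance
(denominator p-1), cancelling multiplicative scatter and baseline offsets.
The second derivative annihilates any linear baseline and sharpens
overlapping absorption features.  LDA is supervised: it is fitted on
training spectra only and then applied to held-out data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .exceptions import DegenerateInputError, InvalidInputError, InvalidParameterError

__all__ = [
    "snv",
    "second_derivative",
    "LdaModel",
    "lda_fit",
    "lda_transform",
    "TRANSFORMS",
]

TRANSFORMS = ("raw", "snv", "sderi", "lda")


def snv(spectra: np.ndarray, on_constant: str = "raise") -> np.ndarray:
    """Standard normal variate: per-spectrum centre and unit sample variance.

    Parameters
    ----------
    spectra : ndarray, shape (..., p)
        One spectrum per trailing axis, p >= 2.
    on_constant : {"raise", "nan"}
        Constant spectra have zero sample standard deviation; ``"raise"``
        raises :class:`DegenerateInputError`, ``"nan"`` flags the offending
        spectra as NaN so the caller can handle them explicitly.
    """
    x = np.asarray(spectra, dtype=np.float64)
    if x.shape[-1] < 2:
        raise InvalidInputError("SNV needs spectra of length >= 2")
    mean = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, ddof=1, keepdims=True)
    degenerate = sd == 0
    if degenerate.any():
        if on_constant == "raise":
            raise DegenerateInputError(
                f"{int(degenerate.sum())} constant spectra have zero standard deviation"
            )
        sd = np.where(degenerate, np.nan, sd)
    return (x - mean) / sd


def second_derivative(
    values: np.ndarray,
    wavelengths: np.ndarray | None = None,
    window: int = 13,
    polyorder: int = 2,
) -> np.ndarray:
    """Savitzky-Golay second derivative along the spectral (last) axis.

    When ``wavelengths`` is given the derivative is scaled by the mean band
    spacing (units: reflectance / nm^2); otherwise it is taken with respect
    to band index.
    """
    if polyorder < 2:
        raise InvalidParameterError(
            f"polyorder must be >= 2 for a second derivative, got {polyorder}"
        )
    if window % 2 == 0 or window <= polyorder:
        raise InvalidParameterError(
            f"window must be odd and exceed polyorder, got {window}"
        )
    x = np.asarray(values, dtype=np.float64)
    if x.shape[-1] < window:
        raise InvalidInputError(
            f"spectrum length {x.shape[-1]} shorter than window {window}"
        )
    delta = 1.0
    if wavelengths is not None:
        w = np.asarray(wavelengths, dtype=float)
        if w.size != x.shape[-1]:
            raise InvalidInputError("wavelength grid does not match spectral axis")
        delta = float(np.mean(np.diff(w)))
    return savgol_filter(
        x, window, polyorder, deriv=2, delta=delta, axis=-1, mode="interp"
    )


@dataclass
class LdaModel:
    """Fitted discriminant projection (columns ordered by eigenvalue)."""

    projection: np.ndarray  # (n_features, d), d <= C - 1
    class_means: np.ndarray  # (C, n_features)
    fitted_classes: np.ndarray  # (C,)
    xbar: np.ndarray  # overall training mean, (n_features,)

    @property
    def n_components(self) -> int:
        return self.projection.shape[1]

    def save(self, path: str) -> None:
        """Portable serialisation (projection matrices + class labels)."""
        np.savez(path, projection=self.projection, class_means=self.class_means,
                 fitted_classes=self.fitted_classes, xbar=self.xbar)


def lda_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int | None = None,
    shrinkage: float | str | None = None,
) -> LdaModel:
    """Fit an LDA projection maximising between/within class scatter.

    ``shrinkage`` regularises the within-class scatter (``"auto"`` for
    Ledoit-Wolf) when it is singular; a singular fit without regularisation
    raises a numerical error suggesting it.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise InvalidInputError("LDA needs at least two classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise InvalidInputError(f"class {c!r} has fewer than two rows")
    d_max = classes.size - 1
    d = d_max if n_components is None else min(n_components, d_max)

    est = LinearDiscriminantAnalysis(
        solver="eigen", shrinkage=shrinkage, n_components=d
    )
    try:
        est.fit(X, y)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "within-class scatter is singular; pass shrinkage='auto' or a "
            "float in (0, 1] to regularise"
        ) from err
    return LdaModel(
        projection=np.asarray(est.scalings_)[:, :d],
        class_means=np.asarray(est.means_),
        fitted_classes=classes,
        xbar=X.mean(axis=0),
    )


def lda_transform(model: LdaModel, X: np.ndarray) -> np.ndarray:
    """Project rows of ``X`` onto the fitted discriminants (M x d)."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[-1] != model.projection.shape[0]:
        raise InvalidInputError(
            f"feature count {X.shape[-1]} does not match fitted "
            f"{model.projection.shape[0]}"
        )
    return (X - model.xbar) @ model.projection


def apply_lda_to_cube(model: LdaModel, cube_data: np.ndarray) -> np.ndarray:
    """Apply a fitted LDA pixelwise to an (h, w, bands) array -> (h, w, d)."""
    h, w, b = cube_data.shape
    flat = cube_data.reshape(-1, b)
    return lda_transform(model, flat).reshape(h, w, model.n_components)
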