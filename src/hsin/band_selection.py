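"""Correlation-based feature selection (CFS) with greedy stepwise search.

Informative wavebands are those highly correlated with the treatment class
but mutually uncorrelated.  A subset S of k bands is scored by the CFS merit

    merit(S) = k * r_cf / sqrt(k + k (k - 1) * r_ff)

where r_cf is the mean class correlation of the members and r_ff the mean
absolute pairwise correlation among them.  The class correlation of a band
is the mean over classes of |Pearson r| between the band and the one-vs-rest
class indicator (the label is nominal, so a single Pearson r is undefined);
a symmetric-uncertainty scorer is available behind the same interface.
Search is pure greedy forward selection: starting empty, the merit-maximising
band is added until no candidate improves the merit by more than
``min_gain`` (ties resolve to the lowest band index).
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError

__all__ = [
    "BandSelectionResult",
    "feature_class_correlation",
    "symmetric_uncertainty_scores",
    "cfs_merit",
    "greedy_stepwise_select",
]


@dataclass
class BandSelectionResult:
    """Selected bands with the merit trace of the greedy search."""

    selected_indices: list
    selected_wavelengths: np.ndarray | None
    merit_trace: list
    class_correlations: np.ndarray = field(repr=False, default=None)
    feature_correlations: np.ndarray = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.selected_indices)

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["band_index", "wavelength_nm", "merit_after_inclusion"])
            for i, idx in enumerate(self.selected_indices):
                wl = (
                    ""
                    if self.selected_wavelengths is None
                    else f"{self.selected_wavelengths[i]:.2f}"
                )
                w.writerow([idx, wl, f"{self.merit_trace[i]:.6f}"])

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "selected_indices": [int(i) for i in self.selected_indices],
                    "selected_wavelengths": None
                    if self.selected_wavelengths is None
                    else [float(w) for w in self.selected_wavelengths],
                    "merit_trace": [float(m) for m in self.merit_trace],
                },
                fh,
                indent=1,
            )


def _zero_variance_warning(n_bad: int):
    warnings.warn(
        f"{n_bad} zero-variance bands scored 0", UserWarning, stacklevel=3
    )


def feature_class_correlation(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-band class-correlation score in [0, 1].

    score_b = mean over classes c of |Pearson r(X[:, b], 1{y == c})|.
    Zero-variance bands score 0 with a warning.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2:
        raise InvalidInputError("X must be (samples, bands)")
    classes = np.unique(y)
    if classes.size < 2 or X.shape[0] < 3:
        raise InvalidInputError("need >= 2 classes and >= 3 samples")
    Xc = X - X.mean(axis=0)
    xnorm = np.sqrt((Xc**2).sum(axis=0))
    bad = xnorm == 0
    if bad.any():
        _zero_variance_warning(int(bad.sum()))
    xnorm_safe = np.where(bad, 1.0, xnorm)
    scores = np.zeros(X.shape[1])
    for c in classes:
        z = (y == c).astype(np.float64)
        zc = z - z.mean()
        znorm = np.sqrt((zc**2).sum())
        if znorm == 0:
            continue
        r = (Xc.T @ zc) / (xnorm_safe * znorm)
        scores += np.abs(r)
    scores /= classes.size
    scores[bad] = 0.0
    return np.clip(scores, 0.0, 1.0)


def symmetric_uncertainty_scores(
    X: np.ndarray, y: np.ndarray, n_bins: int = 10
) -> np.ndarray:
    """Classic-CFS alternative scorer: symmetric uncertainty after binning."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes, yi = np.unique(y, return_inverse=True)
    n = X.shape[0]
    py = np.bincount(yi) / n
    hy = -np.sum(py * np.log2(py, where=py > 0))
    scores = np.zeros(X.shape[1])
    for b in range(X.shape[1]):
        col = X[:, b]
        if col.max() == col.min():
            continue
        edges = np.linspace(col.min(), col.max(), n_bins + 1)
        xb = np.clip(np.digitize(col, edges[1:-1]), 0, n_bins - 1)
        joint = np.zeros((n_bins, classes.size))
        np.add.at(joint, (xb, yi), 1.0)
        joint /= n
        px = joint.sum(axis=1)
        hx = -np.sum(px * np.log2(px, where=px > 0))
        hxy = -np.sum(joint * np.log2(joint, where=joint > 0))
        mi = hx + hy - hxy
        if hx + hy > 0:
            scores[b] = 2.0 * mi / (hx + hy)
    return scores


def cfs_merit(
    subset, class_corr: np.ndarray, feat_corr: np.ndarray
) -> float:
    """CFS merit of a band subset given correlation snapshots."""
    subset = list(subset)
    if not subset:
        raise InvalidInputError("subset must be nonempty")
    k = len(subset)
    r_cf = float(np.mean(class_corr[subset]))
    if k == 1:
        return r_cf
    sub = np.abs(feat_corr[np.ix_(subset, subset)])
    r_ff = float((sub.sum() - np.trace(sub)) / (k * (k - 1)))
    return k * r_cf / np.sqrt(k + k * (k - 1) * r_ff)


def _feature_correlation_matrix(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    norm = np.sqrt((Xc**2).sum(axis=0))
    norm_safe = np.where(norm == 0, 1.0, norm)
    corr = (Xc.T @ Xc) / np.outer(norm_safe, norm_safe)
    corr[norm == 0, :] = 0.0
    corr[:, norm == 0] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def greedy_stepwise_select(
    X: np.ndarray,
    y: np.ndarray,
    max_bands: int | None = None,
    min_gain: float = 0.0,
    wavelengths: np.ndarray | None = None,
    scorer: str = "pearson",
) -> BandSelectionResult:
    """Greedy forward CFS over the bands of ``X`` (samples x bands).

    Deterministic: ties resolve to the lowest band index.  All-constant
    input yields an empty result with a warning.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    n_bands = X.shape[1]
    if n_bands < 1:
        raise InvalidInputError("X must have at least one band")
    if max_bands is None:
        max_bands = n_bands
    if scorer == "pearson":
        class_corr = feature_class_correlation(X, y)
    elif scorer == "symmetric_uncertainty":
        class_corr = symmetric_uncertainty_scores(X, y)
    else:
        raise InvalidInputError(f"unknown scorer {scorer!r}")
    feat_corr = _feature_correlation_matrix(X)

    if np.all(class_corr == 0):
        warnings.warn("all bands constant or uninformative; empty selection",
                      UserWarning, stacklevel=2)
        return BandSelectionResult([], None if wavelengths is None else np.array([]),
                                   [], class_corr, feat_corr)

    selected: list = []
    merit_trace: list = []
    current = -np.inf
    while len(selected) < max_bands:
        best_band, best_merit = None, -np.inf
        for b in range(n_bands):
            if b in selected:
                continue
            m = cfs_merit(selected + [b], class_corr, feat_corr)
            if m > best_merit + 1e-15:  # strict improvement; first (lowest) wins ties
                best_band, best_merit = b, m
        if best_band is None or best_merit - current <= min_gain:
            break
        selected.append(best_band)
        merit_trace.append(best_merit)
        current = best_merit

    wl = None if wavelengths is None else np.asarray(wavelengths)[selected]
    return BandSelectionResult(selected, wl, merit_trace, class_corr, feat_corr)
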