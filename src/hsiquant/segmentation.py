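"""Spectral pixel classification: PCA-based segmentation and correlation classification.

Two supervised routes assign every pixel of an absorbance cube to one of the
tissue classes (DAB-positive, nuclei, background), trained from annotated
regions of interest (ROIs):

* :class:`PCANearestCentroidSegmenter` — principal-component scores of the
  pixel spectra, nearest class centroid in score space. By default spectra are
  SNV-normalised (per-pixel standard normal variate) before PCA, which removes
  the multiplicative chromogen-concentration scale so that weakly and strongly
  stained pixels of one class project to the same point; without it a single
  centroid cannot represent a class whose stain concentration spans a wide
  range.
* :class:`CorrelationClassifier` — Pearson correlation (or cosine similarity)
  between each pixel spectrum and per-class reference spectra; argmax above a
  threshold, else UNCLASSIFIED. Pearson correlation is invariant to positive
  affine rescaling of a spectrum, the property that makes it robust to stain
  concentration and illumination scale.

Both estimators follow the scikit-learn fit/predict API on (n_pixels, n_bands)
matrices; cube-level convenience functions (`pca_segment`, `cf_classify`)
wrap them and return a :class:`LabelMap`. Ties are broken by the fixed class
priority DKK3_POSITIVE < NUCLEI < BACKGROUND.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA

from .classes import CLASS_PRIORITY, TissueClass
from .exceptions import DegenerateSpectraError, ROIError
from .spectral_io import SignalKind, SpectralCube, WavelengthAxis, mean_spectrum

__all__ = [
    "ROISet",
    "ReferenceLibrary",
    "PCAModel",
    "LabelMap",
    "snv",
    "fit_pca",
    "pca_false_colour",
    "pca_segment",
    "extract_references",
    "cf_classify",
    "CorrelationClassifier",
    "PCANearestCentroidSegmenter",
]


@dataclass
class ROISet:
    """Disjoint, non-empty training masks per tissue class."""

    masks: dict[TissueClass, np.ndarray]

    def __post_init__(self) -> None:
        coverage = None
        for cls, mask in self.masks.items():
            mask = np.asarray(mask, dtype=bool)
            self.masks[cls] = mask
            if not mask.any():
                raise ROIError(f"ROI for {TissueClass(cls).name} is empty")
            if coverage is None:
                coverage = mask.astype(int)
            else:
                if mask.shape != coverage.shape:
                    raise ROIError("ROI masks have inconsistent shapes")
                coverage = coverage + mask
        if coverage is not None and coverage.max() > 1:
            raise ROIError("ROI masks overlap; classes must be pairwise disjoint")


@dataclass
class ReferenceLibrary:
    """One mean reference spectrum per class, on a shared wavelength axis."""

    axis: WavelengthAxis
    spectra: dict[TissueClass, np.ndarray]

    def __post_init__(self) -> None:
        for cls, spec in self.spectra.items():
            spec = np.asarray(spec, dtype=float)
            self.spectra[cls] = spec
            if spec.shape != (len(self.axis),):
                raise ValueError(
                    f"reference for {TissueClass(cls).name} does not match the axis length"
                )


@dataclass
class PCAModel:
    """Mean spectrum, orthonormal loadings and explained-variance fractions."""

    mean_: np.ndarray
    components_: np.ndarray  # (n_components, n_bands)
    explained_variance_ratio_: np.ndarray
    explained_variance_: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components_.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) @ self.components_.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return scores @ self.components_ + self.mean_


@dataclass
class LabelMap:
    """Per-pixel class image plus optional per-class score images."""

    classes: np.ndarray
    scores: dict[TissueClass, np.ndarray] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape

    def mask(self, cls: TissueClass) -> np.ndarray:
        return self.classes == int(cls)


def snv(X: np.ndarray) -> np.ndarray:
    """Standard-normal-variate transform per spectrum: (x - mean) / sd.

    Zero-variance spectra are mapped to the zero vector rather than dividing
    by zero.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=-1, keepdims=True)
    sd = X.std(axis=-1, keepdims=True)
    out = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return out


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Orient each loading so its largest-magnitude entry is positive."""
    flips = np.sign(components[np.arange(components.shape[0]),
                               np.argmax(np.abs(components), axis=1)])
    flips[flips == 0] = 1.0
    return components * flips[:, None]


def _fit_pca_pixels(X: np.ndarray, n_components: int) -> PCAModel:
    X = np.asarray(X, dtype=float)
    n_pixels, n_bands = X.shape
    if n_components > n_bands:
        raise ValueError(f"n_components={n_components} exceeds band count {n_bands}")
    if n_pixels < n_components:
        raise ValueError("fewer pixels than requested components")
    total_var = X.var(axis=0).sum()
    if total_var < 1e-18:
        raise DegenerateSpectraError(
            "spectra are spatially constant; the covariance is zero"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    components = _fix_signs(pca.components_)
    return PCAModel(
        mean_=pca.mean_,
        components_=components,
        explained_variance_ratio_=pca.explained_variance_ratio_,
        explained_variance_=pca.explained_variance_,
    )


def fit_pca(cube: SpectralCube, n_components: int) -> PCAModel:
    """PCA of the band-wise covariance of mean-centred pixel spectra.

    Components are eigenvectors of the covariance matrix ordered by
    eigenvalue, with each loading's sign fixed so its largest-magnitude entry
    is positive (makes false-colour output reproducible across refits).
    Requires an absorbance cube: optical density is the quantity that mixes
    linearly under Beer-Lambert, so linear subspace models apply there.
    """
    if cube.signal_kind is not SignalKind.ABSORBANCE:
        raise ValueError("fit_pca expects an ABSORBANCE cube")
    return _fit_pca_pixels(cube.pixels(), n_components)


def pca_false_colour(cube: SpectralCube, model: PCAModel) -> np.ndarray:
    """RGB composite of the first three PC score images, 1st-99th percentile stretch."""
    if model.n_components < 3:
        raise ValueError("false-colour composite needs at least 3 components")
    scores = model.transform(cube.pixels())[:, :3]
    rgb = np.empty((scores.shape[0], 3))
    for ch in range(3):
        lo, hi = np.percentile(scores[:, ch], [1.0, 99.0])
        span = hi - lo if hi > lo else 1.0
        rgb[:, ch] = np.clip((scores[:, ch] - lo) / span, 0.0, 1.0)
    return rgb.reshape(cube.spatial_shape + (3,))


def extract_references(cube: SpectralCube, rois: ROISet) -> ReferenceLibrary:
    """Per-class mean spectrum over each ROI of the (windowed absorbance) cube."""
    spectra = {}
    for cls, mask in rois.masks.items():
        spectra[TissueClass(cls)] = mean_spectrum(cube, mask)
    return ReferenceLibrary(cube.axis, spectra)


def _ordered_classes(classes) -> list[TissueClass]:
    """Classes in fixed tie-break priority order."""
    present = {TissueClass(c) for c in classes}
    return [c for c in CLASS_PRIORITY if c in present] + sorted(
        present - set(CLASS_PRIORITY)
    )


class CorrelationClassifier(ClassifierMixin, BaseEstimator):
    """Reference-spectrum correlation classifier over pixel spectra.

    Parameters
    ----------
    min_corr : float in [-1, 1]
        Pixels whose best similarity falls below this threshold are labelled
        UNCLASSIFIED.
    metric : {"pearson", "cosine"}
        Pearson correlation (centred) or cosine similarity (uncentred).

    Fitted attributes: ``classes_`` (priority order), ``references_``
    (class -> mean training spectrum).
    """

    def __init__(self, min_corr: float = 0.8, metric: str = "pearson"):
        self.min_corr = min_corr
        self.metric = metric

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CorrelationClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_pixels, n_bands) aligned with y")
        if self.metric not in ("pearson", "cosine"):
            raise ValueError(f"unknown similarity metric '{self.metric}'")
        if not -1.0 <= self.min_corr <= 1.0:
            raise ValueError("min_corr must lie in [-1, 1]")
        self.classes_ = np.array([int(c) for c in _ordered_classes(np.unique(y))])
        self.references_ = {
            TissueClass(c): X[y == c].mean(axis=0) for c in self.classes_
        }
        return self

    @classmethod
    def from_references(cls, refs: ReferenceLibrary, **params) -> "CorrelationClassifier":
        est = cls(**params)
        est.classes_ = np.array(
            [int(c) for c in _ordered_classes(refs.spectra.keys())]
        )
        est.references_ = {TissueClass(c): refs.spectra[TissueClass(c)]
                           for c in est.classes_}
        return est

    def _normalise(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.metric == "pearson":
            X = X - X.mean(axis=-1, keepdims=True)
        norms = np.linalg.norm(X, axis=-1, keepdims=True)
        return np.where(norms > 0, X / np.where(norms > 0, norms, 1.0), 0.0)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Similarity of each pixel to each class reference, (n_pixels, n_classes).

        A zero-variance pixel (or reference) yields similarity 0 by
        convention; no division error ever propagates.
        """
        refs = np.stack([self.references_[TissueClass(c)] for c in self.classes_])
        return self._normalise(X) @ self._normalise(refs).T

    def predict(self, X: np.ndarray) -> np.ndarray:
        sims = self.decision_function(X)
        best = np.argmax(sims, axis=1)  # first max wins -> priority tie-break
        labels = self.classes_[best]
        below = sims[np.arange(len(labels)), best] < self.min_corr
        labels = labels.copy()
        labels[below] = int(TissueClass.UNCLASSIFIED)
        return labels


class PCANearestCentroidSegmenter(ClassifierMixin, BaseEstimator):
    """Nearest class centroid in principal-component score space.

    Parameters
    ----------
    n_components : int
        Number of leading components retained for the score space.
    normalise : {"snv", None}
        Per-pixel SNV normalisation before PCA (default). See module
        docstring for why this matters with variable stain concentration.

    The PCA may be fit on a wider pixel population than the labelled training
    pixels via ``fit(X, y, pca_pixels=...)`` (e.g. the whole cube, with
    centroids taken from ROI pixels only).
    """

    def __init__(self, n_components: int = 3, normalise: str | None = "snv"):
        self.n_components = n_components
        self.normalise = normalise

    def _transform_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return snv(X) if self.normalise == "snv" else X

    def fit(
        self, X: np.ndarray, y: np.ndarray, pca_pixels: np.ndarray | None = None
    ) -> "PCANearestCentroidSegmenter":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if self.normalise not in ("snv", None):
            raise ValueError(f"unknown normalisation '{self.normalise}'")
        pool = self._transform_input(pca_pixels if pca_pixels is not None else X)
        self.pca_ = _fit_pca_pixels(pool, self.n_components)
        Xt = self.pca_.transform(self._transform_input(X))
        self.classes_ = np.array([int(c) for c in _ordered_classes(np.unique(y))])
        self.centroids_ = np.stack([Xt[y == c].mean(axis=0) for c in self.classes_])
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Negative Euclidean distance to each class centroid in score space."""
        scores = self.pca_.transform(self._transform_input(X))
        d = np.linalg.norm(scores[:, None, :] - self.centroids_[None, :, :], axis=2)
        return -d

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = -self.decision_function(X)
        return self.classes_[np.argmin(d, axis=1)]  # first min -> priority tie-break


def pca_segment(
    cube: SpectralCube,
    rois: ROISet,
    n_components: int = 3,
    normalise: str | None = "snv",
    model: PCAModel | None = None,
) -> LabelMap:
    """Segment a cube by nearest ROI-centroid in PC-score space.

    The PCA is fit on all cube pixels (unsupervised), centroids are the mean
    PC scores of each ROI's pixels, and every pixel takes the class of the
    nearest centroid (Euclidean; ties broken by class priority). A caller may
    pass a pre-fit ``model``, which then must match the chosen normalisation.
    """
    seg = PCANearestCentroidSegmenter(n_components=n_components, normalise=normalise)
    X = cube.pixels()
    roi_X, roi_y = _roi_training_set(cube, rois)
    if model is not None:
        if model.n_components < n_components:
            raise ValueError("provided model has fewer components than requested")
        seg.pca_ = model
        Xt = model.transform(seg._transform_input(roi_X))[:, :n_components]
        seg.pca_ = PCAModel(
            model.mean_,
            model.components_[:n_components],
            model.explained_variance_ratio_[:n_components],
            model.explained_variance_[:n_components],
        )
        seg.classes_ = np.array(
            [int(c) for c in _ordered_classes(np.unique(roi_y))]
        )
        seg.centroids_ = np.stack([Xt[roi_y == c].mean(axis=0) for c in seg.classes_])
    else:
        seg.fit(roi_X, roi_y, pca_pixels=X)
    labels = seg.predict(X).reshape(cube.spatial_shape)
    dist = -seg.decision_function(X)
    scores = {
        TissueClass(c): dist[:, i].reshape(cube.spatial_shape)
        for i, c in enumerate(seg.classes_)
    }
    return LabelMap(labels.astype(np.uint8), scores)


def _roi_training_set(cube: SpectralCube, rois: ROISet) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for cls, mask in rois.masks.items():
        if mask.shape != cube.spatial_shape:
            raise ROIError("ROI mask shape does not match the cube")
        px = cube.data[mask]
        xs.append(px)
        ys.append(np.full(px.shape[0], int(cls), dtype=int))
    return np.vstack(xs), np.concatenate(ys)


def cf_classify(
    cube: SpectralCube,
    refs: ReferenceLibrary,
    min_corr: float = 0.8,
    metric: str = "pearson",
) -> LabelMap:
    """Correlation-function pixel classification against reference spectra."""
    if len(refs.axis) != cube.n_bands or not np.allclose(
        refs.axis.values, cube.axis.values
    ):
        raise ValueError("cube and reference library are on different wavelength axes")
    clf = CorrelationClassifier.from_references(refs, min_corr=min_corr, metric=metric)
    X = cube.pixels()
    labels = clf.predict(X).reshape(cube.spatial_shape)
    sims = clf.decision_function(X)
    scores = {
        TissueClass(c): sims[:, i].reshape(cube.spatial_shape)
        for i, c in enumerate(clf.classes_)
    }
    return LabelMap(labels.astype(np.uint8), scores)
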