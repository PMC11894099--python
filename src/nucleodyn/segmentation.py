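"""Trainable pixel classification and 3D nucleus segmentation.

A small, deterministic filter-bank pixel classifier stands behind the
probability-map-then-segment design: per-slice Gaussian smoothing, gradient
magnitude and Laplacian-of-Gaussian features feed a regularized logistic
model trained on foreground/background scribbles.  The resulting per-voxel
foreground probability map is thresholded and 26-connected components form
the labelled nuclei, with a minimum-volume filter.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.linear_model import LogisticRegression

__all__ = [
    "FeatureSpec",
    "PixelClassifier",
    "SeparabilityWarning",
    "train_pixel_classifier",
    "predict_probability",
    "segment_nuclei",
    "segment_movie",
    "project_mask_2d",
]


class SeparabilityWarning(UserWarning):
    """Raised when annotated classes are not separable in feature space."""


@dataclass(frozen=True)
class FeatureSpec:
    """Filter bank: which per-slice features feed the classifier."""

    gaussian_sigmas: tuple[float, ...] = (1.0, 2.0, 4.0)
    gradient_sigmas: tuple[float, ...] = (2.0,)
    log_sigmas: tuple[float, ...] = (2.0, 4.0)
    include_raw: bool = True

    @property
    def n_features(self) -> int:
        return (
            int(self.include_raw)
            + len(self.gaussian_sigmas)
            + len(self.gradient_sigmas)
            + len(self.log_sigmas)
        )

    def to_dict(self) -> dict:
        return {
            "gaussian_sigmas": list(self.gaussian_sigmas),
            "gradient_sigmas": list(self.gradient_sigmas),
            "log_sigmas": list(self.log_sigmas),
            "include_raw": self.include_raw,
        }

    @staticmethod
    def from_dict(d: dict) -> "FeatureSpec":
        return FeatureSpec(
            gaussian_sigmas=tuple(d["gaussian_sigmas"]),
            gradient_sigmas=tuple(d["gradient_sigmas"]),
            log_sigmas=tuple(d["log_sigmas"]),
            include_raw=bool(d["include_raw"]),
        )


def compute_features(volume: np.ndarray, spec: FeatureSpec) -> np.ndarray:
    """Feature stack of shape (n_features, z, y, x).

    Filters are applied in-plane (per z-slice) so behaviour is independent
    of the (typically coarse, short) z axis.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValueError(f"expected (z, y, x) volume; got shape {volume.shape}")
    feats = []
    if spec.include_raw:
        feats.append(volume.copy())
    for s in spec.gaussian_sigmas:
        feats.append(
            np.stack([ndimage.gaussian_filter(sl, s) for sl in volume])
        )
    for s in spec.gradient_sigmas:
        feats.append(
            np.stack([ndimage.gaussian_gradient_magnitude(sl, s) for sl in volume])
        )
    for s in spec.log_sigmas:
        feats.append(
            np.stack([ndimage.gaussian_laplace(sl, s) for sl in volume])
        )
    return np.stack(feats)


@dataclass
class PixelClassifier:
    """Linear logistic pixel classifier over a filter-bank feature space."""

    spec: FeatureSpec
    weights: np.ndarray  # (n_features,)
    bias: float
    feature_mean: np.ndarray
    feature_sd: np.ndarray

    def predict_volume(self, volume: np.ndarray) -> np.ndarray:
        """Per-voxel foreground probability map, same shape as ``volume``."""
        feats = compute_features(volume, self.spec)
        if feats.shape[0] != self.weights.size:
            raise ValueError("feature bank does not match training spec")
        flat = feats.reshape(feats.shape[0], -1).T
        z = (flat - self.feature_mean) / self.feature_sd
        logits = z @ self.weights + self.bias
        prob = 1.0 / (1.0 + np.exp(-logits))
        return prob.reshape(volume.shape)

    def save(self, path) -> None:
        payload = {
            "format": "nucleodyn-pixel-classifier-v1",
            "spec": self.spec.to_dict(),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @staticmethod
    def load(path) -> "PixelClassifier":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format") != "nucleodyn-pixel-classifier-v1":
            raise ValueError("not a nucleodyn classifier file")
        return PixelClassifier(
            spec=FeatureSpec.from_dict(payload["spec"]),
            weights=np.asarray(payload["weights"], dtype=np.float64),
            bias=float(payload["bias"]),
            feature_mean=np.asarray(payload["feature_mean"], dtype=np.float64),
            feature_sd=np.asarray(payload["feature_sd"], dtype=np.float64),
        )


def train_pixel_classifier(
    volumes: list[np.ndarray],
    annotations: list[np.ndarray],
    spec: FeatureSpec = FeatureSpec(),
    l2: float = 1.0,
    min_pixels_per_class: int = 50,
) -> PixelClassifier:
    """Fit the classifier on scribble annotations.

    ``annotations[i]`` matches ``volumes[i]`` in shape with values
    0 = unlabelled, 1 = foreground, 2 = background.  Both classes must have
    at least ``min_pixels_per_class`` annotated pixels.  Training minimises
    L2-regularized logistic loss (deterministic lbfgs fit on standardized
    features).
    """
    if len(volumes) != len(annotations) or not volumes:
        raise ValueError("need matching, non-empty volume and annotation lists")
    xs, ys = [], []
    for vol, ann in zip(volumes, annotations):
        ann = np.asarray(ann)
        if ann.shape != np.asarray(vol).shape:
            raise ValueError("annotation shape must match volume shape")
        feats = compute_features(vol, spec)
        for cls, lab in ((1, 1), (2, 0)):
            sel = ann == cls
            if sel.any():
                xs.append(feats[:, sel].T)
                ys.append(np.full(int(sel.sum()), lab))
    if not xs:
        raise ValueError("no annotated pixels")
    X = np.concatenate(xs)
    y = np.concatenate(ys)
    for lab, name in ((1, "foreground"), (0, "background")):
        if (y == lab).sum() < min_pixels_per_class:
            raise ValueError(
                f"need >= {min_pixels_per_class} annotated {name} pixels"
            )
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - mean) / sd

    # uninformative-feature guard: identical class-conditional features
    fg, bgm = Xz[y == 1], Xz[y == 0]
    if np.allclose(fg.mean(axis=0), bgm.mean(axis=0), atol=1e-6) and np.allclose(
        fg.std(axis=0), bgm.std(axis=0), atol=1e-6
    ):
        warnings.warn(
            "annotated classes are indistinguishable in feature space; "
            "probabilities will approximate the class prior",
            SeparabilityWarning,
            stacklevel=2,
        )
    model = LogisticRegression(
        C=1.0 / l2, solver="lbfgs", tol=1e-8, max_iter=1000
    )
    model.fit(Xz, y)
    return PixelClassifier(
        spec=spec,
        weights=model.coef_[0].astype(np.float64),
        bias=float(model.intercept_[0]),
        feature_mean=mean,
        feature_sd=sd,
    )


def predict_probability(movie, classifier: PixelClassifier, frame: int) -> np.ndarray:
    """Foreground probability map of one movie frame (pure function)."""
    return classifier.predict_volume(movie.frame(frame))


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def segment_nuclei(
    prob: np.ndarray,
    prob_threshold: float = 0.5,
    min_volume_vox: int = 30,
) -> np.ndarray:
    """Threshold a probability map into labelled 3D nuclei.

    26-connected components of ``prob >= prob_threshold`` (inclusive);
    components smaller than ``min_volume_vox`` voxels are removed and the
    survivors renumbered 1..K by descending volume (ties broken by original
    scan-order label for determinism).
    """
    if not 0.0 < prob_threshold < 1.0:
        raise ValueError("prob_threshold must lie in (0, 1)")
    prob = np.asarray(prob)
    if prob.ndim != 3:
        raise ValueError("probability map must be 3D (z, y, x)")
    mask = prob >= prob_threshold
    labels, n = ndimage.label(mask, structure=_STRUCT_26)
    if n == 0:
        return labels.astype(np.int32)
    counts = np.bincount(labels.ravel())[1:]  # per original label 1..n
    keep = np.nonzero(counts >= min_volume_vox)[0] + 1
    order = keep[np.lexsort((keep, -counts[keep - 1]))]
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[order] = np.arange(1, order.size + 1, dtype=np.int32)
    return remap[labels]


def segment_movie(
    movie,
    classifier: PixelClassifier,
    prob_threshold: float = 0.5,
    min_volume_vox: int = 30,
) -> np.ndarray:
    """Per-frame labelled nuclei for a whole movie, shape (t, z, y, x)."""
    out = np.empty(movie.data.shape, dtype=np.int32)
    for t in range(movie.n_frames):
        prob = predict_probability(movie, classifier, t)
        out[t] = segment_nuclei(prob, prob_threshold, min_volume_vox)
    return out


def project_mask_2d(label_volume: np.ndarray, label_id: int) -> np.ndarray:
    """Maximum projection along z of one label's voxels (2D bool mask)."""
    label_volume = np.asarray(label_volume)
    if label_volume.ndim != 3:
        raise ValueError("label volume must be 3D (z, y, x)")
    sel = label_volume == label_id
    if not sel.any():
        raise KeyError(f"label {label_id} not present")
    return sel.any(axis=0)
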