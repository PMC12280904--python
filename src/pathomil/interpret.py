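"""Interpretability: SHAP for the linear signature, Grad-CAM for the CNN,
slide-level likelihood heatmaps, and clustering of top-ranked patches.

Because the signature is linear, Shapley values have the exact closed form
``phi_j = beta_j * (x_j - mean_background(x_j))``; the efficiency identity
``base + sum_j phi_j = score(x)`` then holds to rounding error. Grad-CAM
weights the last convolution's channels by their spatially averaged
class-score gradients, rectifies the weighted sum, and upsamples it to the
patch. Influential patches (likelihood x mean CAM intensity) are embedded
with random-forest proximities and agglomerated into k morphology clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize
from sklearn.cluster import AgglomerativeClustering
from sklearn.ensemble import RandomTreesEmbedding

from .core import MissingFeatureError, RGBPatch, SlideLikelihoods
from .patch_model import PatchClassifier
from .signature import SignatureModel, score_slides

__all__ = [
    "ShapExplanation",
    "CamHeatmap",
    "PatchClusterResult",
    "shap_linear",
    "shap_global_ranking",
    "grad_cam",
    "render_slide_heatmap",
    "cluster_top_patches",
]


@dataclass(frozen=True)
class ShapExplanation:
    """Exact Shapley attribution of one slide's signature score."""

    base_value: float
    contributions: pd.Series
    score: float

    def reconstruction_error(self) -> float:
        return abs(self.base_value + float(self.contributions.sum()) - self.score)


@dataclass(frozen=True)
class CamHeatmap:
    """Class-activation map in [0, 1] at patch resolution."""

    heatmap: np.ndarray
    target_class: int

    def __post_init__(self) -> None:
        h = np.asarray(self.heatmap, dtype=float)
        if h.min() < 0 or h.max() > 1:
            raise ValueError("heatmap values must lie in [0, 1]")
        object.__setattr__(self, "heatmap", h)


@dataclass(frozen=True)
class PatchClusterResult:
    """Cluster assignment of the top-ranked patches."""

    patch_indices: np.ndarray
    labels: np.ndarray
    n_clusters: int


def _feature_frame(x: pd.Series | pd.DataFrame) -> pd.DataFrame:
    return x.to_frame().T if isinstance(x, pd.Series) else x


def shap_linear(model: SignatureModel, background: pd.DataFrame,
                x: pd.Series) -> ShapExplanation:
    """Exact Shapley values of the linear signature for one slide.

    ``phi_j = beta_j * (x_j - background_mean_j)``; the base value is the
    score of the background mean.
    """
    if background.empty:
        raise ValueError("background matrix must be non-empty")
    bg_mean = background.mean(axis=0)
    bg_scores = score_slides(model, _feature_frame(bg_mean))
    base = float(bg_scores.iloc[0])
    score = float(score_slides(model, _feature_frame(x)).iloc[0])
    phi = {}
    for name, beta in zip(model.features, model.coefficients):
        if name not in x.index:
            raise MissingFeatureError(name)
        phi[name] = float(beta) * (float(x[name]) - float(bg_mean[name]))
    return ShapExplanation(base_value=base, contributions=pd.Series(phi), score=score)


def shap_global_ranking(model: SignatureModel, X: pd.DataFrame) -> pd.Series:
    """Features ordered by mean absolute Shapley contribution over a cohort."""
    if X.empty:
        raise ValueError("X must be non-empty")
    bg_mean = X.mean(axis=0)
    mat = X[list(model.features)].to_numpy(dtype=float)
    centered = mat - bg_mean[list(model.features)].to_numpy(dtype=float)
    mean_abs = np.abs(centered * model.coefficients).mean(axis=0)
    ranking = pd.Series(mean_abs, index=list(model.features), name="mean_abs_shap")
    return ranking.sort_values(ascending=False, kind="stable")


def grad_cam(classifier: PatchClassifier, patch: RGBPatch, target_class: int = 1) -> CamHeatmap:
    """Gradient-weighted class-activation map for one patch.

    Channel weights are the spatial means of d(logit_target)/d(activation)
    at the last convolution; the ReLU-rectified weighted channel sum is
    min-max normalized (all-zero maps pass through unchanged) and
    bilinearly upsampled to patch resolution.
    """
    activation, grad = classifier.class_activation_gradient(patch, target_class)
    a, g = activation[0], grad[0]  # (C, h, w)
    weights = g.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * a).sum(axis=0), 0.0)
    peak = cam.max()
    if peak > 0:
        cam = (cam - cam.min()) / (peak - cam.min()) if peak > cam.min() else cam / peak
    up = resize(cam, (patch.size, patch.size), order=1, mode="edge",
                anti_aliasing=False, preserve_range=True)
    return CamHeatmap(heatmap=np.clip(up, 0.0, 1.0), target_class=target_class)


def render_slide_heatmap(likelihoods: SlideLikelihoods, manifest: pd.DataFrame,
                         tile_size: int = 512, thumb_tile: int = 16,
                         cmap: str = "coolwarm") -> np.ndarray:
    """Slide thumbnail with each tile colored by its patch likelihood.

    ``manifest`` needs columns ``row`` and ``col`` aligned with the bag
    order; untested grid cells stay white. Returns an RGB uint8 overlay at
    ``thumb_tile`` pixels per tile.
    """
    import matplotlib

    if len(manifest) != len(likelihoods):
        raise ValueError("manifest rows and likelihood entries must align")
    rows = manifest["row"].to_numpy(dtype=int)
    cols = manifest["col"].to_numpy(dtype=int)
    h = (rows.max() + 1) * thumb_tile
    w = (cols.max() + 1) * thumb_tile
    out = np.full((h, w, 3), 255, dtype=np.uint8)
    colors = (np.asarray(matplotlib.colormaps[cmap](likelihoods.probabilities))[:, :3] * 255).astype(np.uint8)
    for r, c, rgb in zip(rows, cols, colors):
        out[r * thumb_tile : (r + 1) * thumb_tile, c * thumb_tile : (c + 1) * thumb_tile] = rgb
    return out


def patch_influence(likelihood: float | np.ndarray, cam: CamHeatmap | np.ndarray) -> float | np.ndarray:
    """Influence ranking score: positive-class likelihood x mean CAM mass."""
    heat = cam.heatmap if isinstance(cam, CamHeatmap) else np.asarray(cam)
    return likelihood * float(np.mean(heat))


def cluster_top_patches(descriptors: np.ndarray, influence: np.ndarray,
                        n_top: int = 500, k: int = 4, seed: int = 0,
                        method: str = "random_forest") -> PatchClusterResult:
    """Cluster the ``n_top`` most influential patches into ``k`` groups.

    Patches are ranked by ``influence`` (descending), embedded with
    totally-random-tree leaf indicators (a random-forest proximity space),
    and agglomerated with Ward linkage; ``method="kmeans"`` is the simpler
    fallback. Patches are canonically ordered before embedding so the
    result does not depend on input order.
    """
    desc = np.asarray(descriptors, dtype=float)
    infl = np.asarray(influence, dtype=float)
    if desc.shape[0] != infl.shape[0]:
        raise ValueError("descriptors and influence must align")
    if k > min(n_top, desc.shape[0]):
        raise ValueError("k exceeds the number of selectable patches")
    n_top = min(n_top, desc.shape[0])
    top = np.argsort(-infl, kind="stable")[:n_top]
    sub = desc[top]
    # canonical ordering -> permutation invariance up to label renaming
    canon = np.lexsort(sub.T[::-1])
    ordered = sub[canon]
    if k == 1:
        labels_ordered = np.zeros(n_top, dtype=int)
    elif method == "random_forest":
        emb = RandomTreesEmbedding(n_estimators=64, max_depth=5, random_state=seed)
        Z = emb.fit_transform(ordered).toarray()
        labels_ordered = AgglomerativeClustering(n_clusters=k).fit_predict(Z)
    elif method == "kmeans":
        from sklearn.cluster import KMeans

        labels_ordered = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(ordered)
    else:
        raise ValueError(f"unknown method: {method!r}")
    labels = np.empty(n_top, dtype=int)
    labels[canon] = labels_ordered
    return PatchClusterResult(patch_indices=top, labels=labels, n_clusters=k)
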