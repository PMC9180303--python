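"""Photo embedding and k-means cluster discovery.

Photos are embedded as fixed-length vectors, the number of clusters is
chosen by scanning k with the elbow (within-cluster sum of squares,
WCSS) and mean-silhouette criteria, and final labels come from seeded
k-means, relabeled by descending cluster size for stable reporting.

The tested default embedding is a deterministic "toy" backend: an 8x8
bilinear-downsampled luminance map concatenated with three 8-bin
per-channel histograms (88 dimensions). A deep-network backend can be
plugged in behind the same interface by passing any callable
image -> vector to :class:`ToyImageEmbedder`'s place in the pipeline.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .pixel_features import as_rgb_array, _luminance

__all__ = [
    "ToyImageEmbedder",
    "KMeansClusterSelector",
    "KSelectionDisagreement",
    "embed_toy",
    "scan_k",
    "select_k",
    "cluster_corpus",
]


class KSelectionDisagreement(ValueError):
    """Raised when the elbow and silhouette criteria disagree in 'agree' mode."""

    def __init__(self, elbow_k: int, silhouette_k: int):
        self.elbow_k = elbow_k
        self.silhouette_k = silhouette_k
        super().__init__(
            f"elbow selects k={elbow_k} but silhouette selects k={silhouette_k}"
        )


def embed_toy(image) -> np.ndarray:
    """88-dim deterministic embedding of one image.

    8x8 bilinear-downsampled luminance scaled to [0, 1] (64 dims),
    followed by 8-bin normalized histograms of R, G and B (24 dims).
    """
    arr = as_rgb_array(image)
    lum = _luminance(arr) / 255.0
    block = resize(lum, (8, 8), order=1, anti_aliasing=False, preserve_range=True)
    n_pix = arr.shape[0] * arr.shape[1]
    hists = [
        np.histogram(arr[..., c], bins=8, range=(0, 256))[0] / n_pix for c in range(3)
    ]
    return np.concatenate([block.ravel(), *hists])


class ToyImageEmbedder(BaseEstimator, TransformerMixin):
    """Stateless transformer applying :func:`embed_toy` row-wise."""

    backend_name = "toy-lum8x8-rgbhist8"

    def fit(self, X, y=None):
        self.n_features_out_ = 88
        return self

    def transform(self, X) -> np.ndarray:
        rows = [embed_toy(img) for img in X]
        return np.vstack(rows) if rows else np.empty((0, 88))


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def _mean_silhouette(
    X: np.ndarray, labels: np.ndarray, sample: int | None, rng: np.random.Generator
) -> float:
    if len(np.unique(labels)) < 2:
        return float("nan")
    if sample is not None and X.shape[0] > sample:
        idx = rng.choice(X.shape[0], size=sample, replace=False)
        X, labels = X[idx], labels[idx]
        if len(np.unique(labels)) < 2:  # degenerate subsample
            return float("nan")
    return float(silhouette_score(X, labels))


def scan_k(
    X: np.ndarray,
    k_range: tuple[int, int] = (2, 10),
    seed: int | None = 0,
    n_init: int = 10,
    silhouette_sample: int | None = 2000,
    standardize: bool = True,
) -> tuple[dict[int, float], dict[int, float]]:
    """WCSS and mean-silhouette curves over a k interval (inclusive).

    The WCSS curve additionally includes k=1 (the total sum of squares
    around the grand centroid, which is the exact k-means optimum for a
    single cluster) so the elbow criterion is defined at k = k_min; the
    silhouette curve covers only the scanned range, as silhouette is
    undefined for one cluster.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    k_min, k_max = k_range
    if k_min < 2 or k_max > n - 1 or k_min > k_max:
        raise ValueError(f"k_range {k_range} must lie within [2, n-1] = [2, {n - 1}]")
    if standardize:
        X = _standardize(X)
    rng = np.random.default_rng(seed)
    wcss: dict[int, float] = {}
    sil: dict[int, float] = {}
    if k_min == 2:
        wcss[1] = float(((X - X.mean(axis=0)) ** 2).sum())
    for k in range(k_min, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, init="k-means++")
        labels = km.fit_predict(X)
        wcss[k] = float(km.inertia_)
        sil[k] = _mean_silhouette(X, labels, silhouette_sample, rng)
    return wcss, sil


def select_k(
    wcss_curve: dict[int, float] | None,
    silhouette_curve: dict[int, float] | None,
    method: str = "silhouette",
) -> int:
    """Choose the cluster count from scan curves.

    silhouette: argmax of mean silhouette (ties -> smaller k).
    elbow: k maximizing the discrete second difference of WCSS
    (ties -> smaller k; needs at least 3 consecutive points).
    agree: both criteria must concur, else :class:`KSelectionDisagreement`.
    """
    if method == "silhouette":
        finite = {k: v for k, v in (silhouette_curve or {}).items() if np.isfinite(v)}
        if not finite:
            raise ValueError("silhouette_curve has no finite values")
        best = max(sorted(finite), key=lambda k: (finite[k], -k))
        return int(best)
    if method == "elbow":
        if not wcss_curve or len(wcss_curve) < 3:
            raise ValueError("elbow selection needs a WCSS curve with >= 3 points")
        ks = sorted(wcss_curve)
        if ks != list(range(ks[0], ks[-1] + 1)):
            raise ValueError("elbow selection needs consecutive k values")
        second_diff = {
            k: wcss_curve[k - 1] - 2 * wcss_curve[k] + wcss_curve[k + 1]
            for k in ks[1:-1]
        }
        best = max(sorted(second_diff), key=lambda k: (second_diff[k], -k))
        return int(best)
    if method == "agree":
        k_e = select_k(wcss_curve, None, "elbow")
        k_s = select_k(None, silhouette_curve, "silhouette")
        if k_e != k_s:
            raise KSelectionDisagreement(k_e, k_s)
        return k_s
    raise ValueError(f"unknown selection method {method!r}")


def cluster_corpus(
    X: np.ndarray,
    k: int,
    seed: int | None = 0,
    n_init: int = 10,
    standardize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Final k-means labels and cluster sizes.

    Labels are relabeled by descending cluster size so cluster 0 is
    always the largest (cluster indexing is otherwise arbitrary).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 2 <= k <= n - 1:
        raise ValueError(f"k={k} must lie within [2, n-1] = [2, {n - 1}]")
    if standardize:
        X = _standardize(X)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, init="k-means++")
    raw = km.fit_predict(X)
    sizes = np.bincount(raw, minlength=k)
    # stable relabel: descending size, ties by original index
    order = np.lexsort((np.arange(k), -sizes))
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[raw]
    return labels, np.bincount(labels, minlength=k)


class KMeansClusterSelector(BaseEstimator, ClusterMixin):
    """K-means clustering with data-driven selection of the cluster count.

    Scans ``k_range`` (inclusive), records the WCSS and mean-silhouette
    curves, selects k by ``method`` and fits final labels relabeled by
    descending cluster size.

    Parameters
    ----------
    k_range : (int, int)
        Inclusive interval of candidate cluster counts, within [2, n-1].
    method : {"silhouette", "elbow", "agree"}
        Selection criterion; "agree" raises on disagreement.
    n_init : int
        k-means++ restarts per k.
    random_state : int or None
        Seed for k-means and the silhouette subsample.
    silhouette_sample : int or None
        Subsample size for the silhouette computation (None = all points).
    standardize : bool
        Z-score each embedding dimension before clustering.
    k : int or None
        Bypass selection and cluster at this fixed k.

    Attributes
    ----------
    k_ : selected cluster count
    labels_ : per-photo labels in [0, k_)
    sizes_ : per-cluster counts (descending)
    wcss_curve_, silhouette_curve_ : selection curves (dict k -> value)
    """

    def __init__(
        self,
        k_range: tuple[int, int] = (2, 10),
        method: str = "silhouette",
        n_init: int = 10,
        random_state: int | None = 0,
        silhouette_sample: int | None = 2000,
        standardize: bool = True,
        k: int | None = None,
    ):
        self.k_range = k_range
        self.method = method
        self.n_init = n_init
        self.random_state = random_state
        self.silhouette_sample = silhouette_sample
        self.standardize = standardize
        self.k = k

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or not np.isfinite(X).all():
            raise ValueError("X must be a finite 2-D array")
        self.wcss_curve_, self.silhouette_curve_ = scan_k(
            X,
            k_range=self.k_range,
            seed=self.random_state,
            n_init=self.n_init,
            silhouette_sample=self.silhouette_sample,
            standardize=self.standardize,
        )
        self.k_ = (
            int(self.k)
            if self.k is not None
            else select_k(self.wcss_curve_, self.silhouette_curve_, self.method)
        )
        self.labels_, self.sizes_ = cluster_corpus(
            X,
            self.k_,
            seed=self.random_state,
            n_init=self.n_init,
            standardize=self.standardize,
        )
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
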