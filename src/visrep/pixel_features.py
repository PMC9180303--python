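"""Pixel-level photo features for visual-representation analysis.

Seventeen features computed from an 8-bit RGB image: per-channel RGB and
HSV saturation/value means and variances, the number of modes in the
KDE-smoothed circular hue histogram, luminance brightness, the
Hasler–Süsstrunk colorfulness statistic, a color-naturalness index (CNI),
luminance contrast, an RGB-space contrast, and a normalized-Laplacian
sharpness measure.

Conventions
-----------
* All statistics are population statistics over the full pixel set.
* Hue is in degrees [0, 360); saturation and value are reported on a
  0–255 scale so their magnitudes are commensurate with the RGB channels.
* Luminance is YUV Y = 0.299 R + 0.587 G + 0.114 B on the 0–255 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dataclass_fields

import numpy as np
from scipy import ndimage

__all__ = [
    "FEATURE_NAMES",
    "PixelFeatureVector",
    "PixelFeatureExtractor",
    "as_rgb_array",
    "channel_stats",
    "hue_peak_count",
    "brightness",
    "colorfulness",
    "naturalness",
    "contrast",
    "rgb_contrast",
    "sharpness",
    "extract_features",
]

#: Feature (column) order used in all tabular outputs.
FEATURE_NAMES = (
    "red_mean",
    "red_variance",
    "green_mean",
    "green_variance",
    "blue_mean",
    "blue_variance",
    "saturation_mean",
    "saturation_variance",
    "value_mean",
    "value_variance",
    "hue_peaks",
    "brightness",
    "colorfulness",
    "naturalness",
    "contrast",
    "rgb_contrast",
    "sharpness",
)

# CNI hue groups (degrees) and the empirical "natural" saturation
# parameters (mu, sigma) per group, on the 0-1 saturation scale.
_CNI_GROUPS = {
    "skin": ((25.0, 70.0), (0.76, 0.52)),
    "grass": ((95.0, 135.0), (0.81, 0.53)),
    "sky": ((185.0, 260.0), (0.43, 0.22)),
}


@dataclass(frozen=True)
class PixelFeatureVector:
    """The 17 pixel-level features of one photo, in reporting order."""

    red_mean: float
    red_variance: float
    green_mean: float
    green_variance: float
    blue_mean: float
    blue_variance: float
    saturation_mean: float
    saturation_variance: float
    value_mean: float
    value_variance: float
    hue_peaks: int
    brightness: float
    colorfulness: float
    naturalness: float
    contrast: float
    rgb_contrast: float
    sharpness: float

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


def as_rgb_array(image) -> np.ndarray:
    """Coerce input to an H×W×3 uint8 array.

    Accepts a numpy array or a PIL image. Alpha channels are dropped and
    grayscale input is promoted by channel replication.
    """
    if hasattr(image, "convert"):  # PIL.Image.Image duck-type
        image = np.asarray(image.convert("RGB"))
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim == 3 and arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"expected an H x W x 3 RGB image, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
            arr = arr.astype(np.uint8)
        else:
            raise ValueError("image must be 8-bit with values in [0, 255]")
    return arr


def _hsv_channels(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hue (degrees, [0,360)), saturation and value on [0,1] as float64."""
    rgb = arr.astype(np.float64) / 255.0
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    v = rgb.max(axis=-1)
    c = v - rgb.min(axis=-1)
    s = np.where(v > 0, c / np.where(v > 0, v, 1.0), 0.0)
    # piecewise hue; chroma-zero pixels get hue 0 by convention
    with np.errstate(invalid="ignore", divide="ignore"):
        hr = np.mod((g - b) / c, 6.0)
        hg = (b - r) / c + 2.0
        hb = (r - g) / c + 4.0
    h = np.where(v == r, hr, np.where(v == g, hg, hb))
    h = np.where(c > 0, h * 60.0, 0.0)
    return h, s, v


def _luminance(arr: np.ndarray) -> np.ndarray:
    rgb = arr.astype(np.float64)
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


def channel_stats(image) -> dict[str, float]:
    """Population means and variances of R, G, B, saturation and value.

    Saturation and value are scaled to 0–255 before the statistics are
    taken, matching the scale of the RGB channels.
    """
    arr = as_rgb_array(image)
    rgb = arr.astype(np.float64)
    _, s, v = _hsv_channels(arr)
    out: dict[str, float] = {}
    for i, name in enumerate(("red", "green", "blue")):
        chan = rgb[..., i]
        out[f"{name}_mean"] = float(chan.mean())
        out[f"{name}_variance"] = float(chan.var())
    for name, chan in (("saturation", s * 255.0), ("value", v * 255.0)):
        out[f"{name}_mean"] = float(chan.mean())
        out[f"{name}_variance"] = float(chan.var())
    return out


def _circular_gaussian_smooth(hist: np.ndarray, bandwidth: float) -> np.ndarray:
    """Smooth a circular histogram with a wrapped Gaussian kernel.

    Exact circular convolution via FFT; the kernel is the Gaussian of the
    minimal circular bin distance, normalized to unit mass.
    """
    n = hist.size
    idx = np.arange(n, dtype=np.float64)
    dist = np.minimum(idx, n - idx)
    kernel = np.exp(-0.5 * (dist / bandwidth) ** 2)
    kernel /= kernel.sum()
    return np.fft.irfft(np.fft.rfft(hist) * np.fft.rfft(kernel), n=n)


def _circular_peaks(curve: np.ndarray, min_prominence: float) -> int:
    """Count local maxima of a circular curve with at least the given prominence.

    A peak is a bin strictly greater than both circular neighbors. Its
    prominence is its height minus the higher of the two minima reached
    while descending (circularly) left and right until a higher bin is met;
    the global maximum's prominence is its height minus the global minimum.
    """
    n = curve.size
    peaks = [
        i
        for i in range(n)
        if curve[i] > curve[(i - 1) % n] and curve[i] > curve[(i + 1) % n]
    ]
    count = 0
    gmin = curve.min()
    for i in peaks:
        h = curve[i]
        if h >= curve.max():
            prom = h - gmin
        else:
            sides = []
            for step in (-1, 1):
                low = h
                j = i
                while True:
                    j = (j + step) % n
                    if curve[j] > h:
                        break
                    low = min(low, curve[j])
                sides.append(low)
            prom = h - max(sides)
        if prom >= min_prominence:
            count += 1
    return count


def hue_peak_count(
    image,
    bandwidth: float = 8.0,
    prominence: float = 0.01,
    sat_threshold: float = 26.0,
) -> int:
    """Number of modes in the smoothed circular hue histogram.

    The hue histogram (360 one-degree bins) is built over pixels whose
    saturation (0–255 scale) exceeds ``sat_threshold``, smoothed by a
    circular Gaussian kernel of ``bandwidth`` bins, and its local maxima
    with prominence at least ``prominence`` × total mass are counted.
    Returns 0 when no pixel passes the saturation gate.
    """
    arr = as_rgb_array(image)
    h, s, _ = _hsv_channels(arr)
    mask = (s * 255.0) > sat_threshold
    if not mask.any():
        return 0
    hues = h[mask]
    hist, _ = np.histogram(hues, bins=360, range=(0.0, 360.0))
    hist = hist.astype(np.float64)
    smooth = _circular_gaussian_smooth(hist, bandwidth)
    return _circular_peaks(smooth, prominence * hist.sum())


def brightness(image) -> float:
    """Mean YUV luminance, 0–255."""
    arr = as_rgb_array(image)
    return float(_luminance(arr).mean())


def colorfulness(image) -> float:
    """Hasler–Süsstrunk colorfulness.

    With opponent channels rg = R − G and yb = (R + G)/2 − B:
    sqrt(sd_rg² + sd_yb²) + 0.3·sqrt(mean_rg² + mean_yb²), population SDs.
    """
    arr = as_rgb_array(image).astype(np.float64)
    rg = arr[..., 0] - arr[..., 1]
    yb = 0.5 * (arr[..., 0] + arr[..., 1]) - arr[..., 2]
    sd = np.sqrt(rg.var() + yb.var())
    mean = np.sqrt(rg.mean() ** 2 + yb.mean() ** 2)
    return float(sd + 0.3 * mean)


def naturalness(image) -> float:
    """Color-naturalness index (CNI) in [0, 1].

    Pixels qualify when their luminance, on a 0–100 scale, lies in
    [20, 80] and their saturation (0–1) exceeds 0.1. Qualifying pixels are
    grouped by hue into skin, grass and sky bands; each group scores
    exp(−0.5·((S̄ − μ)/σ)²) against the group's natural mean saturation,
    and the index is the pixel-count-weighted average of group scores.
    Returns 0 when no pixel qualifies.
    """
    arr = as_rgb_array(image)
    h, s, _ = _hsv_channels(arr)
    lum = _luminance(arr) / 255.0 * 100.0
    qualify = (lum >= 20.0) & (lum <= 80.0) & (s > 0.1)
    total = 0
    weighted = 0.0
    for (lo, hi), (mu, sigma) in _CNI_GROUPS.values():
        grp = qualify & (h >= lo) & (h <= hi)
        n = int(grp.sum())
        if n == 0:
            continue
        s_bar = float(s[grp].mean())
        score = float(np.exp(-0.5 * ((s_bar - mu) / sigma) ** 2))
        weighted += n * score
        total += n
    return weighted / total if total else 0.0


def contrast(image, mode: str = "sd") -> float:
    """Luminance contrast.

    ``sd`` (default): population standard deviation of luminance.
    ``literal``: that SD divided by the pixel count.
    """
    arr = as_rgb_array(image)
    sd = float(_luminance(arr).std())
    if mode == "sd":
        return sd
    if mode == "literal":
        return sd / arr[..., 0].size
    raise ValueError(f"unknown contrast mode {mode!r}")


def rgb_contrast(image) -> float:
    """Contrast extended to RGB space: sqrt(var_R + var_G + var_B)."""
    arr = as_rgb_array(image).astype(np.float64)
    return float(np.sqrt(sum(arr[..., i].var() for i in range(3))))


_LAPLACIAN = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=np.float64)


def sharpness(image, aggregate: str = "sum") -> float:
    """Laplacian sharpness normalized by local average luminance.

    Per pixel: |∇²Y| / max(μ₃ₓ₃, 1) where ∇²Y is the 4-neighbor Laplacian
    of luminance with replicated borders and μ₃ₓ₃ is the 3×3 local mean of
    luminance. Aggregated by ``sum`` (default) or ``mean`` over pixels.
    """
    arr = as_rgb_array(image)
    y = _luminance(arr)
    lap = ndimage.convolve(y, _LAPLACIAN, mode="nearest")
    local_mean = ndimage.uniform_filter(y, size=3, mode="nearest")
    terms = np.abs(lap) / np.maximum(local_mean, 1.0)
    if aggregate == "sum":
        return float(terms.sum())
    if aggregate == "mean":
        return float(terms.mean())
    raise ValueError(f"unknown sharpness aggregate {aggregate!r}")


def extract_features(
    image,
    contrast_mode: str = "sd",
    sharpness_aggregate: str = "sum",
    hue_bandwidth: float = 8.0,
    hue_prominence: float = 0.01,
    hue_sat_threshold: float = 26.0,
) -> PixelFeatureVector:
    """Compute all 17 pixel-level features of one photo."""
    arr = as_rgb_array(image)
    stats = channel_stats(arr)
    return PixelFeatureVector(
        **stats,
        hue_peaks=hue_peak_count(
            arr,
            bandwidth=hue_bandwidth,
            prominence=hue_prominence,
            sat_threshold=hue_sat_threshold,
        ),
        brightness=brightness(arr),
        colorfulness=colorfulness(arr),
        naturalness=naturalness(arr),
        contrast=contrast(arr, mode=contrast_mode),
        rgb_contrast=rgb_contrast(arr),
        sharpness=sharpness(arr, aggregate=sharpness_aggregate),
    )


class PixelFeatureExtractor:
    """Sklearn-style transformer mapping images to 17-dim feature rows.

    Parameters mirror :func:`extract_features`. ``transform`` accepts a
    sequence of images (arrays or PIL images) and returns an (n, 17)
    float array in :data:`FEATURE_NAMES` order. Stateless; ``fit`` only
    validates.
    """

    def __init__(
        self,
        contrast_mode: str = "sd",
        sharpness_aggregate: str = "sum",
        hue_bandwidth: float = 8.0,
        hue_prominence: float = 0.01,
        hue_sat_threshold: float = 26.0,
    ):
        self.contrast_mode = contrast_mode
        self.sharpness_aggregate = sharpness_aggregate
        self.hue_bandwidth = hue_bandwidth
        self.hue_prominence = hue_prominence
        self.hue_sat_threshold = hue_sat_threshold

    def get_params(self, deep: bool = True) -> dict:
        return {
            "contrast_mode": self.contrast_mode,
            "sharpness_aggregate": self.sharpness_aggregate,
            "hue_bandwidth": self.hue_bandwidth,
            "hue_prominence": self.hue_prominence,
            "hue_sat_threshold": self.hue_sat_threshold,
        }

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y=None):
        if self.contrast_mode not in ("sd", "literal"):
            raise ValueError(f"invalid contrast_mode {self.contrast_mode!r}")
        if self.sharpness_aggregate not in ("sum", "mean"):
            raise ValueError(f"invalid sharpness_aggregate {self.sharpness_aggregate!r}")
        self.n_features_out_ = len(FEATURE_NAMES)
        return self

    def transform(self, X) -> np.ndarray:
        rows = [
            extract_features(
                img,
                contrast_mode=self.contrast_mode,
                sharpness_aggregate=self.sharpness_aggregate,
                hue_bandwidth=self.hue_bandwidth,
                hue_prominence=self.hue_prominence,
                hue_sat_threshold=self.hue_sat_threshold,
            ).to_array()
            for img in X
        ]
        return np.vstack(rows) if rows else np.empty((0, len(FEATURE_NAMES)))

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def get_feature_names_out(self, input_features=None):
        return np.array(FEATURE_NAMES, dtype=object)
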