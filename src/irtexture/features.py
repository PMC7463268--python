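"""First-order histogram moments and GLCM/Haralick texture features.

The image is quantized once to ``Ng`` gray levels (default 8) over the
in-mask intensity range; levels are indexed 1..Ng in every formula, which
fixes the scale of level-dependent features such as autocorrelation, sum
average and the cluster moments. Histogram moments are computed on the
quantized in-mask pixels so the first- and second-order statistics share a
single intensity model.

The gray-level co-occurrence matrix (GLCM) counts ordered pairs of in-mask
pixels at a fixed offset; four directions (0°, 45°, 90°, 135°) at distance
``d`` are computed and, matching common reporting practice, each scalar
feature is averaged over the four directions (the unaveraged per-direction
block is also exposed). All entropies use the natural logarithm with the
convention 0·ln 0 = 0 — zero-probability terms are skipped exactly, no
epsilon offsets.

Cluster shade uses the cubic and cluster prominence the quartic exponent
(Haralick's convention). Sum variance is centred on the sum average by
default; centring on the sum entropy (Haralick's original f7) is available
via ``sum_variance_center``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import GrayImage, ParameterError, RegionMask

# (drow, dcol) unit offsets; rows grow downward, so 45° points up-right
DIRECTION_OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}

HIST_FEATURES = (
    "hist_mean",
    "hist_variance",
    "hist_skewness",
    "hist_kurtosis",
    "hist_energy",
    "hist_entropy",
)

GLCM_FEATURES = (
    "glcm_autocorrelation",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_cluster_shade",
    "glcm_cluster_prominence",
    "glcm_dissimilarity",
    "glcm_homogeneity",
    "glcm_difference_variance",
    "glcm_difference_entropy",
    "glcm_entropy",
    "glcm_energy",
    "glcm_sum_average",
    "glcm_sum_entropy",
    "glcm_sum_variance",
    "glcm_maximum_probability",
    "glcm_inverse_difference",
    "glcm_imc1",
    "glcm_imc2",
    "glcm_idn",
    "glcm_idmn",
)

ALL_FEATURES = HIST_FEATURES + GLCM_FEATURES


@dataclass
class FeatureConfig:
    """Quantization and GLCM parameters."""

    ng: int = 8
    distance: int = 1
    symmetric: bool = True
    directions: tuple[int, ...] = (0, 45, 90, 135)
    sum_variance_center: str = "sum_average"  # or "sum_entropy"

    def __post_init__(self) -> None:
        if self.ng < 2:
            raise ParameterError("ng must be >= 2")
        if self.distance < 1:
            raise ParameterError("distance must be >= 1")
        unknown = set(self.directions) - set(DIRECTION_OFFSETS)
        if unknown:
            raise ParameterError(f"unsupported directions: {sorted(unknown)}")
        if self.sum_variance_center not in ("sum_average", "sum_entropy"):
            raise ParameterError("sum_variance_center: sum_average|sum_entropy")


@dataclass
class QuantizedImage:
    """Gray levels 1..Ng; masked-out pixels carry the sentinel 0."""

    levels: np.ndarray
    ng: int
    bin_edges: np.ndarray


@dataclass
class IntensityHistogram:
    counts: np.ndarray  # h(i), i = 1..Ng
    probabilities: np.ndarray  # p(i) = h(i) / in-mask pixel count
    ng: int


@dataclass
class GLCM:
    """Co-occurrence probability matrix with marginals and entropies."""

    P: np.ndarray
    direction: int
    distance: int
    symmetric: bool
    pair_count: int
    ng: int
    # marginals
    px: np.ndarray = field(init=False)
    py: np.ndarray = field(init=False)
    p_sum: np.ndarray = field(init=False)  # p_{x+y}(k), k = 2..2Ng
    p_diff: np.ndarray = field(init=False)  # p_{x-y}(k), k = 0..Ng-1
    # moments of the level marginals
    mu_x: float = field(init=False)
    mu_y: float = field(init=False)
    sigma_x: float = field(init=False)
    sigma_y: float = field(init=False)
    # entropies (natural log)
    hx: float = field(init=False)
    hy: float = field(init=False)
    hxy: float = field(init=False)
    hxy1: float = field(init=False)
    hxy2: float = field(init=False)

    def __post_init__(self) -> None:
        ng = self.ng
        P = self.P
        self.px = P.sum(axis=1)
        self.py = P.sum(axis=0)
        levels = np.arange(1, ng + 1, dtype=np.float64)
        self.mu_x = float(levels @ self.px)
        self.mu_y = float(levels @ self.py)
        self.sigma_x = float(np.sqrt((levels - self.mu_x) ** 2 @ self.px))
        self.sigma_y = float(np.sqrt((levels - self.mu_y) ** 2 @ self.py))
        i = levels[:, None]
        j = levels[None, :]
        self.p_sum = np.zeros(2 * ng - 1)  # index k-2
        self.p_diff = np.zeros(ng)  # index |i-j|
        s_idx = (i + j - 2).astype(int)
        d_idx = np.abs(i - j).astype(int)
        np.add.at(self.p_sum, s_idx.ravel(), P.ravel())
        np.add.at(self.p_diff, d_idx.ravel(), P.ravel())
        self.hx = _entropy(self.px)
        self.hy = _entropy(self.py)
        self.hxy = _entropy(P.ravel())
        outer = np.outer(self.px, self.py)
        nz = P > 0
        self.hxy1 = float(-np.sum(P[nz] * np.log(outer[nz])))
        onz = outer > 0
        self.hxy2 = float(-np.sum(outer[onz] * np.log(outer[onz])))


def _entropy(p: np.ndarray) -> float:
    """-sum p ln p with 0 ln 0 = 0."""
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def quantize(img: GrayImage, mask: RegionMask | None, ng: int) -> QuantizedImage:
    """Uniform-width binning of in-mask intensities to levels 1..Ng.

    Bins span [min, max] of the in-mask intensities; the maximum maps to
    level Ng. All-equal in-mask pixels map to level 1.
    """
    if ng < 2:
        raise ParameterError("ng must be >= 2")
    mask = mask or RegionMask.full(img.pixels.shape)
    if mask.flags.shape != img.pixels.shape:
        raise ParameterError("mask shape does not match image")
    if mask.n_included < 2:
        raise ParameterError("need at least 2 in-mask pixels to quantize")
    arr = img.astype_float()
    vals = arr[mask.flags]
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(arr.shape, dtype=np.int32)
    if hi == lo:
        levels[mask.flags] = 1
        edges = np.array([lo, hi])
    else:
        scaled = np.floor((arr - lo) / (hi - lo) * ng).astype(np.int32) + 1
        levels[mask.flags] = np.clip(scaled[mask.flags], 1, ng)
        edges = np.linspace(lo, hi, ng + 1)
    return QuantizedImage(levels=levels, ng=ng, bin_edges=edges)


def histogram(qimg: QuantizedImage, mask: RegionMask | None = None) -> IntensityHistogram:
    """Level histogram h(i) and probabilities p(i) over in-mask pixels."""
    flags = mask.flags if mask is not None else qimg.levels > 0
    lev = qimg.levels[flags & (qimg.levels > 0)]
    if lev.size == 0:
        raise ParameterError("empty mask: no pixels to histogram")
    counts = np.bincount(lev, minlength=qimg.ng + 1)[1:].astype(np.int64)
    return IntensityHistogram(
        counts=counts, probabilities=counts / counts.sum(), ng=qimg.ng
    )


def histogram_features(hist: IntensityHistogram) -> tuple[dict[str, float], set[str]]:
    """Central moments of the level histogram.

    Kurtosis is non-excess (a normal distribution gives 3). Skewness and
    kurtosis are flagged undefined when the variance is zero.
    """
    p = hist.probabilities
    levels = np.arange(1, hist.ng + 1, dtype=np.float64)
    mean = float(levels @ p)
    var = float((levels - mean) ** 2 @ p)
    undefined: set[str] = set()
    if var > 0:
        sd = np.sqrt(var)
        skew = float((levels - mean) ** 3 @ p / sd**3)
        kurt = float((levels - mean) ** 4 @ p / sd**4)
    else:
        skew = kurt = float("nan")
        undefined |= {"hist_skewness", "hist_kurtosis"}
    feats = {
        "hist_mean": mean,
        "hist_variance": var,
        "hist_skewness": skew,
        "hist_kurtosis": kurt,
        "hist_energy": float(p @ p),
        "hist_entropy": _entropy(p),
    }
    return feats, undefined


def compute_glcm(
    qimg: QuantizedImage,
    mask: RegionMask | None,
    direction: int,
    d: int = 1,
    symmetric: bool = True,
) -> GLCM:
    """Co-occurrence matrix for one direction at distance ``d``.

    Ordered pairs (pixel, pixel at the direction offset scaled by d) are
    counted only when both pixels are in-mask; the symmetric variant also
    counts each transposed pair. Probabilities are normalized by the total
    pair count.
    """
    if direction not in DIRECTION_OFFSETS:
        raise ParameterError(f"direction must be one of {sorted(DIRECTION_OFFSETS)}")
    if d < 1:
        raise ParameterError("distance must be >= 1")
    lev = qimg.levels.copy()
    if mask is not None:
        if mask.flags.shape != lev.shape:
            raise ParameterError("mask shape does not match image")
        lev[~mask.flags] = 0
    ng = qimg.ng
    dr, dc = DIRECTION_OFFSETS[direction]
    dr, dc = dr * d, dc * d
    h, w = lev.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = lev[r0:r1, c0:c1]
    b = lev[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = (a > 0) & (b > 0)
    if not valid.any():
        raise ParameterError(f"no valid pixel pair in direction {direction}°")
    counts = np.bincount(
        (a[valid].astype(np.int64) - 1) * ng + (b[valid].astype(np.int64) - 1),
        minlength=ng * ng,
    ).reshape(ng, ng)
    if symmetric:
        counts = counts + counts.T
    total = int(counts.sum())
    return GLCM(
        P=counts / total,
        direction=direction,
        distance=d,
        symmetric=symmetric,
        pair_count=total,
        ng=ng,
    )


def haralick_features(glcm: GLCM) -> tuple[dict[str, float], set[str]]:
    """Scalar texture statistics of one co-occurrence matrix.

    Correlation is undefined when either marginal standard deviation is
    zero; the first information measure of correlation is undefined when
    max(HX, HY) = 0. Undefined features carry NaN and are listed in the
    returned flag set.
    """
    ng = glcm.ng
    P = glcm.P
    levels = np.arange(1, ng + 1, dtype=np.float64)
    i = levels[:, None]
    j = levels[None, :]
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    k_diff = np.arange(0, ng, dtype=np.float64)

    undefined: set[str] = set()
    feats: dict[str, float] = {}

    feats["glcm_autocorrelation"] = float(np.sum(i * j * P))
    feats["glcm_contrast"] = float(np.sum((i - j) ** 2 * P))
    if glcm.sigma_x > 0 and glcm.sigma_y > 0:
        feats["glcm_correlation"] = float(
            np.sum((i - glcm.mu_x) * (j - glcm.mu_y) * P) / (glcm.sigma_x * glcm.sigma_y)
        )
    else:
        feats["glcm_correlation"] = float("nan")
        undefined.add("glcm_correlation")
    dev = i + j - glcm.mu_x - glcm.mu_y
    feats["glcm_cluster_shade"] = float(np.sum(dev**3 * P))
    feats["glcm_cluster_prominence"] = float(np.sum(dev**4 * P))
    feats["glcm_dissimilarity"] = float(np.sum(np.abs(i - j) * P))
    feats["glcm_homogeneity"] = float(np.sum(P / (1 + (i - j) ** 2)))
    mu_diff = float(k_diff @ glcm.p_diff)
    feats["glcm_difference_variance"] = float((k_diff - mu_diff) ** 2 @ glcm.p_diff)
    feats["glcm_difference_entropy"] = _entropy(glcm.p_diff)
    feats["glcm_entropy"] = glcm.hxy
    feats["glcm_energy"] = float(np.sum(P**2))
    sa = float(k_sum @ glcm.p_sum)
    feats["glcm_sum_average"] = sa
    se = _entropy(glcm.p_sum)
    feats["glcm_sum_entropy"] = se
    feats["glcm_sum_variance"] = float((k_sum - sa) ** 2 @ glcm.p_sum)
    feats["glcm_maximum_probability"] = float(P.max())
    feats["glcm_inverse_difference"] = float(np.sum(P / (1 + np.abs(i - j))))
    denom = max(glcm.hx, glcm.hy)
    if denom > 0:
        feats["glcm_imc1"] = float((glcm.hxy - glcm.hxy1) / denom)
    else:
        feats["glcm_imc1"] = float("nan")
        undefined.add("glcm_imc1")
    feats["glcm_imc2"] = float(
        np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (glcm.hxy2 - glcm.hxy))))
    )
    feats["glcm_idn"] = float(np.sum(P / (1 + np.abs(i - j) / ng)))
    feats["glcm_idmn"] = float(np.sum(P / (1 + (i - j) ** 2 / ng**2)))
    return feats, undefined


def sum_variance_about_entropy(glcm: GLCM) -> float:
    """Sum variance centred on the sum entropy (Haralick's original f7)."""
    ng = glcm.ng
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    se = _entropy(glcm.p_sum)
    return float((k_sum - se) ** 2 @ glcm.p_sum)


@dataclass
class FeatureVector:
    """Direction-averaged features plus the per-direction block."""

    values: dict[str, float]
    per_direction: dict[str, float]
    undefined: set[str]


def extract_features(
    img: GrayImage,
    mask: RegionMask | None = None,
    cfg: FeatureConfig | None = None,
) -> FeatureVector:
    """Histogram block + direction-averaged GLCM block for one image.

    The image is quantized once; the histogram moments are computed on the
    quantized in-mask pixels and each GLCM feature is the arithmetic mean
    over the configured directions. A feature undefined in any direction is
    flagged undefined overall. Per-direction values are exposed with
    ``_0/_45/_90/_135`` suffixes.
    """
    cfg = cfg or FeatureConfig()
    qimg = quantize(img, mask, cfg.ng)
    hist = histogram(qimg, mask)
    hist_vals, undefined = histogram_features(hist)

    per_direction: dict[str, float] = {}
    sums: dict[str, float] = {name: 0.0 for name in GLCM_FEATURES}
    for direction in cfg.directions:
        glcm = compute_glcm(qimg, mask, direction, cfg.distance, cfg.symmetric)
        feats, undef = haralick_features(glcm)
        if cfg.sum_variance_center == "sum_entropy":
            feats["glcm_sum_variance"] = sum_variance_about_entropy(glcm)
        undefined |= undef
        for name, val in feats.items():
            per_direction[f"{name}_{direction}"] = val
            sums[name] += val
    n_dir = len(cfg.directions)
    values = dict(hist_vals)
    for name in GLCM_FEATURES:
        values[name] = float("nan") if name in undefined else sums[name] / n_dir
    return FeatureVector(values=values, per_direction=per_direction, undefined=undefined)
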