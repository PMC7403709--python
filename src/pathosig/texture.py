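"""Second-order (GLCM / Haralick) texture features for H&E tiles.

Each tile is reduced to a 104-dimensional descriptor: 13 Haralick
statistics computed from symmetric, normalized gray-level co-occurrence
matrices at 2 pixel distances x 4 directions.  Texture is computed on
luminance; gray levels are quantized into ``levels`` uniform bins over
the fixed 8-bit range [0, 255] so that per-tile brightness does not leak
into the quantization.

Conventions
-----------
* Image coordinates are 0-based (row, col); the offset for angle ``a``
  at distance ``d`` is 0deg -> (0, d), 45deg -> (-d, d), 90deg -> (-d, 0),
  135deg -> (-d, -d).
* Co-occurrence counts are symmetrized (C + C.T) and normalized to sum 1.
* Natural logarithms throughout, with the convention 0*ln(0) = 0.
* A zero-variance (single-level) GLCM is a well-defined limit:
  correlation := 1, IMC1 := 0, IMC2 := 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GlcmConfig",
    "HARALICK_STATS",
    "to_grayscale",
    "quantize",
    "compute_glcm",
    "haralick13",
    "extract_features",
    "feature_names",
]

#: Canonical order of the 13 Haralick statistics.
HARALICK_STATS = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)

#: Unit offsets (row, col) per direction in degrees.
ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GlcmConfig:
    """Configuration of the co-occurrence feature bank.

    With the defaults, 13 statistics x 2 distances x 4 angles = 104
    features per tile.
    """

    levels: int = 64
    distances: tuple[int, ...] = (1, 2)
    angles: tuple[int, ...] = (0, 45, 90, 135)

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if any(d < 1 or int(d) != d for d in self.distances):
            raise ValueError("distances must be positive integers")
        if any(a not in ANGLE_OFFSETS for a in self.angles):
            raise ValueError(f"angles must be among {sorted(ANGLE_OFFSETS)}")

    @property
    def n_features(self) -> int:
        return len(HARALICK_STATS) * len(self.distances) * len(self.angles)


def feature_names(config: GlcmConfig = GlcmConfig()) -> list[str]:
    """Canonical feature ordering: distance-major, then angle, then statistic."""
    return [
        f"{stat}_d{d}_a{a}"
        for d in config.distances
        for a in config.angles
        for stat in HARALICK_STATS
    ]


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Luminance Y = 0.299 R + 0.587 G + 0.114 B, full float precision.

    Parameters
    ----------
    rgb : (H, W, 3) array of 8-bit values.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {rgb.shape}")
    return rgb.astype(np.float64) @ _LUMA


def quantize(gray: np.ndarray, levels: int = 64) -> np.ndarray:
    """Quantize 8-bit-range intensities into ``levels`` uniform global bins.

    Bin k = floor(v * levels / 256) over the *fixed* range [0, 255] —
    deliberately not per-image min-max, so quantization is identical
    across tiles.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.min() < 0 or gray.max() > 255:
        raise ValueError("gray values must lie in [0, 255]")
    q = np.floor(gray * levels / 256.0).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def compute_glcm(qimg: np.ndarray, distance: int, angle: int, levels: int) -> np.ndarray:
    """Symmetric normalized gray-level co-occurrence matrix.

    Counts ordered pixel pairs (p, p + offset) with the offset implied
    by ``distance`` and ``angle``; pairs with either pixel outside the
    image are excluded.  The count matrix is symmetrized (C + C.T) and
    normalized to sum to one.
    """
    qimg = np.asarray(qimg)
    if qimg.ndim != 2:
        raise ValueError("quantized image must be 2-D")
    if qimg.min() < 0 or qimg.max() >= levels:
        raise ValueError("quantized values out of range for given levels")
    dr, dc = ANGLE_OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    h, w = qimg.shape
    r0, r1 = max(0, -dr), h - max(0, dr)
    c0, c1 = max(0, -dc), w - max(0, dc)
    if r1 <= r0 or c1 <= c0:
        raise ValueError(
            f"image of shape {qimg.shape} smaller than offset ({dr}, {dc})"
        )
    i = qimg[r0:r1, c0:c1].ravel()
    j = qimg[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    counts = np.bincount(i * levels + j, minlength=levels * levels)
    counts = counts.reshape(levels, levels).astype(np.float64)
    counts = counts + counts.T
    return counts / counts.sum()


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats with 0*ln(0) = 0."""
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def haralick13(p: np.ndarray) -> dict[str, float]:
    """The 13 classical Haralick statistics of one normalized symmetric GLCM.

    Sum variance is centered on the sum average (the modern convention);
    difference variance is the variance of the |i-j| distribution.
    """
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("GLCM must be square")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("GLCM must be normalized to sum 1")
    g = p.shape[0]
    idx = np.arange(g, dtype=np.float64)
    ii = idx[:, None]
    jj = idx[None, :]

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(idx @ px)
    mu_y = float(idx @ py)
    var_x = float(((idx - mu_x) ** 2) @ px)
    var_y = float(((idx - mu_y) ** 2) @ py)
    sig_x, sig_y = np.sqrt(var_x), np.sqrt(var_y)

    # distributions of i+j (range 0..2g-2) and |i-j| (range 0..g-1)
    ksum = (ii + jj).astype(np.int64)
    kdiff = np.abs(ii - jj).astype(np.int64)
    p_sum = np.bincount(ksum.ravel(), weights=p.ravel(), minlength=2 * g - 1)
    p_diff = np.bincount(kdiff.ravel(), weights=p.ravel(), minlength=g)
    ks = np.arange(2 * g - 1, dtype=np.float64)
    kd = np.arange(g, dtype=np.float64)

    asm = float((p * p).sum())
    contrast = float((kd**2) @ p_diff)
    degenerate = sig_x == 0 or sig_y == 0
    if degenerate:
        correlation = 1.0
    else:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / (sig_x * sig_y))
    variance = float(((ii - mu_x) ** 2 * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    sum_average = float(ks @ p_sum)
    sum_variance = float(((ks - sum_average) ** 2) @ p_sum)
    sum_entropy = _entropy(p_sum)
    entropy = _entropy(p.ravel())
    mu_d = float(kd @ p_diff)
    difference_variance = float(((kd - mu_d) ** 2) @ p_diff)
    difference_entropy = _entropy(p_diff)

    hx = _entropy(px)
    hy = _entropy(py)
    mask = p > 0
    log_pxpy_on_p = np.log(px[:, None] * py[None, :], where=mask, out=np.zeros_like(p))
    hxy1 = float(-(p[mask] * log_pxpy_on_p[mask]).sum())
    outer = px[:, None] * py[None, :]
    hxy2 = _entropy(outer.ravel())
    if degenerate:
        imc1 = 0.0
        imc2 = 0.0
    else:
        denom = max(hx, hy)
        imc1 = float((entropy - hxy1) / denom) if denom > 0 else 0.0
        imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": correlation,
        "variance": variance,
        "idm": idm,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "entropy": entropy,
        "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
        "imc1": imc1,
        "imc2": imc2,
    }


def extract_features(tile: np.ndarray, config: GlcmConfig = GlcmConfig()) -> pd.Series:
    """Full texture descriptor of one RGB tile.

    Returns a Series indexed by the canonical feature names
    ``{stat}_d{distance}_a{angle}`` (104 values with the default config).
    """
    gray = to_grayscale(tile)
    q = quantize(gray, config.levels)
    values: dict[str, float] = {}
    for d in config.distances:
        for a in config.angles:
            p = compute_glcm(q, d, a, config.levels)
            stats = haralick13(p)
            for stat, v in stats.items():
                values[f"{stat}_d{d}_a{a}"] = v
    out = pd.Series(values).reindex(feature_names(config))
    if not np.isfinite(out.to_numpy()).all():
        raise FloatingPointError("non-finite texture feature computed")
    return out


def features_frame(
    tiles: "dict[str, np.ndarray] | list[tuple[str, np.ndarray]]",
    config: GlcmConfig = GlcmConfig(),
) -> pd.DataFrame:
    """Feature table for many tiles: one row per tile_id, 104 columns."""
    items = tiles.items() if isinstance(tiles, dict) else tiles
    rows = {tid: extract_features(img, config) for tid, img in items}
    return pd.DataFrame.from_dict(rows, orient="index")[feature_names(config)]
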