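"""Full-reference image quality metrics and the edge-sensitivity statistic.

SSIM follows the reference formulation: local means/variances under an
11-tap Gaussian window (sigma 1.5), stabilizers K1=0.01, K2=0.03,
dynamic range L=1 (all images here are normalized to [0, 1]), averaged
over the window positions fully inside the image.  PSNR is
20*log10(L / RMSE) in dB, +inf for identical images.

The sensitivity statistic compares, across two transducer counts i and
j, the change in reconstruction quality against the change in input edge
quality:

    S = [SSIM(N_j, Gt_j) - SSIM(N_i, Gt_i)]
        / [SSIM(edge(X_j), Gt_j) - SSIM(edge(X_i), Gt_i)]

with N the network reconstruction, X the sparse input and Gt the ground
truth; ``edge`` is the Sobel gradient magnitude.  A model whose output
quality moves little while the input degrades a lot scores low
(robust).  The denominator comparing edge(X) against the raw ground
truth is the default; comparing against edge(Gt) is available via
``edge_vs_edge=True`` since either reading is defensible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "SSIMParams", "AlphaParams", "ReconTriplet",
    "mse", "rmse", "psnr", "ssim", "ssim_loss", "alpha_loss",
    "edge_map", "sensitivity",
]


@dataclass(frozen=True)
class SSIMParams:
    window_size: int = 11
    sigma: float = 1.5
    k1: float = 0.01
    k2: float = 0.03
    data_range: float = 1.0

    def kernel(self) -> np.ndarray:
        """Normalized 2-D Gaussian window (sums to 1)."""
        half = (self.window_size - 1) / 2.0
        ax = np.arange(self.window_size) - half
        g = np.exp(-(ax**2) / (2 * self.sigma**2))
        k = np.outer(g, g)
        return k / k.sum()


@dataclass(frozen=True)
class AlphaParams:
    alpha: float = 0.84

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")


@dataclass(frozen=True)
class ReconTriplet:
    """Input X, reconstruction N and ground truth Gt at one element count."""

    x: np.ndarray = field(repr=False)
    n: np.ndarray = field(repr=False)
    gt: np.ndarray = field(repr=False)
    n_elements: int = 0

    def __post_init__(self) -> None:
        if not (self.x.shape == self.n.shape == self.gt.shape):
            raise ValueError("triplet images must be co-shaped")
        if self.n_elements <= 0:
            raise ValueError("n_elements tag must be positive")


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    return x, y


def mse(x: np.ndarray, y: np.ndarray) -> float:
    x, y = _check_pair(x, y)
    return float(np.mean((x - y) ** 2))


def rmse(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.sqrt(mse(x, y)))


def psnr(x: np.ndarray, y: np.ndarray, max_val: float = 1.0) -> float:
    if max_val <= 0:
        raise ValueError("max_val must be positive")
    r = rmse(x, y)
    if r == 0.0:
        return float("inf")
    return float(20.0 * np.log10(max_val / r))


def _valid(a: np.ndarray, win: int) -> np.ndarray:
    pad = (win - 1) // 2
    return a[pad:a.shape[0] - pad, pad:a.shape[1] - pad]


def ssim(x: np.ndarray, y: np.ndarray, params: SSIMParams = SSIMParams()) -> float:
    """Mean local SSIM over fully valid window positions; symmetric."""
    x, y = _check_pair(x, y)
    win = params.window_size
    if min(x.shape) < win:
        raise ValueError(f"image {x.shape} smaller than SSIM window {win}")
    k = params.kernel()

    def f(a):
        return ndimage.convolve(a, k, mode="constant")

    mu_x, mu_y = f(x), f(y)
    var_x = f(x * x) - mu_x**2
    var_y = f(y * y) - mu_y**2
    cov = f(x * y) - mu_x * mu_y
    c1 = (params.k1 * params.data_range) ** 2
    c2 = (params.k2 * params.data_range) ** 2
    s = ((2 * mu_x * mu_y + c1) * (2 * cov + c2)) / (
        (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2))
    return float(np.mean(_valid(s, win)))


def ssim_loss(x: np.ndarray, y: np.ndarray, params: SSIMParams = SSIMParams()) -> float:
    """Structural dissimilarity 1 - SSIM; zero iff structurally identical."""
    return 1.0 - ssim(x, y, params)


def alpha_loss(
    x: np.ndarray,
    y: np.ndarray,
    params: AlphaParams = AlphaParams(),
    ssim_params: SSIMParams = SSIMParams(),
    literal_ssim_term: bool = False,
) -> float:
    """Mixed loss (1 - a) * MSE + a * (1 - SSIM), default a = 0.84.

    ``literal_ssim_term=True`` uses +SSIM instead of (1 - SSIM) as the
    similarity term, for auditing; it rewards dissimilarity under
    minimization and is not used for training.
    """
    a = params.alpha
    term = ssim(x, y, ssim_params) if literal_ssim_term else ssim_loss(x, y, ssim_params)
    return (1.0 - a) * mse(x, y) + a * term


def edge_map(image: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude, min-max normalized to [0, 1].

    Constant images map to all zeros.  Boundary handling is reflective.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("edge_map expects a 2-D image")
    gx = ndimage.sobel(img, axis=1, mode="reflect")
    gy = ndimage.sobel(img, axis=0, mode="reflect")
    mag = np.hypot(gx, gy)
    peak = mag.max()
    if peak > 0:
        mag /= peak
    return mag


class DegenerateSensitivityError(ZeroDivisionError):
    """Raised when the sensitivity denominator vanishes."""


def sensitivity(
    t_i: ReconTriplet,
    t_j: ReconTriplet,
    ssim_params: SSIMParams = SSIMParams(),
    edge_vs_edge: bool = False,
) -> float:
    """Edge-sensitivity ratio between two transducer counts (see module docs)."""
    if t_i.n_elements == t_j.n_elements:
        raise ValueError("sensitivity requires two distinct transducer counts")
    num = ssim(t_j.n, t_j.gt, ssim_params) - ssim(t_i.n, t_i.gt, ssim_params)
    ref_j = edge_map(t_j.gt) if edge_vs_edge else t_j.gt
    ref_i = edge_map(t_i.gt) if edge_vs_edge else t_i.gt
    den = ssim(edge_map(t_j.x), ref_j, ssim_params) - ssim(edge_map(t_i.x), ref_i, ssim_params)
    if den == 0.0:
        raise DegenerateSensitivityError(
            "edge-quality change between the two transducer counts is zero")
    return num / den
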