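"""Idealized 2-D photoacoustic forward model and delay-and-sum reconstruction.

The forward model is a circular Radon-type projection: with the speed of
sound normalized so one time bin corresponds to one radial step ``dr``,
time bin ``t`` of element ``e`` integrates the absorption map over the
arc of pixels whose distance from element ``e`` rounds to ``t * dr``.
Delay-and-sum (DAS) backprojection inverts it approximately by averaging,
for each pixel, the sinogram samples at the pixel's time of flight.  At
low element counts DAS produces the characteristic radial streak
artifacts of sparse-sampled photoacoustic tomography, which is the image
degradation this package's networks are trained to remove.

``dr`` equals the pixel pitch (2 / max(H, W)); the number of time bins
defaults to ceil(1.5 x grid diagonal in pixels), enough to cover every
element-to-pixel propagation path for detector radii up to ~1.9.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import TransducerGeometry
from .phantom import PhantomScene

__all__ = [
    "SinogramSet",
    "default_n_time_bins",
    "forward_project",
    "das_reconstruct",
    "render_ground_truth",
    "simulate_pair",
]


@dataclass(frozen=True)
class SinogramSet:
    """Per-element time series of arc-integrated pressure projections."""

    data: np.ndarray = field(repr=False)  # (n_elements, n_time_bins)
    dr: float = 0.0  # radial bin width in normalized units
    sound_speed: float = 1.0  # normalized: 1 dr per bin

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=np.float64)
        if d.ndim != 2:
            raise ValueError("sinogram data must be 2-D (n_elements, n_time_bins)")
        if not np.all(np.isfinite(d)):
            raise ValueError("sinogram contains non-finite values")
        object.__setattr__(self, "data", d)

    @property
    def n_elements(self) -> int:
        return self.data.shape[0]

    @property
    def n_time_bins(self) -> int:
        return self.data.shape[1]


def default_n_time_bins(grid_size: tuple[int, int]) -> int:
    h, w = grid_size
    return int(np.ceil(np.hypot(h, w) * 1.5))


def _distances(scene: PhantomScene, geometry: TransducerGeometry) -> np.ndarray:
    """(n_elements, H, W) pixel-center distances to each element."""
    x, y = scene.pixel_grid()
    pos = geometry.element_positions
    return np.hypot(
        x[None, :, :] - pos[:, 0, None, None],
        y[None, :, :] - pos[:, 1, None, None],
    )


def forward_project(
    scene: PhantomScene,
    geometry: TransducerGeometry,
    n_time_bins: int | None = None,
) -> SinogramSet:
    """Project a phantom onto a detector array.

    Bin ``t`` of element ``e`` sums the rasterized absorption over all
    pixels whose distance to element ``e`` rounds to ``t * dr`` (nearest
    bin).  An empty scene yields an all-zero sinogram.
    """
    h, w = scene.grid_size
    if n_time_bins is None:
        n_time_bins = default_n_time_bins(scene.grid_size)
    if n_time_bins < 1:
        raise ValueError("n_time_bins must be >= 1")
    dr = 2.0 / max(h, w)
    img = scene.rasterize()
    dist = _distances(scene, geometry)
    bins = np.rint(dist / dr).astype(np.int64)
    np.clip(bins, 0, n_time_bins - 1, out=bins)
    flat_img = img.ravel()
    sino = np.empty((geometry.n_elements, n_time_bins), dtype=np.float64)
    for e in range(geometry.n_elements):
        sino[e] = np.bincount(bins[e].ravel(), weights=flat_img, minlength=n_time_bins)
    return SinogramSet(data=sino, dr=dr)


def das_reconstruct(
    sinogram: SinogramSet,
    geometry: TransducerGeometry,
    grid_size: tuple[int, int],
) -> np.ndarray:
    """Delay-and-sum backprojection onto an H x W grid, in [0, 1].

    Each pixel averages, over elements, the sinogram sample at the
    pixel's nearest time-of-flight bin.  The result is min-max
    normalized to [0, 1] when its dynamic range is nonzero.
    """
    if sinogram.n_elements != geometry.n_elements:
        raise ValueError(
            f"sinogram has {sinogram.n_elements} elements, geometry has {geometry.n_elements}"
        )
    # reuse the scene pixel-grid convention without requiring a scene
    probe = PhantomScene(absorbers=(), grid_size=grid_size)
    dist = _distances(probe, geometry)
    bins = np.rint(dist / sinogram.dr).astype(np.int64)
    np.clip(bins, 0, sinogram.n_time_bins - 1, out=bins)
    elem_idx = np.arange(geometry.n_elements)[:, None, None]
    img = sinogram.data[elem_idx, bins].mean(axis=0)
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    return img


def render_ground_truth(
    scene: PhantomScene,
    geometry_dense: TransducerGeometry,
    grid_size: tuple[int, int],
    n_time_bins: int | None = None,
    rasterized: bool = False,
) -> np.ndarray:
    """Densely sampled reference image in [0, 1].

    By default this is the DAS reconstruction at the full element count,
    mirroring datasets whose ground truth is itself a (dense)
    reconstruction; ``rasterized=True`` returns the noiseless phantom
    raster instead.
    """
    if rasterized:
        return PhantomScene(absorbers=scene.absorbers, grid_size=grid_size,
                            seed=scene.seed).rasterize()
    sino = forward_project(scene, geometry_dense, n_time_bins)
    return das_reconstruct(sino, geometry_dense, grid_size)


def simulate_pair(
    scene: PhantomScene,
    geometry_dense: TransducerGeometry,
    geometry_sparse: TransducerGeometry,
    grid_size: tuple[int, int],
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(sparse_input, ground_truth) image pair for one scene.

    Optional additive Gaussian noise (std ``noise_sigma``) is applied to
    the sparse sinogram before reconstruction.
    """
    sparse_sino = forward_project(scene, geometry_sparse)
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(scene.seed)
        noisy = sparse_sino.data + rng.normal(0.0, noise_sigma * max(sparse_sino.data.max(), 1e-12),
                                              size=sparse_sino.data.shape)
        sparse_sino = SinogramSet(data=noisy, dr=sparse_sino.dr)
    sparse = das_reconstruct(sparse_sino, geometry_sparse, grid_size)
    dense = render_ground_truth(scene, geometry_dense, grid_size)
    return sparse, dense
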