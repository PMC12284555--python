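"""Transducer array geometries for 2-D photoacoustic tomography.

Coordinates are normalized field-of-view units: the reconstruction grid
spans [-1, 1] x [-1, 1], pixel centers, origin at the grid center, y-axis
up.  Detector elements may lie outside the grid (they usually do).

Four array kinds are supported:

``ring``
    elements at equal angular spacing on a full circle,
``semicircle``
    elements spanning a 180-degree arc (both endpoints included),
``multisegment``
    a linear center section flanked by two concave arcs, composed as
    n/2 linear + n/4 + n/4 elements at every sampling level,
``linear``
    elements on a straight line below the field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TransducerGeometry", "make_geometry", "subsample_elements", "GEOMETRY_KINDS"]

GEOMETRY_KINDS = ("ring", "semicircle", "multisegment", "linear")

# angular extents of the two concave wings of the multisegment array,
# chosen so the wings flank the linear center section symmetrically
_MS_LEFT_ARC = (np.pi, np.pi * 4 / 3)        # 180 deg -> 240 deg
_MS_RIGHT_ARC = (-np.pi / 3, 0.0)            # -60 deg -> 0 deg
_MS_LINEAR_Y = -1.0
_MS_LINEAR_HALF_WIDTH = 0.5


@dataclass(frozen=True)
class TransducerGeometry:
    """A fixed 2-D detector array.

    Attributes
    ----------
    kind : str
        One of ``GEOMETRY_KINDS``.
    n_elements : int
        Number of detector elements; equals ``len(element_positions)``.
    element_positions : ndarray, shape (n_elements, 2)
        (x, y) element centers in normalized field-of-view units.
    radius_or_extent : float
        Circle/arc radius for curved kinds, half-width for linear.
    """

    kind: str
    n_elements: int
    element_positions: np.ndarray = field(repr=False)
    radius_or_extent: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.element_positions, dtype=float)
        if pos.shape != (self.n_elements, 2):
            raise ValueError(
                f"element_positions shape {pos.shape} inconsistent with "
                f"n_elements={self.n_elements}"
            )
        object.__setattr__(self, "element_positions", pos)


def _segment_counts(n_elements: int) -> tuple[int, int, int]:
    """Split a multisegment element budget as n/2 linear + n/4 + n/4."""
    if n_elements % 4 != 0:
        raise ValueError(
            f"multisegment arrays require n_elements divisible by 4 "
            f"(n/2 linear + n/4 + n/4 concave); got {n_elements}"
        )
    quarter = n_elements // 4
    return 2 * quarter, quarter, quarter


def make_geometry(kind: str, n_elements: int, radius_or_extent: float = 1.0) -> TransducerGeometry:
    """Lay out a detector array of the given kind.

    Parameters
    ----------
    kind : {"ring", "semicircle", "multisegment", "linear"}
    n_elements : int
        Total element count (multisegment requires a multiple of 4).
    radius_or_extent : float
        Radius of the circle/arc (curved kinds) or half-width (linear),
        in normalized field-of-view units.
    """
    if n_elements < 1:
        raise ValueError("n_elements must be >= 1")
    r = float(radius_or_extent)
    if r <= 0:
        raise ValueError("radius_or_extent must be positive")

    if kind == "ring":
        theta = 2 * np.pi * np.arange(n_elements) / n_elements
        pos = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    elif kind == "semicircle":
        if n_elements == 1:
            theta = np.array([np.pi / 2])
        else:
            theta = np.linspace(0.0, np.pi, n_elements)
        pos = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    elif kind == "linear":
        if n_elements == 1:
            x = np.array([0.0])
        else:
            x = np.linspace(-r, r, n_elements)
        pos = np.column_stack([x, np.full(n_elements, _MS_LINEAR_Y)])
    elif kind == "multisegment":
        n_lin, n_left, n_right = _segment_counts(n_elements)
        x = np.linspace(-_MS_LINEAR_HALF_WIDTH * r, _MS_LINEAR_HALF_WIDTH * r, n_lin)
        linear = np.column_stack([x, np.full(n_lin, _MS_LINEAR_Y * r)])
        tl = np.linspace(*_MS_LEFT_ARC, n_left)
        left = np.column_stack([r * np.cos(tl), r * np.sin(tl)])
        tr = np.linspace(*_MS_RIGHT_ARC, n_right)
        right = np.column_stack([r * np.cos(tr), r * np.sin(tr)])
        # stored order: left wing, linear center, right wing (clockwise sweep)
        pos = np.concatenate([left, linear, right], axis=0)
    else:
        raise ValueError(f"unknown geometry kind {kind!r}; expected one of {GEOMETRY_KINDS}")

    return TransducerGeometry(kind=kind, n_elements=n_elements, element_positions=pos, radius_or_extent=r)


def subsample_elements(geometry: TransducerGeometry, n_keep: int) -> TransducerGeometry:
    """Uniformly decimate a geometry to ``n_keep`` elements.

    Keeps every (n_elements / n_keep)-th element starting at index 0,
    preserving stored order.  For multisegment arrays the decimation is
    applied per segment so the 2:1:1 composition is preserved (e.g.
    256 -> 32 keeps 16 linear + 8 + 8 concave elements).
    """
    n = geometry.n_elements
    if n_keep > n:
        raise ValueError(f"cannot keep {n_keep} of {n} elements")
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    if n % n_keep != 0:
        raise ValueError(f"n_keep={n_keep} must divide n_elements={n}")
    if n_keep == n:
        return geometry

    if geometry.kind == "multisegment":
        n_lin, n_left, n_right = _segment_counts(n)
        k_lin, k_left, k_right = _segment_counts(n_keep)
        if n_left % k_left or n_lin % k_lin:
            raise ValueError(
                f"multisegment decimation {n}->{n_keep} does not preserve segments"
            )
        pos = geometry.element_positions
        left = pos[:n_left][:: n_left // k_left]
        linear = pos[n_left:n_left + n_lin][:: n_lin // k_lin]
        right = pos[n_left + n_lin:][:: n_right // k_right]
        new_pos = np.concatenate([left, linear, right], axis=0)
    else:
        stride = n // n_keep
        new_pos = geometry.element_positions[::stride]

    return TransducerGeometry(
        kind=geometry.kind,
        n_elements=n_keep,
        element_positions=new_pos,
        radius_or_extent=geometry.radius_or_extent,
    )
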