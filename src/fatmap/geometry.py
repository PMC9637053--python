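"""Center-of-rotation (CoR) geometry for a lumbar motion segment.

The pivot of an L4L5 motion segment is approximated as the point 12.5 %
of the way along the disc's mid-sagittal anteroposterior (AP) diameter,
measured from its posterior edge — i.e. the center point of the posterior
quarter of the disc.  All radial fat-mapping distances are measured from
this point.

Coordinate convention: ``(row, col)``, 0-based, origin at the top-left of
the image grid; coordinates are continuous, so the CoR may lie between
pixel centers.  Distances are Euclidean, in pixel units, measured from
pixel centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["COR_FRACTION", "DiscGeometry", "CenterOfRotation", "locate_cor", "distance_map"]

#: Fraction of the posterior→anterior diameter at which the CoR sits.
COR_FRACTION = 0.125


@dataclass(frozen=True)
class DiscGeometry:
    """Posterior and anterior endpoints of the disc's mid-sagittal AP diameter.

    Parameters
    ----------
    posterior_point, anterior_point
        ``(row, col)`` pixel coordinates of the posterior and anterior
        edges of the disc.  They must be distinct.
    """

    posterior_point: tuple[float, float]
    anterior_point: tuple[float, float]

    def __post_init__(self) -> None:
        p = np.asarray(self.posterior_point, dtype=float)
        a = np.asarray(self.anterior_point, dtype=float)
        if p.shape != (2,) or a.shape != (2,):
            raise ValueError("disc endpoints must be 2D (row, col) coordinates")
        if not (np.all(np.isfinite(p)) and np.all(np.isfinite(a))):
            raise ValueError("disc endpoints must be finite")
        if np.allclose(p, a):
            raise ValueError("posterior and anterior disc points coincide")


@dataclass(frozen=True)
class CenterOfRotation:
    """A continuous (row, col) pivot coordinate; sub-pixel positions allowed."""

    point: tuple[float, float]

    def __post_init__(self) -> None:
        pt = np.asarray(self.point, dtype=float)
        if pt.shape != (2,) or not np.all(np.isfinite(pt)):
            raise ValueError("CoR must be a finite (row, col) coordinate")

    @property
    def row(self) -> float:
        return float(self.point[0])

    @property
    def col(self) -> float:
        return float(self.point[1])


def locate_cor(disc: DiscGeometry) -> CenterOfRotation:
    """Place the CoR 12.5 % along the posterior→anterior diameter.

    Returns ``posterior + 0.125 * (anterior - posterior)``, the center of
    the posterior quarter of the AP diameter.
    """
    p = np.asarray(disc.posterior_point, dtype=float)
    a = np.asarray(disc.anterior_point, dtype=float)
    cor = p + COR_FRACTION * (a - p)
    return CenterOfRotation(point=(float(cor[0]), float(cor[1])))


def distance_map(shape: tuple[int, int], cor: CenterOfRotation) -> np.ndarray:
    """Euclidean distance (pixels) from every pixel center to the CoR.

    Pixel centers sit at integer ``(row, col)`` coordinates.  The result is
    non-negative and zero only where a pixel center coincides with the CoR.
    """
    nr, nc = int(shape[0]), int(shape[1])
    if nr <= 0 or nc <= 0:
        raise ValueError(f"shape must be positive, got {shape!r}")
    rows = np.arange(nr, dtype=float)[:, None]
    cols = np.arange(nc, dtype=float)[None, :]
    return np.hypot(rows - cor.row, cols - cor.col)
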