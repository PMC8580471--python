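"""SEM-like 2D stack rendering of a 3D network.

Nodes are projected onto the x-y plane at 10 nm per pixel; luminosity encodes
height, with one level per 0.3 um z bin (10 levels for the 3 um reference
box) and higher luminosity at larger z.  A Sobel gradient pass extracts fibre
outlines and a Gaussian blur smooths them, emulating micrograph texture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import filters

from .network import FibreNetwork


@dataclass
class ProjectionImage:
    data: np.ndarray          # (ny, nx) luminosity in [0, 1]
    pixel_size: float         # metres per pixel (10 nm)
    bin_height: float         # z bin height (0.3 um)
    n_levels: int             # luminosity levels (z bins)

    @property
    def shape(self):
        return self.data.shape


def project(network: FibreNetwork, pixel_size: float = 10e-9,
            bin_height: float = 0.3e-6, draw_segments: bool = False) -> ProjectionImage:
    """Rasterize wrapped node positions; overlaps keep the maximum luminosity.

    ``draw_segments`` additionally rasterizes points interpolated along each
    bond (off by default; nodes only, as in the reference rendering).
    """
    Lx, Ly, Lz = network.box_lengths
    nx = max(int(round(Lx / pixel_size)), 1)
    ny = max(int(round(Ly / pixel_size)), 1)
    n_levels = max(int(round(Lz / bin_height)), 1)
    img = np.zeros((ny, nx))
    pts = network.wrapped_positions()
    if draw_segments:
        p = network.positions
        interp = []
        for f in np.linspace(0.0, 1.0, 5, endpoint=False)[1:]:
            q = (1 - f) * p[:, :-1] + f * p[:, 1:]
            interp.append(q.reshape(-1, 3))
        extra = np.concatenate(interp)
        L = network.box_lengths
        extra = extra - L * np.floor(extra / L)
        pts = np.concatenate([pts, extra])
    if pts.size == 0:
        return ProjectionImage(img, pixel_size, bin_height, n_levels)
    ix = np.minimum((pts[:, 0] / pixel_size).astype(int), nx - 1)
    iy = np.minimum((pts[:, 1] / pixel_size).astype(int), ny - 1)
    iz = np.minimum((pts[:, 2] / bin_height).astype(int), n_levels - 1)
    lum = (iz + 1.0) / n_levels
    np.maximum.at(img, (iy, ix), lum)
    return ProjectionImage(img, pixel_size, bin_height, n_levels)


def stylize(image: ProjectionImage, sigma: float = 2.0) -> ProjectionImage:
    """Sobel gradient magnitude followed by a Gaussian blur (sigma in px)."""
    if image.data.size == 0:
        raise ValueError("empty image")
    out = filters.sobel(image.data)
    if sigma > 0:
        out = filters.gaussian(out, sigma=sigma)
    return ProjectionImage(out, image.pixel_size, image.bin_height,
                           image.n_levels)
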