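"""Pixel-integrated point spread function.

A fluorophore at continuous position ``(x, y)`` (nanometres) illuminates the
detector with a diffraction-limited spot.  We model the spot as a symmetric 2D
Gaussian density with width ``sigma = 0.21 * wavelength / NA`` (the standard
Gaussian approximation to the Airy profile), so the expected fraction of the
emitter's photons landing in a pixel is a product of two 1D Gaussian CDF
differences over the pixel edges.  All PSF evaluations in the package go
through this closed form; a numeric-quadrature oracle is used only in tests.

Conventions
-----------
Positions are 2D, in nanometres, with x along columns and y along rows.
Pixel ``(i, j)`` (0-based, row-major) covers the half-open square
``[j*a, (j+1)*a) x [i*a, (i+1)*a)`` where ``a`` is the pixel size; its centre
is at ``((j + 0.5)*a, (i + 0.5)*a)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

#: sigma of the Gaussian approximation to the Airy disc, in units of lambda/NA.
GAUSSIAN_AIRY_FACTOR = 0.21


def diffraction_limit(wavelength: float, numerical_aperture: float) -> float:
    """Abbe diffraction limit ``lambda / (2 NA)`` in the units of ``wavelength``."""
    if wavelength <= 0 or numerical_aperture <= 0:
        raise ValueError("wavelength and numerical aperture must be positive")
    return wavelength / (2.0 * numerical_aperture)


@dataclass(frozen=True)
class PsfModel:
    """Symmetric 2D Gaussian PSF, normalized to unit mass over the plane.

    Parameters
    ----------
    sigma
        Gaussian width in nm.  Use :meth:`from_optics` to derive it from the
        numerical aperture and emission wavelength, or set it directly (e.g.
        from a calibration measurement).
    """

    sigma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValueError(f"sigma must be positive and finite, got {self.sigma}")

    @classmethod
    def from_optics(
        cls,
        numerical_aperture: float,
        wavelength: float,
        factor: float = GAUSSIAN_AIRY_FACTOR,
    ) -> "PsfModel":
        """Gaussian width ``factor * wavelength / NA`` (wavelength in nm)."""
        if numerical_aperture <= 0 or wavelength <= 0:
            raise ValueError("numerical aperture and wavelength must be positive")
        return cls(sigma=factor * wavelength / numerical_aperture)


@dataclass(frozen=True)
class PixelGrid:
    """Rectangular detector region of interest.

    ``n_rows`` x ``n_cols`` square pixels of side ``pixel_size`` nm, with the
    grid origin at (0, 0) nm.
    """

    n_rows: int
    n_cols: int
    pixel_size: float

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not np.isfinite(self.pixel_size) or self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def width(self) -> float:
        """Extent along x, in nm."""
        return self.n_cols * self.pixel_size

    @property
    def height(self) -> float:
        """Extent along y, in nm."""
        return self.n_rows * self.pixel_size

    @property
    def x_edges(self) -> np.ndarray:
        return np.arange(self.n_cols + 1) * self.pixel_size

    @property
    def y_edges(self) -> np.ndarray:
        return np.arange(self.n_rows + 1) * self.pixel_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def contains(self, position: np.ndarray) -> np.ndarray:
        """Whether position(s) ``(..., 2)`` fall inside the grid rectangle."""
        p = np.asarray(position, dtype=float)
        return (
            (p[..., 0] >= 0.0)
            & (p[..., 0] < self.width)
            & (p[..., 1] >= 0.0)
            & (p[..., 1] < self.height)
        )


def _axis_fractions(edges: np.ndarray, coord: np.ndarray, sigma: float) -> np.ndarray:
    """CDF differences of a 1D Gaussian centred on ``coord`` over pixel edges.

    ``coord`` has shape ``(...,)``; returns shape ``(..., len(edges) - 1)``.
    """
    z = (edges - np.asarray(coord, dtype=float)[..., None]) / sigma
    cdf = ndtr(z)
    return np.diff(cdf, axis=-1)


def pixel_integral(
    position, pixel: tuple[int, int], psf: PsfModel, grid: PixelGrid
) -> float:
    """Fraction of the PSF mass inside one pixel.

    Computes the integral of the normalized Gaussian PSF centred at
    ``position = (x, y)`` over pixel ``(i, j)``; separable closed form.
    """
    x, y = float(position[0]), float(position[1])
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError("position must be finite")
    i, j = pixel
    if not (0 <= i < grid.n_rows and 0 <= j < grid.n_cols):
        raise IndexError(f"pixel {pixel} outside grid {grid.shape}")
    a = grid.pixel_size
    fx = ndtr(((j + 1) * a - x) / psf.sigma) - ndtr((j * a - x) / psf.sigma)
    fy = ndtr(((i + 1) * a - y) / psf.sigma) - ndtr((i * a - y) / psf.sigma)
    return float(fx * fy)


def psf_image(position, psf: PsfModel, grid: PixelGrid) -> np.ndarray:
    """Per-pixel PSF fractions for one emitter, shape ``(n_rows, n_cols)``.

    Entry ``(i, j)`` equals :func:`pixel_integral` at that pixel; the sum over
    the grid is at most 1 and approaches 1 as the grid covers the PSF support.
    """
    p = np.asarray(position, dtype=float)
    if p.shape != (2,) or not np.all(np.isfinite(p)):
        raise ValueError("position must be a finite 2-vector (x, y)")
    fx = _axis_fractions(grid.x_edges, p[0], psf.sigma)
    fy = _axis_fractions(grid.y_edges, p[1], psf.sigma)
    return np.outer(fy, fx)


def captured_fraction(positions, psf: PsfModel, grid: PixelGrid) -> np.ndarray:
    """Total PSF mass falling anywhere on the grid, for positions ``(..., 2)``.

    Equals the sum of :func:`psf_image` over all pixels, in closed form.
    """
    p = np.asarray(positions, dtype=float)
    s = psf.sigma
    fx = ndtr((grid.width - p[..., 0]) / s) - ndtr((0.0 - p[..., 0]) / s)
    fy = ndtr((grid.height - p[..., 1]) / s) - ndtr((0.0 - p[..., 1]) / s)
    return fx * fy


def psf_fraction_at(
    pixels_flat: np.ndarray, positions: np.ndarray, psf: PsfModel, grid: PixelGrid
) -> np.ndarray:
    """PSF fractions at selected pixels for matched emitter positions.

    ``pixels_flat`` holds row-major flat pixel indices and broadcasts against
    ``positions[..., 2]``; used by the sampler for sparse likelihood updates.
    """
    pix = np.asarray(pixels_flat)
    p = np.asarray(positions, dtype=float)
    a = grid.pixel_size
    s = psf.sigma
    j = pix % grid.n_cols
    i = pix // grid.n_cols
    x = p[..., 0]
    y = p[..., 1]
    fx = ndtr(((j + 1) * a - x) / s) - ndtr((j * a - x) / s)
    fy = ndtr(((i + 1) * a - y) / s) - ndtr((i * a - y) / s)
    return fx * fy
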