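"""Gabor filter-bank texture features.

The texture stage convolves the grayscale band average with a bank of
complex Gabor filters (Gaussian-modulated sinusoids), takes the magnitude
of each response, smooths it, z-scores the bands against each other, and
reduces the stack to its leading principal components.  The default bank
is 4 orientations (0, 45, 90, 135 degrees) x 4 wavelengths, i.e. 16
magnitude-response bands.

Frequency-domain form of one filter (radial frequency f = 1/wavelength,
rotated frequency coordinates u', v'):

    G(u, v) = exp(-pi^2 / f^2 * [gamma^2 (u' - f)^2 + n^2 v'^2])

gamma and n are the dimensionless envelope widths; the equivalent spatial
kernel is a Gaussian envelope with standard deviations
sigma_u = gamma * wavelength / sqrt(2) (along the wave) and
sigma_v = n * wavelength / sqrt(2), carrying a complex exponential of the
filter's wavelength.  The default gamma = n gives a ~1-octave half-response
frequency bandwidth, the classical filter-bank design choice.

Filters are applied tile-wise with an overlap margin at least as large as
the kernel half-support, so mosaicking the tile interiors is seam-free:
interior pixels match a whole-image computation to floating-point
tolerance.  The truncated kernel is re-centred to exactly zero mean, so a
constant image yields (numerically) zero magnitude everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve
from sklearn.decomposition import PCA

from .raster import Raster

__all__ = [
    "GaborFilter",
    "GaborBank",
    "TextureStack",
    "DEFAULT_WAVELENGTHS",
    "DEFAULT_ORIENTATIONS",
    "octave_envelope_width",
    "build_bank",
    "required_overlap",
    "apply_bank",
    "normalize_stack",
    "stack_pca",
]

# Wavelengths in pixels: 2*sqrt(2) growing by a factor of 2.5.
DEFAULT_WAVELENGTHS: tuple[float, ...] = (
    2.82842712475,
    7.0710678,
    17.6776695,
    44.19417382,
)
DEFAULT_ORIENTATIONS: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)

#: kernel support is truncated at this many envelope standard deviations
KERNEL_TRUNCATE = 3.0


def octave_envelope_width(bandwidth_octaves: float = 1.0) -> float:
    """Dimensionless envelope width giving the requested frequency bandwidth.

    For a Gaussian envelope with spatial sd ``sigma = c * wavelength`` the
    half-response bandwidth in octaves is B with
    c = (1/pi) * sqrt(ln 2 / 2) * (2^B + 1) / (2^B - 1); the returned value
    is gamma = sqrt(2) * c, matching the frequency-domain parameterization.
    """
    b = 2.0**bandwidth_octaves
    c = (1.0 / math.pi) * math.sqrt(math.log(2) / 2.0) * (b + 1.0) / (b - 1.0)
    return math.sqrt(2.0) * c


@dataclass(frozen=True)
class GaborFilter:
    """One bandpass filter: wavelength (pixels), orientation, envelope widths."""

    wavelength: float
    theta_deg: float
    gamma: float
    n: float

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if not (0.0 <= self.theta_deg < 180.0):
            raise ValueError("theta must lie in [0, 180)")
        if self.gamma <= 0 or self.n <= 0:
            raise ValueError("envelope widths must be positive")

    @property
    def sigma_u(self) -> float:
        """Spatial envelope sd along the wave direction, in pixels."""
        return self.gamma * self.wavelength / math.sqrt(2.0)

    @property
    def sigma_v(self) -> float:
        """Spatial envelope sd across the wave direction, in pixels."""
        return self.n * self.wavelength / math.sqrt(2.0)

    def half_support(self) -> int:
        """Half-width of the truncated spatial kernel, in pixels."""
        return int(math.ceil(KERNEL_TRUNCATE * max(self.sigma_u, self.sigma_v)))

    def kernel(self) -> np.ndarray:
        """Complex spatial kernel, zero-mean and unit envelope mass.

        Rotation convention: u' = u cos(theta) + v sin(theta),
        v' = -u sin(theta) + v cos(theta), with u along columns (x) and
        v along rows (y).
        """
        r = self.half_support()
        y, x = np.mgrid[-r : r + 1, -r : r + 1].astype(float)
        th = math.radians(self.theta_deg)
        u = x * math.cos(th) + y * math.sin(th)
        v = -x * math.sin(th) + y * math.cos(th)
        envelope = np.exp(
            -0.5 * ((u / self.sigma_u) ** 2 + (v / self.sigma_v) ** 2)
        )
        carrier = np.exp(2j * math.pi * u / self.wavelength)
        k = envelope * carrier
        # remove the truncated kernel's residual DC so constant inputs map to 0
        k -= k.mean()
        return k / envelope.sum()


@dataclass(frozen=True)
class GaborBank:
    """An ordered filter bank plus the per-filter post-smoothing widths."""

    filters: tuple[GaborFilter, ...]
    smoothing_sigmas: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.filters) != len(self.smoothing_sigmas):
            raise ValueError("one smoothing sigma per filter required")

    def __len__(self) -> int:
        return len(self.filters)


def build_bank(
    wavelengths: tuple[float, ...] | list[float] = DEFAULT_WAVELENGTHS,
    orientations_deg: tuple[float, ...] | list[float] = DEFAULT_ORIENTATIONS,
    gamma: float | None = None,
    n: float | None = None,
    smoothing_sigma: float | None = None,
) -> GaborBank:
    """Cartesian-product bank, orientation-major then wavelength order.

    ``gamma``/``n`` default to the 1-octave envelope width; the per-filter
    smoothing sigma defaults to wavelength / 2 when not given explicitly.
    """
    if not wavelengths or not orientations_deg:
        raise ValueError("wavelengths and orientations must be non-empty")
    if any(w <= 0 for w in wavelengths):
        raise ValueError("wavelengths must be positive")
    pairs = [(th, w) for th in orientations_deg for w in wavelengths]
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate (wavelength, orientation) pairs")
    g = octave_envelope_width() if gamma is None else gamma
    nn = g if n is None else n
    filters = tuple(
        GaborFilter(wavelength=w, theta_deg=th, gamma=g, n=nn) for th, w in pairs
    )
    sigmas = tuple(
        (f.wavelength / 2.0) if smoothing_sigma is None else smoothing_sigma
        for f in filters
    )
    return GaborBank(filters=filters, smoothing_sigmas=sigmas)


@dataclass(frozen=True)
class TextureStack:
    """Magnitude responses, one band per filter, shape (n_filters, rows, cols)."""

    bands: np.ndarray
    bank: GaborBank
    cell_size: float = 1.0
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.bands.ndim != 3 or self.bands.shape[0] != len(self.bank):
            raise ValueError("band count must equal filter count")

    @property
    def n_bands(self) -> int:
        return self.bands.shape[0]

    def band(self, i: int) -> Raster:
        return Raster(self.bands[i], cell_size=self.cell_size)


def required_overlap(bank: GaborBank) -> int:
    """Smallest tile overlap guaranteeing seam-free mosaicking.

    Equal to the largest filter's truncated-kernel half-support,
    ceil(3 * max(sigma_u, sigma_v)) pixels.
    """
    return max(f.half_support() for f in bank.filters)


def _convolve_magnitude(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    # edge padding keeps image borders free of zero-padding artifacts, so a
    # constant image maps to (numerically) zero magnitude everywhere
    r = kernel.shape[0] // 2
    padded = np.pad(values, r, mode="edge")
    out = fftconvolve(padded, kernel, mode="same")
    return np.abs(out[r : r + values.shape[0], r : r + values.shape[1]])


def apply_bank(
    gray: Raster,
    bank: GaborBank,
    tile: int | None = None,
    overlap: int | None = None,
) -> TextureStack:
    """Magnitude response of every filter, computed tile-wise, then smoothed.

    With ``tile`` set, the image is processed in ``tile`` x ``tile`` blocks
    padded by ``overlap`` pixels of real image data on each side; interiors
    are mosaicked, so interior pixels equal a whole-image computation to
    floating-point tolerance.  Gaussian smoothing (one sigma per filter) is
    applied to each mosaicked magnitude band.
    """
    v = gray.values.astype(float)
    rows, cols = v.shape
    out = np.empty((len(bank), rows, cols), dtype=float)
    kernels = [f.kernel() for f in bank.filters]

    if tile is None:
        for i, k in enumerate(kernels):
            out[i] = _convolve_magnitude(v, k)
    else:
        need = required_overlap(bank)
        if overlap is None:
            overlap = need
        if overlap < need:
            raise ValueError(
                f"overlap {overlap} below the bank's kernel half-support {need}"
            )
        if tile <= 2 * overlap:
            raise ValueError("tile must exceed twice the overlap")
        for r0 in range(0, rows, tile):
            for c0 in range(0, cols, tile):
                r1 = min(r0 + tile, rows)
                c1 = min(c0 + tile, cols)
                rpad0, cpad0 = max(r0 - overlap, 0), max(c0 - overlap, 0)
                rpad1, cpad1 = min(r1 + overlap, rows), min(c1 + overlap, cols)
                window = v[rpad0:rpad1, cpad0:cpad1]
                for i, k in enumerate(kernels):
                    mag = _convolve_magnitude(window, k)
                    out[i, r0:r1, c0:c1] = mag[
                        r0 - rpad0 : r1 - rpad0, c0 - cpad0 : c1 - cpad0
                    ]

    for i, sigma in enumerate(bank.smoothing_sigmas):
        if sigma > 0:
            out[i] = gaussian_filter(out[i], sigma=sigma, mode="nearest")
    return TextureStack(bands=out, bank=bank, cell_size=gray.cell_size)


def normalize_stack(stack: TextureStack) -> TextureStack:
    """Z-score each band independently (mean 0, sd 1); constant bands -> 0."""
    if stack.n_bands < 2:
        raise ValueError("normalization needs at least two bands")
    bands = stack.bands.astype(float).copy()
    for i in range(bands.shape[0]):
        b = bands[i]
        sd = b.std()
        if sd == 0:
            bands[i] = np.zeros_like(b)
        else:
            bands[i] = (b - b.mean()) / sd
    return TextureStack(
        bands=bands, bank=stack.bank, cell_size=stack.cell_size, normalized=True
    )


def stack_pca(
    stack: TextureStack, k: int = 1, return_model: bool = False
):
    """First ``k`` principal-component score rasters of the band stack.

    Pixels are the observations, bands the variables.  Each component's
    sign is fixed so its first non-zero band loading is positive, making
    the decomposition deterministic.
    """
    if not 1 <= k <= stack.n_bands:
        raise ValueError(f"k must lie in [1, {stack.n_bands}]")
    nb, rows, cols = stack.bands.shape
    x = stack.bands.reshape(nb, rows * cols).T
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    for i in range(k):
        loadings = pca.components_[i]
        nz = np.flatnonzero(np.abs(loadings) > 1e-12)
        if nz.size and loadings[nz[0]] < 0:
            pca.components_[i] = -loadings
            scores[:, i] = -scores[:, i]
    rasters = [
        Raster(scores[:, i].reshape(rows, cols), cell_size=stack.cell_size)
        for i in range(k)
    ]
    if return_model:
        return rasters, pca
    return rasters
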