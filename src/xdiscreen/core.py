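"""Grid conventions, Fourier transforms and resolution-shell geometry.

All real-space maps live on square ``N x N`` grids with even ``N``.  The
Fourier convention used throughout the package is the *centered* discrete
transform: the zero-frequency (direct beam) pixel of a structure factor
sits at array index ``(N//2, N//2)``, and the scattering vector of pixel
``(u, v)`` is ``((u - N/2), (v - N/2)) * q_step`` with ``q_step`` in
inverse micrometres.  The forward transform (density -> structure factor)
carries no normalisation; the inverse carries the ``1/N**2`` factor, so
Parseval's theorem reads ``sum |rho|**2 == sum |F|**2 / N**2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DensityMap",
    "StructureFactor",
    "DiffractionPattern",
    "ResolutionShells",
    "forward_structure_factor",
    "inverse_density",
    "make_resolution_shells",
    "fft2c",
    "ifft2c",
    "point_reflect",
    "radial_coordinates",
]


def fft2c(x: np.ndarray) -> np.ndarray:
    """Centered 2D FFT: array-center origin in, array-center origin out."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x)))


def ifft2c(x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c` (carries the 1/N**2 normalisation)."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(x)))


def point_reflect(values: np.ndarray) -> np.ndarray:
    """Point reflection about the array-center pixel ``(N//2, N//2)``.

    Implements ``out[i, j] = values[(-i) % N, (-j) % N]`` relative to the
    centered origin; the unpaired Nyquist row/column maps onto itself.
    For a structure factor of a real density, ``conj(point_reflect(F))``
    equals ``F`` (Friedel symmetry).
    """
    return np.roll(values[::-1, ::-1], 1, axis=(0, 1))


def _check_square_even(values: np.ndarray, name: str) -> None:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"{name} must be a square 2D array, got shape {values.shape}")
    if values.shape[0] % 2 != 0:
        raise ValueError(f"{name} must have even side length, got N={values.shape[0]}")


def _check_finite(values: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        pixel = tuple(int(i) for i in bad)
        raise ValueError(f"{name} contains a non-finite value at pixel {pixel}")


@dataclass
class DensityMap:
    """Real-valued projected electron density on a square grid.

    Parameters
    ----------
    values : ndarray
        ``N x N`` real array of projected density (arbitrary units).
    pixel_size : float
        Real-space sampling interval in nanometres.
    support : ndarray of bool, optional
        Region believed to contain the object.
    """

    values: np.ndarray
    pixel_size: float
    support: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_square_even(self.values, "DensityMap.values")
        _check_finite(self.values, "DensityMap.values")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        if self.support is not None:
            self.support = np.asarray(self.support, dtype=bool)
            if self.support.shape != self.values.shape:
                raise ValueError("support shape must match values shape")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def centroid(self) -> tuple[float, float]:
        """Center of gravity of the density in pixel coordinates."""
        total = self.values.sum()
        if total <= 0:
            raise ValueError("centroid undefined for non-positive total density")
        idx = np.indices(self.values.shape)
        return (
            float((idx[0] * self.values).sum() / total),
            float((idx[1] * self.values).sum() / total),
        )


@dataclass
class StructureFactor:
    """Complex structure factor ``F(S)`` with the zero frequency centered.

    ``q_step`` is the scattering-vector increment per pixel in inverse
    micrometres; phases ``alpha(S) = angle(F)`` lie in ``(-pi, pi]``.
    """

    values: np.ndarray
    q_step: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        _check_square_even(self.values, "StructureFactor.values")
        _check_finite(self.values, "StructureFactor.values")
        if self.q_step <= 0:
            raise ValueError(f"q_step must be positive, got {self.q_step}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)


@dataclass
class DiffractionPattern:
    """Photon-count diffraction intensities with a validity mask.

    ``valid`` is False at beamstop and detector-gap pixels; the observed
    structure amplitude is ``sqrt(counts)`` wherever valid.
    """

    counts: np.ndarray
    valid: np.ndarray
    q_step: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        _check_square_even(self.counts, "DiffractionPattern.counts")
        _check_finite(self.counts, "DiffractionPattern.counts")
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.counts.shape:
            raise ValueError("valid mask shape must match counts shape")
        if np.any(self.counts[self.valid] < 0):
            raise ValueError("counts must be non-negative on valid pixels")
        if self.q_step <= 0:
            raise ValueError(f"q_step must be positive, got {self.q_step}")

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def amplitude(self) -> np.ndarray:
        """Observed structure amplitude |F_obs| = sqrt(counts), 0 where invalid."""
        amp = np.sqrt(np.clip(self.counts, 0, None))
        amp[~self.valid] = 0.0
        return amp


def radial_coordinates(n: int, q_step: float) -> np.ndarray:
    """|S| for every pixel of an ``n x n`` centered reciprocal grid (um^-1)."""
    u = np.arange(n) - n // 2
    return np.hypot(u[:, None], u[None, :]) * q_step


@dataclass
class ResolutionShells:
    """Partition of reciprocal space into equal-width ``|S|`` annuli.

    Shell ``k`` covers ``edges[k] <= |S| < edges[k+1]``; pixels beyond the
    outermost edge (grid corners) carry label ``-1`` ("outside").
    """

    n_shells: int
    edges: np.ndarray
    label: np.ndarray
    q_step: float

    @property
    def centers(self) -> np.ndarray:
        """Shell-center |S| values (um^-1)."""
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def pixel_counts(self) -> np.ndarray:
        """Number of pixels labeled into each shell."""
        inside = self.label >= 0
        return np.bincount(self.label[inside], minlength=self.n_shells)


def forward_structure_factor(dmap: DensityMap) -> StructureFactor:
    """Forward transform from projected density to structure factor.

    Returns the centered, unnormalised DFT of the density.  The q-space
    sampling is ``q_step = 1 / (N * pixel_size)`` expressed in um^-1
    (pixel_size is in nm, hence the factor 1000).
    """
    q_step = 1000.0 / (dmap.n * dmap.pixel_size)
    return StructureFactor(values=fft2c(dmap.values), q_step=q_step)


def inverse_density(
    sf: StructureFactor,
    return_imag_residue: bool = False,
):
    """Inverse transform from structure factor back to a density map.

    The real part of the inverse DFT is returned; for a Friedel-symmetric
    structure factor the imaginary residue is at rounding level.  Set
    ``return_imag_residue=True`` to also receive ``max |Im| / max |Re|``.
    """
    pixel_size = 1000.0 / (sf.n * sf.q_step)
    rho = ifft2c(sf.values)
    dmap = DensityMap(values=rho.real, pixel_size=pixel_size)
    if return_imag_residue:
        scale = np.abs(rho.real).max()
        residue = float(np.abs(rho.imag).max() / scale) if scale > 0 else 0.0
        return dmap, residue
    return dmap


def make_resolution_shells(n: int, q_step: float, n_shells: int) -> ResolutionShells:
    """Divide the reciprocal grid into ``n_shells`` equal-width |S| annuli.

    The binned range runs from 0 to the inscribed maximum ``(N/2) * q_step``;
    corner pixels beyond it are labeled outside (-1).
    """
    if n_shells < 1:
        raise ValueError(f"n_shells must be >= 1, got {n_shells}")
    q_max = (n // 2) * q_step
    edges = np.linspace(0.0, q_max, n_shells + 1)
    s = radial_coordinates(n, q_step)
    label = np.floor(s / q_max * n_shells).astype(int)
    label[s >= q_max] = -1
    return ResolutionShells(n_shells=n_shells, edges=edges, label=label, q_step=q_step)
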