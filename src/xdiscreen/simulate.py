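"""Synthetic phantoms and diffraction patterns.

The simulator emulates single-shot oversampled diffraction data from
clusters of uniform-density colloidal particles: Fraunhofer intensities
proportional to ``|F|**2``, Poisson photon statistics, a square beamstop
shadow at the smallest angles, detector panel-gap stripes, and optional
centro-symmetric (Friedel) averaging.  Background scattering is assumed to
have been subtracted upstream, so patterns here are background-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import j1

from .core import (
    DensityMap,
    DiffractionPattern,
    forward_structure_factor,
    point_reflect,
)

__all__ = [
    "PhantomSpec",
    "NoiseAndMaskSpec",
    "generate_phantom",
    "simulate_pattern",
    "centro_symmetric_average",
    "disk_structure_factor",
]


@dataclass
class PhantomSpec:
    """Recipe for a particle-cluster phantom.

    ``support_fraction`` is the linear fraction of the grid the cluster may
    occupy; keeping it at or below 0.5 per axis enforces the oversampling
    condition required for phase retrieval.
    """

    kind: str = "disk_cluster"  # disk_cluster | urchin_cluster
    n_particles: int = 10
    particle_radius_px: float = 5.0
    density: float = 1.0
    allow_overlap: bool = False
    support_fraction: float = 0.4
    seed: int = 0
    n_spikes: int = 12  # urchin only

    def __post_init__(self) -> None:
        if self.kind not in ("disk_cluster", "urchin_cluster"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if not 0 < self.support_fraction <= 0.5:
            raise ValueError("support_fraction must lie in (0, 0.5] (oversampling)")


@dataclass
class NoiseAndMaskSpec:
    """Photon budget, beamstop/gap mask geometry and symmetrisation flags.

    ``total_photons`` is the expected photon count summed over valid pixels;
    ``None`` disables rescaling so intensities are exactly ``|F|**2``.
    ``apply_poisson=False`` gives the noiseless limit.
    """

    total_photons: float | None = 1e8
    beamstop_halfwidth_px: int = 3
    gap_rows: tuple = ()
    gap_cols: tuple = ()
    apply_poisson: bool = True
    apply_friedel_average: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_photons is not None and self.total_photons <= 0:
            raise ValueError("total_photons must be positive")


def _disk_coverage(n: int, cx: float, cy: float, radius: float,
                   subsamples: int = 8) -> np.ndarray:
    # area-exact rasterisation: interior/exterior pixels are 0/1, boundary
    # pixels get their covered fraction from a subsample grid
    idx = np.arange(n)
    d = np.hypot(idx[:, None] - cx, idx[None, :] - cy)
    cov = (d <= radius).astype(float)
    boundary = np.abs(d - radius) < 0.75
    if boundary.any():
        offs = (np.arange(subsamples) + 0.5) / subsamples - 0.5
        bi, bj = np.nonzero(boundary)
        sx = bi[:, None, None] + offs[None, :, None] - cx
        sy = bj[:, None, None] + offs[None, None, :] - cy
        frac = (sx**2 + sy**2 <= radius**2).mean(axis=(1, 2))
        cov[bi, bj] = frac
    return cov


def _urchin(n: int, cx: float, cy: float, radius: float, n_spikes: int,
            phase: float) -> np.ndarray:
    body = _disk_coverage(n, cx, cy, radius)
    idx = np.arange(n)
    dx = idx[:, None] - cx
    dy = idx[None, :] - cy
    d = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    spikes = np.zeros((n, n))
    spike_len = 0.5 * radius
    half_width = np.pi / n_spikes * 0.5
    for k in range(n_spikes):
        ang = phase + 2 * np.pi * k / n_spikes
        dtheta = np.abs(np.angle(np.exp(1j * (theta - ang))))
        taper = 1.0 - np.clip((d - radius) / spike_len, 0.0, 1.0)
        in_spike = (d > radius) & (d <= radius + spike_len) & (dtheta <= half_width * taper)
        spikes[in_spike] = 1.0
    return np.clip(body + spikes, 0.0, 1.0)


def generate_phantom(spec: PhantomSpec, grid_n: int, pixel_size: float = 25.0,
                     max_retries: int = 2000, return_centers: bool = False):
    """Place ``n_particles`` disks (or urchins) in the central support box.

    Particle centers are drawn uniformly inside the box of linear size
    ``support_fraction * grid_n`` centered on the grid, with rejection
    sampling enforcing non-overlap when requested.  Deterministic for a
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = grid_n
    r = spec.particle_radius_px
    half_box = 0.5 * spec.support_fraction * n
    # particle (plus urchin spikes) must stay inside the support box
    reach = r * (1.5 if spec.kind == "urchin_cluster" else 1.0)
    lo, hi = n / 2 - half_box + reach, n / 2 + half_box - reach
    if hi <= lo:
        raise ValueError("particles do not fit in the support box; "
                         "reduce particle_radius_px or raise support_fraction")
    centers: list[tuple[float, float]] = []
    retries = 0
    while len(centers) < spec.n_particles:
        cx, cy = rng.uniform(lo, hi, size=2)
        if not spec.allow_overlap and any(
            np.hypot(cx - px, cy - py) < 2 * r for px, py in centers
        ):
            retries += 1
            if retries > max_retries:
                raise RuntimeError(
                    f"could not place {spec.n_particles} non-overlapping particles "
                    f"after {retries} retries"
                )
            continue
        centers.append((cx, cy))
    values = np.zeros((n, n))
    for cx, cy in centers:
        if spec.kind == "disk_cluster":
            values += spec.density * _disk_coverage(n, cx, cy, r)
        else:
            values += spec.density * _urchin(n, cx, cy, r, spec.n_spikes,
                                             phase=rng.uniform(0, 2 * np.pi))
    dmap = DensityMap(values=values, pixel_size=pixel_size)
    if return_centers:
        return dmap, centers
    return dmap


def _build_valid_mask(n: int, noise: NoiseAndMaskSpec) -> np.ndarray:
    valid = np.ones((n, n), dtype=bool)
    h = noise.beamstop_halfwidth_px
    if h > 0:
        u = np.abs(np.arange(n) - n // 2)
        valid[np.ix_(u <= h, u <= h)] = False
    for lo, hi in noise.gap_rows:
        valid[lo:hi, :] = False
    for lo, hi in noise.gap_cols:
        valid[:, lo:hi] = False
    if not valid.any():
        raise ValueError("mask leaves no valid pixels")
    return valid


def simulate_pattern(dmap: DensityMap, noise: NoiseAndMaskSpec) -> DiffractionPattern:
    """Oversampled Fraunhofer pattern of ``dmap`` with noise and masking.

    Expected intensities are ``|F|**2`` scaled so that their sum over valid
    pixels equals ``total_photons``; counts are then Poisson draws unless
    ``apply_poisson`` is off.  Rejects maps violating the oversampling
    condition (object extending beyond the central half-box).
    """
    n = dmap.n
    nz = np.argwhere(dmap.values != 0)
    if nz.size:
        mins, maxs = nz.min(axis=0), nz.max(axis=0)
        if (mins < n // 4).any() or (maxs >= 3 * n // 4).any():
            raise ValueError(
                "oversampling violated: object extends beyond the central "
                f"half-box (rows {mins[0]}..{maxs[0]}, cols {mins[1]}..{maxs[1]})"
            )
    sf = forward_structure_factor(dmap)
    lam = np.abs(sf.values) ** 2
    valid = _build_valid_mask(n, noise)
    if noise.total_photons is not None:
        lam *= noise.total_photons / lam[valid].sum()
    if noise.apply_poisson:
        rng = np.random.default_rng(noise.seed)
        counts = rng.poisson(lam).astype(float)
    else:
        counts = lam
    counts[~valid] = 0.0
    pattern = DiffractionPattern(counts=counts, valid=valid, q_step=sf.q_step)
    if noise.apply_friedel_average:
        pattern = centro_symmetric_average(pattern)
    return pattern


def centro_symmetric_average(p: DiffractionPattern) -> DiffractionPattern:
    """Average each pixel with its Friedel mate ``-S``.

    Where both pixels of a pair are valid their mean is assigned to both;
    where only one is valid its value is copied to both (recovering pixels
    lost to panel gaps); where neither is valid the pixel stays invalid.
    The output is exactly Friedel-symmetric on its valid set, and the
    per-pixel Poisson variance on doubly-valid pairs is halved.
    """
    c = p.counts
    v = p.valid
    cr = point_reflect(c)
    vr = point_reflect(v)
    both = v & vr
    only_self = v & ~vr
    only_mate = vr & ~v
    out = np.zeros_like(c)
    out[both] = 0.5 * (c[both] + cr[both])
    out[only_self] = c[only_self]
    out[only_mate] = cr[only_mate]
    return DiffractionPattern(counts=out, valid=v | vr, q_step=p.q_step)


def disk_structure_factor(r0: float, c: float, q: np.ndarray) -> np.ndarray:
    """Signed Airy amplitude of a uniform disk of radius ``r0``.

    ``C * 2 J1(2 pi r0 q) / (2 pi r0 q)``, with value ``C`` at ``q = 0``.
    The sign of the returned amplitude alternates between consecutive zeros
    of ``J1``, encoding the 0/pi phase structure of the disk transform:
    two disks of different radius have per-annulus phase differences that
    are exactly 0 or pi.
    """
    if r0 <= 0:
        raise ValueError(f"disk radius must be positive, got {r0}")
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("scattering-vector lengths must be non-negative")
    x = 2 * np.pi * r0 * q
    out = np.empty_like(x)
    small = x < 1e-12
    out[small] = c
    xs = x[~small]
    out[~small] = c * 2 * j1(xs) / xs
    return out
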