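"""Similarity score, lack of identity, shell trig statistics, FoM, PRTF.

The central quantity is the similarity score between two retrieved maps,

    score(i, j) = sqrt( sum (rho_i - rho_j)**2 / sum (rho_i + rho_j)**2 ),

which by Parseval's theorem equals its reciprocal-space counterpart
``sqrt( sum |F_i - F_j|**2 / sum |F_i + F_j|**2 )``.  When the two maps
share the observed amplitudes |F_obs| (as retrieved maps do), writing
``dalpha = alpha_i - alpha_j`` gives

    |F_i - F_j| = 2 |F_obs| |sin(dalpha/2)|   (the "lack of identity")
    |F_i + F_j| = 2 |F_obs| |cos(dalpha/2)|

so the score is an amplitude-weighted ratio of the sine and cosine of
half the phase difference.  Because low-resolution amplitudes dominate
the weights, the score predominantly measures agreement of the maps'
low-resolution structure — this is what makes it a good screening metric.

Resolution-resolved diagnostics decompose the same trigonometry onto
equal-width |S| shells: the per-shell means of |cos(dalpha/2)| and
|sin(dalpha/2)| (amplitude-unweighted frequency averages), whose limit
for uniformly random phase differences is 2/pi ~ 0.64 (the "random phase
limit"); the figure of merit (magnitude of the probability-weighted mean
phasor of the phase distribution, 0.5 corresponding to a +-60 degree
spread); and the phase-retrieval transfer function (shell-averaged
magnitude of the mean phasor over an ensemble of maps), judged against
fixed thresholds (0.5, 1/e) or the shell-size-dependent half-bit
information curve to estimate an effective resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DensityMap, ResolutionShells, StructureFactor, forward_structure_factor

__all__ = [
    "RANDOM_PHASE_LIMIT",
    "PairPhaseField",
    "ShellTrigSummary",
    "PRTFCurve",
    "FoMMap",
    "similarity_score_real",
    "similarity_score_reciprocal",
    "pair_phase_difference",
    "shell_trig_terms",
    "shell_score_constant_phase",
    "random_phase_limit",
    "fom_map",
    "prtf_curve",
    "half_bit_curve",
    "effective_resolution",
    "score_matrix",
]

#: Closed-form limit of <|cos(dalpha/2)|> (and <|sin(dalpha/2)|>) for
#: uniformly random phase differences: 2/pi, printed as 0.64.
RANDOM_PHASE_LIMIT = 2.0 / np.pi


# ---------------------------------------------------------------------------
# result containers


@dataclass
class PairPhaseField:
    """Per-pixel phase-difference geometry of a map pair (shared |F_obs|)."""

    delta_alpha: np.ndarray   # alpha_i - alpha_j wrapped to (-pi, pi]
    loi: np.ndarray           # lack of identity |F_i - F_j|
    a_field: np.ndarray       # |F_obs| * exp(i (alpha_i + alpha_j) / 2)
    valid: np.ndarray


@dataclass
class ShellTrigSummary:
    """Per-shell averaged |cos(dalpha/2)| and |sin(dalpha/2)| with spreads.

    Empty shells carry NaN, not zero.
    """

    mean_cos: np.ndarray
    mean_sin: np.ndarray
    std_cos: np.ndarray
    std_sin: np.ndarray
    counts: np.ndarray
    shell_centers: np.ndarray


@dataclass
class PRTFCurve:
    """Shell-averaged magnitude of the ensemble-mean phasor."""

    values: np.ndarray
    shell_centers: np.ndarray
    n_maps: int


@dataclass
class FoMMap:
    """Per-pixel figure of merit of the phase distribution across maps."""

    values: np.ndarray
    n_maps: int


# ---------------------------------------------------------------------------
# scores


def _as_values(x) -> np.ndarray:
    return x.values if hasattr(x, "values") else np.asarray(x)


def similarity_score_real(mi: DensityMap, mj: DensityMap, norm: str = "l2") -> float:
    """Similarity score between two aligned maps in real space.

    The default L2 form is ``sqrt(sum (ri - rj)**2 / sum (ri + rj)**2)``:
    zero iff the maps are identical, symmetric in the pair, and equal to 1
    against an all-zero partner.  A non-default L1 variant
    (``sum|ri - rj| / sum|ri + rj|``) is provided for comparison.
    """
    a = _as_values(mi)
    b = _as_values(mj)
    if a.shape != b.shape:
        raise ValueError(f"maps must share a grid, got {a.shape} vs {b.shape}")
    if norm == "l2":
        denom = np.sum((a + b) ** 2)
        if denom == 0:
            raise ValueError("similarity score undefined: sum (ri + rj)**2 is zero")
        return float(np.sqrt(np.sum((a - b) ** 2) / denom))
    if norm == "l1":
        denom = np.sum(np.abs(a + b))
        if denom == 0:
            raise ValueError("similarity score undefined: sum |ri + rj| is zero")
        return float(np.sum(np.abs(a - b)) / denom)
    raise ValueError(f"unknown norm {norm!r}")


def similarity_score_reciprocal(
    fi: StructureFactor | np.ndarray,
    fj: StructureFactor | np.ndarray,
    valid: np.ndarray | None = None,
) -> float:
    """Similarity score computed from structure factors.

    Restricted to ``valid`` pixels when a mask is given; with full-grid
    validity this equals :func:`similarity_score_real` exactly (Parseval).
    """
    a = _as_values(fi)
    b = _as_values(fj)
    if a.shape != b.shape:
        raise ValueError(f"structure factors must share a grid, got {a.shape} vs {b.shape}")
    if valid is None:
        valid = np.ones(a.shape, dtype=bool)
    num = np.sum(np.abs(a[valid] - b[valid]) ** 2)
    den = np.sum(np.abs(a[valid] + b[valid]) ** 2)
    if den == 0:
        raise ValueError("similarity score undefined: sum |Fi + Fj|**2 is zero")
    return float(np.sqrt(num / den))


def pair_phase_difference(
    fi: StructureFactor | np.ndarray,
    fj: StructureFactor | np.ndarray,
    amplitude: np.ndarray | None = None,
    valid: np.ndarray | None = None,
) -> PairPhaseField:
    """Phase difference, lack of identity and averaged-phase field of a pair.

    ``amplitude`` defaults to ``|F_i|`` (retrieved maps share the observed
    amplitudes, so any member's modulus is |F_obs|).
    """
    a = _as_values(fi)
    b = _as_values(fj)
    if a.shape != b.shape:
        raise ValueError("structure factors must share a grid")
    alpha_i = np.angle(a)
    alpha_j = np.angle(b)
    delta = alpha_i - alpha_j
    # wrap to (-pi, pi]
    delta = np.angle(np.exp(1j * delta))
    loi = np.abs(a - b)
    amp = np.abs(a) if amplitude is None else np.asarray(amplitude, dtype=float)
    a_field = amp * np.exp(0.5j * (alpha_i + alpha_j))
    if valid is None:
        valid = np.ones(a.shape, dtype=bool)
    return PairPhaseField(delta_alpha=delta, loi=loi, a_field=a_field, valid=valid)


def shell_score_constant_phase(delta_alpha: float) -> float:
    """Similarity score of a shell with constant phase difference.

    For a uniform-disk (monopole) object the phase difference between two
    reconstructions is 0 or pi throughout each annulus between Bessel
    zeros, and the shell-restricted score collapses to ``|tan(dalpha/2)|``:
    0 at dalpha = 0 and divergent (+inf) at dalpha = pi.
    """
    if not 0 <= delta_alpha <= np.pi:
        raise ValueError(f"delta_alpha must lie in [0, pi], got {delta_alpha}")
    if delta_alpha == np.pi:
        return float("inf")
    return float(abs(np.tan(0.5 * delta_alpha)))


def random_phase_limit(n_samples: int = 1_000_000, seed: int = 0) -> float:
    """Monte-Carlo estimate of <|cos(dalpha/2)|> for uniform phase differences.

    Converges to the closed form :data:`RANDOM_PHASE_LIMIT` = 2/pi
    (printed as 0.64).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    delta = rng.uniform(-np.pi, np.pi, size=n_samples)
    return float(np.mean(np.abs(np.cos(0.5 * delta))))


# ---------------------------------------------------------------------------
# shell statistics


def _to_structure_factors(maps_or_sfs) -> list[np.ndarray]:
    out = []
    for x in maps_or_sfs:
        if isinstance(x, DensityMap):
            out.append(forward_structure_factor(x).values)
        else:
            out.append(_as_values(x))
    return out


def _shell_stats(samples: np.ndarray, labels: np.ndarray, n_shells: int):
    """Mean/std/count of per-pixel samples grouped by shell label."""
    counts = np.bincount(labels, minlength=n_shells).astype(float)
    sums = np.bincount(labels, weights=samples, minlength=n_shells)
    sq = np.bincount(labels, weights=samples**2, minlength=n_shells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
        var = np.where(counts > 0, sq / np.where(counts > 0, counts, 1) - mean**2, np.nan)
    std = np.sqrt(np.clip(var, 0, None))
    return mean, std, counts


def shell_trig_terms(
    maps_or_sfs,
    shells: ResolutionShells,
    valid: np.ndarray | None = None,
    pairs: str = "all",
) -> ShellTrigSummary:
    """Averaged cosine and sine terms of half the phase difference per shell.

    For every unordered pair of the supplied set (``pairs="all"``) or only
    the first two members (``pairs="best"``, the best-pair convention) and
    every valid pixel of shell k, |cos(dalpha/2)| and |sin(dalpha/2)| are
    accumulated; means and standard deviations are amplitude-unweighted
    (the phase-difference appearance *frequency* defines the average).
    """
    sfs = _to_structure_factors(maps_or_sfs)
    if len(sfs) < 2:
        raise ValueError("shell_trig_terms needs at least 2 maps")
    if pairs == "best":
        sfs = sfs[:2]
    elif pairs != "all":
        raise ValueError(f"pairs must be 'all' or 'best', got {pairs!r}")
    if valid is None:
        valid = np.ones(sfs[0].shape, dtype=bool)
    mask = valid & (shells.label >= 0)
    labels = shells.label[mask]
    n_shells = shells.n_shells
    cos_all, sin_all, lab_all = [], [], []
    phases = [np.angle(f) for f in sfs]
    m = len(sfs)
    for i in range(m - 1):
        for j in range(i + 1, m):
            half = 0.5 * (phases[i] - phases[j])[mask]
            cos_all.append(np.abs(np.cos(half)))
            sin_all.append(np.abs(np.sin(half)))
            lab_all.append(labels)
    cos_s = np.concatenate(cos_all)
    sin_s = np.concatenate(sin_all)
    lab = np.concatenate(lab_all)
    mean_cos, std_cos, counts = _shell_stats(cos_s, lab, n_shells)
    mean_sin, std_sin, _ = _shell_stats(sin_s, lab, n_shells)
    return ShellTrigSummary(mean_cos=mean_cos, mean_sin=mean_sin,
                            std_cos=std_cos, std_sin=std_sin,
                            counts=counts, shell_centers=shells.centers)


def fom_map(maps_or_sfs, n_bins: int | None = 36) -> FoMMap:
    """Figure of merit of the per-pixel phase distribution across maps.

    ``FoM(S) = | sum_bins P[alpha_bin(S)] exp(i alpha_bin) |`` with P the
    normalised histogram of the maps' phases at S (``n_bins`` bins over
    (-pi, pi]).  ``n_bins=None`` gives the fine-bin limit, the magnitude
    of the plain mean phasor.  Equals 1 wherever all phases coincide; 0.5
    marks phases spread +-60 degrees about their mean (the conventional
    interpretability threshold).
    """
    sfs = _to_structure_factors(maps_or_sfs)
    m = len(sfs)
    if m < 2:
        raise ValueError("fom_map needs at least 2 maps")
    phases = np.stack([np.angle(f) for f in sfs])  # (M, N, N)
    if n_bins is None:
        resultant = np.mean(np.exp(1j * phases), axis=0)
        return FoMMap(values=np.abs(resultant), n_maps=m)
    # histogram per pixel: map each phase to its bin center, then average
    # the bin-center phasors weighted by appearance frequency -- identical
    # to |sum_b P_b exp(i alpha_b)|
    width = 2 * np.pi / n_bins
    bin_idx = np.floor((phases + np.pi) / width).astype(int)
    bin_idx = np.clip(bin_idx, 0, n_bins - 1)
    centers = -np.pi + (bin_idx + 0.5) * width
    resultant = np.mean(np.exp(1j * centers), axis=0)
    return FoMMap(values=np.abs(resultant), n_maps=m)


def prtf_curve(maps_or_sfs, shells: ResolutionShells,
               valid: np.ndarray | None = None) -> PRTFCurve:
    """Phase-retrieval transfer function of an ensemble.

    Per pixel ``|(1/M) sum_m exp(i alpha_m(S))|``, then circularly (shell)
    averaged.  For M = 2 this equals the shell mean of |cos(dalpha/2)|.
    """
    sfs = _to_structure_factors(maps_or_sfs)
    m = len(sfs)
    if m < 2:
        raise ValueError("prtf_curve needs at least 2 maps")
    phasor = np.mean(np.stack([np.exp(1j * np.angle(f)) for f in sfs]), axis=0)
    per_pixel = np.abs(phasor)
    if valid is None:
        valid = np.ones(per_pixel.shape, dtype=bool)
    mask = valid & (shells.label >= 0)
    mean, _, _ = _shell_stats(per_pixel[mask], shells.label[mask], shells.n_shells)
    return PRTFCurve(values=mean, shell_centers=shells.centers, n_maps=m)


def half_bit_curve(shells: ResolutionShells,
                   pixel_counts: np.ndarray | None = None) -> np.ndarray:
    """Half-bit information threshold per shell.

    ``T(k) = (0.2071 + 1.9102 / sqrt(n_k)) / (1.2071 + 0.9102 / sqrt(n_k))``
    with ``n_k`` the number of independent Fourier samples in shell k
    (pixel count halved for Friedel symmetry, floored at 1).  Decreases
    monotonically toward 0.2071/1.2071 ~ 0.1716; empty shells are NaN.
    """
    counts = shells.pixel_counts() if pixel_counts is None else np.asarray(pixel_counts)
    n_k = np.maximum(counts / 2.0, 1.0)
    t = (0.2071 + 1.9102 / np.sqrt(n_k)) / (1.2071 + 0.9102 / np.sqrt(n_k))
    t = np.where(counts > 0, t, np.nan)
    return t


def effective_resolution(
    curve_values: np.ndarray,
    shell_centers: np.ndarray,
    mode: str = "random_phase_limit",
    threshold: float | None = None,
    shells: ResolutionShells | None = None,
):
    """Effective resolution from the first threshold crossing of a curve.

    Scans shells outward and returns the first shell-center q at which the
    curve falls to or below the criterion: the printed random phase limit
    0.64 (``mode="random_phase_limit"``), the per-shell half-bit values
    (``mode="half_bit"``, requires ``shells``), or a fixed threshold such
    as 0.5 or 1/e (``mode="fixed_threshold"``).

    Returns ``(q_star, 1000 / q_star, crossed)`` with q in um^-1 and the
    resolution in nm.  If the curve never crosses, the largest recorded q
    is returned with ``crossed=False`` (the curve is still informative at
    the highest resolution recorded).
    """
    values = np.asarray(curve_values, dtype=float)
    centers = np.asarray(shell_centers, dtype=float)
    defined = ~np.isnan(values)
    if defined.sum() < 2:
        raise ValueError("effective_resolution needs a curve on >= 2 shells")
    if mode == "random_phase_limit":
        crit = np.full_like(values, 0.64)
    elif mode == "half_bit":
        if shells is None:
            raise ValueError("half_bit mode requires the shell geometry")
        crit = half_bit_curve(shells)
    elif mode == "fixed_threshold":
        if threshold is None:
            raise ValueError("fixed_threshold mode requires a threshold")
        crit = np.full_like(values, threshold)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    for k in np.flatnonzero(defined):
        if not np.isnan(crit[k]) and values[k] <= crit[k]:
            q = float(centers[k])
            return q, 1000.0 / q if q > 0 else float("inf"), True
    q = float(centers[defined][-1])
    return q, 1000.0 / q if q > 0 else float("inf"), False


def score_matrix(maps: list, norm: str = "l2") -> np.ndarray:
    """Symmetric matrix of pairwise similarity scores of aligned maps."""
    m = len(maps)
    if m < 2:
        raise ValueError("score_matrix needs at least 2 maps")
    out = np.zeros((m, m))
    for i in range(m - 1):
        for j in range(i + 1, m):
            s = similarity_score_real(maps[i], maps[j], norm=norm)
            out[i, j] = out[j, i] = s
    return out
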