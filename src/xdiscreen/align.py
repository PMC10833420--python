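"""Registration of retrieved maps to a common frame.

Because the diffraction intensities are centro-symmetric, a retrieved map
is only defined up to a circular translation and a point reflection
(pi rotation).  Maps are registered by (1) center-of-gravity matching,
(2) phase-only correlation (POC) for the integer translation, and (3)
comparing the POC peak of a map against that of its point reflection to
resolve the pi-rotation ambiguity.  The reference frame itself is chosen
by a two-pass procedure: the pair of maps with the smallest similarity
score among all pairs is deemed the most probable pair and its
lower-index member becomes the reference.

All shifts are integer and circular (toroidal); legitimate because the
oversampling condition keeps the object within the central half-box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DensityMap, point_reflect

__all__ = [
    "AlignmentResult",
    "ReferenceSelection",
    "align_center_of_gravity",
    "phase_only_correlation_shift",
    "correct_pi_rotation",
    "select_reference",
    "all_pairs",
]


@dataclass
class AlignmentResult:
    """Outcome of registering one map against a reference."""

    shift: tuple  # (dx, dy): displacement of the map relative to the reference
    pi_rotated: bool = False
    poc_peak: float = 0.0


@dataclass
class ReferenceSelection:
    """Two-pass reference search output."""

    reference_index: int
    best_pair: tuple
    aligned_maps: list
    pairwise_scores: np.ndarray       # pass 1, centroid-aligned, all pairs
    scores_vs_reference: np.ndarray   # pass 2, POC-aligned, vs reference
    alignments: list


def _roll_map(dmap: DensityMap, shift: tuple) -> DensityMap:
    return DensityMap(values=np.roll(dmap.values, shift, axis=(0, 1)),
                      pixel_size=dmap.pixel_size,
                      support=None if dmap.support is None
                      else np.roll(dmap.support, shift, axis=(0, 1)))


def _wrap_shift(s: int, n: int) -> int:
    s %= n
    return s - n if s > n // 2 else s


def align_center_of_gravity(dmap: DensityMap, ref: DensityMap) -> DensityMap:
    """Circularly shift ``dmap`` so its density centroid matches the
    reference's, to the nearest integer pixel.  Total density is conserved
    exactly (circular shift)."""
    cm = dmap.centroid()
    cr = ref.centroid()
    shift = (int(round(cr[0] - cm[0])), int(round(cr[1] - cm[1])))
    return _roll_map(dmap, shift)


def phase_only_correlation_shift(dmap: DensityMap, ref: DensityMap) -> AlignmentResult:
    """Integer translation of ``dmap`` relative to ``ref`` by POC.

    The cross-power spectrum normalised to unit amplitude is inverse
    transformed; the argmax locates the shift ``s`` such that
    ``dmap ~ roll(ref, s)`` and the peak height (in [0, 1], 1 for a pure
    circular shift) measures registration confidence.
    """
    a = dmap.values
    b = ref.values
    if not a.any() or not b.any():
        raise ValueError("phase-only correlation of an all-zero map is undefined")
    r = np.fft.fft2(a) * np.conj(np.fft.fft2(b))
    mag = np.abs(r)
    nonzero = mag > 0
    if not nonzero.any():
        raise ValueError("degenerate (flat) cross-power spectrum")
    r = np.where(nonzero, r / np.where(nonzero, mag, 1.0), 0.0)
    corr = np.fft.ifft2(r).real
    peak_idx = np.unravel_index(np.argmax(corr), corr.shape)
    n = a.shape[0]
    shift = (_wrap_shift(int(peak_idx[0]), n), _wrap_shift(int(peak_idx[1]), n))
    return AlignmentResult(shift=shift, poc_peak=float(corr[peak_idx]))


def correct_pi_rotation(dmap: DensityMap, ref: DensityMap):
    """Resolve the point-reflection ambiguity while aligning to ``ref``.

    POC is evaluated for the map and for its point reflection; the variant
    with the higher peak is translated into register and returned together
    with the alignment record.  Exact peak ties resolve to "not rotated".
    """
    res_id = phase_only_correlation_shift(dmap, ref)
    reflected = DensityMap(values=point_reflect(dmap.values),
                           pixel_size=dmap.pixel_size,
                           support=None if dmap.support is None
                           else point_reflect(dmap.support))
    res_pi = phase_only_correlation_shift(reflected, ref)
    if res_pi.poc_peak > res_id.poc_peak:
        chosen, res, flag = reflected, res_pi, True
    else:
        chosen, res, flag = dmap, res_id, False
    aligned = _roll_map(chosen, (-res.shift[0], -res.shift[1]))
    return aligned, AlignmentResult(shift=res.shift, pi_rotated=flag,
                                    poc_peak=res.poc_peak)


def all_pairs(m: int):
    """Unordered index pairs (i < j) among ``m`` maps; m*(m-1)/2 of them."""
    for i in range(m - 1):
        for j in range(i + 1, m):
            yield i, j


def select_reference(maps: list) -> ReferenceSelection:
    """Two-pass reference search over an ensemble of retrieved maps.

    Pass 1: centroid-align every map to an arbitrary member (index 0) and
    compute the similarity score for all unordered pairs; the pair with
    the smallest score is the most probable pair and its lower-index
    member becomes the reference (ties break lexicographically).

    Pass 2: POC-align every map, with pi-rotation correction, to the
    reference and recompute the scores against the reference.
    """
    from .scoring import similarity_score_real

    m = len(maps)
    if m < 2:
        raise ValueError(f"need at least 2 maps to select a reference, got {m}")
    centroid_aligned = [maps[0]] + [align_center_of_gravity(x, maps[0])
                                    for x in maps[1:]]
    pairwise = np.zeros((m, m))
    best = None
    best_pair = (0, 1)
    for i, j in all_pairs(m):
        s = similarity_score_real(centroid_aligned[i], centroid_aligned[j])
        pairwise[i, j] = pairwise[j, i] = s
        if best is None or s < best:
            best = s
            best_pair = (i, j)
    ref_idx = best_pair[0]
    ref = maps[ref_idx]
    aligned, alignments, scores = [], [], np.zeros(m)
    for i, x in enumerate(maps):
        ax, res = correct_pi_rotation(x, ref)
        aligned.append(ax)
        alignments.append(res)
        scores[i] = similarity_score_real(ax, ref)
    return ReferenceSelection(reference_index=ref_idx, best_pair=best_pair,
                              aligned_maps=aligned, pairwise_scores=pairwise,
                              scores_vs_reference=scores, alignments=alignments)
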