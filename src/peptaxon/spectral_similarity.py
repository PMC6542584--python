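"""Spectrum-level sample comparison via modified cosine of peak intensities.

This is the spectrum-domain counterpart of the peptide-list comparison:
fragment peaks of two spectra are paired greedily (1:1, smallest m/z gap
first) within a fragment tolerance, and the cosine is taken over the paired
intensity products against the full intensity norms.  Two samples are then
compared by the fraction of spectra in each that find a qualifying partner
(precursor within tolerance, cosine above threshold) in the other.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Sequence

import math

from .formats_io import SpectrumRecord


@dataclass(frozen=True)
class SpectralMatch:
    query_spectrum_id: str
    best_target_id: str | None
    cosine: float
    n_matched_peaks: int


def cosine_score(
    a: SpectrumRecord, b: SpectrumRecord, frag_tol: float = 0.02
) -> tuple[float, int]:
    """Greedy 1:1 peak-paired cosine between two spectra.

    Candidate pairs within ``frag_tol`` are consumed in ascending |Δmz| order;
    the score uses the full intensity norms so unmatched peaks penalise it.
    """
    if not a.peaks or not b.peaks:
        raise ValueError("cosine_score undefined for an empty spectrum")
    b_mzs = [p[0] for p in b.peaks]
    pairs: list[tuple[float, int, int]] = []
    for i, (mz_a, _) in enumerate(a.peaks):
        lo = bisect_left(b_mzs, mz_a - frag_tol)
        hi = bisect_right(b_mzs, mz_a + frag_tol)
        for j in range(lo, hi):
            pairs.append((abs(mz_a - b_mzs[j]), i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    dot = 0.0
    n_matched = 0
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        dot += a.peaks[i][1] * b.peaks[j][1]
        n_matched += 1
    norm_a = math.sqrt(sum(p[1] ** 2 for p in a.peaks))
    norm_b = math.sqrt(sum(p[1] ** 2 for p in b.peaks))
    if norm_a == 0.0 or norm_b == 0.0:
        return 0.0, n_matched
    return dot / (norm_a * norm_b), n_matched


def best_match(
    query: SpectrumRecord,
    targets: Sequence[SpectrumRecord],
    target_precursors: Sequence[float],
    prec_tol: float = 1.5,
    frag_tol: float = 0.02,
) -> SpectralMatch:
    """Best cosine match for one query among precursor-compatible targets.

    ``target_precursors`` must be the sorted precursor m/z list of ``targets``
    (targets sorted accordingly).
    """
    lo = bisect_left(target_precursors, query.precursor_mz - prec_tol)
    hi = bisect_right(target_precursors, query.precursor_mz + prec_tol)
    best_cos, best_id, best_n = 0.0, None, 0
    for j in range(lo, hi):
        cos, n = cosine_score(query, targets[j], frag_tol)
        if cos > best_cos:
            best_cos, best_id, best_n = cos, targets[j].spectrum_id, n
    return SpectralMatch(query.spectrum_id, best_id, best_cos, best_n)


def _directional_fraction(
    src: Sequence[SpectrumRecord],
    dst: Sequence[SpectrumRecord],
    prec_tol: float,
    min_cos: float,
    frag_tol: float,
) -> float:
    ordered = sorted(dst, key=lambda s: s.precursor_mz)
    precursors = [s.precursor_mz for s in ordered]
    hits = 0
    for spectrum in src:
        match = best_match(spectrum, ordered, precursors, prec_tol, frag_tol)
        if match.cosine >= min_cos:
            hits += 1
    return hits / len(src)


def sample_spectral_similarity(
    a: Sequence[SpectrumRecord],
    b: Sequence[SpectrumRecord],
    prec_tol: float = 1.5,
    min_cos: float = 0.7,
    frag_tol: float = 0.02,
) -> float:
    """Symmetric fraction of spectra with a qualifying partner in the other sample."""
    if not a or not b:
        raise ValueError("sample_spectral_similarity undefined for an empty spectrum list")
    f_ab = _directional_fraction(a, b, prec_tol, min_cos, frag_tol)
    f_ba = _directional_fraction(b, a, prec_tol, min_cos, frag_tol)
    return 0.5 * (f_ab + f_ba)
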