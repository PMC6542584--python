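"""Peptide-list similarity, classical MDS and shared-protein adjacency.

The core comparison is database-independent: two samples are compared purely
by the canonical peptide strings they share.  The default score is the overlap
coefficient ``|A ∩ B| / min(|A|, |B|)``, which is robust to the large size
asymmetry between sparse degraded samples and rich reference digests; Jaccard
``|A ∩ B| / |A ∪ B|`` is available as an alternative.  The all-pairwise
similarity matrix is converted to a distance matrix (``d = 1 − s``) and
embedded by classical (Torgerson) multidimensional scaling with eigenvalue
clamping; Kruskal stress-1 is always reported so embedding distortion from
non-Euclidean input is visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .peptide_prep import CanonicalPeptide
from .reference_matching import CoverageProfile, ProteinCall

SIMILARITY_MODES = ("overlap", "jaccard")


@dataclass
class SimilarityMatrix:
    labels: list[str]
    s: np.ndarray

    def value(self, a: str, b: str) -> float:
        return float(self.s[self.labels.index(a), self.labels.index(b)])


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray


@dataclass
class MDSEmbedding:
    labels: list[str]
    coords: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # retained top-k spectrum, clamped at zero
    stress1: float


@dataclass
class AdjacencyWeights:
    """Weights for a chord-style shared-protein diagram.

    ``ref_segment``: per reference sample, the sum over its shared ids of the
    mean coverage of that id across the query samples where it was detected.
    ``query_segment``: per (query, reference) pair, the summed unique-peptide
    support in the query for ids detected in both.  ``band``: per pair, the
    number of shared ids.
    """

    shared_ids: list[str]
    ref_segment: dict[str, float]
    query_segment: dict[tuple[str, str], float]
    band: dict[tuple[str, str], int]


def _as_strings(peps: Iterable[CanonicalPeptide | str]) -> set[str]:
    return {p.canonical if isinstance(p, CanonicalPeptide) else p for p in peps}


def pepmatch_score(
    a: Iterable[CanonicalPeptide | str],
    b: Iterable[CanonicalPeptide | str],
    mode: str = "overlap",
) -> float:
    """Similarity in [0, 1] between two peptide lists on canonical strings."""
    sa, sb = _as_strings(a), _as_strings(b)
    if not sa or not sb:
        raise ValueError("pepmatch_score undefined for an empty peptide set")
    if mode not in SIMILARITY_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {SIMILARITY_MODES}")
    inter = len(sa & sb)
    if mode == "overlap":
        return inter / min(len(sa), len(sb))
    return inter / len(sa | sb)


def build_similarity_matrix(
    samples: Mapping[str, Iterable[CanonicalPeptide | str]],
    mode: str = "overlap",
) -> SimilarityMatrix:
    """All-pairwise similarity; each pair evaluated once, diagonal exactly 1."""
    labels = list(samples)
    if len(labels) < 2:
        raise ValueError("need at least 2 samples for a similarity matrix")
    sets = {k: _as_strings(v) for k, v in samples.items()}
    for label, s in sets.items():
        if not s:
            raise ValueError(f"sample {label!r} has no peptides")
    n = len(labels)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pepmatch_score(sets[labels[i]], sets[labels[j]], mode)
    return SimilarityMatrix(labels, m)


def to_distance(s: SimilarityMatrix) -> DistanceMatrix:
    d = 1.0 - s.s
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(s.labels), d)


def classical_mds(dist: DistanceMatrix, k: int = 2) -> MDSEmbedding:
    """Torgerson scaling: double-centre −½D², eigendecompose, scale by √λ.

    Negative eigenvalues (non-Euclidean input) are clamped to zero.  Stress-1
    is computed over the upper triangle against the embedded distances.
    """
    d = np.asarray(dist.d, dtype=float)
    n = d.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples ({n})")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1][:k]
    lam = np.clip(eigvals[order], 0.0, None)
    vecs = eigvecs[:, order]
    # deterministic sign: largest-magnitude loading of each axis positive
    for col in range(vecs.shape[1]):
        pivot = np.argmax(np.abs(vecs[:, col]))
        if vecs[pivot, col] < 0:
            vecs[:, col] = -vecs[:, col]
    coords = vecs * np.sqrt(lam)
    iu = np.triu_indices(n, 1)
    embedded = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    denom = float((d[iu] ** 2).sum())
    if denom == 0.0:
        stress1 = 0.0
    else:
        stress1 = float(np.sqrt(((d[iu] - embedded[iu]) ** 2).sum() / denom))
    return MDSEmbedding(list(dist.labels), coords, lam, stress1)


@dataclass(frozen=True)
class AttributionHit:
    reference_id: str
    score: float
    n_intersect: int


def attribute(
    query: str,
    s: SimilarityMatrix,
    reference_ids: Sequence[str],
    samples: Mapping[str, Iterable[CanonicalPeptide | str]] | None = None,
) -> list[AttributionHit]:
    """Rank references by similarity to the query, descending.

    Ties are broken by larger raw intersection count (when the peptide sets
    are supplied), then by label order.  A top score of 0 means no signal.
    """
    if query in reference_ids:
        raise ValueError(f"query {query!r} appears among reference_ids")
    missing = [r for r in (query, *reference_ids) if r not in s.labels]
    if missing:
        raise ValueError(f"labels not in similarity matrix: {missing}")
    inter: dict[str, int] = {}
    if samples is not None:
        qset = _as_strings(samples[query])
        for r in reference_ids:
            inter[r] = len(qset & _as_strings(samples[r]))
    hits = [
        AttributionHit(r, s.value(query, r), inter.get(r, 0)) for r in reference_ids
    ]
    order = {r: i for i, r in enumerate(reference_ids)}
    hits.sort(key=lambda h: (-h.score, -h.n_intersect, order[h.reference_id]))
    return hits


def _detected(calls: Sequence[ProteinCall]) -> dict[tuple[str, str], ProteinCall]:
    return {
        (c.sample_id, c.entry_id): c for c in calls if c.tier != "absent"
    }


def adjacency_weights(
    query_calls: Sequence[ProteinCall],
    query_profiles: Sequence[CoverageProfile],
    ref_calls: Sequence[ProteinCall],
) -> AdjacencyWeights:
    """Shared-protein adjacency weights between query and reference samples.

    An id is "detected" in a sample when its protein call tier is not absent.
    """
    q_universe = {c.entry_id for c in query_calls}
    r_universe = {c.entry_id for c in ref_calls}
    if not (q_universe & r_universe):
        raise ValueError("query and reference calls share no reference entries")
    q_det = _detected(query_calls)
    r_det = _detected(ref_calls)
    q_samples = sorted({c.sample_id for c in query_calls})
    r_samples = sorted({c.sample_id for c in ref_calls})
    q_ids = {e for (_, e) in q_det}
    r_ids = {e for (_, e) in r_det}
    shared = sorted(q_ids & r_ids)

    cov = {(p.sample_id, p.entry_id): p.coverage_pct for p in query_profiles}
    mean_query_cov: dict[str, float] = {}
    for entry_id in shared:
        values = [
            cov.get((q, entry_id), 0.0) for q in q_samples if (q, entry_id) in q_det
        ]
        mean_query_cov[entry_id] = float(np.mean(values)) if values else 0.0

    ref_segment: dict[str, float] = {}
    for r in r_samples:
        ref_segment[r] = sum(
            mean_query_cov[e] for e in shared if (r, e) in r_det
        )
    query_segment: dict[tuple[str, str], float] = {}
    band: dict[tuple[str, str], int] = {}
    uniq = {(c.sample_id, c.entry_id): c.n_unique_peptides for c in query_calls}
    for q in q_samples:
        for r in r_samples:
            both = [e for e in shared if (q, e) in q_det and (r, e) in r_det]
            band[(q, r)] = len(both)
            query_segment[(q, r)] = float(sum(uniq[(q, e)] for e in both))
    return AdjacencyWeights(shared, ref_segment, query_segment, band)
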