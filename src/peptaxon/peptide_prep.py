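"""Filtering and canonicalization of de novo peptide lists.

Peptide lists from degraded samples are noisy in two systematic ways that the
downstream comparisons must not be sensitive to: isoleucine/leucine are
indistinguishable by fragment mass, and asparagine/glutamine deamidate to
aspartate/glutamate over time (and during sample preparation).  Both are
handled here as residue equivalence classes applied before any matching:

* I → L  (``il_equiv``)
* N → D, Q → E  (``deam_tolerant``)

The standard preparation order is: ALC filter, contaminant removal, then
collapse to unique canonical peptides per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

from .formats_io import AMINO_ACIDS, PeptideTable, ReferenceSet

_IL_TABLE = str.maketrans({"I": "L"})
_DEAM_TABLE = str.maketrans({"N": "D", "Q": "E"})
_BOTH_TABLE = str.maketrans({"I": "L", "N": "D", "Q": "E"})


@dataclass(frozen=True)
class CanonicalPeptide:
    """A distinct canonical peptide string with collapse bookkeeping."""

    canonical: str
    source_count: int = 1
    max_alc: float = 0.0

    def __len__(self) -> int:
        return len(self.canonical)


def canonicalize(peptide: str, il_equiv: bool = True, deam_tolerant: bool = True) -> str:
    """Map a residue string into its equivalence-class representative.

    Deterministic and idempotent: I→L under ``il_equiv``, N→D and Q→E under
    ``deam_tolerant``; the identity when both are off.
    """
    bad = set(peptide) - AMINO_ACIDS
    if bad:
        raise ValueError(f"non-standard residue(s) {sorted(bad)} in {peptide!r}")
    if il_equiv and deam_tolerant:
        return peptide.translate(_BOTH_TABLE)
    if il_equiv:
        return peptide.translate(_IL_TABLE)
    if deam_tolerant:
        return peptide.translate(_DEAM_TABLE)
    return peptide


def filter_alc(table: PeptideTable, min_alc: float = 50.0) -> PeptideTable:
    """Keep rows with ALC >= ``min_alc`` (inclusive threshold), order preserved."""
    return PeptideTable([r for r in table if r.alc >= min_alc])


def filter_contaminants(table: PeptideTable, contaminants: ReferenceSet) -> PeptideTable:
    """Drop peptides that are substrings of any contaminant sequence.

    Matching uses I/L equivalence only (no deamidation mapping): contaminant
    removal must not be looser than the contaminant database itself.
    """
    if len(contaminants) == 0:
        return PeptideTable(list(table.records))
    canon_contaminants = [
        canonicalize(e.sequence, il_equiv=True, deam_tolerant=False) for e in contaminants
    ]
    kept = []
    for rec in table:
        probe = canonicalize(rec.peptide, il_equiv=True, deam_tolerant=False)
        if not any(probe in seq for seq in canon_contaminants):
            kept.append(rec)
    return PeptideTable(kept)


def collapse(
    table: PeptideTable,
    sample_id: str,
    min_len: int = 6,
    il_equiv: bool = True,
    deam_tolerant: bool = True,
) -> list[CanonicalPeptide]:
    """Collapse one sample's rows to unique canonical peptides of length >= min_len.

    Returns one :class:`CanonicalPeptide` per distinct canonical string, in
    lexicographic order, carrying the number of collapsed rows and the best ALC.
    """
    if sample_id not in table.sample_ids():
        raise KeyError(f"sample_id {sample_id!r} not present in table")
    buckets: dict[str, list[float]] = {}
    for rec in table:
        if rec.sample_id != sample_id:
            continue
        canon = canonicalize(rec.peptide, il_equiv=il_equiv, deam_tolerant=deam_tolerant)
        if len(canon) < min_len:
            continue
        buckets.setdefault(canon, []).append(rec.alc)
    return [
        CanonicalPeptide(canonical=c, source_count=len(alcs), max_alc=max(alcs))
        for c, alcs in sorted(buckets.items())
    ]


def canonical_set(peptides: list[CanonicalPeptide]) -> set[str]:
    """The bare canonical strings of a collapsed peptide list."""
    return {p.canonical for p in peptides}
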