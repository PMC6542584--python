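"""Substitution-tolerant peptide-to-reference mapping, coverage and calls.

The mapping stage places each canonical peptide onto every reference entry:
all exact-substring placements are kept; when a peptide has no exact placement
anywhere, placements with exactly one internal mismatch are accepted instead
(candidate amino-acid substitutions).  Coverage profiles, tiered protein calls
(stringent: >= 2 unique peptides; relaxed: >= 1, reported with an asterisk)
and per-position substitution calls are all derived from the placements.

Substitution-call symbols: ``-`` for uncovered positions, ``?`` for
ambiguous/insufficiently supported alternatives, a residue letter otherwise.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .formats_io import ReferenceEntry, ReferenceSet
from .peptide_prep import CanonicalPeptide, canonicalize


@dataclass(frozen=True)
class Substitution:
    ref_pos: int  # 1-based position in the reference sequence
    ref_res: str
    obs_res: str


@dataclass(frozen=True)
class Placement:
    """One placement of a canonical peptide on a reference entry."""

    peptide: str
    entry_id: str
    start: int  # 1-based
    end: int  # 1-based inclusive
    n_subst: int = 0
    subst: Substitution | None = None
    unique: bool = False


@dataclass
class CoverageProfile:
    """Per-residue observation depth for one (sample, reference) pair."""

    entry_id: str
    sample_id: str
    depth: np.ndarray
    observed: dict[int, Counter] = field(default_factory=dict)  # 1-based pos -> residues
    n_unique_peptides: int = 0
    n_peptides: int = 0

    @property
    def coverage_pct(self) -> float:
        if self.depth.size == 0:
            return 0.0
        return 100.0 * float(np.count_nonzero(self.depth)) / self.depth.size


@dataclass(frozen=True)
class ProteinCall:
    entry_id: str
    sample_id: str
    tier: str  # stringent | relaxed | absent
    n_unique_peptides: int
    coverage_pct: float

    @property
    def flag(self) -> str:
        """Asterisk for relaxed-tier calls, mirroring tiered reporting."""
        return "*" if self.tier == "relaxed" else ""


@dataclass
class SubstitutionTable:
    """Symbols and support per (entry_id, sample_id, 1-based position)."""

    symbols: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    support: dict[tuple[str, str], list[int]] = field(default_factory=dict)

    def symbol(self, entry_id: str, sample_id: str, position: int) -> str:
        return self.symbols[(entry_id, sample_id)][position - 1]

    def support_at(self, entry_id: str, sample_id: str, position: int) -> int:
        return self.support[(entry_id, sample_id)][position - 1]

    def n_residue_calls(self) -> int:
        return sum(
            1
            for row in self.symbols.values()
            for sym in row
            if sym not in ("-", "?")
        )


def canonicalize_references(
    refs: ReferenceSet, il_equiv: bool = True, deam_tolerant: bool = True
) -> ReferenceSet:
    """Reference sequences mapped with the same equivalence settings as peptides."""
    return ReferenceSet(
        [
            ReferenceEntry(
                entry_id=e.entry_id,
                sequence=canonicalize(e.sequence, il_equiv, deam_tolerant),
                taxon=e.taxon,
                clade=e.clade,
                is_marker=e.is_marker,
                description=e.description,
            )
            for e in refs
        ]
    )


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _placements_for_peptide(
    pep: str,
    encoded_refs: list[tuple[str, np.ndarray]],
    max_subst: int,
    min_subst_len: int,
) -> list[Placement]:
    m = len(pep)
    pep_arr = _encode(pep)
    exact: list[Placement] = []
    one_subst: list[tuple[int, Placement]] = []  # (entry input index, placement)
    for entry_idx, (entry_id, ref_arr) in enumerate(encoded_refs):
        if ref_arr.size < m:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(ref_arr, m)
        mismatch = windows != pep_arr
        n_mismatch = mismatch.sum(axis=1)
        for offset in np.nonzero(n_mismatch == 0)[0]:
            start = int(offset) + 1
            exact.append(Placement(pep, entry_id, start, start + m - 1))
        if max_subst >= 1 and m >= min_subst_len:
            for offset in np.nonzero(n_mismatch == 1)[0]:
                pos_in_pep = int(np.nonzero(mismatch[offset])[0][0])
                if pos_in_pep in (0, m - 1):
                    continue  # terminal residues are unreliable in de novo data
                start = int(offset) + 1
                ref_pos = start + pos_in_pep
                sub = Substitution(
                    ref_pos=ref_pos,
                    ref_res=chr(ref_arr[ref_pos - 1]),
                    obs_res=pep[pos_in_pep],
                )
                one_subst.append(
                    (
                        entry_idx,
                        Placement(pep, entry_id, start, start + m - 1, 1, sub),
                    )
                )
    if exact:
        return exact
    return [p for _, p in one_subst]


def place_peptides(
    peps: Iterable[CanonicalPeptide | str],
    refs: ReferenceSet,
    max_subst: int = 1,
    min_subst_len: int = 6,
) -> list[Placement]:
    """Place peptides onto references, allowing at most one internal mismatch.

    For each peptide all exact-substring placements are returned; only when
    none exists (and the peptide is at least ``min_subst_len`` long) are
    single-mismatch placements returned, with the mismatch never at a terminal
    residue.  ``unique`` is set when every retained placement of the peptide
    lies in a single entry.  Output order per peptide: fewest mismatches,
    leftmost start, entry input order.
    """
    if len(refs) == 0:
        raise ValueError("empty reference set")
    encoded = [(e.entry_id, _encode(e.sequence)) for e in refs]
    placements: list[Placement] = []
    for pep in peps:
        seq = pep.canonical if isinstance(pep, CanonicalPeptide) else pep
        found = _placements_for_peptide(seq, encoded, max_subst, min_subst_len)
        if not found:
            continue
        found.sort(key=lambda p: (p.n_subst, p.start, refs.index_of(p.entry_id)))
        unique = len({p.entry_id for p in found}) == 1
        placements.extend(
            Placement(p.peptide, p.entry_id, p.start, p.end, p.n_subst, p.subst, unique)
            for p in found
        )
    return placements


def compute_coverage(
    placements: Sequence[Placement], refs: ReferenceSet, sample_id: str
) -> list[CoverageProfile]:
    """Aggregate placements into per-entry coverage profiles for one sample.

    Depth is incremented once per placement per covered position; multi-mapping
    peptides contribute to coverage everywhere they place but count toward
    ``n_unique_peptides`` of no entry.
    """
    profiles = {
        e.entry_id: CoverageProfile(
            entry_id=e.entry_id,
            sample_id=sample_id,
            depth=np.zeros(len(e.sequence), dtype=np.int32),
        )
        for e in refs
    }
    peptides_per_entry: dict[str, set[str]] = {e.entry_id: set() for e in refs}
    unique_per_entry: dict[str, set[str]] = {e.entry_id: set() for e in refs}
    for p in placements:
        if p.entry_id not in profiles:
            raise ValueError(f"placement refers to unknown entry {p.entry_id!r}")
        prof = profiles[p.entry_id]
        if p.start < 1 or p.end > prof.depth.size:
            raise ValueError(
                f"placement {p.start}-{p.end} outside entry {p.entry_id!r} "
                f"(length {prof.depth.size})"
            )
        prof.depth[p.start - 1 : p.end] += 1
        for i, res in enumerate(p.peptide):
            pos = p.start + i
            prof.observed.setdefault(pos, Counter())[res] += 1
        peptides_per_entry[p.entry_id].add(p.peptide)
        if p.unique:
            unique_per_entry[p.entry_id].add(p.peptide)
    out = []
    for e in refs:
        prof = profiles[e.entry_id]
        prof.n_peptides = len(peptides_per_entry[e.entry_id])
        prof.n_unique_peptides = len(unique_per_entry[e.entry_id])
        out.append(prof)
    return out


def call_proteins(
    profiles: Sequence[CoverageProfile],
    stringent_min: int = 2,
    relaxed_min: int = 1,
) -> list[ProteinCall]:
    """Tiered protein calls from unique-peptide support."""
    calls = []
    for prof in profiles:
        if prof.n_unique_peptides >= stringent_min:
            tier = "stringent"
        elif prof.n_unique_peptides >= relaxed_min:
            tier = "relaxed"
        else:
            tier = "absent"
        calls.append(
            ProteinCall(
                entry_id=prof.entry_id,
                sample_id=prof.sample_id,
                tier=tier,
                n_unique_peptides=prof.n_unique_peptides,
                coverage_pct=prof.coverage_pct,
            )
        )
    return calls


def call_substitutions(
    profiles: Sequence[CoverageProfile],
    refs: ReferenceSet,
    min_support: int = 2,
) -> SubstitutionTable:
    """Per-position residue calls against the (canonicalized) reference.

    ``-`` where depth is zero; the reference residue where every observation
    agrees with it; an alternative residue where at least ``min_support``
    observations support that single alternative; ``?`` otherwise.
    """
    table = SubstitutionTable()
    for prof in profiles:
        ref_seq = refs.get(prof.entry_id).sequence
        symbols: list[str] = []
        support: list[int] = []
        for pos in range(1, len(ref_seq) + 1):
            if prof.depth[pos - 1] == 0:
                symbols.append("-")
                support.append(0)
                continue
            obs = prof.observed.get(pos, Counter())
            ref_res = ref_seq[pos - 1]
            alts = {r: c for r, c in obs.items() if r != ref_res}
            if not alts:
                symbols.append(ref_res)
                support.append(obs.get(ref_res, int(prof.depth[pos - 1])))
            elif len(alts) == 1:
                (alt, count), = alts.items()
                if count >= min_support:
                    symbols.append(alt)
                    support.append(count)
                else:
                    symbols.append("?")
                    support.append(count)
            else:
                symbols.append("?")
                support.append(sum(alts.values()))
        table.symbols[(prof.entry_id, prof.sample_id)] = symbols
        table.support[(prof.entry_id, prof.sample_id)] = support
    return table


def alignment_report(
    table: SubstitutionTable,
    entry_id: str,
    sample_ids: Sequence[str],
    positions: Sequence[int],
) -> pd.DataFrame:
    """Grid of substitution-call symbols, samples as rows, positions as columns."""
    data = {}
    for sample_id in sample_ids:
        key = (entry_id, sample_id)
        if key not in table.symbols:
            raise KeyError(f"no substitution calls for entry {entry_id!r} / sample {sample_id!r}")
        row = table.symbols[key]
        for pos in positions:
            if not 1 <= pos <= len(row):
                raise ValueError(f"position {pos} outside entry {entry_id!r} (length {len(row)})")
        data[sample_id] = [row[pos - 1] for pos in positions]
    return pd.DataFrame.from_dict(
        data, orient="index", columns=[str(p) for p in positions]
    )
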