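"""Independent brute-force oracles used to check the fast implementations.

These deliberately re-derive the contracts from their definitions (substring
enumeration, exhaustive offset/mismatch scans) and share no code with the
package internals.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right


def brute_cleavage_sites(seq: str, enzyme: str) -> set[int]:
    residues = {"trypsin": "KR", "elastase": "AVSGLI"}[enzyme]
    sites = set()
    for i in range(1, len(seq)):
        if seq[i - 1] in residues:
            if enzyme == "trypsin" and seq[i] == "P":
                continue
            sites.add(i)
    return sites


def brute_digest(seq: str, enzyme: str, max_missed: int) -> set[tuple[str, int, int]]:
    """Every substring whose boundaries are cleavage sites (or termini) and
    whose interior contains at most ``max_missed`` cleavage sites."""
    sites = brute_cleavage_sites(seq, enzyme)
    sorted_sites = sorted(sites)
    out = set()
    n = len(seq)
    for a in range(n):
        if a != 0 and a not in sites:
            continue
        for b in range(a + 1, n + 1):
            if b != n and b not in sites:
                continue
            internal = bisect_left(sorted_sites, b) - bisect_right(sorted_sites, a)
            if internal <= max_missed:
                out.add((seq[a:b], a + 1, b))
    return out


def brute_place(
    pep: str,
    entries: list[tuple[str, str]],
    max_subst: int = 1,
    min_subst_len: int = 6,
) -> set[tuple[str, int, int | None]]:
    """Exhaustive (entry, offset, mismatch-pattern) scan.

    Returns {(entry_id, 1-based start, mismatched peptide index or None)}:
    all exact placements, or — only if there are none anywhere — all
    single-mismatch placements with the mismatch at an internal residue of a
    peptide at least ``min_subst_len`` long.
    """
    m = len(pep)
    exact: set[tuple[str, int, int | None]] = set()
    one: set[tuple[str, int, int | None]] = set()
    for entry_id, seq in entries:
        for off in range(len(seq) - m + 1):
            mismatches = [k for k in range(m) if seq[off + k] != pep[k]]
            if not mismatches:
                exact.add((entry_id, off + 1, None))
            elif (
                max_subst >= 1
                and len(mismatches) == 1
                and m >= min_subst_len
                and mismatches[0] not in (0, m - 1)
            ):
                one.add((entry_id, off + 1, mismatches[0]))
    return exact if exact else one
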