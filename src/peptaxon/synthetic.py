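"""Seeded generator of ground-truthed reference proteomes and degraded samples.

Reference proteomes are built so that distant taxa share repeated
low-complexity (RLC) blocks verbatim — poly-A runs, (GA)n repeats and G-rich
stretches, the structural sequence that carries no taxonomic signal — while
taxon-specific segments diverge from a common ancestor at a configurable
per-site substitution rate.  Clade-specific marker proteins are emitted for
their clade only.  Degraded samples are produced by in-silico digestion
(trypsin and/or elastase), biased peptide loss (hydrolysis-prone Ser/Asp-rich
peptides survive less often), per-site deamidation (N→D, Q→E), and sparse
sequencing errors with near-isobaric confusions (N↔GG, Q↔AG).

Every stochastic step draws from a stream derived from ``(seed, stream
name)``, so each sample is independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .formats_io import (
    Mod,
    PeptideRecord,
    PeptideTable,
    ReferenceEntry,
    ReferenceSet,
    SpectrumRecord,
)

AA = "ACDEFGHIKLMNPQRSTVWY"

# monoisotopic residue masses (Da)
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
PROTON = 1.007276
WATER = 18.010565
DEAMIDATION_SHIFT = 0.98402

#: residues C-terminal to which each protease cleaves
CLEAVAGE_RESIDUES = {"trypsin": "KR", "elastase": "AVSGLI"}

#: hydrolysis-prone residues; peptides rich in these survive burial less often
HYDROLYSIS_PRONE = frozenset("SDNE")


@dataclass
class SyntheticConfig:
    """Knobs for panel generation and sample degradation. ``seed`` is mandatory."""

    seed: int
    n_taxa: int = 4
    n_proteins_per_taxon: int = 3
    rlc_pool_size: int = 6
    mu: float = 0.05
    marker_clades: dict[str, str] = field(
        default_factory=lambda: {
            "freshwater": "marker_freshwater",
            "marine": "marker_marine",
        }
    )
    enzymes: tuple[str, ...] = ("trypsin", "elastase")
    max_missed_cleavages: int = 2
    len_range: tuple[int, int] = (6, 30)
    p_survive: float = 0.3
    hydrolysis_penalty: float = 0.5
    p_deam: float = 0.3
    p_err: float = 0.05
    alc_mean_good: float = 85.0
    alc_mean_err: float = 62.0
    alc_spread: float = 8.0
    n_segments_range: tuple[int, int] = (4, 7)
    segment_len_range: tuple[int, int] = (20, 50)
    marker_len: int = 360

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("mu", "p_survive", "hydrolysis_penalty", "p_deam", "p_err"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.len_range[0] < 1 or self.len_range[1] < self.len_range[0]:
            raise ValueError(f"bad len_range {self.len_range}")
        if self.rlc_pool_size == 0 and not self.marker_clades:
            raise ValueError(
                "rlc_pool_size 0 with no marker clades: nothing distinguishes taxa"
            )
        for enz in self.enzymes:
            if enz not in CLEAVAGE_RESIDUES:
                raise ValueError(f"unknown enzyme {enz!r}")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying generated references or a degraded sample."""

    sample_id: str | None = None
    source_taxon: str | None = None
    planted_substitutions: list[tuple[str, int, str, str]] = field(default_factory=list)
    noise: dict = field(default_factory=dict)
    peptide_provenance: list[dict] = field(default_factory=list)
    rlc_regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    taxon_clade: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(stream.encode())])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def _rlc_block(rng: np.random.Generator) -> str:
    kind = rng.integers(3)
    if kind == 0:  # poly-A
        return "A" * int(rng.integers(5, 13))
    if kind == 1:  # (GA)n repeat
        return "GA" * int(rng.integers(3, 9))
    length = int(rng.integers(6, 15))  # degenerate G-rich stretch
    return "".join(rng.choice(list("GGGAS"), size=length))


def _mutate(rng: np.random.Generator, seq: str, mu: float) -> str:
    if mu == 0.0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < mu)[0]
    for i in hits:
        choices = [a for a in AA if a != out[i]]
        out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def _taxon_names(n: int) -> list[str]:
    return [f"taxon{i + 1:02d}" for i in range(n)]


def taxon_clades(cfg: SyntheticConfig) -> dict[str, str]:
    """Round-robin clade assignment for the panel's taxa."""
    clades = list(cfg.marker_clades) or ["unknown"]
    return {t: clades[i % len(clades)] for i, t in enumerate(_taxon_names(cfg.n_taxa))}


def generate_references(cfg: SyntheticConfig) -> tuple[ReferenceSet, SyntheticTruth]:
    """Build the multi-taxon reference panel with shared RLC architecture.

    Each protein slot has one architecture — alternating ancestor-derived
    unique segments and RLC blocks drawn from the shared pool — realised once
    per taxon by mutating the unique segments at per-site rate ``mu``.  RLC
    blocks are copied verbatim into every taxon.  Marker proteins are fresh
    random sequences emitted once per clade.
    """
    rng = _rng(cfg.seed, "references")
    pool = [_rlc_block(rng) for _ in range(cfg.rlc_pool_size)]
    clade_of = taxon_clades(cfg)
    truth = SyntheticTruth(taxon_clade=dict(clade_of))

    # architecture per protein slot: list of ("rlc", block) / ("unique", ancestor)
    architectures = []
    for _ in range(cfg.n_proteins_per_taxon):
        n_seg = int(rng.integers(cfg.n_segments_range[0], cfg.n_segments_range[1] + 1))
        arch: list[tuple[str, str]] = []
        for s in range(n_seg):
            seg_len = int(
                rng.integers(cfg.segment_len_range[0], cfg.segment_len_range[1] + 1)
            )
            arch.append(("unique", _random_seq(rng, seg_len)))
            if s < n_seg - 1 and pool:
                arch.append(("rlc", pool[int(rng.integers(len(pool)))]))
        architectures.append(arch)

    entries: list[ReferenceEntry] = []
    for taxon in _taxon_names(cfg.n_taxa):
        for j, arch in enumerate(architectures):
            parts: list[str] = []
            rlc_regions: list[tuple[int, int]] = []
            pos = 0
            for kind, seg in arch:
                realised = _mutate(rng, seg, cfg.mu) if kind == "unique" else seg
                if kind == "rlc":
                    rlc_regions.append((pos + 1, pos + len(realised)))
                parts.append(realised)
                pos += len(realised)
            entry_id = f"{taxon}_p{j + 1}"
            entries.append(
                ReferenceEntry(
                    entry_id=entry_id,
                    sequence="".join(parts),
                    taxon=taxon,
                    clade=clade_of[taxon],
                )
            )
            truth.rlc_regions[entry_id] = rlc_regions

    for clade, marker_id in cfg.marker_clades.items():
        core = _random_seq(rng, cfg.marker_len)
        block = pool[int(rng.integers(len(pool)))] if pool else ""
        mid = len(core) // 2
        seq = core[:mid] + block + core[mid:]
        entries.append(
            ReferenceEntry(
                entry_id=marker_id,
                sequence=seq,
                taxon=clade,
                clade=clade,
                is_marker=True,
            )
        )
        truth.rlc_regions[marker_id] = (
            [(mid + 1, mid + len(block))] if block else []
        )
    refset = ReferenceSet(entries)
    refset.validate()
    return refset, truth


# ---------------------------------------------------------------------------
# digestion


def cleavage_sites(sequence: str, enzyme: str) -> list[int]:
    """Positions i such that the bond after residue i (1-based) is cleaved."""
    if enzyme not in CLEAVAGE_RESIDUES:
        raise ValueError(f"unknown enzyme {enzyme!r}")
    residues = CLEAVAGE_RESIDUES[enzyme]
    sites = []
    for i in range(1, len(sequence)):
        if sequence[i - 1] in residues:
            if enzyme == "trypsin" and sequence[i] == "P":
                continue
            sites.append(i)
    return sites


def digest(
    sequence: str, enzyme: str, max_missed: int = 0
) -> list[tuple[str, int, int]]:
    """In-silico digestion: (peptide, start, end) with <= ``max_missed`` missed cleavages.

    Trypsin cleaves after K/R except before P; elastase after A/V/S/G/L/I.
    Coordinates are 1-based inclusive on the input sequence.
    """
    boundaries = [0, *cleavage_sites(sequence, enzyme), len(sequence)]
    out = []
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(boundaries))):
            start, end = boundaries[i], boundaries[j]
            out.append((sequence[start:end], start + 1, end))
    return out


# ---------------------------------------------------------------------------
# degradation


_ISOBARIC = (("N", "GG"), ("GG", "N"), ("Q", "AG"), ("AG", "Q"))


def _apply_error(rng: np.random.Generator, seq: str) -> tuple[str, dict]:
    """One de novo sequencing error: near-isobaric confusion or a residue swap."""
    ops: list[tuple[str, str, int]] = []
    for src, dst in _ISOBARIC:
        start = 0
        while (i := seq.find(src, start)) != -1:
            ops.append((src, dst, i))
            start = i + 1
    # a uniform single-residue swap is always available
    ops.append(("swap", "", int(rng.integers(len(seq)))))
    src, dst, i = ops[int(rng.integers(len(ops)))]
    if src == "swap":
        choices = [a for a in AA if a != seq[i]]
        new = seq[:i] + choices[int(rng.integers(len(choices)))] + seq[i + 1 :]
        return new, {"kind": "swap", "position": i + 1}
    new = seq[:i] + dst + seq[i + len(src) :]
    return new, {"kind": f"{src}->{dst}", "position": i + 1}


def degrade_sample(
    refs: ReferenceSet,
    source_taxon: str,
    cfg: SyntheticConfig,
    sample_id: str = "sample1",
    planted_substitutions: Sequence[tuple[str, int, str]] | None = None,
) -> tuple[PeptideTable, SyntheticTruth]:
    """Simulate a degraded de novo peptide list for one sample.

    The source proteome (taxon proteins plus the clade marker) is digested
    with the configured enzymes; peptides inside ``len_range`` survive a
    Bernoulli draw (penalised when more than half their residues are
    hydrolysis-prone S/D/N/E), then receive per-site deamidation, sparse
    sequencing errors, and an ALC draw.  ``planted_substitutions`` is a list
    of (entry_id, 1-based position, alternative residue) applied to the source
    sequence before digestion and recorded in the truth.
    """
    source_entries = [e for e in refs if e.taxon == source_taxon and not e.is_marker]
    if not source_entries:
        raise ValueError(f"source taxon {source_taxon!r} not present in references")
    clade = source_entries[0].clade
    source_entries += [e for e in refs if e.is_marker and e.clade == clade]

    truth = SyntheticTruth(
        sample_id=sample_id,
        source_taxon=source_taxon,
        noise={
            "p_survive": cfg.p_survive,
            "hydrolysis_penalty": cfg.hydrolysis_penalty,
            "p_deam": cfg.p_deam,
            "p_err": cfg.p_err,
        },
    )
    sequences: dict[str, str] = {e.entry_id: e.sequence for e in source_entries}
    for entry_id, pos, alt in planted_substitutions or []:
        seq = sequences[entry_id]
        if not 1 <= pos <= len(seq):
            raise ValueError(f"planted position {pos} outside {entry_id!r}")
        truth.planted_substitutions.append((entry_id, pos, seq[pos - 1], alt))
        sequences[entry_id] = seq[: pos - 1] + alt + seq[pos:]

    rng = _rng(cfg.seed, f"sample:{sample_id}")
    lo, hi = cfg.len_range
    records: list[PeptideRecord] = []
    for entry in source_entries:
        seq = sequences[entry.entry_id]
        for enzyme in cfg.enzymes:
            for fragment, start, end in digest(seq, enzyme, cfg.max_missed_cleavages):
                if not lo <= len(fragment) <= hi:
                    continue
                prone = sum(fragment.count(r) for r in HYDROLYSIS_PRONE)
                p = cfg.p_survive
                if prone > 0.5 * len(fragment):
                    p *= cfg.hydrolysis_penalty
                if rng.random() >= p:
                    continue
                observed = fragment
                error_info: dict | None = None
                if rng.random() < cfg.p_err:
                    observed, error_info = _apply_error(rng, observed)
                mods: list[Mod] = []
                deam_sites = []
                chars = list(observed)
                for i, res in enumerate(chars):
                    if res in "NQ" and rng.random() < cfg.p_deam:
                        chars[i] = "D" if res == "N" else "E"
                        mods.append(Mod(i + 1, "deamidation"))
                        deam_sites.append(i + 1)
                observed = "".join(chars)
                mean = cfg.alc_mean_err if error_info else cfg.alc_mean_good
                alc = float(np.clip(rng.normal(mean, cfg.alc_spread), 0.0, 100.0))
                rec = PeptideRecord(
                    sample_id=sample_id,
                    peptide=observed,
                    alc=round(alc, 1),
                    mods=tuple(mods),
                    charge=int(rng.integers(2, 4)),
                    enzyme=enzyme,
                )
                records.append(rec)
                truth.peptide_provenance.append(
                    {
                        "entry_id": entry.entry_id,
                        "start": start,
                        "end": end,
                        "enzyme": enzyme,
                        "deamidated_positions": deam_sites,
                        "error": error_info,
                        "observed": observed,
                    }
                )
    if not records:
        raise ValueError(
            f"no peptides survived simulation for sample {sample_id!r} "
            f"(p_survive={cfg.p_survive}); raise p_survive or enlarge the panel"
        )
    table = PeptideTable(records)
    table.validate()
    return table, truth


def reference_digest_peptides(
    refs: ReferenceSet, taxon: str, cfg: SyntheticConfig, min_len: int | None = None
) -> set[str]:
    """The noiseless in-range digest of one taxon's proteome (plus clade marker).

    This is the 'rich, well-preserved reference sample' counterpart of
    :func:`degrade_sample`; returned as raw (non-canonical) peptide strings.
    """
    entries = [e for e in refs if e.taxon == taxon and not e.is_marker]
    if not entries:
        raise ValueError(f"taxon {taxon!r} not present in references")
    clade = entries[0].clade
    entries += [e for e in refs if e.is_marker and e.clade == clade]
    lo, hi = cfg.len_range
    if min_len is not None:
        lo = max(lo, min_len)
    peptides: set[str] = set()
    for entry in entries:
        for enzyme in cfg.enzymes:
            for fragment, _, _ in digest(entry.sequence, enzyme, cfg.max_missed_cleavages):
                if lo <= len(fragment) <= hi:
                    peptides.add(fragment)
    return peptides


# ---------------------------------------------------------------------------
# spectra


def peptide_mz(peptide: str, charge: int = 1, deam_shift_sites: int = 0) -> float:
    mass = sum(RESIDUE_MASS[r] for r in peptide) + WATER
    mass += deam_shift_sites * DEAMIDATION_SHIFT
    return (mass + charge * PROTON) / charge


def fragment_mzs(peptide: str, mods: Sequence[Mod] = ()) -> list[float]:
    """Singly-charged monoisotopic b- and y-ion m/z for every backbone cleavage.

    A deamidation mod adds its mass shift only when the annotated residue is
    still N/Q (when the deamidated product D/E is already written into the
    string, the shift is part of the residue mass).
    """
    n = len(peptide)
    if n == 0:
        raise ValueError("zero-length peptide")
    masses = [RESIDUE_MASS[r] for r in peptide]
    for mod in mods:
        if mod.kind == "deamidation" and peptide[mod.position - 1] in "NQ":
            masses[mod.position - 1] += DEAMIDATION_SHIFT
        elif mod.kind == "oxidation":
            masses[mod.position - 1] += 15.99491
        elif mod.kind == "carbamidomethyl":
            masses[mod.position - 1] += 57.02146
    mzs = []
    prefix = 0.0
    for k in range(n - 1):
        prefix += masses[k]
        mzs.append(prefix + PROTON)  # b(k+1)
    suffix = 0.0
    for k in range(n - 1):
        suffix += masses[n - 1 - k]
        mzs.append(suffix + WATER + PROTON)  # y(k+1)
    return mzs


def emit_spectra(table: PeptideTable, charge: int = 1) -> list[SpectrumRecord]:
    """Idealised unit-intensity b/y spectra for every peptide row."""
    spectra = []
    for i, rec in enumerate(table):
        if not rec.peptide:
            raise ValueError(f"row {i}: zero-length peptide")
        mass = sum(RESIDUE_MASS[r] for r in rec.peptide) + WATER
        for mod in rec.mods:
            if mod.kind == "deamidation" and rec.peptide[mod.position - 1] in "NQ":
                mass += DEAMIDATION_SHIFT
            elif mod.kind == "oxidation":
                mass += 15.99491
            elif mod.kind == "carbamidomethyl":
                mass += 57.02146
        precursor = (mass + charge * PROTON) / charge
        peaks = sorted((mz, 1.0) for mz in fragment_mzs(rec.peptide, rec.mods))
        spectra.append(
            SpectrumRecord(
                spectrum_id=f"{rec.sample_id}_{i + 1}",
                precursor_mz=precursor,
                charge=charge,
                peaks=peaks,
            )
        )
    return spectra
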