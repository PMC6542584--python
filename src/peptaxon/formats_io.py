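"""Readers and writers for every external representation the pipeline touches.

Supported formats
-----------------
* peptide tables — TSV with a fixed header (``sample_id``, ``peptide``,
  ``alc``, ``mods``, ``charge``, ``enzyme``); unknown columns are ignored.
  Modifications are encoded ``"pos:kind;pos:kind"`` with 1-based positions.
* reference proteins — FASTA with metadata packed into the header as
  ``entry_id|taxon|clade[|marker]``.
* fragment spectra — MGF (``BEGIN IONS``/``END IONS`` blocks).
* labelled square matrices — TSV, first row and column carry the labels.

All residue strings use the 20 standard one-letter amino acids and all
coordinates are 1-based inclusive.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

MOD_KINDS = frozenset({"deamidation", "carbamidomethyl", "oxidation"})

#: residues a modification kind may legally annotate.  Deamidation is allowed
#: on D/E as well as N/Q because simulated (and many real, post-Spider) peptide
#: strings report the deamidated product residue directly.
_MOD_RESIDUES = {
    "deamidation": frozenset("NQDE"),
    "carbamidomethyl": frozenset("C"),
    "oxidation": frozenset("M"),
}

ENZYMES = frozenset({"trypsin", "elastase", "unknown"})


class FormatError(ValueError):
    """Raised when an external file violates its documented dialect."""


@dataclass(frozen=True)
class Mod:
    """A single residue modification at a 1-based peptide position."""

    position: int
    kind: str


@dataclass
class PeptideRecord:
    """One de novo peptide observation."""

    sample_id: str
    peptide: str
    alc: float
    mods: tuple[Mod, ...] = ()
    charge: int | None = None
    enzyme: str = "unknown"

    def validate(self) -> None:
        bad = set(self.peptide) - AMINO_ACIDS
        if bad or not self.peptide:
            raise FormatError(
                f"peptide {self.peptide!r} contains non-standard residue(s) "
                f"{sorted(bad) if bad else '(empty)'}"
            )
        if not 0.0 <= self.alc <= 100.0:
            raise FormatError(f"alc {self.alc} outside [0, 100]")
        if self.enzyme not in ENZYMES:
            raise FormatError(f"unknown enzyme {self.enzyme!r}")
        if self.charge is not None and self.charge < 1:
            raise FormatError(f"charge must be positive, got {self.charge}")
        for mod in self.mods:
            if mod.kind not in MOD_KINDS:
                raise FormatError(f"unknown modification kind {mod.kind!r}")
            if not 1 <= mod.position <= len(self.peptide):
                raise FormatError(
                    f"mod position {mod.position} outside peptide "
                    f"{self.peptide!r} (length {len(self.peptide)})"
                )
            residue = self.peptide[mod.position - 1]
            if residue not in _MOD_RESIDUES[mod.kind]:
                raise FormatError(
                    f"{mod.kind} not allowed on residue {residue!r} "
                    f"(position {mod.position} of {self.peptide!r})"
                )


@dataclass
class PeptideTable:
    """An ordered collection of :class:`PeptideRecord` rows."""

    records: list[PeptideRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PeptideRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def sample_ids(self) -> list[str]:
        """Distinct sample ids in first-appearance order."""
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.sample_id, None)
        return list(seen)

    def for_sample(self, sample_id: str) -> "PeptideTable":
        return PeptideTable([r for r in self.records if r.sample_id == sample_id])

    def validate(self) -> None:
        for rec in self.records:
            rec.validate()


@dataclass
class ReferenceEntry:
    """A labelled reference protein sequence."""

    entry_id: str
    sequence: str
    taxon: str = "unknown"
    clade: str = "unknown"
    is_marker: bool = False
    description: str = ""


@dataclass
class ReferenceSet:
    """Uniquely-keyed reference entries in input order."""

    entries: list[ReferenceEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {e.entry_id: i for i, e in enumerate(self.entries)}
        if len(self._index) != len(self.entries):
            seen: set[str] = set()
            for e in self.entries:
                if e.entry_id in seen:
                    raise FormatError(f"duplicate entry_id {e.entry_id!r}")
                seen.add(e.entry_id)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ReferenceEntry]:
        return iter(self.entries)

    def __contains__(self, entry_id: str) -> bool:
        return entry_id in self._index

    def get(self, entry_id: str) -> ReferenceEntry:
        return self.entries[self._index[entry_id]]

    def index_of(self, entry_id: str) -> int:
        return self._index[entry_id]

    def taxa(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.taxon, None)
        return list(seen)

    def validate(self) -> None:
        for e in self.entries:
            if not e.sequence:
                raise FormatError(f"entry {e.entry_id!r} has empty sequence")
            bad = set(e.sequence) - AMINO_ACIDS
            if bad:
                raise FormatError(
                    f"entry {e.entry_id!r} contains non-standard residue(s) {sorted(bad)}"
                )


@dataclass
class SpectrumRecord:
    """A fragment spectrum: peaks sorted ascending by m/z."""

    spectrum_id: str
    precursor_mz: float
    charge: int
    peaks: list[tuple[float, float]]

    def validate(self) -> None:
        if not self.peaks:
            raise FormatError(f"spectrum {self.spectrum_id!r} has no peaks")
        mzs = [p[0] for p in self.peaks]
        if any(b < a for a, b in zip(mzs, mzs[1:])):
            raise FormatError(f"spectrum {self.spectrum_id!r} peaks not sorted")
        if any(p[1] < 0 for p in self.peaks):
            raise FormatError(f"spectrum {self.spectrum_id!r} has negative intensity")


# ---------------------------------------------------------------------------
# peptide tables


def _parse_mods(text: str, row_no: int) -> tuple[Mod, ...]:
    text = text.strip()
    if not text:
        return ()
    mods = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            pos_s, kind = chunk.split(":", 1)
            mods.append(Mod(int(pos_s), kind.strip()))
        except ValueError as exc:
            raise FormatError(f"row {row_no}: malformed mods field {text!r}") from exc
    return tuple(mods)


def _format_mods(mods: Sequence[Mod]) -> str:
    return ";".join(f"{m.position}:{m.kind}" for m in mods)


PEPTIDE_TABLE_COLUMNS = ("sample_id", "peptide", "alc", "mods", "charge", "enzyme")


def read_peptide_table(path: str | Path) -> PeptideTable:
    """Parse a TSV peptide table; unknown columns are ignored, order preserved."""
    records: list[PeptideRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, header row required")
        missing = {"sample_id", "peptide", "alc"} - set(reader.fieldnames)
        if missing:
            raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
        for row_no, row in enumerate(reader, start=2):
            peptide = (row["peptide"] or "").strip().upper()
            try:
                alc = float(row["alc"])
            except (TypeError, ValueError):
                raise FormatError(f"{path} row {row_no}: bad alc value {row['alc']!r}")
            charge_s = (row.get("charge") or "").strip()
            charge = int(charge_s) if charge_s else None
            enzyme = (row.get("enzyme") or "unknown").strip() or "unknown"
            rec = PeptideRecord(
                sample_id=(row["sample_id"] or "").strip(),
                peptide=peptide,
                alc=alc,
                mods=_parse_mods(row.get("mods") or "", row_no),
                charge=charge,
                enzyme=enzyme,
            )
            try:
                rec.validate()
            except FormatError as exc:
                raise FormatError(f"{path} row {row_no}: {exc}") from exc
            records.append(rec)
    return PeptideTable(records)


def write_peptide_table(table: PeptideTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PEPTIDE_TABLE_COLUMNS)
        for rec in table:
            writer.writerow(
                [
                    rec.sample_id,
                    rec.peptide,
                    format(rec.alc, "g"),
                    _format_mods(rec.mods),
                    "" if rec.charge is None else rec.charge,
                    rec.enzyme,
                ]
            )


# ---------------------------------------------------------------------------
# FASTA references


_TRUE_MARKERS = {"marker", "true", "1", "yes"}


def _entry_from_seqrecord(rec: SeqRecord) -> ReferenceEntry:
    header = rec.description or rec.id
    fields = header.split("|")
    entry_id = fields[0].strip()
    taxon = fields[1].strip() if len(fields) > 1 and fields[1].strip() else "unknown"
    clade = fields[2].strip() if len(fields) > 2 and fields[2].strip() else "unknown"
    is_marker = len(fields) > 3 and fields[3].strip().lower() in _TRUE_MARKERS
    sequence = str(rec.seq).upper().replace("*", "")
    return ReferenceEntry(
        entry_id=entry_id,
        sequence=sequence,
        taxon=taxon,
        clade=clade,
        is_marker=is_marker,
        description=header,
    )


def read_fasta(path: str | Path) -> ReferenceSet:
    """Read references from FASTA with ``entry_id|taxon|clade[|marker]`` headers."""
    entries = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        entry = _entry_from_seqrecord(rec)
        if entry.entry_id in seen:
            raise FormatError(f"{path}: duplicate entry_id {entry.entry_id!r}")
        if not entry.sequence:
            raise FormatError(f"{path}: entry {entry.entry_id!r} has empty sequence")
        seen.add(entry.entry_id)
        entries.append(entry)
    refset = ReferenceSet(entries)
    refset.validate()
    return refset


def write_fasta(refs: ReferenceSet, path: str | Path) -> None:
    records = []
    for e in refs:
        header = f"{e.entry_id}|{e.taxon}|{e.clade}"
        if e.is_marker:
            header += "|marker"
        records.append(SeqRecord(Seq(e.sequence), id=header, description=""))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# MGF spectra


def read_mgf(path: str | Path) -> list[SpectrumRecord]:
    """Parse MGF BEGIN IONS/END IONS blocks (PEPMASS required per block)."""
    spectra: list[SpectrumRecord] = []
    in_block = False
    title: str | None = None
    pepmass: float | None = None
    charge = 1
    peaks: list[tuple[float, float]] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                if in_block:
                    raise FormatError(f"{path} line {line_no}: nested BEGIN IONS")
                in_block, title, pepmass, charge, peaks = True, None, None, 1, []
            elif line == "END IONS":
                if not in_block:
                    raise FormatError(f"{path} line {line_no}: END IONS without BEGIN")
                if pepmass is None:
                    raise FormatError(f"{path} line {line_no}: block missing PEPMASS")
                sid = title if title is not None else f"spectrum_{len(spectra) + 1}"
                spectrum = SpectrumRecord(sid, pepmass, charge, sorted(peaks))
                spectrum.validate()
                spectra.append(spectrum)
                in_block = False
            elif in_block:
                if "=" in line and not line[0].isdigit():
                    key, value = line.split("=", 1)
                    key = key.upper()
                    if key == "TITLE":
                        title = value.strip()
                    elif key == "PEPMASS":
                        pepmass = float(value.split()[0])
                    elif key == "CHARGE":
                        charge = int(value.strip().rstrip("+-"))
                else:
                    parts = line.split()
                    if len(parts) < 2:
                        raise FormatError(f"{path} line {line_no}: malformed peak {line!r}")
                    peaks.append((float(parts[0]), float(parts[1])))
    if in_block:
        raise FormatError(f"{path}: unterminated BEGIN IONS block")
    return spectra


def write_mgf(spectra: Iterable[SpectrumRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.spectrum_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.5f}\n")
            fh.write(f"CHARGE={s.charge}+\n")
            for mz, intensity in s.peaks:
                fh.write(f"{mz:.5f} {intensity:.5f}\n")
            fh.write("END IONS\n")


# ---------------------------------------------------------------------------
# labelled matrices


def write_matrix(labels: Sequence[str], m: np.ndarray, path: str | Path) -> None:
    """Write a labelled square matrix as TSV with 6 significant digits."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise FormatError(f"matrix not square: shape {m.shape}")
    if len(labels) != m.shape[0]:
        raise FormatError(f"{len(labels)} labels for matrix of size {m.shape[0]}")
    if len(set(labels)) != len(labels):
        raise FormatError("matrix labels not unique")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["label", *labels])
        for label, row in zip(labels, m):
            writer.writerow([label, *(format(v, ".6g") for v in row)])


def read_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if not header:
            raise FormatError(f"{path}: empty matrix file")
        labels = header[1:]
        rows = []
        for row in reader:
            if row[0] != labels[len(rows)]:
                raise FormatError(
                    f"{path}: row label {row[0]!r} does not match column order"
                )
            rows.append([float(v) for v in row[1:]])
    m = np.array(rows, dtype=float)
    if m.shape != (len(labels), len(labels)):
        raise FormatError(f"{path}: matrix not square")
    return labels, m
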