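"""ORF ingestion, validation and sequence-level classification.

An ORF here is a post-splicing coding sequence: in frame 0, at least 300 nt
by default, with no internal stop codon.  A terminal stop codon is optional
(supplementary sequence sets differ in whether they keep it) but its absence
is logged so mixed conventions are visible.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

_DNA_TO_RNA = str.maketrans("Tt", "Uu")
_RNA_TO_DNA = str.maketrans("Uu", "Tt")
_STOP_DNA = frozenset({"TAA", "TAG", "TGA"})
_DNA_ALPHABET = frozenset("ACGTN")

#: Default minimum ORF length in nucleotides.
MIN_ORF_LENGTH = 300

#: Length-bin boundaries (nt) and their labels; only the 300-499 vs >=500
#: contrast carries biological weight, the finer splits are for reporting.
LENGTH_BINS = ((300, 500, "300-499"), (500, 1000, "500-999"),
               (1000, 2000, "1000-1999"), (2000, math.inf, "≥2000"))


@dataclass(frozen=True)
class Verdict:
    """Validation outcome; truthy iff the sequence is acceptable."""

    ok: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.ok


def validate_orf(sequence: str, min_length: int = MIN_ORF_LENGTH) -> Verdict:
    """Check that a DNA string is an acceptable in-frame coding sequence.

    Acceptable means: alphabet {A,C,G,T} (N anywhere is a rejection, so codon
    counts stay unambiguous), length >= ``min_length``, length divisible by 3,
    and no stop codon in frame 0 before the final codon.
    """
    seq = sequence.upper()
    if not set(seq) <= _DNA_ALPHABET:
        return Verdict(False, "alphabet")
    if "N" in seq:
        return Verdict(False, "ambiguous base")
    if len(seq) < min_length:
        return Verdict(False, "length")
    if len(seq) % 3:
        return Verdict(False, "frame")
    for i in range(0, len(seq) - 3, 3):
        if seq[i:i + 3] in _STOP_DNA:
            return Verdict(False, "internal stop")
    return Verdict(True)


@dataclass(frozen=True)
class OrfRecord:
    """One validated coding sequence with flags and derived statistics."""

    orf_id: str
    sequence: str
    is_ribosomal: bool = False
    is_viral: bool = False

    @property
    def length_nt(self) -> int:
        return len(self.sequence)

    @property
    def gc_percent(self) -> float:
        seq = self.sequence.upper()
        gc = seq.count("G") + seq.count("C")
        return 100.0 * gc / len(seq)

    @property
    def has_terminal_stop(self) -> bool:
        return self.sequence[-3:].upper() in _STOP_DNA


def codons_of(record: "OrfRecord | str") -> list[str]:
    """Split a record (or raw DNA string) into RNA-alphabet codons in order."""
    seq = record.sequence if isinstance(record, OrfRecord) else record
    rna = seq.upper().translate(_DNA_TO_RNA)
    return [rna[i:i + 3] for i in range(0, len(rna), 3)]


def rna_to_dna(seq: str) -> str:
    return seq.translate(_RNA_TO_DNA)


def gc_group(record: OrfRecord) -> int:
    """GC bin: gc_percent rounded half-away-from-zero to an integer percent."""
    return int(math.floor(record.gc_percent + 0.5))


def length_group(record: "OrfRecord | int") -> str:
    """Length bin label for a record (or a raw nt length)."""
    n = record.length_nt if isinstance(record, OrfRecord) else int(record)
    for lo, hi, label in LENGTH_BINS:
        if lo <= n < hi:
            return label
    raise ValueError(f"length {n} below the minimum ORF length")


@dataclass
class OrfSet:
    """An ordered collection of OrfRecords with unique identifiers."""

    records: list[OrfRecord]
    provenance: str = ""
    _index: dict[str, OrfRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for rec in self.records:
            if rec.orf_id in self._index:
                raise ValueError(f"duplicate ORF id {rec.orf_id!r}")
            self._index[rec.orf_id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[OrfRecord]:
        return iter(self.records)

    def __contains__(self, orf_id: str) -> bool:
        return orf_id in self._index

    def get(self, orf_id: str) -> OrfRecord:
        return self._index[orf_id]

    @property
    def ids(self) -> list[str]:
        return [rec.orf_id for rec in self.records]

    def subset(self, member_ids: Iterable[str], provenance: str | None = None) -> "OrfSet":
        wanted = set(member_ids)
        missing = wanted - self._index.keys()
        if missing:
            raise KeyError(f"unknown ORF ids: {sorted(missing)[:5]}")
        recs = [rec for rec in self.records if rec.orf_id in wanted]
        return OrfSet(recs, provenance or self.provenance)

    def with_flags(self, flags: Mapping[str, tuple[bool, bool]]) -> "OrfSet":
        """Return a copy with (is_ribosomal, is_viral) applied per id."""
        recs = []
        for rec in self.records:
            if rec.orf_id in flags:
                ribo, viral = flags[rec.orf_id]
                rec = replace(rec, is_ribosomal=ribo, is_viral=viral)
            recs.append(rec)
        return OrfSet(recs, self.provenance)

    def to_fasta(self, path: "Path | str") -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(f">{rec.orf_id}\n")
                for i in range(0, len(rec.sequence), 70):
                    fh.write(rec.sequence[i:i + 70] + "\n")


def read_orf_fasta(
    path: "Path | str",
    strict: bool = False,
    min_length: int = MIN_ORF_LENGTH,
    skip_log: "Path | str | None" = None,
) -> OrfSet:
    """Read a DNA FASTA of ORFs, validating each record.

    In strict mode any invalid record raises; otherwise invalid records are
    skipped, logged, and (optionally) written to a TSV skip log with columns
    ``orf_id`` and ``reason``.  Duplicate identifiers are always fatal.
    """
    records: list[OrfRecord] = []
    skipped: list[tuple[str, str]] = []
    seen: set[str] = set()
    n_parsed = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_parsed += 1
        if rec.id in seen:
            raise ValueError(f"duplicate ORF id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        verdict = validate_orf(seq, min_length=min_length)
        if verdict:
            orf = OrfRecord(rec.id, seq.upper())
            if not orf.has_terminal_stop:
                logger.info("ORF %s has no terminal stop codon", rec.id)
            records.append(orf)
        else:
            if strict:
                raise ValueError(f"invalid ORF {rec.id!r}: {verdict.reason}")
            logger.warning("skipping ORF %s: %s", rec.id, verdict.reason)
            skipped.append((rec.id, verdict.reason or ""))
    if n_parsed == 0:
        raise ValueError(f"no FASTA records found in {path}")
    if skip_log is not None:
        with open(skip_log, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["orf_id", "reason"])
            writer.writerows(skipped)
    return OrfSet(records, provenance=str(path))


def read_flags_tsv(path: "Path | str") -> dict[str, tuple[bool, bool]]:
    """Read a flags TSV (orf_id, is_ribosomal, is_viral) into a mapping."""
    truthy = {"1", "true", "yes"}
    flags: dict[str, tuple[bool, bool]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            flags[row["orf_id"]] = (
                row.get("is_ribosomal", "0").strip().lower() in truthy,
                row.get("is_viral", "0").strip().lower() in truthy,
            )
    return flags


def write_flags_tsv(path: "Path | str", orfs: OrfSet) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["orf_id", "is_ribosomal", "is_viral"])
        for rec in orfs:
            writer.writerow([rec.orf_id, int(rec.is_ribosomal), int(rec.is_viral)])


def ribosomal_ids_from_descriptions(descriptions: Mapping[str, str]) -> set[str]:
    """Ids whose free-text annotation mentions 'ribosomal' (case-insensitive)."""
    return {oid for oid, text in descriptions.items() if "ribosomal" in text.lower()}
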