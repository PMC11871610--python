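"""Sequence and alignment I/O: FASTA, MSA format interconversion, identifier diffs.

Sequences are normalised on input: letters upper-cased, ``.`` gaps mapped to
``-``, and characters outside the configured alphabet rejected (or mapped to
``X`` with ``loose=True``).  Four alignment dialects are supported as the
common interchange set: aligned FASTA, A3M (lowercase letters are insertions
relative to the query and are removed when converting to columnar formats),
Clustal and Stockholm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import FormatError

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Default residue alphabet: the 20 standard amino acids plus ambiguity
#: codes (X, B, Z), the rare translated residues U/O, and the gap character.
DEFAULT_ALPHABET = frozenset(STANDARD_AA) | frozenset("XBZUO-")

MSA_FORMATS = ("fasta", "a3m", "clustal", "stockholm")


@dataclass
class SequenceRecord:
    """A named amino-acid sequence; the unit of FASTA I/O."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id or any(ch.isspace() for ch in self.id):
            raise ValueError(f"invalid sequence id {self.id!r}")
        if not self.seq:
            raise ValueError(f"empty sequence for id {self.id!r}")

    def degapped(self) -> str:
        return self.seq.replace("-", "")


@dataclass
class Alignment:
    """An ordered set of equal-length gapped sequences."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self):
        widths = {len(r.seq) for r in self.records}
        if len(widths) > 1:
            ragged = next(
                r.id for r in self.records if len(r.seq) != len(self.records[0].seq)
            )
            raise FormatError(f"ragged alignment: record {ragged!r} has deviant width")

    @property
    def width(self) -> int:
        return len(self.records[0].seq) if self.records else 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def normalize_seq(seq: str, alphabet: frozenset[str] = DEFAULT_ALPHABET,
                  loose: bool = False) -> str:
    """Upper-case, map ``.`` to ``-``, and validate against *alphabet*.

    With ``loose=True`` out-of-alphabet characters become ``X`` instead of
    raising.
    """
    out = seq.upper().replace(".", "-")
    bad = [ch for ch in set(out) if ch not in alphabet]
    if bad:
        if loose:
            for ch in bad:
                out = out.replace(ch, "X")
        else:
            raise FormatError(
                f"characters {sorted(bad)} outside alphabet; pass loose=True to map to X"
            )
    return out


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, dedup: bool = False, loose: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Duplicate ids raise by default; with ``dedup=True`` later copies get
    ``_1``, ``_2`` … suffixes (with a warning) so downstream feature joins
    stay unambiguous.
    """
    text = Path(path).read_text()
    records = _parse_fasta_text(text, loose=loose)
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return _resolve_duplicates(records, dedup=dedup)


def _parse_fasta_text(text: str, loose: bool = False) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    header: str | None = None
    desc = ""
    chunks: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if header is not None:
                records.append(_make_record(header, desc, chunks, loose))
            fields = line[1:].strip().split(None, 1)
            if not fields:
                raise FormatError("FASTA header with empty id")
            header = fields[0]
            desc = fields[1] if len(fields) > 1 else ""
            chunks = []
        elif line.strip():
            if header is None:
                raise FormatError("sequence data before first FASTA header")
            chunks.append(line.strip())
    if header is not None:
        records.append(_make_record(header, desc, chunks, loose))
    return records


def _make_record(header, desc, chunks, loose) -> SequenceRecord:
    seq = normalize_seq("".join(chunks), loose=loose)
    return SequenceRecord(id=header, seq=seq, description=desc)


def _resolve_duplicates(records: list[SequenceRecord], dedup: bool) -> list[SequenceRecord]:
    seen: dict[str, int] = {}
    out = []
    for rec in records:
        if rec.id in seen:
            if not dedup:
                raise FormatError(
                    f"duplicate id {rec.id!r}; pass dedup=True to suffix-deduplicate"
                )
            seen[rec.id] += 1
            new_id = f"{rec.id}_{seen[rec.id]}"
            warnings.warn(f"duplicate id {rec.id!r} renamed to {new_id!r}")
            seen.setdefault(new_id, 0)
            rec = SequenceRecord(id=new_id, seq=rec.seq, description=rec.description)
        else:
            seen[rec.id] = 0
        out.append(rec)
    return out


def write_fasta(records: Iterable[SequenceRecord], path, wrap: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at *wrap* columns."""
    records = list(records)
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in records written to one file")
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i:i + wrap] + "\n")


# ---------------------------------------------------------------------------
# MSA reading / writing / conversion

def read_alignment(path, fmt: str, loose: bool = False) -> Alignment:
    """Read an MSA in one of the supported dialects into an :class:`Alignment`."""
    fmt = fmt.lower()
    if fmt not in MSA_FORMATS:
        raise ValueError(f"unsupported MSA format {fmt!r}; choose from {MSA_FORMATS}")
    if fmt == "a3m":
        return _read_a3m(path, loose=loose)
    if fmt == "fasta":
        return Alignment(records=read_fasta(path, loose=loose))
    # Clustal / Stockholm through Biopython; annotation lines (#=GC etc.)
    # are dropped by the reader, sequences and ids kept.
    try:
        bio_aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise FormatError(f"{path}: cannot parse as {fmt}: {exc}") from exc
    records = [
        SequenceRecord(id=r.id, seq=normalize_seq(str(r.seq), loose=loose))
        for r in bio_aln
    ]
    return Alignment(records=records)


def _read_a3m(path, loose: bool = False) -> Alignment:
    """Read A3M: lowercase letters are insertions relative to the query and
    are removed, leaving the columnar (query-width) alignment."""
    raw = _parse_fasta_like_a3m(Path(path).read_text())
    if not raw:
        raise FormatError(f"{path}: no A3M records found")
    records = []
    for rid, desc, seq in raw:
        # lowercase letters and '.' placeholders are insertion-level; the
        # remaining upper-case letters and '-' are the match columns
        matched = "".join(ch for ch in seq if not ch.islower() and ch != ".")
        records.append(
            SequenceRecord(id=rid, seq=normalize_seq(matched, loose=loose),
                           description=desc)
        )
    widths = {len(r.seq) for r in records}
    if len(widths) > 1:
        bad = next(r.id for r in records if len(r.seq) != len(records[0].seq))
        raise FormatError(f"A3M record {bad!r} does not match query width "
                          f"after insertion removal")
    return Alignment(records=records)


def _parse_fasta_like_a3m(text: str) -> list[tuple[str, str, str]]:
    out = []
    header = None
    desc = ""
    chunks: list[str] = []
    for line in text.splitlines():
        if line.startswith("#"):  # a3m may carry a header line
            continue
        if line.startswith(">"):
            if header is not None:
                out.append((header, desc, "".join(chunks)))
            fields = line[1:].strip().split(None, 1)
            header = fields[0] if fields else ""
            desc = fields[1] if len(fields) > 1 else ""
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if header is not None:
        out.append((header, desc, "".join(chunks)))
    return out


def write_alignment(aln: Alignment, path, fmt: str, wrap: int = 60) -> None:
    fmt = fmt.lower()
    if fmt not in MSA_FORMATS:
        raise ValueError(f"unsupported MSA format {fmt!r}; choose from {MSA_FORMATS}")
    if not aln.records:
        raise ValueError("refusing to write an empty alignment")
    if fmt in ("fasta", "a3m"):
        # Converting INTO a3m from columnar formats emits plain upper-case
        # rows (no insertions are invented), i.e. valid aligned FASTA.
        write_fasta(aln.records, path, wrap=wrap)
        return
    bio_aln = MultipleSeqAlignment(
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in aln.records
    )
    buf = StringIO()
    AlignIO.write(bio_aln, buf, fmt)
    Path(path).write_text(buf.getvalue())


def convert_msa(in_path, in_fmt: str, out_fmt: str, out_path) -> Alignment:
    """Convert an MSA between formats; returns the parsed alignment."""
    aln = read_alignment(in_path, in_fmt)
    write_alignment(aln, out_path, out_fmt)
    return aln


# ---------------------------------------------------------------------------
# Identifier diffing

def diff_identifiers(set_a: Iterable[str], set_b: Iterable[str]):
    """Partition two identifier collections into (only_a, only_b, shared).

    Hash-set based, so linear in input size; duplicates are collapsed.
    """
    a = set(set_a)
    b = set(set_b)
    return a - b, b - a, a & b
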