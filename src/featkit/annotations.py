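"""Extraction of experimental evidence from UniProtKB flat-text entries.

Streams entries one at a time (constant memory per entry) and exposes the
fields relevant to residue-level machine learning: positional features
(TRANSMEM, BINDING, ...), accession lists, database cross-references (PDB
codes in particular) and the taxon id for species-level filtering.  Parsing
is delegated to Biopython's SwissProt reader; this module normalises its
output to 1-based inclusive coordinates and flags fuzzy bounds ('<', '>',
'?'), which are excluded from ML regions by default to avoid off-by-one
label noise.  The XML dialect is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SwissProt
from Bio.SeqFeature import ExactPosition

from .errors import FormatError


@dataclass
class FeatureSpan:
    type: str
    start: int       # 1-based inclusive
    end: int         # 1-based inclusive
    description: str = ""
    fuzzy: bool = False


@dataclass
class UniProtEntry:
    accessions: list[str]            # primary first
    entry_name: str
    sequence: str
    taxon_id: str | None = None
    features: list[FeatureSpan] = field(default_factory=list)
    xrefs: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def primary_accession(self) -> str:
        return self.accessions[0]

    def pdb_ids(self) -> list[str]:
        return [xid for db, xid, _ in self.xrefs if db == "PDB"]


def _convert_feature(feat) -> FeatureSpan | None:
    loc = feat.location
    if loc is None:
        return None
    fuzzy = not (isinstance(loc.start, ExactPosition)
                 and isinstance(loc.end, ExactPosition))
    try:
        start = int(loc.start) + 1   # SeqFeature is 0-based half-open
        end = int(loc.end)
    except (TypeError, ValueError):
        # fully unknown position ('?')
        return FeatureSpan(type=feat.type, start=0, end=0,
                           description=_feat_note(feat), fuzzy=True)
    return FeatureSpan(type=feat.type, start=start, end=end,
                       description=_feat_note(feat), fuzzy=fuzzy)


def _feat_note(feat) -> str:
    note = feat.qualifiers.get("note", "") if hasattr(feat, "qualifiers") else ""
    return note if isinstance(note, str) else "; ".join(note)


def parse_uniprot_text(source) -> Iterator[UniProtEntry]:
    """Stream :class:`UniProtEntry` objects from a flat-text file or handle.

    Raises :class:`FormatError` for a truncated final entry (missing '//').
    """
    own = False
    if isinstance(source, (str, Path)):
        handle = open(source)
        own = True
    else:
        handle = source
    try:
        for record in SwissProt.parse(handle):
            features = []
            for feat in record.features:
                span = _convert_feature(feat)
                if span is not None:
                    features.append(span)
            taxon = record.taxonomy_id[0] if record.taxonomy_id else None
            xrefs = [(ref[0], ref[1], "; ".join(ref[2:])) if len(ref) > 1
                     else (ref[0], "", "") for ref in record.cross_references]
            yield UniProtEntry(
                accessions=list(record.accessions),
                entry_name=record.entry_name,
                sequence=str(record.sequence),
                taxon_id=taxon,
                features=features,
                xrefs=xrefs,
            )
    except ValueError as exc:
        raise FormatError(f"malformed UniProt flat text: {exc}") from exc
    finally:
        if own:
            handle.close()


def filter_entries(entries: Iterable[UniProtEntry],
                   accessions: Iterable[str] | None = None,
                   taxon_id: str | int | None = None):
    """Single-pass subset of a parsed stream.

    Matches an entry when ANY of its accessions (primary or secondary) is in
    *accessions*, and/or its taxon matches *taxon_id*.  Returns
    (matched entries, accessions never seen).
    """
    wanted = set(accessions) if accessions is not None else None
    taxon = str(taxon_id) if taxon_id is not None else None
    matched: list[UniProtEntry] = []
    seen: set[str] = set()
    for entry in entries:
        if taxon is not None and entry.taxon_id != taxon:
            continue
        if wanted is not None:
            hits = wanted.intersection(entry.accessions)
            if not hits:
                continue
            seen.update(hits)
        matched.append(entry)
    missing = sorted(wanted - seen) if wanted is not None else []
    return matched, missing


def features_to_regions(entry: UniProtEntry, feature_type: str,
                        include_fuzzy: bool = False) -> list[tuple[int, int]]:
    """Sorted (start, end) regions for one feature type, 1-based inclusive.

    Fuzzy-bounded features are excluded by default; with
    ``include_fuzzy=True`` they are clamped to [1, len(sequence)].  A type
    with no features yields an empty list.
    """
    length = len(entry.sequence)
    regions = []
    for span in entry.features:
        if span.type != feature_type:
            continue
        if span.fuzzy and not include_fuzzy:
            continue
        start, end = span.start, span.end
        if span.fuzzy:
            start = max(start, 1)
            end = min(end, length) if end >= 1 else length
        if start < 1 or end > length or start > end:
            continue
        regions.append((start, end))
    return sorted(regions)


def write_regions_tsv(rows: Iterable[tuple[str, int, int, str]], path) -> None:
    """Write (protein, start, end, type) regions as TSV, 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("protein\tstart\tend\ttype\n")
        for protein, start, end, ftype in rows:
            fh.write(f"{protein}\t{start}\t{end}\t{ftype}\n")
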