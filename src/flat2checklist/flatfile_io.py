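"""Reading of EMBL and GenBank flat files into a simple record model.

The flat-file dialect is detected from the file extension ('.embl' or
'.gb'), the heavy lifting of tokenizing the format is delegated to
Biopython, and the result is converted into a small, explicit model in
which feature locations keep the 1-based inclusive coordinates that the
flat file itself prints.  Downstream checklist columns (intron start and
end positions) are reported in exactly these coordinates.

Only the feature table and the DNA sequence of each record are used;
identification, description and reference lines beyond the entry header
and the source organism are parsed by Biopython but ignored here.
"""

from __future__ import annotations

import enum
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.SeqFeature import (
    AfterPosition,
    BeforePosition,
    Location,
    SeqFeature,
)

from .errors import FlatFileSyntaxError, RecordProcessingError, UnsupportedExtensionError

__all__ = [
    "FileFormat",
    "FeatureLocation",
    "Feature",
    "SequenceRecord",
    "detect_format",
    "parse_flatfile",
    "parse_location",
]


class FileFormat(enum.Enum):
    """Flat-file dialect, inferred from the input file extension."""

    EMBL = "embl"
    GENBANK = "genbank"


class Strand(enum.Enum):
    PLUS = "+"
    MINUS = "-"


@dataclass(frozen=True)
class FeatureLocation:
    """A feature location in 1-based inclusive flat-file coordinates.

    ``partial5``/``partial3`` are biological 5'/3' partiality flags: for
    a minus-strand location the '<' marker on the low coordinate marks
    the 3' end as partial, mirroring the complement.
    """

    intervals: tuple[tuple[int, int], ...]
    strand: Strand = Strand.PLUS
    partial5: bool = False
    partial3: bool = False

    @property
    def start(self) -> int:
        """Lowest coordinate spanned (flat-file numbering)."""
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        """Highest coordinate spanned (flat-file numbering)."""
        return self.intervals[-1][1]


@dataclass(frozen=True)
class Feature:
    """One annotation feature: INSDC key, location and qualifiers.

    Qualifiers are an ordered multi-map: each name maps to the list of
    values it was given, in file order.
    """

    key: str
    location: FeatureLocation
    qualifiers: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def first(self, qualifier: str) -> str | None:
        """First value of *qualifier*, or None when absent."""
        values = self.qualifiers.get(qualifier)
        return values[0] if values else None


@dataclass(frozen=True)
class SequenceRecord:
    """One parsed flat-file entry."""

    record_id: str
    organism: str
    sequence: str
    features: tuple[Feature, ...]

    @property
    def source(self) -> Feature | None:
        """The source feature, when present at the top of the table."""
        if self.features and self.features[0].key == "source":
            return self.features[0]
        return None


def detect_format(path: str) -> FileFormat:
    """Infer the flat-file dialect from the file extension.

    Exactly two endings are accepted, case-insensitively: '.embl' maps
    to EMBL, '.gb' to GenBank.
    """
    suffix = Path(str(path)).suffix.lower()
    if suffix == ".embl":
        return FileFormat.EMBL
    if suffix == ".gb":
        return FileFormat.GENBANK
    raise UnsupportedExtensionError(
        f"cannot infer flat-file format of '{path}': the file ending must be "
        "'.embl' (EMBL format) or '.gb' (GenBank format)"
    )


# --- location parsing -------------------------------------------------------

_REJECTED_OPERATORS = {"order"}


def _position_partial(pos) -> tuple[bool, bool]:
    """(before, after) fuzziness of a Biopython position."""
    return isinstance(pos, BeforePosition), isinstance(pos, AfterPosition)


def _from_biopython_location(loc, seq_len: int, record_id: str = "?") -> FeatureLocation:
    """Convert a Biopython location to the 1-based model, validating bounds."""
    operator = getattr(loc, "operator", None)
    if operator in _REJECTED_OPERATORS:
        raise RecordProcessingError(
            record_id, f"unsupported location operator '{operator}(...)'"
        )
    parts = list(loc.parts)
    for part in parts:
        if part.ref is not None:
            raise RecordProcessingError(
                record_id, f"remote sequence reference in location '{loc}' is not supported"
            )
    strand = Strand.MINUS if loc.strand == -1 else Strand.PLUS
    intervals = []
    for part in sorted(parts, key=lambda p: int(p.start)):
        start = int(part.start) + 1  # Biopython is 0-based half-open
        end = int(part.end)
        if not (1 <= start <= end <= seq_len):
            raise RecordProcessingError(
                record_id,
                f"location interval {start}..{end} lies outside the sequence "
                f"(length {seq_len})",
            )
        intervals.append((start, end))
    # fuzziness ('<'/'>') on the extreme coordinates of the whole location
    low_pos = min((p.start for p in parts), key=int)
    high_pos = max((p.end for p in parts), key=int)
    low_before = isinstance(low_pos, BeforePosition)
    high_after = isinstance(high_pos, AfterPosition)
    if strand is Strand.PLUS:
        partial5, partial3 = low_before, high_after
    else:  # mirrored under complement: '<' on the low coordinate is the 3' end
        partial5, partial3 = high_after, low_before
    return FeatureLocation(
        intervals=tuple(intervals), strand=strand, partial5=partial5, partial3=partial3
    )


def parse_location(location_text: str, seq_len: int, record_id: str = "?") -> FeatureLocation:
    """Parse one feature-table location string.

    Supports plain intervals ``a..b``, single bases ``a``,
    ``complement(...)`` and ``join(...)``; ``<``/``>`` markers set the
    partiality flags.  ``order(...)`` and remote references are rejected
    as per-record errors, as are coordinates outside ``[1, seq_len]``.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            loc = Location.fromstring(location_text, length=seq_len)
    except Exception as exc:
        raise RecordProcessingError(
            record_id, f"unparseable feature location '{location_text}': {exc}"
        ) from None
    if loc is None:
        raise RecordProcessingError(
            record_id, f"unparseable feature location '{location_text}'"
        )
    return _from_biopython_location(loc, seq_len, record_id)


# --- flat-file parsing ------------------------------------------------------

_EMBL_ID_LEN = re.compile(r"^ID\s.*?(\d+)\s+BP\.?\s*$")
_LOCUS_LEN = re.compile(r"^LOCUS\s+\S+\s+(\d+)\s+bp\b")


def _declared_lengths(path: Path, fmt: FileFormat) -> list[int]:
    """Sequence lengths declared on the ID/LOCUS line of each entry."""
    pattern = _EMBL_ID_LEN if fmt is FileFormat.EMBL else _LOCUS_LEN
    lengths = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            m = pattern.match(line)
            if m:
                lengths.append(int(m.group(1)))
    return lengths


def _convert_feature(feat: SeqFeature, seq_len: int, record_id: str) -> Feature:
    qualifiers: dict[str, tuple[str, ...]] = {}
    for name, values in feat.qualifiers.items():
        if not name:
            continue
        if isinstance(values, (list, tuple)):
            qualifiers[name] = tuple(str(v) for v in values)
        else:
            qualifiers[name] = (str(values),)
    location = _from_biopython_location(feat.location, seq_len, record_id)
    return Feature(key=feat.type, location=location, qualifiers=qualifiers)


def parse_flatfile(path: str, fmt: FileFormat | None = None) -> list[SequenceRecord]:
    """Parse a multi-record flat file into SequenceRecord values, in file order.

    Sequence letters are uppercased and line-wrapping removed; features
    keep their file order.  Structural problems (no entries, malformed
    entries, a declared sequence length that disagrees with the sequence
    block) abort parsing with :class:`FlatFileSyntaxError`.
    """
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"input flat file not found: '{path}'")
    if fmt is None:
        fmt = detect_format(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio_records = list(SeqIO.parse(str(p), fmt.value))
    except Exception as exc:
        raise FlatFileSyntaxError(f"malformed {fmt.name} flat file '{path}': {exc}") from None
    if not bio_records:
        raise FlatFileSyntaxError(
            f"no sequence records found in '{path}' (empty or malformed {fmt.name} file)"
        )
    declared = _declared_lengths(p, fmt)
    records: list[SequenceRecord] = []
    for index, bio_rec in enumerate(bio_records):
        # prefer the ID/LOCUS entry name over the versioned accession
        record_id = bio_rec.name if bio_rec.name not in ("", "<unknown name>") else bio_rec.id
        sequence = str(bio_rec.seq).upper()
        if len(sequence) == 0:
            raise FlatFileSyntaxError(f"entry '{record_id}' contains no sequence")
        if index < len(declared) and declared[index] != len(sequence):
            raise FlatFileSyntaxError(
                f"entry '{record_id}' declares {declared[index]} bp but its sequence "
                f"block holds {len(sequence)} letters"
            )
        features = tuple(
            _convert_feature(f, len(sequence), record_id) for f in bio_rec.features
        )
        organism = ""
        if features and features[0].key == "source":
            organism = features[0].first("organism") or ""
        records.append(
            SequenceRecord(
                record_id=record_id,
                organism=organism,
                sequence=sequence,
                features=features,
            )
        )
    return records
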