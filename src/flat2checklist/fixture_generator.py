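"""Seeded generator of dummy EMBL/GenBank flat files with ground truth.

Each generated record reproduces the structural layout of one of the six
barcoding markers (a gene spanning an intron; two genes flanking an
intergenic spacer; matK inside the trnK intron; a single rRNA gene; the
18S-ITS1-5.8S-ITS2-28S ladder; a flank rRNA plus an ETS misc_RNA) over
a random DNA sequence derived from the seed.  Alongside the flat-file
text, a manifest records the exact feature layout and the checklist row
the record should yield; the expected values are computed here directly
from the generation parameters, never by running the extraction code,
so the manifest can serve as an independent oracle for the whole
pipeline.

The renderers emit real flat-file text by hand — standard EMBL
ID/FT/SQ line types with 60-residue wrapped sequence lines, and GenBank
LOCUS/FEATURES/ORIGIN blocks — so parsing exercises genuine
line-wrapping and interleaving.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .checklist_schema import ChecklistType, get_schema
from .flatfile_io import FileFormat

__all__ = ["FixtureFeature", "ManifestEntry", "FixtureRecord", "FixtureManifest",
           "make_record", "make_file"]

MIN_LENGTH = 200
MAX_LENGTH = 2000


@dataclass
class FixtureFeature:
    """Ground truth for one generated annotation feature (plus strand)."""

    key: str
    start: int
    end: int
    partial5: bool = False
    partial3: bool = False
    qualifiers: list[tuple[str, str]] = field(default_factory=list)

    @property
    def location_text(self) -> str:
        left = f"{'<' if self.partial5 else ''}{self.start}"
        right = f"{'>' if self.partial3 else ''}{self.end}"
        return f"{left}..{right}"

    def as_dict(self) -> dict:
        return {
            "key": self.key,
            "start": self.start,
            "end": self.end,
            "partial5": self.partial5,
            "partial3": self.partial3,
            "qualifiers": [list(q) for q in self.qualifiers],
        }


@dataclass
class ManifestEntry:
    """Ground truth for one generated record, including its expected row."""

    record_id: str
    marker: ChecklistType
    organism: str
    sequence: str
    features: list[FixtureFeature]
    expected_status: str  # "ok" or "skip"
    expected_values: dict[str, str]  # marker + universal columns, minus ENV_SAMPLE

    def expected_row(self, env_sample: bool = False) -> dict[str, str]:
        """The full expected checklist row in schema column order."""
        schema = get_schema(self.marker)
        row = {}
        for name in schema.column_names:
            if name == "ENV_SAMPLE":
                row[name] = "yes" if env_sample else "no"
            else:
                row[name] = self.expected_values.get(name, "")
        return row

    def as_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "marker": self.marker.value,
            "organism": self.organism,
            "sequence": self.sequence,
            "features": [f.as_dict() for f in self.features],
            "expected_status": self.expected_status,
            "expected_values": self.expected_values,
        }


@dataclass
class FixtureRecord:
    """One generated record: the manifest entry plus flat-file renderers."""

    manifest: ManifestEntry

    def text(self, fmt: FileFormat) -> str:
        if fmt is FileFormat.EMBL:
            return _render_embl(self.manifest)
        return _render_genbank(self.manifest)


@dataclass
class FixtureManifest:
    """Ground truth for a whole generated flat file, in file order."""

    path: str
    fmt: FileFormat
    records: list[ManifestEntry]

    def as_dict(self) -> dict:
        return {
            "path": self.path,
            "format": self.fmt.name,
            "records": [r.as_dict() for r in self.records],
        }


# --- record construction ----------------------------------------------------


def _random_sequence(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def _source_feature(length: int, organism: str, extra: dict[str, str] | None) -> FixtureFeature:
    qualifiers = [("organism", organism), ("mol_type", "genomic DNA")]
    for name, value in (extra or {}).items():
        qualifiers.append((name, value))
    return FixtureFeature("source", 1, length, qualifiers=qualifiers)


def make_record(
    marker: ChecklistType | str,
    seed: int,
    *,
    record_id: str | None = None,
    organism: str = "Arabidopsis thaliana",
    length: int = 700,
    source_qualifiers: dict[str, str] | None = None,
    partial5: bool = False,
    partial3: bool = False,
    # gene_intron
    gene_note: str = "trnL",
    intron_number: str | None = "1",
    include_intron: bool = True,
    include_gene: bool = True,
    # IGS
    gene1: str = "trnH",
    gene2: str = "psbA",
    spacer_product: str | None = None,
    flank1_present: bool = True,
    flank2_present: bool = True,
    include_spacer: bool = True,
    # trnK_matK
    has_intron: bool = True,
    has_trna: bool = False,
    # rRNA
    sediment: str = "18S",
    rrna_product: str | None = None,
    include_product: bool = True,
    # ITS / ETS
    has_18s: bool = True,
    has_its1: bool = True,
    has_58s: bool = True,
    has_its2: bool = True,
    has_28s: bool = True,
    isolation_source: str | None = None,
    ets_note: str | None = "5'",
) -> FixtureRecord:
    """Generate one dummy record of the given marker structure.

    The feature layout follows the marker's canonical structure; toggles
    allow deliberately incomplete records for skip-path tests.  The
    manifest's expected values are derived from the same parameters that
    produced the features.
    """
    marker = ChecklistType(marker) if isinstance(marker, str) else marker
    if not (MIN_LENGTH <= length <= MAX_LENGTH):
        raise ValueError(
            f"length must lie in [{MIN_LENGTH}, {MAX_LENGTH}], got {length}"
        )
    rng = random.Random(seed)
    sequence = _random_sequence(rng, length)
    rid = record_id or f"DUMMY{seed}"
    extra = dict(source_qualifiers or {})
    if isolation_source is not None:
        extra["isolation_source"] = isolation_source
    features = [_source_feature(length, organism, extra)]
    expected: dict[str, str] = {"ORGANISM_NAME": organism, "SEQUENCE": sequence}
    for name, value in extra.items():
        expected[name] = value
    status = "ok"
    L = length

    if marker is ChecklistType.gene_intron:
        g1, g2 = 10, L - 10
        i1, i2 = max(11, L // 5), min(g2 - 1, (4 * L) // 5)
        if include_gene:
            features.append(FixtureFeature("gene", g1, g2, qualifiers=[("note", gene_note)]))
        if include_intron:
            quals = [("gene", gene_note)]
            if intron_number is not None:
                quals.append(("number", intron_number))
            features.append(
                FixtureFeature("intron", i1, i2, partial5, partial3, qualifiers=quals)
            )
        if include_gene and include_intron:
            expected.update({
                "GENE": gene_note,
                "5'_PARTIAL": "yes" if partial5 else "no",
                "3'_PARTIAL": "yes" if partial3 else "no",
                "5'_INTRON": str(i1),
                "3'_INTRON": str(i2),
                "NUMBER": intron_number if intron_number is not None else "1",
            })
        else:
            status = "skip"

    elif marker is ChecklistType.IGS:
        third = L // 3
        product = spacer_product or f"{gene1}-{gene2} intergenic spacer"
        if flank1_present:
            features.append(FixtureFeature("gene", 5, third, qualifiers=[("note", gene1)]))
        if include_spacer:
            features.append(
                FixtureFeature("misc_feature", third + 1, 2 * third,
                               qualifiers=[("product", product)])
            )
        if flank2_present:
            features.append(
                FixtureFeature("gene", 2 * third + 1, L - 5, qualifiers=[("note", gene2)])
            )
        if include_spacer:
            expected.update({
                "GENE1": gene1,
                "G1PRESENT": "yes" if flank1_present else "no",
                "GENE2": gene2,
                "G2PRESENT": "yes" if flank2_present else "no",
            })
        else:
            status = "skip"

    elif marker is ChecklistType.trnK_matK:
        if has_trna:
            features.append(
                FixtureFeature("tRNA", 5, L - 5, qualifiers=[("gene", "trnK-UUU")])
            )
        if has_intron:
            features.append(
                FixtureFeature("intron", 30, L - 30,
                               qualifiers=[("gene", "trnK"), ("number", "1")])
            )
        m1, m2 = max(31, L // 7), min(L - 31, (6 * L) // 7)
        features.append(
            FixtureFeature("gene", m1, m2, partial5, partial3,
                           qualifiers=[("gene", "matK"), ("note", "matK")])
        )
        if has_intron or has_trna:
            expected.update({
                "5'_CDS": "no" if partial5 else "yes",
                "3'_CDS": "no" if partial3 else "yes",
                "5'_PARTIAL": "yes" if partial5 else "no",
                "3'_PARTIAL": "yes" if partial3 else "no",
                "INTRON": "yes",
            })
        else:
            status = "skip"

    elif marker is ChecklistType.rRNA:
        quals = [("gene", f"{sediment} rRNA")]
        if include_product:
            quals.append(("product", rrna_product or f"{sediment} ribosomal RNA"))
        features.append(
            FixtureFeature("rRNA", 1, L, partial5=True, partial3=True, qualifiers=quals)
        )
        if include_product:
            expected["SEDIMENT"] = sediment
        else:
            status = "skip"

    elif marker is ChecklistType.ITS:
        bounds = [1] + [round(L * f) for f in (0.2, 0.4, 0.6, 0.8)] + [L]
        segments = list(zip(bounds[:-1], bounds[1:]))
        if has_18s:
            features.append(
                FixtureFeature("rRNA", segments[0][0], segments[0][1], partial5=True,
                               qualifiers=[("gene", "18S rRNA")])
            )
        if has_its1:
            features.append(
                FixtureFeature("misc_RNA", segments[1][0] + 1, segments[1][1],
                               qualifiers=[("note", "internal transcribed spacer 1")])
            )
        if has_58s:
            features.append(
                FixtureFeature("rRNA", segments[2][0] + 1, segments[2][1],
                               qualifiers=[("gene", "5.8S rRNA")])
            )
        if has_its2:
            features.append(
                FixtureFeature("misc_RNA", segments[3][0] + 1, segments[3][1],
                               qualifiers=[("note", "internal transcribed spacer 2")])
            )
        if has_28s:
            features.append(
                FixtureFeature("rRNA", segments[4][0] + 1, segments[4][1], partial3=True,
                               qualifiers=[("gene", "28S rRNA")])
            )
        if any((has_18s, has_28s, has_58s)) or any((has_its1, has_its2)):
            expected.update({
                "18S": "yes" if has_18s else "no",
                "ITS1": "yes" if has_its1 else "no",
                "ITS2": "yes" if has_its2 else "no",
                "28S": "yes" if has_28s else "no",
                "5.8S": "yes" if (has_its1 and has_its2) else "no",
            })
            if isolation_source is not None:
                expected["ISOLATION_SOURCE"] = isolation_source
        else:
            status = "skip"

    elif marker is ChecklistType.ETS:
        half = L // 2
        if has_18s:
            features.append(
                FixtureFeature("rRNA", 1, half, partial5=True,
                               qualifiers=[("gene", "18S rRNA")])
            )
        if has_28s:
            features.append(
                FixtureFeature("rRNA", half + 1, L, partial3=True,
                               qualifiers=[("gene", "28S rRNA")])
            )
        if ets_note is not None:
            note = f"{ets_note} ETS"
            start = half + 1 if ets_note == "5'" and has_18s else 1
            end = L if ets_note == "5'" and has_18s else max(half, 2)
            features.append(
                FixtureFeature("misc_RNA", start, end, qualifiers=[("note", note)])
            )
        if ets_note is not None:
            ets_type = ets_note
            contradiction = (ets_note == "5'" and not has_18s and has_28s) or (
                ets_note == "3'" and not has_28s and has_18s
            )
            if contradiction:
                ets_type = ""  # note contradicts the annotated flank
        elif has_18s and not has_28s:
            ets_type = "5'"
        elif has_28s and not has_18s:
            ets_type = "3'"
        else:
            ets_type = ""  # no note and ambiguous/absent flanks: not convertible
        if ets_type:
            expected.update({
                "ETS_TYPE": ets_type,
                "18S": "yes" if has_18s else "no",
                "28S": "yes" if has_28s else "no",
            })
        else:
            status = "skip"
    else:  # pragma: no cover
        raise ValueError(f"unknown marker {marker!r}")

    entry = ManifestEntry(
        record_id=rid,
        marker=marker,
        organism=organism,
        sequence=sequence,
        features=features,
        expected_status=status,
        expected_values=expected,
    )
    return FixtureRecord(manifest=entry)


# --- flat-file rendering ----------------------------------------------------


def _quote(name: str, value: str) -> str:
    if name == "number" and value.isdigit():
        return value  # /number is an unquoted integer qualifier
    return f'"{value}"'


def _render_embl(entry: ManifestEntry) -> str:
    seq = entry.sequence
    length = len(seq)
    counts = {base: seq.count(base) for base in "ACGT"}
    other = length - sum(counts.values())
    lines = [
        f"ID   {entry.record_id}; SV 1; linear; genomic DNA; STD; PLN; {length} BP.",
        "XX",
        f"AC   {entry.record_id};",
        "XX",
        "DE   dummy barcoding sequence record",
        "XX",
        f"OS   {entry.organism}",
        "OC   Eukaryota.",
        "XX",
        "FH   Key             Location/Qualifiers",
        "FH",
    ]
    for feature in entry.features:
        lines.append(f"FT   {feature.key:<16}{feature.location_text}")
        for name, value in feature.qualifiers:
            lines.append(f"FT                   /{name}={_quote(name, value)}")
    lines.append("XX")
    lines.append(
        f"SQ   Sequence {length} BP; {counts['A']} A; {counts['C']} C; "
        f"{counts['G']} G; {counts['T']} T; {other} other;"
    )
    lowered = seq.lower()
    for offset in range(0, length, 60):
        chunk = lowered[offset:offset + 60]
        groups = " ".join(chunk[i:i + 10] for i in range(0, len(chunk), 10))
        line = "     " + groups
        position = str(min(offset + 60, length))
        lines.append(line + position.rjust(80 - len(line)))
    lines.append("//")
    return "\n".join(lines) + "\n"


def _render_genbank(entry: ManifestEntry) -> str:
    seq = entry.sequence
    length = len(seq)
    lines = [
        f"LOCUS       {entry.record_id:<16} {length:>11} bp    DNA     linear   PLN 01-JAN-2019",
        "DEFINITION  dummy barcoding sequence record.",
        f"ACCESSION   {entry.record_id}",
        f"VERSION     {entry.record_id}.1",
        "KEYWORDS    .",
        f"SOURCE      {entry.organism}",
        f"  ORGANISM  {entry.organism}",
        "            Eukaryota.",
        "FEATURES             Location/Qualifiers",
    ]
    for feature in entry.features:
        lines.append(f"     {feature.key:<16}{feature.location_text}")
        for name, value in feature.qualifiers:
            lines.append(f"                     /{name}={_quote(name, value)}")
    lines.append("ORIGIN")
    lowered = seq.lower()
    for offset in range(0, length, 60):
        chunk = lowered[offset:offset + 60]
        groups = " ".join(chunk[i:i + 10] for i in range(0, len(chunk), 10))
        lines.append(f"{offset + 1:>9} {groups}")
    lines.append("//")
    return "\n".join(lines) + "\n"


def make_file(
    entries: list[FixtureRecord],
    fmt: FileFormat,
    path: str,
    write_manifest: bool = True,
) -> FixtureManifest:
    """Write a multi-record flat file (possibly empty) and return its manifest.

    When *write_manifest* is true, a JSON manifest is written next to
    the flat file under '<path>.manifest.json'.
    """
    target = Path(path)
    text = "".join(record.text(fmt) for record in entries)
    target.write_text(text, encoding="utf-8", newline="")
    manifest = FixtureManifest(
        path=str(path), fmt=fmt, records=[r.manifest for r in entries]
    )
    if write_manifest:
        manifest_path = Path(str(path) + ".manifest.json")
        manifest_path.write_text(
            json.dumps(manifest.as_dict(), indent=1), encoding="utf-8"
        )
    return manifest
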