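"""Data processing: fill one checklist row per audited sequence record.

Mandatory columns are extracted first; only when they all succeed are
the optional columns filled ("mandatory before optional").  Each
checklist type has its own special parsing rules:

* gene_intron — intron start/end and 5'/3' partiality come from the
  intron *location*, never from qualifier text.
* IGS — the two flanking gene names are parsed out of the spacer
  misc_feature's product; their presence in the record is reported.
* trnK_matK — INTRON is yes iff an intron feature or a trnK-UUU tRNA
  feature exists; CDS completeness flags mirror the matK location
  partiality.
* rRNA — SEDIMENT is the Svedberg token recognized inside the rRNA
  product and must be one of the nine permitted values.
* ITS — 18S/28S and ITS1/ITS2 presence are feature-presence tests; the
  completeness of the 5.8S gene is inferred from ITS1 and ITS2 both
  being present; for environmental samples ISOLATION_SOURCE becomes
  mandatory.
* ETS — the ETS type (5'/3') is read from the misc_RNA note or, absent
  one, inferred from which flanking rRNA gene is annotated.

Feature and qualifier spellings encountered during processing are
checked against the bundled INSDC dictionary; a near miss names the
canonical spelling in the error message.  All failures here are
per-record (the record is skipped), never fatal to the run.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .checklist_schema import (
    ChecklistSchema,
    ChecklistType,
    Requirement,
    ValueKind,
    get_schema,
    mandatory_columns,
)
from .errors import RecordProcessingError
from .flatfile_io import Feature, SequenceRecord
from .insdc_dictionary import validate_feature_key, validate_qualifier

__all__ = [
    "ChecklistRow",
    "extract_common",
    "extract_gene_intron",
    "extract_igs",
    "extract_trnK_matK",
    "extract_rRNA",
    "extract_its",
    "extract_ets",
    "extract_optional",
    "build_row",
    "validate_row",
]

logger = logging.getLogger("flat2checklist")

#: Note strings recognized for the internal transcribed spacers; matching is
#: case-insensitive and substring-based, so both the abbreviation and the
#: spelled-out form are accepted.
ITS1_TOKENS = ("its1", "internal transcribed spacer 1")
ITS2_TOKENS = ("its2", "internal transcribed spacer 2")


@dataclass
class ChecklistRow:
    """Column name -> text value for one successfully processed record."""

    checklist: ChecklistType
    values: dict[str, str] = field(default_factory=dict)

    def merged(self, other: "ChecklistRow") -> "ChecklistRow":
        merged = dict(self.values)
        merged.update(other.values)
        return ChecklistRow(self.checklist, merged)


def sanitize_cell(value: str) -> str:
    """Replace tab/CR/LF runs with single spaces to keep the TSV intact."""
    return re.sub(r"[\t\r\n]+", " ", value)


# --- small matching helpers -------------------------------------------------


def _features(record: SequenceRecord, key: str) -> list[Feature]:
    return [f for f in record.features if f.key == key]


def _mentions(feature: Feature, name: str, qualifiers=("gene", "note", "product")) -> bool:
    """Case-insensitive substring test of *name* against qualifier values.

    Deliberately loose so that e.g. 'trnH' matches an annotation of
    'trnH-GUG'.
    """
    lowered = name.lower()
    for qualifier in qualifiers:
        for value in feature.qualifiers.get(qualifier, ()):
            if lowered in value.lower():
                return True
    return False


def _five_prime_most(features: list[Feature]) -> Feature:
    return min(features, key=lambda f: f.location.start)


def _yes_no(flag: bool) -> str:
    return "yes" if flag else "no"


def find_ets_note(record: SequenceRecord) -> tuple[Feature, str] | None:
    """The misc_RNA feature with a 5'/3' ETS note and the type it names."""
    for feature in _features(record, "misc_RNA"):
        for value in feature.qualifiers.get("note", ()):
            text = value.replace("′", "'").lower()
            if "5' ets" in text:
                return feature, "5'"
            if "3' ets" in text:
                return feature, "3'"
    return None


def _has_flank(record: SequenceRecord, flank: str) -> bool:
    return any(
        _mentions(f, flank, qualifiers=("gene",)) for f in _features(record, "rRNA")
    )


# --- universal columns ------------------------------------------------------


def extract_common(record: SequenceRecord, env_sample: bool) -> ChecklistRow:
    """ORGANISM_NAME, ENV_SAMPLE and SEQUENCE, shared by all checklist types.

    ENV_SAMPLE reflects the run-level environmental-sample flag and is
    therefore identical for every record of a file.
    """
    if not record.organism:
        raise RecordProcessingError(
            record.record_id, "source feature lacks an organism qualifier"
        )
    return ChecklistRow(
        checklist=None,
        values={
            "ORGANISM_NAME": record.organism,
            "ENV_SAMPLE": _yes_no(env_sample),
            "SEQUENCE": record.sequence,
        },
    )


# --- marker-specific extraction --------------------------------------------


def extract_gene_intron(record: SequenceRecord) -> ChecklistRow:
    """gene_intron columns; coordinates and partiality come from the location."""
    rid = record.record_id
    introns = _features(record, "intron")
    if not introns:
        raise RecordProcessingError(rid, "no intron feature")
    if len(introns) > 1:
        numbers = [f.first("number") for f in introns]
        if None in numbers or len(set(numbers)) != len(numbers):
            raise RecordProcessingError(
                rid,
                f"{len(introns)} intron features without distinguishing number "
                "qualifiers — cannot decide which intron the checklist describes",
            )
        logger.warning(
            "record '%s': %d intron features; using the 5'-most", rid, len(introns)
        )
    intron = _five_prime_most(introns)
    genes = [f for f in _features(record, "gene") if f.first("note")]
    if not genes:
        raise RecordProcessingError(rid, "no gene feature with a note qualifier")
    gene = _five_prime_most(genes)
    loc = intron.location
    number = intron.first("number")
    if number is None:
        number = "1"  # barcoding introns are first introns; documented default
    return ChecklistRow(
        ChecklistType.gene_intron,
        {
            "GENE": gene.first("note"),
            "5'_PARTIAL": _yes_no(loc.partial5),
            "3'_PARTIAL": _yes_no(loc.partial3),
            "5'_INTRON": str(loc.start),
            "3'_INTRON": str(loc.end),
            "NUMBER": number,
        },
    )


_SPACER_SUFFIX = re.compile(r"\s*(intergenic\s+)?spacer\s*$", re.IGNORECASE)


def extract_igs(record: SequenceRecord) -> ChecklistRow:
    """IGS columns from the spacer misc_feature and the flanking genes."""
    rid = record.record_id
    spacers = [f for f in _features(record, "misc_feature") if f.first("product")]
    if not spacers:
        raise RecordProcessingError(rid, "no misc_feature with a product qualifier")
    if len(spacers) > 1:
        logger.warning(
            "record '%s': %d spacer misc_features; using the 5'-most", rid, len(spacers)
        )
    product = _five_prime_most(spacers).first("product")
    stem = _SPACER_SUFFIX.sub("", product).strip()
    parts = [p for p in re.split(r"[-–—/]", stem) if p.strip()]
    if len(parts) != 2:
        raise RecordProcessingError(
            rid,
            f"cannot parse two flanking gene names from spacer product '{product}' "
            "(expected the form 'geneA-geneB intergenic spacer')",
        )
    gene1, gene2 = (p.strip() for p in parts)
    gene_feats = _features(record, "gene")
    present1 = any(_mentions(f, gene1, ("note", "gene")) for f in gene_feats)
    present2 = any(_mentions(f, gene2, ("note", "gene")) for f in gene_feats)
    return ChecklistRow(
        ChecklistType.IGS,
        {
            "GENE1": gene1,
            "G1PRESENT": _yes_no(present1),
            "GENE2": gene2,
            "G2PRESENT": _yes_no(present2),
        },
    )


def extract_trnK_matK(record: SequenceRecord) -> ChecklistRow:
    """trnK/matK columns; CDS completeness mirrors the matK location partiality."""
    rid = record.record_id
    genes = _features(record, "gene")
    matk = [f for f in genes if _mentions(f, "matK", ("note", "gene"))]
    if not matk:
        matk = [f for f in genes if _mentions(f, "trnK", ("note", "gene"))]
    if not matk:
        raise RecordProcessingError(rid, "no matK/trnK gene feature")
    loc = _five_prime_most(matk).location
    has_intron = bool(_features(record, "intron"))
    has_trnk_trna = any(
        _mentions(f, "trnK", ("gene", "note")) for f in _features(record, "tRNA")
    )
    return ChecklistRow(
        ChecklistType.trnK_matK,
        {
            "5'_CDS": _yes_no(not loc.partial5),
            "3'_CDS": _yes_no(not loc.partial3),
            "5'_PARTIAL": _yes_no(loc.partial5),
            "3'_PARTIAL": _yes_no(loc.partial3),
            "INTRON": _yes_no(has_intron or has_trnk_trna),
        },
    )


def _sediment_token(product: str, permitted: frozenset[str]) -> str | None:
    """The permitted Svedberg token inside *product*, canonically spelled.

    Longest tokens are tried first and a digit/dot must not precede the
    match, so '25S' is never mistaken for '5S' and '15S' matches nothing.
    """
    for token in sorted(permitted, key=len, reverse=True):
        if re.search(rf"(?<![\d.]){re.escape(token)}", product, re.IGNORECASE):
            return token
    return None


def extract_rRNA(record: SequenceRecord) -> ChecklistRow:
    """SEDIMENT from the rRNA feature's product value."""
    rid = record.record_id
    schema = get_schema(ChecklistType.rRNA)
    permitted = schema.column("SEDIMENT").permitted_values
    rrnas = [f for f in _features(record, "rRNA") if f.first("product")]
    if not rrnas:
        raise RecordProcessingError(rid, "no rRNA feature with a product qualifier")
    if len(rrnas) > 1:
        logger.warning(
            "record '%s': %d rRNA features with product; using the 5'-most", rid, len(rrnas)
        )
    product = _five_prime_most(rrnas).first("product")
    token = _sediment_token(product, permitted)
    if token is None:
        allowed = ", ".join(sorted(permitted))
        raise RecordProcessingError(
            rid,
            f"rRNA product '{product}' contains no permitted sediment token "
            f"(permitted: {allowed})",
        )
    return ChecklistRow(ChecklistType.rRNA, {"SEDIMENT": token})


def extract_its(record: SequenceRecord, env_sample: bool) -> ChecklistRow:
    """ITS columns; 5.8S completeness is inferred from ITS1 and ITS2 presence."""
    rid = record.record_id
    has_18s = _has_flank(record, "18S")
    has_28s = _has_flank(record, "28S")
    misc = _features(record, "misc_RNA")

    def _has_its(tokens) -> bool:
        for feature in misc:
            for value in feature.qualifiers.get("note", ()):
                lowered = value.lower()
                if any(t in lowered for t in tokens):
                    return True
        return False

    has_its1 = _has_its(ITS1_TOKENS)
    has_its2 = _has_its(ITS2_TOKENS)
    values = {
        "18S": _yes_no(has_18s),
        "ITS1": _yes_no(has_its1),
        "ITS2": _yes_no(has_its2),
        "28S": _yes_no(has_28s),
        "5.8S": _yes_no(has_its1 and has_its2),
    }
    if has_its1 and has_its2:
        logger.info("record '%s': 5.8S inferred complete (ITS1 and ITS2 present)", rid)
    if env_sample:
        source = record.source
        isolation = source.first("isolation_source") if source else None
        if not isolation:
            raise RecordProcessingError(
                rid,
                "environmental sample without an isolation_source qualifier "
                "(ISOLATION_SOURCE is mandatory when ENV_SAMPLE is 'yes')",
            )
        values["ISOLATION_SOURCE"] = isolation
    return ChecklistRow(ChecklistType.ITS, values)


def extract_ets(record: SequenceRecord) -> ChecklistRow:
    """ETS columns; the ETS type comes from the note or the annotated flank."""
    rid = record.record_id
    has_18s = _has_flank(record, "18S")
    has_28s = _has_flank(record, "28S")
    note = find_ets_note(record)
    if note is not None:
        ets_type = note[1]
        if ets_type == "5'" and has_28s and not has_18s:
            raise RecordProcessingError(
                rid, "note names a 5' ETS but only the 28S flank is annotated"
            )
        if ets_type == "3'" and has_18s and not has_28s:
            raise RecordProcessingError(
                rid, "note names a 3' ETS but only the 18S flank is annotated"
            )
    elif has_18s and not has_28s:
        ets_type = "5'"
    elif has_28s and not has_18s:
        ets_type = "3'"
    else:
        raise RecordProcessingError(
            rid,
            "cannot infer the ETS type: no misc_RNA feature with a 5'/3' ETS note "
            "and the annotated flanking rRNA genes are ambiguous",
        )
    return ChecklistRow(
        ChecklistType.ETS,
        {"ETS_TYPE": ets_type, "18S": _yes_no(has_18s), "28S": _yes_no(has_28s)},
    )


_MARKER_EXTRACTORS = {
    ChecklistType.gene_intron: lambda record, env: extract_gene_intron(record),
    ChecklistType.IGS: lambda record, env: extract_igs(record),
    ChecklistType.trnK_matK: lambda record, env: extract_trnK_matK(record),
    ChecklistType.rRNA: lambda record, env: extract_rRNA(record),
    ChecklistType.ITS: extract_its,
    ChecklistType.ETS: lambda record, env: extract_ets(record),
}


# --- optional columns and assembly -----------------------------------------


def _spell_check(record: SequenceRecord) -> None:
    """Verify INSDC spelling of every feature key and qualifier name."""
    for feature in record.features:
        key_result = validate_feature_key(feature.key)
        if not key_result.ok:
            hint = f" (did you mean '{key_result.suggestion}'?)" if key_result.suggestion else ""
            raise RecordProcessingError(
                record.record_id,
                f"feature key '{feature.key}' is not INSDC-compliant{hint}",
            )
        for qualifier in feature.qualifiers:
            result = validate_qualifier(feature.key, qualifier)
            if not result.ok:
                hint = f" (did you mean '{result.suggestion}'?)" if result.suggestion else ""
                raise RecordProcessingError(
                    record.record_id,
                    f"qualifier '{qualifier}' is not INSDC-compliant for feature "
                    f"'{feature.key}'{hint}",
                )


def extract_optional(
    record: SequenceRecord, schema: ChecklistSchema, row: ChecklistRow
) -> ChecklistRow:
    """Fill the optional columns of *row*; absent qualifiers yield empty cells.

    Runs only after mandatory extraction succeeded.  All feature keys
    and qualifier names of the record are spell-checked against the
    INSDC dictionary here; a misspelling skips the record and the error
    message carries the canonical suggestion.
    """
    _spell_check(record)
    source = record.source
    values = dict(row.values)
    for column in schema.columns:
        if column.requirement is not Requirement.OPTIONAL or column.name in values:
            continue
        value = ""
        if column.source_feature == "source" and column.source_qualifier and source:
            value = source.first(column.source_qualifier) or ""
        values[column.name] = value
    return ChecklistRow(row.checklist, values)


def validate_row(
    schema: ChecklistSchema, row: ChecklistRow, env_sample: bool, record_id: str = "?"
) -> None:
    """Check the assembled row against the schema's requirement and value kinds."""
    ets_type = row.values.get("ETS_TYPE", "5'")
    for column in mandatory_columns(schema, env_sample=env_sample, ets_type=ets_type):
        if not row.values.get(column.name):
            raise RecordProcessingError(
                record_id, f"mandatory column '{column.name}' has no value"
            )
    for column in schema.columns:
        value = row.values.get(column.name, "")
        if not value:
            continue
        if column.value_kind is ValueKind.YES_NO and value not in ("yes", "no"):
            raise RecordProcessingError(
                record_id, f"column '{column.name}' must be 'yes' or 'no', got '{value}'"
            )
        if column.value_kind is ValueKind.INTEGER and not value.isdigit():
            raise RecordProcessingError(
                record_id, f"column '{column.name}' must be an integer, got '{value}'"
            )
        if column.value_kind is ValueKind.ENUM and value not in (column.permitted_values or ()):
            raise RecordProcessingError(
                record_id, f"column '{column.name}' holds impermissible value '{value}'"
            )


def build_row(
    record: SequenceRecord, checklist: ChecklistType, env_sample: bool
) -> ChecklistRow:
    """Run the full data-processing step for one audited record.

    Mandatory columns first (universal, then marker-specific with the
    checklist's special rules), optional columns second; the finished
    row is ordered by the schema and validated.  Any failure raises
    :class:`RecordProcessingError` and the caller skips the record.
    """
    schema = get_schema(checklist)
    common = extract_common(record, env_sample)
    marker = _MARKER_EXTRACTORS[checklist](record, env_sample)
    partial = ChecklistRow(checklist, {**common.values, **marker.values})
    complete = extract_optional(record, schema, partial)
    ordered = {
        name: sanitize_cell(complete.values.get(name, ""))
        for name in schema.column_names
    }
    row = ChecklistRow(checklist, ordered)
    validate_row(schema, row, env_sample, record.record_id)
    return row
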