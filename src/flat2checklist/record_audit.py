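"""Per-record input audit.

Two checks run on every record before data processing.  First, marker
abbreviations found among the annotation qualifiers are compared with
the synonyms of the selected checklist type: recognizable markers that
all belong to *other* checklists indicate a wrong checklist selection
by the user and abort the whole run.  Second, the record is checked for
the minimal annotation features required to fill the checklist's
mandatory columns; a record failing this is skipped, not fatal.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .checklist_schema import ChecklistType, get_schema
from .flatfile_io import Feature, SequenceRecord

__all__ = [
    "AuditStatus",
    "AuditOutcome",
    "parse_marker_abbreviations",
    "check_checklist_coherence",
    "check_feature_prerequisites",
    "audit_record",
]

#: Qualifier names scanned for marker abbreviations.
_MARKER_QUALIFIERS = ("gene", "note", "product", "standard_name")


class AuditStatus(enum.Enum):
    OK = "ok"
    SKIP = "skip"
    FATAL = "fatal"


@dataclass(frozen=True)
class AuditOutcome:
    status: AuditStatus
    reason: str
    record_id: str

    @property
    def ok(self) -> bool:
        return self.status is AuditStatus.OK


def _ok(record_id: str) -> AuditOutcome:
    return AuditOutcome(AuditStatus.OK, "", record_id)


def _skip(record_id: str, reason: str) -> AuditOutcome:
    return AuditOutcome(AuditStatus.SKIP, f"record '{record_id}': {reason}", record_id)


def _all_synonyms() -> frozenset[str]:
    synonyms: set[str] = set()
    for checklist in ChecklistType:
        synonyms |= get_schema(checklist).marker_synonyms
    return frozenset(synonyms)


def parse_marker_abbreviations(record: SequenceRecord) -> set[str]:
    """Marker abbreviations recognized in the record's annotations.

    All synonym-set entries across the six checklists are matched
    case-insensitively as substrings of the gene, note, product and
    standard_name qualifier values of the record's non-source features.
    """
    found: set[str] = set()
    synonyms = _all_synonyms()
    for feature in record.features:
        if feature.key == "source":
            continue
        for qualifier in _MARKER_QUALIFIERS:
            for value in feature.qualifiers.get(qualifier, ()):
                lowered = value.lower()
                for synonym in synonyms:
                    if synonym.lower() in lowered:
                        found.add(synonym)
    return found


def check_checklist_coherence(
    markers: set[str], checklist: ChecklistType, record_id: str = "?"
) -> AuditOutcome:
    """Test whether recognized markers are coherent with the selected checklist.

    Markers disjoint from the selected schema's synonym set indicate an
    incorrect checklist selection and are fatal.  An empty marker set is
    deferred to prerequisite checking and passes here.
    """
    if not markers:
        return _ok(record_id)
    schema = get_schema(checklist)
    if markers & schema.marker_synonyms:
        return _ok(record_id)
    listed = ", ".join(sorted(markers))
    return AuditOutcome(
        AuditStatus.FATAL,
        f"record '{record_id}': marker abbreviations ({listed}) are incoherent with "
        f"checklist type '{checklist.value}' — likely an incorrect checklist selection",
        record_id,
    )


# --- feature prerequisite helpers ------------------------------------------


def _features(record: SequenceRecord, key: str) -> list[Feature]:
    return [f for f in record.features if f.key == key]


def _has_qualifier(feature: Feature, qualifier: str) -> bool:
    return bool(feature.qualifiers.get(qualifier))


def _qualifier_mentions(feature: Feature, name: str, qualifiers=("gene", "note", "product")) -> bool:
    """True if any of the given qualifier values mentions *name* (case-insensitive)."""
    lowered = name.lower()
    for qualifier in qualifiers:
        for value in feature.qualifiers.get(qualifier, ()):
            if lowered in value.lower():
                return True
    return False


def _ets_misc_rna(record: SequenceRecord) -> Feature | None:
    """The misc_RNA feature carrying a 5'/3' ETS note, if any."""
    for feature in _features(record, "misc_RNA"):
        for value in feature.qualifiers.get("note", ()):
            text = value.replace("′", "'").lower()
            if "5' ets" in text or "3' ets" in text:
                return feature
    return None


def _flank_rrna(record: SequenceRecord, flank: str) -> bool:
    return any(
        _qualifier_mentions(f, flank, qualifiers=("gene",))
        for f in _features(record, "rRNA")
    )


def check_feature_prerequisites(
    record: SequenceRecord, checklist: ChecklistType
) -> AuditOutcome:
    """Check that the record can in principle fill every mandatory marker column.

    Failures skip the record; they never abort the run.  A record whose
    source feature is missing or lacks an organism qualifier is also
    skipped, because ORGANISM_NAME is mandatory for every checklist.
    """
    rid = record.record_id
    if record.source is None:
        return _skip(rid, "no source feature at the top of the feature table")
    if not record.organism:
        return _skip(rid, "source feature lacks an organism qualifier")

    if checklist is ChecklistType.gene_intron:
        if not _features(record, "intron"):
            return _skip(rid, "no intron feature (required for checklist 'gene_intron')")
        if not any(_has_qualifier(f, "note") for f in _features(record, "gene")):
            return _skip(rid, "no gene feature with a note qualifier (GENE column)")
    elif checklist is ChecklistType.IGS:
        if not any(_has_qualifier(f, "product") for f in _features(record, "misc_feature")):
            return _skip(rid, "no misc_feature with a product qualifier (spacer name)")
    elif checklist is ChecklistType.trnK_matK:
        has_intron = bool(_features(record, "intron"))
        has_trnk_trna = any(
            _qualifier_mentions(f, "trnK") for f in _features(record, "tRNA")
        )
        if not (has_intron or has_trnk_trna):
            return _skip(
                rid, "neither an intron feature nor a tRNA feature for gene trnK-UUU"
            )
        if not any(
            _qualifier_mentions(f, "matK") or _qualifier_mentions(f, "trnK")
            for f in _features(record, "gene")
        ):
            return _skip(rid, "no matK/trnK gene feature")
    elif checklist is ChecklistType.rRNA:
        if not any(_has_qualifier(f, "product") for f in _features(record, "rRNA")):
            return _skip(
                rid, "no rRNA feature with a product qualifier (SEDIMENT column)"
            )
    elif checklist is ChecklistType.ITS:
        has_rrna = any(_has_qualifier(f, "gene") for f in _features(record, "rRNA"))
        has_misc = any(_has_qualifier(f, "note") for f in _features(record, "misc_RNA"))
        if not (has_rrna or has_misc):
            return _skip(
                rid, "neither an rRNA feature with gene nor a misc_RNA feature with note"
            )
    elif checklist is ChecklistType.ETS:
        has_flank = _flank_rrna(record, "18S") or _flank_rrna(record, "28S")
        if not (has_flank or _ets_misc_rna(record) is not None):
            return _skip(
                rid,
                "neither a flanking 18S/28S rRNA feature nor a misc_RNA feature "
                "with a 5'/3' ETS note",
            )
    return _ok(rid)


def audit_record(record: SequenceRecord, checklist: ChecklistType) -> AuditOutcome:
    """Full input audit: coherence first (fatal), then prerequisites (skip)."""
    markers = parse_marker_abbreviations(record)
    outcome = check_checklist_coherence(markers, checklist, record.record_id)
    if not outcome.ok:
        return outcome
    return check_feature_prerequisites(record, checklist)
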