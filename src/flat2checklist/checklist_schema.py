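"""The six Webin checklist schemas.

Each schema lists its columns in output order, the requirement level of
each column, the flat-file feature/qualifier it is copied from or the
special parsing rule that computes it, and the marker-abbreviation
synonyms the input audit matches against.  Definitions live in a
bundled, user-editable YAML file; this module loads them and adds the
universal columns shared by every checklist type.

Column order: ORGANISM_NAME and ENV_SAMPLE first, marker-specific
columns next in checklist order, optional columns alphabetically, and
SEQUENCE always last (so users can insert e.g. a LOCALITY column right
before it).
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .errors import ConfigurationError

__all__ = [
    "ChecklistType",
    "ValueKind",
    "Requirement",
    "ColumnSpec",
    "ChecklistSchema",
    "get_schema",
    "mandatory_columns",
]


class ChecklistType(enum.Enum):
    """The six supported checklist types, named as on the command line."""

    gene_intron = "gene_intron"
    IGS = "IGS"
    trnK_matK = "trnK_matK"
    rRNA = "rRNA"
    ITS = "ITS"
    ETS = "ETS"


class ValueKind(enum.Enum):
    TEXT = "text"
    INTEGER = "integer"
    YES_NO = "yes_no"
    ENUM = "enum"


class Requirement(enum.Enum):
    MANDATORY = "mandatory"
    CONDITIONAL = "conditional"
    OPTIONAL = "optional"


@dataclass(frozen=True)
class ColumnSpec:
    """One checklist column: where its value comes from and what it must hold."""

    name: str
    value_kind: ValueKind
    requirement: Requirement
    source_feature: str | None = None
    source_qualifier: str | None = None
    special_rule: str | None = None
    permitted_values: frozenset[str] | None = None


@dataclass(frozen=True)
class ChecklistSchema:
    """Full definition of one checklist type."""

    checklist: ChecklistType
    columns: tuple[ColumnSpec, ...]
    marker_synonyms: frozenset[str]
    description: str = ""
    ena_accession: str | None = None

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns)

    def column(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)


_UNIVERSAL_HEAD = (
    ColumnSpec(
        "ORGANISM_NAME", ValueKind.TEXT, Requirement.MANDATORY,
        source_feature="source", source_qualifier="organism",
    ),
    ColumnSpec(
        "ENV_SAMPLE", ValueKind.YES_NO, Requirement.MANDATORY, special_rule="env_flag",
    ),
)

_SEQUENCE_COLUMN = ColumnSpec(
    "SEQUENCE", ValueKind.TEXT, Requirement.MANDATORY, special_rule="sequence",
)


def _column_from_yaml(entry: dict, requirement_override: str | None = None) -> ColumnSpec:
    permitted = entry.get("permitted")
    return ColumnSpec(
        name=str(entry["name"]),
        value_kind=ValueKind(entry["kind"]),
        requirement=Requirement(requirement_override or entry["requirement"]),
        source_feature=entry.get("feature"),
        source_qualifier=entry.get("qualifier"),
        special_rule=entry.get("rule"),
        permitted_values=frozenset(str(v) for v in permitted) if permitted else None,
    )


@functools.lru_cache(maxsize=1)
def _load_schemas() -> dict[ChecklistType, ChecklistSchema]:
    text = resources.files("flat2checklist.data").joinpath(
        "checklist_schemas.yaml"
    ).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    shared_optional = [str(name) for name in data["shared_optional_columns"]]
    schemas: dict[ChecklistType, ChecklistSchema] = {}
    for name, entry in data["checklists"].items():
        checklist = ChecklistType(name)
        marker_columns = [_column_from_yaml(c) for c in entry["columns"]]
        optional: list[ColumnSpec] = [
            c for c in marker_columns if c.requirement is Requirement.OPTIONAL
        ]
        marker = [c for c in marker_columns if c.requirement is not Requirement.OPTIONAL]
        for qualifier in shared_optional:
            optional.append(
                ColumnSpec(
                    qualifier, ValueKind.TEXT, Requirement.OPTIONAL,
                    source_feature="source", source_qualifier=qualifier,
                )
            )
        optional.sort(key=lambda c: c.name.lower())
        columns = (*_UNIVERSAL_HEAD, *marker, *optional, _SEQUENCE_COLUMN)
        schemas[checklist] = ChecklistSchema(
            checklist=checklist,
            columns=columns,
            marker_synonyms=frozenset(str(s) for s in entry["synonyms"]),
            description=entry.get("description", ""),
            ena_accession=entry.get("ena_accession"),
        )
    return schemas


def get_schema(checklist: ChecklistType | str) -> ChecklistSchema:
    """Return the full schema for one of the six checklist types.

    Checklist names are matched exactly (case-sensitively) against the
    published names; anything else raises :class:`ConfigurationError`
    listing the valid names.
    """
    if isinstance(checklist, str):
        try:
            checklist = ChecklistType(checklist)
        except ValueError:
            valid = ", ".join(t.value for t in ChecklistType)
            raise ConfigurationError(
                f"unknown checklist type '{checklist}'; valid types are: {valid}"
            ) from None
    return _load_schemas()[checklist]


def mandatory_columns(
    schema: ChecklistSchema,
    env_sample: bool = False,
    ets_type: str = "5'",
) -> tuple[ColumnSpec, ...]:
    """Mandatory columns, with conditional columns promoted where their condition holds.

    Promotions: for ITS run on environmental samples, ISOLATION_SOURCE
    becomes mandatory; for ETS, the flank column matching the ETS type
    (5' ETS => 18S, 3' ETS => 28S) is mandatory while the other flank
    stays optional.
    """
    out = []
    for col in schema.columns:
        if col.requirement is Requirement.MANDATORY:
            out.append(col)
        elif col.requirement is Requirement.CONDITIONAL:
            if col.special_rule == "env_promotion" and env_sample:
                out.append(col)
            elif col.special_rule == "ets_flank":
                flank = "18S" if ets_type == "5'" else "28S"
                if col.name == flank:
                    out.append(col)
    return tuple(out)
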