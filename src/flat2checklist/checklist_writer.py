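"""Serialization of checklist rows to the tab-delimited Webin file.

One header line with the column names, one data line per successfully
processed record, tab-separated, UTF-8, '\\n' terminators, SEQUENCE as
the last field.  Cells are sanitized upstream, so no quoting dialect is
needed; the file loads in any spreadsheet editor and checklists with
identical schemas can be concatenated (dropping the second header).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .checklist_schema import ChecklistSchema
from .extractors import ChecklistRow

__all__ = ["ChecklistDocument", "WrittenFileReport", "write_checklist"]

logger = logging.getLogger("flat2checklist")


@dataclass
class ChecklistDocument:
    """A schema plus the ordered rows destined for one output file."""

    schema: ChecklistSchema
    rows: list[ChecklistRow] = field(default_factory=list)


@dataclass(frozen=True)
class WrittenFileReport:
    path: str
    n_rows: int


def render_checklist(doc: ChecklistDocument) -> str:
    """The full TSV text for a document (header plus data lines)."""
    header = doc.schema.column_names
    lines = ["\t".join(header)]
    for row in doc.rows:
        if tuple(row.values.keys()) != header:
            raise ValueError(
                "row columns do not match the schema (internal error): "
                f"{tuple(row.values.keys())!r} != {header!r}"
            )
        lines.append("\t".join(row.values[name] for name in header))
    return "\n".join(lines) + "\n"


def write_checklist(
    doc: ChecklistDocument, path: str, force: bool = False
) -> WrittenFileReport:
    """Write the checklist file; refuse to overwrite unless *force* is set.

    The refusal protects checklists a user may already have edited by
    hand before submission.
    """
    target = Path(path)
    if target.exists() and not force:
        raise FileExistsError(
            f"output file '{path}' already exists; pass force=True (--force) to overwrite"
        )
    text = render_checklist(doc)
    if not doc.rows:
        logger.warning("no rows to write; '%s' will contain only the header line", path)
    target.write_text(text, encoding="utf-8", newline="")
    return WrittenFileReport(path=str(path), n_rows=len(doc.rows))
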