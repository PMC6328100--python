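"""Exception hierarchy shared across the conversion pipeline.

Two severities matter downstream: errors that abort the whole run
(unreadable or malformed input, wrong checklist selection) and errors
that only skip the current sequence record.
"""


class Flat2ChecklistError(Exception):
    """Base class for all errors raised by this package."""


class UnsupportedExtensionError(Flat2ChecklistError):
    """Input filename does not end in '.embl' or '.gb'."""


class FlatFileSyntaxError(Flat2ChecklistError):
    """The flat file is malformed; parsing aborts the run."""


class ConfigurationError(Flat2ChecklistError):
    """Invalid run configuration, e.g. an unknown checklist type."""


class RecordProcessingError(Flat2ChecklistError):
    """Per-record failure during data processing; the record is skipped."""

    def __init__(self, record_id: str, reason: str):
        self.record_id = record_id
        self.reason = reason
        super().__init__(f"record '{record_id}': {reason}")


class CoherenceAbort(Flat2ChecklistError):
    """Marker abbreviations contradict the selected checklist type.

    Indicates an incorrect checklist selection by the user; the whole
    run is aborted and no output file is produced.
    """

    def __init__(self, record_id: str, reason: str):
        self.record_id = record_id
        self.reason = reason
        super().__init__(f"record '{record_id}': {reason}")
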