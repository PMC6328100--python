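"""INSDC feature/qualifier spell-checking.

A bundled, versioned subset of the INSDC feature-table definition maps
each feature key to its permitted qualifiers.  Data processing consults
it to make sure feature and qualifier names are spelled in compliance
with the INSDC vocabulary before their values are transferred into
checklist columns.

Membership tests are case-sensitive ("rRNA" != "rrna").  A near miss —
a case variant or a close misspelling of a known name — yields a
distinct verdict carrying the canonical spelling so diagnostics can
suggest it.
"""

from __future__ import annotations

import difflib
import enum
import functools
from dataclasses import dataclass
from importlib import resources

import yaml

__all__ = [
    "Verdict",
    "ValidationResult",
    "dictionary_version",
    "known_feature_keys",
    "permitted_qualifiers",
    "validate_feature_key",
    "validate_qualifier",
]


class Verdict(enum.Enum):
    VALID = "valid"
    UNKNOWN_KEY = "unknown-key"
    UNKNOWN_QUALIFIER = "unknown-qualifier-for-key"
    NEAR_MISS = "near-miss"


@dataclass(frozen=True)
class ValidationResult:
    verdict: Verdict
    suggestion: str | None = None

    @property
    def ok(self) -> bool:
        return self.verdict is Verdict.VALID


@functools.lru_cache(maxsize=1)
def _load() -> tuple[str, dict[str, frozenset[str]]]:
    text = resources.files("flat2checklist.data").joinpath("insdc_features.yaml").read_text(
        encoding="utf-8"
    )
    data = yaml.safe_load(text)
    table = {key: frozenset(quals) for key, quals in data["features"].items()}
    return data["version"], table


def dictionary_version() -> str:
    """Version string of the bundled INSDC definition subset."""
    return _load()[0]


def known_feature_keys() -> frozenset[str]:
    return frozenset(_load()[1])


def permitted_qualifiers(key: str) -> frozenset[str]:
    """Permitted qualifier names for a valid feature key."""
    return _load()[1][key]


def _near_miss(name: str, candidates) -> str | None:
    """Canonical spelling for a case-variant or close misspelling, if any."""
    lowered = {c.lower(): c for c in candidates}
    if name.lower() in lowered:
        return lowered[name.lower()]
    close = difflib.get_close_matches(name, list(candidates), n=1, cutoff=0.8)
    return close[0] if close else None


def validate_feature_key(key: str) -> ValidationResult:
    """Spell-check one feature key against the INSDC dictionary."""
    table = _load()[1]
    if key in table:
        return ValidationResult(Verdict.VALID)
    suggestion = _near_miss(key, table)
    if suggestion:
        return ValidationResult(Verdict.NEAR_MISS, suggestion)
    return ValidationResult(Verdict.UNKNOWN_KEY)


def validate_qualifier(key: str, qualifier: str) -> ValidationResult:
    """Spell-check one qualifier name within a valid feature key."""
    permitted = permitted_qualifiers(key)
    if qualifier in permitted:
        return ValidationResult(Verdict.VALID)
    suggestion = _near_miss(qualifier, permitted)
    if suggestion:
        return ValidationResult(Verdict.NEAR_MISS, suggestion)
    return ValidationResult(Verdict.UNKNOWN_QUALIFIER)
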