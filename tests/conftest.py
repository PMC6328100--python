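import pytest

from flat2checklist.checklist_schema import ChecklistType
from flat2checklist.fixture_generator import make_file, make_record
from flat2checklist.flatfile_io import FileFormat, parse_flatfile

EXT = {FileFormat.EMBL: "embl", FileFormat.GENBANK: "gb"}


@pytest.fixture(params=list(FileFormat), ids=lambda f: f.name.lower())
def file_format(request):
    return request.param


@pytest.fixture
def marker_file(tmp_path, file_format):
    """Factory: write a fixture flat file of given records, return (path, manifest)."""

    def _make(records, name="fixture"):
        path = tmp_path / f"{name}.{EXT[file_format]}"
        manifest = make_file(records, file_format, str(path), write_manifest=False)
        return str(path), manifest

    return _make


@pytest.fixture
def complete_records():
    """One prerequisite-complete record per checklist type."""
    return {
        marker: make_record(marker, seed=11 + i, record_id=f"REC{i}")
        for i, marker in enumerate(ChecklistType)
    }


@pytest.fixture
def parsed_record(tmp_path):
    """Factory: render one FixtureRecord to EMBL, parse it back, return the record."""

    def _parse(fixture_record, fmt=FileFormat.EMBL):
        path = tmp_path / f"one_{fixture_record.manifest.record_id}.{EXT[fmt]}"
        make_file([fixture_record], fmt, str(path), write_manifest=False)
        return parse_flatfile(str(path))[0]

    return _parse
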