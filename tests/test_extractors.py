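"""Data processing: marker-specific extraction and the special parsing rules."""

import pytest

from flat2checklist.checklist_schema import ChecklistType, get_schema
from flat2checklist.errors import RecordProcessingError
from flat2checklist.extractors import (
    build_row,
    extract_common,
    extract_ets,
    extract_gene_intron,
    extract_igs,
    extract_its,
    extract_optional,
    extract_rRNA,
    extract_trnK_matK,
    sanitize_cell,
)
from flat2checklist.fixture_generator import make_record
from flat2checklist.flatfile_io import Feature, FeatureLocation, SequenceRecord


def _with_feature_qualifiers(record, key, qualifiers):
    """Copy of *record* with the qualifiers of the first *key* feature replaced."""
    features = []
    replaced = False
    for feature in record.features:
        if feature.key == key and not replaced:
            features.append(Feature(feature.key, feature.location, dict(qualifiers)))
            replaced = True
        else:
            features.append(feature)
    return SequenceRecord(record.record_id, record.organism, record.sequence,
                          tuple(features))


class TestCommon:
    def test_universal_columns(self, parsed_record):
        record = parsed_record(make_record("rRNA", seed=1, organism="Arabidopsis thaliana"))
        row = extract_common(record, env_sample=False)
        assert row.values["ORGANISM_NAME"] == "Arabidopsis thaliana"
        assert row.values["ENV_SAMPLE"] == "no"
        assert row.values["SEQUENCE"] == record.sequence

    def test_env_flag_applies_to_the_whole_file(self, parsed_record):
        record = parsed_record(make_record("rRNA", seed=1))
        assert extract_common(record, env_sample=True).values["ENV_SAMPLE"] == "yes"


class TestGeneIntron:
    def test_coordinates_and_number_from_fixture(self, parsed_record):
        fixture = make_record("gene_intron", seed=2, gene_note="trnL intron",
                              intron_number="1")
        record = parsed_record(fixture)
        truth = fixture.manifest.expected_values
        row = extract_gene_intron(record)
        assert row.values["GENE"] == "trnL intron"
        assert row.values["5'_INTRON"] == truth["5'_INTRON"]
        assert row.values["3'_INTRON"] == truth["3'_INTRON"]
        assert row.values["NUMBER"] == "1"
        assert (row.values["5'_PARTIAL"], row.values["3'_PARTIAL"]) == ("no", "no")

    @pytest.mark.parametrize("partial5,partial3", [(True, False), (False, True), (True, True)])
    def test_partiality_comes_from_the_location(self, parsed_record, partial5, partial3):
        record = parsed_record(
            make_record("gene_intron", seed=3, partial5=partial5, partial3=partial3)
        )
        row = extract_gene_intron(record)
        assert row.values["5'_PARTIAL"] == ("yes" if partial5 else "no")
        assert row.values["3'_PARTIAL"] == ("yes" if partial3 else "no")

    def test_qualifier_text_cannot_override_location(self, parsed_record):
        """Intron coordinates are taken from the location, never from qualifiers."""
        record = parsed_record(make_record("gene_intron", seed=4))
        baseline = extract_gene_intron(record)
        mutated = _with_feature_qualifiers(
            record, "intron",
            {"gene": ("trnL",), "number": ("1",), "note": ("start=1 end=9999 partial",)},
        )
        row = extract_gene_intron(mutated)
        assert row.values["5'_INTRON"] == baseline.values["5'_INTRON"]
        assert row.values["3'_INTRON"] == baseline.values["3'_INTRON"]
        assert row.values["5'_PARTIAL"] == baseline.values["5'_PARTIAL"]

    def test_single_intron_without_number_defaults_to_one(self, parsed_record):
        record = parsed_record(make_record("gene_intron", seed=5, intron_number=None))
        assert extract_gene_intron(record).values["NUMBER"] == "1"


class TestIGS:
    def test_flanking_genes_present(self, parsed_record):
        record = parsed_record(make_record("IGS", seed=6, gene1="trnH", gene2="psbA"))
        row = extract_igs(record)
        assert row.values == {
            "GENE1": "trnH", "G1PRESENT": "yes", "GENE2": "psbA", "G2PRESENT": "yes",
        }

    def test_absent_flanking_genes(self, parsed_record):
        record = parsed_record(
            make_record("IGS", seed=7, flank1_present=False, flank2_present=False)
        )
        row = extract_igs(record)
        assert (row.values["G1PRESENT"], row.values["G2PRESENT"]) == ("no", "no")

    def test_gene_name_matching_tolerates_anticodon_suffix(self, parsed_record):
        fixture = make_record("IGS", seed=8, gene1="trnH", gene2="psbA")
        record = parsed_record(fixture)
        relaxed = _with_feature_qualifiers(record, "gene", {"note": ("trnH-GUG",)})
        assert extract_igs(relaxed).values["G1PRESENT"] == "yes"

    def test_single_token_product_is_an_error(self, parsed_record):
        record = parsed_record(make_record("IGS", seed=9, spacer_product="spacer"))
        with pytest.raises(RecordProcessingError, match="flanking gene names"):
            extract_igs(record)


class TestTrnKMatK:
    def test_complete_region(self, parsed_record):
        record = parsed_record(make_record("trnK_matK", seed=10))
        row = extract_trnK_matK(record)
        assert row.values == {
            "5'_CDS": "yes", "3'_CDS": "yes",
            "5'_PARTIAL": "no", "3'_PARTIAL": "no", "INTRON": "yes",
        }

    def test_partial_matk_mirrors_cds_flags(self, parsed_record):
        record = parsed_record(make_record("trnK_matK", seed=11, partial5=True))
        row = extract_trnK_matK(record)
        assert (row.values["5'_CDS"], row.values["5'_PARTIAL"]) == ("no", "yes")
        assert (row.values["3'_CDS"], row.values["3'_PARTIAL"]) == ("yes", "no")

    @pytest.mark.parametrize(
        "has_intron,has_trna,expected",
        [(True, False, "yes"), (False, True, "yes"), (True, True, "yes")],
    )
    def test_intron_yes_iff_intron_or_trnk_trna(self, parsed_record, has_intron,
                                                has_trna, expected):
        record = parsed_record(
            make_record("trnK_matK", seed=12, has_intron=has_intron, has_trna=has_trna)
        )
        assert extract_trnK_matK(record).values["INTRON"] == expected


class TestRRNA:
    @pytest.mark.parametrize(
        "sediment", ["5S", "5.8S", "12S", "16S", "18S", "23S", "25S", "26S", "28S"]
    )
    def test_all_permitted_sediments(self, parsed_record, sediment):
        record = parsed_record(make_record("rRNA", seed=13, sediment=sediment))
        assert extract_rRNA(record).values["SEDIMENT"] == sediment

    @pytest.mark.parametrize("product", ["17S ribosomal RNA", "15S rRNA", "ribosomal RNA"])
    def test_impermissible_products_are_errors(self, parsed_record, product):
        record = parsed_record(make_record("rRNA", seed=14, rrna_product=product))
        with pytest.raises(RecordProcessingError, match="sediment"):
            extract_rRNA(record)

    def test_token_is_recognized_inside_longer_product_text(self, parsed_record):
        record = parsed_record(
            make_record("rRNA", seed=15, rrna_product="5.8S ribosomal RNA, partial")
        )
        assert extract_rRNA(record).values["SEDIMENT"] == "5.8S"


class TestITS:
    def test_full_ladder_infers_58s_complete(self, parsed_record):
        record = parsed_record(make_record("ITS", seed=16))
        row = extract_its(record, env_sample=False)
        assert row.values["18S"] == "yes" and row.values["28S"] == "yes"
        assert row.values["ITS1"] == "yes" and row.values["ITS2"] == "yes"
        assert row.values["5.8S"] == "yes"

    @pytest.mark.parametrize(
        "has_its1,has_its2", [(True, False), (False, True), (False, False)]
    )
    def test_58s_not_inferred_without_both_spacers(self, parsed_record, has_its1, has_its2):
        record = parsed_record(
            make_record("ITS", seed=17, has_its1=has_its1, has_its2=has_its2)
        )
        assert extract_its(record, env_sample=False).values["5.8S"] == "no"

    def test_env_sample_takes_isolation_source(self, parsed_record):
        record = parsed_record(make_record("ITS", seed=18, isolation_source="soil"))
        row = extract_its(record, env_sample=True)
        assert row.values["ISOLATION_SOURCE"] == "soil"

    def test_env_sample_without_isolation_source_fails(self, parsed_record):
        record = parsed_record(make_record("ITS", seed=19))
        with pytest.raises(RecordProcessingError, match="isolation_source"):
            extract_its(record, env_sample=True)
        # the same record converts fine as a non-environmental sample
        assert extract_its(record, env_sample=False).values["ITS1"] == "yes"


class TestETS:
    def test_note_names_the_type(self, parsed_record):
        record = parsed_record(
            make_record("ETS", seed=20, ets_note="5'", has_18s=True, has_28s=False)
        )
        row = extract_ets(record)
        assert row.values == {"ETS_TYPE": "5'", "18S": "yes", "28S": "no"}

    def test_type_inferred_from_flank_when_no_note(self, parsed_record):
        record = parsed_record(
            make_record("ETS", seed=21, ets_note=None, has_18s=False, has_28s=True)
        )
        assert extract_ets(record).values["ETS_TYPE"] == "3'"

    def test_contradictory_note_and_flank_is_an_error(self, parsed_record):
        record = parsed_record(
            make_record("ETS", seed=22, ets_note="5'", has_18s=False, has_28s=True)
        )
        with pytest.raises(RecordProcessingError):
            extract_ets(record)

    def test_no_note_and_ambiguous_flanks_is_an_error(self, parsed_record):
        record = parsed_record(
            make_record("ETS", seed=23, ets_note=None, has_18s=True, has_28s=True)
        )
        with pytest.raises(RecordProcessingError):
            extract_ets(record)


class TestOptionalAndAssembly:
    def test_optional_qualifier_is_copied(self, parsed_record):
        fixture = make_record(
            "rRNA", seed=24, source_qualifiers={"specimen_voucher": "FR-2018-017"}
        )
        record = parsed_record(fixture)
        row = build_row(record, ChecklistType.rRNA, env_sample=False)
        assert row.values["specimen_voucher"] == "FR-2018-017"

    def test_absent_optional_qualifiers_yield_empty_cells(self, parsed_record):
        record = parsed_record(make_record("rRNA", seed=25))
        row = build_row(record, ChecklistType.rRNA, env_sample=False)
        assert row.values["country"] == "" and row.values["isolate"] == ""

    def test_misspelled_qualifier_names_canonical_spelling(self, parsed_record):
        record = parsed_record(make_record("rRNA", seed=26))
        schema = get_schema(ChecklistType.rRNA)
        partial = extract_common(record, env_sample=False)
        bad = _with_feature_qualifiers(
            record, "source",
            {"organism": (record.organism,), "countryy": ("France",)},
        )
        with pytest.raises(RecordProcessingError, match="country"):
            extract_optional(bad, schema, partial)

    def test_mandatory_failure_prevents_optional_extraction(self, parsed_record):
        """Mandatory-first ordering: a record whose mandatory extraction fails
        is rejected before optional columns are touched."""
        record = parsed_record(make_record("rRNA", seed=27, include_product=False))
        with pytest.raises(RecordProcessingError, match="rRNA"):
            build_row(record, ChecklistType.rRNA, env_sample=False)

    def test_row_is_in_schema_order_with_sequence_last(self, parsed_record):
        record = parsed_record(make_record("ITS", seed=28))
        row = build_row(record, ChecklistType.ITS, env_sample=False)
        schema = get_schema(ChecklistType.ITS)
        assert tuple(row.values.keys()) == schema.column_names
        assert list(row.values)[-1] == "SEQUENCE"
        assert row.values["SEQUENCE"].isupper()

    def test_extraction_is_pure(self, parsed_record):
        record = parsed_record(make_record("gene_intron", seed=29))
        first = build_row(record, ChecklistType.gene_intron, env_sample=False)
        second = build_row(record, ChecklistType.gene_intron, env_sample=False)
        assert first == second

    def test_cell_sanitization_replaces_separators(self):
        assert sanitize_cell("a\tb\r\nc") == "a b c"
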