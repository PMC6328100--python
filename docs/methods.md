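# Methods

## The conversion model

The package converts annotated flat-file records of six DNA-barcoding
markers into ENA Webin checklist rows.  A flat file holds one or more
records, each consisting of a feature table (a `source` feature at the
top carrying record-level metadata, annotation features below) and the
interleaved DNA sequence.  The converter assumes record-per-row
semantics throughout: one input record yields at most one output row,
rows appear in input order, and rows are buffered and written
collectively after the loop so that an aborted run never leaves a
truncated checklist behind.

Processing is a strict two-stage loop per record:

1. **Input audit.**  (a) Marker abbreviations are collected by
   case-insensitive substring search of a per-checklist synonym table
   against the `gene`, `note`, `product` and `standard_name` qualifier
   values of non-source features.  If abbreviations are found but none
   belongs to the selected checklist's synonym set, the run aborts — the
   user selected the wrong checklist, and converting the rest would
   produce a wrong submission wholesale.  An empty abbreviation set is
   not evidence of a mismatch and is deferred to the prerequisite check.
   (b) Feature prerequisites: the record must contain the features from
   which every mandatory marker column can in principle be filled (an
   intron feature for `gene_intron`; a spacer `misc_feature` with
   `product` for `IGS`; an intron or trnK-UUU tRNA plus a matK/trnK gene
   for `trnK_matK`; an `rRNA` with `product` for `rRNA`; an `rRNA` with
   `gene` or `misc_RNA` with `note` for `ITS`; a flanking 18S/28S rRNA
   or an ETS-note `misc_RNA` for `ETS`).  Prerequisite failures skip the
   record only.  A missing source feature or organism qualifier is also
   a prerequisite skip, since `ORGANISM_NAME` is universally mandatory.

2. **Data processing.**  Universal columns first, then the
   marker-specific mandatory columns under the special rules listed in
   the README, then — only if all of that succeeded — the optional
   columns, copied from source-feature qualifiers of the same name.
   During this stage all feature keys and qualifier names are
   spell-checked against a bundled INSDC feature-table subset; a
   misspelling skips the record with the canonical spelling suggested.
   Any processing failure is per-record.

Coordinates stay 1-based inclusive, exactly as printed in the flat
file, end to end; checklist intron positions are therefore in flat-file
coordinates.  Partiality is biological: for a minus-strand location the
`<` marker on the low coordinate flags the 3' end.

## Parameters that matter

* `-c` checklist type: one of `gene_intron`, `IGS`, `trnK_matK`,
  `rRNA`, `ITS`, `ETS` (exact, case-sensitive names).  It selects the
  column schema, the synonym set used by the audit and the special
  rules applied.
* `-e` environmental-sample flag (`yes`/`no`): applies to every record
  of the file, fills `ENV_SAMPLE`, and for `ITS` promotes
  `ISOLATION_SOURCE` from optional to mandatory.
* `--force`: overwrite an existing output file.  The default refusal
  protects checklists already edited by hand.
* Input format is decided solely by the file extension, `.embl` or
  `.gb` (case-insensitive); nothing else is accepted, including `.gbk`.

## Design choices where the design was open

* **ETS mandatory count.**  The ETS checklist carries three
  marker-specific columns (`18S`, `ETS_TYPE`, `28S`) but five mandatory
  columns in total.  We treat `ETS_TYPE` as mandatory and promote only
  the flank column matching the ETS type (5' ETS ⇒ `18S`, 3' ETS ⇒
  `28S`), giving 3 universal + 1 + 1 = 5.  This is the only reading
  consistent with both the published count and the either/or flank
  prerequisite; `mandatory_columns()` takes the ETS type as an argument
  (default 5').
* **ETS prerequisites and inference.**  A single annotated flank
  suffices for the audit; the ETS type is then read from the `misc_RNA`
  note, or inferred from which flank is annotated when no note exists.
  Both flanks annotated with no note is ambiguous and a per-record
  error, as is a note contradicting the annotated flank.
* **Optional columns.**  ENA's optional column inventories are
  checklist-version dependent; we ship a documented common subset
  (clone, collection_date, country, ecotype, haplotype, isolate,
  lat_lon, PCR_primers, specimen_voucher, strain), each copied from the
  source qualifier of the same name.  The schema file
  (`src/flat2checklist/data/checklist_schemas.yaml`) is plain YAML and
  user-extensible without code changes, as is the synonym table and the
  INSDC dictionary (`data/insdc_features.yaml`, compiled from INSDC
  feature-table definition 11.3).
* **Column order.**  `ORGANISM_NAME`, `ENV_SAMPLE`, marker columns in
  checklist order, optional columns alphabetically, `SEQUENCE` last —
  so users can insert columns (e.g. `LOCALITY`) right before
  `SEQUENCE`, and checklists with identical schemas concatenate.
* **Multi-candidate features.**  When several features could fill a
  single-feature slot (two rRNA features, two spacers), the 5'-most is
  used and a warning logged; rows are never multiplied.  Multiple
  introns are an error unless distinguished by `number` qualifiers.  A
  single intron without a `number` qualifier defaults to `NUMBER=1`,
  since the common barcoding introns are first introns.
* **Name matching.**  Gene-name presence tests (`G1PRESENT`, flank
  tests, trnK-UUU) are case-insensitive substring matches, so `trnH`
  matches an annotation of `trnH-GUG`.  ITS1/ITS2 recognize both the
  abbreviation and the spelled-out "internal transcribed spacer 1/2".
* **Exit codes.**  0 success, 1 usage/configuration, 2 parse failure
  (also: refusing to overwrite), 3 coherence abort — so the tool can be
  scripted inside larger workflows.  Diagnostics go to standard error;
  fatal error messages and the run summary to standard output.

## Numerical and degenerate-input behaviour

* Locations support intervals, single bases, `complement(...)`,
  `join(...)` and `<`/`>` partiality markers; `order(...)` and remote
  references are rejected per record.  Coordinates outside
  `[1, length]` are per-record errors.
* An empty input file, a malformed entry, or an ID/LOCUS line whose
  declared length disagrees with the sequence block aborts parsing.
* Cell values are sanitized (tab/CR/LF → space) before writing; output
  is UTF-8 with `\n` terminators, one header line, the same number of
  tabs on every line, `SEQUENCE` last.
* Zero surviving rows still produce a header-only file, with a warning.

## What the synthetic data emulates — and what it does not

The bundled generator (`fixture_generator`) produces seeded dummy
records whose *feature layout* matches each marker's canonical
structure: a gene spanning an intron; two genes flanking a spacer; matK
inside the trnK intron; a single rRNA gene; the 18S–ITS1–5.8S–ITS2–28S
ladder; a flank rRNA plus an ETS misc_RNA.  Sequences are uniform
random DNA; EMBL and GenBank text is rendered by hand with standard
line types and 60-residue wrapping.  Each record's manifest — its exact
layout and the checklist row it should produce — is computed from the
generation parameters directly, never by running the extraction code,
so manifests serve as an independent oracle for the whole pipeline.

What passing these tests shows: the parsing, audit, rule application
and serialization are internally correct on structurally realistic
records in both dialects, including partial, incomplete and
deliberately damaged variants.  What it does not show: robustness to
the full variety of real annotation tools' flat-file quirks
(non-standard qualifier spellings, unusual location constructs, taxa
outside the synonym tables), or the validity of submissions against
ENA's own server-side validators, which remain the authority on
taxonomy and qualifier value syntax.

The default generated record is 700 bp (valid range 200–2000 bp), a
realistic length for these markers.  The test suite and the acceptance
script run on tens of small multi-record files (up to 4 records of
240–900 bp each; 60 randomized files in the acceptance run, 100 in the
test suite), which is ample to exercise every code path while keeping
the whole run within seconds.

## Known limitations

* Protein records, CON/WGS entries and flat-file *writing* (other than
  the dummy generator) are unsupported.
* No taxonomic validation of organism names and no syntax validation of
  qualifier values (lat_lon grammar etc.) — ENA's validator does that.
* The bundled optional-column subset is smaller than ENA's full
  per-checklist sets; extend the YAML schema file as needed.
* The ENA checklist accessions (ERT numbers) are not emitted; the
  schema file carries a slot for them, and real Webin templates may
  expect a preamble line users can prepend after generation.
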