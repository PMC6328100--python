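# flat2checklist

Convert annotated **EMBL** (`.embl`) or **GenBank** (`.gb`) flat files of
common plant and fungal DNA-barcoding markers into tab-delimited,
marker-specific **ENA Webin checklists** that are ready for upload through
ENA's interactive submission system.

## Who this is for

Plant and fungal biologists routinely sequence standardized barcoding
regions — plastid introns and intergenic spacers, the trnK/matK region,
and the nuclear ribosomal cistron (18S–ITS1–5.8S–ITS2–28S plus the ETS) —
and annotate them with suites such as Geneious, Artemis or DnaSP, which
export EMBL- or GenBank-formatted flat files.  ENA's interactive Webin
route, however, accepts tab-delimited "checklist" spreadsheets whose
column sets differ per marker.  This package automates that conversion:
one input flat file with any number of sequence records becomes one
checklist with one row per record, which can be edited in any spreadsheet
program and then uploaded.

## How it works

Six checklist types are supported, each with the mandatory column set of
the corresponding Webin checklist (universal columns `ORGANISM_NAME`,
`ENV_SAMPLE` and `SEQUENCE` included):

| checklist     | marker                                | mandatory columns |
|---------------|---------------------------------------|-------------------|
| `gene_intron` | any gene intron (e.g. trnL)           | 9                 |
| `IGS`         | any intergenic spacer (e.g. trnH–psbA)| 7                 |
| `trnK_matK`   | plastid trnK/matK region              | 8                 |
| `rRNA`        | 18S/28S/5.8S nuclear ribosomal rDNA   | 4                 |
| `ITS`         | nuclear ribosomal internal spacer     | 7                 |
| `ETS`         | nuclear ribosomal external spacer     | 5                 |

Every record passes through two stages.  The **input audit** checks that
the marker abbreviations found among the annotations are coherent with
the selected checklist type (a contradiction aborts the whole run — it
indicates the wrong checklist was selected) and that the minimally
necessary features are present (a failure skips just that record).
**Data processing** then fills the columns, mandatory first, optional
second, applying per-marker rules: intron coordinates and 5'/3'
partiality are read from the feature *location* (never from qualifier
text); `trnK_matK` requires an intron feature or a trnK-UUU tRNA feature;
the completeness of the 5.8S gene is inferred from the joint presence of
ITS1 and ITS2; for environmental samples the `ISOLATION_SOURCE` column
becomes mandatory; the rRNA `SEDIMENT` value must be one of the nine
permitted Svedberg tokens (5S, 5.8S, 12S, 16S, 18S, 23S, 25S, 26S, 28S).
Feature and qualifier spellings are checked against a bundled INSDC
dictionary along the way.

## Worked example

The bundled generator writes dummy flat files with the exact structure of
each marker; here a three-record trnK/matK file in EMBL format:

```python
from flat2checklist.fixture_generator import make_record, make_file
from flat2checklist.flatfile_io import FileFormat

records = [make_record("trnK_matK", seed=s, record_id=f"SEQ{s}",
                       organism="Amaranthus tricolor", length=500)
           for s in (1, 2, 3)]
make_file(records, FileFormat.EMBL, "example_trnKmatK.embl")
```

Converting it from the shell:

```console
$ flat2checklist -i example_trnKmatK.embl -o example_trnKmatK.tsv -c trnK_matK -e no
3 of 3 sequence records written to 'example_trnKmatK.tsv' (0 skipped)
```

The first columns of the resulting checklist (`SEQUENCE`, the last
column, holds the full uppercase sequence):

```
ORGANISM_NAME        ENV_SAMPLE  5'_CDS  3'_CDS  5'_PARTIAL  3'_PARTIAL  INTRON
Amaranthus tricolor  no          yes     yes     no          no          yes
Amaranthus tricolor  no          yes     yes     no          no          yes
Amaranthus tricolor  no          yes     yes     no          no          yes
```

Each row says: the matK coding region is complete at both ends (`5'_CDS`
/ `3'_CDS` yes, the partiality flags no) and the record carries the trnK
intron (`INTRON` yes) — exactly what ENA's trnK/matK checklist needs to
rebuild the annotation on its side.  Records that cannot fill their
mandatory columns are skipped with a logged reason; selecting a checklist
that contradicts the annotated marker aborts with exit code 3 and writes
no output.

The four run parameters are `-i` (input flat file), `-o` (output
checklist), `-c` (checklist type) and `-e` (environmental-sample
classification, `yes`/`no`).  Add `--force` to overwrite an existing
output file.  The same functionality is available as a library through
`flat2checklist.convert(RunConfig(...))`.

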