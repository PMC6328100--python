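# Definitions of the six ENA Webin checklist types handled by this tool.
#
# Each checklist lists its marker-specific columns in checklist order.
# Column fields: name, kind (text | integer | yes_no | enum), requirement
# (mandatory | conditional | optional), feature/qualifier (the flat-file
# annotation the value is copied from) and/or rule (a special parsing
# rule applied by the extractors).  The universal mandatory columns
# ORGANISM_NAME, ENV_SAMPLE and SEQUENCE plus the shared optional
# columns below are added to every checklist by the loader.
#
# `synonyms` are the marker abbreviations used by the input audit to
# test whether a record's annotations are coherent with the selected
# checklist type; matching is case-insensitive on substrings of
# gene/note/product/standard_name qualifier values.
#
# `ena_accession` is a slot for the authoritative ENA checklist
# accession (ERT number); fill it in if your submission requires it.
#
# The file is user-editable: optional columns and synonyms may be
# extended without code changes.
version: 1

# Optional columns shared by all checklist types; each is copied from
# the source feature's qualifier of the same name when present.  This is
# a documented subset of ENA's per-checklist optional column sets.
shared_optional_columns:
  - clone
  - collection_date
  - country
  - ecotype
  - haplotype
  - isolate
  - lat_lon
  - PCR_primers
  - specimen_voucher
  - strain

checklists:
  gene_intron:
    description: any gene intron
    ena_accession: null
    synonyms: [trnL, trnG, rpl16, rps16, petD, intron]
    columns:
      - {name: GENE, kind: text, requirement: mandatory, feature: gene, qualifier: note}
      - {name: "5'_PARTIAL", kind: yes_no, requirement: mandatory, feature: intron, rule: intron_location}
      - {name: "3'_PARTIAL", kind: yes_no, requirement: mandatory, feature: intron, rule: intron_location}
      - {name: "5'_INTRON", kind: integer, requirement: mandatory, feature: intron, rule: intron_location}
      - {name: "3'_INTRON", kind: integer, requirement: mandatory, feature: intron, rule: intron_location}
      - {name: NUMBER, kind: integer, requirement: mandatory, feature: intron, qualifier: number}

  IGS:
    description: any intergenic spacer
    ena_accession: null
    synonyms: [trnH, psbA, trnL, trnF, atpB, rbcL, spacer, IGS]
    columns:
      - {name: GENE1, kind: text, requirement: mandatory, feature: misc_feature, qualifier: product}
      - {name: G1PRESENT, kind: yes_no, requirement: mandatory, feature: gene, qualifier: note}
      - {name: GENE2, kind: text, requirement: mandatory, feature: misc_feature, qualifier: product}
      - {name: G2PRESENT, kind: yes_no, requirement: mandatory, feature: gene, qualifier: note}

  trnK_matK:
    description: plastid trnK/matK gene region
    ena_accession: null
    synonyms: [matK, trnK, trnK-UUU]
    columns:
      - {name: "5'_CDS", kind: yes_no, requirement: mandatory, feature: gene, qualifier: note}
      - {name: "3'_CDS", kind: yes_no, requirement: mandatory, feature: gene, qualifier: note}
      - {name: "5'_PARTIAL", kind: yes_no, requirement: mandatory, feature: gene, qualifier: note}
      - {name: "3'_PARTIAL", kind: yes_no, requirement: mandatory, feature: gene, qualifier: note}
      - {name: INTRON, kind: yes_no, requirement: mandatory, feature: "intron, tRNA", qualifier: gene, rule: trnk_intron}

  rRNA:
    description: 18S/28S/5.8S nuclear ribosomal rDNA gene
    ena_accession: null
    synonyms: [5S, 5.8S, 12S, 16S, 18S, 23S, 25S, 26S, 28S, rRNA, rDNA]
    columns:
      - name: SEDIMENT
        kind: enum
        requirement: mandatory
        feature: rRNA
        qualifier: product
        rule: sediment_token
        permitted: [5S, 5.8S, 12S, 16S, 18S, 23S, 25S, 26S, 28S]

  ITS:
    description: nuclear ribosomal internal transcribed spacer
    ena_accession: null
    synonyms: [ITS, ITS1, ITS2, 5.8S, 18S, 28S]
    columns:
      - {name: ISOLATION_SOURCE, kind: text, requirement: conditional, feature: source, qualifier: isolation_source, rule: env_promotion}
      - {name: 18S, kind: yes_no, requirement: mandatory, feature: rRNA, qualifier: gene}
      - {name: ITS1, kind: yes_no, requirement: mandatory, feature: misc_RNA, qualifier: note}
      - {name: ITS2, kind: yes_no, requirement: mandatory, feature: misc_RNA, qualifier: note}
      - {name: 28S, kind: yes_no, requirement: mandatory, feature: rRNA, qualifier: gene}
      - {name: 5.8S, kind: yes_no, requirement: optional, rule: its_58s_completeness}

  ETS:
    description: nuclear ribosomal external transcribed spacer
    ena_accession: null
    synonyms: [ETS, "5' ETS", "3' ETS", 18S, 28S]
    columns:
      - {name: 18S, kind: yes_no, requirement: conditional, feature: rRNA, qualifier: gene, rule: ets_flank}
      - name: ETS_TYPE
        kind: enum
        requirement: mandatory
        feature: misc_RNA
        qualifier: note
        rule: ets_type
        permitted: ["5'", "3'"]
      - {name: 28S, kind: yes_no, requirement: conditional, feature: rRNA, qualifier: gene, rule: ets_flank}
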