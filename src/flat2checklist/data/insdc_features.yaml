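# Subset of the INSDC Feature Table Definition (document version 11.3,
# https://www.insdc.org/submitting-standards/feature-table/) covering the
# feature keys that occur in plant/fungal barcoding records plus their
# permitted qualifiers.  Keys and qualifier names are case-significant.
# The file is user-extensible: add keys or qualifiers as plain YAML.
version: "INSDC Feature Table Definition 11.3"
features:
  source:
    - altitude
    - clone
    - collected_by
    - collection_date
    - country
    - culture_collection
    - db_xref
    - dev_stage
    - ecotype
    - environmental_sample
    - geo_loc_name
    - haplotype
    - host
    - identified_by
    - isolate
    - isolation_source
    - lat_lon
    - mol_type
    - note
    - organelle
    - organism
    - PCR_primers
    - specimen_voucher
    - strain
    - sub_species
    - tissue_type
    - type_material
    - variety
  gene:
    - allele
    - db_xref
    - experiment
    - function
    - gene
    - gene_synonym
    - inference
    - locus_tag
    - map
    - note
    - old_locus_tag
    - operon
    - phenotype
    - pseudo
    - pseudogene
    - standard_name
  intron:
    - allele
    - db_xref
    - experiment
    - function
    - gene
    - gene_synonym
    - inference
    - locus_tag
    - map
    - note
    - number
    - old_locus_tag
    - operon
    - pseudo
    - pseudogene
    - standard_name
  exon:
    - allele
    - db_xref
    - experiment
    - function
    - gene
    - gene_synonym
    - inference
    - locus_tag
    - map
    - note
    - number
    - old_locus_tag
    - pseudo
    - pseudogene
    - standard_name
  CDS:
    - allele
    - codon_start
    - db_xref
    - experiment
    - function
    - gene
    - gene_synonym
    - inference
    - locus_tag
    - map
    - note
    - number
    - old_locus_tag
    - operon
    - product
    - protein_id
    - pseudo
    - pseudogene
    - standard_name
    - translation
    - transl_except
    - transl_table
  tRNA:
    - allele
    - anticodon
    - db_xref
    - experiment
    - function
    - gene
    - gene_synonym
    - inference
    - locus_tag
    - map
    - note
    - old_locus_tag
    - operon
    - product
    - pseudo
    - pseudogene
    - standard_name
  rRNA:
    - allele
    - db_xref
    - experiment
    - function
    - gene
    - gene_synonym
    - inference
    - locus_tag
    - map
    - note
    - old_locus_tag
    - operon
    - product
    - pseudo
    - pseudogene
    - standard_name
  misc_RNA:
    - allele
    - db_xref
    - experiment
    - function
    - gene
    - gene_synonym
    - inference
    - locus_tag
    - map
    - note
    - old_locus_tag
    - operon
    - product
    - pseudo
    - pseudogene
    - standard_name
  misc_feature:
    - allele
    - db_xref
    - experiment
    - function
    - gene
    - gene_synonym
    - inference
    - locus_tag
    - map
    - note
    - number
    - old_locus_tag
    - phenotype
    - product
    - pseudo
    - pseudogene
    - standard_name
  mRNA:
    - allele
    - db_xref
    - experiment
    - function
    - gene
    - gene_synonym
    - inference
    - locus_tag
    - map
    - note
    - old_locus_tag
    - operon
    - product
    - pseudo
    - pseudogene
    - standard_name
  repeat_region:
    - allele
    - db_xref
    - experiment
    - function
    - gene
    - gene_synonym
    - inference
    - locus_tag
    - map
    - note
    - old_locus_tag
    - rpt_family
    - rpt_type
    - rpt_unit_range
    - rpt_unit_seq
    - standard_name
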