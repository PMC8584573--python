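# Packaged cohort fixture

`pcd_variants.tsv` is the published 112-variant primary-ciliary-dyskinesia
cohort table (28 genes, 66 patients), transcribed field-for-field from the
source publication's variant table. Missing cells are encoded as `-`.

Columns: gene symbol, RefSeq transcript, HGVS cDNA and protein change,
consequence label, dbSNP id, novelty marker, gnomAD exome allele frequency,
homozygote-reported marker, JSD conservation score, full-conservation marker,
the five predictor scores (ranked MetaLR, ranked MetaSVM, PHRED-scaled CADD,
ranked REVEL, Condel), the published k-means cluster colors for the
REVEL-vs-Condel scatter view (`Scatter`) and the five-score MDS view (`MDS`),
and the ACMG classification. Red = possibly pathogenic, blue = uncertain,
green = possibly benign. Exactly the 83 missense rows carry complete
five-score panels and cluster labels.

## Known inconsistencies in the source (transcribed as printed, not corrected)

- The running text reports 19 DNAH5 variants; the table contains 18 DNAH5
  rows (and 21 DNAH11 rows, matching the text).
- The running text's scatter-cluster group statistics transpose the names
  REVEL and Condel relative to the table columns: all six printed statistics
  match the table exactly once the two names are swapped (e.g., printed
  "REVEL median 0.855" for the red scatter cluster is the red cluster's
  Condel median; its REVEL median is 0.706). The table's Condel column is
  verifiably genuine Condel — its deleterious/neutral suffixes split exactly
  at Condel's published 0.469 decision threshold, and the MDS-cluster
  paragraph's Condel statistics match the same column.
- The possibly-benign (green) MDS cluster's CADD summary computes to
  mean 13.9 / median 14.2 on this transcription vs printed 13.7 / 13.3;
  all other printed group statistics reproduce exactly.
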