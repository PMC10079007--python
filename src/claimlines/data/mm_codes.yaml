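# Multiple-myeloma case definition: an ICD-10 code that must appear on a
# confirmed diagnosis record together with one of the Japanese local
# disease codes used by DPC-style hospital claims.
icd10: ["C90.0"]
japanese_disease_codes:
  - "2030003"
  - "8839397"
  - "8840039"
  - "8842090"
  - "8847152"
  - "8847175"
  - "8847250"
  - "8847258"
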