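# ICD-10 prefixes identifying baseline renal impairment.
# A trailing "x" in the source list (N18.x, N19.x) means every subcode;
# prefix matching handles that.
prefixes:
  - "I12.0"
  - "I13.1"
  - "N03.2"
  - "N03.3"
  - "N03.4"
  - "N03.5"
  - "N03.6"
  - "N03.7"
  - "N05.2"
  - "N05.3"
  - "N05.4"
  - "N05.5"
  - "N05.6"
  - "N05.7"
  - "N18"
  - "N19"
  - "N25.0"
  - "Z49.0"
  - "Z49.1"
  - "Z49.2"
  - "Z94.0"
  - "Z99.2"
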