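# Canonical regimen names for drug sets, as used in treatment-pattern
# reporting for multiple myeloma.  Unlisted sets fall back to a sorted
# join of drug abbreviations.
regimens:
  Vd:     [bortezomib, dexamethasone]
  VRd:    [bortezomib, lenalidomide, dexamethasone]
  Rd:     [lenalidomide, dexamethasone]
  MP:     [melphalan, prednisolone]
  VMP:    [bortezomib, melphalan, prednisolone]
  VCd:    [bortezomib, cyclophosphamide, dexamethasone]
  DRd:    [daratumumab, lenalidomide, dexamethasone]
  IRd:    [ixazomib, lenalidomide, dexamethasone]
  KRd:    [carfilzomib, lenalidomide, dexamethasone]
  VAD:    [vincristine, doxorubicin, dexamethasone]
  Cy+Dex: [cyclophosphamide, dexamethasone]
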