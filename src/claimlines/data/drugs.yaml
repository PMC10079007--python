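# Anti-myeloma drug dictionary.
# route: parenteral drugs default to a 28-day grace period; oral drugs to
#   42 days (28-day supply + 14), reflecting supply-aware persistence.
# abbrev: single-letter/short token used for canonical regimen naming and
#   for the deterministic fallback name of unmapped drug sets.
# steroid: steroids join regimens but never anchor a line or trigger a switch.
drugs:
  bortezomib:     {route: parenteral, abbrev: V,   steroid: false}
  carfilzomib:    {route: parenteral, abbrev: K,   steroid: false}
  daratumumab:    {route: parenteral, abbrev: D,   steroid: false}
  elotuzumab:     {route: parenteral, abbrev: E,   steroid: false}
  isatuximab:     {route: parenteral, abbrev: Isa, steroid: false}
  vincristine:    {route: parenteral, abbrev: Vcr, steroid: false}
  doxorubicin:    {route: parenteral, abbrev: A,   steroid: false}
  lenalidomide:   {route: oral,       abbrev: R,   steroid: false}
  pomalidomide:   {route: oral,       abbrev: P,   steroid: false}
  thalidomide:    {route: oral,       abbrev: T,   steroid: false}
  ixazomib:       {route: oral,       abbrev: I,   steroid: false}
  melphalan:      {route: oral,       abbrev: M,   steroid: false}
  cyclophosphamide: {route: oral,     abbrev: Cy,  steroid: false}
  panobinostat:   {route: oral,       abbrev: Pan, steroid: false}
  dexamethasone:  {route: oral,       abbrev: d,   steroid: true}
  prednisolone:   {route: oral,       abbrev: Pred, steroid: true}

grace_days:
  parenteral: 28
  oral: 42
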