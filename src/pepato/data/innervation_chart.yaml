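# Default myotomal innervation chart for the 8 standard lower-limb muscles.
# Conventional myotome assignments; each segment's six slices are uniformly
# innervated. This file is data, not code: replace it with a chart of your
# own (same schema) to change the muscle-to-segment mapping.
provenance: "conventional lower-limb myotome assignments; uniform within-segment innervation"
subsegments:
  - segment: L2
    slice: 1
    muscles: [ReFe, VaLa, VaMe]
  - segment: L2
    slice: 2
    muscles: [ReFe, VaLa, VaMe]
  - segment: L2
    slice: 3
    muscles: [ReFe, VaLa, VaMe]
  - segment: L2
    slice: 4
    muscles: [ReFe, VaLa, VaMe]
  - segment: L2
    slice: 5
    muscles: [ReFe, VaLa, VaMe]
  - segment: L2
    slice: 6
    muscles: [ReFe, VaLa, VaMe]
  - segment: L3
    slice: 1
    muscles: [ReFe, VaLa, VaMe]
  - segment: L3
    slice: 2
    muscles: [ReFe, VaLa, VaMe]
  - segment: L3
    slice: 3
    muscles: [ReFe, VaLa, VaMe]
  - segment: L3
    slice: 4
    muscles: [ReFe, VaLa, VaMe]
  - segment: L3
    slice: 5
    muscles: [ReFe, VaLa, VaMe]
  - segment: L3
    slice: 6
    muscles: [ReFe, VaLa, VaMe]
  - segment: L4
    slice: 1
    muscles: [ReFe, TiAn, VaLa, VaMe]
  - segment: L4
    slice: 2
    muscles: [ReFe, TiAn, VaLa, VaMe]
  - segment: L4
    slice: 3
    muscles: [ReFe, TiAn, VaLa, VaMe]
  - segment: L4
    slice: 4
    muscles: [ReFe, TiAn, VaLa, VaMe]
  - segment: L4
    slice: 5
    muscles: [ReFe, TiAn, VaLa, VaMe]
  - segment: L4
    slice: 6
    muscles: [ReFe, TiAn, VaLa, VaMe]
  - segment: L5
    slice: 1
    muscles: [BiFe, GaLa, SeTe, Sol, TiAn]
  - segment: L5
    slice: 2
    muscles: [BiFe, GaLa, SeTe, Sol, TiAn]
  - segment: L5
    slice: 3
    muscles: [BiFe, GaLa, SeTe, Sol, TiAn]
  - segment: L5
    slice: 4
    muscles: [BiFe, GaLa, SeTe, Sol, TiAn]
  - segment: L5
    slice: 5
    muscles: [BiFe, GaLa, SeTe, Sol, TiAn]
  - segment: L5
    slice: 6
    muscles: [BiFe, GaLa, SeTe, Sol, TiAn]
  - segment: S1
    slice: 1
    muscles: [BiFe, GaLa, SeTe, Sol]
  - segment: S1
    slice: 2
    muscles: [BiFe, GaLa, SeTe, Sol]
  - segment: S1
    slice: 3
    muscles: [BiFe, GaLa, SeTe, Sol]
  - segment: S1
    slice: 4
    muscles: [BiFe, GaLa, SeTe, Sol]
  - segment: S1
    slice: 5
    muscles: [BiFe, GaLa, SeTe, Sol]
  - segment: S1
    slice: 6
    muscles: [BiFe, GaLa, SeTe, Sol]
  - segment: S2
    slice: 1
    muscles: [BiFe, GaLa, SeTe, Sol]
  - segment: S2
    slice: 2
    muscles: [BiFe, GaLa, SeTe, Sol]
  - segment: S2
    slice: 3
    muscles: [BiFe, GaLa, SeTe, Sol]
  - segment: S2
    slice: 4
    muscles: [BiFe, GaLa, SeTe, Sol]
  - segment: S2
    slice: 5
    muscles: [BiFe, GaLa, SeTe, Sol]
  - segment: S2
    slice: 6
    muscles: [BiFe, GaLa, SeTe, Sol]
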