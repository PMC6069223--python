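{
  "_comment": "Default 17-parameter visualization panel. This membership is a shipped default of this package, not a published set; edit freely. Groups: Ang = angular, Len = length/velocity magnitudes, Vol = volumetric/area.",
  "Ang": [2, 6, 9, 12, 13, 40],
  "Len": [1, 14, 15, 3, 5, 32],
  "Vol": [10, 11, 31, 38, 39]
}
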