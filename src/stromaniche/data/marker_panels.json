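{
  "MSC": ["Lepr", "Adipoq", "Cxcl12"],
  "OLC": ["Bglap", "Spp1", "Sp7"],
  "Fibroblast": ["S100a4", "Fn1", "Dcn"],
  "Chondrocyte": ["Col2a1", "Sox9", "Acan"],
  "Pericyte": ["Acta2", "Myh11", "Mcam"],
  "AEC": ["Cdh5", "Cd34", "Pecam1", "Ly6a"],
  "SEC": ["Cdh5", "Cd34", "Pecam1", "Flt4", "Il6st"]
}
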