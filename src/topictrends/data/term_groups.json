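{
  "Agriculture": ["agricult*", "crop*", "farm*", "yield*"],
  "Forestry": ["tree*", "timber", "wood", "deforestation", "forest"],
  "Fishery": ["fish", "aquatic", "water*", "freshwater", "sea", "wetland*"],
  "Policy": ["policy", "implementation", "stakeholders", "sustainable", "approach", "challenges"],
  "Economics": ["income", "cost*", "benefit*", "pay*", "pes", "financial", "evaluate", "incentives", "market"],
  "Nature conservation": ["natur*", "conservation", "protect*", "threatened"],
  "Taxonomic categories": ["bee*", "flower", "insect*", "bird", "reef", "coral", "invertebrates", "bacterial", "microbial"],
  "CICES ES categories": ["climate", "invasive", "cultural", "production", "soil", "pest control", "pollinat*", "organic carbon", "sequestration", "enemies", "nutrient flow", "biomass", "erosion", "timber", "emission*", "reduction", "invasive"]
}
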