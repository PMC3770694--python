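{
  "description": "Out-of-Africa-style calibrated neutral demography for the demography-aware Tajima's D null. Sizes are in chromosomes, times in generations before present. AFR: African; EUR: European; ASIA: East Asian (also the proxy history for America and Oceania). Constants are editable: substitute published values here to change the null without touching code.",
  "populations": [
    {"name": "AFR", "initial_size": 24000},
    {"name": "EUR", "initial_size": 100000, "growth_rate": 0.0055},
    {"name": "ASIA", "initial_size": 100000, "growth_rate": 0.0055}
  ],
  "migration": [
    ["AFR", "EUR", 0.000032],
    ["AFR", "ASIA", 0.000008],
    ["EUR", "ASIA", 0.000019]
  ],
  "events": [
    {"type": "size_change", "time": 350, "population": "EUR", "size": 7700},
    {"type": "size_change", "time": 400, "population": "ASIA", "size": 7700},
    {"type": "size_change", "time": 1200, "population": "EUR", "size": 1500},
    {"type": "size_change", "time": 1250, "population": "EUR", "size": 7700},
    {"type": "size_change", "time": 1500, "population": "ASIA", "size": 1200},
    {"type": "size_change", "time": 1550, "population": "ASIA", "size": 7700},
    {"type": "split", "time": 2000, "derived": ["EUR", "ASIA"], "ancestral": "OOA", "ancestral_size": 7700},
    {"type": "size_change", "time": 3450, "population": "OOA", "size": 500},
    {"type": "size_change", "time": 3500, "population": "OOA", "size": 7700},
    {"type": "split", "time": 3550, "derived": ["AFR", "OOA"], "ancestral": "ANC", "ancestral_size": 24000},
    {"type": "size_change", "time": 17000, "population": "ANC", "size": 12500}
  ],
  "mutation_rate": 1.5e-8,
  "recombination_rate": 1.0e-8,
  "generation_time": 29.0
}
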