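[
 {"name": "ATP production from glucose", "category": "1. Carbohydrates",
  "objective": {"ATPASE": 1.0},
  "allowed_uptakes": ["glucose", "o2"], "allowed_secretions": ["byp"]},
 {"name": "ATP production from lactate", "category": "2. Carboxylic acids",
  "objective": {"ATPASE": 1.0},
  "allowed_uptakes": ["lactate", "o2"], "allowed_secretions": ["byp"]},
 {"name": "ATP production from acetoacetate (ketone-body degradation)",
  "category": "2. Carboxylic acids", "objective": {"ATPASE": 1.0},
  "allowed_uptakes": ["acetoacetate", "o2"], "allowed_secretions": ["byp"]},
 {"name": "ATP production from acetate", "category": "2. Carboxylic acids",
  "objective": {"ATPASE": 1.0},
  "allowed_uptakes": ["acetate", "o2"], "allowed_secretions": ["byp"]},
 {"name": "ATP production from palmitate", "category": "3. Lipids",
  "objective": {"ATPASE": 1.0},
  "allowed_uptakes": ["palmitate", "o2"], "allowed_secretions": ["byp"]},
 {"name": "ATP production from stearate", "category": "3. Lipids",
  "objective": {"ATPASE": 1.0},
  "allowed_uptakes": ["stearate", "o2"], "allowed_secretions": ["byp"]},
 {"name": "ATP production from oleate", "category": "3. Lipids",
  "objective": {"ATPASE": 1.0},
  "allowed_uptakes": ["oleate", "o2"], "allowed_secretions": ["byp"]},
 {"name": "ATP production from alpha-linoleate", "category": "3. Lipids",
  "objective": {"ATPASE": 1.0},
  "allowed_uptakes": ["alpha_linoleate", "o2"], "allowed_secretions": ["byp"]},
 {"name": "ATP production from eicosapentaenoate", "category": "3. Lipids",
  "objective": {"ATPASE": 1.0},
  "allowed_uptakes": ["epa", "o2"], "allowed_secretions": ["byp"]},
 {"name": "ATP production from docosahexaenoate", "category": "3. Lipids",
  "objective": {"ATPASE": 1.0},
  "allowed_uptakes": ["dha", "o2"], "allowed_secretions": ["byp"]},
 {"name": "Glycogen formation from glucose", "category": "1. Carbohydrates",
  "objective": {"GS": 0.1},
  "allowed_uptakes": ["glucose", "o2"],
  "allowed_secretions": ["byp", "glycogen"]},
 {"name": "ATP production from glycogen store", "category": "1. Carbohydrates",
  "objective": {"ATPASE": 0.5},
  "allowed_uptakes": ["glycogen", "o2"], "allowed_secretions": ["byp"]},
 {"name": "NADPH production from glucose", "category": "5. Nucleic acids",
  "objective": {"NADPH_DEMAND": 0.01},
  "allowed_uptakes": ["glucose", "o2"], "allowed_secretions": ["byp"]},
 {"name": "Ceramide synthesis", "category": "3. Lipids",
  "objective": {"DEMAND_cer": 0.001},
  "allowed_uptakes": ["palmitate", "stearate", "oleate", "alpha_linoleate", "epa", "dha", "glucose", "o2"],
  "allowed_secretions": ["byp"]},
 {"name": "Cardiolipin synthesis", "category": "3. Lipids",
  "objective": {"DEMAND_cl": 0.001},
  "allowed_uptakes": ["palmitate", "stearate", "oleate", "alpha_linoleate", "epa", "dha", "glucose", "o2"],
  "allowed_secretions": ["byp"]},
 {"name": "Phosphatidylcholine synthesis", "category": "3. Lipids",
  "objective": {"DEMAND_pc": 0.001},
  "allowed_uptakes": ["palmitate", "stearate", "oleate", "alpha_linoleate", "epa", "dha", "glucose", "o2"],
  "allowed_secretions": ["byp"]},
 {"name": "Phosphatidylethanolamine synthesis", "category": "3. Lipids",
  "objective": {"DEMAND_pe": 0.001},
  "allowed_uptakes": ["palmitate", "stearate", "oleate", "alpha_linoleate", "epa", "dha", "glucose", "o2"],
  "allowed_secretions": ["byp"]},
 {"name": "Sphingomyelin synthesis", "category": "3. Lipids",
  "objective": {"DEMAND_sm": 0.001},
  "allowed_uptakes": ["palmitate", "stearate", "oleate", "alpha_linoleate", "epa", "dha", "glucose", "o2"],
  "allowed_secretions": ["byp"]}
]
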