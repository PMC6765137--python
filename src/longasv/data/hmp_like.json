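{
  "name": "hmp_like",
  "description": "Synthetic analog of a 20-strain staggered mock community (HMP HM-783D-style): rrnDB-style 16S copy numbers, genome proportions spanning three orders of magnitude. Allele sequences are generated, not biological.",
  "seed": 20190704,
  "divergence": 4,
  "length": 1450,
  "chimera_fraction": 0.02,
  "rc_fraction": 0.5,
  "rates": {"substitution": 1.1e-4, "insertion": 2.2e-4, "deletion": 1.0e-4},
  "quality": {"p_max": 0.9, "low_min": 30, "low_max": 92},
  "strains": [
    {"name": "Bacillus_cereus", "copies": [6, 3, 2, 1], "proportion": 1.0},
    {"name": "Clostridium_beijerinckii", "copies": [7, 4, 2, 1], "proportion": 0.6952},
    {"name": "Escherichia_coli", "copies": [2, 1, 1, 1, 1, 1], "proportion": 0.4833},
    {"name": "Streptococcus_agalactiae", "copies": [4, 3], "proportion": 0.336},
    {"name": "Acinetobacter_baumanii", "copies": [3, 2, 1], "proportion": 0.2336},
    {"name": "Staphylococcus_aureus", "copies": [5, 1], "proportion": 0.1624},
    {"name": "Listeria_monocytogenes", "copies": [5, 1], "proportion": 0.1129},
    {"name": "Rhodobacter_sphaeroides", "copies": [3, 1], "proportion": 0.0785},
    {"name": "Enterococcus_faecalis", "copies": [3, 1], "proportion": 0.0546},
    {"name": "Lactobacillus_gasseri", "copies": [6], "proportion": 0.0379},
    {"name": "Staphylococcus_epidermidis", "copies": [6], "proportion": 0.0264},
    {"name": "Streptococcus_mutans", "copies": [6], "proportion": 0.0183},
    {"name": "Bacteroides_vulgatus", "copies": [7], "proportion": 0.0127},
    {"name": "Pseudomonas_aeruginosa", "copies": [4], "proportion": 0.0089},
    {"name": "Neisseria_meningitidis", "copies": [4], "proportion": 0.0062},
    {"name": "Streptococcus_pneumoniae", "copies": [4], "proportion": 0.0043},
    {"name": "Propionibacterium_acnes", "copies": [3], "proportion": 0.0030},
    {"name": "Deinococcus_radiodurans", "copies": [3], "proportion": 0.0021},
    {"name": "Actinomyces_odontolyticus", "copies": [2], "proportion": 0.0014},
    {"name": "Helicobacter_pylori", "copies": [2], "proportion": 0.001}
  ]
}
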