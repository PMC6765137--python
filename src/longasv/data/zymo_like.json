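{
  "name": "zymo_like",
  "description": "Synthetic analog of an 8-strain equimolar-genome mock community (ZymoBIOMICS-style): vendor 16S copy numbers, 29 distinct alleles at integral within-genome ratios. Allele sequences are generated, not biological.",
  "seed": 20190703,
  "divergence": 4,
  "length": 1450,
  "chimera_fraction": 0.02,
  "rc_fraction": 0.5,
  "rates": {"substitution": 1.1e-4, "insertion": 2.2e-4, "deletion": 1.0e-4},
  "quality": {"p_max": 0.9, "low_min": 30, "low_max": 92},
  "strains": [
    {"name": "Pseudomonas_aeruginosa", "copies": [4], "proportion": 0.125},
    {"name": "Escherichia_coli", "copies": [3, 1, 1, 1, 1], "proportion": 0.125},
    {"name": "Salmonella_enterica", "copies": [2, 1, 1, 1, 1, 1], "proportion": 0.125},
    {"name": "Lactobacillus_fermentum", "copies": [3, 1, 1], "proportion": 0.125},
    {"name": "Enterococcus_faecalis", "copies": [3, 1], "proportion": 0.125},
    {"name": "Staphylococcus_aureus", "copies": [2, 1, 1, 1, 1], "proportion": 0.125},
    {"name": "Listeria_monocytogenes", "copies": [2, 1, 1, 1, 1], "proportion": 0.125},
    {"name": "Bacillus_subtilis", "copies": [9, 1], "proportion": 0.125}
  ]
}
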