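# The "paper-mirror" scenario: a fully synthetic analogue of the study design.
# Five bulk microglia datasets (three whole-tissue, one grey-matter, one
# white-matter), each with every catalog GPCR gene planted at a controlled
# percentile: 15 core genes high everywhere, 2 regionally biased genes medium
# in GM / high in WM / low elsewhere, and all remaining GPCR genes kept below
# the medium band with a >= 0.05 percentile safety margin. Plus a single-cell
# dataset with a 10% disease-associated cluster in which the six homeostatic
# marker genes shift down and CXCR4 shifts up.
scenario: paper_mirror
species: human

core_genes:
  - CX3CR1
  - GPR34
  - GPR183
  - P2RY12
  - P2RY13
  - ADGRG1
  - ADORA3
  - ADRB2
  - CCR1
  - C3AR1
  - C5AR1
  - LPAR5
  - LPAR6
  - PTAFR
  - P2RY6

rescue_genes:
  - CXCR4
  - PTGER4

bulk:
  n_whole_datasets: 3
  n_genes: 800
  n_samples: 6
  noise_sd: 0.002
  core_percentile_range: [0.91, 0.995]
  rescue_gm_percentile_range: [0.73, 0.81]
  rescue_wm_percentile_range: [0.91, 0.995]
  rescue_other_percentile_range: [0.52, 0.62]
  background_gpcr_percentile_range: [0.10, 0.62]

single_cell:
  n_cells: 1600
  cluster_proportions:
    homeostatic: 0.75
    disease: 0.10
    monocyte: 0.10
    lymphocyte: 0.05
  panel_baseline_mean: 5.0
  rescue_baseline_mean: 1.0
  other_gpcr_mean: 0.5
  n_background_genes: 100
  dispersion: 2.0
  depth_sdlog: 0.3
  marker_shifts:
    - [CX3CR1, disease, 0.3]
    - [GPR34, disease, 0.3]
    - [GPR183, disease, 0.3]
    - [P2RY12, disease, 0.3]
    - [P2RY13, disease, 0.3]
    - [ADGRG1, disease, 0.3]
    - [CXCR4, disease, 3.0]
    - [CXCR4, monocyte, 3.0]

region:
  n_donors: 8
  donor_sd: 0.10
  effects:
    - [CXCR4, 2.5]
    - [PTGER4, 2.5]
    - [ADGRE5, 1.5]

contrast:
  fc_threshold: 2.0
  alpha: 0.05
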