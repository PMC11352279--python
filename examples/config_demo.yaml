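# Scaled-down two-condition demo configuration.
# Same population laws as the built-in defaults, fewer cells per cohort so a
# full `granulemetrics report` finishes in under a minute.
voxel_size_nm: 9.202
coloc_threshold_nm: 25.0
phb_density: 1.170
conditions:
  untreated:
    treated: false
    n_cells: 4
    cell_length_nm: [1600.0, 2800.0]
    cell_radius_nm: 400.0
    phb:
      count_law: [poisson, 7]
      diameter_mean_nm: 179.0
      diameter_sd_nm: 55.6
      placement: polar_cluster
      cluster_max_spacing_nm: 400.0
    pp:
      count_law: [fixed, 1]
      diameter_mean_nm: 106.0
      diameter_sd_nm: 34.0
      placement: near_other_class
      coloc_prob: 0.58
      coloc_gap_nm: 10.0
  cm_treated:
    treated: true
    n_cells: 4
    cell_length_nm: [1600.0, 2800.0]
    cell_radius_nm: 400.0
    phb:
      count_law: [uniform, 1, 3]
      diameter_mean_nm: 383.0
      diameter_sd_nm: 86.5
      placement: dispersed_polar
    pp:
      count_law: [fixed, 1]
      diameter_mean_nm: 202.0
      diameter_sd_nm: 34.0
      placement: near_other_class
      coloc_prob: 0.55
      coloc_gap_nm: 10.0
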