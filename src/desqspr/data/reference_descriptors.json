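{
  "comment": [
    "EEig02d reference values for the nine hydrogen-bond donors, as printed in",
    "the two source tables, which disagree on five rows. The row labels of the",
    "candidate-descriptor table (table4) are permuted relative to the summary",
    "table (table5): a phenol->guaiacol->furfuryl 3-cycle and a levulinic<->",
    "triethylene-glycol swap explain both its EEig02d and ESpm02d columns.",
    "The running text supports table5 for guaiacol (1.983) and phenol (1.521).",
    "'authoritative' is the value used for lookups; 'calibration' marks the",
    "text-consistent rows used to calibrate the matrix convention.",
    "molar_volume_cm3_mol comes from the same summary table.",
    "espm02d_printed is the candidate table's ESpm02d column under its printed",
    "(permuted) labels, kept verbatim for provenance."
  ],
  "eeig02d": {
    "1,2-Propanediol":    {"table4": 1.054, "table5": 1.054, "authoritative": 1.054, "conflict": false, "calibration": true},
    "1,4-Butanediol":     {"table4": 1.519, "table5": 1.519, "authoritative": 1.519, "conflict": false, "calibration": true},
    "2,3-Butanediol":     {"table4": 1.519, "table5": 1.519, "authoritative": 1.519, "conflict": false, "calibration": true},
    "Diethylene glycol":  {"table4": 1.713, "table5": 1.713, "authoritative": 1.713, "conflict": false, "calibration": true},
    "Furfuryl alcohol":   {"table4": 1.983, "table5": 1.547, "authoritative": 1.547, "conflict": true,  "calibration": false},
    "Guaiacol":           {"table4": 1.521, "table5": 1.983, "authoritative": 1.983, "conflict": true,  "calibration": true},
    "Levulinic acid":     {"table4": 2.242, "table5": 3.515, "authoritative": 3.515, "conflict": true,  "calibration": false},
    "Phenol":             {"table4": 1.547, "table5": 1.521, "authoritative": 1.521, "conflict": true,  "calibration": true},
    "Triethylene glycol": {"table4": 3.515, "table5": 2.242, "authoritative": 2.242, "conflict": true,  "calibration": false}
  },
  "molar_volume_cm3_mol": {
    "1,2-Propanediol": 72.93, "1,4-Butanediol": 88.81, "2,3-Butanediol": 89.69,
    "Diethylene glycol": 95.05, "Furfuryl alcohol": 86.37, "Guaiacol": 109.53,
    "Levulinic acid": 102.45, "Phenol": 87.96, "Triethylene glycol": 133.63
  },
  "candidate_descriptors": {
    "columns": ["H6m", "RDF065u", "RTm", "ESpm02d", "EEig02d"],
    "note": "3D columns (H6m, RDF065u, RTm) are reference numbers only, never computed here; row labels as printed (permuted, see comment).",
    "rows": {
      "1,2-Propanediol":    [0.0,   0.0,   1.953, 2.349, 1.054],
      "1,4-Butanediol":     [0.0,   0.0,   2.032, 2.349, 1.519],
      "2,3-Butanediol":     [0.0,   0.0,   2.289, 2.673, 1.519],
      "Diethylene glycol":  [0.003, 0.052, 1.879, 2.636, 1.713],
      "Furfuryl alcohol":   [0.0,   0.978, 2.86,  3.228, 1.983],
      "Guaiacol":           [0.0,   0.0,   2.187, 2.876, 1.521],
      "Levulinic acid":     [0.004, 1.207, 2.335, 3.065, 2.242],
      "Phenol":             [0.0,   0.157, 2.377, 2.902, 1.547],
      "Triethylene glycol": [0.01,  1.861, 3.469, 3.423, 3.515]
    }
  }
}
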