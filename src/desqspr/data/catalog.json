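[
  {"id": 1, "ratio": "1:3", "temperatures_K": [293, 303, 313, 323], "fixed_T_K": null,
   "hbds": ["1,2-Propanediol", "1,4-Butanediol", "2,3-Butanediol", "Diethylene glycol",
            "Guaiacol", "Phenol", "Triethylene glycol", "Furfuryl alcohol", "Levulinic acid"],
   "P_range_bar": [0.515, 5.853], "x_range": [0.0014, 0.0311], "n": 181,
   "fixed_T_subsets": [3, 5, 7, 9], "role": "training"},
  {"id": 2, "ratio": "1:4", "temperatures_K": [293, 303, 313, 323], "fixed_T_K": null,
   "hbds": ["1,2-Propanediol", "1,4-Butanediol", "2,3-Butanediol", "Diethylene glycol",
            "Guaiacol", "Phenol", "Triethylene glycol", "Furfuryl alcohol", "Levulinic acid"],
   "P_range_bar": [0.521, 5.842], "x_range": [0.0014, 0.0326], "n": 181,
   "fixed_T_subsets": [4, 6, 8, 10], "role": "training"},
  {"id": 3, "ratio": "1:3", "temperatures_K": [293], "fixed_T_K": 293,
   "hbds": ["1,2-Propanediol", "1,4-Butanediol", "2,3-Butanediol", "Diethylene glycol",
            "Guaiacol", "Phenol", "Triethylene glycol"],
   "P_range_bar": [0.515, 5.294], "x_range": [0.0021, 0.0282], "n": 36,
   "fixed_T_subsets": [], "role": "training"},
  {"id": 4, "ratio": "1:4", "temperatures_K": [293], "fixed_T_K": 293,
   "hbds": ["1,2-Propanediol", "1,4-Butanediol", "2,3-Butanediol", "Diethylene glycol",
            "Guaiacol", "Phenol", "Triethylene glycol"],
   "P_range_bar": [0.521, 5.26], "x_range": [0.0022, 0.0288], "n": 36,
   "fixed_T_subsets": [], "role": "training"},
  {"id": 5, "ratio": "1:3", "temperatures_K": [303], "fixed_T_K": 303,
   "hbds": ["1,2-Propanediol", "1,4-Butanediol", "2,3-Butanediol", "Diethylene glycol",
            "Guaiacol", "Phenol", "Triethylene glycol", "Furfuryl alcohol", "Levulinic acid"],
   "P_range_bar": [0.553, 5.828], "x_range": [0.002, 0.0311], "n": 49,
   "fixed_T_subsets": [], "role": "training"},
  {"id": 6, "ratio": "1:4", "temperatures_K": [303], "fixed_T_K": 303,
   "hbds": ["1,2-Propanediol", "1,4-Butanediol", "2,3-Butanediol", "Diethylene glycol",
            "Guaiacol", "Phenol", "Triethylene glycol", "Furfuryl alcohol", "Levulinic acid"],
   "P_range_bar": [0.725, 5.815], "x_range": [0.0027, 0.0326], "n": 49,
   "fixed_T_subsets": [], "role": "training"},
  {"id": 7, "ratio": "1:3", "temperatures_K": [313], "fixed_T_K": 313,
   "hbds": ["1,2-Propanediol", "1,4-Butanediol", "2,3-Butanediol", "Diethylene glycol",
            "Guaiacol", "Phenol", "Triethylene glycol", "Furfuryl alcohol", "Levulinic acid"],
   "P_range_bar": [0.575, 5.817], "x_range": [0.0017, 0.0266], "n": 48,
   "fixed_T_subsets": [], "role": "training"},
  {"id": 8, "ratio": "1:4", "temperatures_K": [313], "fixed_T_K": 313,
   "hbds": ["1,2-Propanediol", "1,4-Butanediol", "2,3-Butanediol", "Diethylene glycol",
            "Guaiacol", "Phenol", "Triethylene glycol", "Furfuryl alcohol", "Levulinic acid"],
   "P_range_bar": [0.534, 5.688], "x_range": [0.0014, 0.0281], "n": 48,
   "fixed_T_subsets": [], "role": "training"},
  {"id": 9, "ratio": "1:3", "temperatures_K": [323], "fixed_T_K": 323,
   "hbds": ["1,2-Propanediol", "1,4-Butanediol", "2,3-Butanediol", "Diethylene glycol",
            "Guaiacol", "Phenol", "Triethylene glycol", "Furfuryl alcohol", "Levulinic acid"],
   "P_range_bar": [0.631, 5.853], "x_range": [0.0014, 0.0212], "n": 48,
   "fixed_T_subsets": [], "role": "training"},
  {"id": 10, "ratio": "1:4", "temperatures_K": [323], "fixed_T_K": 323,
   "hbds": ["1,2-Propanediol", "1,4-Butanediol", "2,3-Butanediol", "Diethylene glycol",
            "Guaiacol", "Phenol", "Triethylene glycol", "Furfuryl alcohol", "Levulinic acid"],
   "P_range_bar": [0.547, 5.842], "x_range": [0.0014, 0.0234], "n": 48,
   "fixed_T_subsets": [], "role": "training"},
  {"id": 11, "ratio": "1:3", "temperatures_K": [298, 333], "fixed_T_K": null,
   "hbds": ["Furfuryl alcohol", "Levulinic acid", "Glycerol"],
   "P_range_bar": [0.859, 10.0], "x_range": [0.0018, 0.0454], "n": 13,
   "fixed_T_subsets": [], "role": "external"},
  {"id": 12, "ratio": "1:4", "temperatures_K": [298, 333], "fixed_T_K": null,
   "hbds": ["Triethylene glycol", "Ethylene glycol", "Furfuryl alcohol", "Levulinic acid", "Urea"],
   "P_range_bar": [0.826, 10.0], "x_range": [0.0022, 0.0419], "n": 15,
   "fixed_T_subsets": [], "role": "external"}
]
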