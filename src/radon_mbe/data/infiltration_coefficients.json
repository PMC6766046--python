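{
  "1": {
    "label": "detached house, groundwater used",
    "materials": ["concrete", "red_brick", "cement_block", "soil", "wood", "other"],
    "has_cracks": true,
    "has_floors": true,
    "coefficients": {
      "intercept": -15.89,
      "greenery": 0.18,
      "district_gm": 2.73,
      "material:red_brick": -1.52,
      "material:cement_block": -0.41,
      "material:soil": -2.54,
      "material:wood": -8.01,
      "material:other": -3.22,
      "cracks_ge2": 1.17,
      "floors_ge2": -4.94
    },
    "se": {
      "intercept": 6.05,
      "greenery": 0.07,
      "district_gm": 0.07,
      "material:red_brick": 3.0,
      "material:cement_block": 2.96,
      "material:soil": 3.98,
      "material:wood": 5.48,
      "material:other": 3.52,
      "cracks_ge2": 2.44,
      "floors_ge2": 2.34
    }
  },
  "2": {
    "label": "detached house, no groundwater",
    "materials": ["concrete", "red_brick", "cement_block", "soil", "wood", "other"],
    "has_cracks": true,
    "has_floors": true,
    "coefficients": {
      "intercept": -8.9,
      "greenery": 0.12,
      "district_gm": 2.72,
      "material:red_brick": -2.62,
      "material:cement_block": -4.76,
      "material:soil": -0.22,
      "material:wood": -5.32,
      "material:other": -7.16,
      "cracks_ge2": 2.43,
      "floors_ge2": -5.56
    },
    "se": {
      "intercept": 2.58,
      "greenery": 0.03,
      "district_gm": 0.02,
      "material:red_brick": 1.37,
      "material:cement_block": 1.43,
      "material:soil": 2.81,
      "material:wood": 2.75,
      "material:other": 2.06,
      "cracks_ge2": 1.64,
      "floors_ge2": 1.35
    }
  },
  "3": {
    "label": "other residence, groundwater used",
    "materials": ["concrete", "red_brick", "cement_block"],
    "has_cracks": false,
    "has_floors": false,
    "coefficients": {
      "intercept": 4.49,
      "greenery": -0.1,
      "district_gm": 2.59,
      "material:red_brick": -4.0,
      "material:cement_block": -6.88
    },
    "se": {
      "intercept": 5.77,
      "greenery": 0.04,
      "district_gm": 0.07,
      "material:red_brick": 1.68,
      "material:cement_block": 1.68
    }
  },
  "4": {
    "label": "other residence, no groundwater",
    "materials": ["concrete", "red_brick", "cement_block", "other"],
    "has_cracks": true,
    "has_floors": true,
    "coefficients": {
      "intercept": 11.09,
      "greenery": 0.08,
      "district_gm": 2.48,
      "material:red_brick": 1.29,
      "material:cement_block": -2.81,
      "material:other": -14.19,
      "cracks_ge2": 2.24,
      "floors_ge2": -0.58
    },
    "se": {
      "intercept": 2.11,
      "greenery": 0.03,
      "district_gm": 0.02,
      "material:red_brick": 1.71,
      "material:cement_block": 3.29,
      "material:other": 9.13,
      "cracks_ge2": 2.58,
      "floors_ge2": 1.49
    }
  }
}
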