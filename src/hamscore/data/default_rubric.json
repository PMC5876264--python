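{
  "age_years": [
    {
      "points": 1,
      "lower": 18,
      "upper": 26,
      "lower_inclusive": true,
      "upper_inclusive": false
    },
    {
      "points": 2,
      "lower": 26,
      "upper": 32,
      "lower_inclusive": true,
      "upper_inclusive": false
    },
    {
      "points": 3,
      "lower": 32,
      "upper": null,
      "lower_inclusive": true,
      "upper_inclusive": false
    }
  ],
  "n_muscles": [
    {
      "points": 0,
      "lower": 0,
      "upper": 1,
      "lower_inclusive": true,
      "upper_inclusive": false
    },
    {
      "points": 1,
      "lower": 1,
      "upper": 2,
      "lower_inclusive": true,
      "upper_inclusive": false
    },
    {
      "points": 2,
      "lower": 2,
      "upper": 3,
      "lower_inclusive": true,
      "upper_inclusive": false
    },
    {
      "points": 3,
      "lower": 3,
      "upper": null,
      "lower_inclusive": true,
      "upper_inclusive": false
    }
  ],
  "transverse_pct": [
    {
      "points": 0,
      "lower": 0.0,
      "upper": 25.0,
      "lower_inclusive": true,
      "upper_inclusive": false
    },
    {
      "points": 1,
      "lower": 25.0,
      "upper": 50.0,
      "lower_inclusive": true,
      "upper_inclusive": false
    },
    {
      "points": 2,
      "lower": 50.0,
      "upper": 75.0,
      "lower_inclusive": true,
      "upper_inclusive": false
    },
    {
      "points": 3,
      "lower": 75.0,
      "upper": null,
      "lower_inclusive": true,
      "upper_inclusive": false
    }
  ],
  "retraction_cm": [
    {
      "points": 0,
      "lower": 0.0,
      "upper": 0.0,
      "lower_inclusive": true,
      "upper_inclusive": true
    },
    {
      "points": 1,
      "lower": 0.0,
      "upper": 2.0,
      "lower_inclusive": false,
      "upper_inclusive": false
    },
    {
      "points": 2,
      "lower": 2.0,
      "upper": null,
      "lower_inclusive": true,
      "upper_inclusive": false
    }
  ],
  "sagittal_cm": [
    {
      "points": 0,
      "lower": 0.0,
      "upper": 0.0,
      "lower_inclusive": true,
      "upper_inclusive": true
    },
    {
      "points": 1,
      "lower": 0.0,
      "upper": 5.0,
      "lower_inclusive": false,
      "upper_inclusive": false
    },
    {
      "points": 2,
      "lower": 5.0,
      "upper": 10.0,
      "lower_inclusive": true,
      "upper_inclusive": false
    },
    {
      "points": 3,
      "lower": 10.0,
      "upper": null,
      "lower_inclusive": true,
      "upper_inclusive": false
    }
  ],
  "location": {
    "proximal": 1,
    "middle": 2,
    "distal": 3
  },
  "insertion": {
    "no": 0,
    "yes": 2
  }
}
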