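{
  "name": "dem-adult-italian-norms",
  "version": "1.0",
  "description": "Published adult normative cutoffs for the DEM test (Italian normative sample, n=521, ages 20-79). Correction equations are additive centered terms with reversed regression coefficients; sex coded male=1, female=0. All subtests: lower adjusted score is better.",
  "direction": "higher_worse",
  "sex_coding": {"M": 1, "F": 0},
  "equations": {
    "vt": {
      "terms": [
        {"predictor": "age", "transform": "cube", "coef": 0.000012, "center": 150382.9},
        {"predictor": "education", "transform": "inverse", "coef": 48.074, "center": 0.0854}
      ]
    },
    "aht": {
      "terms": [
        {"predictor": "age", "transform": "cube", "coef": 0.000017, "center": 150382.9},
        {"predictor": "education", "transform": "inverse", "coef": 57.49, "center": 0.0854}
      ]
    },
    "ratio": {
      "terms": [
        {"predictor": "age", "transform": "cube", "coef": 0.00000016, "center": 150382.9}
      ]
    },
    "errors": {
      "terms": [
        {"predictor": "education", "transform": "inverse", "coef": 3.02, "center": 0.0854},
        {"predictor": "sex", "transform": "identity", "coef": 0.307, "center": 0.495}
      ]
    }
  },
  "tolerance": {
    "note": "Values as printed; for ratio and errors the printed ITL/OTL columns appear swapped relative to the stated ordering, and the ES0 cutoffs below follow the equivalent-score table (1.33 and 2.2).",
    "vt": {"itl": 38.1, "otl": 40.4},
    "aht": {"itl": 41.8, "otl": 45.3},
    "ratio": {"itl": 1.33, "otl": 1.26},
    "errors": {"itl": 2.2, "otl": 1.9}
  },
  "es_bands": {
    "note": "Lower bound (in the worse direction) of ES0..ES3; scores better than the last bound earn ES4. The errors ES2 and ES3 bands are printed identically (0.8-0.2); assignments in that band are flagged ambiguous.",
    "vt": [40.4, 34.2, 31.9, 29.9],
    "aht": [45.3, 37.7, 34.7, 32.0],
    "ratio": [1.33, 1.18, 1.12, 1.08],
    "errors": [2.2, 0.9, 0.2, 0.2]
  },
  "percentiles": {
    "levels": [99, 95, 90, 85, 80, 75, 70, 65, 60, 55, 50, 45, 40, 35, 30, 25, 20, 15, 10, 5, 4, 3, 2, 1],
    "vt":     [20.9, 22.8, 24.2, 25.3, 26.2, 26.8, 27.5, 28.2, 28.9, 29.4, 29.9, 30.5, 31.0, 31.7, 32.5, 33.2, 33.9, 35.2, 36.7, 39.2, 40.0, 40.5, 41.2, 43.3],
    "aht":    [22.1, 24.7, 26.2, 27.1, 27.9, 28.6, 29.3, 30.1, 30.8, 31.5, 32.0, 33.0, 33.9, 34.7, 35.4, 36.3, 37.5, 38.5, 39.8, 43.4, 44.2, 45.5, 48.0, 49.1],
    "ratio":  [0.83, 0.93, 0.95, 0.98, 1.00, 1.02, 1.02, 1.03, 1.05, 1.06, 1.08, 1.09, 1.10, 1.12, 1.13, 1.15, 1.16, 1.19, 1.23, 1.29, 1.31, 1.34, 1.37, 1.41],
    "errors": [-0.5, -0.3, -0.2, -0.1, -0.1, -0.1, -0.1, 0.0, 0.0, 0.1, 0.2, 0.2, 0.2, 0.2, 0.2, 0.3, 0.9, 0.9, 1.2, 1.9, 2.1, 2.2, 2.9, 3.9]
  }
}
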