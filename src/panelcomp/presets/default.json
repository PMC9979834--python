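{
  "version": 1,
  "description": "Default scenario: overgrowth dynamics with more competitor cover at 1 m, more polyps and bare space at 3 m, low polyp cover overall; removal targets 0.5.",
  "dynamics": {
    "variant": "overgrowth",
    "depths": {
      "1": {"a0": 0.28, "a1": 1.2, "a2": -0.25, "delta": 0.002, "b0": 5.0, "b1": 0.6, "b2": -0.4, "extra": 0.001},
      "3": {"a0": 0.10, "a1": 0.5, "a2": -0.35, "delta": 0.002, "b0": 17.5, "b1": 0.8, "b2": -0.3, "extra": 0.004}
    },
    "r_A": 0.5,
    "r_O": 0.5
  },
  "manova": {
    "cells": {
      "1,C": [0.02, 0.28, 0.28, 0.24, 0.18],
      "1,A": [0.015, 0.33, 0.26, 0.23, 0.165],
      "1,O": [0.06, 0.42, 0.21, 0.18, 0.13],
      "3,C": [0.06, 0.50, 0.20, 0.12, 0.12],
      "3,A": [0.045, 0.555, 0.18, 0.11, 0.11],
      "3,O": [0.13, 0.61, 0.11, 0.08, 0.07]
    },
    "Z_scale": 0.05,
    "Sigma_scale": 0.08
  },
  "competitor_split_alpha": [4.0, 4.0, 6.0, 0.5, 0.5, 0.3]
}
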