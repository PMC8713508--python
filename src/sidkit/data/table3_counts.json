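{
  "n_decedents": 50,
  "signs": {
    "decreased_response_verbal": {
      "median_onset_days": 2.0,
      "ci95_days": [1.5, 2.5],
      "n_within_72h": 38,
      "mortality_72h": [29, 38],
      "mortality_24h": [18, 38]
    },
    "decreased_response_visual": {
      "median_onset_days": 2.0,
      "ci95_days": [1.0, 3.0],
      "n_within_72h": 37,
      "mortality_72h": [28, 37],
      "mortality_24h": [16, 37]
    },
    "peripheral_cyanosis": {
      "median_onset_days": 1.0,
      "ci95_days": [0.4, 1.6],
      "n_within_72h": 16,
      "mortality_72h": [16, 16],
      "mortality_24h": [10, 16]
    },
    "mandibular_respiration": {
      "median_onset_days": 1.0,
      "ci95_days": [0.7, 1.3],
      "n_within_72h": 22,
      "mortality_72h": [21, 22],
      "mortality_24h": [14, 22]
    },
    "death_rattle": {
      "median_onset_days": 1.0,
      "ci95_days": [0.8, 2.5],
      "n_within_72h": 15,
      "mortality_72h": [13, 15],
      "mortality_24h": [10, 15]
    },
    "neck_hyperextension": {
      "median_onset_days": 3.0,
      "ci95_days": [1.2, 4.8],
      "n_within_72h": 14,
      "mortality_72h": [8, 14],
      "mortality_24h": [5, 14]
    },
    "eyes_unable_to_close": {
      "median_onset_days": 1.0,
      "ci95_days": [0.6, 1.7],
      "n_within_72h": 11,
      "mortality_72h": [11, 11],
      "mortality_24h": [8, 11]
    },
    "nasolabial_drooping": {
      "median_onset_days": 1.0,
      "ci95_days": [0.4, 1.6],
      "n_within_72h": 12,
      "mortality_72h": [8, 12],
      "mortality_24h": [7, 12]
    },
    "cheyne_stokes": {
      "median_onset_days": 2.5,
      "ci95_days": [0.2, 4.8],
      "n_within_72h": 8,
      "mortality_72h": [4, 8],
      "mortality_24h": [2, 8]
    },
    "radial_pulselessness": {
      "median_onset_days": 0.5,
      "ci95_days": [0.7, 1.1],
      "n_within_72h": 20,
      "mortality_72h": [20, 20],
      "mortality_24h": [17, 20]
    },
    "apnea": {
      "median_onset_days": null,
      "ci95_days": null,
      "n_within_72h": 0,
      "mortality_72h": null,
      "mortality_24h": null
    }
  }
}
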