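{
  "decreased_response_verbal": "Decreased response to verbal stimuli",
  "decreased_response_visual": "Decreased response to visual stimuli",
  "peripheral_cyanosis": "Peripheral cyanosis",
  "mandibular_respiration": "Respiration with mandibular movement",
  "death_rattle": "Death rattle",
  "neck_hyperextension": "Hyperextension of the neck",
  "eyes_unable_to_close": "Inability to close the eyes",
  "nasolabial_drooping": "Drooping of the nasolabial fold",
  "cheyne_stokes": "Cheyne-Stokes breathing",
  "radial_pulselessness": "Pulselessness of the radial artery",
  "apnea": "Apnea",
  "shock_index_gt1": "Shock index >1.0"
}
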