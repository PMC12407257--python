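{
  "port_types": [
    "eeg_raw", "eog_raw", "emg_raw", "ecg_raw",
    "fnirs_intensity", "fnirs_hb",
    "epochs", "events", "features", "power_series",
    "coupling_result", "model", "predictions", "stats", "figure", "any"
  ],
  "rules": {
    "eeg_raw": ["eeg_raw", "any"],
    "eog_raw": ["eog_raw", "any"],
    "emg_raw": ["emg_raw", "any"],
    "ecg_raw": ["ecg_raw", "any"],
    "fnirs_intensity": ["fnirs_intensity", "any"],
    "fnirs_hb": ["fnirs_hb", "any"],
    "epochs": ["epochs", "any"],
    "events": ["events", "any"],
    "features": ["features", "any"],
    "power_series": ["power_series", "any"],
    "coupling_result": ["coupling_result", "any"],
    "model": ["model", "any"],
    "predictions": ["predictions", "any"],
    "stats": ["stats", "any"],
    "figure": ["figure", "any"],
    "any": ["any"]
  },
  "entry_category": "data_input"
}
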