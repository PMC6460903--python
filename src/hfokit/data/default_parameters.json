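{
  "fir-hilbert-stockwell": {
    "fir": {"low_hz": 80.0, "high_hz": 250.0, "n_taps": 513, "self_convolve": false},
    "detect": {"threshold_sd": 3.0, "min_duration_s": 0.01, "min_peaks": 6,
               "peak_threshold_sd": 3.0, "merge_gap_s": 0.01},
    "classify": {"peak_trough_ratio": 2.0, "context_s": 0.1}
  },
  "fir-rms-stockwell": {
    "fir": {"low_hz": 80.0, "high_hz": 250.0, "n_taps": 513, "self_convolve": false},
    "detect": {"window_s": 0.003, "threshold_sd": 5.0, "min_duration_s": 0.006,
               "min_peaks": 6, "peak_threshold_sd": 3.0, "merge_gap_s": 0.01},
    "classify": {"peak_trough_ratio": 2.0, "context_s": 0.1}
  },
  "emd-rms-stockwell": {
    "emd": {"first_imf": 1, "n_imfs": 2, "epsilon": 0.2},
    "detect": {"window_s": 0.003, "threshold_sd": 5.0, "min_duration_s": 0.006,
               "min_peaks": 6, "peak_threshold_sd": 3.0, "merge_gap_s": 0.01},
    "classify": {"peak_trough_ratio": 2.0, "context_s": 0.1}
  },
  "fir-rms-bump": {
    "fir": {"low_hz": 80.0, "high_hz": 250.0, "n_taps": 513, "self_convolve": false},
    "detect": {"window_s": 0.003, "threshold_sd": 5.0, "min_duration_s": 0.006,
               "min_peaks": 6, "peak_threshold_sd": 3.0, "merge_gap_s": 0.01},
    "classify": {}
  },
  "fir-rms-svm": {
    "fir": {"low_hz": 80.0, "high_hz": 250.0, "n_taps": 513, "self_convolve": false},
    "detect": {"window_s": 0.003, "threshold_sd": 5.0, "min_duration_s": 0.006,
               "min_peaks": 6, "peak_threshold_sd": 3.0, "merge_gap_s": 0.01},
    "timefeat": {"selection": ["mAmp", "dAmp", "dtEx", "dur", "gdPos", "gdNeg",
                               "rmaxA", "rminA", "linLen", "numEx", "sdAEx", "sdDtEx"]},
    "freqfeat": {"f_lo": 0.0, "f_hi": 850.0, "bin_hz": 10.0, "normalize": true},
    "classify": {"model_file": null}
  },
  "fir-hilbert-svm": {
    "fir": {"low_hz": 80.0, "high_hz": 250.0, "n_taps": 513, "self_convolve": false},
    "detect": {"threshold_sd": 3.0, "min_duration_s": 0.01, "min_peaks": 6,
               "peak_threshold_sd": 3.0, "merge_gap_s": 0.01},
    "timefeat": {"selection": ["mAmp", "dAmp", "dtEx", "dur", "gdPos", "gdNeg",
                               "rmaxA", "rminA", "linLen", "numEx", "sdAEx", "sdDtEx"]},
    "freqfeat": {"f_lo": 0.0, "f_hi": 850.0, "bin_hz": 10.0, "normalize": true},
    "classify": {"model_file": null}
  }
}
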