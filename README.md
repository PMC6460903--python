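# hfokit

Modular detection and classification of high-frequency oscillations (HFOs)
in EEG recordings: scriptable library plus CLI covering preprocessing
(windowed-sinc FIR filtering, empirical mode decomposition), events-of-interest
detection (sliding RMS, Hilbert envelope), classification (Stockwell-transform
peak/trough rule, SVM with wrapper feature-subset selection), validation
metrics, reporting, and a configurable process/activity pipeline — all
exercisable end-to-end on synthetic EEG with exact ground truth.

## Layout

| module | role |
|---|---|
| `hfokit.signal_model` | Recording/Channel/EventMarker types, segmentation, marker CSV/JSON |
| `hfokit.edf` | minimal EDF/EDF+C reader and writer (16-bit samples, TAL annotations) |
| `hfokit.synthetic` | pink-noise background, injected ripple/fast-ripple bursts and spike transients, labeled datasets |
| `hfokit.preprocess` | Blackman-windowed sinc FIR (low/high/band-pass, self-convolution), EMD and IMF-subset recomposition |
| `hfokit.detect` | RMS and Hilbert-envelope EOI detectors |
| `hfokit.features` | 12 time-domain features, binned Tukey-window spectral features, table concatenation |
| `hfokit.classify_stockwell` | S-transform (FFT formulation) and the spectral peak/trough classification rule |
| `hfokit.classify_svm` | scaling, ANOVA ranking, greedy-forward wrapper selection, C/γ grid search, learning/validation/classification modes |
| `hfokit.evaluate` | event matching, sensitivity/precision/FDR/F1, HFO activity and correlation reports |
| `hfokit.pipeline` | process-definition XML, activity registry/plugins, sequential execution with error vectors |

## CLI

```sh
# synthetic recording with ground truth
hfokit simulate --seed 3 --duration 60 --ripples 10 --fast-ripples 5 --spikes 5 \
    --out-edf sim.edf --out-markers truth.csv

# detect EOIs on the 80-250 Hz band
hfokit detect --detector rms --band 80:250 --input sim.edf --out detected.csv

# classify with the Stockwell rule (or --model MODEL for a trained SVM)
hfokit classify --input sim.edf --markers detected.csv --out classified.csv

# train / validate an SVM model on labeled markers
hfokit train --input sim.edf --markers labeled.csv --ratio 0.1 --seed 0 --model model.bin
hfokit validate --input sim.edf --markers labeled.csv --model model.bin

# activity report
hfokit report --input sim.edf --markers classified.csv

# run a bundled process definition end to end
hfokit run-process --process fir-rms-stockwell --input sim.edf --out out.csv
```

Six predefined processes ship in
`src/hfokit/data/predefined_processes.xml` with default parameters in
`default_parameters.json`; custom activities can be registered at runtime via
`hfokit.pipeline.register_activity` and referenced from user XML definitions.

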