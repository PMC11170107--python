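# meahazard

Acute neuronal hazard scoring from multi-well micro-electrode-array (MEA)
spike-train recordings.

From spike-timestamp exports (CSV), the package

1. computes per-well electrophysiology parameters — weighted mean firing
   rate, burst duration via Poisson-Surprise burst detection, area under the
   pairwise cross-correlogram (AuCC), median/mean inter-spike interval,
   firing/network cessation flags, and an extended 43-name panel — with
   active-electrode (> 0.1 Hz) and active-well (> 40 % active electrodes) QC;
2. converts them to baseline-corrected, vehicle-normalized ΔΔ% effect sizes
   per condition (each well is its own control; exact Wilcoxon–Mann–Whitney
   comparison vs same-plate vehicle wells);
3. calibrates per-parameter effect zones from statistical tolerance
   intervals (Howe's k-factor, 95 %/95 % default, distribution-free
   fallback) on vehicle and positive-control ΔΔ% distributions;
4. maps each condition through a weighted scoring matrix (data, not code —
   JSON) to a total score and one of four hazard labels:
   `non-neuroactive` (green), `neuroactive` (yellow), `hazard` (orange),
   `high hazard` (red);
5. provides the supporting statistics: repeated-split LASSO parameter
   selection with frequency ranking and balanced-error-rate (BER)
   evaluation, stepwise reduction, confusion metrics (sensitivity,
   specificity, balanced accuracy, BER, PPV, NPV, Cohen's κ), a
   Random-Forest inhibitory/excitatory/vehicle direction classifier, and
   reference-panel predictivity evaluation;
6. ships a seeded synthetic plate simulator (48 wells × 16 electrodes,
   30-min phases, vehicle variability, parameterized drug-effect profiles)
   so the whole pipeline is testable without external data.

## CLI

All stages are composable subcommands over plain-text interfaces
(spike lists, plate maps, feature/effect tables as CSV; config and scoring
matrix as JSON). Every run writes a `<out>.manifest.json` with the config
hash, seed and input digests; identical config + seed reproduce
byte-identical outputs.

```sh
meahazard simulate  --seed 1 --out-dir run/                # spike_list.csv + plate_map.csv
meahazard features  --spikes run/spike_list.csv --out run/features.csv
meahazard normalize --features run/features.csv --plate-map run/plate_map.csv --out run/dd.csv
meahazard calibrate --dd run/dd.csv --out run/calibrated.json --report run/calibration.csv
meahazard score     --config run/calibrated.json --dd run/dd.csv --out run/report.csv
meahazard select    --table table.csv --repeats 100 --out selection.csv
meahazard classify  --train train.csv --predict effects.csv --out predictions.csv
meahazard evaluate  --report run/report.csv --labels labels.csv --out predictivity.csv
```

`calibrate` needs ΔΔ% tables containing `vehicle` and `positive_control`
wells; `score` refuses to run without calibrated cutoffs in its config.

## Layout

```
src/meahazard/
  io_formats.py            spike lists, plate maps, configs, reports
  spike_features.py        QC, WMFR, Poisson-Surprise bursts, AuCC, ISI, panel
  effect_normalization.py  ΔΔ% effect sizes + rank-sum comparison
  cutoff_calibration.py    tolerance intervals and zone boundaries
  hazard_scoring.py        scoring matrix -> total score -> label
  parameter_selection.py   LASSO selection, stepwise reduction, metrics
  direction_classifier.py  Random-Forest direction probabilities
  reference_evaluation.py  predictivity vs reference risk classes
  synthetic_mea.py         seeded plate simulator
  pipeline.py              in-process orchestration
  cli.py                   argparse subcommands
```
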