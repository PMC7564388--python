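# eegarousal

Resting-EEG vigilance staging and arousal-stability scoring with a
biostatistics layer, plus a synthetic EEG + cohort generator that stands
in for raw study data.

The pipeline classifies every second of a 20-minute eyes-closed resting
EEG into one of seven vigilance stages (0, A1, A2, A3, B1, B2/3, C),
condenses the 1200-label trajectory into an Arousal Stability Score
(1–14), dichotomizes subjects into hyperaroused (score ≥ 13) vs.
non-hyperaroused groups, and compares the groups on questionnaire
outcomes (ANOVA with Levene's test, χ², Mann–Whitney U, binary
screening metrics).

## Layout

| module | contents |
| --- | --- |
| `eegarousal.synthetic` | ground-truth stage scripts, stage-faithful EEG synthesis, cohort generation |
| `eegarousal.preproc` | EDF/BrainVision IO, 0.5–70 Hz band-pass + 50 Hz notch, resampling to 100 Hz, 1-s segmentation, artifact flagging, spindle/K-complex detection |
| `eegarousal.staging` | per-second spectral/EOG features and the stage decision cascade |
| `eegarousal.stability` | Arousal Stability Score and the hyperarousal dichotomy |
| `eegarousal.stats` | ANOVA (one/two-way, partial η²), Levene, uncorrected Pearson χ², Mann–Whitney U with tie-corrected Z, sensitivity/specificity/AUC/Youden |
| `eegarousal.pipeline` | end-to-end orchestration, descriptives report, figure |
| `eegarousal.cli` | `eegarousal` command-line interface |

## CLI

```bash
eegarousal simulate-cohort --n-hyper 19 --n-nonhyper 41 --seed 1 --out cohort.csv
eegarousal simulate-eeg --profile declining --b1-minute 3 --seed 1 --out rec.edf
eegarousal stage --input rec.edf --out stages.tsv
eegarousal score --stages stages.tsv --out result.json
eegarousal analyze --table participants_scored.csv --out report/
eegarousal run-all --config config.yaml --seed 42 --out run_out/
```

`run-all` generates a cohort, synthesizes one 20-min EEG per
participant, preprocesses, stages and scores each, and writes the full
analysis (`report.json`, `descriptives.tsv`, a group-means figure, and
per-participant stage/score files). Runs are deterministic for a fixed
seed. The YAML config mirrors `PipelineConfig` (see
`tests/test_pipeline.py::TestConfigAndCLI` for a worked example).

## Notes

- All classifier thresholds (`ClassifierThresholds`) and synthesis
  amplitudes (`SynthesisConfig`) are this package's defaults, tuned so
  the default cascade separates the synthetic stages with margin; they
  are configurable and are *not* the constants of the original staging
  software.
- Artifact rejection is amplitude/variance flagging (not ICA), and
  graphoelements are detected automatically (sigma-band envelope for
  spindles, biphasic low-frequency transients for K-complexes) with a
  TSV annotation-override path that mimics a human-rater workflow.
- No EDF library is available in the target environment, so
  `eegarousal.preproc.edf` implements the plain 16-bit/1-s-record EDF
  subset directly; BrainVision multiplexed float32/int16 is likewise
  self-contained.
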