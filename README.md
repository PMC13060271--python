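# attnpupil

Analysis pipeline for interrupted, reverberant auditory spatial-attention
pupillometry experiments: trial/block design with exact counterbalancing and
a prospective power analysis, pupil preprocessing (blink interpolation,
zero-phase Butterworth filtering, epoching, tonic/phasic baselining),
serial-recall behavioral statistics (repeated-measures ANOVA, Bonferroni
post-hocs), cluster-based and scalar sign-flip permutation tests, peak
latency/amplitude analysis, and room-acoustics utilities (sweep
deconvolution, Schroeder RT60, direct-path windowing).

A synthetic-data generator (additive Erlang event kernels on a tonic level
with AR(1) noise and Poisson blink gaps, plus a serial-recall response model
with primacy/recency structure) makes every stage testable without real
recordings.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(power-analysis and design numbers, permutation-oracle equivalence, type-I
calibration, full-pipeline parameter recovery, signal-processing and
acoustics oracles).

## CLI

```sh
# generate a synthetic cohort (designs, pupil recordings, responses)
attnpupil simulate --n-subjects 10 --seed 1 --out data/

# run the full analysis (preprocess -> behavior -> cluster/peak statistics)
attnpupil analyze --data data/ --out results/ --seed 1

# RT60 of an impulse response (CSV with an 'amplitude' column, or WAV)
attnpupil acoustics --ir ir.csv --sampling-rate 48000 --window 0.005
```

All parameters can be supplied via `--config config.json` mirroring
`attnpupil.pipeline_io.RunConfig`. Outputs are CSV/JSON; every results
bundle embeds the config hash and root seed, and reruns with the same
config are byte-reproducible.

## Layout

- `src/attnpupil/trial_design.py` — power analysis, design, schedules
- `src/attnpupil/synthetic_data.py` — pupil and behavior generators
- `src/attnpupil/pupil_preprocess.py` — blink interpolation, filter, epochs, baselining
- `src/attnpupil/behavior_stats.py` — scoring, accuracy tables, RM-ANOVA, post-hocs
- `src/attnpupil/timecourse_stats.py` — cluster-based sign-flip permutation test
- `src/attnpupil/peak_stats.py` — peak measures, scalar sign-flip tests
- `src/attnpupil/room_acoustics.py` — deconvolution, Schroeder RT60, windowing
- `src/attnpupil/pipeline_io.py`, `cli.py` — orchestration and CLI
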