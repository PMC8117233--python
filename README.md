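# gazeperim

Continuous gaze-tracking perimetry in Python: simulate an observer tracking a
pseudo-random-walk stimulus under gaze-contingent visual field defects, then
reconstruct the visual field map from the eye/stimulus time series by two
complementary routes and evaluate the reconstructions against ground truth.

## What it does

1. **Stimulus simulation** (`gazeperim.trajectory`) — velocity-random-walk
   stimulus paths (smooth pursuit), optionally interleaved with displacement
   jumps (saccadic pursuit), confined to the display field by reflection.
2. **Gaze-contingent defects** (`gazeperim.scotoma`) — central (10° disk),
   peripheral (all but a 10° hole), right-hemifield, or no loss; occlusion is
   decided in retinotopic coordinates r = stimulus − gaze.
3. **Synthetic observer** (`gazeperim.observer`) — a closed-loop tracker with
   predictive pursuit (delayed percept, velocity matching plus positional
   catch-up), undershooting corrective saccades, occlusion-gated feedback,
   escalating visual search (local probes, then a systematic sweep toward the
   estimated loss zone), compensatory gaze bias away from a consistently lost
   direction, and blink/attention lapses; full cohorts (N participants × 4
   defect conditions × 6 repetitions × 2 contrasts × 2 pursuit modes, 20-s
   trials at 240 Hz) are reproducible from one seed.
4. **TFCE route** (`gazeperim.tfce`, `gazeperim.mapping`,
   `gazeperim.evaluation`) — threshold-free cluster enhancement of the
   eye-stimulus deviation series (E = 2, H = 0.5, dh = range/2500), percentile
   thresholding against a pooled normative distribution, back-projection into
   a 1°-cell retinotopic grid, λ optimization by grand-average 2D Spearman
   accuracy, and participant-aware five-fold cross-validation.
5. **Recurrent-network route** (`gazeperim.rnn`) — a pure-numpy two-stream
   model (three bidirectional GRU layers over downsampled gaze/stimulus
   windows + a dense categorical stream), jointly trained softmax heads for
   per-step scotoma classification and 4-class defect-shape classification
   (loss weights α = 0.75, β = 0.25, RMSprop, batch size 128, 4.17-s windows
   downsampled from 240 Hz to 60 Hz), ensemble shape prediction over the 24
   per-trial windows, point-wise map reconstruction, and a miscalibration
   robustness harness (constant gaze offsets up to 5°).
6. **IO and CLI** (`gazeperim.trial_io`, `gazeperim.cli`) — versioned
   tab-separated trial files with a JSON header, map/norms/model round-trips,
   YAML configuration and a `gazeperim` command-line front end.

## Command line

```sh
# simulate a 2-participant cohort over all four defect conditions
gazeperim simulate --participants 2 --seed 7 --out scratch/cohort

# TFCE series, normative distribution, map reconstruction
gazeperim tfce --trials scratch/cohort --out scratch/tfce
gazeperim build-norms --trials scratch/cohort --out scratch/norms.txt
gazeperim reconstruct --trials scratch/cohort --norms scratch/norms.txt \
    --lam 87.4 --out scratch/map.txt

# lambda optimization and cross-validated evaluation
gazeperim optimize-lambda --trials scratch/cohort
gazeperim evaluate --trials scratch/cohort --folds 5 --out scratch/report.json

# recurrent network: train, predict, robustness table
gazeperim rnn-train --trials scratch/cohort --iterations 2000 --out scratch/model
gazeperim rnn-predict --model scratch/model --trials scratch/cohort \
    --out scratch/rnn_map.txt
gazeperim robustness --model scratch/model --trials scratch/cohort
```

All commands accept `--config <yaml>` with sections `trial`, `walk`,
`observer`, `protocol`, `tfce`, `grid`, `rnn` mapping 1:1 onto the config
dataclasses; explicit flags override config keys. Every run logs its seeds
and a config hash, so any artifact is reproducible from the logged
information alone.

## Layout

```
src/gazeperim/
  trajectory.py   stimulus random-walk generator
  scotoma.py      defect geometry + ground-truth occlusion labels
  observer.py     synthetic tracking observer, protocol, cohorts
  tfce.py         deviation series, TFCE transform, norms, binarization
  mapping.py      retinotopic back-projection, field maps, mean deviation
  evaluation.py   2D Spearman, λ optimization, CV, error maps, summaries
  rnn/            numpy BiGRU layers, two-stream model, training, inference
  trial_io.py     on-disk formats (trials, manifests, maps, norms, models)
  cli.py          command-line interface
tests/            unit, property and acceptance suites
scripts/          acceptance report generator
```
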