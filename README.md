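# semg2angle

Continuous estimation of lower-limb joint angles (hip, knee, ankle) from
surface-EMG envelopes, across four movement patterns (gait, obstacle
crossing, squatting, knee flexion–extension).

The pipeline:

1. **sim** — synthetic session generator: pattern-specific periodic joint
   trajectories (with cycle-to-cycle amplitude variability), a known
   saturating joint-state → muscle-activation map with a 50 ms
   electromechanical lead, activation-modulated 20–450 Hz noise carriers
   with 50 Hz line interference, and three-marker planar geometry whose
   vertex angle reproduces the commanded angles exactly.
2. **preprocess** — 4th-order Butterworth band-pass (20–450 Hz), 50 Hz
   notch (Q = 35), full-wave rectification + 10 Hz low-pass envelope;
   15 Hz zero-phase low-pass on markers, three-point cosine-formula joint
   angles; everything resampled to a common 20 Hz analysis rate.
3. **windows** — sliding-window expansion (W = 10, S = 1 ⇒ T − W + 1
   windows per trial), with per-fold z-score normalization.
4. **nets** — a NumPy neural-network stack with hand-written backprop:
   - `cb_tcn`: causal/dilated TCN encoder → convolutional block attention
     (channel + temporal) → TCN decoder → linear head;
   - baselines `ed_tcn` (same cascade, no attention), `tcn` (single
     stage), `lstm` (2-layer), and `wiener` (FIR least squares over the
     window's lags with optional ridge).
5. **trainer** — Adam + L2, MSE loss, batch 50, 50 epochs, LR halved
   every 10 epochs from 1e-3; 5-fold cross-validation split by contiguous
   trial blocks (leakage-free; window-level splitting available for
   comparison).
6. **evalstats** — R², RMSE, range-normalized RMSE per joint and fold;
   one-way ANOVA + Tukey HSD model comparison with star binning.

No deep-learning framework is required: models are small and train in
seconds-to-minutes on one CPU, and every layer's gradient is verified
against finite differences in the test suite.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria; its end-to-end
case trains the cascaded model under 5-fold CV for three seeds and takes
a few minutes of CPU. Everything else runs in seconds.

## CLI

```sh
# write 5 synthetic gait trials (plain CSV + YAML manifests)
semg2angle simulate --pattern gait --n-trials 5 --seed 0 --out sessions/

# condition them onto the 20 Hz analysis base (in place)
semg2angle preprocess sessions/trial*

# cross-validate one model, write per-fold metrics
semg2angle evaluate sessions/trial* --config experiment.yaml --out results.csv

# compare architectures with ANOVA + Tukey tables
semg2angle compare sessions/trial* --config experiment.yaml \
    --models cb_tcn,ed_tcn,tcn,lstm,wiener --out comparison/
```

An experiment config is a single YAML file:

```yaml
sim:    {pattern: gait, n_trials: 5, snr_db: 20.0}
window: {W: 10, S: 1, target_policy: last_sample}
model:  {architecture: cb_tcn, channels: 64, kernel: 3, dilations: [1, 2]}
train:  {epochs: 50, batch: 50, lr0: 0.001, folds: 5, split_policy: by_block}
```

## Layout

```
src/semg2angle/
  session.py      RawSession / GroundTruth / ProcessedTrial + text I/O
  sim.py          synthetic session generator
  preprocess.py   filters, envelopes, joint angles, resampling
  windows.py      sliding-window expansion + normalization
  nets/           layers, TCN, CBAM, LSTM, Wiener, model zoo
  trainer.py      Adam, LR schedule, training loop, cross-validation
  evalstats.py    metrics, aggregation, ANOVA + Tukey comparison
  cli.py          click command group
```
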