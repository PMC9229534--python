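# gaitmyo

Non-contact estimation of knee-extensor muscle activity during walking from
two inertial measurement units (IMUs), for wearable-biomechanics and
rehabilitation researchers who want per-gait-cycle muscle-effort estimates
without keeping EMG electrodes on the skin.

Surface EMG is expensive to wear well: skin preparation, electrode
placement, cabling.  `gaitmyo` implements the alternative: record walking
once with ankle/knee IMUs *and* sEMG, learn the mapping from per-cycle gait
kinematics to normalized muscle activity, and afterwards estimate activity
from the IMUs alone.  The package covers the whole measurement chain plus a
physics-consistent simulator that provides ground truth for every stage.

## What it computes

**Per-cycle kinematic features** from the ankle IMU (tri-axial acceleration
in G, angular velocity in deg/s, 400 Hz):

- gait events from the sagittal shank angular velocity — heel strike (HS),
  flat foot (FF), toe-off (TO), mid-swing (MS); stance = HS→TO, swing =
  TO→next HS;
- sensor attitude q̂(t) from an extended Kalman filter whose measurement
  covariance adapts to the motion state,
  σ_k² = (1/(N+1)) Σ_{i=k−N..k} (‖a_i‖ − 1)² (a in G),
  so gravity corrections are trusted when the foot is on the ground and
  suppressed while it swings;
- zero-velocity-update (ZUPT) integration of the gravity-free global
  acceleration: v(t) accumulates only during swing and is pinned to zero
  during stance, cancelling integrator drift every stride;
- walking distance X(t) = ∫‖v‖dt (a staircase curve) and stride lengths
  l_i = X(t_HS(i)) − X(t_HS(i−1)), with strides ≤ 30 cm discarded as
  missteps;
- swing-phase peaks a_peak = max‖a⃗‖, ω_peak = max‖ω⃗‖, v_peak = max‖v⃗‖,
  and stance/swing durations.

**%MVC activity targets** from sEMG (1000 Hz): 20–450 Hz zero-phase
band-pass, 100 ms sliding RMS envelope, normalization by the peak RMS of a
maximum-voluntary-contraction (MVC) trial, per-cycle mean and peak %MVC for
the rectus femoris (RFM) and lateral gastrocnemius (OGM).

**The activity model**: a feed-forward network (7 hidden layers × 12 relu
units, Adam, log-cosh loss, 20% of connections randomly masked during
training) per target, mapping the 8 features — a_peak, ω_peak, v_peak,
l_stride, stance time, swing time, BMI, lower-limb ratio — to %MVC, with
seeded 8:2 train/validation splits, exhaustive grid search and
repeated-split evaluation reporting R² mean ± std.

## Worked example

```python
from gaitmyo import (GaitSimParams, simulate_session, extract_gait_features,
                     MuscleActivityANN, split_dataset)
from gaitmyo.simulate import simulate_feature_dataset

# a simulated 10-stride walk (1.2 m strides at 2 Hz) with default sensor noise
session, truth = simulate_session(GaitSimParams(n_strides=10, seed=1))
features = extract_gait_features(session)
print(features[["cycle_index", "l_stride", "v_peak", "stance_time"]].head(3))
#    cycle_index  l_stride  v_peak  stance_time
# 0           -1     1.199  11.234          NaN
# 1            0     1.196  11.216        0.298
# 2            1     1.198  11.218        0.300

# fit the activity model on a 2000-cycle feature table
df = simulate_feature_dataset(n_cycles=2000, noise_frac=0.05, seed=1)
train, val = split_dataset(df, ratio=0.8, seed=1)
res = MuscleActivityANN.from_dataframe(train, target="mvc_avg_ogm").fit(seed=1)
print(res.summary())
print(f"validation R2: {res.rsquared_on(val):.3f}")
```

```
Muscle Activity ANN Results
==============================================
Target:               mvc_avg_ogm
Observations:         1600
Features:             8
Hidden layers:        7 x 12 (relu)
Dropout:              20%
Optimizer / loss:     adam / logcosh
Parameters:           1057
Epochs run:           274
R² (fit data):        0.8816
==============================================
validation R2: 0.896
```

The recovered stride lengths sit within ~1% of the true 1.2 m (the
noiseless chain recovers them to ~0.2%), and the model explains ~90% of the
variance of the average gastrocnemius activity per cycle on held-out
cycles.  `res.predict(new_features)` returns %MVC estimates for unseen
cycles.

The same chain is scriptable from the shell:

```sh
gaitmyo simulate walk/ --n-strides 12 --seed 3   # session dir + ground truth
gaitmyo run walk/ out/                           # features → targets → models
gaitmyo evaluate out/dataset.csv out/eval --n-repeats 20
```

## Documentation

`docs/methods.md` describes the models, their assumptions, the simulator
and its limits, and all tunable parameters with defaults and units.
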