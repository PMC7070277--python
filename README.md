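# gaitgrnn

Continuous prediction of lower-limb joint angles from multi-source gait
signals, for exoskeleton and rehabilitation-robotics control research.

An exoskeleton that follows its wearer needs the next instant's hip, knee
and ankle angles before they happen. Because surface electromyography
(sEMG) leads force production by roughly 40–100 ms, muscle activity is a
usable preview of motion; plantar pressure adds the gait-phase (stance vs
swing) information that pure kinematics and sEMG lack at the
stance-to-swing transition. `gaitgrnn` implements that idea end to end:

* **Model** — a general regression neural network (GRNN), i.e.
  Nadaraya–Watson kernel regression with a Gaussian kernel. For stored
  training patterns $X_i$ with targets $Y_i$, the prediction at a query
  $X$ is

  $$\hat Y(X) = \frac{\sum_{i=1}^{n} Y_i \exp\!\big(-D_i^2/2\sigma^2\big)}
                      {\sum_{i=1}^{n} \exp\!\big(-D_i^2/2\sigma^2\big)},
  \qquad D_i^2 = \lVert X - X_i \rVert^2 .$$

  The single smoothing factor $\sigma$ is chosen by a golden-section line
  search on the leave-one-out mean squared error, on the interval
  $(10^{-6}, 0.2)$ with termination width $0.01$.
* **Inputs** (7 features at 100 Hz): current hip angle; RMS of three
  band-pass-filtered thigh sEMG channels (rectus femoris, biceps femoris,
  semitendinosus) over non-overlapping 20-sample windows; window means of
  three plantar-pressure channels (big toe, forefoot, heel).
  **Outputs** (3): hip, knee and ankle angles at the next 10 ms step.
* **Preprocessing** — minimal-order Butterworth band-pass (pass 20–500 Hz
  within 3 dB, stop 10/570 Hz at 20 dB, zero-phase application) for sEMG;
  least-squares cubic-spline fit-and-resample to 100 Hz for angles;
  coif5 level-6 wavelet denoising for pressure features and predicted
  angle series; min-max normalization to [0, 1] fitted on training data
  only.
* **Evaluation** — chronological 2/3–1/3 train/test split; per-joint
  RMSE, mean relative error (MRE), Pearson correlation γ and mean
  maximum positive/negative error per gait cycle; an input-ablation
  experiment (angle-only → +sEMG → +pressure) quantifies each signal
  source's contribution.

No public recordings exist for this protocol, so the package ships a
seeded synthetic gait generator (`gaitgrnn.synthetic`) that emulates the
acquisition: periodic hip/knee/ankle kinematics, burst-like 20–500 Hz
sEMG with drift, noise floor and stride-to-stride amplitude variability,
and stance-locked pressure bumps with sparse spikes — all driven by one
latent gait phase.

## Worked example

```python
from gaitgrnn import GaitParameters, JointAngleGRNN, generate_recording

rec = generate_recording(GaitParameters(n_cycles=30, seed=42))
model = JointAngleGRNN.from_recording(rec, ablation="angle_semg_pressure")
res = model.fit(sigma="optimize")
print(res.summary())
```

```
Joint-angle prediction error analysis  [inputs: angle_semg_pressure]
sigma = 0.00770239 (optimize); n_train = 1999, n_test = 1000

Index                                    Hip        Knee       Ankle
Mean Maximum Positive Error           1.0045      3.6130      0.6647
Mean Maximum Negative Error          -1.3716     -3.4346     -0.9480
RMSE                                  0.3456      0.8541      0.2072
MRE                                   0.0280      7.5129      7.9915
gamma                                 0.9997      0.9991      0.9993
```

Reading the table: the optimized bandwidth (σ ≈ 0.008 on normalized
inputs) predicts the held-out last third of the recording with sub-degree
RMSE and γ > 0.999 for every joint; the extreme-error rows are the mean
over gait cycles of the largest signed over/under-shoot within each
cycle, in degrees. MRE is unstable for joints whose angle crosses zero
(knee and ankle here) — the near-zero samples dominate the relative
error, which is why RMSE and γ are the headline numbers.

The same pipeline is available from the shell:

```sh
gaitgrnn simulate --cycles 30 --seed 42 --out rec.csv
gaitgrnn run-all --recording rec.csv --ablation full --sigma auto \
    --report report.json --model-out model.json --predictions-out pred.csv
gaitgrnn predict --model model.json --recording rec.csv --out pred2.csv
gaitgrnn evaluate --predictions pred2.csv
```

`run-all` prints the summary table and writes a JSON report; `predict`
with the saved model reproduces the run's held-out predictions
bit-exactly. A YAML config file (see `gaitgrnn.RunConfig`) fixes every
tunable — filter edges, window sizes, wavelet, search interval, split
fraction — and its hash is embedded in every artifact.

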