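# fielddrift

Does the hand location at which electrically evoked touch is felt stay put?

When a nerve-cuff electrode in an amputee's residual limb is stimulated, the
person feels touch at a specific spot on their phantom hand — the *projected
field*. In a closed-loop prosthesis, that electrode is wired to a force sensor
on the prosthetic thumb, so for months or years the user feels thumb contact
somewhere that may not match the thumb. A central plasticity question is
whether the projected field migrates toward the sensor's location with
experience, or stays fixed. `fielddrift` implements the statistical machinery
to answer it from longitudinal mapping sessions, plus a simulator of the
feedback channel itself and summaries of home-use logs.

## The statistic

Each pair of consecutive mapping sessions gives a displacement step of the
projected-field centroid: distance $d_j$ (mm) and direction $\theta_j$. The
test statistic is the distance-weighted **vector strength**

$$\mathrm{vs} = \frac{\sqrt{\left(\sum_j d_j \sin\theta_j\right)^2 +
\left(\sum_j d_j \cos\theta_j\right)^2}}{\sum_j d_j}$$

— the resultant length of the step vectors over the total path length, 1 for
perfectly consistent direction and near 0 for isotropic jitter. The null
("no migration") keeps the observed distances and redraws each direction
i.i.d. Uniform$(0, 2\pi)$, 10,000 times by default; the p-value is the
add-one-corrected upper-tail proportion
$p = (1 + \#\{\mathrm{vs}_\mathrm{null} \ge \mathrm{vs}_\mathrm{obs}\})/(n_\mathrm{mc}+1)$.
The statistic is invariant to the digitization scale and orientation of the
hand template.

Around that core: a drifting-random-walk generator (half-normal step lengths,
von Mises directions about the bearing to a target; concentration κ = 0 is
exactly the uniform null), a type-I/power calibration harness, the
force→pulse-frequency feedback encoder (linear 5–30 Hz mapping, 5-s safety
cap, charge-balanced asymmetric biphasic pulses, ascending-limits threshold
search), and usage-log summaries.

## Worked example

```sh
fielddrift simulate --seed 42 --out-dir demo       # null cohort: kappa = 0
fielddrift analyze --records demo/field_records.csv --seed 42 --out demo/analysis.json
fielddrift report --analysis demo/analysis.json --usage demo/usage_log.csv
```

prints

```
| participant | n_steps | vs | p | step median (mm) | wear (h/day) | stim (min/day) |
|---|---|---|---|---|---|---|
| P1 | 11 | 0.1160 | 0.9219 | 0.325 | 15.6 | 40.6 |
| P2 | 11 | 0.4047 | 0.2501 | 0.540 | 15.2 | 40.6 |
| P3 | 11 | 0.3985 | 0.3264 | 0.289 | 15.1 | 41.7 |
```

Three simulated participants, 12 mapping sessions each under the
uniform-direction null: all vector strengths are small, every p-value is far
above 0.05 (no spurious drift detected), and median step sizes sit well under
a millimetre — the jitter regime the generator emulates. The usage columns
are the mean daily wear hours and stimulation minutes from the simulated
logs. With directed drift the picture flips:

```sh
fielddrift calibrate --kappa 8 --n-sims 200 --n-mc 1000 --seed 42
# rejection rate at alpha=0.05, kappa=8.0: 1.0000
```

i.e. the test detects strongly concentrated drift in every simulated cohort,
while `--kappa 0` reproduces the nominal 5% false-positive rate.

The same library surface is importable directly (`fielddrift.drift_test`,
`fielddrift.encode_contact`, ...); see `docs/methods.md` for the model
details and design choices.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, by running the installed package on freshly built inputs, the
feedback encoder's published operating points: the pulse frequency at
full-scale and at minimal in-contact sensor readout, and the total
stimulation time delivered during a 10-s sustained contact under the safety
cap. Results are written as JSON to `--out`.
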