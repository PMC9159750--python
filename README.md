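# mtdetect

Detecting scene-relative object motion during self-motion from the conflict
between binocular disparity and motion parallax, with macaque area MT as the
neural substrate. When an observer translates while fixating, a
world-stationary object's depth from motion parallax (d_MP) agrees with its
depth from disparity (d_BD); an object moving through the scene breaks that
agreement, and the conflict ΔDepth = d_MP − d_BD is the only reliable cue to
its motion. MT neurons with *incongruent* depth-sign tuning for the two cues
("opposite" cells) respond selectively to such conflicts, and their activity
predicts perceptual detection.

The package is organised as an analysis project for researchers in systems
and computational neuroscience: a library under `src/mtdetect/` implements
every stage — stimulus geometry, a synthetic MT-population generator,
depth-sign tuning and congruency indices, ideal-observer and
choice-probability metrics, behavioral psychometrics and choice regression,
and correlated-noise pseudo-population decoding — and numbered drivers under
`analysis/` run the stages in order on synthetic data, so the whole chain is
reproducible without any recorded dataset.

## Core quantities

- **DSDI** (depth-sign discrimination index), per tuning curve:
  `DSDI = (1/4) Σᵢ (R_far(i) − R_near(i)) / (|R_far(i) − R_near(i)| + σ_avg(i))`
  over the four symmetric depth pairs; negative = near-preferring.
  `DSDI_dyn` is the same statistic over the three symmetric ΔDepth pairs of
  the dynamic-object responses. Significance by permutation across depths.
- **R_MP_BD**: Pearson correlation of the two 9-point depth-tuning curves;
  its sign (when significant) classifies cells congruent vs opposite.
- **NP** (neurometric performance): mean rank-based ROC area discriminating
  dynamic-in-RF from pooled stationary-in-RF trials over nonzero ΔDepth.
- **DP** (detection probability): choice-sorted ROC area on ambiguous
  (ΔDepth = 0) trials; DP > 0.5 means higher firing predicts a
  "dynamic-in-my-RF" report.
- **Decoding**: pseudo-population responses `r = µ + Q·r_rand∘σ` with noise
  correlations `r_ij = 1.1·(0.5 − |NP_i − NP_j|)` and a linear-discriminant
  readout (90/10 split, ambiguous trials never trained on); sorting
  ambiguous test trials by the decoder's output yields predicted detection
  probabilities (DP_pred).

See `docs/methods.md` for the full model description, parameter defaults,
and numerical conventions.

## Worked example

```bash
python analysis/02_simulate_population.py
python analysis/03_tuning_congruency.py
python analysis/04_choice_probability.py
```

prints, on the default seeded population (100 neurons, 35 repetitions per
condition):

```
population: 100 neurons, 49 opposite, 81 near-preferring for motion parallax
accuracy by ΔDepth:
  -1.53 deg: 100.0 %
  -0.57 deg:  90.0 %
  -0.21 deg:  70.0 %
  +0.00 deg:  51.4 %
  ...
peak response ratio vs R_MP_BD: Spearman R = -0.83 (p = 2.1e-26)
DSDI_dyn vs ΔDSDI:              Spearman R = +0.93 (p = 2.5e-44)
mean NP = 0.608; mean DP = 0.559 (t-test vs 0.5: p = 2.1e-07)
DP vs NP: Spearman R = +0.68 (p = 4e-15)
```

Behavior is at chance for ΔDepth = 0 and saturates with conflict magnitude;
cells whose two depth-tuning curves disagree (negative R_MP_BD) respond
preferentially to dynamic objects (peak response ratio above 1), their
ΔDepth-sign preference follows the difference of their two DSDIs, and the
neurons that prefer dynamic objects (NP > 0.5) are the ones whose firing
predicts the animal's report on ambiguous trials (DP > 0.5).
`analysis/05_behavior.py` shows the choice regression assigning nearly all
weight to |ΔDepth|, and `analysis/06_population_decoding.py` shows the
linear readout reaching ~0.98 accuracy, the correlated-noise simulation
recreating the DP–NP relationship (R ≈ +0.8 vs ≈ +0.2 with independent
noise), and the most conflict-selective tercile out-decoding the least
selective one (0.88 vs 0.76).

The same chain runs end-to-end as a single seeded pipeline:

```python
from mtdetect.io import run_pipeline
manifest = run_pipeline({"seed": 0}, out_dir="results/pipeline")
```

which writes all tables, the five summary figures, and a manifest recording
every derived seed.

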