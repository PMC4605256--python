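# gaitdyn

Phase-dependent local dynamic stability of daily-life walking, from trunk
accelerometry — a reusable, tested analysis pipeline plus a synthetic
cohort generator with known ground truth.

The pipeline consumes continuous triaxial (AP/ML/V) trunk acceleration
recordings sampled at 100 Hz and a cohort manifest (subject id, fall
status), and produces:

* **walking bouts** (≥ 60 s) via an amplitude filter + frequency-domain
  energy filter;
* **preprocessing**: orthogonal-wavelet detrending, intrastep 3D velocity,
  step onsets as vertical-velocity maxima;
* **two 6D state spaces** per bout (differential coordinates
  `[a_AP, a_ML, a_V, v_AP, v_ML, v_V]`, and delayed coordinates over the
  velocity channels with lag 3), with AMI-based lag selection available;
* **phase-dependent local dynamic stability λ** for perturbations at 0, 20,
  40, 60, 80 % of the step cycle — reaction curves ⟨d_i(t)⟩ with
  neighbour-count and stride-time-percentile exclusion rules, and two λ
  definitions (regression slope over the first 10 % of the cycle; log
  ratio at 10 % of the cycle) — plus the conventional per-axis λ_wolf
  (Wolf's algorithm, 6D delay embedding, lag 8);
* **35 conventional gait features** (harmonic ratios, step/stride
  regularity, step symmetry, RMS/range, dominant-frequency shape, timing
  and bout statistics);
* **PLS-DA** (NIPALS, 4 latent variables) with **target projection**:
  per-subject discriminant scores and per-feature TP loadings in [−1, 1]
  that rank each feature's faller/nonfaller discriminant value;
  leave-one-out cross-validated sensitivity/specificity/AUC for the three
  predictor matrices X₁ (46 features), X₂ (38, without phase-λ), X₃
  (8 phase-λ only);
* **test–retest ICC** (two-way absolute agreement, single measures) of the
  phase-λ features over the first vs last third of walking bouts, and
  per-feature Mann–Whitney group comparison.

The synthetic-data module simulates multi-bout recordings with known step
events and a controllable, phase-dependent perturbation contraction rate
that can differ between simulated faller/nonfaller groups; it is the
ground-truth oracle for the test suite.

## Command line

```sh
# simulate a cohort (columnar CSV recordings + truth sidecars + manifest)
gaitdyn simulate --seed 1 --n-per-group 5 --bouts 3 --out cohort/

# detect walking bouts in one recording
gaitdyn detect-bouts cohort/FA001.csv

# full analysis on a recorded cohort
gaitdyn run-all --mode real-data --manifest cohort/manifest.csv --out results/

# full analysis on an in-process synthetic cohort
gaitdyn run-all --mode synthetic --seed 1 --out results/

# PLS-DA on a previously computed feature matrix
gaitdyn discriminate --features-csv results/features.csv \
    --labels-csv cohort/manifest.csv

# summarise a written results bundle
gaitdyn report --results results/
```

A YAML config file (`--config`) can pre-set any module parameter
(`simulate:` and `pipeline:` sections); explicit flags override it.

Outputs are plain text: `features.csv` (subjects × named features),
`lambda.csv`, `tp_loadings.csv`, `group_comparison.csv`, `icc.csv`,
`roc_X*.csv` and `metrics.json`, each stamped with a hash of the
scientific configuration. Reruns with the same config and seed are
byte-identical.

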