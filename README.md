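# eyefatigue

Eye-fatigue assessment for head-mounted-display (HMD) users from
eye-tracking and optometry data, exercised end to end on a calibrated
synthetic cohort.

The pipeline:

1. **synthetic_data** — seeded synthetic cohorts (default 105 subjects × 4
   measurement epochs, active and control arms). Optometry panels (BCC,
   NRA, PRA, PR, PL, LTR, LTL) drift along a latent per-subject fatigue
   trajectory with population means/SDs matched to per-epoch calibration
   constants; 20-s, 75-Hz gaze windows are built as alternating
   fixation–saccade processes with blinks inserted as invalid-sample runs,
   so the downstream detector recovers the generated event statistics.
2. **ssq_scoring** — 16-item simulator-sickness questionnaire scoring
   (unit-weight N/O/D columns, total = column sum × 3.74).
3. **ground_truth** — weighted optometric fatigue `F = Σ wᵢ·indicatorᵢ`
   with reciprocal mean-change weights, per-subject baseline unification,
   equal-step 2/3/4-class discretization, and paired-t trend tests.
4. **gaze_features** — I-DT fixation detection (200 ms minimum duration,
   1° dispersion threshold), blink detection from maximal invalid runs,
   scanpath metrics, and the ten-feature vector
   (NF, DF, MF, VF, BT, DB, MB, VB, SL, ML) with unification.
5. **mrmr** — plug-in mutual information (bits) and greedy
   minimal-redundancy-maximal-relevance ranking; feature sets 1–10 plus the
   fixed blink set.
6. **assessment** — SVM grid (4 kernels × {2,3,4}-class classification,
   ε-SVR and ν-SVR; C = 1; repeated 320/100 holdout) and the two
   deliverable bundles: an *eye tracker* model (set 10) and a *blink
   detector* model (blink set), each producing three graded outputs and one
   continuous output.
7. **pipeline / cli** — one-command orchestration with a reproducibility
   manifest (derived seeds, file digests, stage timings).

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: generator
calibration and pipeline recovery at 3× the simulation SEM, I-DT oracle
equivalence on random streams, MRMR greedy certificates and a
planted-blink-signal construction, mutual-information identities, SVM
protocol sanity, and the SSQ worked examples.

## CLI

```bash
eyefatigue run-all --seed 1 --outdir out/            # full pipeline, both arms
eyefatigue simulate --seed 1 --outdir sim/           # cohort CSV bundle
eyefatigue ssq --responses sim/ssq.csv --out scores.csv
eyefatigue ground-truth --optometry sim/optometry.csv --outdir gt/
eyefatigue features --gaze-dir sim/gaze --outdir feats/
eyefatigue rank --features feats/features_unified.csv \
    --fatigue gt/fatigue.csv --classes 4 --out ranking.json
eyefatigue assess --model out/model_blink_detector.joblib \
    --features '{"BT": 2.1, "DB": 0.6, "MB": 0.05, "VB": 0.001}'
```

All outputs are machine-readable (CSV/JSON/YAML); `manifest.json` records
the config, derived stage seeds, and SHA-256 digests of every artifact, and
reruns with the same seed reproduce identical digests.

## Data formats

- **Gaze CSV** — header `t,x,y,valid`; `t` seconds (6 decimals), `x`/`y`
  pixels, `valid ∈ {0,1}`; invalid rows have empty `x`/`y`.
- **Optometry CSV** — `subject,epoch,arm,BCC,NRA,PRA,PR,PL,LTR,LTL`.
- **SSQ CSV** — `subject,epoch,item_1..item_16`.
- **Feature CSV** — `subject,epoch,NF,DF,MF,VF,BT,DB,MB,VB,SL,ML`.
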