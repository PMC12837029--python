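# mixcal

Space-filling mixture designs and multivariate UV-Vis calibration for
two-component analyses, with a full validation battery.

The toolkit covers the whole workflow for resolving two strongly overlapping
UV absorbers from mixture spectra:

- **designs** — calibration/validation mixture designs: 5-level full
  factorial, Monte Carlo, Latin hypercube, and a self-contained Sobol
  sequence (direction-number / Gray-code implementation, d ≤ 10), plus
  space-filling diagnostics (minimum pairwise distance, grid coverage).
- **spectra_sim** — synthetic two-component spectra from Gaussian band
  libraries with Beer–Lambert mixing, instrument noise and baseline drift;
  preprocessing (trim, mean-center, bin) and a moving-window SNR profile.
- **calibration** — NIPALS PLS2 with leave-one-out latent-variable
  selection, and a single-hidden-layer network trained by
  Levenberg–Marquardt with early stopping (purelin or tansig hidden layer,
  optional PCA input compression).
- **selection** — binary-GA wavelength selection with two fitness
  functions: cross-validated RMSE (GA-PLS) and an information-complexity
  score (ICOMP = −2 log L + 2·C(Σ)).
- **validation** — RMSE/recovery metrics, nested cross-validation with
  bootstrap CIs, Y-randomization, applicability domain (Williams plot),
  pooled t / variance-ratio F comparison statistics, Friedman rank test.
- **greenness** — multi-criteria solvent greenness index and radar tables.
- **workflow_cli** — one-config orchestration of the full
  3-sampler × 3-model comparison experiment with seed derivation and an
  artifact manifest.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (published-table
statistics reproduced exactly, oracle equivalences, linear-limit checks,
parameter recovery, validation-battery behavior).

## CLI

```bash
mixcal design --sampler lhs --n 13 --bounds "AZM=10:30,MPM=10:30" --seed 1 --out design.csv
mixcal design-report --design design.csv --grid 10
mixcal simulate --design design.csv --seed 1 --out spectra.csv --conc-out conc.csv
mixcal fit --model pls --spectra spectra.csv --conc conc.csv --out model.json
mixcal predict --model model.json --spectra new.csv --out pred.csv
mixcal select --fitness icomp --spectra spectra.csv --conc conc.csv --out selection.json
mixcal validate --model model.json --spectra val.csv --conc val_conc.csv --out report.json
mixcal greenness --solvents solvents.yaml --out green.json
mixcal run --config experiment.yaml --out rundir/
```

`mixcal run` executes the end-to-end experiment (factorial calibration →
simulation → PLS/GA-PLS/ANN fits → MC/LHS/Sobol validation sets →
comparison matrix + uniformity reports + Friedman test) and writes a
manifest of artifact hashes; reruns with the same master seed are
byte-identical.

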