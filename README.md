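# honeynir

Chemometric pipeline for portable near-infrared (NIR) analysis of honey:

- **Spectral preprocessing** — log(1/R) conversion, SNV, MSC, detrend,
  SNV-DT and gap-segment derivatives identified by the four-digit
  `d,g,s1,s2` code (treatment strings like `"None 1,4,4,1"` or
  `"SNV-DT 2,8,6,1"`).
- **Calibration** — modified partial least squares (MPLS: per-factor
  residual re-standardization) per physicochemical parameter, with PCA /
  Mahalanobis H-statistic spectral-outlier screening (H > 3), grouped
  cross-validation (SECV/RMSECV), T ≥ 2.5 chemical-outlier elimination,
  treatment-grid model selection (max RSQ, then min SECV), and the usual
  descriptors (N, mean, SD, estimated range, SEC, RSQ, SECV, RPD).
- **External validation** — residuals, RMSE, bias, SEP, SEP(C), paired
  Student test.
- **Discriminant classification** — canonical LDA of botanical honey type
  on physicochemical + main-pollen variables, with eigenvalues, relative
  percentages, canonical correlations, Wilks' lambda chain, Bartlett
  chi-square/DF/p, and resubstitution or leave-one-out confusion matrices.
- **Pollen typing** — frequency classes (predominant / secondary /
  important minor / minor) and rule-based honey-type assignment from
  pollen percentages (plus electrical conductivity for honeydew).
- **Synthetic data** — a seeded generator producing spectra (Gaussian
  constituent bands on a shared matrix background, multiplicative /
  additive / quadratic scatter, replicate-scan averaging), truncated-normal
  reference tables, Dirichlet pollen profiles, labels and a stratified
  84/16 calibration/validation split, so the whole pipeline is testable
  without any external data.

## CLI

```bash
honeynir simulate  --seed 1 --out data/                      # write synthetic CSVs
honeynir calibrate --data data/ --seed 1 --out reports/ \
                   --treatments "None 1,4,4,1;SNV 1,4,4,1"
honeynir validate  --models reports/models --data data/ --out reports/val
honeynir lda       --data data/ --seed 1 --out reports/ [--loo] [--priors equal]
honeynir pollen-type --pollen data/pollen.csv --reference data/reference.csv \
                     --out types.csv
honeynir all       --seed 1 --out run/                       # simulate + calibrate + lda
```

`calibrate` writes a calibration-descriptor table
(`Variable, Math Treatment, N, Mean, SD, Est.Min, Est.Max, SEC, RSQ, SECV, RPD`),
an external-validation table (`Constituent, Mean Residual, RMSE, p`),
per-parameter model JSONs and a removed-sample log; `lda` writes the
discriminant-function diagnostics and confusion-matrix CSVs. Every report
regenerates bit-identically from the same config and seed. A YAML config
may supply any option (CLI flags take precedence).

## Library

```python
import honeynir as hn

ds = hn.generate_dataset(hn.SyntheticConfig(seed=1))
cal = ds.ids_in("calibration")
sel = hn.select_best_model(ds.spectra.subset(cal),
                           ds.reference.loc[cal, "moisture"].to_numpy(),
                           parameter="moisture")
print(sel.best.treatment, sel.best.stats.RSQ, sel.best.stats.RPD)
```

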