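# cassava-gsua

Desk-scale global sensitivity and uncertainty analysis (GSUA) toolkit built
around a mechanistic daily-time-step cassava growth simulator.

The package has three layers:

1. **Crop simulation** — a cohort-based cassava model (`crop_model`) driven by
   thermal time, with Beer-law canopy light interception, radiation-use-
   efficiency assimilation, spill-over allocation to storage roots, leaf
   senescence, and a soil-water drought factor supplied by a tipping-bucket
   water balance (`soil_water`). Daily weather comes from a calibrated
   stochastic generator or DSSAT-style WTH/CSV files (`weather`).
2. **Parameter uncertainty** — the 16 genotype-specific parameters (GSPs) are
   described by truncated parametric distributions (`distributions`, packaged
   catalogue in `data/gsp_distributions.yaml`), with maximum-likelihood
   fitting, AIC ranking, Kolmogorov–Smirnov statistics, and a uniform
   fallback for sparse data.
3. **Sensitivity machinery** — Morris-type elementary-effects screening with
   uniformity-enhanced trajectory selection (`esu_screening`) and
   variance-based Sobol first/total-order indices with bootstrap CIs and
   uncertainty summaries (`sobol_gsua`), orchestrated over four
   environments (cool/warm × rainfed/unlimited) by `pipeline`.

Analytic benchmark functions with closed-form Sobol indices
(`test_functions`) serve as independent oracles.

## CLI

```bash
cassava-gsua gen-weather --site warm --years 30 --seed 11 --out warm.wth
cassava-gsua sample-esu -r 24 --out design.csv
cassava-gsua simulate --params design.csv --site warm --out sims.csv
cassava-gsua analyze-esu --desk --out esu_out/
cassava-gsua analyze-sobol --desk --params NODWT,PARUE,LAXS --out sobol_out/
cassava-gsua report --desk --plots --out report/
```

`--desk` selects the reduced preset (5 years, r=8 trajectories, n=64 Sobol
base samples); omit it for the full-scale protocol (30 years, r=24, n=512).
A YAML config (`--config`) can override any `ExperimentConfig` field.

## Layout

```
src/cassava_gsua/
  distributions.py    truncated distribution families, fitting, K-S/AIC
  gsp.py              packaged GSP distribution catalogue
  weather.py          stochastic generator, WTH/CSV I/O, thermal time
  soil_water.py       tipping-bucket balance, drought stress factor
  crop_model.py       batched daily crop simulator, six season outputs
  esu_screening.py    Morris/eSU designs, elementary effects, selection
  sobol_gsua.py       Sobol designs, index estimators, uncertainty summaries
  test_functions.py   Ishigami / g-function / additive oracles
  pipeline.py         four-treatment experiment orchestration
  cli.py              click-based CLI
  data/               GSP catalogue, site profiles, soil profiles
```
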