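# mortalq

Longitudinal quantile reference curves for frailty trajectories in **mortal
cohorts**: deficit-accumulation Frailty Index construction, stabilized
inverse-probability-of-observation weights, weighted quantile regression,
cluster bootstrap inference, and centile-style reference curves — with a
synthetic cohort generator whose true quantile coefficients are known in
closed form.

## The problem

Ageing panel studies follow older adults every couple of years and measure a
Frailty Index (FI): the proportion of health deficits present out of a fixed
battery of items (FI ∈ [0, 1], typically 40 items, valid when ≥ 35 carry
information). Two features of such panels break naive trajectory models:

* **Death.** Frailer people die sooner. A model that pools all observations
  implicitly describes an "immortal cohort" and understates frailty
  progression, most severely in the upper tail where mortality concentrates.
* **Intermittent missingness and dropout.** Frailer people are also less
  likely to be re-interviewed, so the observed records over-represent the
  healthy.

`mortalq` implements marginal quantile regression of the FI trajectory for
the population alive at each age. For individual *i* at occasion *j* the
τ-quantile model is

    Q_τ(FI_ij | X_ij) = β0τ + βsτ·S_i + βeτ·E_i + βbaτ·BA_i + βaτ·A_ij
                        + βasτ·A_ij·S_i + βaeτ·A_ij·E_i + βabaτ·A_ij·BA_i

with sex S, education E (years, centered at the sample mean), baseline age
BA and current age A (years, centered at 65), and optionally a birth-cohort
indicator Bo (born 1946+) with its age interaction. Fits at τ = 0.1, 0.5,
0.9 trace the low, median and high reference trajectories.

Estimation minimizes the weighted check loss Σ w·ρ_τ(y − Xβ) under an
independence working assumption (an exact linear program; within-person
correlation is handled by the variance step). Each observed record of an
individual alive at occasion *j* ≥ 2 is weighted by the stabilized weight

    w*_ij = P(R_ij=1 | Al_ij=1, X̄_ij) / P(R_ij=1 | Al_ij=1, X̄_ij, FI̅_ik)

— an MCAR-model probability (sex, study-entry indicator) over an MAR-model
probability (additionally the most recent observed FI, an
observed-at-previous-visit indicator, and the lagged-FI × sex interaction),
both logistic regressions pooled over the alive person-waves. Standard
errors come from a bootstrap that resamples individuals (not observations),
B = 200 by default, sharing resample draws across τ so that cross-quantile
coefficient-equality tests are valid.

## Worked example

```python
from mortalq import (SimConfig, simulate_cohort, InverseProbabilityWeighter,
                     fit_all, true_quantile_coefficients, education_offset_years)

cfg = SimConfig(n_individuals=2000, seed=42)   # biennial 6-wave mortal cohort
panel = simulate_cohort(cfg)

weights = InverseProbabilityWeighter().fit_transform(panel)
fits = fit_all(panel, weights=weights, taus=(0.1, 0.5, 0.9))
for tau in (0.1, 0.5, 0.9):
    print(f"tau={tau}: weighted age slope {fits[tau]['age']:.5f} "
          f"(truth {true_quantile_coefficients(cfg, tau)['age']:.5f})")
print(f"education offset at the median: "
      f"{education_offset_years(fits[0.5]):.1f} years")
```

prints

```
tau=0.1: weighted age slope 0.00267 (truth 0.00286)
tau=0.5: weighted age slope 0.00559 (truth 0.00670)
tau=0.9: weighted age slope 0.00948 (truth 0.01054)
education offset at the median: 14.7 years
```

The simulated cohort (21.8% deceased, heavy intermittent missingness) has a
location–scale structure, so the true age slope grows with τ: upper-tail
frailty progresses fastest. The weighted fits recover the slopes despite
frailty-dependent attrition; the unweighted fits underestimate them (compare
`fit_all(panel, taus=...)` without weights). `education_offset_years`
converts the fitted median slopes into an interpretable quantity — how many
additional years of education offset one year of ageing in the median FI
trajectory; e.g. a median age slope of 0.0067 with an age × education
coefficient of −0.0004 implies an offset of 16.75 years.

Inference and curves:

```python
from mortalq import cluster_bootstrap, coefficient_table, curve_bands, CovariateProfile

ens = cluster_bootstrap(panel, taus=(0.1, 0.5, 0.9), B=200, seed=1)
table = coefficient_table(ens)            # estimate / SE / p / cross-tau p per term
prof = CovariateProfile(sex=1, education=9.6)  # female, mean education, entry at 65
curve = curve_bands(ens, prof, tau=0.9)   # reference curve with 95% bands
```

## Command line

```bash
mortalq simulate --seed 1 --out panel.csv          # + truth sidecar + config echo
mortalq build-fi --items raw.csv --spec items.yaml --out fi.csv
mortalq weights --panel panel.csv --out weights.csv
mortalq fit --panel panel.csv --weights weights.csv --out fit.csv
mortalq infer --panel panel.csv --bootstrap 200 --seed 1 --out coef.csv
mortalq curves --panel panel.csv --weights weights.csv --out curves.csv
mortalq run --config pipeline.yaml --out outdir/    # full pipeline + manifest
```

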