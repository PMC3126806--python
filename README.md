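# twinvar

Does an obesity-promoting environment amplify the genetic variation in body
mass index? `twinvar` is a pipeline for answering that question with the
classical twin design: it decomposes BMI variance into additive genetic (A)
and environmental (C/D/E) components within sex × birth-year strata of a
two-wave twin survey, then regresses the per-stratum additive genetic
standard deviation (AGSD) on stratum-level proxies of the obesogenic
environment — obesity prevalence, overweight prevalence, and mean BMI — by
DerSimonian–Laird random-effects meta-regression. A positive proxy
coefficient is the signature of gene–environment interaction: the same gene
pool expressing more variance where the environment is more obesogenic.

The package is aimed at quantitative-genetics and epidemiology researchers
who want a tested, reusable implementation of this two-stage design, and it
ships a synthetic twin-cohort generator so the whole pipeline is testable
without access to any registry data.

## The model

For a twin pair with BMI (x₁, x₂) in one stratum,

    (x₁, x₂) ~ N₂( (μ, μ),  [[σ²A+σ²E, c], [c, σ²A+σ²E]] ),
    c = σ²A (MZ pairs),   c = ½σ²A (same-sex DZ pairs),

fitted by full-information maximum likelihood (twins without a responding
co-twin contribute univariate densities); ACE/ADE/AE/E variants and
likelihood-ratio model selection are provided, with AE forced by default.
Stage two fits, per proxy and per outcome component (A-SD and E-SD),

    AGSD_i = β₀ + β₁·proxy_i + β₂·sex_i + β₃·age_i + β₄·sex_i×proxy_i + β₅·survey_i + u_i + e_i,

with u_i ~ N(0, τ²) (DerSimonian–Laird), e_i ~ N(0, se_i²), and weights
1/(se_i² + τ²). See `docs/methods.md` for the full account.

## Worked example

Generate a synthetic two-wave cohort (164 strata, 150 pairs per stratum,
AGSD rising 0.095 kg/m² per obesity percentage point) and analyze it:

```bash
twinvar simulate --seed 1 --out scratch/sim
twinvar analyze --input scratch/sim/cohort.csv --out scratch/results
```

which prints

```
wrote 41820 records over 164 strata to scratch/sim
obesity_pct: beta=+0.0739, +2.6% of mean AGSD per unit (+25.9% per 10 units)
overweight_pct: beta=+0.0201, +0.7% of mean AGSD per unit (+7.1% per 10 units)
mean_bmi: beta=+0.1575, +5.5% of mean AGSD per unit (+55.2% per 10 units)
results written to scratch/results
```

`scratch/results/` then holds `stratum_table.csv` (one row per stratum:
counts, obesity/overweight prevalence, mean BMI, fitted AGV/AGSD with
standard error, heritability), `meta_table.csv` (the six meta-regression
fits: three proxies × A/E outcomes, estimates and p-values per moderator),
and `run_log.json` (exclusion-flowchart counts and skipped strata). The
obesity coefficient of 0.074 sits below the generating 0.095 because the
regression uses *realized* stratum prevalences, which at 150 pairs/stratum
carry enough estimation noise to attenuate the slope — the errors-in-variables
effect quantified in `docs/methods.md`; the validation study below uses
larger strata precisely to keep it below Monte-Carlo error. The relative
increase lines express each slope as a percentage of the population-mean
AGSD (e.g. a 0.1 kg/m² rise on a mean AGSD of 3 kg/m² is 3.3% per point,
33.3% per 10 points).

The same steps are available as library calls:

```python
import twinvar as tv

cohort, truth = tv.simulate_cohort(tv.GeneratorConfig(seed=1))
result = tv.run_analysis(cohort)
result.meta_results[("obesity_pct", "A")].coef("proxy")
```

`twinvar recover --replicates 20 --seed 1` runs the simulate → analyze loop
repeatedly and reports bias and coverage for the recovered slope, and
`twinvar analyze --overlap-sensitivity` re-runs the analysis with
second-wave pairs that overlap the first wave removed.

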