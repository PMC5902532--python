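# radetriment

**The ICRP 103 radiation-detriment model, computed from cancer-registry data.**

Radiation-protection quantities such as effective dose rest on the ICRP 103
*detriment*: a weighted absolute risk that combines, for each organ or
tissue *T*, a radiation-dependent nominal risk coefficient with a
radiation-*independent* "severity" of the resulting cancer,

```
D_T = R_T · (k_T + (1 − k_T) · q_T) · L_rel,T = R_T · d_T
```

where

- `R_T` — nominal risk coefficient (radiation-induced cancer incidence per
  10,000 persons per Sv), taken as a fixed ICRP constant;
- `k_T` — lethality factor: the ratio of the survival-weighted,
  age-standardized cumulative mortality rate to the corresponding incidence
  rate, `k_T = ᴹP_S,T / ᴵP_S,T`;
- `q_T = q_min + k_T·(1 − q_min)` — loss of quality of life, with the ICRP
  floors `q_min = 0` (skin), `0.2` (thyroid), `0.1` (all other sites);
- `L_rel,T` — relative life lost: the remaining life expectancy at the mean
  age at death from cancer *T*, normalized so its average over the computed
  sites is 1.

The severity components `k`, `q`, `L_rel` are derived from ordinary
registry inputs — per-year, 5-year-age-group counts of deaths and incident
cases plus the population at risk — through a period life table built from
the same year's all-cause mortality. Because diagnosis and treatment
improve over time, these components drift, and with them the detriment,
even though the radiation physics does not change. This package is for
radiation-protection scientists and epidemiologists who want to compute
those components, per-organ and total detriments, and their temporal
trends, from their own registry extracts or from fully synthetic registries
with known ground truth.

## What is in the box

- `demography` — age-specific rates, cumulative rates (direct age
  standardization), period survival functions, remaining life expectancy;
- `lethality` — survival-weighted cumulative mortality/incidence rates and
  site-wise / overall lethality factors;
- `life_lost` — survival-weighted mean age at death, absolute and relative
  life lost;
- `detriment` — quality-of-life weighting, severity, per-organ rows, total
  detriment, severity-vs-lethality curves, and the bundled USA-2012 worked
  example;
- `trends` — per-year pipeline runs, baseline-normalized (percent) series,
  percent declines, and a linear-regression incidence proxy for sites whose
  incidence series must be reconstructed (e.g. non-melanoma skin cancer);
- `synthetic` — a registry generator (Gompertz all-cause hazard,
  exponential age-incidence curves, per-site true lethality, linear secular
  multipliers; expected-value or Poisson counts) so every stage can be
  verified without any data download;
- `DetrimentModel` / `DetrimentResults` — the top-level interface: bind a
  dataset, `fit()`, inspect tidy tables and `summary()`;
- a `radetriment` command-line tool with `simulate`, `compute`, `trends`
  and `worked-example` subcommands.

## Worked example

The bundled reference evaluation (USA, 2012; printed input factors, frozen
gonads/remainder rows from ICRP 103):

```python
from radetriment import usa_2012_detriment_table
print(usa_2012_detriment_table().summary())
```

```
site        ICD-10          R       k       q   L_rel        D
esophagus   C15            15    0.94    0.95    0.95     14.2
stomach     C16            79    0.46    0.51    0.89     51.7
colon       C18            65    0.38    0.44    0.84     35.6
liver       C22            30    0.75    0.78    0.96     27.2
lung        C34           114    0.83    0.85    0.80     88.9
bone        C40-C41         7    0.44    0.50    2.10     10.6
skin        C44          1000    0.00    0.00    0.73      3.4
breast      C50           112    0.16    0.24    1.03     41.7
ovary       C56            11    0.62    0.66    0.93      8.9
bladder     C67            43    0.21    0.29    0.64     12.1
thyroid     C73            33    0.03    0.22    0.85      6.8
bone_marrow C91-C95        42    0.49    0.54    0.95     30.5
gonads      -              20    0.80    0.82    1.32     25.4
remainder   -             144    0.49    0.54    1.03    113.5
total detriment                                         470.6
total detriment: 4.71 % per Sv
```

Each row multiplies the risk coefficient by the severity
`(k + (1−k)q)·L_rel`; the total, 470.6 per 10,000 per Sv (≈ 4.7% per Sv),
is the sum over the 14 organs. Note the structure the numbers reveal: skin
has by far the largest `R` (1000) but a detriment of only ~3.4 because its
lethality is tiny and `q_min = 0`, while lung combines a large `R` with
high lethality into the largest computed detriment.

The same pipeline on a synthetic registry, end to end:

```python
from radetriment import DetrimentModel, TrendSeries, percent_change, synthetic

scenario = synthetic.lethality_decline_scenario()   # 1980–2012, 12 sites,
data = synthetic.generate(scenario)                 # mortality rates ×1.0→0.7
results = DetrimentModel(data).fit()

k = TrendSeries("overall lethality", "1", results.overall_lethality)
D = TrendSeries("total detriment", "per 10,000 per Sv", results.total_detriment)
print(round(percent_change(k, 1980, 2012), 1))      # 30.0
print(round(percent_change(D, 1980, 2012), 1))      # 12.8
```

A 30% linear decline in cancer mortality rates (incidence and all-cause
mortality held fixed) propagates into exactly a 30% decline of the overall
lethality factor but only a ~13% decline of the total detriment: the
quality-of-life floor `q_min`, the unchanged life-lost pattern and the
frozen gonads/remainder rows all damp the effect. This structural
attenuation — detriment falling far more slowly than lethality — is the
model's central behaviour under improving cancer survival.

The same run from the shell:

```sh
radetriment simulate --scenario scenario.yaml --out data/
radetriment compute  --data data/ --out results/
radetriment trends   --results results/ --baseline-year 1980 --out trends/ --plot
radetriment worked-example
```

## Data format

Long CSV, one pair of files per dataset:

- `events.csv`: `year, age_lower, site, kind, count` with
  `kind ∈ {death, incidence}`; all-cause deaths under the sentinel site
  `ALL_CAUSE`;
- `population.csv`: `year, age_lower, population` (mean persons at risk).

Age rows must tile the configured grid (default: 0, 5, …, 85+; the open
top group uses a nominal midpoint of 87.5 years). Validation is strict and
reports the offending line number.

Real registry sources (SEER/CDC, RKI, GEKID, …) are deliberately not
fetched by this package; export your extract into the CSV schema above.
See `docs/methods.md` for the model conventions, assumptions, and known
limitations.
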