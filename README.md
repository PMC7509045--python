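# amubench

Farm-level antimicrobial-usage (AMU) quantification and benchmarking for pig
production. The package computes two families of usage indicators from
electronic treatment-journal records:

- **NT / ATI** — number of treatments and the animal treatment index
  (treatments per animal per year), where one treatment is one application to
  one animal on one day, counted once per active agent;
- **nDDD / nDDD per animal per year** — defined daily doses, i.e. administered
  active-substance mass divided by `ddd (mg/kg/day) × standard weight (kg)`,
  normalized by the yearly animal denominator (animals housed for sows,
  produced for piglets and fatteners).

On top of the indicators it provides percentile benchmarking (flagging the top
5/10/25 % usage farms per age category under either indicator, with
order-independent tie handling) and concordance analysis between the two
indicators: percent agreement and Cohen's Kappa on the high/low
classifications, Spearman's Rho on the continuous values, and Bland–Altman
limits of agreement (mean ± 1.96 × SD of the per-farm differences).

A deterministic synthetic-data generator produces farms, censuses, and
journals with the statistical structure the analysis assumes — including
log-normal dose deviations that make the two indicator families diverge — so
the whole pipeline is testable without any proprietary data.

## CLI

```sh
# generate synthetic inputs (journal.csv, census.csv, catalog.csv, truth.csv)
amubench simulate --seed 1 --out-dir scratch/sim

# inclusion filters with a per-stage reconciliation
amubench validate --journal scratch/sim/journal.csv \
                  --census scratch/sim/census.csv \
                  --catalog scratch/sim/catalog.csv

# per-farm indicator table
amubench compute --journal scratch/sim/journal.csv \
                 --census scratch/sim/census.csv \
                 --catalog scratch/sim/catalog.csv \
                 --out scratch/indicators.csv

# downstream analyses from the indicator table
amubench benchmark --indicators scratch/indicators.csv --out scratch/classifications.csv
amubench agree     --indicators scratch/indicators.csv --out-dir scratch/agree
amubench summarize --indicators scratch/indicators.csv --out scratch/summary.csv

# everything at once (simulated or from files)
amubench run --simulate --seed 1 --out-dir scratch/run
```

`amubench run` writes `indicators.csv`, `summary.csv`, `classifications.csv`,
`agreement.csv`, `correlation.csv`, `bland_altman.csv`,
`bland_altman_limits.csv`, and a `manifest.json` recording the seed, a config
hash, and record counts at every filter stage.

## Input formats

- Journal CSV: `event_id,farm_id,age_category,substance,amount_mg,n_animals,n_days,application_date,entry_date`
  (one row per event × substance; rows sharing `event_id` form one
  combination-product event). Amounts are total mg of active substance for
  the whole event; dates are ISO-8601.
- Census CSV: `farm_id,age_category,animals_per_year,continuous_recording`.
- DDD catalog CSV: `substance,ddd_mg_per_kg,substance_class,long_acting_factor`
  (last column optional; long-acting factors are parsed but disregarded
  unless explicitly enabled).

Age categories: `suckling_piglet`, `weaned_piglet`, `fattening_pig`,
`lactating_sow`, `gestating_sow`, with standard weights 4/12/50/220/220 kg.

Validation filters (all config-exposed): study window (default 2018-10-01 to
2019-09-30), journal entry no later than 7 days after application,
continuous-recording flag in the census, and plausibility caps (group size,
treatment duration, implied per-day dose at most 10 × ddd).

## Synthetic generator

`amubench simulate` (or `amubench.synthetic.generate`) draws herd sizes,
therapy events, substances, and administered amounts from one seed via
per-farm counter-based streams, so adding farms never perturbs existing
farms' draws. `configs/simulate_default.yaml` documents every knob. The
generator also emits `truth.csv` with per-event indicator contributions so
pipeline recovery can be verified exactly.

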