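# Default synthetic-data generator settings.
#
# Herd-size medians follow realistic magnitudes per age category; therapy
# events per farm-year are negative-binomial; administered amounts deviate
# multiplicatively (log-normal) from the catalog's defined daily dose, which
# makes the treatment-based and dose-based indicators diverge. All values
# here equal the built-in defaults; override any subset.

n_fattening: 60
n_breeding: 45
n_farrow_finish: 30
n_sow_pool: 15

herd_medians:
  suckling_piglet: 2200
  weaned_piglet: 2000
  fattening_pig: 1050
  lactating_sow: 22
  gestating_sow: 75
herd_sigma: 0.5            # log-normal dispersion of herd sizes

event_rates:               # mean therapy events per farm-year
  suckling_piglet: 5
  weaned_piglet: 8
  fattening_pig: 4
  lactating_sow: 3
  gestating_sow: 2
event_dispersion: 2.0      # negative-binomial shape (smaller = more overdispersed)

combo_rate: 0.10           # probability an event uses a two-agent combination product
dose_deviation_sigma: 0.3  # log-normal sigma of administered dose vs catalog ddd
weight_deviation_sigma: 0.15  # log-normal sigma of true treated weight vs standard weight
error_rate: 0.0            # fraction of records corrupted (amount x100 or late entry)
entry_lag_mean: 2.0        # Poisson mean of journal-entry lag, clipped to 7 days

window_start: "2018-10-01"
window_end: "2019-09-30"
seed: 0
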