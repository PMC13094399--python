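# heatrisk

Climate-vulnerability screening for dryland species from gridded
maximum-temperature data.

Extreme heat is an escalating threat in arid and semi-arid ecosystems,
and managers need a fast, transparent way to triage which threatened
species face novel heat under future climates before committing to heavy
mechanistic modelling. `heatrisk` implements such a screening framework,
developed around Australia's threatened dryland mammals but applicable
to any taxa with mapped ranges: it compares each species' *baseline heat
envelope* with projected conditions under a scenario ensemble, classifies
heat risk, maps thermal refugia within the historical range, and screens
translocation (release) sites against species thermal maxima. It also
includes the supporting trait-association and literature-tally
statistics, and a synthetic-data generator that builds inputs with
analytically known ground truth so every stage can be verified without
any climate-data download.

## The statistic at the core

For a species *s* with current range polygon `C` and historical range
polygon `H` (with `C ⊆ H` for contracted species), let BIO5 denote the
maximum temperature of the warmest month (°C) from a baseline
climatology. The **heat envelope** for an epoch is the observed range of
BIO5 over the range's grid cells,

    E = [min BIO5, max BIO5],   TM = max BIO5  (the thermal maximum),

and `Δ = TM_hist − TM_curr` measures retreat from the hottest parts of
the historical range. For each of *k* future layers (here 5 GCMs × 3
SSPs = 15 scenarios, mid-century), the **overlap** is the percentage of
current-range cells whose projected BIO5 remains within the envelope
(upper tail: value ≤ TM). With ensemble mean `m` and standard error
`SE = SD/√k`, species are classified using the conservative lower bounds
`m − SE`:

* **low risk** — > 50 % overlap with both the current and historical envelope;
* **moderate risk** — > 50 % with the historical envelope only;
* **high risk** — neither (novel heat relative to both envelopes).

A species is moved up one tier when the SE band crosses a criterion
(`upgraded = True`). Refugia maps classify every historical-range cell by
whether its projected BIO5 stays at or below `TM_hist` under *all*,
*some* or *no* scenarios; site screening compares each release site's
projected BIO5 (per-site mildest, mean and most extreme scenario) against
both thermal maxima.

## Worked example

Generate a synthetic bundle (one species per tier) and run the full
pipeline:

```python
from heatrisk import RunConfig, run_screening, simulate_bundle

bundle = simulate_bundle("demo/inputs", seed=42, n_per_tier=1)
cfg = RunConfig(baseline=bundle["baseline"], futures=bundle["futures"],
                ranges=bundle["ranges"], sites=bundle["sites"],
                traits=bundle["traits"], studies=bundle["studies"],
                out="demo/out", seed=42)
outputs = run_screening(cfg)
```

`demo/out/risk.csv` then contains (rounded):

```
   species_id     tier  upgraded  mean_current  se_current  mean_historical  se_historical  delta_tm
    sp_high_1     high     False            30           0            38.61           5.46       0.5
     sp_low_1      low     False            80           0            90.00           2.55       2.0
sp_moderate_1 moderate     False            30           0            80.00           8.12       2.5
```

Each generated species was constructed to hit those overlap targets, so
the low-risk species keeps 80 %/90 % of its current range within its
current/historical envelope across the ensemble, the moderate-risk
species is sheltered only by its historical envelope (mean 80 %, but
30 % against its current envelope), and the high-risk species falls
below 50 % against both. `refugia_fractions.csv` gives the share of each
historical range remaining below the historical TM under all/some/no
scenarios (e.g. 0.490/0.480/0.030 for the high-risk species), and
`site_summary.csv` reports the percentage of release sites projected
above each TM under the mild/mean/extreme scenario (e.g. 66.7 % of the
high-risk species' sites exceed its current TM under the ensemble mean).
The same pipeline is available from the shell via `heatrisk simulate`,
`heatrisk run --config cfg.yaml`, and per-stage subcommands
(`envelopes`, `classify`, `refugia`, `sites`, `traits`).

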