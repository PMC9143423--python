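# riverflux

Analysis pipeline for monthly river contaminant monitoring campaigns:
pharmaceutical and illicit-drug concentrations measured alongside river
discharge at a network of stations, turned into contaminant **mass flows**
(fluxes), summarised by an intervention-period **loss factor** and explored
with **PCA** pattern tables. It was built around campaigns that bracket the
COVID-19 lockdowns — 12 stations on two rivers (Sava and Drava), 16 monthly
samples, 18 compounds in 8 therapeutic categories — but every piece
(registries, calendar, panels) is configurable.

It is aimed at environmental chemists and wastewater-based-epidemiology
analysts who have long-format concentration/discharge tables and want a
tested, reproducible route from raw CSVs to loss tables and score plots.

## The statistics at the core

**Mass flow.** For concentration $c$ (ng/L) and discharge $Q$ (m³/s) the
contaminant mass flow is $L = c\,Q$, in µg/s (the unit identity
1 ng/L × 1 m³/s = 1 µg/s makes the plain product the answer). Expressing
results as flux removes the influence of river-flow variation on measured
concentrations.

**Censoring.** Observations below an analyte's limit of quantification
(LOQ, 0.2–0.9 ng/L here) are left-censored; they are carried as an explicit
`<LOQ` marker and substituted by LOQ/10 (configurable) in one visible step.

**Loss factor.** With campaign months split into pooled lockdown (LCK) and
out-of-lockdown (OOL) strata, each station $i$ contributes the ratio of its
period-average mass flows, and for each analyte

$$F \;=\; \frac{1}{N}\sum_{i=1}^{N} \frac{L_i(\mathrm{OOL})}{L_i(\mathrm{LCK})},$$

with the sample standard deviation of the per-station ratios as dispersion.
$F \ge 1.5$ flags a substantial loss during lockdowns; $F \ge 2$ means the
flux more than halved.

**Patterns.** Station × month and category × month total-flux matrices are
column-centred and decomposed by PCA; scores expose river splits and
groups of co-varying categories. Group assignment is deliberately left to
the analyst — the package emits scores, loadings, explained-variance
fractions and a score-distance matrix.

Because the original campaign's raw data was never publicly released, the
package ships a synthetic-campaign generator (`riverflux.simulate`) with
the same statistical structure — log-normal concentrations with per-analyte
multiplicative lockdown suppression, seasonal discharge, LOQ censoring —
which backs the whole test suite and makes every stage verifiable.

## Worked example

```python
import riverflux as rf

dataset, truth = rf.simulate(rf.SimulationConfig(seed=1))   # study-shaped campaign
flows = rf.compute_mass_flows(rf.align(dataset))            # impute <LOQ, join discharge
table = rf.factor_table(flows)                              # per-analyte loss factors
print(table.head(6).round(2).to_string(index=False))
```

```
                analyte river    f  stdev  n_sites  substantial_loss  halved
            Venlafaxine Drava 4.30   0.78        5              True    True
            Venlafaxine  Sava 3.40   0.56        7              True    True
4-Formylaminoantipyrine  Sava 2.75   0.36        7              True    True
 O-Desmethylvenlafaxine Drava 2.45   0.62        5              True    True
               Cotinine Drava 2.40   0.54        5              True    True
               Cotinine  Sava 2.10   0.40        7              True    True
```

Each row is one analyte on one river: `f` is the mean over stations of the
OOL/LCK flux ratio (venlafaxine's flux during lockdowns dropped more than
four-fold on the Drava in this draw), `stdev` its across-station spread,
and the flags mark the 1.5 and 2.0 thresholds. The generator injected
per-analyte multipliers matching the published loss factors, and the
pipeline recovers them.

```python
matrix = rf.build_site_matrix(flows, dataset.sites,
                              months=dataset.calendar.campaign_months())
res = rf.pca(matrix, n_components=2)
print("PC1 %.1f%%  PC2 %.1f%%" % tuple(100 * res.explained_variance_fraction))
```

```
PC1 87.1%  PC2 6.2%
```

The first two components carry most of the between-station variance; the
scores (`res.scores`) separate the two rivers and the upstream/downstream
halves of the larger one.

The same pipeline runs from the shell:

```sh
riverflux run --simulate --seed 1 --out results/        # or --conc/--flows/... CSVs
riverflux simulate --seed 1 --out fixture/              # write a synthetic CSV campaign
riverflux factors --conc c.csv --flows q.csv --analytes a.csv --sites s.csv
```

`run` writes the mass-flow table, river/category aggregate series, pooled
and per-lockdown factor tables, PCA scores/loadings/distances, and a JSON
summary stamped with the configuration hash.

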