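# pppflux

Stable-isotope tracing analysis of pentose phosphate pathway (PPP) branch
fluxes from 1,2-¹³C₂ glucose labelling time courses.

## The problem

When cells are fed a 1:1 mixture of 1,2-¹³C₂ glucose and natural glucose,
the two PPP branches write distinguishable mass signatures into ribulose
5-phosphate (Ru5P): the oxidative branch releases the labelled C1 as CO₂ and
produces **singly labelled (m1) Ru5P**, while the non-oxidative branch
reassembles pentoses from F6P/GAP fragments that retain both labels,
producing **doubly labelled (m2) Ru5P**. Fitting the accumulation of each
isotopologue over a short (0–900 s) time course therefore yields separate
flux surrogates for the two branches — the approach used to show that
silencing 6PGD (or its upstream regulators AR and SREBP1) suppresses
oxidative PPP flux in prostate cancer cells.

`pppflux` provides, for analysts working with such tracing data:

- **Isotopologue pre-processing** — normalisation of ion-count intensities
  to mass-isotopologue distributions (MIDs), natural-abundance correction via
  a binomial convolution matrix solved as nonnegative least squares, and
  mean-enrichment summaries.
- **A forward labelling simulator** — label propagation through G6P, F6P,
  GAP and Ru5P pools under steady-state metabolism with the tracer-specific
  atom-transition rules, used both as a synthetic-data generator (control +
  knockdown scenarios, replicate noise) and to reason about experiment design.
- **CSTR turnover inference** — each pool behaves as a continuous
  stirred-tank reactor, so an isotopologue fraction follows
  `m(t) = m_max · (1 − e^(−D·t)) + m_initial`, where `D` (s⁻¹) is the pool's
  dilution (turnover) rate. `D` is estimated by bounded multi-start least
  squares; its uncertainty by a least-squares Monte Carlo (parametric
  bootstrap over per-timepoint replicate noise, default n = 1000 draws).
- **Empirical hypothesis tests** — paired draw differences give the
  one-sided empirical p-value `p = (r + 1)/(n + 1)` against
  H₀: D_treatment − D_control ≥ 0.
- **A pipeline CLI** — `pppflux simulate | correct | qc | fit | compare |
  run`, TOML configuration, run manifests, long-format CSV throughout.

## Worked example

Simulate the default experiment (control plus 6PGD-, AR- and SREBP1-like
knockdowns, 7 time points, triplicates) and run the full pipeline:

```bash
pppflux run --out-dir ppprun --n-draws 100 --seed 4
```

which prints the comparison report (also written to `ppprun/comparison.csv`):

```
condition metabolite isotopologue    D_hat  D_ci_low  D_ci_high   r     n  p_empirical
    siCon       Ru5P           m1 0.015482  0.014348   0.016816 NaN   NaN          NaN
    siCon       Ru5P           m2 0.001594  0.001213   0.002006 NaN   NaN          NaN
   si6PGD       Ru5P           m1 0.010855  0.009982   0.011751 0.0 100.0     0.009901
   si6PGD       Ru5P           m2 0.001264  0.001145   0.001367 4.0 100.0     0.049505
     siAR       Ru5P           m1 0.007721  0.007099   0.008544 0.0 100.0     0.009901
     siAR       Ru5P           m2 0.000746  0.000433   0.001176 0.0 100.0     0.009901
 siSREBP1       Ru5P           m1 0.007191  0.006816   0.007645 0.0 100.0     0.009901
 siSREBP1       Ru5P           m2 0.000805  0.000364   0.001223 1.0 100.0     0.019802
```

Read it as follows: `D_hat` is the fitted dilution rate of the Ru5P
isotopologue (s⁻¹) with a 95 % Monte Carlo draw interval; `r` counts paired
draws in which the knockdown rate was not below control, and `p_empirical =
(r+1)/(n+1)`. The oxidative readout (m1) drops in every knockdown and its p
sits at the attainable floor, while the non-oxidative readout (m2) is
clearly reduced only when both branches are scaled down (siAR/siSREBP1) —
the branch-specific pattern the tracer is designed to resolve. The
steady-state QC stage (written to `ppprun/qc_steady_state.csv`) confirms all
conditions reached the same G6P enrichment (≈ 1/6 for a 1:1 spike), e.g.

```
condition  enrichment_mean  enrichment_sd  n_replicates  abs_diff_vs_control  flagged
    siCon         0.166878       0.002048             3             0.000000    False
   si6PGD         0.162847       0.001237             3             0.004032    False
```

so branch fluxes can be compared across conditions without enrichment-bias
correction.

To analyse your own measurements, point the pipeline at a long-format CSV
(`condition, replicate, metabolite, n_carbons, mass_shift, time_s, value,
value_type`) via a TOML config with `input_path`, or call
`pppflux.compare_all` / `pppflux.monte_carlo_fit` directly.

## Layout

- `src/pppflux/isotope.py` — MID types, normalisation, natural-abundance
  correction, enrichment.
- `src/pppflux/simulate.py` — tracer/network configuration, labelling ODEs,
  steady states, experiment generator.
- `src/pppflux/cstr.py` — CSTR model, least-squares Monte Carlo,
  empirical p-values, comparison reports.
- `src/pppflux/io.py`, `src/pppflux/pipeline.py`, `src/pppflux/cli.py` —
  CSV/TOML I/O, QC, orchestration, CLI.
- `docs/methods.md` — model assumptions, parameter choices, numerical
  details and limitations.
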