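# founderage

Dating a founder mutation from the decay of linkage disequilibrium (LD)
across short tandem repeat (STR) markers flanking the disease locus, plus
the demographic and prevalence arithmetic that accompanies such an analysis.

The package provides:

* **haplotype_io** — data model and TSV/PED-MAP readers and writers for
  marker maps and phased carrier/control STR haplotypes; a packaged
  8-marker map and its published per-marker LD index values.
* **ld_stats** — group allele frequencies, ancestral-haplotype inference
  (modal allele with a near-tie rule that can yield two-allele states),
  the Bengtsson–Thomson LD index δ = (p_D − p_N)/(1 − p_N), and observed
  ancestral-allele proportions.
* **age_moment** — two moment estimators of allele age: the closed form
  g = ln δ / ln(1 − θ), and a mutation-corrected Markov iteration
  K = θR + μM + (1 − θ − μ)I run until the observed ancestral proportion is
  reached; genetic-distance conversions (linear / Haldane / Kosambi,
  cM/Mb factor) and per-marker aggregation into mean ± SD, years, and a
  calendar date.
* **mrca_inference** — likelihood estimation of generations to the most
  recent common ancestor from per-chromosome first-discordance positions,
  with a profile-likelihood 95% interval, and a Bayesian posterior with a
  uniform or exponential-growth prior. Two per-side likelihoods are
  provided: the exact nested single-crossover model (default) and a
  simpler marker-independent composite.
* **demography_epi** — exponential growth rate r = ln(T1/T0)/g,
  generations→years→calendar conversions, carrier frequencies with exact
  (Clopper–Pearson) intervals, projections, and 2×2 association statistics.
* **synthetic_data** — a forward-in-time star-genealogy simulator
  (nested recombination per side, stepwise ±1 STR mutation, control
  chromosomes from configurable allele frequencies) and a parameter-recovery
  harness reporting bias, RMSE and interval coverage.
* **cli** — a `founderage` command wiring files to the modules, with a
  reproducibility manifest written next to every output.

## CLI

```sh
founderage convert    --in cohort.ped --map markers.tsv --out cohort.tsv
founderage delta      --hap cohort.tsv --map markers.tsv --out delta.tsv
founderage age        --method risch --delta delta.tsv --map markers.tsv --out age.json
founderage age        --method markov --hap cohort.tsv --map markers.tsv --out age.json
founderage simulate   --config sim.yaml --out sim.tsv
founderage recover    --config recover.yaml --out report.tsv
founderage prevalence --count 11 --n 402
founderage date       --g 13 --years-per-gen 25 --anchor 1990
```

Marker maps are TSVs with columns `marker side dist_cM repeat_unit mu`
(side is `proximal` or `distal` relative to the mutation). Haplotypes are
wide TSVs with columns `chrom_id family_id group independent` followed by
one integer repeat-number column per marker (`NA` for missing). PED/MAP
input is accepted but **assumed phased** — each individual's two allele
columns per locus become two chromosome records. Simulation YAML configs
take `g_true`, `map` (path to a marker TSV), `founder` (marker → allele),
optional `control_freqs`, `n_carriers`, `n_controls`, `seed`; recovery
configs add `g_true_values`, `estimators`, `n_replicates`.

## Notes on conventions

* The linear map function θ = cM/100 is the default and is applied as-is
  even beyond 0.5 (a warning is logged); this is the convention under
  which the packaged δ table reproduces the published moment summary.
* Per-marker ages aggregate with the sample SD (n − 1 denominator).
* Elapsed years are rounded to an integer before the calendar subtraction,
  so years and dates are always consistent.
* The MRCA likelihood defaults to the nested single-crossover model, which
  is exact for the simulator's (and the estimators' implied) star
  genealogy; the composite marker-independent variant is available via
  `likelihood="composite"` but underestimates larger ages.
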