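# ssrpipe

A toolkit for the computational side of microsatellite (SSR) marker
development in non-model organisms — written around the workflow used to
develop markers for the invasive zebra mussel from shotgun-assembled
contigs. It covers every desk stage of such a campaign:

1. **Mining** — detect maximal perfect tandem repeats (periods 2–5,
   homopolymers excluded) in assembled contigs, and merge neighbouring
   tracts separated by < 100 bp into compound loci.
2. **Pruning** — keep Potential Amplifiable Loci (PAL): ≥ 5 repeat units in
   some component, ≥ 30 bp flanks, and a feasible primer pair (GC, Tm,
   amplicon size-bin constraints, with the universal 19-nt genotyping tail).
3. **Characterization** — per-locus A, Ho, Nei's unbiased Hs, PIC, the
   Hardy–Weinberg exact probability test (Levene's conditional
   distribution, enumerated or Monte Carlo), genotypic LD permutation
   tests, Chakraborty / Brookfield-1 null-allele estimators, rarefied
   allelic richness, and Benjamini–Yekutieli FDR correction.
4. **Structure** — Weir–Cockerham θ (global, per locus, pairwise with
   permutation significance), three-level AMOVA with Φ statistics, and a
   STRUCTURE-style admixture Gibbs sampler with ln P(D)-based selection
   of K.
5. **Yield accounting** — phase percentages, the polymorphic yield
   (polymorphic loci / PAL loci), and the validation effort
   `median markers ÷ yield` for downstream applications.

A synthetic-data module generates (a) contigs with planted SSR tracts and a
ground-truth table over repeat-sanitized background, and (b)
multi-population diploid genotypes under the Balding–Nichols island model
with controllable F_ST and null-allele rates — so the whole pipeline is
testable without any sequence download. See `docs/methods.md` for the
models and conventions.

## Worked example

```python
from ssrpipe import PhaseCounts, phase_summary, effort_table

report = phase_summary(PhaseCounts(288, 93, 81, 14))
print(report.summary())
print(effort_table({"population_genetics": 7, "genetic_mapping": 209},
                   report.polymorphic_yield / 100).to_string(index=False))
```

prints

```
initial SSRs:        288
PAL:                 93 (32.29%)
PCR positive:        81 (28.13%)
polymorphic:         14 (4.86%)
polymorphic yield:   15.05% of PAL

        application  median_markers  required_initial_ssr
population_genetics               7                 46.51
    genetic_mapping             209               1388.70
```

Reading: of 288 mined SSRs, 93 (32.29%) survived pruning to PAL, 81
amplified, and 14 were polymorphic, a polymorphic yield of 14/93 = 15.05%.
At that yield, a population-genetics panel (median 7 markers) requires
about 47 initial candidate loci; a genetic-mapping panel (median 209)
requires about 1 389.

The same stages are available from the shell; a full synthetic demo run is

```bash
ssrpipe run --out-dir demo_out --seed 7 --structure-reps 1000
# pipeline done: 5 SSRs, 5 PAL, theta=0.0424, K*=1; outputs in demo_out
```

which writes the mined-locus, PAL, primer, per-locus statistics, pairwise
F_ST, AMOVA, ln P(D) and yield tables plus a manifest of every per-stage
seed. Individual subcommands: `simulate genome`, `simulate genotypes`,
`mine`, `pal`, `primers`, `stats`, `fst`, `amova`, `structure`, `yield`.

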