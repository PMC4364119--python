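# Methods

`ssrpipe` implements the computational side of a microsatellite (SSR) marker
development campaign: mining tandem repeats from assembled contigs, pruning
them to Potential Amplifiable Loci (PAL), screening primer feasibility,
characterizing genotyped markers with population-genetics statistics, and
quantifying the campaign's polymorphic yield and the validation effort
implied by it. This note records the models, the defaults and why they were
chosen, the numerical conventions, and what the synthetic test bed does and
does not show.

## SSR detection

The detector reports **maximal perfect tandem tracts**: runs `s[i:j]` with
`s[k] == s[k+p]` for all `k` in `[i, j-p)` that can be extended in neither
direction. Each tract is reported once, under its **primitive period** — the
motif (first full unit) must not be a whole-number power of a shorter word,
which also prevents a tract from surfacing under rotated or doubled motifs.
By Fine and Wilf's periodicity theorem, a tract of at least two full units
that also carries a shorter period has a non-primitive first unit, so the
primitivity test on the motif is sufficient. `N` never matches any base, so
tracts cannot cross ambiguous positions.

Defaults: periods 2–5 (homopolymer lengths are unreliable on pyrosequencing
platforms and are excluded; hexanucleotides fall outside the cap), at least
5 full repeat units, and a 15 bp floor on tract span. The length floor is
the translation of a score-threshold screen for perfect repeats where each
aligned base scores 2, so a score threshold of 30 corresponds to 15 bp.
Partial trailing units extend the span but do not count toward the unit
tally. For perfect repeats this detector is deterministic and exactly
verifiable against an exhaustive oracle; it does not attempt imperfect or
degenerate repeats, which is the main respect in which it is narrower than
stochastic-alignment repeat finders.

Neighbouring tracts on one contig separated by **strictly less than 100 bp**
chain transitively into one *compound* locus; component order is positional.
Overlapping spans are refused rather than merged: interleaved tracts of
different periods cannot form a well-ordered compound and essentially do not
arise outside adversarial sequences.

PAL pruning keeps a locus when (a) **some** component has ≥ 5 full units —
the per-component reading, chosen because published compound loci with one
long and one short component are routinely accepted; (b) both flanks
(measured to the contig ends) are ≥ 30 bp; and (c) the primer gate passes.
Every rejected locus is logged with the first rule that removed it.
Compound loci are tabulated by their first component's period.

## Primer feasibility

The gate scans 18–27 nt windows in the left flank (forward) and the
reverse-complemented right flank (reverse), requiring GC in [40%, 60%], a
Wallace-rule melting temperature (2·(A+T) + 4·(G+C) °C) in [50, 65] °C, no
mononucleotide run of 4+, a G/C 3' terminus, no `N`, pair ΔTm ≤ 5 °C, and an
amplicon (inclusive of both primers, containing the whole tract) inside one
of three multiplex-friendly bins: 100–150, 200–300, 350–450 bp. Bins are
preferred smallest-first (shorter amplicons genotype more reliably); among
feasible pairs the choice is minimal ΔTm, then shorter amplicon, then
leftmost forward start — fully deterministic. Forward primers carry the
19-nt universal tail `CACGACGTTGTAAAACGAC` for dye-labelled three-primer
genotyping. The Wallace rule was chosen over nearest-neighbour
thermodynamics because it is closed-form and adequate for a feasibility
gate; the constraint set is a conventional design default, and the gate is a
screening device, not a replacement for a thermodynamic design tool.
Feasibility is monotone: relaxing any single constraint can only grow the
feasible set.

## Synthetic data

`generate_genome` plants specified tracts (optionally compound) into i.i.d.
uniform background DNA and then *repeat-sanitizes* the background: any
tract of period 1–5 that a slightly-permissive detector (≥ 4 units or ≥ 8
bp) would report, and that is not a planted span, is re-sampled (planted
bases are never touched, and boundary bases that would extend a plant are
re-sampled too). Detection on these genomes therefore has an exact truth
set, and recall/precision can be scored at 100%/100%. What this does *not*
emulate: real flank sequence composition, imperfect repeats, assembly
artefacts, or the genome-wide repeat density of a real mollusc assembly —
passing tests show detector correctness, not field performance on 454
contigs.

`generate_genotypes` draws multi-population diploid genotypes from the
Balding–Nichols island model: per locus, ancestral frequencies `p ~
Dirichlet(1, …, 1)` and population frequencies `~ Dirichlet(p·(1−F)/F)`, so
`F` is the expected Weir–Cockerham differentiation (at `F = 0` the
ancestral frequencies are copied exactly). Genotypes are two independent
gametes; with probability `null_rate` a gamete is a null allele — two nulls
give missing data (amplification failure), one null records the individual
as homozygous for the visible allele, the classic cause of heterozygote
deficit. Allele "sizes" are `100 + 2·index` bp, a dinucleotide-like ladder,
so GenePop size coding is exercised. Default design: 6 populations × 8
diploids × 14 loci in two groups ("basins"), mirroring a small-scale marker
validation survey. The model has no mutation process, no linkage (loci are
unlinked by construction) and exchangeable populations — it supports
estimator calibration, not demographic realism.

## Per-locus statistics

* Expected heterozygosity uses **Nei's unbiased estimator**
  `Hs = 2n/(2n−1)·(1 − Σp²)`; with 8 diploids per site the small-sample
  correction is material.
* `PIC = 1 − Σp² − Σ_{i<j} 2 p_i² p_j²` (computed as
  `1 − Σp² − ((Σp²)² − Σp⁴)`).
* The **HWE exact test** is the two-sided probability test on Levene's
  conditional distribution of genotype arrays given allele counts:
  `P = n!·Πa_i!·2^H / ((2n)!·Πn_ij!)`, p = Σ of probabilities of arrays no
  more probable than the observed one. Arrays are enumerated when at most
  10⁶ exist (recursion over allele pairings); otherwise Monte Carlo samples
  arrays by randomly pairing the 2n gene copies, with the `(1+b)/(1+reps)`
  estimator, 100 000 replicates by default, seed-deterministic. Probability
  ties are compared with a 10⁻⁹ log-scale tolerance.
* **Linkage disequilibrium**: summed G statistic over per-population
  two-locus genotype contingency tables; null by permuting one locus's
  genotypes among individuals within populations (10 000 permutations
  default).
* **Null alleles**: Chakraborty `(Hs−Ho)/(Hs+Ho)` and Brookfield-1
  `(Hs−Ho)/(1+Hs)`; non-positive estimates are reported as 0 with an
  explicit no-evidence flag. "Null alleles present" is operationalized as
  Brookfield-1 > 0 together with an HWE deficit at p < 0.05. Under the
  generator's null mechanism, Chakraborty is approximately unbiased for the
  null frequency while Brookfield-1 is conservative (≈ 0.14 at a true rate
  of 0.2 with highly heterozygous loci), which the recovery tolerance of
  ±0.07 reflects.
* **Allelic richness** by hypergeometric rarefaction,
  `Ar(g) = Σ_i [1 − C(N−N_i, g)/C(N, g)]`; `Ar(N) = A`, `Ar(1) = 1`.
* Multiple testing uses **Benjamini–Yekutieli** step-up FDR (valid under
  arbitrary dependence), delegated to `statsmodels`.
* Monomorphic-locus conventions: HWE p = 1, LD p = 1, PIC = 0, Hs = 0.

## Population structure

**Weir–Cockerham θ** is computed from the a/b/c variance components per
allele and locus, aggregated as a ratio of sums over alleles and loci (the
estimator's recommended aggregation). Pairwise θ significance permutes
whole individuals between the two populations; p-values are BY-adjusted
across pairs. On Balding–Nichols data the multilocus estimate recovers the
generating F within ±0.01 at 8 × 50 × 100 scale.

**AMOVA** uses 0/1 allele-identity distances between gene copies
(microsatellite size is not treated as additive). Per set of gene copies,
`SS = (n² − Σc_u²)/(2n)` per locus; three-level SSDs follow from within-
population, within-group and total SS, with the standard unequal-size
coefficients for the variance components; with a single group the
decomposition collapses to two levels. Negative variance components are
reported as computed and clamped only for the percentage display, with a
flag. Permutation schemes per level: gene copies among all populations
(Φ_ST), gene copies among populations within groups (Φ_SC), whole
populations among groups (Φ_CT). Multi-locus data are handled per locus
and summed.

**Admixture clustering** (`AdmixtureModel(...).fit()` → `StructureResult`)
is a Gibbs sampler over latent origins `z` of each allele copy: cluster
allele frequencies `~ Dirichlet(λ + counts)`, individual admixture `~
Dirichlet(α + origin counts)`, `z ~ categorical ∝ q_k·p_k(allele)`. α = 1
and λ = 1 are fixed — the independent-frequency model with no ancestry
hyperprior updating. `ln P(D)` is estimated as `mean(lnL) − var(lnL)/2`
over post-burn-in sweeps; label switching is resolved at reporting time by
greedy matching of q columns against the first post-burn-in sweep (the
ln P(D) estimate is label-invariant). Defaults are 2 000 burn-in / 10 000
sweeps, a desk-scale chain length exposed as flags; at the tested problem
sizes the ln P(D) ranking across K is stable well before this length.
`select_k` applies a parsimony rule: the smallest K within 2 ln-units of
the best `ln P(D)`. Because α is fixed at 1, posterior admixture is
shrunk toward uniform by one pseudo-count per cluster; with 30 loci at
F = 0.25 the mean max-q for two clean populations sits near 0.90–0.91,
which the recovery check measures on a 3-replicate aggregate.

## Yield and validation effort

Phase percentages are `100·count/n_initial`. The **polymorphic yield** is
polymorphic loci / PAL loci — the denominator is the PAL count, the reading
under which the published counts (14 of 93 → 15.05%) are internally
consistent; the alternative denominator (loci that amplified, 81) does not
reproduce the printed yield and is not used. **Validation effort** for an
application is its median marker requirement divided by the yield fraction.
Descriptive statistics use the sample (n−1) standard deviation. All
internal arithmetic is full-precision; reporting rounds half-up to 2
decimals.

## Determinism and problem sizes

Every stochastic routine takes an explicit seed; the CLI derives per-stage
seeds from one global seed plus a stable stage label, so adding a stage
never perturbs earlier stages, and reruns are byte-identical. Test and
acceptance problem sizes (10 kb oracle sequences, 20 θ replicates at
8 × 50 × 100, 3 admixture replicates at 2 × 30 × 30, 1 000–2 000 HWE
replicates) were chosen as the smallest scales at which the simulation
noise is comfortably inside each criterion's tolerance.

## Known limitations

Perfect repeats only; Wallace-rule Tm with no dimer/hairpin or specificity
(BLAST) screening; no correlated-allele-frequency prior, LOCPRIOR or ΔK
heuristic in the admixture module; AMOVA offers the 0/1 distance only (no
R_ST / stepwise-mutation variant); null-allele handling covers the two
closed-form estimators, not stutter or large-allele dropout diagnostics;
sequencing reads and assembly are upstream of scope — contigs are inputs.
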