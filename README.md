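# clonesplice

Analysis toolkit for **co-resident spliceosome-mutant clones** in clonal
hematopoiesis, built around the situation where two independent *SF3B1*-mutant
clones share one bone marrow: it quantifies their competition from
longitudinal VAF measurements, reconstructs their phylogenies from
single-cell-derived colony genotypes, dates when each driver mutation was
acquired, and performs genotype-aware cryptic-splicing (PSI/dPSI) analysis of
single-cell junction counts. A synthetic-data generator with full ground
truth makes every stage runnable and testable without any external data.

Intended users: computational hematologists and methodologists working on
clonal dynamics, somatic phylogenies, or spliceosome-mutant mis-splicing who
want the whole chain — generator, estimators, filters — as an importable,
tested library.

## Models

**Clonal competition.** Mutant clone fractions `f_i` evolve by replicator
(multi-type logistic) dynamics against an implicit wild-type population with
selection coefficient 0:

```
df_i/dt = f_i (s_i − Σ_j f_j s_j),   f_i(t) = f_i(0) e^{s_i t} / (f_wt(0) + Σ_j f_j(0) e^{s_j t})
```

`s_i` is clone *i*'s fitness advantage per year. A heterozygous diploid
variant is observed at VAF `f_i/2` through binomial ddPCR droplet sampling.
The fit inverts exactly this generative model by least squares, with
seeded parametric-bootstrap standard errors.

**Colony enrichment.** With bulk VAF `v`, the expected mutant-cell fraction
among colonies is `min(1, 2v)`; `k` mutant colonies of `n` are tested with
the exact binomial tail (two-sided = 2×min(tails), capped at 1).

**Molecular clock.** Colony mutation burdens follow `Poisson(rate × age)`;
the rate MLE is `Σ burden / Σ age` with an exact (Garwood) profile CI. On a
perfect phylogeny (nested/disjoint variant carrier sets; violations of the
three-gamete condition are an explicit error), a driver acquired on a branch
with `m_before` mutations above it and `m_through` through its end is dated
to `[m_before, m_through]/rate` years, with 95% bounds from exact Poisson
count intervals, clamped to the age at sampling.

**Splicing.** PSI = `100 × inclusion / (inclusion + exclusion)` junction
reads per pseudobulk genotype group (missing below a coverage threshold);
dPSI = clone PSI − mean of per-donor control PSIs. Events are classified
geometrically (SE, A3SS, A5SS, RI via an intron-coverage proxy, MXE), then
filtered: *common* if both clones' |dPSI| > 2 (same direction),
*mutation-biased* if one clone's |dPSI| > 2 while the other's < 2. Coding
consequence is the cryptic-vs-canonical offset mod 3 within the CDS.

## Worked example

`python examples/01_clonal_dynamics.py` prints:

```
SF3B1-N626D: VAF 0.428 at month 0 -> 0.001 at month 168
SF3B1-K666N: VAF 0.050 at month 0 -> 0.408 at month 168
SF3B1-N626D: s = -0.521/yr (SE 0.009, true -0.520)
SF3B1-K666N: s = +0.059/yr (SE 0.007, true +0.065)
clones invert in frequency at month 44.9
colony enrichment: 105/121 vs 0.54 expected -> p = 1.39e-14 (clone dominates the compartment)
```

The founder clone collapses from 43% VAF to the detection floor while its
competitor rises from ~5% to ~41%; the fitted selection coefficients recover
the generative truth (the negative sign marks the outcompeted clone) and the
linear-interpolation crossing of the two trajectories falls at month ~45.
The last line is the exact binomial test of 105 mutant colonies out of 121
against the 0.54 fraction expected from a 27% bulk VAF — overwhelming
evidence that the clone dominates that progenitor compartment.

`python examples/02_clone_tree_dating.py` continues with colony phylogenies:

```
clock rate: 18.0 mutations/yr [95% CI 18.0, 18.1]
SF3B1-N626D: acquired 0.0-23.5 yr after birth (true 20; diagnosis at 66)
SF3B1-K666N: acquired 0.0-32.2 yr after birth (true 30; diagnosis at 66)
```

Both drivers date to decades before the donor's sampling age, and each 95%
interval brackets the planted acquisition time. The remaining examples cover
the splicing analysis (`03`) and the end-to-end pipeline driver (`04`);
`clonesplice --help` lists the equivalent shell commands.

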