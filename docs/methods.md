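# Methods

## Scope and model of the system

The package models one bone marrow containing two (generally *k*) mutant
clones plus wild-type (WT) hematopoiesis, observed through four windows:
longitudinal ddPCR VAFs of each driver, genotypes of single-cell-derived
colonies sorted from progenitor compartments, whole-genome mutation burdens
of those colonies, and single-cell splice-junction counts with per-cell
genotype labels. Each window has a generator that emits it synthetically
with ground truth, and an estimator that inverts it.

## Clonal competition

Fractions follow replicator dynamics `df_i/dt = f_i (s_i − Σ f_j s_j)` with
WT as the reference at `s = 0`; mutant coefficients are therefore fitness
advantages *relative to WT*, per year, which is the identifiable
parametrisation (adding a constant to every clone's fitness, WT included,
changes nothing observable). The closed-form solution
`f_i(t) ∝ f_i(0) exp(s_i t)` is used everywhere — generator and fit share
one implementation, so fitting inverts exactly the simulated process; an
independent ODE integration in the tests guards that shared code.

Observation model: heterozygous diploid VAF `= f/2`, droplet counts
`Binomial(droplets, VAF)`. Digital counting motivates pure binomial noise
with no overdispersion term; the droplet count (default 10,000) is
configurable since real assay depths vary and are rarely reported.

The fit is unweighted least squares over all series jointly, with initial
fractions mapped through a multinomial logit (WT as baseline) so they stay
in the simplex, and endpoints-based starting values. VAFs reported as 0%
are treated as censored at a detection limit (default 0.1%, the typical
ddPCR floor): censored points contribute a one-sided residual penalising
only predictions above the limit. Uncertainty comes from a seeded
parametric bootstrap (default 200 resamples) because the binomial
observation model makes resampling cheap and assumption-light.

Inversion detection interpolates the two trajectories linearly between
visits — deliberately model-free, so a crossing claim does not depend on
the fitted dynamics — and returns the earliest crossing; identical curves
return the start of the shared window (documented tie rule).

Colony enrichment uses the exact binomial tail. The null fraction is twice
the contemporaneous bulk VAF (heterozygous diploid), following the
observation that stem-cell-derived colonies mirror bulk VAFs. Two-sided
p-values are `2 × min(tails)` capped at 1; the direction-agnostic default
is conservative, and both sidedness choices clear the worked example's
significance bound.

## Colony genotypes and the molecular clock

Colony identities per compartment are multinomial in the compartment's
clone fractions (remainder WT). Mutation accrual is clock-like: a clone
founded at age `t_acq` contributes a shared trunk of
`1 + Poisson(rate × t_acq)` mutations (driver included) to every colony,
and each colony adds private `Poisson(rate × (age − t_acq))` mutations, so
total burdens are `Poisson(rate × age)` — the assumption the rate estimator
and the dating procedure invert. Genotyping error, when enabled, is allele
dropout (true calls lost at the given rate): symmetric 0↔1 flips would
flood a matrix whose columns are the union of all colonies' private
mutations with false positives at a rate no colony-WGS caller exhibits.

Tree reconstruction is the classic perfect-phylogeny construction: variants
with identical carrier sets merge onto one branch (ordered
lexicographically — the tie rule), carrier sets must be pairwise nested or
disjoint (otherwise an incompatibility error names an offending variant
pair), and each branch's parent is the smallest strictly containing carrier
set. Missing genotype entries are excluded from carrier sets — colony
dropout is technical, and treating it as absence would manufacture
three-gamete violations. Branch lengths are mutation counts; Newick output
stores the mutation list in the node label, so the tree round-trips.

Rate estimation is Poisson regression through the origin of burden on age,
whose MLE `Σ burden / Σ age` and exact (Garwood, chi-square) profile CI
have closed forms; per-clone stratification is a per-subgroup call.

Dating composes two pieces at a fixed rate: the driver's branch spans
molecular time `[m_before, m_through]` (mutations above the branch;
through its end), and each endpoint carries exact Poisson count
uncertainty before division by the rate. The 95% interval is the lower
Garwood limit of `m_before` to the upper limit of `m_through`, divided by
the rate and clamped to age at sampling; the point estimate is the
midpoint. Composing count uncertainty at fixed rate (rather than also
propagating rate uncertainty) is a deliberate choice: with hundreds of
colonies the rate CI is far narrower than the count intervals, and the
composition keeps the interval exact rather than approximate. Coverage
simulations at 18 mutations/yr confirm ≥90% empirical coverage.

## Splicing

Junction counts are simulated per cell and event: coverage is negative
binomial (mean 50, size 5 — realistic single-cell overdispersion),
inclusion reads binomial in the true PSI, and reads on two-junction paths
are split multinomially so path totals are preserved and pooled PSI stays
unbiased. Planted events get their own fully coding three-exon gene; the
cryptic isoform is left out of the annotation (except MXE, where both
isoforms are annotated), which is what lets the analysis side recognise
cryptic junctions. Defaults — 100 cells per clone, three control donors,
planted |dPSI| of 15 against a control PSI of 30, 50 events across the five
types — describe the targeted study scale; per-cell junction coverage is
far below a real full-length single-cell library (which sees thousands of
junctions per cell) because only planted events are simulated, so the
per-event read depth, not the junction catalogue, is the calibrated
quantity.

Analysis is pseudobulk-first: single-cell junction sparsity makes per-cell
PSI noisy, so counts are summed per genotype group (control donors stay
separate) before PSI; `psi_table` also accepts the ungrouped per-cell table
when per-cell values are wanted. PSI needs ≥10 supporting reads per event
per group (the literature states no threshold; 10 suppresses the worst
small-count noise without discarding whole groups). dPSI subtracts the
unweighted mean of per-donor control PSIs, each donor subject to the same
coverage threshold — robust to donor depth imbalance.

Event classification is purely geometric over intron-keyed junctions
(0-based half-open throughout; the GTF reader converts 1-based annotation):
shared lower bound → A3SS on plus / A5SS on minus strand, shared upper
bound the reverse; a skip junction across an annotated internal exon
flanked by two junctions → SE; two annotated junction pairs flanking
non-overlapping internal exons → MXE; intron retention cannot be seen in
junction counts at all, so RI events use an intronic-coverage proxy row
(kind `intron_proxy`) that the generator emits and real pipelines can
supply from intron read depth. Unmatched geometry yields `unclassified`,
not an error.

The filters implement the 2% rules: common requires both |dPSI| > 2 *with
concordant signs* (magnitude-only wording is ambiguous; discordant shifts
are biologically not "the same event in both clones" — a flag disables the
sign requirement), X-biased requires |dPSI_X| > 2 and the other clone
< 2, values exactly on a threshold are indeterminate, both below is null.
The labels partition every record; no multiple-testing correction is
applied because the procedure is a fixed-threshold filter, not a test.
Consequence annotation reduces to the cryptic-vs-canonical offset (exon
length for SE, intron length for RI) mod 3 within the transcript's CDS
span; events confined to UTR are noncoding, events with no overlapping
transcript unannotated.

## Randomness and determinism

One seed drives everything, split into named independent streams
(`SeedSequence([seed, stream_id])`: trajectories=1, colonies=2,
junctions=3), so each generator is reproducible in isolation and identical
seeds give bit-identical outputs — the pipeline test asserts byte-identical
files. The bootstrap derives its own stream from the caller's seed.

## Problem sizes

Defaults run the full study scale (240 colonies at 18 mutations/yr, ~500
cells × 50 events) in seconds. The recovery studies use 20 replicates for
competition fitting, 200 for dating coverage, 100 for multinomial
goodness-of-fit and rate-CI coverage, and 10 simulated datasets for the
splicing filters; the phylogeny oracle sweeps 300 random matrices of up to
6 variants × 8 colonies, where the containment-poset oracle is exhaustive.

## What the synthetic data does and does not show

The generator reproduces the *statistical* structure the estimators assume:
logistic competition, binomial droplet noise, multinomial compartments,
Poisson clocks, binomial inclusion counts. It omits real-data features —
assay batch effects and VAF overdispersion, copy-number events distorting
the VAF↔fraction map, subclonal structure within clones, donor-to-donor
control PSI variation (control donors share one true PSI), junction
mis-mapping, and expression-level confounding of junction coverage. Passing
recovery tests therefore demonstrates correctness of the inference given
the model, not robustness to model violation; the censoring rule, dropout
error model and `min_shared` clustering knob are the places where mild
violations are absorbed.

## Known limitations

* The VAF↔cell-fraction map supports only heterozygous diploid variants;
  CNV/homozygosity raise an explicit unsupported-model error.
* Clone clustering links colonies by shared variants; it resolves disjoint
  clones (the motivating setting) but does not split nested subclones into
  separate labels — the tree, not the clustering, represents nesting.
* Dating assumes the clock rate is constant over life and shared by trunk
  and branch; pediatric-onset or mutator phenotypes would violate this.
* RI quantification is only as good as the supplied intron-coverage proxy.
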