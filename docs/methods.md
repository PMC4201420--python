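# Methods

This note records the models implemented in `panelpower`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would want to know about.

## Diversity statistics

Per-locus statistics are direct-count estimators: allele frequencies are
counts over 2 × (non-missing individuals); *He* = 1 − Σp² is uncorrected
by default, with the small-sample factor 2n/(2n − 1) available via
`locus_summary(..., corrected=True)`. At the reference sample size
(n = 285) the two estimators differ by < 0.2%, below the rounding of the
published per-locus table, so the ambiguity is unresolvable and the
simpler estimator is the default. *Fis* = (*He* − *Ho*)/*He* is defined as
0 for a monomorphic locus (He = 0). Recomputing *Fis* from the rounded
published *Ho*/*He* columns reproduces the published column to ±0.001
everywhere except the near-monomorphic diagnostic locus, where
Ho = He = 0.042 print identically and the quotient is dominated by
rounding.

## Hardy–Weinberg exact test

The test is conditional on allele counts. Rather than a
Metropolis-weighted cell-switching chain, the sampler walks over
*arrangements of the 2n gene copies into n ordered pairs* by random
transpositions. A uniformly random pairing of gene copies induces exactly
the conditional distribution of genotype tables under random union of
gametes (probability ∝ 2^H / Π n_ij!), so every transposition is accepted
and the update is O(1) via incremental bookkeeping of
S = H·log 2 − Σ log n_ij!.

Two p-values are offered: the two-sided **probability** test (default) —
the visited-state fraction with S ≤ S_obs (+10⁻¹² to include ties) — and a
one-sided **heterozygote-deficiency** test (fraction with H ≤ H_obs),
matching the deficiency-oriented testing of panel validation studies.
Defaults are a 10,000-step dememorisation followed by 100,000 counted
steps; a batch-means standard error (20 batches) is available because
successive states are autocorrelated and a naive binomial SE would
understate the Monte-Carlo error. The chain body is compiled with numba
when available; the pure-Python path is the reference implementation.
Bonferroni correction is strict (p < α/m) with m = the number of p-values
passed in, so testing 25 loci in 2 populations at α = 0.05 thresholds at
0.001.

## Exclusion probabilities

The primary PE is the single-parent, no-known-parent form (power-sum
formula above): the probability that a random HWE individual shares no
allele with a random HWE offspring. Its semantics are locked by a
brute-force oracle (enumeration over all offspring × candidate genotype
combinations) with which it agrees to 10⁻¹² on random frequency vectors;
this form also reproduces the published magnitudes (≈0.77 at He ≈ 0.93,
≈0.15 at He ≈ 0.53), which the one-parent-known form does not. The
known-parent and parent-pair variants are computed by exact enumeration
(O(k³)/O(k²) in the allele count) rather than closed forms, trading speed
for transparency; they are secondary outputs. CumPE accumulates
independent loci as 1 − Π(1 − PEₗ); its final value is invariant to locus
order, the running values follow kit order.

## Synthetic-data generator

The generator reproduces the *statistical profile* of the reference
panel, not its unpublished allele frequencies. Per locus and species, a
geometric series pᵢ ∝ rⁱ is solved by bisection so that Na and He match
the published values (|He − target| ≤ 10⁻⁶); optional Dirichlet jitter
(re-tempered to restore He) makes profiles irregular. In the default
two-species build both species draw from a shared allele-size ladder
(spaced by the repeat length, anchored at the marker's size range) with
opposite frequency ranks: each species matches its own diversity, common
alleles in one are rare or absent in the other. This makes the species
pair *strongly* diverged — an idealisation chosen because the study's own
simulations start from species-specific frequency estimates of two
distinct species, and because the diagnostic-locus behaviour (one allele
at ≈0.98 in one species, polymorphic in the other) emerges directly from
the published (Na, He) pairs. A Balding–Nichols alternative
(`divergence=c`: species B ~ Dirichlet(p_A(1−c)/c)) produces *correlated*
pairs with E[Fst] = c for sensitivity work. Consequences for
interpretation: classification error rates measured on the default build
are best-case for between-species divergence (0% misclassification at 100
per class even for single kits, where the study saw ~0.1–1.3% at 5000 per
class with real frequency overlap), while parentage accuracy depends on
within-species diversity, which is matched, and lands on the study's
values.

Parentage populations follow the published design: 500 sampled adults
(333 females, 167 males), 1000 offspring, 20% "known". Known is
interpreted as *both* true parents inside the sampled pool and the
remaining 80% with neither (`sampling_mode="paired"`, the default,
matching the design's fixed proportion exactly); an `"independent"` mode
samples the pool from a 5× larger universe so each parent is present with
probability 0.2, producing the single-parent-sampled cases the outcome
taxonomy also covers. Mating pairs are uniform with replacement (polygamy
allowed) — the original simulation tool's mating scheme is not described.
Genotyping error (1%/locus) replaces one uniformly chosen allele with a
fresh draw from the population frequencies, so the realised per-allele
mismatch rate is rate/2 × (1 − Σp²); the error is applied to offspring
and adults (scope configurable), since all genotypes in a real study pass
through the same pipeline. All generators are bit-reproducible given
their seed; a single run seed fans out through `SeedSequence.spawn`.

Not emulated: linkage between loci, null alleles and allelic dropout
(error is symmetric replacement), mutation, family structure among the
unsampled parents, and within-species geographic structure. Passing tests
therefore validate the panel's *power arithmetic* under idealised
population genetics, not robustness to those artefacts.

## Admixture model

The sampler is the standard uncorrelated-frequencies admixture Gibbs
scheme: z (per-copy origin) ~ q·p; q ~ Dirichlet(α + copy counts);
p ~ Dirichlet(1 + allele counts) per cluster × locus; missing calls are
skipped. α is updated by Metropolis (uniform prior (0, 10], normal
proposal sd 0.05) **by default**. A fixed α = 1 was considered and
rejected: the Dirichlet prior then caps the posterior-mean q of a
purebred at (2L + 1)/(2L + 2) — 0.917 at 5 loci — so the expected ≥ 0.99
assignment of purebreds on diagnostic data is unreachable regardless of
chain length; with α inferred it collapses to ~0.01 on separated data and
purebreds reach q ≥ 0.998. Supplying `cluster_freqs` clamps p, reducing
the model to per-individual q estimation, which is cross-checked against
1-D quadrature of the exact posterior in the tests (agreement < 0.02).

Chain defaults are 5,000 burn-in + 5,000 kept sweeps and 100–500
individuals per class — desk-scale choices that already separate the
classes cleanly on 8–25 matched-diversity loci; the study-scale
50,000 + 50,000 × 15,000 individuals is reachable via flags. Label
switching is resolved against known purebred references after the run.
Thresholds are data-driven per run (grid step 0.005, ties broken toward
the widest hybrid interval, then the lowest cutpoint); the published
(0.240, 0.780) pair is one realisation on the real data, not a constant
of the method. A single chain is run per configuration, as in the
original study; split runs under different seeds agree on these data, but
no convergence diagnostic is gated on.

## Parentage likelihoods

Per-locus LOD terms use the mixture likelihood ((1−e)·T + e·P(g_o)) /
P(g_o) in log₁₀, where T marginalises the unknown parent over HWE and the
exact T is locked by an exhaustive-enumeration oracle (agreement 10⁻¹⁰).
e defaults to 10⁻⁴, reading the study's "0.01%" calculation error
literally; note this is deliberately far below the 1% simulated
genotyping error — e only needs to keep mismatching loci finite (−4 per
locus) so that one or two mistyped loci dent, but do not erase, a true
parent's LOD. Pairs are evaluated unordered (field samples are typically
unsexed). Decisions take the best pair if pair-LOD ≥ 10, else the best
single if single-LOD ≥ 5, else none, with pair-over-single precedence
because a single assignment when both parents are sampled is scored as an
error. Pair enumeration is restricted to candidates with single LOD above
0 (configurable prescreen): a true parent's single LOD at 25 matched
loci is ~15–25, while an unrelated adult's is strongly negative, so the
restriction is a documented approximation that reduces ~125,000 pairs per
offspring to a handful. Ties break deterministically by candidate order.

Accuracy within a decision type (e.g. "single-parent accuracy") is
reported as correct/total *among offspring receiving that decision*, and
is vacuously 1.0 when the decision never occurs — under the paired
sampling mode legitimate single assignments cannot arise, so that row is
informative only in the independent mode. Error rates and overall
accuracy are always over all offspring.

## Problem sizes

Defaults throughout are the sizes used by the analysis drivers and the
test suite: parentage at the full published design (500 adults, 1000
offspring, 3 replicates), discrimination at 100 individuals per class
with 5,000 + 5,000 sweeps, HWE calibration at 1,000 replicates of n = 100
with 2,000 + 10,000 chain steps. These reproduce the published
magnitudes; larger sizes only narrow Monte-Carlo noise.
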