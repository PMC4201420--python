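# panelpower

Power validation of microsatellite multiplex panels for species
discrimination, hybrid detection, and parentage analysis — built around a
25-locus, three-kit panel co-amplifying in two hybridizing coral trout
species (*Plectropomus leopardus* and *P. maculatus*).

Microsatellite panels are routinely used as genetic barcodes: to tell two
sympatric species apart, to flag interspecific hybrids, and to assign
offspring to parents in wild populations. Whether a given panel is *powerful
enough* for those tasks depends on its per-locus allelic diversity, and the
honest way to find out is simulation: generate genotypes with the panel's
own allele-frequency structure, run the downstream analyses, and count the
errors. This package implements that validation loop end to end for
researchers characterising codominant marker panels.

## What it computes

**Diversity and power statistics** (`panelpower.diversity`). Per locus:
number of alleles *Na*, observed and expected heterozygosity
*Ho*, *He* = 1 − Σᵢpᵢ², fixation index *Fis* = (*He* − *Ho*)/*He*; a
Monte-Carlo exact test of Hardy–Weinberg proportions (a switching chain
over gene-copy pairings whose stationary law is the exact conditional
distribution of genotype tables given allele counts), with strict
Bonferroni correction; and the single-parent exclusion probability from
allele-frequency power sums aₖ = Σᵢpᵢᵏ,

    PE = 1 − 4a₂ + 2a₂² + 4a₃ − 3a₄,

accumulated over a kit as CumPE = 1 − Π(1 − PEₗ). Known-parent and
parent-pair exclusion variants are computed by exact enumeration.

**Synthetic populations** (`panelpower.synthpop`). Only (Na, He) per locus
and species are published for the reference panel, so the generator solves
geometric-series frequencies pᵢ ∝ rⁱ (r by bisection) to hit each (Na, He)
pair exactly, including the near-monomorphic diagnostic locus (one allele
at ≈0.98). It then simulates HWE purebreds, F1 hybrids (one allele from
each species per locus), and parentage populations: 500 candidate adults
at a 2:1 female:male ratio, 1000 offspring of which 20% have their true
parents in the candidate pool, and 1% per-locus genotyping error
(single-allele replacement from the population frequencies).

**Species/hybrid classification** (`panelpower.admixture`). A Gibbs
sampler for the K=2 admixture model (per-copy latent origin z, Dirichlet
cluster frequencies, per-individual admixture q with a Metropolis-updated
concentration α) yields posterior assignment probabilities; thresholds
(t_low, t_high) on the species-A axis are optimised by grid search to
minimise three-class misclassification (q ≤ t_low → species B,
q > t_high → species A, hybrid between).

**Parentage assignment** (`panelpower.parentage`). Error-tolerant LOD
scores, per locus log₁₀(((1−e)·T + e·P(g_o))/P(g_o)) with T the Mendelian
transmission probability (unknown parent integrated over the population)
and e a small calculation-error weight (default 10⁻⁴); pair-over-single
decisions at LOD thresholds 5 (single) and 10 (pair); and an outcome
taxonomy (correct single/pair/exclusion, type I false positives, type II
false negatives, single-when-pair-present) with overall accuracy
= (correct assignments + correct exclusions)/N.

## Worked example

```python
from panelpower import load_fixture_panel
from panelpower.synthpop import ParentageDesign, build_species_pair
from panelpower.parentage import ParentageConfig, parentage_report

panel, summary = load_fixture_panel()          # 25 loci, kits of 9/8/8
model = build_species_pair(summary, panel)     # (Na, He)-matched profiles
rep = parentage_report(model.freqs_a, ParentageDesign(seed=1),
                       ParentageConfig(), n_replicates=3)
print(rep.round(4))
```

prints

```
                    sim-1  sim-2  sim-3  average
single_accuracy       1.0  0.000  0.000   0.3333
pair_accuracy         1.0  1.000  1.000   1.0000
exclusion_accuracy    1.0  1.000  1.000   1.0000
type_I_rate           0.0  0.001  0.002   0.0010
type_II_rate          0.0  0.000  0.000   0.0000
overall_accuracy      1.0  0.999  0.998   0.9990
```

— with the full design, 99.9% of the 1000 offspring per replicate are
correctly assigned to a sampled parent pair or correctly excluded; the
rare errors are chance false positives among the 800 offspring whose
parents were never sampled (type I), and no sampled parent is missed
(type II = 0). Accuracy within a decision type is vacuously 1 when that
decision never occurs. The numbered drivers under `analysis/` run the
three studies (panel statistics, kit-by-kit species discrimination,
parentage accuracy) and write their tables to `results/`; the same
functionality is exposed as `panelpower {stats|simulate|discriminate|
parentage|all}`.

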