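# Methods

## The analysis in outline

Three populations are compared: two neighbouring focal woods (here called
`gamlingay` and `waresley`) and a distant outgroup (`wales`).  Called
diploid genotypes at biallelic SNPs are the substrate throughout; the
package deliberately operates downstream of variant calling (only the
hard-filter rule `QD < 2.0 || SOR > 3.0 || FS > 200` is re-implemented, on
VCF INFO fields).  Genotype likelihoods are not modelled: hard calls
suffice to exercise every downstream statistic, and the simulator controls
genotype quality directly.

Coordinates are 0-based half-open everywhere in memory; conversion to
VCF's 1-based positions and GFF3's 1-based inclusive intervals happens
only in `vcfio`.

## F_ST estimators and window modes

Two per-site estimators are implemented and always labelled in output,
because the upstream tools this analysis mirrors do not document a
formula:

* **Hudson** (ratio-of-averages form): with sample frequencies
  `p_i = c_i/n_i` over `n_i` called alleles,
  `num = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)`,
  `den = p1(1−p2) + p2(1−p1)`.  Sample-size robust and the standard PBS
  substrate; the default.
* **Weir–Cockerham (1984)**: full diploid variance components a/b/c from
  genotype counts including observed heterozygosity; `num = a`,
  `den = a+b+c`.

Window values come in two modes: *weighted* = Σnum/Σden over sites in the
window (ratio of averages, the default and the PBS input) and
*unweighted* = mean of per-site ratios over sites with `den > 0`.  Sites
where any population has fewer than 4 called alleles are skipped; sites
fixed for the same allele in both populations contribute (0, 0) and are
excluded from unweighted means.  Windows with fewer than `min_sites` used
sites (default 5 for ≥2-kb windows, 2 for 500-bp sliding windows) are
emitted but flagged invalid — tiny windows produce wild ratios.

## Population branch statistics

Pairwise window F_ST is clamped to `[0, 1−10⁻⁶]` and transformed to a
divergence branch length `T = −log(1 − F_ST)` (natural log; a different
base only rescales).  Negative window F_ST — sampling noise around zero
divergence — therefore maps to branch length 0 while the raw value stays
in the output.  For branches (A, B, outgroup O):

    PBS_A = (T_AB + T_AO − T_BO) / 2

and rotations.  The identities `PBS_A + PBS_B = T_AB` and
`ΣPBS = ΣT/2` hold exactly and are asserted in tests.  The genome scan
uses 2-kb non-overlapping windows; gene scoring uses 500-bp windows
sliding by 100 bp.  Outlier windows (default threshold PBS > 0.05) are
classed `focal1-only` / `focal2-only` / `both` on the two focal branches.

zF_ST standardizes the focal-pair window F_ST by the genome-wide mean and
SD of valid windows; the attached p-value is the one-sided upper-tail
standard normal probability.  A one-sided tail is a documented choice —
the transform is strictly monotone, so rankings are identical to raw
F_ST regardless.

## Diversity statistics

Per-site unbiased heterozygosity is `2p(1−p)·n/(n−1)`; window π divides
the summed site values by the full window span (an all-sites denominator:
the simulator emits every site, and invariant sites carry zero
heterozygosity but full span).  Tajima's D uses the classical constants
(a1, a2, b1, b2, c1, c2, e1, e2) evaluated at the window's mean called
allele count; windows with fewer than 3 segregating sites (configurable)
or n < 4 are undefined.  Note that the default simulator frequency law,
Uniform(0.05, 0.95), has an excess of intermediate-frequency variants by
construction, so D is strongly positive on default draws; D centres near
zero only under the `neutral` (truncated 1/x) ancestral law, which is what
the corresponding property test uses.

## The synthetic-data generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

* **Frequencies** — Balding–Nichols: ancestral `p0` from
  Uniform(0.05, 0.95) (avoids near-fixed sites that degenerate F_ST
  estimators; a truncated-1/x `neutral` law is available for
  site-frequency-spectrum-sensitive statistics), then per branch
  `p_k ~ Beta(p0(1−F)/F, (1−p0)(1−F)/F)`, so `var(p_k) = F·p0(1−p0)`.
  `F = 0` copies `p0` exactly.  Defaults: F = 0.01 on both focal branches
  (putting genome-wide weighted F_ST at the observed 0.01 order of
  magnitude) and 0.05 on the outgroup branch; 20,000 SNPs on 2 × 1 Mb
  contigs (≈10 SNPs per kb); sample sizes 40/40/22 diploids.
* **Selected loci** — a planted locus is a *sweep footprint*: every SNP
  within `sweep_width` bp (default 1200) of the position draws with
  `F_sel` (> background F, enforced) on the focal branch only.  Sites are
  otherwise independent, so a literal single-SNP "locus" would be diluted
  by its window's ~20 background sites and could never reliably top a
  windowed scan; the footprint emulates the coherent multi-SNP shift that
  hitchhiking produces, which is what windowed scans are designed to
  detect.  The default width came from an operating-characteristic design
  study: wider footprints detect better on the focal branch but leak onto
  the sister branch, because the `T_AB`/`T_BO` cancellation in the sister
  branch's PBS is noisy on fully-swept windows (outgroup sampling noise,
  log convexity).  1200 bp gives ≥95% focal-top recovery with ≤5%
  sister-branch misattribution at the default conditions.
* **Genotypes** — Binomial(2, p_k) per diploid; written as VCF v4.2 with
  synthetic QD/SOR/FS INFO fields, of which a configurable fraction
  (default 5%) violates exactly one hard-filter criterion.
* **Annotation** — genes of 2 kb tiled every 4 kb; every gene gets one
  background GO term; the planted term contains every gene overlapping a
  planted footprint plus seeded decoys up to a configurable set size.
* **Broods** — split-sibling dyads, one arm per carcass class.  Clutch
  size ~ Poisson(base 15 + 4·1[large] + offset·1[derived]); the offset
  (default 5 eggs) is an *elevation* shift — it applies in both
  environments, leaving the slope untouched.  Brood size equals clutch
  minus a Binomial(clutch, 0.3) culling deficit applied only to the
  derived population on small carcasses when enabled.  Egg length/width
  are normal (1.7 / ~1.0 mm) with mean width shrinking slightly with
  clutch size (an egg size–number trade-off); ~65% of eggs carry
  measurements, mirroring partial egg visibility in real breeding boxes.

One master seed governs a run; per-stage RNG streams derive from it with
fixed offsets, so each stage is independently reproducible.

What the generator does *not* emulate: linkage disequilibrium between
sites (beyond the all-or-nothing sweep footprint), coalescent genealogy,
sequencing error or genotype uncertainty, shared drift between the two
neighbouring woods, spatial or temporal structure in trapping data.
Passing tests therefore demonstrate that the statistics and their
machinery behave correctly under a controlled generative model — not that
the pipeline would reproduce any particular field study's numbers.

## Gene scoring and enrichment

A gene's divergence score on a branch is the **maximum** PBS among valid
sliding windows with ≥1 bp overlap of the half-open gene body; genes with
no valid overlapping window are excluded from ranking (counted).  Ties
rank lexicographically by gene ID for determinism.

Enrichment is the weighted Kolmogorov–Smirnov running statistic: hits add
`|score|^p` normalized over the in-set sum, misses subtract `1/(N−N_hit)`;
ES is the signed extremal deviation.  The null is gene-label permutation —
one label permutation per iteration shared across terms, preserving
inter-term overlap structure.  `NES = ES / mean(|null ES| of matching
sign)`; the nominal p is the add-one fraction of same-sign null ES at
least as extreme; FDR q follows the sign-stratified NES-comparison
procedure with a cumulative-min monotonicity pass from the least-extreme
end.  Defaults are the community baseline: weight p = 1, 1000
permutations, set-size bounds [10, 500]; all configurable.

One caveat drives a non-default choice in cross-branch comparisons: with
p > 0 the permutation null's scale depends on each list's score tail, so
two branches with very different outlier weight (a swept branch vs. a
quiet one) have incommensurable NES values — the swept branch's fattened
null can *deflate* its NES below the quiet branch's despite a much larger
ES.  Comparisons of one term's NES *across* branches therefore use p = 0,
where the null depends only on ranks and is identical for every branch.
Within-branch tables keep p = 1.  GO terms are taken as a flat, already
propagated gene→term map; negative (depleted) terms are reported with
their sign rather than dropped.

## Phenotype computations

* Egg volume: prolate spheroid `V = π w² L / 6` (sphere when L = w).
* Carcass-use efficiency: brood mass / carcass mass; the logit uses
  empirical shrinkage `ε = 1/(2·n_obs)` only at the boundaries
  (E ≤ 0 or ≥ 1), which are flagged.
* Reaction norms: per complete dyad, elevation = mean(small, large) and
  slope = large − small; the decomposition is invertible.  Elevation as
  the cross-treatment mean (rather than the small-carcass intercept) is a
  documented choice.  Dyads with a missing arm or unmeasurable trait are
  excluded and counted.
* Population contrasts on either component use two-sided permutation
  tests over dyad labels: exact by exhaustive enumeration when
  `C(n, n_A)` ≤ the permutation budget, otherwise add-one Monte-Carlo.
  Mixed-model analyses of the original field designs are deliberately not
  re-implemented; the permutation contrast is a methodological
  substitution, not a reproduction of any particular test statistic.
* Guild relative abundance: per-woodland species proportions, reported to
  one decimal percent.

## Numerical and degenerate-input conventions

F_ST clamp before the log as above; argmax ties broken by smallest start
coordinate; terminal partial windows emitted and flagged in scan mode,
sliding mode emits full windows only; empty gene-set intersections and
whole-list sets are errors for ES; missing INFO values follow a
configurable pass/fail policy (default pass); all-missing sites carry
zero called alleles and drop out of every statistic.

## Problem sizes used in checks

The replicated checks run at deliberately modest scale: 20k-SNP genomes
(2 × 1 Mb) for locus recovery across 100 seeds; 8k-SNP single-contig
genomes with 100–200 genes for enrichment power (100 replicates) and null
calibration (60 null genomes, ~650 term-tests); 50 dyads per population
for the reaction-norm signature (100 seeds).  These sizes give the
acceptance properties comfortable margins while keeping a full run in the
low minutes on one CPU.

## Known limitations

* PBS polarization degrades when the outgroup is close or small: the
  sister-branch leakage analysed above scales with outgroup drift and
  sampling noise, which is why the misattribution bound is 5%, not 0%.
* The Weir–Cockerham estimator here is two-population; the multi-way
  generalization is out of scope.
* Multi-allelic records are skipped (counted), not decomposed.
* π uses the full window span; with real all-sites VCFs containing
  uncallable regions this understates diversity.
* GSEA FDR q is the permutation-estimated proportion, clipped to [0, 1];
  with few terms it is coarse (q = 0 is common for a clear top term).
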