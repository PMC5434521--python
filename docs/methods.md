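# Methods

`scaffoldphase` implements a two-step strategy for phasing a dense marker
panel (whole-genome-sequence scale) in a population where a nested sparse
panel (genotyping-array scale) is available on many more relatives: phase
the dense panel with linkage disequilibrium (LD) alone, phase the sparse
panel with Mendelian and half-sib linkage rules completed by LD, and align
the LD pre-phase onto that familially anchored *scaffold* so that the
long-range paternal/maternal assignment of every dense marker is inherited
from the scaffold.  This note documents the models, the parameters that
matter, the synthetic data, and the numerical choices.

## Population simulator (`pedsim`)

The simulator emulates a closed livestock nucleus:

* **Founder LD.** Founder haplotypes are drawn with replacement from a
  pool of `n_founder_haplotypes` ancestral haplotypes (default 30), each
  copy mutated per marker with probability
  `mutation_rate_per_marker` (default 0.005).  A small pool gives long
  shared haplotypes and strong LD, as in real livestock populations with
  small effective size; the pool size and mutation rate are the two knobs
  controlling haplotype sharing.  Sites with minor-allele frequency below
  `maf_min` (default 0.01) are resampled.
* **Pedigree.** Discrete generations; each generation pairs the previous
  one into `n_founders/2` random matings with `offspring_per_mating`
  offspring (defaults: 20 founders, 3 generations, 2 offspring → ~60
  animals, 40 of which have genotyped parents and can be evaluated).
* **Meiosis.** Haldane model: crossover counts are Poisson in the map
  length (default 1 cM/Mb over a 100-Mb chromosome ≈ 1 crossover per
  gamete), positions uniform on the genetic scale, no interference.
* **Panels.** 2,000 dense markers at uniform-random positions with a
  nested, evenly subsampled scaffold of 100 markers (≈1 per cM).
* **Error model.** Optional symmetric genotype perturbation: with
  probability `genotype_error_rate` a call is replaced by a random
  *different* legal dosage.  Truth haplotypes (with parental origin and
  recorded crossovers) are retained pre-error.

What the simulator does **not** emulate: site-frequency spectra of real
sequence data, genotype-likelihood uncertainty, structural variation,
selection, sex chromosomes, or map errors.  Passing tests therefore
demonstrate correctness of the algorithms under idealised marker data,
not performance on real sequencing artefacts.

## LD-only phasing (`ld_phase`)

A diploid Li–Stephens copying model: the hidden state is an ordered pair
of conditioning haplotypes taken from the current estimates of the other
individuals; transitions switch the copied haplotype with probability
`1 − exp(−4·Ne·d/K)` per interval (`d` in Morgans, `K` conditioning
haplotypes, `Ne` default 200); emissions allow a symmetric allele mismatch
(`mismatch_rate`, default 10⁻³).  At a heterozygous site the ordering of
the two alleles across the copied pair is the phase call; sites where both
copied haplotypes carry the same allele are phase-uninformative.

Iteration schedule.  A single conditional chain (re-phase each individual
against everyone else's current haplotypes, repeat) mixes far too slowly
from a random start: its errors are mutually reinforcing.  Three devices
fix this, all LD-only:

1. **Junction voting within a run** — during the `n_main` Viterbi sweeps
   (after `n_burnin` posterior-sampling sweeps) we record, for every pair
   of consecutive heterozygous sites, whether the alt alleles landed on
   the same haplotype, and take the per-junction majority.  Voting on
   junctions rather than absolute site states makes the average invariant
   to the arbitrary global orientation of each sweep.
2. **Independent restarts** — `n_restarts` (default 5) runs from different
   random initialisations, with a fresh random subset of `n_states`
   (default 60) conditioning haplotypes per decode, are combined by a
   second junction-wise majority.  Restart errors are nearly independent,
   so the majority suppresses them roughly cubically.
3. **Polish sweeps** — `n_polish` (default 3) final conditional Viterbi
   sweeps against the full panel.  Once the panel is mostly correct the
   conditional decoder is self-consistent at the truth, and these sweeps
   converge onto it.

On the default simulated conditions this yields ≈0.2 residual phase
switches per animal per chromosome while the paternal/maternal
orientation remains exactly random (~50% mismatch with the Mendelian
phase), the behaviour expected of LD-only phasing.  Windowed processing
(`window_mb`, 10% overlap, majority stitching at overlap heterozygous
sites) is available but off by default: at these marker counts a whole
chromosome is a single comfortable window and stitching only adds switch
risk.

## Familial phasing (`mendel_phase`) and the scaffold

"Phasable" SNPs — heterozygous in the offspring and homozygous in at
least one genotyped parent — have a forced phase under Mendelian
segregation; they are both the anchor of the scaffold and the evaluation
truth.  Parents with ≥ `min_offspring` (default 4) genotyped offspring are
additionally phased by a greedy minimum-recombination chaining of the
transmitted alleles with a majority vote across offspring (tie → chain
break; a chain is used only when one of its sites is itself
Mendel-anchored, which pins the chain's absolute orientation).  The LD
engine then completes the remaining heterozygous sites with the anchored
alleles as hard constraints (constraint-inconsistent allele orderings are
excluded from the emission, and the constraints are re-imposed exactly on
output).  The result (the scaffold) is phased with known parental origin
for every individual with a genotyped parent and, on default simulated
conditions, misassigns ≈0.3% of heterozygous scaffold sites.

## Scaffold alignment (`scaffold_align`)

Per individual and chromosome a two-state HMM over the scaffold sites
that are heterozygous and phased in both panels: state *same* or
*flipped* describes the orientation of the pre-phased dense pair relative
to the scaffold pair.  Emissions compare the dense allele at the scaffold
position with the scaffold haplotype (error `flip_error`, default 0.01 —
a single discordant scaffold site between agreeing neighbours does *not*
flip a segment, which is the intended robustness to singleton errors);
transitions use `p_switch = 1 − exp(−switch_rate_per_cm·d)` clipped to
0.5 (an unclipped value above 0.5 would be an improper transition;
default rate 0.02/cM).  Scaffold sites lying in dense-panel segments with
fewer than `min_segment_snps` (default 3) markers contribute no evidence;
such segments inherit the surrounding orientation.

Between two decoded sites of unequal state the dense pair must be flipped
at an interior changepoint.  With no evidence inside the interval the
documented fallback places the cut at the segment-map boundary nearest
the interval midpoint (`place_changepoint`; exact ties break toward the
lower position).  That blind rule leaves an average quarter-interval of
dense markers mis-oriented per pre-phase switch, which at a 1-cM scaffold
spacing would dominate the error budget, so by default the aligner
refines each changepoint to the pre-phase's most likely internal switch
position: every candidate cut in the interval is scored by the haploid
Li–Stephens log-likelihood of the two re-oriented haplotypes over a
±`refine_context` (15) marker window against the other individuals'
pre-phased haplotypes, and the maximum wins.  On clean simulations this
places the cut within a marker or two of the true switch.

Output invariants: flipping never changes genotypes; at scaffold
positions the output equals the scaffold phase exactly; an individual
with no informative site on a chromosome keeps its pre-phase there with
`origin_known=False` (warning).

## Evaluation (`phase_metrics`)

Error proportion = mismatches of assigned parental origin versus the
Mendelian phase over phasable SNPs, reported per animal (the averaging
unit) and pooled.  Runs of equal match status form correct/incorrect
segments (`last − first + 1` bp; a singleton segment has length 1 bp);
switches are the transitions between statuses; filters discard singletons
or segments with <5 phasable SNPs *and* <5 kb, re-merging the flanks.
Distances to the nearest switch use inter-SNP midpoints; chromosomes
without a switch use the distance to the nearer chromosome end so maxima
stay finite.

## Imputation (`hap_impute`)

Pre-phased scaffold haplotypes are decoded haploidly against phased dense
reference haplotypes (forward–backward; transition
`1 − exp(−4·Ne·d/K)`, emission mismatch 10⁻³ at typed sites), state
posteriors are interpolated to untyped dense sites by genetic-distance
weighting of the flanking typed sites, and the haplotype dosage is the
posterior-weighted mean of reference alleles.  Genotype dosage = sum of
the two haplotype dosages.  Note the copy-fidelity of the decoder depends
on `ρ = 4·Ne·d/K`: with few reference haplotypes and wide typed spacing
the prior permits free switching, which is the correct model behaviour
but means the "perfect copy" limit requires small `ρ`.  Cross-validation
imputes disjoint seeded pools from the remaining individuals.  The error
rate is L1: Σ|dosage − genotype| / (2·number of SNPs), reported both
averaged per chromosome×animal and pooled per allele; r² is the squared
Pearson correlation of dosage with observed genotype per SNP
(zero-variance SNPs excluded and counted).  Longest IBS runs are measured
midpoint-to-midpoint of the flanking discordant intervals, so a single
matching marker spans its local inter-marker interval.

## AHAP scaffold enrichment (`ahap_scaffold`)

Scaffold haplotypes are clustered in non-overlapping windows of
`window_markers` (20) scaffold markers by k-modes on alleles (Hamming
distance, `K` = 50 by default, 5 seeded initialisations keeping the
lowest within-cluster cost, assignment ties to the lower label).  A dense
marker is *perfectly associated* when every haplotype within each cluster
of its window carries one allele; such markers are phased for any
individual by looking up its two haplotype clusters, and added to the
scaffold.  Enrichment shortens the intervals the aligner interpolates
across and never alters original scaffold sites.  The windowed-cluster
reading of "a set of 50 ancestral haplotypes" (rather than a genome-wide
hidden-Markov cluster model) is a deliberate simplification with the same
input/output contract.

## Experiment pipeline and problem sizes

`run_experiment` composes: simulate → GEN-P1 (LD-only sparse) → GEN-P2
(familial+LD sparse) → WGS-P1 (LD-only dense) → WGS-P2 (align) →
evaluation of both → cross-validated imputation under both pre-phasings →
longest-IBS diagnostics → optional AHAP pass, and writes a TSV bundle
with a seed-stamped manifest.  The default study conditions are one
100-Mb chromosome, 2,000/100 markers and ~60 animals, which one CPU
phases end to end in a few minutes; the paired-scenario comparisons
(imputation r², longest IBS) are run at a deliberately weakened LD
setting (single restart, two main sweeps, 30 states) on a smaller panel
because with the full-strength phaser the two pre-phasings are already
nearly identical on clean data and the contrast carried by familial
information — clearly visible in the weak setting — vanishes into noise.
By default the whole population forms the dense phasing panel; the
training/holdout split that removes parents of evaluated animals from the
panel (to avoid trivially copying a parent's haplotypes) is available as
`exclude_parents_from_training`.

The "LD-only origin randomness" summary (`ld_origin_randomness`) has its
own measurement design.  Its expectation is 50% for *any* LD-only phase,
but its Monte-Carlo variance depends strongly on the phaser: the
ensembled phaser leaves chromosomes nearly switch-free, so each animal's
mismatch proportion collapses to a single 0-or-1 orientation coin and the
mean over ~40 animals has a standard error near 8 points — useless at
desk scale.  A single-pass Li–Stephens chain (one main iteration, no
ensembling) produces ~30 phase switches per chromosome — the switch
density reported for LD-only tools on real dense panels — so per-animal
proportions concentrate around one half; averaging over 8 replicate
simulated populations brings the standard error below 2 points.

## Numerical choices and degenerate inputs

* All HMM scores in log space (Viterbi) or scaled linear space
  (forward/backward); transition factorisation keeps the diploid decode
  at O(K²) per site.
* Exact ties: nearest-scaffold assignment and changepoint placement break
  toward the lower position; junction-vote ties break the evidence (the
  junction is treated as unlinked/arbitrary); k-modes assignment ties take
  the lower label; mode ties take the ref allele.
* Individuals with ≤1 heterozygous site have a unique consistent phase
  and bypass all ambiguity; single-individual panels are rejected (no
  conditioning haplotypes); a chromosome without scaffold markers is an
  error for the segment map and for imputation.
* Every stochastic component takes an explicit seed; identical seeds give
  bit-identical outputs (tested).

## Known limitations

* The LD phaser targets desk-scale panels (10²–10⁴ markers, ≤ a few
  hundred samples); it has no PBWT-style state compression, so very large
  K or marker counts become slow.
* The aligner re-orients whole segments only; it never re-estimates
  dense-site phase within an interval, so local pre-phase errors that do
  not flip a whole block pass through unchanged.
* The familial phaser handles duos/trios and half-sib linkage chains, not
  general pedigree peeling.
* Cross-dataset presence filters and assembly-diagnostic filters are
  reported as not-evaluated rather than implemented.
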