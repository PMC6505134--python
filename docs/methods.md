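# Methods

`regrowqtl` analyses the inheritance of *regrowth* — the ability of a plant
to restart a life cycle from basal axillary buds after flowering and
senescence — in F2 intercross populations of the perennial teosinte
*Zea diploperennis* (Zd) with annual maize. The package has three analytical
layers (segregation models, a SNP filtration cascade, a binary-trait genome
scan) plus a synthetic-data generator that every layer is validated against.

## Genetic model

Regrowth is treated as a binary phenotype (R / NR) controlled by `k`
dominant, **complementary** loci: a plant regrows iff it carries at least
one Zd allele at *every* causal locus. In an F2 this gives an expected
regrowing fraction of (3/4)^k — the classical 3:1, 9:7 and 27:37 ratios for
k = 1, 2, 3. Backcrossing the F1 to the Zd parent fixes a dominant allele
everywhere (all progeny regrow); backcrossing to maize gives (1/2)^k.

Goodness of fit of observed (n_R, n_NR) counts uses the Pearson chi-square
over the two phenotype classes with **df = 1 and no continuity correction**;
this choice reproduces the independently verifiable published table cells
(0.7499, 0.5862, 1.0000, 0.6547, 0.0438, 0.0833) to four decimals, which a
Yates-corrected statistic does not. Model selection takes the candidate with
the largest p-value, breaking ties toward smaller k (parsimony).

For the k = 2 model, the genotype distribution at a marker fully linked to
one causal locus, conditional on phenotype, is

* regrowing plants: (P(AA), P(AB), P(BB)) = (1/3, 2/3, 0),
* non-regrowing plants: (1/7, 2/7, 4/7).

These are computed in exact rational arithmetic (`fractions.Fraction`) and
converted to floats only at the boundary, so expected counts in the filter
below carry no 0.333… rounding drift.

## SNP filtration cascade

Four stages run in fixed order on a plants × markers genotype matrix coded
{AA = Zd homozygote, AB, BB = maize homozygote, MISSING}:

1. **Site filters** — drop sites with call rate < 0.2 or minor allele
   frequency < 0.01 (alleles counted from non-missing calls).
2. **Missingness + imputation** — drop sites missing in *more than* 20% of
   plants (strict inequality), then impute every remaining MISSING call as
   AB. The heterozygote is the non-committal call in a biparental cross
   where both alleles are known to be present.
3. **Model-constrained contingency chi-square** — per SNP, the 6 observed
   cells (R/NR × AA/AB/BB) are compared with expected counts = subpopulation
   size × the conditional distributions above; χ² = Σ(O−E)²/E over cells
   with E > 0, and **df = 4** (6 cells − 2 subpopulation-total constraints),
   giving the critical value χ²₀.₀₅,₄ = 9.49. A cell with E = 0 contributes
   nothing when empty but forces rejection when occupied: the limit of
   (O−E)²/E as E→0 with O > 0 is +∞, i.e. a single BB regrower disqualifies
   a marker as perfectly linked. SNPs with χ² < 9.49 are kept.
4. **Haplotype-cluster collapsing** — a left-to-right sweep per chromosome
   merges a marker into the open cluster iff its post-imputation genotype
   vector is *identical* (no mismatch tolerance) to the cluster signature
   and it lies within 100 bp of the cluster's **first** member; the first
   member represents the cluster. The window is anchored at the first
   member (cluster span ≤ 100 bp) rather than chained gaps; the two
   readings coincide on all worked examples.

The E = 0 rejection rule makes stage 3 deliberately severe: at a couple of
hundred plants, even a marker 2–3 cM from a causal locus usually shows one
double-recombinant BB regrower and is rejected, so survivors concentrate
tightly around causal loci (this is tested as a positional-enrichment
property).

## Genome scan

A single-locus binary-trait scan in the interval-mapping tradition:

* **Genetic map.** The default convention converts physical position to map
  position uniformly at 1 cM/Mbp (the scan consumes bp positions and
  reports bp intervals; no empirical genetic map is assumed). An
  `em_estimated` mode estimates adjacent-pair recombination fractions by
  numerical maximum likelihood over the F2 joint genotype distribution and
  chains the Haldane distances; it exists for validating simulated data.
  The Haldane map function (no crossover interference) is used throughout:
  r = (1 − e^(−2d/100))/2.
* **Conditional genotype probabilities.** A 3-state hidden Markov chain per
  chromosome per plant: state prior 1/4 : 1/2 : 1/4, transitions from r via
  two independent meioses, emission 1−ε for the observed call and ε/2 for
  each wrong call (default ε = 1e-4; MISSING is uninformative). Richer
  asymmetric error models exist; the symmetric split is documented and
  fixed. Pseudomarkers are inserted evenly so grid spacing ≤ 1 cM.
  Posteriors come from a scaled forward–backward pass, vectorised over
  plants.
* **Penetrance EM.** At every grid position the model is a 3-component
  Bernoulli mixture with weights w_ig and penetrances π_g = P(R | g).
  E-step: membership ∝ w_ig·π_g^y(1−π_g)^(1−y); M-step: π_g = weighted
  phenotype mean. π is initialised from the w-weighted phenotype means
  (clipped to [1e-3, 1−1e-3]) and clamped to [1e-12, 1−1e-12] during
  iteration to avoid log(0). Convergence: log-likelihood change < 1e-8,
  max 1000 iterations, vectorised across all positions. The null model has
  one common penetrance with closed-form MLE = mean(y).
  LOD = (ℓ₁ − ℓ₀)/ln 10; a LOD below −1e-6 raises an internal error (EM
  must at least match the null) and values in (−1e-6, 0) are floored to 0.
* **Permutation threshold.** Phenotype labels are permuted across plants,
  the full EM scan re-run (no shortcut approximation), and the genome-wide
  maximum LOD recorded; the threshold is the order statistic
  ⌈(1−α)·n_perm⌉ of the sorted maxima — no interpolation, so the value is
  reproducible across platforms. Default 1000 replicates at α = 0.05; a
  warning is issued when n_perm < 1/α.
* **Interval calling.** Per chromosome, the interval runs from the first to
  the last *observed* marker (pseudomarkers excluded) with LOD ≥ threshold,
  closed in bp; the peak is the leftmost marker of maximal LOD.

## Synthetic data generator

The generator emulates GBS-derived F2 genotype matrices so that every
downstream stage can be exercised without external data:

* fully inbred parents (Zd = AA, maize = BB everywhere); F1 = AB; F2 from
  two independently simulated gametes; backcrosses use a constant recurrent
  gamete;
* meiosis with **no interference**: crossover counts Poisson with mean =
  map length in Morgans, positions uniform in genetic distance — pairwise
  recombination follows Haldane's function in expectation, matching the
  scan's assumption;
* physical ↔ genetic coupling is uniform per chromosome (default
  1 cM/Mbp), so simulated data feed the scan's default map directly;
* phenotype from the complementary-dominant rule, then misclassification:
  `delta` converts truly regrowable plants to NR (dormancy or transplant
  loss can hide regrowth; this is the documented direction of scoring
  error, default 0), and `reverse_error` (default 0) the converse;
* GBS noise after phenotyping: per-**site** missingness drawn from
  Beta(1, 9) (mean 10%, reflecting locus-to-locus depth variation; a fixed
  rate can be forced), and genotyping error that turns AB into a random
  homozygote and a homozygote into AB;
* optional transmission distortion: a per-locus probability β that a
  heterozygous parent transmits the maize allele, imposed by rejection
  sampling of whole gametes so the linkage structure around the distorted
  locus is preserved;
* a `TruthRecord` (causal genotypes, pre-misclassification regrowability,
  applied noise counts, seed) accompanies every population; all randomness
  derives from one integer seed through deterministic sub-streams, and
  identical (config, seed) gives identical output.

The generator does **not** model read-level data (no depths, no allele
imbalance), crossover interference, linked modifier loci, or
time-dependent dormancy; passing tests therefore demonstrate correctness of
the analysis machinery under the stated model, not robustness to every
artefact of real GBS data.

## Validation problem sizes

The property-based checks run at deliberately scaled sizes chosen to keep
Monte-Carlo error well below the tested effects: parameter recovery uses 20
replicates of 200 plants × 500 markers on ten 100-Mbp chromosomes with
~10% missingness, ε-level genotyping error and 200-replicate permutation
thresholds; type-I calibration uses 200 null replicates of 60 plants × 30
markers on two chromosomes with 100-replicate thresholds; oracle checks use
exact closed forms, brute-force 6-cell sums (1000 random SNPs) and
numerical integration of the χ²₁ density.

## Known limitations

* The conditional genotype distributions (and therefore the model filter)
  are derived only for k = 2; other k values raise an error.
* The scan is strictly single-locus: no covariates, no multiple-QTL or
  epistasis models, no Haley–Knott approximation.
* The 1 cM/Mbp map convention is a declared default, not an estimate;
  empirical thresholds and intervals depend on it.
* Genotype tables are held dense in memory; matrices far beyond ~10⁵
  markers × 10³ plants would need chunking.
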