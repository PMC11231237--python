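# Methods

`ssrpop` implements the complete analysis chain used in microsatellite
surveys of semi-domesticated plants: per-locus quality control, diversity
summaries, hierarchical F-statistics, Bayesian admixture clustering, and
coalescent/ABC random-forest choice among explicit dispersal scenarios.
This note records the models, the parameter choices that matter, and the
design decisions taken where the design was genuinely open.

## Genotype data model

The unit of data is a diploid codominant genotype: an unordered pair of
allele sizes (bp) per sample per locus. A cell is either complete or
wholly missing; half-called cells are coerced to missing at ingest because
every estimator downstream assumes complete diploid cells. Samples carry a
locality label (these are collections of plants, not demes in the
biological sense) and localities may carry (lat, lon) coordinates.

The missingness filter removes samples whose missing fraction exceeds the
threshold (default 0.40), then recomputes locus missingness on the
retained samples and removes loci, repeating both passes to a fixpoint.
The sample-first order follows the usual QC sequence for SSR panels; the
fixpoint iteration makes the filter idempotent, which one pass alone does
not guarantee.

## Synthetic study emulation

Because the original genotype deposit is private, the package ships a
generator that emulates its statistical structure, and every downstream
stage is tested against that emulation.

* **Ancestral pools.** K gene pools share a per-locus allele ladder
  (dinucleotide 2-bp spacing by default). Pool frequencies follow the
  correlated-frequencies F-model: pool k's frequencies at a locus are
  Dirichlet(p_anc · (1 − F_k)/F_k) around a common ancestral vector, so
  F_k behaves like a per-pool drift/F_ST parameter.
* **Individuals.** Each sample draws its ancestry vector q (fixed per
  locality in the study preset), then each gene copy draws a pool by q and
  an allele from that pool. Inbreeding is modelled by within-individual
  allele copying: with probability F_target the second copy duplicates the
  first, giving an expected heterozygote deficit of F_target (equivalent
  to partial selfing at equilibrium, and directly controlled by one
  parameter).
* **Null alleles** are a hidden allele per locus: a carrier heterozygote
  appears homozygous for its visible allele, a double-null cell becomes
  missing — exactly the detection model the Brookfield estimator assumes.
  Missingness is applied last.

The **study preset** is a 192-sample, 24-locus, 7-locality survey with
five pools (Peruvian Amazonia, Brazilian Amazonia, Peruvian Andes,
Colombia, Mexico). Five localities are pure; Venezuela–Antilles is an even
two-pool mixture (0.5/0.5 of the Peruvian-Amazonian and Colombian pools)
and Central America a three-pool mixture (0.4 Mexico / 0.3 Colombia /
0.3 Peruvian Amazonia). Locality sizes (69/18/18/21/37/10/19) and
per-locality inbreeding targets (≈0.5 everywhere except ≈0.06 in Peruvian
Amazonia) are preset constants taken from the survey design the generator
emulates. Per-pool drift is set roughly inversely proportional to each
pool's sample mass (0.40/0.25/0.45/0.25/0.10 in the pool order above),
scaled so the emulated survey's multilocus θ lands near 0.2; the Andes
pool is the most drifted, which reproduces the qualitative pattern the
downstream analyses should recover (lowest diversity and largest pairwise
divergence in the Andes, highest diversity in admixed Mesoamerica).
Ladders have 20 slots per locus, giving a pooled allele count near 350.
Missing rate is 5% (well under the 40% filter); the preset carries no
null alleles.

What the emulation does **not** model: genotyping error other than null
alleles and missingness, allele-size homoplasy across pools beyond the
shared ladder, linkage between loci, and within-locality spatial or family
structure. Tests passing on this emulation therefore certify the
estimators and the inference machinery, not the biological conclusions one
would draw from real data.

## Locus QC

* **Brookfield null-allele estimator**: r = (He − Ho)/(1 + He) from the
  observed allele frequencies per locus per locality (the no-missing-
  information variant; the alternative that uses missing cells as putative
  null homozygotes is not implemented). Negative raw estimates are
  reported alongside the value truncated at zero; at least five complete
  genotypes are required.
* **HWE**: chi-square over genotype classes against expectations from
  observed allele frequencies, with a Monte-Carlo null built by shuffling
  the 2n gene copies and re-pairing (preserves allele frequencies
  exactly); p-values use the (b+1)/(m+1) correction. Default 1000
  permutations. Under simulated equilibrium the type-I rate at α = 0.05
  calibrates to the nominal level (acceptance suite).
* **Multiple testing**: Benjamini–Hochberg step-up (via statsmodels) in
  two separate families — per locality across loci, and per locus across
  localities — because "deviation in more than one population" is read
  from the second family.
* **r̄d (standardized index of association)**: per-locus pair distance is
  the number of allele differences between two genotypes scaled to
  {0, 0.5, 1}; missing loci are excluded pairwise (contributing 0 to the
  pair's total). r̄d = (V_O − ΣV_i) / (2 Σ_{i<j} √(V_i V_j)) with
  population variances over sample pairs; the permutation null shuffles
  genotypes among individuals independently per locus.
* **Genotype accumulation**: for x = 1..L−1 loci, the distribution of
  distinct multilocus genotypes over random locus subsets; a missing cell
  never matches anything (conservative MLG splitting).

## Diversity

Ho is the heterozygote fraction among complete genotypes; He = 1 − Σp̂²;
uHe = He·2n/(2n−1). Locality means are over loci with standard errors
s.d./√L. F = 1 − Ho/He per locus, averaged over loci with He > 0 (the
ratio-of-means alternative is emitted alongside, since either convention
appears in published tables). Rarefied allelic richness uses the exact
hypergeometric inclusion probability at a standardized size g; g defaults
to the smallest complete-copy count over locality × locus cells (reported
in the output, since published tables rarely state it). Private allelic
richness follows the ADZE construction: the expected number of alleles
present in a size-g subsample of one locality and absent from independent
size-g subsamples of all others. Both rarefaction estimators are verified
against exhaustive enumeration on all instances with ≤ 8 gene copies.

## Differentiation

* **Weir–Cockerham (1984)** per-allele variance components a, b, c with
  multilocus ratio estimators θ = Σa/Σ(a+b+c), F_IT = 1 − Σc/Σ(a+b+c),
  F_IS = 1 − Σc/Σ(b+c); confidence intervals are percentile bootstrap over
  loci (default 10,000 draws). Loci with a single genotype per population
  or one allele contribute zero components.
* **Pairwise θ** restricts the same estimator to locality pairs; negative
  point estimates are retained in the matrix and clamped only for Mantel
  linearization.
* **AMOVA** decomposes gene-copy mismatch distances (count of loci with
  different alleles, pairwise-complete and rescaled to L; an `rst` switch
  uses squared size differences instead) into among-locality,
  among-individual-within-locality and within-individual components with
  the standard unequal-size coefficients. Φ statistics: among-localities
  σa/σtot, among-samples σb/(σb+σc), samples-total (σa+σb)/σtot.
  Permutation schemes per level: whole individuals among localities; gene
  copies among individuals within localities; gene copies globally. All
  schemes re-index a single precomputed distance matrix.
* **Mantel IBD**: Pearson correlation of θ/(1−θ) against Euclidean
  distance on coordinates as given (a deliberate fidelity choice — the
  emulated workflow used plain Euclidean distance on lat/lon; a
  great-circle option would be a one-line change but is off). The null
  permutes locality labels of the genetic matrix. The statistic and its
  square are both reported without interpreting the sign of the square.
* **PCA** on the column-mean-imputed, centered allele dosage matrix
  (one 0/1/2 column per allele). **DAPC** = PCA reduction (default:
  enough axes for 80% variance, capped at n − groups) followed by linear
  discriminant analysis, with membership probabilities from the
  discriminant-space Gaussian model (scikit-learn's LDA).

## Admixture model

A Gibbs sampler over the classical admixture model with correlated allele
frequencies: latent pool-of-origin per gene copy, cluster frequencies with
the F-model prior Dirichlet(p_A(1 − F_k)/F_k) around the empirical
ancestral frequency vector (the ancestral vector is fixed at its empirical
estimate rather than sampled — a simplification that matters little when
n is large relative to K), per-cluster drift F_k and the ancestry
concentration α updated by Metropolis steps (lognormal proposals; uniform
priors on (0.001, 0.999) and (0, 10] respectively). ln Pr(data|K) is
approximated by mean(lnL) − var(lnL)/2 over post-burn-in sweeps.

Chains are initialized from a k-means partition of the allele dosage
matrix by default (`init="random"` restores a diffuse start). At
desk-scale sweep counts a diffuse start frequently strands a chain in a
label-degenerate mode; the k-means start removes most of that failure mode
while the sampler still mixes over the posterior around the mode.
Desk-scale defaults are thousands of sweeps, not the million-iteration
chains used with real data; both are reachable through parameters.

K selection implements both criteria in common use: mean LnP(K), and the
second-difference ratio ΔK = |L(K+1) − 2L(K) + L(K−1)| / s.d.(L(K)) over
independent runs. Run alignment solves the column-assignment problem
exactly (Hungarian algorithm on the Frobenius agreement objective — the
quantity the greedy CLUMPP heuristic approximates); the consensus is the
mean of aligned Q matrices.

**Known limitation.** On the study preset, ΔK does not reliably choose
K = 5. The per-cluster likelihood gains are necessarily unequal — the
survey's localities range from 69 samples to 10, and the two admixed
localities tie the smallest pool (Peruvian Amazonia) to the Colombian pool
until the last split — so the largest second difference usually sits at
K = 4 rather than 5 (ΔK's preference for the strongest hierarchical level
is well documented). Mean LnP(K) rises steeply to K = 5 and flattens
after, and the K = 5 solution itself recovers the generating structure
cleanly (each pure locality dominated by a distinct cluster; admixture
proportions within 0.05–0.1). The acceptance suite states the ΔK
recovery check as specified and reports its failure honestly rather than
substituting a criterion that passes.

The popinfo-style option is a soft locality prior (the ancestry prior of a
sample is biased toward its locality's current mean ancestry), not the
migrant-ancestry machinery; it is off by default and all reported
experiments run unsupervised.

## Dispersal scenarios and ABC-RF

Eight demes (Mexico, Central America, Antilles, Venezuela, Colombia,
Brazilian Amazonia, Peruvian Amazonia, Peruvian Andes) with effective
sizes N1..N8 and events at times t1 < ... < t5 (years; divided by a
10-year generation time and rounded up). Five topologies are encoded from
a verbal description of the candidate dispersal histories (Mexican origin;
Brazilian-Amazonian origin via Peru and Colombia; two independent centers;
independent Amazonian centers with admixed Mesoamerica; northern South
American origin). The exact branching detail beyond that description is
unavailable, so the encodings are provisional; admixture events (with
uniform(0.1, 0.9) proportions) appear only in scenario 4, whose
description alone names admixed destinations. Default priors are standard
SSR-scale ranges — N log-uniform on [10², 10⁵], t uniform on
[100, 10000] years with the ordering constraints, mean mutation rate
log-uniform on [10⁻⁴, 10⁻³] with per-locus Gamma(2) rates, GSM geometric
parameter uniform on [0, 0.3] — and a "tight" preset (narrow,
well-separated windows) serves the recovery experiments.

The simulator is a backward-in-time structured coalescent: within-deme
coalescence at rate k(k−1)/(4N) per generation, divergence events move
lineage sets, admixture events assign each lineage to a source by
Bernoulli(r). Mutations are Poisson on branches; allele sizes take ±
geometric(1 − p_step) steps (p_step = 0 is the strict stepwise model).
Verified against the analytic E[T2] = 2N, the total-tree-length formula,
and the mutational variance of pair differences.

Summary statistics (116 entries for 8 demes) cover the families a
practitioner computes for SSR ABC: per deme — mean allele number,
expected heterozygosity, allele-size variance, M index; per deme pair —
Weir–Cockerham θ, (δμ)², and allele-sharing distance. This is a
documented subset rather than a tool-specific 400+ catalogue; the subset
is sufficient to separate the five default topologies under tight priors
(≥ 80% POD recovery at 5000 training simulations in the acceptance
suite). Scenario choice is a 500-tree random-forest classifier with equal
prior scenario probability; the posterior probability of the chosen
scenario comes from a second regression forest trained on the classifier's
out-of-bag correctness indicator (vote fraction as fallback); error rates
come from freshly simulated pseudo-observed datasets per scenario.

## Reproducibility and problem sizes

Every stochastic routine takes an explicit seed; the pipeline derives all
stage seeds from one master seed and records a config hash, package
version and per-stage timings in a manifest. Test and acceptance runs use
deliberately scaled problem sizes chosen as the package's desk-scale
defaults: 1000-permutation HWE tests, 199–999 permutations for Mantel and
AMOVA, hundreds of Gibbs sweeps per admixture run, 5000 training
simulations with 10 loci and 5 diploid samples per deme for scenario
recovery. The full-scale settings used with real data (10,000 bootstraps,
million-iteration chains, 500,000 simulations) are plain parameter
changes.
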