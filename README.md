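# ssrpop

Population genetics for microsatellite (SSR) surveys of semi-domesticated
plants: from raw diploid genotype tables through locus QC, diversity and
hierarchical differentiation, Bayesian admixture clustering, and
coalescent/ABC random-forest choice among explicit dispersal scenarios.

The package is aimed at the workflow used to ask where a crop was
domesticated: genotype a few hundred accessions from named localities at a
few dozen SSR loci, establish that the loci are usable (null alleles,
Hardy–Weinberg, linkage, discriminating power), summarize diversity per
locality (N, A, rarefied Ar and private-allele richness, Ho/He/uHe, F),
quantify structure (Weir–Cockerham F-statistics, pairwise F_ST, AMOVA,
Mantel isolation-by-distance, PCA/DAPC, STRUCTURE-style admixture with
ΔK/LnP model choice), and finally rank explicit demographic scenarios by
simulating microsatellite data under each and classifying the observed
summary statistics with a random forest (ABC-RF).

The core statistical machinery, in the field's notation:

* Weir–Cockerham variance components per locus and allele — a (among
  populations), b (among individuals within populations), c (within
  individuals) — with multilocus ratio estimators
  θ = Σa/Σ(a+b+c), F_IT = 1 − Σc/Σ(a+b+c), F_IS = 1 − Σc/Σ(b+c).
* AMOVA on gene-copy mismatch distances with Φ-statistics and
  permutation tests at each level.
* Rarefaction: Ar(g) = Σ_a [1 − C(2n−n_a, g)/C(2n, g)], extended to
  private alleles across localities (ADZE-style).
* The admixture model with correlated allele frequencies
  (P_k ~ Dirichlet(p_A(1−F_k)/F_k)), fit by Gibbs sampling, with Evanno's
  ΔK and mean LnP(K) for choosing K and exact (Hungarian) CLUMPP-style
  run alignment.
* A backward-in-time structured coalescent with generalized stepwise
  mutation, feeding a reference table of summary statistics to a
  random-forest scenario classifier with POD-based error rates.

Because the motivating genotype matrix is private, a first-class
synthetic-data module emulates it: 192 samples, 24 loci, 7 localities,
five ancestral gene pools (two localities admixed), inbreeding F ≈ 0.5.
All tests and the acceptance suite run against this emulation; see
`docs/methods.md` for what the emulation does and does not capture.

## Worked example

```python
import ssrpop

# the synthetic study emulation (or read_csv / read_genepop / read_structure)
ds, truth = ssrpop.study_preset(seed=1)

tab = ssrpop.diversity_table(ds)
print(tab[["locality", "N", "A", "Ho", "He", "F"]].round(3).to_string(index=False))

fh = ssrpop.wc_f_statistics(ds, n_boot=1000, seed=0)
print(f"F_ST={fh.f_st:.3f}  F_IS={fh.f_is:.3f}  F_IT={fh.f_it:.3f}")
```

prints

```
locality   N   A    Ho    He     F
 species 192 348 0.354 0.859 0.588
     MEX  69 259 0.395 0.799 0.505
  CenAme  18 203 0.467 0.804 0.422
 VEN-ANT  18 169 0.360 0.761 0.530
     COL  21 142 0.277 0.690 0.570
  BRA-AM  37 141 0.279 0.622 0.545
  PER-AM  10  90 0.512 0.531 0.026
 PER-AND  19  92 0.239 0.543 0.551
F_ST=0.184  F_IS=0.516  F_IT=0.605
```

Read: the pooled sample is diverse (He ≈ 0.86) but heterozygote-poor
(Ho ≈ 0.35), i.e. strongly inbred (F ≈ 0.5–0.6 in most localities — the
Peruvian-Amazonian locality is the outbred exception by design). The
admixed Mesoamerican localities are the most diverse and the Andean
locality the least; differentiation among localities is moderate
(θ ≈ 0.18) while most variance sits within localities.

The same analyses are scriptable from the shell:

```
ssrpop simulate-data --preset study --seed 1 --out demo
ssrpop diversity --in demo.csv --out diversity.csv
ssrpop structure-stats --in demo.csv --boot 1000 --perm 199 --seed 1 --out diff/
ssrpop admixture --in demo.csv --kmin 1 --kmax 7 --reps 3 --iters 400 --burnin 150 --seed 1 --out adm/
ssrpop abc simulate --n 5000 --tight-priors --seed 1 --out ref.csv
ssrpop pipeline config.yaml
```

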