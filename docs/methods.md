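# Methods

## The problem

A population that expands across a landscape by repeated budding of small
founder groups (a *serial-founder* process) leaves three coupled
signatures: genetic diversity decays with distance from the origin,
background LD and homozygosity rise along the expansion axis, and the
founding order is mirrored both in pairwise genetic distances and — when
languages diverge along the same settlement tree — in linguistic
distances. An equilibrium *isolation-by-distance* (IBD) regime produces
the distance-structured differentiation but **not** the origin-anchored
diversity cline, so the two regimes can be separated by regressing
diversity statistics on distance from the putative origin. This package
implements the full chain: a spatially explicit expansion simulator,
generators for all three synthetic regimes, the diversity / LD / ROH
statistics, ancestry masking and tract-length admixture dating,
FST / f-statistics / Mantel / Procrustes machinery, and FST-based route
reconstruction.

## Expansion simulator

The landscape is a `height x width` lattice of demes with diploid
carrying capacity `K` per habitable cell. A scenario specifies an
impassable band of rows (standing in for the central rainforest belt)
with corridor cells left open; the three canonical geometries are
*northern* (an open passage at the eastern flank, around the band),
*southern* (a corridor through the band near the western flank) and
*both*. Per generation, each occupied deme undergoes, in order:

1. **stochastic logistic growth** — the next diploid census is
   `Binomial(K, p)` with `p = clip((N + r N (1 - N/K)) / K, 0, 1)`,
   which keeps censuses integral and capped at `K`. The update rule is a
   modelling choice: any scheme with this mean and integer support would
   serve.
2. **Wright–Fisher resampling** — each offspring haplotype draws two
   parental haplotypes uniformly; within each chromosome the starting
   parent is random and crossovers fall as a Poisson process on the
   genetic map (constant 1 cM/Mb in generated data).
3. **symmetric migration** — with each occupied von Neumann (4-)
   neighbour, `Binomial(min(2N_i, 2N_j), m)` haplotypes are swapped, so
   the global haplotype count is conserved.
4. **colonization** — once a deme's census exceeds
   `colonization_threshold * K`, every empty habitable neighbour is
   founded by `F` haplotypes sampled without replacement from the
   source. The threshold rule (rather than probabilistic budding) is a
   documented stand-in; it is the simplest rule reproducing a
   travelling colonization wave with tunable founder strength.

Arrival generations and founding edges (source deme, daughter deme,
generation) are recorded; the edges form a tree rooted at the origin
that downstream modules use as ground truth. All randomness comes from a
single counter-based Philox stream per simulation, so a run is a pure
function of (inputs, seed).

Forward simulation of full haplotypes replaces coalescent genealogies:
at desk scale it directly yields phased panels consumable by every
downstream statistic, with no intermediate tree format.

## Scenario inference

Each candidate geometry is simulated with parameters drawn from
independent uniform priors (`r in [0.2, 1.0]`, `m in [0.01, 0.2]`,
`F in {2..20}`, threshold in `[0.3, 0.7]`). A simulation is summarised
by the vector of pairwise Hudson FST values between the sampled
populations; support for a scenario against an observed dataset is the
squared Pearson correlation r² between observed and simulated vectors,
aggregated as the **maximum** over simulations (the max-profile is a
standard ABC point support) and reported together with the top-decile
mean so that sensitivity to the aggregation is visible. Ranking is by
r2_max, ties by the decile mean, then name. Simulations in which a
sampled deme is never colonized (or the summary is undefined) are
excluded from the aggregation symmetrically across scenarios.

The desk default is 200 draws per scenario on a 5 x 6 toy world with a
two-row barrier, 240 SNPs on one 1-Morgan chromosome and 12 diploids per
sampled deme; the full-scale million-draw design is reachable through
configuration but is not a default.

## Diversity statistics

* **Haplotype richness** — windows of `window_snps = 20` consecutive
  SNPs; within each window `g = 20` haplotypes (ten diploids, the
  smallest population accepted into analyses) are subsampled without
  replacement `reps = 10` times and distinct rows counted; averages are
  taken over repetitions, windows and chromosomes. The closed-form
  hypergeometric expectation serves as the testing oracle.
* **Haplotype heterozygosity** — unbiased estimator
  `(n/(n-1))(1 - sum p_h^2)` per window over haplotype frequencies.
* **LD decay** — squared Pearson correlation between allele indicators
  of SNP pairs up to 500 kb apart, pairwise-complete over missing data,
  binned by physical distance.
* **ROH** — haplotype pairs are folded into diploid genotypes and
  scanned greedily left-to-right for maximal runs with at most
  `het_allowance = 1` heterozygous call, reported when spanning at least
  `min_snps = 50` SNPs and `min_kb = 500` kb. Five summary parameters
  (mean size, total length, short/long sums split at 1.6 Mb, F_ROH =
  total ROH length over mapped genome length) and six length classes
  (<0.5, 0.5–1, 1–2, 2–4, 4–8, >8 Mb) are reported; the class sums
  conserve the total exactly. The thresholds follow common array-data
  practice and are all configurable.
* **Decline with distance** — ordinary least squares of a
  per-population statistic on great-circle km from the origin
  (haversine, R = 6371.0088 km), with the two-sided t-test on the
  slope. A constant statistic returns slope 0, r² 0, p 1.

## Ancestry masking and admixture dating

Local-ancestry tracts (BED-like, 0-based half-open, with bp and cM
coordinates) are consumed, not inferred. Masking sets every allele
inside a non-target tract to MISSING per haploid genome; the per-sample
target fraction is cM-weighted (matching the Morgan units of the dating
estimator) and averaged over the two haplotypes. Downstream datasets
keep populations with mean target fraction >= 0.70 and >= 10 samples,
downsampling larger populations to 30.

Dating uses the exponential tract-length estimator. After a single
pulse `t` generations ago contributing fraction `m` of non-target
ancestry, the non-target tract length is approximately
`Exp((1 - m) t)` per Morgan, so `t_hat = 1 / ((1 - m_hat) L_bar)` with
`m_hat` the cM-weighted non-target fraction and `L_bar` the mean length
of *uncensored* non-target tracts (tracts touching a chromosome end are
excluded, since their true length is unobserved). Confidence intervals
are a percentile bootstrap over haplotypes. This closed-form estimator
replaces co-ancestry-curve dating: it is implementable from tract input
alone and its accuracy is checkable against generated truth, where it
recovers a 30-generation pulse within 20 %.

## Distances, f-statistics, Mantel, Procrustes

* **FST** — Hudson's estimator in ratio-of-averages form,
  `mean[(p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)] /
  mean[p1(1-p2) + p2(1-p1)]`, excluding MISSING alleles per SNP per
  population; pairs without usable SNPs are NaN with a warning. A
  two-population Weir–Cockerham estimator is available behind a flag as
  a cross-check.
* **f3 / f4** — `f3(C;A,B) = mean[(c-a)(c-b) - c(1-c)/(n_C-1)]` (the
  correction is on by default; an uncorrected mode exists for
  hand-checkable examples) and `f4(A,B;C,D) = mean[(a-b)(c-d)]`, with
  leave-one-block-out jackknife standard errors on blocks of
  `block_snps = 100` SNPs and `Z = estimate / SE`.
* **Geographic distance** — pairwise haversine km between population
  coordinates.
* **Linguistic distance** — the Hamming proportion over mutually scored
  meaning slots of a multistate cognate matrix. (The matrix-to-distance
  transform is a package choice; Hamming proportion is the minimal
  assumption-free option for multistate data.)
* **Mantel / partial Mantel** — Pearson correlation over upper-triangle
  entries (partial: after element-wise OLS residualisation of both
  triangles on the third matrix), with two-sided permutation p-values
  from simultaneous row/column permutation, default 9,999 permutations.
  Under independence the p-values are uniform (checked by KS test).
* **PCA** — dosage matrix mean-imputed per SNP, centred by `2p` and
  scaled by `sqrt(p(1-p))`; all-missing and monomorphic SNPs are
  dropped. The sign of each component is fixed by making its
  largest-magnitude loading positive, so output is deterministic.
* **Procrustes** — least-squares similarity transform (rotation +
  scale + translation) of one 2-D configuration onto another via the
  SVD solution; the Procrustes correlation is
  `sqrt(1 - SS_min / SS_B)` and the p-value permutes the row
  correspondence.

## Route reconstruction

"Tracing nearest FST values over the landscape" is formalised as
origin-seeded Prim accretion: repeatedly attach the unattached
population with minimal FST to any attached one, directing the edge
outward — which yields the FST minimum spanning tree rooted at the
origin. Ties break by smaller great-circle distance, then
lexicographically, making the output invariant to label order. This is
the minimal formal object consistent with arrow-style route figures and
with the leave-one-out behaviour in which removing a hub population
re-attaches its children to their next-nearest attached neighbours.

The gradient surface interpolates the origin-anchored FST profile onto
a hexagonal lattice (rows `hex_size * sqrt(3)/2` degrees apart,
alternate rows offset by half a cell) by inverse-distance weighting
(default power 2, configurable) and reports per cell the magnitude of a
least-squares local plane fitted through neighbouring cells — exact for
planar fields regardless of neighbour geometry. Cells with no
population within the IDW cutoff are flagged empty.

## Synthetic-data generators

* **Serial-founder** (the *small-world* fixture): a 12 x 8 grid,
  K = 25, r = 0.8, m = 0.05, F = 6, threshold 0.5, 70 generations,
  2 chromosomes x 2,000 SNPs on 150-cM maps; 18 populations of 10–30
  diploids sampled evenly along the arrival order. The founding tree is
  recorded as truth.
* **Stepping-stone**: an 8 x 5 grid fully occupied at K = 20 from
  generation 0 and run for `20 K = 400` generations of burn-in (enough
  for migration-drift FST to approach equilibrium at m = 0.05); 12
  populations sampled. No founding tree exists, so no diversity cline
  is expected.
* **Admixed**: one ancestral frequency spectrum drifted in two isolated
  populations of 50 diploids for `0.3 * 2N = 30` generations (giving
  source FST in the 0.1–0.2 regime, large enough for f3 tests to have
  power at n = 30 without claiming realism), mixed in a single pulse
  (default `t = 30` generations ago, `m = 0.2`) into a population of
  250 diploids, then randomly mated with Poisson recombination over
  2 x 1,000 SNPs on 150-cM maps. Ancestry labels are carried through
  every meiosis, so the recorded tracts are exact up to the SNP grid
  (boundaries are placed at inter-SNP midpoints; at 0.15 cM spacing
  the discretisation bias on mean tract length is a few per cent). 50
  diploids are sampled, along with 30 from each source so that
  f-statistics can be computed on the same panel.
* **Cognates**: meaning-slot columns evolve along the founding tree
  under infinite-alleles substitution (each substitution draws a
  previously unused state — cognate classes never revert), producing
  multistate matrices whose Hamming distances grow with tree path
  length.

What these generators deliberately do **not** emulate: real African
geography or climate forcing, empirical recombination maps, mutation
after the founding of the ancestral pool, ascertainment bias of
genotyping arrays, and multi-wave or continuous admixture. Passing
tests therefore demonstrate internal consistency of the method chain
under the stated models, not performance on real data.

## Numerical and design notes

* MISSING alleles are encoded as −1 in `int8` haplotype matrices; all
  genomic intervals are 0-based half-open.
* A sample carrying both QC flags is counted once, under
  `low_call_rate` (call-rate filtering is applied first), which makes
  the QC report arithmetic exact.
* Hudson FST pairs with zero usable SNPs, linguistic pairs with no
  shared slots and empty hex cells are NaN-flagged rather than errors;
  genuinely degenerate inputs (too few samples, populations or blocks)
  raise typed exceptions.
* Problem sizes in the test suite and the acceptance script (ten
  replicate datasets per regime, 200 prior draws per scenario, toy
  grids up to 12 x 8) are chosen so the full chain runs on a single
  CPU at desk scale; every size is configurable upward.

## Known limitations

* The colonization rule is threshold-based budding; probabilistic
  budding or distance-decayed colonization are not implemented.
* The dating estimator assumes a single pulse; continuous gene flow
  biases `t_hat` toward intermediate values.
* The route tree is a global MST; per-linguistic-group tracing is
  supported only through the `exclude` mechanism and label subsetting.
* The Weir–Cockerham cross-check implements the two-population haploid
  allele-count form only.
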