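# rangexpand

Spatially explicit range-expansion simulation and serial-founder
population-genetic analysis.

## What it is for

When a population expands across a landscape by repeated small founder
groups, it leaves a characteristic trail: genetic diversity declines
with distance from the origin, pairwise differentiation (F<sub>ST</sub>)
traces the founding order, admixture with resident groups gets
progressively younger along the route, and languages carried by the
migrants diverge along the same settlement tree. An equilibrium
isolation-by-distance regime mimics the differentiation pattern but not
the diversity cline. `rangexpand` is a toolkit for detecting and
reconstructing such expansions — built around the population history of
Bantu-speaking populations across sub-Saharan Africa, and exercisable
end-to-end on synthetic data at desk scale.

It provides:

* a deme-lattice forward Wright–Fisher **expansion simulator** with
  scenario-specific habitat barriers and corridors (northern / southern
  / both routes), recording arrival times and the founding tree;
* **ABC-style scenario comparison**: r² support of each route geometry
  against an observed pairwise-F<sub>ST</sub> summary, over uniform
  prior draws;
* **diversity statistics** — rarefied haplotype richness, unbiased
  haplotype heterozygosity, LD decay within 500 kb, runs of
  homozygosity (five parameters, six length classes) — and their
  regression on great-circle distance from the origin;
* **ancestry masking** from local-ancestry tracts, ≥ 70 %
  target-ancestry filtering, and **tract-length admixture dating**
  (`t̂ = 1 / ((1 − m̂) · L̄)` Morgans) with bootstrap intervals;
* **Hudson F<sub>ST</sub>**, f3 / f4 with block-jackknife Z scores,
  great-circle and cognate (Hamming) distance matrices, **Mantel /
  partial Mantel** permutation tests, PCA and **Procrustes** alignment
  to geography;
* **route tracing** (origin-seeded minimum spanning tree over
  F<sub>ST</sub>, with leave-one-out) and a hexagonal
  F<sub>ST</sub>-gradient surface;
* **synthetic-data generators** (serial-founder, stepping-stone,
  admixed-with-exact-tracts, cognate matrices) with recorded ground
  truth, so every stage is testable without any data download.

See `docs/methods.md` for the models, estimators and their assumptions.

## Worked example

Generate a serial-founder dataset, measure the diversity cline, and
date the admixture pulse of an admixed dataset:

```python
from rangexpand import admixture, diversity, synthetic

panel, manifest, truth = synthetic.generate_serial_founder_dataset(seed=1)
rich = diversity.haplotype_richness(panel, manifest, seed=3)
reg = diversity.diversity_distance_regression(rich, manifest,
                                              truth.origin_latlon)
print(f"slope {reg.slope:.3e} per km, p = {reg.p:.2e}, r2 = {reg.r2:.2f}")

_, tracts, _, atruth = synthetic.generate_admixed_dataset(seed=5)
date = admixture.date_admixture_from_tracts(tracts)
print(f"t_hat = {date.t_hat:.1f} generations (truth "
      f"{atruth.params['t_admix']}), m_hat = {date.m_hat:.3f}")
```

Output:

```
slope -7.625e-04 per km, p = 1.16e-03, r2 = 0.49
t_hat = 29.2 generations (truth 30), m_hat = 0.204
```

The negative, significant slope is the serial-founder signature —
haplotype richness decays along the expansion path (a stepping-stone
dataset generated with `generate_stepping_stone_dataset` shows no such
decline). The tract-length estimator recovers the simulated
30-generation admixture pulse within a few percent.

The same pipeline is available from the shell:

```bash
rangexpand generate --model serial-founder --seed 1 --out-dir out/
rangexpand diversity --panel out/panel.tsv --manifest out/manifest.csv \
    --origin-lat 8.0 --origin-lon 8.0 --out-prefix out/div
rangexpand fst --panel out/panel.tsv --manifest out/manifest.csv \
    --out out/fst.tsv
rangexpand routes --fst out/fst.tsv --manifest out/manifest.csv \
    --origin P00 --out out/routes.tsv
```

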