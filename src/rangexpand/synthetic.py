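"""Synthetic dataset generators with known ground truth.

Three generators emulate the statistical structure the analyses assume,
so the whole pipeline is testable without any external data:

* **serial-founder** — wraps the expansion simulator: populations of
  10-30 diploids sampled along the colonized lattice, diversity declining
  with distance from the origin, the founding tree recorded as truth;
* **stepping-stone** — the same lattice fully occupied from generation 0
  (no expansion) and run to migration-drift equilibrium: differentiation
  grows with lattice separation but there is no origin-anchored
  diversity cline;
* **admixed** — two source populations drifted apart from one ancestral
  gene pool, mixed in a single pulse ``t`` generations before present
  with proportion ``m``, then randomly mated with Poisson recombination;
  ancestry is tracked along every haplotype, so the recorded tracts are
  exact and non-target tract lengths are approximately exponential with
  mean ``1/((1-m) t)`` Morgans.

A cognate-matrix generator evolves multistate meaning-slot columns along
the founding tree under infinite-alleles substitution, producing
languages that diverge with tree distance.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AncestryTractSet, GenotypePanel, SampleManifest
from .exceptions import RangexpandError
from .sim import (
    Cell,
    GeneticsConfig,
    ScenarioSpec,
    _map_axes,
    _meiosis_batch,
    build_landscape,
    sample_panel,
    simulate_expansion,
)


@dataclass
class SyntheticTruth:
    """Ground truth recorded by a generator; determines outputs given seed."""

    generator: str
    params: dict
    seed: int
    founding_edges: list[tuple[Cell, Cell, int]] = field(default_factory=list)
    deme_of_pop: dict[str, Cell] = field(default_factory=dict)
    origin_cell: Cell | None = None
    origin_latlon: tuple[float, float] | None = None
    tracts: AncestryTractSet | None = None


# ----------------------------------------------------------------------
# Serial-founder generator (the "small-world" expansion fixture)
# ----------------------------------------------------------------------

@dataclass
class SerialFounderConfig:
    """Defaults give the small-world fixture: a 12 x 8 lattice, 18
    sampled populations, 2 chromosomes x 2,000 SNPs."""

    width: int = 12
    height: int = 8
    K: int = 25
    n_pops: int = 18
    growth_rate: float = 0.8
    migration_rate: float = 0.05
    founder_size: int = 6
    colonization_threshold: float = 0.5
    generations: int = 70
    min_n: int = 10
    max_n: int = 30
    genetics: GeneticsConfig = field(default_factory=lambda: GeneticsConfig(
        n_chrom=2, snps_per_chrom=2000, cM_length=150.0))


def small_world_config() -> SerialFounderConfig:
    """The end-to-end fixture configuration (runs the pipeline at desk scale)."""
    return SerialFounderConfig()


def _linguistic_group(cell: Cell, origin: Cell, width: int,
                      height: int) -> str:
    if cell == origin:
        return "NW-BSP2"
    r, c = cell
    if c < width / 2:
        return "WW-BSP" if r < height / 2 else "SW-BSP"
    return "E-BSP"


def generate_serial_founder_dataset(
        config: SerialFounderConfig | None = None, seed: int = 0,
) -> tuple[GenotypePanel, SampleManifest, SyntheticTruth]:
    """Expansion dataset: populations strung along the colonization wave."""
    cfg = config or SerialFounderConfig()
    scenario = ScenarioSpec(
        name="both", growth_rate=cfg.growth_rate,
        migration_rate=cfg.migration_rate, founder_size=cfg.founder_size,
        colonization_threshold=cfg.colonization_threshold)
    grid = build_landscape(cfg.width, cfg.height, scenario,
                           origin=(8.0, 8.0), K=cfg.K)
    res = simulate_expansion(grid, scenario, cfg.genetics,
                             cfg.generations, seed)
    rng = np.random.default_rng(seed + 1)
    colonized = sorted(res.colonized,
                       key=lambda c: (res.arrival_time[c], c))
    if len(colonized) < cfg.n_pops:
        raise RangexpandError(
            f"only {len(colonized)} demes colonized; need {cfg.n_pops}")
    pick = np.unique(np.linspace(0, len(colonized) - 1,
                                 cfg.n_pops).round().astype(int))
    demes = [colonized[i] for i in pick]
    sampling = []
    for d in demes:
        cap = min(cfg.max_n, res.census(d))
        sampling.append((d, int(rng.integers(cfg.min_n, cap + 1))))
    groups = [_linguistic_group(d, grid.origin_cell, cfg.width, cfg.height)
              for d in demes]
    panel, manifest = sample_panel(
        res, sampling, seed=seed + 2, linguistic_groups=groups)
    truth = SyntheticTruth(
        generator="serial_founder",
        params={"width": cfg.width, "height": cfg.height, "K": cfg.K,
                "r": cfg.growth_rate, "m": cfg.migration_rate,
                "F": cfg.founder_size,
                "threshold": cfg.colonization_threshold},
        seed=seed,
        founding_edges=res.founding_edges,
        deme_of_pop={p: d for p, d in
                     zip(manifest.populations, demes)},
        origin_cell=grid.origin_cell,
        origin_latlon=grid.cell_coords(grid.origin_cell),
    )
    return panel, manifest, truth


# ----------------------------------------------------------------------
# Stepping-stone (isolation-by-distance) generator
# ----------------------------------------------------------------------

@dataclass
class SteppingStoneConfig:
    width: int = 8
    height: int = 5
    K: int = 20
    n_pops: int = 12
    migration_rate: float = 0.05
    burn_in_factor: int = 20           # burn-in = factor * K generations
    min_n: int = 10
    max_n: int = 30
    genetics: GeneticsConfig = field(default_factory=lambda: GeneticsConfig(
        n_chrom=2, snps_per_chrom=800, cM_length=120.0))


def generate_stepping_stone_dataset(
        config: SteppingStoneConfig | None = None, seed: int = 0,
) -> tuple[GenotypePanel, SampleManifest, SyntheticTruth]:
    """Equilibrium lattice dataset: IBD without a diversity cline."""
    cfg = config or SteppingStoneConfig()
    scenario = ScenarioSpec(name="both", growth_rate=0.8,
                            migration_rate=cfg.migration_rate,
                            founder_size=2, colonization_threshold=0.5)
    grid = build_landscape(cfg.width, cfg.height, scenario,
                           origin=(8.0, 8.0), K=cfg.K)
    burn_in = cfg.burn_in_factor * cfg.K
    res = simulate_expansion(grid, scenario, cfg.genetics, burn_in, seed,
                             start_full=True)
    rng = np.random.default_rng(seed + 1)
    cells = sorted(res.final_haplotypes)
    pick = np.unique(np.linspace(0, len(cells) - 1,
                                 cfg.n_pops).round().astype(int))
    demes = [cells[i] for i in pick]
    sampling = [(d, int(rng.integers(cfg.min_n,
                                     min(cfg.max_n, res.census(d)) + 1)))
                for d in demes]
    groups = [_linguistic_group(d, grid.origin_cell, cfg.width, cfg.height)
              for d in demes]
    panel, manifest = sample_panel(res, sampling, seed=seed + 2,
                                   linguistic_groups=groups)
    truth = SyntheticTruth(
        generator="stepping_stone",
        params={"width": cfg.width, "height": cfg.height, "K": cfg.K,
                "m": cfg.migration_rate, "burn_in": burn_in},
        seed=seed,
        deme_of_pop={p: d for p, d in zip(manifest.populations, demes)},
        origin_cell=grid.origin_cell,
        origin_latlon=grid.cell_coords(grid.origin_cell),
    )
    return panel, manifest, truth


# ----------------------------------------------------------------------
# Admixed generator with exact ancestry tracts
# ----------------------------------------------------------------------

@dataclass
class AdmixedConfig:
    t_admix: int = 30                 # generations since the pulse
    m_admix: float = 0.2              # non-target admixture fraction
    n_sample: int = 50                # admixed diploids sampled
    N_admixed: int = 250              # admixed population diploid size
    N_source: int = 50                # each source population diploid size
    source_drift_factor: float = 0.3  # drift gens = factor * 2 * N_source
    n_source_sample: int = 30         # diploids sampled per source
    target_label: str = "WCA"
    other_label: str = "wRHG"
    genetics: GeneticsConfig = field(default_factory=lambda: GeneticsConfig(
        n_chrom=2, snps_per_chrom=1000, cM_length=150.0))


def _drift(pool: np.ndarray, generations: int, axes, rng) -> np.ndarray:
    pos_concat, chrom_ids, n_chrom, m_tot = axes
    for _ in range(generations):
        pool = _meiosis_batch(pool, pool.shape[0], pos_concat, chrom_ids,
                              n_chrom, m_tot, rng)
    return pool


def _tracts_from_labels(hap_id: str, labels_row: np.ndarray,
                        variants: pd.DataFrame, names: dict[int, str],
                        rows: list) -> None:
    """Append run-length tracts (midpoint boundaries) for one haplotype."""
    chroms = list(dict.fromkeys(variants["chrom"]))
    chrom_arr = variants["chrom"].to_numpy()
    bp = variants["pos_bp"].to_numpy()
    cm = variants["pos_cM"].to_numpy()
    for chrom in chroms:
        sel = np.flatnonzero(chrom_arr == chrom)
        lab = labels_row[sel]
        cbp, ccm = bp[sel], cm[sel]
        change = np.flatnonzero(lab[1:] != lab[:-1])
        starts = np.r_[0, change + 1]
        ends = np.r_[change, len(lab) - 1]
        for s, e in zip(starts, ends):
            start_bp = int(cbp[s] if s == 0
                           else (cbp[s - 1] + cbp[s] + 1) // 2)
            end_bp = int(cbp[e] + 1 if e == len(lab) - 1
                         else (cbp[e] + cbp[e + 1] + 1) // 2)
            start_cM = float(ccm[s] if s == 0
                             else (ccm[s - 1] + ccm[s]) / 2)
            end_cM = float(ccm[e] if e == len(lab) - 1
                           else (ccm[e] + ccm[e + 1]) / 2)
            rows.append((hap_id, chrom, start_bp, end_bp,
                         start_cM, end_cM, names[int(lab[s])]))


def generate_admixed_dataset(
        config: AdmixedConfig | None = None, seed: int = 0,
) -> tuple[GenotypePanel, AncestryTractSet, SampleManifest, SyntheticTruth]:
    """Single-pulse admixed population with exactly recorded tracts.

    The returned panel holds the admixed population plus samples from
    both source populations (so f3-style admixture tests can run on it);
    tracts cover the admixed samples only.
    """
    cfg = config or AdmixedConfig()
    if cfg.t_admix <= 0:
        raise ValueError("t_admix must be > 0")
    rng = np.random.Generator(np.random.Philox(seed))
    variants = cfg.genetics.variant_table()
    axes = _map_axes(variants)
    L = cfg.genetics.n_snps
    anc_freqs = rng.uniform(*cfg.genetics.freq_range, L)
    drift_gens = int(round(cfg.source_drift_factor * 2 * cfg.N_source))
    src = {}
    for key in ("A", "B"):
        pool = (rng.random((2 * cfg.N_source, L)) < anc_freqs
                ).astype(np.int8)
        src[key] = _drift(pool, drift_gens, axes, rng)

    n_hap = 2 * cfg.N_admixed
    from_b = rng.random(n_hap) < cfg.m_admix
    picks_a = rng.integers(0, src["A"].shape[0], n_hap)
    picks_b = rng.integers(0, src["B"].shape[0], n_hap)
    pool = np.where(from_b[:, None], src["B"][picks_b], src["A"][picks_a])
    anc = np.where(from_b[:, None], np.int8(1), np.int8(0)) \
        * np.ones((1, L), dtype=np.int8)
    pos_concat, chrom_ids, n_chrom, m_tot = axes
    for _ in range(cfg.t_admix):
        pool, anc = _meiosis_batch(pool, n_hap, pos_concat, chrom_ids,
                                   n_chrom, m_tot, rng, companions=(anc,))

    sel = np.sort(rng.choice(cfg.N_admixed, cfg.n_sample, replace=False))
    hap_rows, man_rows, sample_ids, tract_rows = [], [], [], []
    names = {0: cfg.target_label, 1: cfg.other_label}
    for j, dip in enumerate(sel):
        sid = f"ADM_{j:03d}"
        sample_ids.append(sid)
        for h in range(2):
            row = 2 * int(dip) + h
            hap_rows.append(pool[row])
            _tracts_from_labels(f"{sid}_h{h}", anc[row], variants,
                                names, tract_rows)
        man_rows.append((sid, "ADM", "SIM", "E-BSP", -5.0, 25.0, set()))
    for key, pop, grp, lat, lon in (
            ("A", "SRC_WCA", "non-BSP", 5.0, 12.0),
            ("B", "SRC_OTH", "non-BSP", -20.0, 20.0)):
        dips = np.sort(rng.choice(cfg.N_source, cfg.n_source_sample,
                                  replace=False))
        for j, dip in enumerate(dips):
            sid = f"{pop}_{j:03d}"
            sample_ids.append(sid)
            hap_rows.append(src[key][2 * int(dip)])
            hap_rows.append(src[key][2 * int(dip) + 1])
            man_rows.append((sid, pop, "SIM", grp, lat, lon, set()))

    panel = GenotypePanel(variants=variants.copy(),
                          haplotypes=np.vstack(hap_rows).astype(np.int8),
                          sample_ids=sample_ids)
    manifest = SampleManifest(pd.DataFrame(
        man_rows, columns=["sample_id", "population", "country",
                           "linguistic_group", "latitude", "longitude",
                           "qc_flags"]))
    tracts = AncestryTractSet(pd.DataFrame(
        tract_rows, columns=["haplotype_id", "chrom", "start_bp", "end_bp",
                             "start_cM", "end_cM", "ancestry"]))
    truth = SyntheticTruth(
        generator="admixed",
        params={"t_admix": cfg.t_admix, "m_admix": cfg.m_admix,
                "N_admixed": cfg.N_admixed, "N_source": cfg.N_source,
                "drift_generations": drift_gens},
        seed=seed,
        tracts=tracts,
    )
    return panel, tracts, manifest, truth


# ----------------------------------------------------------------------
# Cognate-matrix generator
# ----------------------------------------------------------------------

def generate_cognate_matrix(truth: SyntheticTruth, n_slots: int = 60,
                            sub_prob: float = 0.1,
                            seed: int = 0) -> pd.DataFrame:
    """Evolve a multistate cognate matrix along the founding tree.

    Each meaning slot starts in state 0 at the origin deme and evolves
    along founding edges; a substitution (probability ``sub_prob`` per
    edge) draws a brand-new integer state (infinite-alleles, so cognate
    classes never revert).  Rows are the sampled populations.
    """
    if not truth.founding_edges or truth.origin_cell is None:
        raise RangexpandError(
            "truth has no founding tree; cognate evolution needs one")
    rng = np.random.default_rng(seed)
    children: dict[Cell, list[Cell]] = {}
    for parent, child, _gen in truth.founding_edges:
        children.setdefault(parent, []).append(child)
    states: dict[Cell, np.ndarray] = {
        truth.origin_cell: np.zeros(n_slots, dtype=np.int64)}
    counter = 1
    stack = [truth.origin_cell]
    while stack:
        node = stack.pop()
        for child in children.get(node, []):
            s = states[node].copy()
            mut = rng.random(n_slots) < sub_prob
            for k in np.flatnonzero(mut):
                s[k] = counter
                counter += 1
            states[child] = s
            stack.append(child)
    rows = {}
    for pop, deme in truth.deme_of_pop.items():
        if deme not in states:
            raise RangexpandError(
                f"deme {deme} of population {pop} not on the founding tree")
        rows[pop] = states[deme]
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=[f"slot_{k}" for k in range(n_slots)])


def tree_path_lengths(truth: SyntheticTruth) -> pd.DataFrame:
    """Pairwise founding-tree path lengths (edge counts) between populations."""
    if not truth.founding_edges or truth.origin_cell is None:
        raise RangexpandError("truth has no founding tree")
    parent = {child: par for par, child, _g in truth.founding_edges}

    def path_to_root(cell: Cell) -> list[Cell]:
        path = [cell]
        while path[-1] in parent:
            path.append(parent[path[-1]])
        return path

    pops = list(truth.deme_of_pop)
    out = np.zeros((len(pops), len(pops)))
    paths = {p: path_to_root(truth.deme_of_pop[p]) for p in pops}
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            pi, pj = paths[pops[i]], paths[pops[j]]
            common = set(pi) & set(pj)
            di = next(k for k, c in enumerate(pi) if c in common)
            dj = next(k for k, c in enumerate(pj) if c in common)
            out[i, j] = out[j, i] = di + dj
    return pd.DataFrame(out, index=pops, columns=pops)
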