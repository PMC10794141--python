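"""Spatially explicit forward-in-time Wright-Fisher expansion simulator.

The demographic model is a rectangular lattice of demes (panmictic
subpopulations), each with a diploid carrying capacity ``K``.  A scenario
places an impassable habitat barrier (a band of rows standing in for the
rainforest belt) with one or more open corridor cells, so that the three
canonical expansion geometries — a northern passage, a southern corridor,
or both — can be compared.  Starting from a single origin deme at carrying
capacity, every generation each occupied deme undergoes

1. stochastic logistic growth — the next diploid census is a Binomial draw
   with mean ``N + r N (1 - N/K)``, capped at ``K``;
2. Wright-Fisher resampling of ``2N`` haplotypes from the parental pool,
   with per-chromosome Poisson recombination on the genetic (cM) map;
3. symmetric migration — with each occupied 4-neighbour, a
   ``Binomial(min(2N_i, 2N_j), m)``-sized swap of haplotypes, so the total
   haplotype count is conserved;
4. colonization — once a deme's census exceeds
   ``colonization_threshold * K``, each empty habitable 4-neighbour is
   founded by ``F`` haplotypes sampled from the source.

Genealogy bookkeeping records the arrival generation of every deme and the
founding edge (source deme, daughter deme, generation), which together form
a tree rooted at the origin — the "founding tree" used as ground truth by
the synthetic-data generators.

All randomness flows from a single counter-based (Philox) stream seeded by
one integer, so identical inputs and seed give bitwise-identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypePanel, SampleManifest
from .exceptions import ConfigurationError, RangexpandError, SamplingError

logger = logging.getLogger(__name__)

Cell = tuple[int, int]  # (row, col)

SCENARIO_NAMES = ("northern", "southern", "both")


@dataclass
class ScenarioSpec:
    """One expansion scenario: barrier geometry plus demographic rates.

    Parameters
    ----------
    name : str
        One of ``northern``, ``southern``, ``both``.
    barrier_rows : tuple (start, stop)
        Half-open row range of the impassable band; ``None`` for no barrier.
    corridors : set of (row, col)
        Cells inside the band that remain habitable (the open passages).
    growth_rate : float
        Logistic growth rate ``r`` per generation (> 0).
    migration_rate : float
        Per-neighbour haplotype swap probability ``m`` (0 <= m <= 0.25,
        so a 4-neighbour deme can never export more than its census).
    founder_size : int
        Number of founding haplotypes ``F`` (>= 2).
    colonization_threshold : float
        Fraction of ``K`` a deme must exceed before it buds daughters.
    """

    name: str
    barrier_rows: tuple[int, int] | None = None
    corridors: frozenset[Cell] = field(default_factory=frozenset)
    growth_rate: float = 0.8
    migration_rate: float = 0.05
    founder_size: int = 6
    colonization_threshold: float = 0.5

    def __post_init__(self) -> None:
        self.corridors = frozenset(tuple(c) for c in self.corridors)
        if self.name not in SCENARIO_NAMES:
            raise ConfigurationError(
                f"scenario name must be one of {SCENARIO_NAMES}")
        if self.growth_rate <= 0:
            raise ConfigurationError("growth_rate must be > 0")
        if not 0.0 <= self.migration_rate <= 0.25:
            raise ConfigurationError("migration_rate must be in [0, 0.25]")
        if self.founder_size < 2:
            raise ConfigurationError("founder_size must be >= 2")
        if not 0.0 < self.colonization_threshold:
            raise ConfigurationError("colonization_threshold must be > 0")


@dataclass
class DemeGrid:
    """Lattice landscape: habitability, carrying capacities, coordinates."""

    width: int
    height: int
    habitable: np.ndarray          # bool (height, width)
    K: np.ndarray                  # int (height, width); 0 on barrier
    origin_cell: Cell
    lat: np.ndarray                # (height,) latitude per row
    lon: np.ndarray                # (width,) longitude per column

    def __post_init__(self) -> None:
        self.habitable = np.asarray(self.habitable, dtype=bool)
        self.K = np.asarray(self.K, dtype=int)
        if self.habitable.shape != (self.height, self.width):
            raise ConfigurationError("habitable mask shape mismatch")
        if not self.habitable[self.origin_cell]:
            raise ConfigurationError("origin cell is not habitable")
        if (self.K[self.habitable] < 1).any():
            raise ConfigurationError("K must be >= 1 on habitable cells")
        if (self.K[~self.habitable] != 0).any():
            raise ConfigurationError("K must be 0 on barrier cells")

    def cell_coords(self, cell: Cell) -> tuple[float, float]:
        """(latitude, longitude) of a cell centre."""
        return float(self.lat[cell[0]]), float(self.lon[cell[1]])

    def neighbours(self, cell: Cell) -> list[Cell]:
        """Habitable von Neumann neighbours, in fixed N/S/W/E order."""
        r, c = cell
        out = []
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < self.height and 0 <= cc < self.width \
                    and self.habitable[rr, cc]:
                out.append((rr, cc))
        return out


@dataclass
class GeneticsConfig:
    """Genome layout for a simulation.

    ``n_chrom`` chromosomes, each carrying ``snps_per_chrom`` evenly spaced
    SNPs on a ``cM_length``-cM map.  Physical positions follow a constant
    1 cM/Mb map.  ``init_freqs`` are the standing-variation allele
    frequencies in the source population; if ``None`` they are drawn
    uniformly from ``freq_range`` when the simulation starts.
    """

    n_chrom: int = 1
    snps_per_chrom: int = 200
    cM_length: float = 100.0
    init_freqs: np.ndarray | None = None
    freq_range: tuple[float, float] = (0.1, 0.9)

    @property
    def n_snps(self) -> int:
        return self.n_chrom * self.snps_per_chrom

    def variant_table(self) -> pd.DataFrame:
        recs = []
        spacing_bp = self.cM_length * 1e6 / self.snps_per_chrom
        for c in range(self.n_chrom):
            for j in range(self.snps_per_chrom):
                bp = int(round((j + 1) * spacing_bp))
                recs.append((f"chr{c + 1}", bp, bp * 1e-6))
        return pd.DataFrame(recs, columns=["chrom", "pos_bp", "pos_cM"])


@dataclass
class ExpansionResult:
    """Outcome of one expansion simulation."""

    grid: DemeGrid
    arrival_time: np.ndarray                  # float (height,width), inf if never
    founding_edges: list[tuple[Cell, Cell, int]]
    final_haplotypes: dict[Cell, np.ndarray]  # (n_hap, n_snps) int8 per deme
    variants: pd.DataFrame
    rng_seed: int
    generations_run: int

    @property
    def colonized(self) -> list[Cell]:
        rr, cc = np.nonzero(np.isfinite(self.arrival_time))
        return [(int(r), int(c)) for r, c in zip(rr, cc)]

    def census(self, cell: Cell) -> int:
        """Diploid census of a deme (haplotype count // 2)."""
        return self.final_haplotypes[cell].shape[0] // 2

    def validate(self) -> None:
        if self.arrival_time[self.grid.origin_cell] != 0:
            raise RangexpandError("origin arrival time is not 0")
        children = [e[1] for e in self.founding_edges]
        if len(children) != len(set(children)):
            raise RangexpandError("a deme has more than one founding edge")
        expected = {c for c in self.colonized if self.arrival_time[c] > 0}
        if set(children) != expected:
            raise RangexpandError("founding edges do not cover colonized demes")


# ----------------------------------------------------------------------
# Landscape construction
# ----------------------------------------------------------------------

def build_landscape(width: int, height: int, scenario: ScenarioSpec,
                    origin: tuple[float, float], *, K: int = 20,
                    lat_range: tuple[float, float] = (8.0, -32.0),
                    lon_range: tuple[float, float] = (8.0, 42.0),
                    ) -> DemeGrid:
    """Build the deme lattice for one scenario.

    Row 0 carries ``lat_range[0]`` (the northern edge).  The barrier band
    given by ``scenario.barrier_rows`` is uninhabitable except at the
    scenario's corridor cells.  ``origin`` is a (lat, lon) pair mapped to
    the nearest cell.
    """
    if width < 2 or height < 2:
        raise ConfigurationError("grid must be at least 2x2")
    lat = np.linspace(lat_range[0], lat_range[1], height)
    lon = np.linspace(lon_range[0], lon_range[1], width)
    habitable = np.ones((height, width), dtype=bool)
    if scenario.barrier_rows is not None:
        r0, r1 = scenario.barrier_rows
        if not 0 <= r0 < r1 <= height:
            raise ConfigurationError("barrier_rows outside the grid")
        habitable[r0:r1, :] = False
        for (r, c) in scenario.corridors:
            if r0 <= r < r1:
                if not (0 <= c < width):
                    raise ConfigurationError(f"corridor {(r, c)} outside grid")
                habitable[r, c] = True
    o_row = int(np.argmin(np.abs(lat - origin[0])))
    o_col = int(np.argmin(np.abs(lon - origin[1])))
    if not habitable[o_row, o_col]:
        raise ConfigurationError(
            f"origin maps to cell {(o_row, o_col)} inside a closed barrier")
    Karr = np.where(habitable, K, 0)
    return DemeGrid(width=width, height=height, habitable=habitable,
                    K=Karr, origin_cell=(o_row, o_col), lat=lat, lon=lon)


# ----------------------------------------------------------------------
# Meiosis
# ----------------------------------------------------------------------

def _map_axes(variants: pd.DataFrame):
    """Concatenated-Morgan axis and per-chrom ids for vectorised meiosis."""
    chroms = list(dict.fromkeys(variants["chrom"]))
    chrom_ids = np.array([chroms.index(c) for c in variants["chrom"]],
                         dtype=np.int64)
    pos_M = variants["pos_cM"].to_numpy() / 100.0
    pos_concat = np.empty_like(pos_M)
    offset = 0.0
    m_tot = 0.0
    for ci, c in enumerate(chroms):
        sel = chrom_ids == ci
        p = pos_M[sel]
        span = p.max() if len(p) else 0.0
        pos_concat[sel] = p + offset
        offset += span
        m_tot += span
    return pos_concat, chrom_ids, len(chroms), m_tot


def _meiosis_batch(pool: np.ndarray, n_children: int, pos_concat: np.ndarray,
                   chrom_ids: np.ndarray, n_chrom: int, m_tot: float,
                   rng: np.random.Generator,
                   companions: tuple[np.ndarray, ...] = (),
                   ):
    """Produce ``n_children`` recombinant haplotypes from a parental pool.

    Each child picks two parental haplotypes uniformly at random; within
    each chromosome the starting parent is random and crossovers fall as a
    Poisson process on the genetic map.  ``companions`` are extra matrices
    row-aligned with ``pool`` (e.g. ancestry labels) recombined with the
    same breakpoints.
    """
    n_pool, L = pool.shape
    a = rng.integers(0, n_pool, n_children)
    b = rng.integers(0, n_pool, n_children)
    start = rng.integers(0, 2, (n_children, n_chrom), dtype=np.int8)
    parity = start[:, chrom_ids].astype(np.int32)
    k = rng.poisson(m_tot, n_children)
    total = int(k.sum())
    if total:
        xs = rng.uniform(0.0, m_tot, total)
        child_of = np.repeat(np.arange(n_children), k)
        idx = np.searchsorted(pos_concat, xs)
        counts = np.zeros((n_children, L + 1), dtype=np.int32)
        np.add.at(counts, (child_of, idx), 1)
        parity += np.cumsum(counts[:, :L], axis=1)
    take_a = (parity & 1) == 0
    out = [np.where(take_a, pool[a], pool[b])]
    for comp in companions:
        out.append(np.where(take_a, comp[a], comp[b]))
    return out if companions else out[0]


# ----------------------------------------------------------------------
# Simulation
# ----------------------------------------------------------------------

def simulate_expansion(grid: DemeGrid, scenario: ScenarioSpec,
                       genetics: GeneticsConfig, generations: int,
                       seed: int, *, start_full: bool = False,
                       stop_after_colonized: list[Cell] | None = None,
                       post_colonization_generations: int = 10,
                       ) -> ExpansionResult:
    """Run the forward expansion model.

    With ``start_full=True`` every habitable deme starts occupied at
    carrying capacity (the equilibrium stepping-stone configuration; no
    colonization happens because no cell is empty).  With
    ``stop_after_colonized`` the run ends
    ``post_colonization_generations`` generations after every listed cell
    has been colonized (still capped at ``generations``).
    """
    if generations <= 0:
        raise ValueError("generations must be > 0")
    rng = np.random.Generator(np.random.Philox(seed))
    variants = genetics.variant_table()
    pos_concat, chrom_ids, n_chrom, m_tot = _map_axes(variants)
    L = genetics.n_snps

    freqs = genetics.init_freqs
    if freqs is None:
        freqs = rng.uniform(*genetics.freq_range, L)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (L,):
        raise ConfigurationError("init_freqs length must equal n_snps")

    arrival = np.full((grid.height, grid.width), np.inf)
    edges: list[tuple[Cell, Cell, int]] = []
    pools: dict[Cell, np.ndarray] = {}

    if start_full:
        rr, cc = np.nonzero(grid.habitable)
        for r, c in zip(rr, cc):
            cell = (int(r), int(c))
            n_hap = 2 * int(grid.K[cell])
            pools[cell] = (rng.random((n_hap, L)) < freqs).astype(np.int8)
            arrival[cell] = 0
    else:
        o = grid.origin_cell
        n_hap = 2 * int(grid.K[o])
        pools[o] = (rng.random((n_hap, L)) < freqs).astype(np.int8)
        arrival[o] = 0

    if not grid.habitable.any():
        logger.warning("all-barrier grid: no expansion possible")

    thr = scenario.colonization_threshold
    r_growth = scenario.growth_rate
    m = scenario.migration_rate
    F = scenario.founder_size
    targets = ([tuple(t) for t in stop_after_colonized]
               if stop_after_colonized else None)
    countdown: int | None = None
    gens_run = 0

    for g in range(1, generations + 1):
        occupied = sorted(pools)
        # 1 & 2: logistic growth + Wright-Fisher resampling with recombination
        for cell in occupied:
            pool = pools[cell]
            K = int(grid.K[cell])
            N = pool.shape[0] / 2.0
            target = N + r_growth * N * (1.0 - N / K)
            p = min(max(target / K, 0.0), 1.0)
            N_next = max(int(rng.binomial(K, p)), 1)
            pools[cell] = _meiosis_batch(pool, 2 * N_next, pos_concat,
                                         chrom_ids, n_chrom, m_tot, rng)
        # 3: symmetric migration between occupied neighbour pairs
        if m > 0:
            for cell in occupied:
                r0, c0 = cell
                for nb in ((r0 + 1, c0), (r0, c0 + 1)):  # each pair once
                    if nb in pools:
                        _swap_haplotypes(pools, cell, nb, m, rng)
        # 4: colonization of empty habitable neighbours
        for cell in occupied:
            pool = pools[cell]
            if pool.shape[0] / 2.0 <= thr * grid.K[cell]:
                continue
            for nb in grid.neighbours(cell):
                if nb in pools or not np.isinf(arrival[nb]):
                    continue
                n_found = min(F, pool.shape[0])
                sel = np.sort(rng.choice(pool.shape[0], n_found,
                                         replace=False))
                pools[nb] = pool[sel].copy()
                arrival[nb] = g
                edges.append((cell, nb, g))
        gens_run = g
        if countdown is not None:
            countdown -= 1
            if countdown <= 0:
                break
        elif targets is not None and \
                all(np.isfinite(arrival[t]) for t in targets):
            countdown = post_colonization_generations

    result = ExpansionResult(grid=grid, arrival_time=arrival,
                             founding_edges=edges, final_haplotypes=pools,
                             variants=variants, rng_seed=seed,
                             generations_run=gens_run)
    result.validate()
    return result


def _swap_haplotypes(pools: dict[Cell, np.ndarray], a: Cell, b: Cell,
                     m: float, rng: np.random.Generator) -> None:
    pa, pb = pools[a], pools[b]
    n_max = min(pa.shape[0], pb.shape[0])
    n_mig = int(rng.binomial(n_max, m))
    if n_mig == 0:
        return
    ia = rng.choice(pa.shape[0], n_mig, replace=False)
    ib = rng.choice(pb.shape[0], n_mig, replace=False)
    tmp = pa[ia].copy()
    pa[ia] = pb[ib]
    pb[ib] = tmp


def save_expansion_result(result: ExpansionResult, out_dir) -> None:
    """Persist an ExpansionResult as a directory of TSVs.

    Writes ``arrival_times.tsv`` (row, col, arrival generation; ``inf``
    for never-colonized cells) and ``founding_edges.tsv``.  Haplotype
    stores are panel-shaped data and are exported via
    :func:`sample_panel` + :mod:`rangexpand.dataio` instead.
    """
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [(r, c, result.arrival_time[r, c])
            for r in range(result.grid.height)
            for c in range(result.grid.width)]
    pd.DataFrame(rows, columns=["row", "col", "arrival_generation"]) \
        .to_csv(out / "arrival_times.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(p[0], p[1], c[0], c[1], g) for p, c, g in result.founding_edges],
        columns=["parent_row", "parent_col", "child_row", "child_col",
                 "generation"],
    ).to_csv(out / "founding_edges.tsv", sep="\t", index=False)


# ----------------------------------------------------------------------
# Sampling a genotype panel from a simulation
# ----------------------------------------------------------------------

def sample_panel(result: ExpansionResult,
                 sampling: list[tuple[Cell, int]],
                 pop_names: list[str] | None = None,
                 *, seed: int = 0,
                 linguistic_groups: list[str] | None = None,
                 country: str = "SIM",
                 ) -> tuple[GenotypePanel, SampleManifest]:
    """Draw diploid samples from colonized demes into a panel + manifest.

    ``sampling`` lists (deme cell, number of diploids).  Haplotypes are
    drawn without replacement (in store order, so sampling a full deme
    reproduces its store exactly) and paired consecutively into diploids.
    Manifest coordinates are the deme cell centres.
    """
    rng = np.random.Generator(np.random.Philox(seed))
    if pop_names is None:
        pop_names = [f"P{i:02d}" for i in range(len(sampling))]
    if linguistic_groups is None:
        linguistic_groups = ["non-BSP"] * len(sampling)
    hap_rows = []
    manifest_rows = []
    sample_ids: list[str] = []
    for (cell, n_dip), pop, grp in zip(sampling, pop_names,
                                       linguistic_groups):
        cell = tuple(cell)
        if cell not in result.final_haplotypes:
            raise SamplingError(f"deme {cell} was never colonized")
        store = result.final_haplotypes[cell]
        if 2 * n_dip > store.shape[0]:
            raise SamplingError(
                f"deme {cell} holds {store.shape[0]} haplotypes; "
                f"cannot draw {n_dip} diploids")
        sel = np.sort(rng.choice(store.shape[0], 2 * n_dip, replace=False))
        lat, lon = result.grid.cell_coords(cell)
        for j in range(n_dip):
            sid = f"{pop}_{j:03d}"
            sample_ids.append(sid)
            hap_rows.append(store[sel[2 * j]])
            hap_rows.append(store[sel[2 * j + 1]])
            manifest_rows.append((sid, pop, country, grp, lat, lon, set()))
    panel = GenotypePanel(
        variants=result.variants.copy(),
        haplotypes=np.vstack(hap_rows).astype(np.int8),
        sample_ids=sample_ids,
    )
    manifest = SampleManifest(pd.DataFrame(
        manifest_rows,
        columns=["sample_id", "population", "country", "linguistic_group",
                 "latitude", "longitude", "qc_flags"]))
    return panel, manifest
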