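"""ABC-style comparison of expansion scenarios.

Each candidate route geometry (northern passage, southern corridor, or
both) is simulated many times with demographic parameters drawn from
independent uniform priors.  Every simulation is reduced to a summary
vector of pairwise Hudson FST values between the sampled populations, and
a scenario's support against an observed dataset is the squared Pearson
correlation (r^2) between observed and simulated vectors — reported as
the maximum over simulations together with the mean over the top decile,
so that sensitivity of the max-profile support is visible.  Scenarios are
ranked by r2_max (ties by the top-decile mean, then name).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import GenotypePanel, SampleManifest
from .correlations import hudson_fst_matrix
from .exceptions import (
    AlignmentError,
    DegenerateInputError,
    RangexpandError,
)
from .sim import (
    Cell,
    GeneticsConfig,
    ScenarioSpec,
    build_landscape,
    sample_panel,
    simulate_expansion,
)

logger = logging.getLogger(__name__)


@dataclass
class SummaryStatVector:
    """Pairwise-FST summary of one dataset (observed or simulated)."""

    labels: list[tuple[str, str]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = [tuple(l) for l in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        if len(self.labels) != len(self.values):
            raise RangexpandError("summary labels/values length mismatch")


@dataclass
class ScenarioSupport:
    scenario: str
    n_sims: int
    r2_max: float
    r2_top_decile_mean: float
    best_params: dict | None = None
    n_failed: int = 0


@dataclass
class UniformPriors:
    """Independent uniform priors for the scenario sweep."""

    growth_rate: tuple[float, float] = (0.2, 1.0)
    migration_rate: tuple[float, float] = (0.01, 0.2)
    founder_size: tuple[int, int] = (2, 20)          # inclusive
    colonization_threshold: tuple[float, float] = (0.3, 0.7)

    def draw(self, rng: np.random.Generator) -> dict:
        return {
            "growth_rate": float(rng.uniform(*self.growth_rate)),
            "migration_rate": float(rng.uniform(*self.migration_rate)),
            "founder_size": int(rng.integers(self.founder_size[0],
                                             self.founder_size[1] + 1)),
            "colonization_threshold": float(
                rng.uniform(*self.colonization_threshold)),
        }


@dataclass
class RouteWorld:
    """A toy two-route geography for scenario comparison.

    A ``height x width`` lattice with an impassable band of rows (the
    rainforest belt).  The southern scenario opens a corridor through the
    band near the western edge; the northern scenario opens a passage at
    the eastern edge (going around the forest); ``both`` opens both.
    """

    width: int = 5
    height: int = 6
    K: int = 16
    barrier_rows: tuple[int, int] = (2, 4)
    southern_cols: tuple[int, ...] = (1,)
    northern_cols: tuple[int, ...] = (4,)
    origin_latlon: tuple[float, float] = (8.0, 8.0)
    sampled_demes: tuple[Cell, ...] = (
        (0, 0), (1, 0), (0, 4), (1, 4), (1, 2), (4, 0), (5, 0), (5, 2),
        (4, 4), (5, 4))
    n_per_deme: int = 12
    genetics: GeneticsConfig = field(
        default_factory=lambda: GeneticsConfig(
            n_chrom=1, snps_per_chrom=240, cM_length=100.0))
    max_generations: int = 120
    post_colonization_generations: int = 12

    def scenario(self, name: str, **params) -> ScenarioSpec:
        cols = {"southern": self.southern_cols,
                "northern": self.northern_cols,
                "both": self.southern_cols + self.northern_cols}[name]
        corridors = frozenset(
            (r, c) for r in range(*self.barrier_rows) for c in cols)
        return ScenarioSpec(name=name, barrier_rows=self.barrier_rows,
                            corridors=corridors, **params)

    def simulate(self, name: str, seed: int,
                 **params) -> tuple[GenotypePanel, SampleManifest] | None:
        """One simulated dataset, or None if a sampled deme stays empty."""
        spec = self.scenario(name, **params)
        grid = build_landscape(self.width, self.height, spec,
                               self.origin_latlon, K=self.K)
        res = simulate_expansion(
            grid, spec, self.genetics, self.max_generations, seed,
            stop_after_colonized=list(self.sampled_demes),
            post_colonization_generations=self.post_colonization_generations)
        for d in self.sampled_demes:
            if d not in res.final_haplotypes or \
                    res.census(d) < self.n_per_deme:
                return None
        return sample_panel(
            res, [(d, self.n_per_deme) for d in self.sampled_demes],
            seed=seed + 1)


# ----------------------------------------------------------------------
# Operations
# ----------------------------------------------------------------------

def compute_summary(panel: GenotypePanel,
                    manifest: SampleManifest) -> SummaryStatVector:
    """Pairwise Hudson FST vector in the manifest's population-pair order.

    Entries equal :func:`rangexpand.correlations.hudson_fst_matrix`
    values taken in upper-triangle order.
    """
    dm = hudson_fst_matrix(panel, manifest)
    labels = [(dm.labels[i], dm.labels[j])
              for i in range(len(dm.labels))
              for j in range(i + 1, len(dm.labels))]
    values = dm.condensed()
    if not np.isfinite(values).any():
        raise RangexpandError(
            "all FST denominators are zero: panel is monomorphic "
            "across every population pair")
    return SummaryStatVector(labels, values)


def scenario_support(observed: SummaryStatVector,
                     sims: list[tuple[dict, SummaryStatVector]],
                     scenario: str) -> ScenarioSupport:
    """Support of one scenario: max and top-decile-mean r^2 over sims."""
    if len(observed.values) < 3:
        raise DegenerateInputError(
            "fewer than 3 population pairs: r^2 has no degrees of freedom")
    r2s, params_used = [], []
    n_failed = 0
    for params, sim in sims:
        if sim is None:
            n_failed += 1
            continue
        if sim.labels != observed.labels:
            raise AlignmentError(
                "simulated summary pair labels differ from observed")
        ok = np.isfinite(observed.values) & np.isfinite(sim.values)
        if ok.sum() < 3 or np.std(sim.values[ok]) == 0:
            n_failed += 1
            continue
        r = np.corrcoef(observed.values[ok], sim.values[ok])[0, 1]
        r2s.append(r * r)
        params_used.append(params)
    if not r2s:
        return ScenarioSupport(scenario, 0, 0.0, 0.0, None, n_failed)
    r2s = np.asarray(r2s)
    order = np.argsort(r2s)[::-1]
    n_top = max(1, len(r2s) // 10)
    return ScenarioSupport(
        scenario=scenario,
        n_sims=len(r2s),
        r2_max=float(r2s[order[0]]),
        r2_top_decile_mean=float(r2s[order[:n_top]].mean()),
        best_params=params_used[order[0]],
        n_failed=n_failed,
    )


def rank_scenarios(supports: list[ScenarioSupport]) -> list[ScenarioSupport]:
    """Descending by r2_max; ties by top-decile mean, then name."""
    if not supports:
        raise ValueError("no scenario supports to rank")
    return sorted(supports,
                  key=lambda s: (-s.r2_max, -s.r2_top_decile_mean,
                                 s.scenario))


def run_scenario_sweep(world: RouteWorld, scenario: str,
                       observed: SummaryStatVector, n_sims: int,
                       seed: int,
                       priors: UniformPriors | None = None,
                       ) -> ScenarioSupport:
    """Simulate ``n_sims`` prior draws under one scenario and score them."""
    priors = priors or UniformPriors()
    rng = np.random.default_rng(seed)
    sims: list[tuple[dict, SummaryStatVector | None]] = []
    for k in range(n_sims):
        params = priors.draw(rng)
        sim_seed = int(rng.integers(0, 2 ** 31 - 1))
        data = world.simulate(scenario, sim_seed, **params)
        if data is None:
            sims.append((params, None))
            continue
        panel, manifest = data
        try:
            sims.append((params, compute_summary(panel, manifest)))
        except RangexpandError:
            sims.append((params, None))
    return scenario_support(observed, sims, scenario)


def compare_scenarios(world: RouteWorld, observed: SummaryStatVector,
                      n_sims: int, seed: int,
                      scenario_names: tuple[str, ...] = ("northern",
                                                         "southern", "both"),
                      priors: UniformPriors | None = None,
                      ) -> list[ScenarioSupport]:
    """Sweep every scenario and return supports ranked best-first."""
    supports = [
        run_scenario_sweep(world, name, observed, n_sims,
                           seed + 1000 * i, priors)
        for i, name in enumerate(scenario_names)
    ]
    return rank_scenarios(supports)
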