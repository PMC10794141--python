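"""Landscape construction and Wright-Fisher expansion dynamics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rangexpand.diversity import haplotype_heterozygosity
from rangexpand.exceptions import ConfigurationError, SamplingError
from rangexpand.sim import (
    SCENARIO_NAMES,
    GeneticsConfig,
    ScenarioSpec,
    build_landscape,
    sample_panel,
    simulate_expansion,
)

def corridor_world(n_cells, K=20, **scenario_kwargs):
    """A 1 x n corridor: two grid rows with the second row barred."""
    spec = ScenarioSpec(name="southern", barrier_rows=(1, 2),
                        corridors=frozenset(), **scenario_kwargs)
    grid = build_landscape(n_cells, 2, spec, origin=(8.0, 8.0), K=K)
    assert grid.origin_cell == (0, 0)
    return grid, spec


def test_scenario_names_enumerate_three_routes():
    assert set(SCENARIO_NAMES) == {"northern", "southern", "both"}
    with pytest.raises(ConfigurationError):
        ScenarioSpec(name="western")


def test_no_barrier_means_all_habitable():
    spec = ScenarioSpec(name="both")
    grid = build_landscape(6, 4, spec, origin=(8.0, 8.0))
    assert grid.habitable.all()


def test_hand_counted_habitable_cells():
    """10x10 grid, 2 barrier rows, a 2x2-cell corridor: 84 habitable."""
    spec = ScenarioSpec(name="southern", barrier_rows=(4, 6),
                        corridors={(4, 3), (4, 4), (5, 3), (5, 4)})
    grid = build_landscape(10, 10, spec, origin=(8.0, 8.0))
    assert int(grid.habitable.sum()) == 100 - 20 + 4


def test_origin_inside_closed_barrier_rejected():
    spec = ScenarioSpec(name="southern", barrier_rows=(0, 1))
    with pytest.raises(ConfigurationError, match="barrier"):
        build_landscape(5, 5, spec, origin=(8.0, 8.0))


def test_mirrored_corridor_masks_are_mirror_identical():
    """Northern and southern masks are fliplr-images of each other when
    their corridor geometry is mirrored."""
    w = 7
    south = ScenarioSpec(name="southern", barrier_rows=(2, 4),
                         corridors={(2, 1), (3, 1)})
    north = ScenarioSpec(name="northern", barrier_rows=(2, 4),
                         corridors={(2, w - 2), (3, w - 2)})
    gs = build_landscape(w, 6, south, origin=(8.0, 8.0))
    gn = build_landscape(w, 6, north, origin=(8.0, 8.0))
    assert np.array_equal(gs.habitable, np.fliplr(gn.habitable))
    assert (gs.habitable != gn.habitable).sum() == 4  # corridors only


def test_no_migration_high_threshold_stays_at_origin():
    """m = 0 and threshold > 1 confine the population to the origin."""
    spec = ScenarioSpec(name="both", migration_rate=0.0,
                        colonization_threshold=1.5)
    grid = build_landscape(4, 4, spec, origin=(8.0, 8.0), K=10)
    res = simulate_expansion(grid, spec,
                             GeneticsConfig(snps_per_chrom=20),
                             generations=15, seed=1)
    assert res.colonized == [grid.origin_cell]
    assert np.isfinite(res.arrival_time).sum() == 1


@pytest.mark.parametrize("seed", range(20))
def test_corridor_arrival_times_increase_monotonically(seed):
    """On a 1x12 corridor the colonization wave moves strictly outward."""
    grid, spec = corridor_world(12, growth_rate=1.0, founder_size=6,
                                colonization_threshold=0.5)
    res = simulate_expansion(grid, spec,
                             GeneticsConfig(snps_per_chrom=10),
                             generations=80, seed=seed)
    arr = res.arrival_time[0]
    assert np.isfinite(arr).all()
    assert (np.diff(arr) > 0).all()


def test_wright_fisher_allele_frequency_variance():
    """One deme at fixed census: var of the one-generation allele-
    frequency change matches the binomial p(1-p)/2N expectation."""
    spec = ScenarioSpec(name="both", migration_rate=0.0,
                        colonization_threshold=2.0)
    grid = build_landscape(2, 2, spec, origin=(8.0, 8.0), K=25)
    gen = GeneticsConfig(n_chrom=1, snps_per_chrom=1, cM_length=1.0,
                         init_freqs=np.array([0.5]))
    deltas = []
    for seed in range(2000):
        res = simulate_expansion(grid, spec, gen, generations=1, seed=seed)
        pool = res.final_haplotypes[grid.origin_cell]
        p0 = 0.5  # origin initialised by Bernoulli(0.5) draws
        # measure change from the realised initial frequency instead:
        rng = np.random.Generator(np.random.Philox(seed))
        init = (rng.random((50, 1)) < 0.5).astype(np.int8)
        deltas.append(pool.mean() - init.mean())
    var = np.var(deltas)
    expected = 0.5 * 0.5 / 50
    assert abs(var - expected) <= 0.10 * expected


def test_migration_conserves_total_haplotype_count():
    """With census pinned at K, symmetric swaps keep the global total."""
    spec = ScenarioSpec(name="both", migration_rate=0.2)
    grid = build_landscape(4, 3, spec, origin=(8.0, 8.0), K=15)
    res = simulate_expansion(grid, spec,
                             GeneticsConfig(snps_per_chrom=30),
                             generations=25, seed=3, start_full=True)
    total = sum(p.shape[0] for p in res.final_haplotypes.values())
    assert total == 2 * 15 * 12


def test_small_founder_size_lowers_terminal_diversity():
    """F = 4 founders lose more terminal-deme heterozygosity than
    F = 2K along a corridor, in at least 18 of 20 paired seeds."""
    K = 50
    wins = 0
    for seed in range(20):
        het = {}
        for F in (4, 2 * K):
            grid, spec = corridor_world(6, K=K, founder_size=F,
                                        growth_rate=0.8,
                                        colonization_threshold=0.5)
            res = simulate_expansion(
                grid, spec,
                GeneticsConfig(snps_per_chrom=100, cM_length=50.0),
                generations=50, seed=seed,
                stop_after_colonized=[(0, 5)],
                post_colonization_generations=10)
            panel, manifest = sample_panel(res, [((0, 5), 20)], seed=seed)
            het[F] = haplotype_heterozygosity(panel, manifest,
                                              window_snps=10).iloc[0]
        wins += het[4] < het[2 * K]
    assert wins >= 18


def test_corridor_serial_founder_richness_decline():
    """Pooled over 10 seeds, haplotype richness regresses negatively on
    deme index along a 1x15 corridor."""
    from rangexpand.diversity import haplotype_richness
    xs, ys = [], []
    for seed in range(10):
        grid, spec = corridor_world(15, K=20, founder_size=6,
                                    growth_rate=0.8,
                                    colonization_threshold=0.5)
        res = simulate_expansion(
            grid, spec,
            GeneticsConfig(n_chrom=1, snps_per_chrom=400, cM_length=60.0),
            generations=120, seed=seed,
            stop_after_colonized=[(0, 14)],
            post_colonization_generations=60)
        sampling = [((0, c), 10) for c in range(15)]
        panel, manifest = sample_panel(res, sampling, seed=seed)
        rich = haplotype_richness(panel, manifest, window_snps=20,
                                  g=20, reps=5, seed=seed)
        for k, pop in enumerate(manifest.populations):
            xs.append(k)
            ys.append(rich[pop])
    fit = stats.linregress(xs, ys)
    assert fit.slope < 0
    assert fit.pvalue < 0.01


def test_identical_seed_gives_identical_results():
    grid, spec = corridor_world(8)
    gen = GeneticsConfig(snps_per_chrom=50)
    a = simulate_expansion(grid, spec, gen, generations=30, seed=9)
    b = simulate_expansion(grid, spec, gen, generations=30, seed=9)
    assert np.array_equal(a.arrival_time, b.arrival_time)
    assert a.founding_edges == b.founding_edges
    for cell in a.final_haplotypes:
        assert np.array_equal(a.final_haplotypes[cell],
                              b.final_haplotypes[cell])


def test_generations_must_be_positive():
    grid, spec = corridor_world(4)
    with pytest.raises(ValueError):
        simulate_expansion(grid, spec, GeneticsConfig(), 0, seed=1)


# ----------------------------------------------------------------------
# sample_panel
# ----------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_result():
    grid, spec = corridor_world(5, K=15)
    return simulate_expansion(grid, spec,
                              GeneticsConfig(snps_per_chrom=40),
                              generations=40, seed=5)


def test_exhaustive_sample_reproduces_deme_store(small_result):
    cell = small_result.grid.origin_cell
    n = small_result.census(cell)
    panel, _ = sample_panel(small_result, [(cell, n)], seed=0)
    assert np.array_equal(panel.haplotypes,
                          small_result.final_haplotypes[cell][:2 * n])


def test_sampling_ploidy_bookkeeping(small_result):
    panel, manifest = sample_panel(small_result,
                                   [(small_result.grid.origin_cell, 10)],
                                   seed=0)
    assert panel.haplotypes.shape[0] == 20
    assert len(manifest.table) == 10


def test_sampling_is_deterministic(small_result):
    cell = small_result.grid.origin_cell
    a, _ = sample_panel(small_result, [(cell, 5)], seed=3)
    b, _ = sample_panel(small_result, [(cell, 5)], seed=3)
    assert np.array_equal(a.haplotypes, b.haplotypes)


def test_sampling_uncolonized_deme_raises(small_result):
    assert (1, 1) not in small_result.final_haplotypes
    with pytest.raises(SamplingError):
        sample_panel(small_result, [((1, 1), 5)], seed=0)


def test_manifest_coordinates_match_deme_cells(small_result):
    cell = (0, 2)
    panel, manifest = sample_panel(small_result, [(cell, 5)], seed=0)
    lat, lon = small_result.grid.cell_coords(cell)
    assert manifest.coords_of(manifest.populations[0]) == (lat, lon)


def test_expansion_result_persists_as_tsv_directory(small_result, tmp_path):
    from rangexpand.sim import save_expansion_result
    save_expansion_result(small_result, tmp_path / "run")
    arrivals = pd.read_csv(tmp_path / "run" / "arrival_times.tsv", sep="\t")
    assert len(arrivals) == small_result.grid.height \
        * small_result.grid.width
    edges = pd.read_csv(tmp_path / "run" / "founding_edges.tsv", sep="\t")
    assert len(edges) == len(small_result.founding_edges)
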