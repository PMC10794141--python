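"""Shared fixtures: small hand-built panels and cached synthetic datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rangexpand.containers import GenotypePanel, SampleManifest


def make_panel(haplotypes, sample_ids=None, chrom="chr1", spacing_bp=10_000,
               cM_per_Mb=1.0, variants=None) -> GenotypePanel:
    """Panel from a haplotype matrix with evenly spaced positions."""
    H = np.asarray(haplotypes, dtype=np.int8)
    n_hap, n_var = H.shape
    assert n_hap % 2 == 0
    if sample_ids is None:
        sample_ids = [f"S{i:03d}" for i in range(n_hap // 2)]
    if variants is None:
        bp = (np.arange(n_var) + 1) * spacing_bp
        variants = pd.DataFrame({
            "chrom": [chrom] * n_var,
            "pos_bp": bp,
            "pos_cM": bp * 1e-6 * cM_per_Mb,
        })
    return GenotypePanel(variants=variants, haplotypes=H,
                         sample_ids=sample_ids)


def make_manifest(pop_of_sample: dict[str, str],
                  coords: dict[str, tuple[float, float]] | None = None,
                  group: str = "non-BSP") -> SampleManifest:
    coords = coords or {}
    rows = []
    pops = list(dict.fromkeys(pop_of_sample.values()))
    for sid, pop in pop_of_sample.items():
        lat, lon = coords.get(pop, (float(pops.index(pop)), 10.0))
        rows.append((sid, pop, "SIM", group, lat, lon, set()))
    return SampleManifest(pd.DataFrame(
        rows, columns=["sample_id", "population", "country",
                       "linguistic_group", "latitude", "longitude",
                       "qc_flags"]))


def random_panel(rng: np.random.Generator, n_samples=4, n_var=12,
                 missing_rate=0.0) -> GenotypePanel:
    H = rng.integers(0, 2, (2 * n_samples, n_var)).astype(np.int8)
    if missing_rate:
        H[rng.random(H.shape) < missing_rate] = -1
    return make_panel(H)


@pytest.fixture(scope="session")
def admixed_dataset():
    """One admixed dataset with exact tracts (t=30, m=0.2)."""
    from rangexpand.synthetic import generate_admixed_dataset
    return generate_admixed_dataset(seed=11)


@pytest.fixture(scope="session")
def serial_founder_dataset():
    """One small-world serial-founder dataset."""
    from rangexpand.synthetic import generate_serial_founder_dataset
    return generate_serial_founder_dataset(seed=7)


@pytest.fixture(scope="session")
def founder_datasets():
    """Ten small-world serial-founder replicates (seeds 0-9)."""
    from rangexpand.synthetic import generate_serial_founder_dataset
    return [generate_serial_founder_dataset(seed=s) for s in range(10)]


@pytest.fixture(scope="session")
def stepping_datasets():
    """Ten stepping-stone equilibrium replicates (seeds 0-9)."""
    from rangexpand.synthetic import generate_stepping_stone_dataset
    return [generate_stepping_stone_dataset(seed=s) for s in range(10)]
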