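"""Shared test fixtures and small builders.

Everything is generated programmatically; no data files.  Simulated
fixtures use fixed seeds so the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from panelkit.containers import GenotypeMatrix, HaplotypePanel


def make_variants(n: int, start: int = 1, spacing: int = 100) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [f"snp{i + 1}" for i in range(n)],
            "contig": "1",
            "pos": np.arange(start, start + n, dtype=np.int64) * spacing,
            "ref": "A",
            "alt": "C",
        }
    )


def make_samples(n: int, region: str = "test") -> pd.DataFrame:
    return pd.DataFrame(
        {"sample": [f"{region}_{i:03d}" for i in range(n)], "region": region}
    )


def make_gm(genotypes, region: str = "test") -> GenotypeMatrix:
    g = np.asarray(genotypes, dtype=np.int8)
    return GenotypeMatrix(g, make_variants(g.shape[0]), make_samples(g.shape[1], region))


def make_panel(haplotypes, regions=None) -> HaplotypePanel:
    h = np.asarray(haplotypes, dtype=np.int8)
    n_samples = h.shape[1] // 2
    samples = make_samples(n_samples)
    if regions is not None:
        samples["region"] = regions
    return HaplotypePanel(h, make_variants(h.shape[0]), samples)


@pytest.fixture(scope="session")
def small_cohort():
    """One-region cohort with a planted parent-offspring pair.

    Weak-coherence, many-marker regime: kinship estimation wants many
    quasi-independent sites, so the block structure is thinned.
    """
    from panelkit.simpop import RegionSpec, SimulationConfig, simulate_cohort

    cfg = SimulationConfig(
        n_variants=30000,
        n_founder_haplotypes=400,
        recomb_rate_per_interval=0.01,
        regions=[RegionSpec("alpha", 40, 2, 200)],
        seed=11,
        array_fraction=0.1,
        planted_relative_pairs=1,
        ld_coherence=0.2,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def two_region_panel():
    """Two drifted regions (F_ST ~ 0.01) as a phased panel."""
    from panelkit.simpop import RegionSpec, SimulationConfig, drift_split, simulate_founders

    cfg = SimulationConfig(
        n_variants=3000,
        n_founder_haplotypes=400,
        recomb_rate_per_interval=0.01,
        regions=[RegionSpec("north", 60, 4, 200), RegionSpec("south", 60, 4, 200)],
        seed=5,
        planted_relative_pairs=0,
    )
    founders = simulate_founders(cfg)
    return drift_split(founders, cfg.regions, cfg.recomb_rate_per_interval, 55)
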