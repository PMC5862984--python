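"""Shared fixtures: small deterministic panels and the emulated cohort."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hhmap import simulate
from hhmap.blocks import define_blocks
from hhmap.io_formats import HaplotypePanel, qc_filter


def make_panel(haps, chrom="1", start_bp=1000, spacing=1000, ids=None):
    """Build a HaplotypePanel from an (N, 2, S) array of allele codes."""
    haps = np.asarray(haps, dtype=np.int8)
    n, _, s = haps.shape
    ids = ids or [f"s{i}" for i in range(n)]
    tbl = pd.DataFrame(
        {
            "id": [f"snp{k}" for k in range(s)],
            "chrom": chrom,
            "pos_bp": start_bp + spacing * np.arange(s),
            "cM": np.nan,
        }
    )
    return HaplotypePanel(ids, tbl, haps)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture(scope="session")
def small_cohort():
    """300 individuals, 20 blocks, generation 20 (dirichlet structure)."""
    cfg = simulate.PanelConfig(
        n_individuals=300, n_blocks_per_chrom=(10, 10), alleles_per_block=(2, 8), seed=41
    )
    panel, gmap, blocks = simulate.synth_base_panel(cfg)
    gen20 = simulate.forward_simulate(panel, gmap, 20, seed=42)
    return gen20, gmap, blocks


@pytest.fixture(scope="session")
def recovery_cohort():
    """N=1000 emulated panel used for parameter-recovery style checks."""
    cfg = simulate.emulated_cohort_config(
        n_individuals=1000, n_blocks_per_chrom=(18, 18, 18), seed=7
    )
    panel, gmap, _ = simulate.synth_base_panel(cfg)
    gen20 = qc_filter(simulate.forward_simulate(panel, gmap, 20, seed=7))
    blocks = define_blocks(gen20, gmap, 5.0)
    return gen20, gmap, blocks


@pytest.fixture(scope="session")
def cohort_2186():
    """Full-size emulated cohort (N=2186) shared by the acceptance tests."""
    cfg = simulate.emulated_cohort_config(seed=11)
    panel, gmap, _ = simulate.synth_base_panel(cfg)
    gen20 = qc_filter(simulate.forward_simulate(panel, gmap, 20, seed=11))
    blocks = define_blocks(gen20, gmap, 5.0)
    return gen20, gmap, blocks
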