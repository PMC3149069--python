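import numpy as np
import pandas as pd
import pytest

import cnastats as cna


@pytest.fixture
def probe_map_small():
    """30 probes on two chromosomes, 5 kb spacing."""
    rows = []
    for i in range(20):
        rows.append((f"p{i:03d}", "1", 5000 * (i + 1)))
    for i in range(10):
        rows.append((f"p{i + 20:03d}", "2", 5000 * (i + 1)))
    return cna.ProbeMap(
        pd.DataFrame(rows, columns=["probe_id", "chromosome", "position"])
    )


@pytest.fixture
def genes_small():
    """Two genes on chr1 (probes 0-4 and 10-14) and one on chr2 (probes 2-6
    of chr2), given the 2 kb flank and 5 kb spacing."""
    rows = [
        ("gA", "1", 5000 - 1500, 25000 + 1500),
        ("gB", "1", 55000 - 1500, 75000 + 1500),
        ("gC", "2", 15000 - 1500, 35000 + 1500),
    ]
    return cna.GeneTable(
        pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])
    )


@pytest.fixture
def small_cohort():
    """Deterministic small cohort: 6 germline + 10 tumor samples."""
    cfg = cna.SimulationConfig(
        seed=7, n_probes=1500, n_chromosomes=3, noise_sd=0.1,
        segment_length_mean=20, selection_strength=1.0,
        group_specs=(
            cna.GroupSpec("blood", "blood", "none", 6, 1.0, 1.0),
            cna.GroupSpec("early", "tumor", "early", 7, 8.0, 3.0),
            cna.GroupSpec("late", "tumor", "late", 3, 20.0, 5.0),
        ),
    )
    pm, genes = cna.simulate_probe_map_and_genes(cfg)
    cn, design, truth = cna.simulate_cohort(cfg, pm, genes, return_truth=True)
    calls = cna.call_cnas(cna.median_smooth(cn))
    return {
        "config": cfg, "probe_map": pm, "genes": genes, "cn": cn,
        "design": design, "truth": truth, "calls": calls,
    }
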