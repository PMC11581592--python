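import numpy as np
import pandas as pd
import pytest

from flowregions import (
    Partition,
    RegionalFlowModel,
    SyntheticConfig,
    generate_encounters,
    generate_geography,
    generate_reference_partition,
    link_transfers,
    planted_partition,
    select_cohort,
)
from flowregions.graph import FlowGraph
from flowregions.synthetic import CONDITION_LABELS


@pytest.fixture
def triangles():
    """Two disconnected unit-weight triangles."""
    g = FlowGraph()
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        g.add_edge(a, b, 1.0)
    return g


@pytest.fixture
def triangle_partition():
    return Partition({0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1})


def random_graph(seed, n_min=4, n_max=8, p=0.5, ensure_edge=True):
    """Random weighted graph for oracle comparisons (loops excluded)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_min, n_max + 1))
    g = FlowGraph()
    for i in range(n):
        g.add_node(i)
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    for i, j in edges:
        if rng.random() < p:
            g.add_edge(i, j, float(rng.integers(1, 6)))
    if ensure_edge and g.total_weight == 0:
        i, j = edges[int(rng.integers(0, len(edges)))]
        g.add_edge(i, j, float(rng.integers(1, 6)))
    return g


@pytest.fixture
def small_system():
    """Compact synthetic system for fast structural tests."""
    cfg = SyntheticConfig(
        n_communities=3, zips_per_community=9, hospitals_per_community=2,
        n_encounters=3000, seed=11,
    )
    geo = generate_geography(cfg)
    enc = generate_encounters(geo, cfg)
    cohort = select_cohort(enc, set(CONDITION_LABELS))
    transfers = link_transfers(cohort)
    return cfg, geo, enc, cohort, transfers


@pytest.fixture(scope="session")
def benchmark_runs():
    """Ten seeded end-to-end runs of the benchmark system.

    Shared by the recovery and comparison-direction suites so the
    (relatively) expensive simulations are done once per session.
    """
    out = []
    for seed in range(10):
        cfg = SyntheticConfig(seed=seed)
        geo = generate_geography(cfg)
        enc = generate_encounters(geo, cfg)
        cohort = select_cohort(enc, set(CONDITION_LABELS))
        transfers = link_transfers(cohort)
        res = RegionalFlowModel(cohort, transfers, geo).fit(seed=seed)
        reference = generate_reference_partition(geo, cfg)
        report = res.compare(reference)
        out.append({
            "seed": seed,
            "n_regions": res.n_regions,
            "n_phase1": res.ren.phase1_partition.n_communities,
            "ari": res.rand_index(planted_partition(geo)),
            "ren_li": float(report.ren_table["localization_index"].mean()),
            "ref_li": float(report.reference_table["localization_index"].mean()),
            "ren_msi": float(report.ren_table["market_share_index"].mean()),
            "ref_msi": float(report.reference_table["market_share_index"].mean()),
            "q_ren": report.ren_modularity_phase1,
            "q_ref": report.reference_modularity_phase1,
        })
    return out


def toy_cohort(rows):
    """Build an encounter frame from (id, patient, zip, facility, adm, disch) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["encounter_id", "patient_key", "home_zip", "facility",
                 "admission_day", "discharge_day"],
    )
    df["age"] = 40
    df["elective"] = False
    df["admission_source"] = "home"
    df["condition"] = "cond_01"
    df["transfer_ind"] = False
    return df
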