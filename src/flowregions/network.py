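"""Flow-graph construction for both detection phases.

Phase 1 is a bipartite-shaped zip/hospital graph: the weight between a
zip unit and a hospital is the number of index encounters flowing from
residents of that unit to that hospital.  Phase 2 aggregates transfers
onto the phase-1 communities: nodes are communities, edge weights are
transfer volumes between them (either direction summed), and transfers
that stay within a community become self-loops so that total weight is
conserved.
"""

from __future__ import annotations

from typing import Mapping, Optional

import pandas as pd

from .community import Partition
from .graph import FlowGraph

__all__ = ["build_phase1_graph", "build_phase2_graph", "EmptyCohortError"]


class EmptyCohortError(ValueError):
    """Raised when a graph is requested from an empty cohort."""


def build_phase1_graph(
    cohort: pd.DataFrame,
    transfers: Optional[pd.DataFrame] = None,
    geography=None,
    include_isolated: bool = False,
) -> FlowGraph:
    """Home-zip -> hospital volume graph over index encounters.

    If ``transfers`` is given, receiving legs of linked transfer pairs
    are dropped first so that a transferred patient contributes a single
    index encounter (home to initial hospital) and is not double-counted.
    Zip units or hospitals without any encounter are included as isolated
    nodes only when ``geography`` is supplied and ``include_isolated`` is
    set.
    """
    if cohort is None or len(cohort) == 0:
        raise EmptyCohortError("cannot build a flow graph from an empty cohort")
    df = cohort
    if transfers is not None and len(transfers):
        df = df.loc[~df["encounter_id"].isin(set(transfers["receiver_id"]))]
    if len(df) == 0:
        raise EmptyCohortError("no index encounters remain after dropping transfer legs")
    zset = set(df["home_zip"])
    overlap = zset & set(df["facility"])
    if overlap:
        raise ValueError(f"zip and hospital ids collide: {sorted(overlap)[:5]}")

    g = FlowGraph()
    counts = df.groupby(["home_zip", "facility"], sort=True).size()
    for (z, h), w in counts.items():
        g.add_node(z, kind="zip")
        g.add_node(h, kind="hospital")
        g.add_edge(z, h, float(w))
    if include_isolated and geography is not None:
        for z in geography.zip_ids:
            if z not in g:
                g.add_node(z, kind="zip")
        for h in geography.hospital_ids:
            if h not in g:
                g.add_node(h, kind="hospital")
    return g


def build_phase2_graph(
    phase1_partition: Partition,
    transfers: pd.DataFrame,
    hospital_to_node: Optional[Mapping] = None,
) -> FlowGraph:
    """Community-level transfer graph.

    Nodes are the phase-1 communities; the weight between two communities
    is the number of transfer pairs between them in either direction, and
    within-community transfers become self-loops.  ``hospital_to_node``
    optionally maps facility ids to phase-1 graph node ids (identity by
    default).  A transfer touching a facility absent from the phase-1
    partition is an error naming the facility.
    """
    g = FlowGraph()
    for c in set(phase1_partition.labels.values()):
        g.add_node(c, kind="community")

    def community_of(facility):
        node = hospital_to_node[facility] if hospital_to_node else facility
        if node not in phase1_partition:
            raise KeyError(
                f"transfer references facility {facility!r} with no phase-1 community"
            )
        return phase1_partition[node]

    for row in transfers.itertuples(index=False):
        g.add_edge(community_of(row.sender_facility),
                   community_of(row.receiver_facility), 1.0)
    return g
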