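"""Two-phase region detection and geographic footprints.

``detect_rens`` composes the full procedure: build the zip/hospital flow
graph, detect phase-1 communities by modularity optimization, aggregate
interhospital transfers onto those communities, detect phase-2
communities of the transfer graph, and read the final regional networks
off the composition (a zip or hospital's region is the phase-2 community
of its phase-1 community).  Phase-1 communities untouched by any
transfer remain standalone regions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from shapely.geometry import mapping
from shapely.ops import unary_union

from .community import DEFAULT_MIN_GAIN, Partition, louvain, modularity
from .graph import FlowGraph
from .network import build_phase1_graph, build_phase2_graph
from .synthetic import GeographyTable

log = logging.getLogger(__name__)

__all__ = ["RegionSet", "RenResult", "build_footprints", "detect_rens"]


@dataclass
class RegionSet:
    """One detected region: member zip units, hospitals, and footprint."""

    label: int
    zip_ids: List[str]
    hospital_ids: List[str]
    footprint: object  # shapely geometry (union of member zip polygons)

    @property
    def area(self) -> float:
        return float(self.footprint.area)

    @property
    def perimeter(self) -> float:
        """Total boundary length, all rings of the union included."""
        return float(self.footprint.length)

    def to_feature(self) -> dict:
        return {
            "type": "Feature",
            "properties": {
                "region": int(self.label),
                "zip_ids": list(self.zip_ids),
                "hospital_ids": list(self.hospital_ids),
                "area": self.area,
                "perimeter": self.perimeter,
            },
            "geometry": mapping(self.footprint),
        }


def build_footprints(partition: Partition, geography: GeographyTable) -> List[RegionSet]:
    """Union member zip polygons into one footprint per region.

    Every zip unit of the geography must carry a label.  Hospitals are
    attached by their own partition label when present, else by their
    host zip's label.
    """
    poly_of: Dict[str, object] = {}
    for row in geography.zips.itertuples(index=False):
        if not row.geometry.is_valid or row.geometry.area <= 0:
            raise ValueError(f"invalid polygon for zip unit {row.zip_id!r}")
        poly_of[row.zip_id] = row.geometry
        if row.zip_id not in partition:
            raise KeyError(f"zip unit {row.zip_id!r} has no region label")

    members: Dict[int, List[str]] = {}
    for z in geography.zip_ids:
        members.setdefault(partition[z], []).append(z)

    host = geography.hospitals.set_index("hospital_id")["zip_id"]
    hosp_members: Dict[int, List[str]] = {}
    for h in geography.hospital_ids:
        label = partition[h] if h in partition else partition[host.loc[h]]
        hosp_members.setdefault(label, []).append(h)

    out = []
    for label in sorted(members):
        fp = unary_union([poly_of[z] for z in members[label]])
        out.append(RegionSet(label=int(label), zip_ids=sorted(members[label]),
                             hospital_ids=sorted(hosp_members.get(label, [])),
                             footprint=fp))
    return out


@dataclass
class RenResult:
    """Everything the two-phase detection produced."""

    partition: Partition            # final region label per zip unit & hospital
    phase1_partition: Partition
    phase2_partition: Partition     # phase-1 community -> region
    modularity_phase1: float
    modularity_phase2: Optional[float]
    regions: List[RegionSet] = field(default_factory=list)
    filled_zips: List[str] = field(default_factory=list)
    graph_phase1: Optional[FlowGraph] = None
    graph_phase2: Optional[FlowGraph] = None

    @property
    def n_regions(self) -> int:
        return self.partition.n_communities

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.partition.to_csv(out / "ren_partition.csv")
        self.phase1_partition.to_csv(out / "phase1_partition.csv")
        fc = {"type": "FeatureCollection",
              "features": [r.to_feature() for r in self.regions]}
        (out / "ren_footprints.geojson").write_text(json.dumps(fc))


def _canonicalize_by_volume(partition: Partition, cohort: pd.DataFrame) -> Partition:
    """Relabel regions 0..C-1 by descending index-encounter volume."""
    vol: Dict[int, int] = {c: 0 for c in set(partition.labels.values())}
    for z, cnt in cohort.groupby("home_zip").size().items():
        if z in partition:
            vol[partition[z]] += int(cnt)
    order = sorted(vol, key=lambda c: (-vol[c], c))
    mapping_ = {c: i for i, c in enumerate(order)}
    return partition.relabel(mapping_)


def detect_rens(
    cohort: pd.DataFrame,
    transfers: pd.DataFrame,
    geography: Optional[GeographyTable] = None,
    seed: int = 0,
    restarts: int = 5,
    min_gain: float = DEFAULT_MIN_GAIN,
) -> RenResult:
    """Run the full two-phase detection and (optionally) map to geography.

    With zero transfers the phase-2 stage is degenerate and the final
    regions equal the phase-1 communities (logged).  When a geography is
    supplied, zip units without any cohort encounter are assigned to the
    region of the nearest labelled zip centroid so that footprints tile;
    those units are listed in ``result.filled_zips``.
    """
    g1 = build_phase1_graph(cohort, transfers=transfers)
    p1, q1 = louvain(g1, seed=seed, restarts=restarts, min_gain=min_gain)

    if transfers is None or len(transfers) == 0:
        log.info("no transfers: final regions are the phase-1 communities")
        final = p1
        p2 = Partition({c: c for c in set(p1.labels.values())})
        g2, q2 = None, None
    else:
        g2 = build_phase2_graph(p1, transfers)
        p2, q2 = louvain(g2, seed=seed, restarts=restarts, min_gain=min_gain)
        final = Partition({n: p2[p1[n]] for n in p1.nodes})

    final = _canonicalize_by_volume(final, cohort)
    filled: List[str] = []
    regions: List[RegionSet] = []
    if geography is not None:
        labels = final.labels
        known = geography.zips["zip_id"].isin(labels)
        if (~known).any():
            kz = geography.zips.loc[known]
            kx, ky = kz["cx"].to_numpy(), kz["cy"].to_numpy()
            kid = kz["zip_id"].to_numpy()
            for row in geography.zips.loc[~known].itertuples(index=False):
                d2 = (kx - row.cx) ** 2 + (ky - row.cy) ** 2
                labels[row.zip_id] = labels[kid[int(np.argmin(d2))]]
                filled.append(row.zip_id)
            log.info("assigned %d encounter-free zip unit(s) to nearest region",
                     len(filled))
        host = geography.hospitals.set_index("hospital_id")["zip_id"]
        for h in geography.hospital_ids:
            if h not in labels:
                labels[h] = labels[host.loc[h]]
        final = Partition(labels)
        regions = build_footprints(final, geography)

    return RenResult(
        partition=final,
        phase1_partition=p1,
        phase2_partition=p2,
        modularity_phase1=q1,
        modularity_phase2=q2,
        regions=regions,
        filled_zips=filled,
        graph_phase1=g1,
        graph_phase2=g2,
    )
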