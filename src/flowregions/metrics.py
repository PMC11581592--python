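"""Spatial-accuracy and network-characteristic metrics.

Per-region battery used to compare a detected regional partition against
a reference partition of the same geography:

* localization index (LI) — fraction of a region's resident encounters
  treated inside the region (higher is better);
* market share index (MSI) — fraction of encounters treated in a region
  whose patients live elsewhere (lower is better);
* net patient flow (NPF) — incoming / outgoing encounter ratio (1 is a
  balanced region; undefined when nothing flows out);
* connectivity — number of interhospital transfers staying inside the
  region;
* compactness — corrected perimeter-area ratio P / (2 sqrt(pi A)),
  normalized so a disc scores exactly 1 (smaller = more compact,
  scale-invariant);
* modularity — global quality of the partition on the phase-1 flow graph.

A reclassification analysis quantifies how far the two partitions
disagree, anchored per reference region at its central transfer hub,
and Mann-Whitney U tests compare per-region metric distributions.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .community import Partition, modularity
from .network import build_phase1_graph
from .regions import RegionSet, build_footprints

log = logging.getLogger(__name__)

__all__ = [
    "localization_index",
    "market_share_index",
    "net_patient_flow",
    "connectivity",
    "compactness",
    "reclassification",
    "ReclassificationSummary",
    "mann_whitney_u",
    "compare_methods",
    "ComparisonReport",
    "percentage",
    "metrics_table",
]


def percentage(numerator: float, denominator: float) -> float:
    """Percentage rounded half-up to 2 decimals (report convention)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    frac = Decimal(numerator) / Decimal(denominator) * 100
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _index_frame(cohort: pd.DataFrame, partition: Partition,
                 transfers: Optional[pd.DataFrame] = None,
                 include_transfer_legs: bool = False) -> pd.DataFrame:
    """Encounters annotated with home and treatment region labels."""
    df = cohort
    if not include_transfer_legs and transfers is not None and len(transfers):
        df = df.loc[~df["encounter_id"].isin(set(transfers["receiver_id"]))]
    missing = [z for z in df["home_zip"].unique() if z not in partition]
    missing += [h for h in df["facility"].unique() if h not in partition]
    if missing:
        raise KeyError(f"encounters reference unlabelled unit(s): {sorted(set(missing))[:5]}")
    out = pd.DataFrame({
        "home_region": [partition[z] for z in df["home_zip"]],
        "treat_region": [partition[h] for h in df["facility"]],
    })
    return out


def localization_index(cohort: pd.DataFrame, partition: Partition,
                       transfers: Optional[pd.DataFrame] = None,
                       include_transfer_legs: bool = False) -> pd.Series:
    """Per-region LI; NaN (flagged) for regions with no resident encounters."""
    df = _index_frame(cohort, partition, transfers, include_transfer_legs)
    regions = sorted(set(partition.labels.values()))
    residents = df.groupby("home_region").size()
    inside = df.loc[df["home_region"] == df["treat_region"]].groupby("home_region").size()
    li = pd.Series(
        [inside.get(r, 0) / residents[r] if residents.get(r, 0) else np.nan
         for r in regions],
        index=pd.Index(regions, name="region"), name="localization_index")
    li.attrs["undefined"] = [r for r in regions if not residents.get(r, 0)]
    return li


def market_share_index(cohort: pd.DataFrame, partition: Partition,
                       transfers: Optional[pd.DataFrame] = None,
                       include_transfer_legs: bool = False) -> pd.Series:
    """Per-region MSI; NaN (flagged) for regions treating no encounters."""
    df = _index_frame(cohort, partition, transfers, include_transfer_legs)
    regions = sorted(set(partition.labels.values()))
    treated = df.groupby("treat_region").size()
    outsiders = df.loc[df["home_region"] != df["treat_region"]].groupby("treat_region").size()
    msi = pd.Series(
        [outsiders.get(r, 0) / treated[r] if treated.get(r, 0) else np.nan
         for r in regions],
        index=pd.Index(regions, name="region"), name="market_share_index")
    msi.attrs["undefined"] = [r for r in regions if not treated.get(r, 0)]
    return msi


def net_patient_flow(cohort: pd.DataFrame, partition: Partition,
                     transfers: Optional[pd.DataFrame] = None,
                     include_transfer_legs: bool = False) -> pd.Series:
    """Per-region NPF = incoming/outgoing; NaN (flagged) when outgoing is 0."""
    df = _index_frame(cohort, partition, transfers, include_transfer_legs)
    regions = sorted(set(partition.labels.values()))
    cross = df.loc[df["home_region"] != df["treat_region"]]
    incoming = cross.groupby("treat_region").size()
    outgoing = cross.groupby("home_region").size()
    npf = pd.Series(
        [incoming.get(r, 0) / outgoing[r] if outgoing.get(r, 0) else np.nan
         for r in regions],
        index=pd.Index(regions, name="region"), name="net_patient_flow")
    npf.attrs["undefined"] = [r for r in regions if not outgoing.get(r, 0)]
    return npf


def connectivity(transfers: pd.DataFrame, partition: Partition) -> pd.Series:
    """Per-region count of transfers with both endpoints inside the region."""
    regions = sorted(set(partition.labels.values()))
    counts = {r: 0 for r in regions}
    for row in transfers.itertuples(index=False):
        a, b = partition[row.sender_facility], partition[row.receiver_facility]
        if a == b:
            counts[a] += 1
    return pd.Series(counts, name="connectivity").rename_axis("region")


def compactness(region: RegionSet) -> float:
    """Corrected perimeter-area ratio P / (2 sqrt(pi A)); disc = 1."""
    if region.area <= 0:
        raise ValueError(f"region {region.label} has zero area")
    return region.perimeter / (2.0 * math.sqrt(math.pi * region.area))


# ---------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------

def mann_whitney_u(x, y) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U test (U of the first sample, p value).

    The exact null distribution is enumerated when both samples are small
    (min(n1, n2) <= 8) and tie-free; otherwise the normal approximation
    with midranks, tie correction and continuity correction is used.
    """
    x = np.asarray(list(x), float)
    y = np.asarray(list(y), float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("Mann-Whitney U requires two non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------
# reclassification
# ---------------------------------------------------------------------

@dataclass
class ReclassificationSummary:
    """Reference-region-anchored disagreement between two partitions."""

    per_region: pd.DataFrame   # columns: reference_region, hub, matched_region,
    #                            n_hospitals, hospital_pct, index_visit_pct, transfer_pct
    overall_hospital_pct: float
    n_hospitals_reclassified: int
    n_hospitals_total: int
    skipped_regions: List[int] = field(default_factory=list)

    def stat(self, column: str) -> Dict[str, float]:
        v = self.per_region[column].dropna()
        if v.empty:
            return {"mean": float("nan"), "median": float("nan"),
                    "iqr_low": float("nan"), "iqr_high": float("nan")}
        return {
            "mean": float(v.mean()),
            "median": float(v.median()),
            "iqr_low": float(v.quantile(0.25)),
            "iqr_high": float(v.quantile(0.75)),
        }


def _transfer_degree(transfers: pd.DataFrame) -> Dict[str, int]:
    deg: Dict[str, int] = {}
    for row in transfers.itertuples(index=False):
        deg[row.sender_facility] = deg.get(row.sender_facility, 0) + 1
        deg[row.receiver_facility] = deg.get(row.receiver_facility, 0) + 1
    return deg


def reclassification(
    reference_partition: Partition,
    ren_partition: Partition,
    cohort: pd.DataFrame,
    transfers: pd.DataFrame,
    hospital_ids: Optional[List[str]] = None,
) -> ReclassificationSummary:
    """How much of each reference region moved to a different detected region.

    For each reference region the *central transfer hub* is the member
    hospital with the largest total transfer degree (ties: larger index
    encounter volume, then smaller id).  The region is matched to the
    detected region containing its hub; members assigned elsewhere count
    as reclassified.  Percentages are reported per reference region for
    hospitals, for index-visit volume, and for transfer volume (both
    volume variants weight each hospital by its encounter share).
    Reference regions without hospitals are skipped with a warning.
    """
    if hospital_ids is None:
        hospital_ids = sorted(set(cohort["facility"]))
    for h in hospital_ids:
        if h not in reference_partition or h not in ren_partition:
            raise KeyError(f"hospital {h!r} is missing from one of the partitions")
    deg = _transfer_degree(transfers)
    vol = cohort.groupby("facility").size().to_dict()

    by_ref: Dict[int, List[str]] = {}
    for h in hospital_ids:
        by_ref.setdefault(reference_partition[h], []).append(h)

    rows = []
    skipped: List[int] = []
    n_reclass = 0
    for ref_label in sorted(set(reference_partition.labels.values())):
        members = by_ref.get(ref_label, [])
        if not members:
            skipped.append(ref_label)
            log.warning("reference region %s has no hospitals; skipped", ref_label)
            continue
        hub = min(members,
                  key=lambda h: (-deg.get(h, 0), -vol.get(h, 0), str(h)))
        matched = ren_partition[hub]
        moved = [h for h in members if ren_partition[h] != matched]
        n_reclass += len(moved)
        w_idx = sum(vol.get(h, 0) for h in members)
        w_idx_moved = sum(vol.get(h, 0) for h in moved)
        w_tr = sum(deg.get(h, 0) for h in members)
        w_tr_moved = sum(deg.get(h, 0) for h in moved)
        rows.append({
            "reference_region": ref_label,
            "hub": hub,
            "matched_region": matched,
            "n_hospitals": len(members),
            "hospital_pct": percentage(len(moved), len(members)),
            "index_visit_pct": percentage(w_idx_moved, w_idx) if w_idx else np.nan,
            "transfer_pct": percentage(w_tr_moved, w_tr) if w_tr else np.nan,
        })
    per_region = pd.DataFrame(rows)
    total = sum(len(v) for v in by_ref.values())
    overall = percentage(n_reclass, total) if total else float("nan")
    return ReclassificationSummary(
        per_region=per_region,
        overall_hospital_pct=overall,
        n_hospitals_reclassified=n_reclass,
        n_hospitals_total=total,
        skipped_regions=skipped,
    )


# ---------------------------------------------------------------------
# comparison report
# ---------------------------------------------------------------------

def metrics_table(
    cohort: pd.DataFrame,
    transfers: pd.DataFrame,
    partition: Partition,
    geography=None,
    regions: Optional[List[RegionSet]] = None,
) -> pd.DataFrame:
    """Per-region metric battery for one partition."""
    li = localization_index(cohort, partition, transfers)
    msi = market_share_index(cohort, partition, transfers)
    npf = net_patient_flow(cohort, partition, transfers)
    conn = connectivity(transfers, partition)
    table = pd.concat([li, msi, npf, conn], axis=1)
    if regions is None and geography is not None:
        regions = build_footprints(partition, geography)
    if regions is not None:
        comp = pd.Series({r.label: compactness(r) for r in regions},
                         name="compactness").rename_axis("region")
        table = pd.concat([table, comp], axis=1)
    return table


def _describe(col: pd.Series) -> Dict[str, float]:
    v = col.dropna()
    if v.empty:
        return {"mean": float("nan"), "sd": float("nan"),
                "min": float("nan"), "max": float("nan")}
    return {"mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
            "min": float(v.min()), "max": float(v.max())}


@dataclass
class ComparisonReport:
    """Side-by-side evaluation of detected vs reference partitions."""

    ren_table: pd.DataFrame
    reference_table: pd.DataFrame
    ren_modularity_phase1: float
    reference_modularity_phase1: float
    tests: Dict[str, Dict[str, float]]
    reclassification: ReclassificationSummary
    ren_modularity_phase2: Optional[float] = None

    METRICS = ["localization_index", "market_share_index", "net_patient_flow",
               "connectivity", "compactness"]

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for metric in self.METRICS:
            if metric not in self.ren_table.columns:
                continue
            a = _describe(self.ren_table[metric])
            b = _describe(self.reference_table[metric])
            t = self.tests.get(metric, {})
            rows.append({
                "metric": metric,
                "ren_mean": a["mean"], "ren_sd": a["sd"],
                "ren_min": a["min"], "ren_max": a["max"],
                "ref_mean": b["mean"], "ref_sd": b["sd"],
                "ref_min": b["min"], "ref_max": b["max"],
                "U": t.get("U", float("nan")),
                "p_value": t.get("p", float("nan")),
            })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        rc = self.reclassification
        return {
            "metrics": self.summary_frame().to_dict(orient="records"),
            "modularity": {
                "ren_phase1": self.ren_modularity_phase1,
                "reference_phase1": self.reference_modularity_phase1,
                "ren_phase2": self.ren_modularity_phase2,
            },
            "reclassification": {
                "overall_hospital_pct": rc.overall_hospital_pct,
                "n_hospitals_reclassified": rc.n_hospitals_reclassified,
                "n_hospitals_total": rc.n_hospitals_total,
                "hospital": rc.stat("hospital_pct"),
                "index_visit": rc.stat("index_visit_pct"),
                "transfer": rc.stat("transfer_pct"),
            },
            "per_region": {
                "ren": self.ren_table.reset_index().to_dict(orient="records"),
                "reference": self.reference_table.reset_index().to_dict(orient="records"),
            },
        }

    def to_json(self, path=None) -> str:
        def clean(o):
            if isinstance(o, float) and math.isnan(o):
                return None
            if isinstance(o, dict):
                return {k: clean(v) for k, v in o.items()}
            if isinstance(o, list):
                return [clean(v) for v in o]
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return clean(float(o))
            return o

        text = json.dumps(clean(self.to_dict()), indent=2)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text

    def to_csv(self, path) -> None:
        self.summary_frame().to_csv(path, index=False)


def compare_methods(
    cohort: pd.DataFrame,
    transfers: pd.DataFrame,
    geography,
    ren_partition: Partition,
    reference_partition: Partition,
) -> ComparisonReport:
    """Full method comparison: metrics, modularity, tests, reclassification."""
    g1 = build_phase1_graph(cohort, transfers=transfers)
    q_ren = modularity(g1, _restrict(ren_partition, g1))
    q_ref = modularity(g1, _restrict(reference_partition, g1))

    ren_tab = metrics_table(cohort, transfers, ren_partition, geography)
    ref_tab = metrics_table(cohort, transfers, reference_partition, geography)

    tests: Dict[str, Dict[str, float]] = {}
    for metric in ComparisonReport.METRICS:
        if metric not in ren_tab.columns or metric not in ref_tab.columns:
            continue
        a = ren_tab[metric].dropna()
        b = ref_tab[metric].dropna()
        if len(a) and len(b):
            u, p = mann_whitney_u(a, b)
            tests[metric] = {"U": u, "p": p}

    rc = reclassification(reference_partition, ren_partition, cohort, transfers,
                          hospital_ids=sorted(geography.hospital_ids)
                          if geography is not None else None)
    return ComparisonReport(
        ren_table=ren_tab,
        reference_table=ref_tab,
        ren_modularity_phase1=q_ren,
        reference_modularity_phase1=q_ref,
        tests=tests,
        reclassification=rc,
    )


def _restrict(partition: Partition, graph) -> Partition:
    return Partition({n: partition[n] for n in graph.nodes})
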