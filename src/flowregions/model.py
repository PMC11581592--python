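"""Model / results surface for regional-network delineation.

`RegionalFlowModel` holds the prepared inputs (cohort, linked transfers,
geography); `fit` runs the two-phase modularity-optimization detection
and returns a `RegionalFlowResults` carrying the partition, per-phase
modularity, detected regions, per-region metrics, and comparison tools.

    >>> model = RegionalFlowModel.from_encounters(encounters, geography)
    >>> res = model.fit(seed=7)
    >>> print(res.summary())
    >>> report = res.compare(reference_partition)
"""

from __future__ import annotations

import logging
from typing import Optional, Set

import pandas as pd

from .cohort import link_transfers, select_cohort
from .community import DEFAULT_MIN_GAIN, Partition, adjusted_rand_index
from .metrics import ComparisonReport, compare_methods, metrics_table, percentage
from .regions import RenResult, detect_rens
from .synthetic import CONDITION_LABELS, GeographyTable

log = logging.getLogger(__name__)

__all__ = ["RegionalFlowModel", "RegionalFlowResults"]


class RegionalFlowModel:
    """Two-phase regional-network model over patient-flow data.

    Parameters
    ----------
    cohort
        Eligibility-filtered encounter table.
    transfers
        Linked transfer pairs (possibly empty).
    geography
        Optional `GeographyTable` for footprints and compactness.
    """

    def __init__(self, cohort: pd.DataFrame, transfers: pd.DataFrame,
                 geography: Optional[GeographyTable] = None):
        self.cohort = cohort
        self.transfers = transfers
        self.geography = geography

    @classmethod
    def from_encounters(
        cls,
        encounters: pd.DataFrame,
        geography: Optional[GeographyTable] = None,
        eligible_conditions: Optional[Set[str]] = None,
    ) -> "RegionalFlowModel":
        """Apply cohort rules and transfer linkage to raw encounter rows."""
        if eligible_conditions is None:
            eligible_conditions = set(CONDITION_LABELS)
        cohort = select_cohort(encounters, eligible_conditions)
        transfers = link_transfers(cohort)
        return cls(cohort, transfers, geography)

    def fit(self, seed: int = 0, restarts: int = 5,
            min_gain: float = DEFAULT_MIN_GAIN) -> "RegionalFlowResults":
        """Run two-phase detection; deterministic given ``seed``."""
        ren = detect_rens(self.cohort, self.transfers, self.geography,
                          seed=seed, restarts=restarts, min_gain=min_gain)
        return RegionalFlowResults(self, ren)


class RegionalFlowResults:
    """Fitted regional networks plus diagnostics."""

    def __init__(self, model: RegionalFlowModel, ren: RenResult):
        self.model = model
        self.ren = ren

    # -- convenience views --------------------------------------------
    @property
    def partition(self) -> Partition:
        return self.ren.partition

    @property
    def regions(self):
        return self.ren.regions

    @property
    def n_regions(self) -> int:
        return self.ren.n_regions

    @property
    def modularity_phase1(self) -> float:
        return self.ren.modularity_phase1

    @property
    def modularity_phase2(self):
        return self.ren.modularity_phase2

    def metrics(self) -> pd.DataFrame:
        """Per-region LI / MSI / NPF / connectivity (/ compactness)."""
        return metrics_table(self.model.cohort, self.model.transfers,
                             self.partition, self.model.geography,
                             regions=self.regions or None)

    def rand_index(self, other: Partition) -> float:
        """Adjusted Rand index against another partition of the same nodes."""
        common = set(self.partition.nodes) & set(other.nodes)
        return adjusted_rand_index(
            Partition({n: self.partition[n] for n in common}),
            Partition({n: other[n] for n in common}),
        )

    def compare(self, reference: Partition) -> ComparisonReport:
        """Full metric / modularity / reclassification comparison."""
        report = compare_methods(self.model.cohort, self.model.transfers,
                                 self.model.geography, self.partition, reference)
        report.ren_modularity_phase2 = self.ren.modularity_phase2
        return report

    def summary(self) -> str:
        """Human-readable fit summary (statsmodels-style text block)."""
        n_idx = len(self.model.cohort) - len(self.model.transfers)
        lines = [
            "Regional Flow Network Results",
            "=" * 46,
            f"{'Encounters (cohort rows)':34s}{len(self.model.cohort):>12,d}",
            f"{'Index encounters':34s}{n_idx:>12,d}",
            f"{'Interhospital transfers':34s}{len(self.model.transfers):>12,d}",
        ]
        if len(self.model.cohort):
            pct = percentage(len(self.model.transfers), len(self.model.cohort))
            lines.append(f"{'Transfer share (%)':34s}{pct:>12.2f}")
        lines += [
            f"{'Phase-1 communities':34s}{self.ren.phase1_partition.n_communities:>12d}",
            f"{'Phase-1 modularity Q':34s}{self.modularity_phase1:>12.4f}",
        ]
        if self.modularity_phase2 is not None:
            lines.append(f"{'Phase-2 modularity Q':34s}{self.modularity_phase2:>12.4f}")
        lines += [
            f"{'Regional networks detected':34s}{self.n_regions:>12d}",
            "=" * 46,
        ]
        tab = self.metrics()
        with pd.option_context("display.float_format", "{:.4f}".format):
            lines.append(tab.to_string())
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        self.ren.write(out_dir)

    def plot(self, ax=None):
        """Static footprint map with transfer lines (decoration only)."""
        import matplotlib.pyplot as plt
        from matplotlib import colormaps

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 5))
        cmap = colormaps["tab20"]
        for r in self.regions:
            geoms = getattr(r.footprint, "geoms", [r.footprint])
            for g in geoms:
                x, y = g.exterior.xy
                ax.fill(x, y, color=cmap(r.label % 20), alpha=0.5)
        if self.model.geography is not None:
            hosp = self.model.geography.hospitals
            zc = self.model.geography.zips.set_index("zip_id")[["cx", "cy"]]
            host = hosp.set_index("hospital_id")["zip_id"]
            for row in self.model.transfers.itertuples(index=False):
                a = zc.loc[host.loc[row.sender_facility]]
                b = zc.loc[host.loc[row.receiver_facility]]
                ax.plot([a.cx, b.cx], [a.cy, b.cy], color="navy", lw=0.3, alpha=0.3)
            ax.scatter(zc.loc[host, "cx"], zc.loc[host, "cy"],
                       s=hosp["volume"].clip(upper=200), c="crimson", zorder=3)
        ax.set_aspect("equal")
        ax.set_title(f"{self.n_regions} regional networks")
        return ax
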