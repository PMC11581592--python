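"""Synthetic health systems with planted community structure.

Real statewide encounter databases (all-payer inpatient/ED records) are
restricted, so every downstream stage of the pipeline is exercised on
synthetic systems instead: a rectangular grid of zip units partitioned
into ``n_communities`` contiguous blocks, hospitals with heavy-tailed
volumes (one dominant hub per community), and encounter tables in which
patients are admitted within their home block with probability
``1 - mixing_mu`` and a small fraction of encounters generate an
interhospital transfer.  The planted block structure is the ground truth
that community detection should recover, and a perturbed copy of it plays
the role of the legacy referral-region partition that the detected
regions are compared against.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping

from .community import Partition

__all__ = [
    "SyntheticConfig",
    "GeographyTable",
    "generate_geography",
    "generate_encounters",
    "generate_reference_partition",
    "planted_partition",
    "ENCOUNTER_COLUMNS",
    "CONDITION_LABELS",
]

#: documented column order of the encounter CSV dialect
ENCOUNTER_COLUMNS = [
    "encounter_id",
    "patient_key",
    "home_zip",
    "facility",
    "admission_day",
    "discharge_day",
    "age",
    "elective",
    "admission_source",
    "condition",
    "transfer_ind",
    "transfer_src",
]

#: twelve abstract emergency-surgery condition labels with a skewed
#: frequency mix (a few dominant conditions, a long tail), mirroring the
#: strong imbalance seen in real emergency-surgery case mixes
CONDITION_LABELS = [f"cond_{i:02d}" for i in range(1, 13)]
_CONDITION_WEIGHTS = np.array(
    [0.041, 0.046, 0.057, 0.019, 0.003, 0.018, 0.034, 0.013, 0.066, 0.013, 0.210, 0.480]
)
_CONDITION_WEIGHTS = _CONDITION_WEIGHTS / _CONDITION_WEIGHTS.sum()

_STREAM_GEOGRAPHY = 0
_STREAM_ENCOUNTERS = 1
_STREAM_REFERENCE = 2


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic health system.

    Defaults describe the benchmark system used throughout the test
    battery: 4 planted communities of 25 zip units and 3 hospitals each,
    50 000 encounters, 2% cross-community admission leakage, a 1%
    interhospital-transfer rate (matching the ~0.8-1.2% rates seen in
    statewide emergency-surgery cohorts), 2% transfer leakage, and a
    reference partition perturbed on 25% of zip units.
    """

    n_communities: int = 4
    zips_per_community: int = 25
    hospitals_per_community: int = 3
    n_encounters: int = 50_000
    mixing_mu: float = 0.02
    transfer_rate: float = 0.01
    transfer_mixing: float = 0.02
    reference_perturbation: float = 0.25
    dirty_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for name in ("n_communities", "zips_per_community",
                     "hospitals_per_community", "n_encounters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("mixing_mu", "transfer_rate", "transfer_mixing",
                     "reference_perturbation", "dirty_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.hospitals_per_community > self.zips_per_community:
            raise ValueError(
                "hospitals_per_community cannot exceed zips_per_community "
                f"({self.hospitals_per_community} > {self.zips_per_community})"
            )

    def rng(self, stream: int) -> np.random.Generator:
        # one independent stream per output table so e.g. changing
        # n_encounters never alters the geography
        return np.random.default_rng([int(self.seed), int(stream)])

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        return cls(**json.loads(text))


@dataclass
class GeographyTable:
    """Zip units (with planted labels and unit-square polygons) and hospitals.

    ``zips`` columns: zip_id, community, cx, cy (centroid), geometry
    (shapely polygon).  ``hospitals`` columns: hospital_id, zip_id,
    community, volume, trauma_level.
    """

    zips: pd.DataFrame
    hospitals: pd.DataFrame

    @property
    def zip_ids(self) -> List[str]:
        return list(self.zips["zip_id"])

    @property
    def hospital_ids(self) -> List[str]:
        return list(self.hospitals["hospital_id"])

    def polygon_of(self, zip_id: str):
        row = self.zips.loc[self.zips["zip_id"] == zip_id]
        if row.empty:
            raise KeyError(f"unknown zip unit {zip_id!r}")
        return row["geometry"].iloc[0]

    def validate(self) -> None:
        zset = set(self.zips["zip_id"])
        missing = set(self.hospitals["zip_id"]) - zset
        if missing:
            raise ValueError(f"hospitals hosted in unknown zip units: {sorted(missing)}")
        for zid, poly in zip(self.zips["zip_id"], self.zips["geometry"]):
            if not poly.is_valid or poly.area <= 0:
                raise ValueError(f"invalid polygon for zip unit {zid!r}")

    # -- serialization -------------------------------------------------
    def zips_geojson(self) -> dict:
        feats = []
        for row in self.zips.itertuples(index=False):
            feats.append({
                "type": "Feature",
                "properties": {
                    "zip_id": row.zip_id,
                    "community": int(row.community),
                    "cx": float(row.cx),
                    "cy": float(row.cy),
                },
                "geometry": mapping(row.geometry),
            })
        return {"type": "FeatureCollection", "features": feats}

    def write(self, zips_path, hospitals_path) -> None:
        Path(zips_path).write_text(json.dumps(self.zips_geojson()))
        self.hospitals.to_csv(hospitals_path, index=False)

    @classmethod
    def read(cls, zips_path, hospitals_path) -> "GeographyTable":
        from shapely.geometry import shape

        fc = json.loads(Path(zips_path).read_text())
        rows = []
        for f in fc["features"]:
            p = f["properties"]
            rows.append((p["zip_id"], p["community"], p["cx"], p["cy"],
                         shape(f["geometry"])))
        zips = pd.DataFrame(rows, columns=["zip_id", "community", "cx", "cy", "geometry"])
        hospitals = pd.read_csv(hospitals_path)
        return cls(zips=zips, hospitals=hospitals)


def generate_geography(config: SyntheticConfig) -> GeographyTable:
    """Lay out zip units as contiguous community blocks and place hospitals.

    Communities are horizontal strips of unit-square cells (near-square
    blocks side by side), so adjacent communities share a boundary.
    Hospital volumes are drawn from a Zipf(2) tail and the top hospital
    of each community is inflated past the block's combined remainder,
    guaranteeing one dominant transfer hub per community.
    """
    rng = config.rng(_STREAM_GEOGRAPHY)
    K, Z, H = config.n_communities, config.zips_per_community, config.hospitals_per_community
    cols = math.ceil(math.sqrt(Z))
    zip_rows = []
    for c in range(K):
        x0 = c * cols
        for z in range(Z):
            col, row = z % cols, z // cols
            poly = box(x0 + col, row, x0 + col + 1, row + 1)
            zip_rows.append((f"z{c:02d}_{z:03d}", c, x0 + col + 0.5, row + 0.5, poly))
    zips = pd.DataFrame(zip_rows, columns=["zip_id", "community", "cx", "cy", "geometry"])

    hosp_rows = []
    for c in range(K):
        block = zips.loc[zips["community"] == c, "zip_id"].to_numpy()
        hosts = rng.choice(block, size=H, replace=False)
        vols = np.sort(rng.zipf(2.0, size=H))[::-1].astype(np.int64) + 1
        if H > 1:
            vols[0] = vols[1:].sum() + int(rng.integers(5, 20))
        else:
            vols[0] += int(rng.integers(5, 20))
        trauma = rng.random(H) < 0.25
        trauma[0] = True  # the hub carries advanced resources
        for j in range(H):
            hosp_rows.append((f"h{c:02d}_{j}", hosts[j], c, int(vols[j]), bool(trauma[j])))
    hospitals = pd.DataFrame(
        hosp_rows, columns=["hospital_id", "zip_id", "community", "volume", "trauma_level"]
    )
    geo = GeographyTable(zips=zips, hospitals=hospitals)
    geo.validate()
    return geo


def _volume_choice(rng, hospitals: pd.DataFrame, mask: np.ndarray, size: int) -> np.ndarray:
    """Sample hospital ids volume-proportionally from the masked subset."""
    sub = hospitals.loc[mask]
    p = sub["volume"].to_numpy(float)
    p = p / p.sum()
    return rng.choice(sub["hospital_id"].to_numpy(), size=size, p=p)


def generate_encounters(geo: GeographyTable, config: SyntheticConfig) -> pd.DataFrame:
    """Draw the encounter table, including planted transfers and dirty rows.

    Index encounters pick a home zip uniformly; the destination hospital
    is volume-proportional within the home community with probability
    ``1 - mixing_mu`` and volume-proportional outside it otherwise.  A
    fraction ``transfer_rate`` of clean index encounters gains a linked
    second encounter at a different facility admitted 0-1 days after
    discharge, routed hub-ward within the sending hospital's community
    unless it leaks (``transfer_mixing``).  A fraction ``dirty_fraction``
    of index rows violates exactly one cohort rule (minor age, elective
    flag, non-home source, or ineligible condition) to exercise filters.
    The ``transfer_src`` column records the planted sending encounter id
    (ground-truth annotation used only for validation).
    """
    rng = config.rng(_STREAM_ENCOUNTERS)
    hosp = geo.hospitals
    n = config.n_encounters

    zip_ids = geo.zips["zip_id"].to_numpy()
    zip_comm = geo.zips.set_index("zip_id")["community"]
    home = rng.choice(zip_ids, size=n)
    home_comm = zip_comm.loc[home].to_numpy()

    leak = rng.random(n) < config.mixing_mu
    facility = np.empty(n, dtype=object)
    for c in np.unique(home_comm):
        inside = (home_comm == c) & ~leak
        outside = (home_comm == c) & leak
        if inside.any():
            facility[inside] = _volume_choice(
                rng, hosp, (hosp["community"] == c).to_numpy(), int(inside.sum()))
        if outside.any():
            other = (hosp["community"] != c).to_numpy()
            if not other.any():  # single-community system: no outside exists
                other = np.ones(len(hosp), bool)
            facility[outside] = _volume_choice(rng, hosp, other, int(outside.sum()))

    admission = rng.integers(0, 360, size=n)
    los = rng.integers(0, 8, size=n)
    age = rng.integers(18, 96, size=n)
    condition = rng.choice(CONDITION_LABELS, size=n, p=_CONDITION_WEIGHTS)

    df = pd.DataFrame({
        "encounter_id": [f"e{i:07d}" for i in range(n)],
        "patient_key": [f"p{i:07d}" for i in range(n)],
        "home_zip": home,
        "facility": facility,
        "admission_day": admission,
        "discharge_day": admission + los,
        "age": age,
        "elective": False,
        "admission_source": "home",
        "condition": condition,
        "transfer_ind": False,
        "transfer_src": pd.NA,
    })

    # dirty rows: exactly one violated rule each
    n_dirty = int(round(config.dirty_fraction * n))
    dirty_idx = rng.choice(n, size=n_dirty, replace=False) if n_dirty else np.array([], int)
    kinds = rng.integers(0, 4, size=n_dirty)
    for i, kind in zip(dirty_idx, kinds):
        if kind == 0:
            df.loc[i, "age"] = int(rng.integers(1, 18))
        elif kind == 1:
            df.loc[i, "elective"] = True
        elif kind == 2:
            df.loc[i, "admission_source"] = "other"
        else:
            df.loc[i, "condition"] = "cond_ineligible"

    # planted transfers off clean index rows
    clean = np.ones(n, bool)
    clean[dirty_idx] = False
    xfer = (rng.random(n) < config.transfer_rate) & clean
    xfer_idx = np.flatnonzero(xfer)
    hosp_comm = hosp.set_index("hospital_id")["community"]
    extra = []
    for j, i in enumerate(xfer_idx):
        send_fac = df.at[i, "facility"]
        c = int(hosp_comm.loc[send_fac])
        leak_t = rng.random() < config.transfer_mixing
        if leak_t:
            cand = (hosp["community"] != c).to_numpy()
        else:
            cand = ((hosp["community"] == c) &
                    (hosp["hospital_id"] != send_fac)).to_numpy()
        if not cand.any():
            cand = (hosp["hospital_id"] != send_fac).to_numpy()
        dest = _volume_choice(rng, hosp, cand, 1)[0]
        gap = int(rng.integers(0, 2))
        adm = int(df.at[i, "discharge_day"]) + gap
        extra.append({
            "encounter_id": f"t{j:07d}",
            "patient_key": df.at[i, "patient_key"],
            "home_zip": df.at[i, "home_zip"],
            "facility": dest,
            "admission_day": adm,
            "discharge_day": adm + int(rng.integers(0, 8)),
            "age": int(df.at[i, "age"]),
            "elective": False,
            "admission_source": "home",
            "condition": df.at[i, "condition"],
            "transfer_ind": True,
            "transfer_src": df.at[i, "encounter_id"],
        })
    if extra:
        df = pd.concat([df, pd.DataFrame(extra)], ignore_index=True)
    return df[ENCOUNTER_COLUMNS]


def planted_partition(geo: GeographyTable) -> Partition:
    """Ground-truth partition: every zip unit and hospital gets its planted label."""
    labels: Dict[str, int] = {}
    for row in geo.zips.itertuples(index=False):
        labels[row.zip_id] = int(row.community)
    for row in geo.hospitals.itertuples(index=False):
        labels[row.hospital_id] = int(row.community)
    return Partition(labels)


def generate_reference_partition(geo: GeographyTable, config: SyntheticConfig) -> Partition:
    """Perturbed copy of the planted partition (legacy referral-region analogue).

    A fixed count ``round(reference_perturbation * n_zips)`` of zip units
    is relabelled to the community of the nearest zip centroid belonging
    to a different community; hospitals inherit their (possibly
    relabelled) host zip's label.
    """
    rng = config.rng(_STREAM_REFERENCE)
    zips = geo.zips
    labels = {row.zip_id: int(row.community) for row in zips.itertuples(index=False)}
    n_flip = int(round(config.reference_perturbation * len(zips)))
    if n_flip and zips["community"].nunique() > 1:
        flips = rng.choice(zips["zip_id"].to_numpy(), size=n_flip, replace=False)
        cx = zips["cx"].to_numpy()
        cy = zips["cy"].to_numpy()
        comm = zips["community"].to_numpy()
        zid = zips["zip_id"].to_numpy()
        for z in flips:
            i = int(np.flatnonzero(zid == z)[0])
            other = comm != comm[i]
            d2 = (cx - cx[i]) ** 2 + (cy - cy[i]) ** 2
            d2[~other] = np.inf
            labels[z] = int(comm[int(np.argmin(d2))])
    for row in geo.hospitals.itertuples(index=False):
        labels[row.hospital_id] = labels[row.zip_id]
    return Partition(labels)
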