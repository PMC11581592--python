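"""Cohort eligibility and interhospital-transfer linkage.

Eligibility mirrors the inclusion rules of statewide emergency-surgery
cohorts: adults (age >= 18), nonelective presentation, admitted from
home, with a primary diagnosis among the eligible condition labels.

Transfers are identified longitudinally: two encounters of the same
patient at two *different* facilities whose admission follows the prior
discharge by 0-1 days form a transfer pair; encounters carrying a raw
transfer indicator but lacking a temporally adjacent sender are reported
rather than linked.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Set

import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["select_cohort", "link_transfers", "SchemaError",
           "TRANSFER_PAIR_COLUMNS", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = [
    "encounter_id", "patient_key", "home_zip", "facility",
    "admission_day", "discharge_day", "age", "elective",
    "admission_source", "condition",
]

TRANSFER_PAIR_COLUMNS = [
    "sender_id", "receiver_id", "sender_facility", "receiver_facility", "gap_days",
]

#: linkage window: receiving admission minus sending discharge, in days
MAX_TRANSFER_GAP_DAYS = 1


class SchemaError(ValueError):
    """An expected encounter-table column is missing."""


def _check_schema(encounters: pd.DataFrame, columns: Iterable[str]) -> None:
    missing = [c for c in columns if c not in encounters.columns]
    if missing:
        raise SchemaError(f"encounter table is missing required column(s): {missing}")


def select_cohort(
    encounters: pd.DataFrame,
    eligible_conditions: Set[str],
) -> pd.DataFrame:
    """Apply the four eligibility rules; per-rule exclusion counts are logged.

    Rules are applied in sequence (adult age, nonelective, home admission
    source, eligible condition), so each excluded row is counted against
    the first rule it violates.  The counts are also attached to the
    result as ``df.attrs["exclusions"]``.
    """
    _check_schema(encounters, REQUIRED_COLUMNS)
    df = encounters
    counts: Dict[str, int] = {}
    for rule, keep in [
        ("age_under_18", df["age"] >= 18),
        ("elective", ~df["elective"].astype(bool)),
        ("non_home_source", df["admission_source"] == "home"),
        ("ineligible_condition", df["condition"].isin(set(eligible_conditions))),
    ]:
        before = len(df)
        df = df.loc[keep.loc[df.index]]
        counts[rule] = before - len(df)
    total = sum(counts.values())
    log.info("cohort selection: %d of %d rows retained; exclusions %s",
             len(df), len(encounters), counts)
    out = df.reset_index(drop=True).copy()
    out.attrs["exclusions"] = counts
    out.attrs["n_excluded"] = total
    return out


def link_transfers(cohort: pd.DataFrame) -> pd.DataFrame:
    """Link interhospital transfer pairs within each patient's history.

    For every encounter (as a candidate receiver), candidate senders are
    the patient's earlier encounters (by admission day, then discharge
    day, then encounter id) at a *different* facility whose discharge
    precedes the receiver's admission by 0-1 days.  Each receiver is
    linked to at most one sender; ties resolve to the sender with the
    later discharge day, then the smaller facility id.  Chains A->B->C
    decompose into the pairs (A,B) and (B,C).

    Returns a frame with columns ``sender_id, receiver_id,
    sender_facility, receiver_facility, gap_days``.  Encounters whose raw
    transfer indicator is set but which could not be linked are collected
    in ``result.attrs["unlinked_indicator"]``.
    """
    _check_schema(cohort, REQUIRED_COLUMNS)
    pairs: List[tuple] = []
    unlinked: List[str] = []
    multi = cohort[cohort.duplicated("patient_key", keep=False)]
    has_ind = "transfer_ind" in cohort.columns

    for _, grp in multi.groupby("patient_key", sort=False):
        g = grp.sort_values(["admission_day", "discharge_day", "encounter_id"],
                            kind="mergesort")
        recs = list(g.itertuples(index=False))
        for ri, r in enumerate(recs):
            # senders must precede the receiver in the time sort, so a
            # fully simultaneous pair is linked in one direction only
            cands = [
                s for s in recs[:ri]
                if s.facility != r.facility
                and 0 <= r.admission_day - s.discharge_day <= MAX_TRANSFER_GAP_DAYS
            ]
            if not cands:
                if has_ind and getattr(r, "transfer_ind", False):
                    unlinked.append(r.encounter_id)
                continue
            best = max(cands, key=lambda s: (s.discharge_day, _neg_str(s.facility)))
            pairs.append((best.encounter_id, r.encounter_id, best.facility,
                          r.facility, int(r.admission_day - best.discharge_day)))

    if has_ind:
        solo_flagged = cohort.loc[
            cohort["transfer_ind"].astype(bool)
            & ~cohort.duplicated("patient_key", keep=False),
            "encounter_id",
        ]
        unlinked.extend(solo_flagged.tolist())

    out = pd.DataFrame(pairs, columns=TRANSFER_PAIR_COLUMNS)
    out = out.sort_values(["receiver_id"], kind="mergesort").reset_index(drop=True)
    if unlinked:
        log.warning("%d indicator-flagged encounter(s) had no adjacent sender "
                    "and were left unlinked", len(unlinked))
    out.attrs["unlinked_indicator"] = sorted(set(unlinked))
    return out


class _neg_str:
    """Orders strings in reverse, for use inside a max() key tuple."""

    __slots__ = ("s",)

    def __init__(self, s):
        self.s = s

    def __lt__(self, other):
        return self.s > other.s

    def __eq__(self, other):
        return self.s == other.s
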