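"""Encounter records and observation-history coding for the dead-recovery design.

Each monthly survey is an *occasion*.  Every capture, recapture or carcass
recovery is one :class:`SnailRecord`; per individual these are compiled into
an :class:`EncounterHistory`, a vector of observation codes over occasions:

====  =========================================================
code  meaning
====  =========================================================
1     live juvenile encountered (first capture or recapture)
2     juvenile recovered dead, cause other than predation
3     juvenile recovered dead, predation
4     live adult encountered
5     adult recovered dead, other cause
6     adult recovered dead, predation
7     not encountered
====  =========================================================

Occasions are 1-based and contiguous; each maps to a calendar month (1-12) so
month effects are shared across years.  A dead recovery is coded at the
occasion the carcass was found; the latent death is attributed to the
preceding inter-occasion interval.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SITES = ("mainland", "island")
STAGES = ("juvenile", "adult")
MICROHABITATS = ("hibernation", "ground", "arboreal")
STATUSES = ("live", "dead_other", "dead_predated")

#: CSV schema for raw encounter records (header required, UTF-8, comma).
RECORD_COLUMNS = [
    "individual_id",
    "occasion",
    "calendar_month",
    "site",
    "stage",
    "microhabitat",
    "status",
    "R_mean",
    "G_mean",
    "B_mean",
    "Y_grey",
]

NOT_SEEN = 7

# (stage, status) -> observation code
_CODE = {
    ("juvenile", "live"): 1,
    ("juvenile", "dead_other"): 2,
    ("juvenile", "dead_predated"): 3,
    ("adult", "live"): 4,
    ("adult", "dead_other"): 5,
    ("adult", "dead_predated"): 6,
}

DEAD_CODES = frozenset({2, 3, 5, 6})


@dataclass
class SnailRecord:
    """One capture/recapture/recovery event of one marked snail."""

    individual_id: str
    occasion: int
    calendar_month: int
    site: str
    stage: str
    microhabitat: str
    status: str
    colour: float = float("nan")

    def __post_init__(self) -> None:
        if self.occasion < 1:
            raise ValueError(f"{self.individual_id}: occasion must be >= 1")
        if not 1 <= self.calendar_month <= 12:
            raise ValueError(f"{self.individual_id}: calendar_month must be in 1..12")
        for name, value, allowed in (
            ("site", self.site, SITES),
            ("stage", self.stage, STAGES),
            ("microhabitat", self.microhabitat, MICROHABITATS),
            ("status", self.status, STATUSES),
        ):
            if value not in allowed:
                raise ValueError(
                    f"{self.individual_id}: unknown {name} {value!r} (allowed: {allowed})"
                )

    @property
    def code(self) -> int:
        return _CODE[(self.stage, self.status)]


@dataclass
class EncounterHistory:
    """Observation codes of one individual over all occasions."""

    individual_id: str
    first_capture: int  # 1-based occasion of first live capture
    codes: np.ndarray  # int vector, length T, values 1..7
    colour: float
    stage_at_first: str
    site: str = "mainland"

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)


def read_records(path: str | Path | io.TextIOBase) -> list[SnailRecord]:
    """Read raw encounter records from the CSV schema.

    Malformed rows are reported with their (1-based, header-exclusive) line
    numbers; a missing column raises immediately.
    """
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns and c not in
               ("R_mean", "G_mean", "B_mean", "Y_grey")]
    if missing:
        raise ValueError(f"schema error: missing columns {missing}")
    has_colour = "col" in df.columns
    out: list[SnailRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(
                SnailRecord(
                    individual_id=str(row.individual_id),
                    occasion=int(row.occasion),
                    calendar_month=int(row.calendar_month),
                    site=str(row.site),
                    stage=str(row.stage),
                    microhabitat=str(row.microhabitat),
                    status=str(row.status),
                    colour=float(row.col) if has_colour else float("nan"),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValueError("malformed rows:\n" + "\n".join(errors))
    return out


def records_to_frame(records: Iterable[SnailRecord]) -> pd.DataFrame:
    """Round-trip helper: records back into the tabular schema."""
    return pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in records],
            "occasion": [r.occasion for r in records],
            "calendar_month": [r.calendar_month for r in records],
            "site": [r.site for r in records],
            "stage": [r.stage for r in records],
            "microhabitat": [r.microhabitat for r in records],
            "status": [r.status for r in records],
            "col": [r.colour for r in records],
        }
    )


def build_histories(records: Sequence[SnailRecord], T: int) -> list[EncounterHistory]:
    """Compile validated records into per-individual encounter histories.

    Occasions without an event are coded 7.  Raises a consistency error
    naming the individual on stage reversal (adult back to juvenile) or any
    event after a dead recovery.  Output order follows first appearance of
    each individual in the input after sorting events by occasion, so the
    result is invariant to input row order.
    """
    if not records:
        return []
    max_occ = max(r.occasion for r in records)
    if T < max_occ:
        raise ValueError(f"T={T} is smaller than the largest occasion {max_occ}")

    by_id: dict[str, list[SnailRecord]] = {}
    for r in sorted(records, key=lambda r: (r.individual_id, r.occasion)):
        by_id.setdefault(r.individual_id, []).append(r)

    histories = []
    for ind in sorted(by_id):
        events = by_id[ind]
        codes = np.full(T, NOT_SEEN, dtype=np.int64)
        dead_seen = False
        prev_stage = None
        for ev in events:
            if dead_seen:
                raise ValueError(f"individual {ind}: event after a dead recovery")
            if prev_stage == "adult" and ev.stage == "juvenile":
                raise ValueError(f"individual {ind}: stage reversal adult->juvenile")
            if codes[ev.occasion - 1] != NOT_SEEN:
                # several captures within one survey window: first event wins
                continue
            codes[ev.occasion - 1] = ev.code
            if ev.status != "live":
                dead_seen = True
            prev_stage = ev.stage
        first = events[0]
        if first.status != "live":
            raise ValueError(
                f"individual {ind}: first record must be a live capture"
            )
        histories.append(
            EncounterHistory(
                individual_id=ind,
                first_capture=first.occasion,
                codes=codes,
                colour=first.colour,
                stage_at_first=first.stage,
                site=first.site,
            )
        )
    return histories


def validate_history(h: EncounterHistory) -> list[str]:
    """Check the structural invariants of one history; return violations.

    Valid histories have code 7 strictly before first capture, a live code
    (1 or 4) at first capture, no encounters after a dead-recovery code, and
    no stage reversal among live codes.
    """
    v: list[str] = []
    codes = h.codes
    f = h.first_capture - 1
    if not 0 <= f < len(codes):
        return [f"{h.individual_id}: first_capture outside 1..{len(codes)}"]
    if np.any(codes[:f] != NOT_SEEN):
        v.append(f"{h.individual_id}: encounter before first capture")
    if codes[f] not in (1, 4):
        v.append(f"{h.individual_id}: code at first capture is {codes[f]}, not 1 or 4")
    dead_at = np.flatnonzero(np.isin(codes, list(DEAD_CODES)))
    if dead_at.size > 1:
        v.append(f"{h.individual_id}: more than one dead recovery")
    if dead_at.size >= 1:
        after = codes[dead_at[0] + 1 :]
        if np.any(after != NOT_SEEN):
            v.append(f"{h.individual_id}: encounter after death")
    live = codes[(codes == 1) | (codes == 4)]
    if np.any(np.diff(np.where(live == 4, 1, 0)) < 0):
        v.append(f"{h.individual_id}: stage reversal adult->juvenile")
    return v


def histories_to_matrix(histories: Sequence[EncounterHistory]) -> pd.DataFrame:
    """Serialize histories as a CSV-ready matrix (rows = individuals)."""
    T = len(histories[0].codes) if histories else 0
    mat = pd.DataFrame(
        [h.codes for h in histories],
        index=[h.individual_id for h in histories],
        columns=[f"occ{t}" for t in range(1, T + 1)],
    )
    mat.index.name = "individual_id"
    mat["first_capture"] = [h.first_capture for h in histories]
    mat["col"] = [h.colour for h in histories]
    mat["stage_at_first"] = [h.stage_at_first for h in histories]
    return mat


def matrix_to_histories(df: pd.DataFrame) -> list[EncounterHistory]:
    """Inverse of :func:`histories_to_matrix`."""
    occ_cols = [c for c in df.columns if c.startswith("occ")]
    out = []
    for ind, row in df.iterrows():
        out.append(
            EncounterHistory(
                individual_id=str(ind),
                first_capture=int(row["first_capture"]),
                codes=row[occ_cols].to_numpy(dtype=np.int64),
                colour=float(row["col"]),
                stage_at_first=str(row["stage_at_first"]),
            )
        )
    return out
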