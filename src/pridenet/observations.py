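"""Observation-log ingestion for animal social network analysis.

The raw material of a gambit-of-the-group study is a set of delimited text
logs collected during repeated observation sessions of a known group
(here, a lion pride monitored up to three times a day):

* ``scans.csv`` — group-composition scans: which individuals were within
  the grouping threshold (e.g. 50 m) of each other when the group settled;
* ``events.csv`` — directed social interaction bouts (play, head-rubbing
  greeting, social licking) with initiator, recipient and acceptance;
* ``roster.csv`` — the individuals, their sex, birth date / age class and
  membership window;
* ``kinship.csv`` — a square matrix of coefficients of genetic relatedness.

This module parses and validates those logs into an :class:`ObservationSet`
and provides the two observation-level transforms the analysis needs:
bout de-duplication (bouts of the same directed behaviour separated by less
than one minute are one bout) and roster subsetting (e.g. the dual
cub-inclusion / cub-exclusion analyses).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BEHAVIORS = ("play", "greeting", "social_licking")
ALL_SOCIAL = "all_social"

SEXES = ("female", "male")
AGE_CLASSES = ("adult", "cub")

#: default bout-independence gap: a new bout requires >= 1 minute without
#: the behaviour between the end of one bout and the start of the next
BOUT_GAP = dt.timedelta(seconds=60)


class ObservationError(ValueError):
    """Raised when an observation log violates a structural invariant."""


def _parse_date(value, *, what: str, line: int | None = None) -> dt.date | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        loc = f" (line {line})" if line is not None else ""
        raise ObservationError(f"malformed {what} {value!r}{loc}") from exc


def _parse_timestamp(value, *, line: int | None = None) -> dt.datetime:
    if isinstance(value, dt.datetime):
        return value
    try:
        return dt.datetime.fromisoformat(str(value).strip())
    except ValueError as exc:
        loc = f" (line {line})" if line is not None else ""
        raise ObservationError(f"malformed timestamp {value!r}{loc}") from exc


@dataclass(frozen=True)
class Individual:
    """One group member with the attributes used by attribute-matrix tests.

    Either ``birth_date`` or ``age_class`` must be given; when both are
    present they are kept as-is (the age class is authoritative for the
    cub/adult split, the birth date for age-similarity).
    """

    id: str
    sex: str
    birth_date: dt.date | None = None
    age_class: str | None = None
    present_from: dt.date | None = None
    present_to: dt.date | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ObservationError("individual id must be a non-empty string")
        if self.sex not in SEXES:
            raise ObservationError(f"{self.id}: sex must be one of {SEXES}, got {self.sex!r}")
        if self.birth_date is None and self.age_class is None:
            raise ObservationError(f"{self.id}: birth_date or age_class required")
        if self.age_class is not None and self.age_class not in AGE_CLASSES:
            raise ObservationError(
                f"{self.id}: age_class must be one of {AGE_CLASSES}, got {self.age_class!r}"
            )
        if (
            self.present_from is not None
            and self.present_to is not None
            and self.present_from > self.present_to
        ):
            raise ObservationError(f"{self.id}: present_from after present_to")

    def age_years(self, on: dt.date) -> float | None:
        """Age in (fractional) years on a reference date, if birth date known."""
        if self.birth_date is None:
            return None
        return (on - self.birth_date).days / 365.25

    def is_cub(self, on: dt.date | None = None, cub_age_years: float = 2.0) -> bool:
        if self.age_class is not None:
            return self.age_class == "cub"
        assert self.birth_date is not None
        on = on or dt.date.today()
        return (on - self.birth_date).days / 365.25 < cub_age_years


@dataclass(frozen=True)
class GroupScan:
    """One settled group composition: who was present, who was not."""

    session_id: str
    timestamp: dt.datetime
    present: frozenset[str]
    absent: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.present:
            raise ObservationError(f"scan {self.session_id}: empty present set")
        overlap = self.present & self.absent
        if overlap:
            raise ObservationError(
                f"scan {self.session_id}: ids both present and absent: {sorted(overlap)}"
            )


@dataclass(frozen=True)
class InteractionEvent:
    """One directed social interaction bout."""

    timestamp: dt.datetime
    initiator: str
    recipient: str
    behavior: str
    accepted: bool = True

    def __post_init__(self) -> None:
        if self.initiator == self.recipient:
            raise ObservationError(
                f"event at {self.timestamp}: initiator == recipient ({self.initiator})"
            )
        if self.behavior not in BEHAVIORS:
            raise ObservationError(
                f"event at {self.timestamp}: unknown behavior {self.behavior!r}; "
                f"expected one of {BEHAVIORS}"
            )

    @property
    def stream(self) -> tuple[str, str, str]:
        """The (initiator, recipient, behavior) stream this bout belongs to."""
        return (self.initiator, self.recipient, self.behavior)


@dataclass
class ObservationSet:
    """A validated bundle of roster, scans, events and kinship matrix."""

    roster: tuple[Individual, ...]
    scans: tuple[GroupScan, ...] = ()
    events: tuple[InteractionEvent, ...] = ()
    kinship: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.roster = tuple(self.roster)
        self.scans = tuple(self.scans)
        self.events = tuple(self.events)
        self.validate()

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(ind.id for ind in self.roster)

    @property
    def cub_ids(self) -> tuple[str, ...]:
        return tuple(ind.id for ind in self.roster if ind.is_cub())

    @property
    def adult_ids(self) -> tuple[str, ...]:
        return tuple(ind.id for ind in self.roster if not ind.is_cub())

    def individual(self, id_: str) -> Individual:
        for ind in self.roster:
            if ind.id == id_:
                return ind
        raise KeyError(id_)

    def validate(self) -> None:
        ids = [ind.id for ind in self.roster]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ObservationError(f"duplicate roster ids: {dupes}")
        known = set(ids)
        for scan in self.scans:
            stray = (scan.present | scan.absent) - known
            if stray:
                raise ObservationError(
                    f"scan {scan.session_id}: unknown ids {sorted(stray)}"
                )
        for ev in self.events:
            for who in (ev.initiator, ev.recipient):
                if who not in known:
                    raise ObservationError(f"event at {ev.timestamp}: unknown id {who!r}")
        if self.kinship is not None:
            k = self.kinship
            if list(k.index) != list(k.columns):
                raise ObservationError("kinship matrix index and columns disagree")
            stray = set(k.index) - known
            if stray:
                raise ObservationError(f"kinship matrix has unknown ids {sorted(stray)}")
            vals = k.to_numpy(dtype=float)
            if not np.allclose(vals, vals.T, equal_nan=True):
                raise ObservationError("kinship matrix not symmetric")
            off = vals[~np.eye(len(k), dtype=bool)]
            if np.nanmin(off) < 0 or np.nanmax(off) > 1:
                raise ObservationError("kinship coefficients must lie in [0, 1]")

    def kinship_full(self, fill: float = 0.0) -> pd.DataFrame:
        """Kinship matrix re-indexed on the full roster.

        Individuals missing from the kinship file (e.g. an introduced,
        unrelated male) get ``fill`` relatedness to everyone, with a log
        warning so the default never passes silently.
        """
        ids = list(self.ids)
        if self.kinship is None:
            logger.warning("no kinship matrix; assuming all individuals unrelated")
            out = pd.DataFrame(np.zeros((len(ids), len(ids))), index=ids, columns=ids)
        else:
            missing = [i for i in ids if i not in self.kinship.index]
            if missing:
                logger.warning(
                    "individuals %s absent from the kinship matrix; "
                    "defaulting their relatedness to everyone to %.3g",
                    missing,
                    fill,
                )
            out = self.kinship.reindex(index=ids, columns=ids).astype(float)
            out = out.fillna(fill)
        np.fill_diagonal(out.values, 1.0)
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _split_ids(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
        return frozenset()
    return frozenset(tok.strip() for tok in str(cell).split("|") if tok.strip())


def read_roster(path: str | Path) -> tuple[Individual, ...]:
    df = pd.read_csv(path, dtype=str)
    required = {"id", "sex"}
    if not required <= set(df.columns):
        raise ObservationError(f"{path}: roster needs columns {sorted(required)}")
    roster = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        roster.append(
            Individual(
                id=str(row["id"]).strip(),
                sex=str(row["sex"]).strip(),
                birth_date=_parse_date(row.get("birth_date"), what="birth_date", line=line),
                age_class=(str(row["age_class"]).strip() or None)
                if "age_class" in df.columns and pd.notna(row.get("age_class"))
                else None,
                present_from=_parse_date(row.get("present_from"), what="present_from", line=line),
                present_to=_parse_date(row.get("present_to"), what="present_to", line=line),
            )
        )
    return tuple(roster)


def read_scans(path: str | Path, roster_ids: Sequence[str]) -> tuple[GroupScan, ...]:
    df = pd.read_csv(path, dtype=str)
    known = set(roster_ids)
    scans = []
    for i, row in df.iterrows():
        line = i + 2
        present = _split_ids(row["present"])
        absent = _split_ids(row.get("absent"))
        stray = (present | absent) - known
        if stray:
            raise ObservationError(f"{path} line {line}: unknown ids {sorted(stray)}")
        if not absent:
            absent = frozenset(known - present)
        scans.append(
            GroupScan(
                session_id=str(row["session_id"]).strip(),
                timestamp=_parse_timestamp(row["timestamp"], line=line),
                present=present,
                absent=absent,
            )
        )
    return tuple(scans)


def read_events(path: str | Path, roster_ids: Sequence[str]) -> tuple[InteractionEvent, ...]:
    df = pd.read_csv(path, dtype=str)
    known = set(roster_ids)
    events = []
    for i, row in df.iterrows():
        line = i + 2
        initiator = str(row["initiator"]).strip()
        recipient = str(row["recipient"]).strip()
        for who in (initiator, recipient):
            if who not in known:
                raise ObservationError(f"{path} line {line}: unknown id {who!r}")
        if initiator == recipient:
            raise ObservationError(
                f"{path} line {line}: initiator == recipient ({initiator})"
            )
        accepted_raw = str(row.get("accepted", "true")).strip().lower()
        events.append(
            InteractionEvent(
                timestamp=_parse_timestamp(row["timestamp"], line=line),
                initiator=initiator,
                recipient=recipient,
                behavior=str(row["behavior"]).strip(),
                accepted=accepted_raw in ("1", "true", "yes", "t"),
            )
        )
    return tuple(events)


def read_kinship(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = [str(i).strip() for i in df.index]
    df.columns = [str(c).strip() for c in df.columns]
    return df.astype(float)


def read_observations(
    scan_path: str | Path,
    event_path: str | Path,
    roster_path: str | Path,
    kinship_path: str | Path | None = None,
) -> ObservationSet:
    """Parse the four delimited logs into a validated :class:`ObservationSet`."""
    roster = read_roster(roster_path)
    ids = [ind.id for ind in roster]
    scans = read_scans(scan_path, ids)
    events = read_events(event_path, ids)
    kinship = read_kinship(kinship_path) if kinship_path is not None else None
    return ObservationSet(roster=roster, scans=scans, events=events, kinship=kinship)


def write_observations(obs: ObservationSet, out_dir: str | Path) -> dict[str, Path]:
    """Write the four-log CSV dialect read by :func:`read_observations`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / f"{name}.csv" for name in ("roster", "scans", "events", "kinship")}

    pd.DataFrame(
        {
            "id": [i.id for i in obs.roster],
            "sex": [i.sex for i in obs.roster],
            "birth_date": [i.birth_date.isoformat() if i.birth_date else "" for i in obs.roster],
            "age_class": [i.age_class or "" for i in obs.roster],
            "present_from": [
                i.present_from.isoformat() if i.present_from else "" for i in obs.roster
            ],
            "present_to": [i.present_to.isoformat() if i.present_to else "" for i in obs.roster],
        }
    ).to_csv(paths["roster"], index=False)

    pd.DataFrame(
        {
            "session_id": [s.session_id for s in obs.scans],
            "timestamp": [s.timestamp.isoformat() for s in obs.scans],
            "present": ["|".join(sorted(s.present)) for s in obs.scans],
            "absent": ["|".join(sorted(s.absent)) for s in obs.scans],
        }
    ).to_csv(paths["scans"], index=False)

    pd.DataFrame(
        {
            "timestamp": [e.timestamp.isoformat() for e in obs.events],
            "initiator": [e.initiator for e in obs.events],
            "recipient": [e.recipient for e in obs.events],
            "behavior": [e.behavior for e in obs.events],
            "accepted": [str(e.accepted).lower() for e in obs.events],
        }
    ).to_csv(paths["events"], index=False)

    if obs.kinship is not None:
        obs.kinship.to_csv(paths["kinship"], index_label="id")
    else:
        del paths["kinship"]
    return paths


# ---------------------------------------------------------------------------
# observation-level transforms
# ---------------------------------------------------------------------------

def deduplicate_bouts(
    events: Iterable[InteractionEvent], gap: dt.timedelta = BOUT_GAP
) -> tuple[InteractionEvent, ...]:
    """Collapse repeat records of the same bout into one event per bout.

    Within each (initiator, recipient, behavior) stream, an event whose
    timestamp is less than ``gap`` after the previously *retained* event of
    that stream is considered a continuation of the same bout and dropped.
    Streams are independent: A->B play does not interrupt B->A play.

    Events are returned in global timestamp order (ties broken by stream),
    so the operation is idempotent.
    """
    if gap < dt.timedelta(0):
        raise ValueError(f"gap must be non-negative, got {gap}")
    ordered = sorted(events, key=lambda e: (e.timestamp, e.stream))
    last_kept: dict[tuple[str, str, str], dt.datetime] = {}
    kept: list[InteractionEvent] = []
    for ev in ordered:
        prev = last_kept.get(ev.stream)
        if prev is not None and (ev.timestamp - prev) < gap:
            continue
        kept.append(ev)
        last_kept[ev.stream] = ev.timestamp
    return tuple(kept)


def subset_observations(obs: ObservationSet, exclude: Iterable[str]) -> ObservationSet:
    """Drop a set of individuals and every datum that touches them.

    Scans have the excluded ids removed from both their present and absent
    sets (scans left with an empty present set are dropped); events with an
    excluded initiator or recipient are dropped; the kinship matrix is
    sub-indexed. Used for the adults-only reanalysis that removes cub data.
    """
    exclude = set(exclude)
    stray = exclude - set(obs.ids)
    if stray:
        raise ObservationError(f"cannot exclude unknown ids {sorted(stray)}")
    keep = [ind for ind in obs.roster if ind.id not in exclude]
    if not keep:
        raise ObservationError("excluding every individual leaves an empty network")
    if not exclude:
        return obs

    scans = []
    for s in obs.scans:
        present = s.present - exclude
        if not present:
            continue
        scans.append(replace(s, present=present, absent=s.absent - exclude))
    events = tuple(
        e for e in obs.events if e.initiator not in exclude and e.recipient not in exclude
    )
    kinship = obs.kinship
    if kinship is not None:
        keep_k = [i for i in kinship.index if i not in exclude]
        kinship = kinship.loc[keep_k, keep_k]
    return ObservationSet(roster=tuple(keep), scans=tuple(scans), events=events, kinship=kinship)


def data_point_accounting(obs: ObservationSet) -> dict[str, int]:
    """Per-type record counts, mirroring field-study data-point bookkeeping."""
    counts = {"composition": len(obs.scans)}
    for b in BEHAVIORS:
        counts[b] = sum(1 for e in obs.events if e.behavior == b)
    counts["total"] = counts["composition"] + sum(counts[b] for b in BEHAVIORS)
    return counts
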