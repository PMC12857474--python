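"""Daily residential timelines and long-term-institutionalization (LTI) spells.

Multi-payer stay records (nursing home, hospital, emergency department,
hospice) are resolved into one setting per calendar day — the residential
history — and scanned for LTI spells: runs of nursing-home (NH) days that may
be interrupted by any number of acute hospital or ED days and by community
gaps of at most ``max_community_gap`` days.  A spell qualifies as LTI when its
cumulative NH-day count exceeds ``day_threshold`` (default: more than 90
days).  Payer is deliberately ignored: VA-paid and non-VA NH days count alike.

Cohort-entry exclusions (baseline LTI or hospice, no face-to-face care,
baseline death, institutionalized on the last baseline day) are applied here
as well, since they are defined in terms of the same timeline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SETTINGS",
    "StayRecord",
    "SpellRule",
    "Timeline",
    "LTISpell",
    "build_timeline",
    "detect_lti_spells",
    "detect_spells_table",
    "lti_outcome_flags",
    "apply_cohort_exclusions",
]

#: Closed set of stay settings.  ``encounter`` records (outpatient
#: face-to-face contacts) carry no residential information and never
#: contribute to the timeline; they matter only for cohort exclusions.
SETTINGS = ("NH", "hospital", "ED", "hospice", "encounter")

# Resolution priority when stays overlap on a day: acute care supersedes
# custodial location (keeps "interrupted by acute hospital days" semantics).
_PRIORITY = {"community": 0, "hospice": 1, "NH": 2, "ED": 3, "hospital": 4}
_CODE_TO_SETTING = {0: "community", 1: "hospice", 2: "NH", 3: "ED", 4: "hospital"}
_NH_CODE = 2
_COMMUNITY_CODE = 0


@dataclass(frozen=True)
class StayRecord:
    """One interval of care in a single setting.

    ``start`` and ``end`` are inclusive calendar dates (a one-day stay has
    ``start == end``); internally they are converted to half-open day spans.
    """

    person_id: str
    setting: str
    start: date
    end: date
    payer: str = "VA"
    face_to_face: bool = False

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise ValueError(f"unknown setting {self.setting!r}; expected one of {SETTINGS}")
        if self.end < self.start:
            raise ValueError(
                f"stay for {self.person_id} has end {self.end} before start {self.start}"
            )


@dataclass(frozen=True)
class SpellRule:
    """Parameters of the LTI spell definition.

    day_threshold
        A spell qualifies when cumulative NH days exceed this (strictly).
    max_community_gap
        Longest run of community days that does not end a spell.
    interrupting_settings
        Settings whose days never break a spell and never count as NH days.
        Hospice is included by default: it neither breaks a spell nor
        contributes NH days.
    """

    day_threshold: int = 90
    max_community_gap: int = 7
    interrupting_settings: frozenset[str] = frozenset({"hospital", "ED", "hospice"})

    def __post_init__(self) -> None:
        if self.day_threshold < 1:
            raise ValueError("day_threshold must be >= 1")
        if self.max_community_gap < 0:
            raise ValueError("max_community_gap must be >= 0")


@dataclass
class Timeline:
    """Resolved daily location for one person over a contiguous date range."""

    person_id: str
    start: date
    codes: np.ndarray  # int8 setting codes, one per day from ``start``

    @property
    def end(self) -> date:
        """Last covered day (inclusive)."""
        return self.start + timedelta(days=len(self.codes) - 1)

    def setting_on(self, day: date) -> str:
        offset = (day - self.start).days
        if not 0 <= offset < len(self.codes):
            raise KeyError(f"{day} outside timeline [{self.start}, {self.end}]")
        return _CODE_TO_SETTING[int(self.codes[offset])]

    def to_series(self) -> pd.Series:
        idx = pd.date_range(self.start, periods=len(self.codes), freq="D")
        return pd.Series([_CODE_TO_SETTING[int(c)] for c in self.codes], index=idx)


@dataclass(frozen=True)
class LTISpell:
    person_id: str
    spell_start: date
    spell_end: date
    nh_days: int
    qualifying: bool


def _paint_codes(
    starts: np.ndarray, ends: np.ndarray, settings: Iterable[str], range_start: date, n_days: int
) -> np.ndarray:
    """Resolve overlapping stays onto a day grid by painting in priority order."""
    codes = np.zeros(n_days, dtype=np.int8)
    settings = list(settings)
    order = sorted(range(len(starts)), key=lambda i: _PRIORITY[settings[i]])
    for i in order:
        a = max(starts[i], 0)
        b = min(ends[i] + 1, n_days)  # inclusive end -> half-open
        if a < b:
            codes[a:b] = _PRIORITY[settings[i]]
    return codes


def build_timeline(
    stays: Sequence[StayRecord] | pd.DataFrame,
    range_start: date,
    range_end: date,
) -> Timeline:
    """Resolve one person's stays into a daily timeline over [range_start, range_end].

    Days covered by no stay resolve to community.  Overlaps resolve by
    priority hospital > ED > NH > hospice.  Encounter records are ignored.

    Raises ``ValueError`` (with the record index) for stays with end < start.
    """
    if range_end < range_start:
        raise ValueError("empty timeline range")
    n_days = (range_end - range_start).days + 1

    if isinstance(stays, pd.DataFrame):
        df = stays
        person = str(df["person_id"].iloc[0]) if len(df) else ""
        recs = list(
            zip(df["setting"], pd.to_datetime(df["start"]).dt.date, pd.to_datetime(df["end"]).dt.date)
        )
    else:
        person = stays[0].person_id if stays else ""
        recs = [(s.setting, s.start, s.end) for s in stays]

    keep, starts, ends, setts = [], [], [], []
    for i, (setting, s, e) in enumerate(recs):
        if e < s:
            raise ValueError(f"stay record {i} has end {e} before start {s}")
        if setting == "encounter":
            continue
        starts.append((s - range_start).days)
        ends.append((e - range_start).days)
        setts.append(setting)

    codes = _paint_codes(np.asarray(starts, dtype=int), np.asarray(ends, dtype=int), setts, range_start, n_days)
    return Timeline(person_id=person, start=range_start, codes=codes)


def detect_lti_spells(
    timeline: Timeline,
    rule: SpellRule = SpellRule(),
    death_date: date | None = None,
) -> list[LTISpell]:
    """Scan a resolved timeline for maximal NH spells under ``rule``.

    A spell opens on an NH day, accumulates NH days, survives interrupting
    settings for any duration and community runs of at most
    ``max_community_gap`` days, and closes when a longer community run occurs
    or the timeline (or the person's life) ends.  ``spell_end`` is the last NH
    day of the spell.  A spell already past the threshold when death ends it
    remains qualifying.
    """
    codes = timeline.codes
    if death_date is not None:
        n = (death_date - timeline.start).days + 1
        if n <= 0:
            return []
        codes = codes[:n]

    interrupting = {_PRIORITY[s] for s in rule.interrupting_settings}
    spells: list[LTISpell] = []
    in_spell = False
    spell_start_off = last_nh_off = -1
    nh_days = 0
    community_run = 0

    def close() -> None:
        nonlocal in_spell, nh_days
        spells.append(
            LTISpell(
                person_id=timeline.person_id,
                spell_start=timeline.start + timedelta(days=spell_start_off),
                spell_end=timeline.start + timedelta(days=last_nh_off),
                nh_days=nh_days,
                qualifying=nh_days > rule.day_threshold,
            )
        )
        in_spell = False
        nh_days = 0

    for off, c in enumerate(codes):
        c = int(c)
        if c == _NH_CODE:
            if not in_spell:
                in_spell = True
                spell_start_off = off
            nh_days += 1
            last_nh_off = off
            community_run = 0
        elif c in interrupting:
            community_run = 0
        else:  # community (or a setting configured to behave like it)
            if in_spell:
                community_run += 1
                if community_run > rule.max_community_gap:
                    close()
                    community_run = 0
    if in_spell:
        close()
    return spells


def detect_spells_table(
    stays: pd.DataFrame,
    rule: SpellRule = SpellRule(),
    range_start: date | None = None,
    range_end: date | None = None,
    deaths: Mapping[str, date] | pd.Series | None = None,
) -> pd.DataFrame:
    """Detect spells for every person in a stays table.

    Only persons with at least one NH stay can have spells, so everyone else
    is skipped.  Returns a DataFrame with columns person_id, spell_start,
    spell_end, nh_days, qualifying (empty but well-formed when no spells).
    """
    cols = ["person_id", "spell_start", "spell_end", "nh_days", "qualifying"]
    if len(stays) == 0:
        return pd.DataFrame(columns=cols)
    stays = stays.copy()
    stays["start"] = pd.to_datetime(stays["start"]).dt.date
    stays["end"] = pd.to_datetime(stays["end"]).dt.date

    if deaths is not None and not isinstance(deaths, Mapping):
        deaths = {k: v for k, v in deaths.dropna().items()}
    deaths = deaths or {}

    nh_persons = set(stays.loc[stays["setting"] == "NH", "person_id"])
    rows = []
    for pid, grp in stays[stays["person_id"].isin(nh_persons)].groupby("person_id", sort=True):
        lo = range_start or min(grp["start"])
        hi = range_end or max(grp["end"])
        grp = grp[(grp["end"] >= lo) & (grp["start"] <= hi)]
        if not len(grp):
            continue
        tl = build_timeline(grp, lo, hi)
        dd = deaths.get(pid)
        if isinstance(dd, pd.Timestamp):
            dd = dd.date()
        for sp in detect_lti_spells(tl, rule, death_date=dd):
            rows.append((pid, sp.spell_start, sp.spell_end, sp.nh_days, sp.qualifying))
    return pd.DataFrame(rows, columns=cols)


def _qualifying_candidates(
    stays: pd.DataFrame, rule: SpellRule, lo: date, hi: date
) -> pd.DataFrame:
    """Restrict a stays table to persons who could possibly hold a qualifying
    spell: cumulative NH stay-days inside [lo, hi] must exceed the day
    threshold (a necessary condition, since spell NH days never exceed the
    person's total NH days in range).  Purely a performance filter."""
    if len(stays) == 0:
        return stays
    s = pd.to_datetime(stays["start"])
    e = pd.to_datetime(stays["end"])
    lo_ts, hi_ts = pd.Timestamp(lo), pd.Timestamp(hi)
    nh = stays["setting"] == "NH"
    days = (e.clip(upper=hi_ts) - s.clip(lower=lo_ts)).dt.days + 1
    days = days.where(nh & (e >= lo_ts) & (s <= hi_ts), 0)
    totals = days.groupby(stays["person_id"]).sum()
    keep = set(totals[totals > rule.day_threshold].index)
    return stays[stays["person_id"].isin(keep)]


def lti_outcome_flags(
    stays_outcome: pd.DataFrame,
    person_ids: Iterable[str],
    window_start: date,
    window_end: date,
    horizon: date | None = None,
    rule: SpellRule = SpellRule(),
    deaths: Mapping[str, date] | pd.Series | None = None,
) -> pd.Series:
    """Two-year LTI outcome per person.

    A person is LTI-positive when a qualifying spell *starts* inside
    [window_start, window_end]; NH-day accumulation may continue past the
    window end up to ``horizon`` (default: 180 days past the window end).
    """
    if horizon is None:
        horizon = window_end + timedelta(days=180)
    spells = detect_spells_table(
        _qualifying_candidates(stays_outcome, rule, window_start, horizon),
        rule, range_start=window_start, range_end=horizon, deaths=deaths,
    )
    pos: set[str] = set()
    if len(spells):
        ok = spells["qualifying"] & (spells["spell_start"] >= window_start) & (
            spells["spell_start"] <= window_end
        )
        pos = set(spells.loc[ok, "person_id"])
    ids = list(person_ids)
    return pd.Series([pid in pos for pid in ids], index=ids, dtype=bool, name="lti")


def apply_cohort_exclusions(
    persons: pd.DataFrame,
    stays_baseline: pd.DataFrame,
    deaths: pd.Series,
    index_date: date,
    rule: SpellRule = SpellRule(),
) -> tuple[pd.Index, dict[str, int]]:
    """Apply the four cohort-entry exclusions, in order, counting each person once.

    (a) qualifying LTI spell or any hospice stay during the baseline year;
    (b) no face-to-face encounter during the baseline year;
    (c) death during the baseline year;
    (d) resolved setting hospital or NH on the last baseline day.

    The baseline year is the 365 days ending the day before ``index_date``.
    Returns (eligible person index, ordered exclusion tally).
    """
    for name, tbl in (("persons", persons), ("stays_baseline", stays_baseline)):
        if tbl is None:
            raise ValueError(f"data-contract error: required table {name!r} missing")
    if deaths is None:
        raise ValueError("data-contract error: required table 'deaths' missing")

    baseline_start = index_date - timedelta(days=365)
    last_day = index_date - timedelta(days=1)

    st = stays_baseline.copy()
    st["start"] = pd.to_datetime(st["start"])
    st["end"] = pd.to_datetime(st["end"])
    lo_ts, hi_ts = pd.Timestamp(baseline_start), pd.Timestamp(last_day)
    in_year = st[(st["end"] >= lo_ts) & (st["start"] <= hi_ts)]

    death_map = pd.to_datetime(deaths.dropna()).dt.date
    died_baseline = set(death_map[(death_map >= baseline_start) & (death_map <= last_day)].index)

    spells = detect_spells_table(
        _qualifying_candidates(in_year, rule, baseline_start, last_day),
        rule, range_start=baseline_start, range_end=last_day,
        deaths=death_map,
    )
    lti_base = set(spells.loc[spells["qualifying"], "person_id"]) if len(spells) else set()
    hospice = set(in_year.loc[in_year["setting"] == "hospice", "person_id"])

    f2f = in_year[(in_year["setting"] == "encounter") & in_year["face_to_face"].astype(bool)]
    has_f2f = set(f2f["person_id"])

    inst_last = set(
        in_year.loc[
            in_year["setting"].isin(["hospital", "NH"])
            & (in_year["start"] <= hi_ts)
            & (in_year["end"] >= hi_ts),
            "person_id",
        ]
    )
    # Overlap priority on the last day does not matter here: either resolved
    # setting (hospital or NH) triggers the same exclusion.

    tally = {"baseline_lti_or_hospice": 0, "no_face_to_face": 0, "baseline_death": 0,
             "institutionalized_last_day": 0}
    eligible = []
    for pid in persons["person_id"]:
        if pid in lti_base or pid in hospice:
            tally["baseline_lti_or_hospice"] += 1
        elif pid not in has_f2f:
            tally["no_face_to_face"] += 1
        elif pid in died_baseline:
            tally["baseline_death"] += 1
        elif pid in inst_last:
            tally["institutionalized_last_day"] += 1
        else:
            eligible.append(pid)
    return pd.Index(eligible, name="person_id"), tally
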