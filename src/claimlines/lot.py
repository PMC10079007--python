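"""Rule-based derivation of regimens and lines of therapy from drug events.

The algorithm reconstructs treatment episodes from dated drug
administrations the way treatment-pattern studies of administrative claims
do, using three rules:

* **Establishment** — a drug starts a regimen only if it is administered
  again within its grace period (single stray administrations never found a
  regimen).
* **Addition** — another drug administered within 28 days of the regimen's
  first administration, and itself persisting under its own grace period,
  joins the regimen instead of starting a new one.
* **Switch** — a drug outside the current regimen that is administered and
  persists while the regimen is still active starts a new regimen on its
  first administration date.

A line of therapy (LoT) ends at the earliest of: the day before a
switch-initiated regimen; the last administration once every member drug
has been silent longer than its grace period plus a 14-day slack
(discontinuation); the death date; or the end of the data.  Lines are
numbered consecutively from 1; duration is the closed interval
``end - start + 1`` days.

Steroids (dexamethasone, prednisolone) join regimens but, by default,
neither anchor a line nor trigger a switch: otherwise ubiquitous steroid
prescriptions would fragment lines.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

from . import codes
from ._util import POST_SCT_WINDOW_DAYS, as_date
from .config import GraceConfig

logger = logging.getLogger(__name__)

__all__ = [
    "RegimenEpisode",
    "TherapyLine",
    "establish_regimen",
    "detect_switch",
    "segment_lines",
    "derive_lines",
    "canonical_name",
    "classify_post_sct",
]

END_REASONS = ("switch", "discontinuation-gap", "death", "data-end")


@dataclass(frozen=True)
class RegimenEpisode:
    """A contiguous period on one drug set.

    ``end`` is the last administration of any member drug within the
    episode; ``alive_until`` is the last day the episode could still have
    been continued (every member's last administration plus its grace
    period and the discontinuation slack, maximised over members).
    """

    drugs: frozenset[str]
    start: dt.date
    end: dt.date
    admin_dates: dict[str, tuple[dt.date, ...]] = field(compare=False)
    alive_until: dt.date = field(compare=False, default=None)

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("episode end precedes start")


@dataclass(frozen=True)
class TherapyLine:
    line_number: int
    regimen: str
    drugs: frozenset[str]
    start: dt.date
    end: dt.date
    end_reason: str

    @property
    def duration_days(self) -> int:
        return (self.end - self.start).days + 1


def _normalize_events(drug_events, grace: GraceConfig) -> dict[str, list[dt.date]]:
    """Build per-drug sorted unique administration dates.

    Accepts an iterable of ``(date, drug)`` pairs or a DataFrame with
    ``date`` and ``drug`` columns.  Events for drugs outside the dictionary
    are dropped with a warning, as required for auditability.
    """
    if hasattr(drug_events, "itertuples"):  # DataFrame
        pairs = [(as_date(r.date), str(r.drug)) for r in drug_events.itertuples()]
    else:
        pairs = [(as_date(d), str(g)) for d, g in drug_events]
    dictionary = codes.load_drug_dictionary()
    admins: dict[str, set[dt.date]] = {}
    unknown: set[str] = set()
    for date, drug in pairs:
        if drug not in dictionary and drug not in grace.grace_days:
            unknown.add(drug)
            continue
        admins.setdefault(drug, set()).add(date)
    for drug in sorted(unknown):
        msg = f"ignoring administrations of unknown drug {drug!r}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=3)
    return {d: sorted(v) for d, v in admins.items()}


def _next_admin(dates: list[dt.date], after: dt.date) -> dt.date | None:
    i = bisect_right(dates, after)
    return dates[i] if i < len(dates) else None


def _persists(dates: list[dt.date], t: dt.date, grace_days: int) -> bool:
    """True if the drug is administered again within its grace period after t."""
    nxt = _next_admin(dates, t)
    return nxt is not None and (nxt - t).days <= grace_days


def _first_admin_at_or_after(dates: list[dt.date], t: dt.date) -> dt.date | None:
    i = bisect_left(dates, t)
    return dates[i] if i < len(dates) else None


def _build_episode(admins: dict[str, list[dt.date]], start: dt.date,
                   grace: GraceConfig, cut_at: dt.date | None = None) -> RegimenEpisode:
    """Assemble the episode anchored at ``start``.

    Membership comes from the addition window; coverage is then swept as a
    union over members: the episode stays alive at time t as long as some
    member's last administration is within its grace + slack of t, so a
    member may pause and resume while another member keeps the line alive.
    ``cut_at`` truncates the sweep strictly before a switch date.
    """
    window_end = start + dt.timedelta(days=grace.addition_window_days)
    first_admin: dict[str, dt.date] = {}
    for drug, dates in admins.items():
        t0 = _first_admin_at_or_after(dates, start)
        if t0 is None or t0 > window_end:
            continue
        if cut_at is not None and t0 >= cut_at:
            continue
        if _persists(dates, t0, grace.grace(drug)):
            first_admin[drug] = t0
    if not first_admin:
        raise ValueError("no persisting drug at episode start")
    slack = grace.discontinuation_slack_days
    events = sorted(
        (t, d)
        for d, t0 in first_admin.items()
        for t in admins[d]
        if t >= t0 and (cut_at is None or t < cut_at)
    )
    chains: dict[str, list[dt.date]] = {d: [] for d in first_admin}
    alive: dt.date | None = None
    last: dt.date | None = None
    for t, d in events:
        if alive is not None and t > alive:
            break  # every member silent beyond grace + slack: line lapsed
        thr = t + dt.timedelta(days=grace.grace(d) + slack)
        chains[d].append(t)
        last = t if last is None else max(last, t)
        alive = thr if alive is None else max(alive, thr)
    members = {d: tuple(v) for d, v in chains.items() if v}
    return RegimenEpisode(
        drugs=frozenset(members),
        start=start,
        end=last,
        admin_dates=members,
        alive_until=alive,
    )


def _find_anchor(admins: dict[str, list[dt.date]], at_or_after: dt.date | None,
                 grace: GraceConfig) -> dt.date | None:
    """Earliest administration of a non-steroid drug that persists."""
    best = None
    for drug, dates in admins.items():
        if grace.is_steroid(drug):
            continue
        g = grace.grace(drug)
        i = 0 if at_or_after is None else bisect_left(dates, at_or_after)
        for t in dates[i:]:
            if best is not None and t >= best:
                break
            if _persists(dates, t, g):
                best = t
                break
    return best


def _find_switch(admins: dict[str, list[dt.date]], episode: RegimenEpisode,
                 grace: GraceConfig) -> dt.date | None:
    """Earliest persisting administration of a non-member, non-steroid drug
    strictly after the episode start and no later than its alive-until day."""
    best = None
    for drug, dates in admins.items():
        if drug in episode.drugs or grace.is_steroid(drug):
            continue
        g = grace.grace(drug)
        i = bisect_right(dates, episode.start)
        for t in dates[i:]:
            if t > episode.alive_until:
                break
            if best is not None and t >= best:
                break
            if _persists(dates, t, g):
                best = t
                break
    return best


def establish_regimen(drug_events, grace: GraceConfig | None = None) -> list[RegimenEpisode]:
    """Derive the date-ordered regimen episodes for one patient.

    Episodes are separated either by a switch (the next episode starts
    while the previous is alive) or by a discontinuation gap.
    """
    grace = grace or GraceConfig()
    admins = _normalize_events(drug_events, grace)
    episodes: list[RegimenEpisode] = []
    cursor: dt.date | None = None
    while True:
        start = _find_anchor(admins, cursor, grace)
        if start is None:
            break
        ep = _build_episode(admins, start, grace)
        switch_at = _find_switch(admins, ep, grace)
        if switch_at is not None:
            # membership and coverage stop at the switch date
            ep = _build_episode(admins, start, grace, cut_at=switch_at)
            episodes.append(ep)
            cursor = switch_at
        else:
            episodes.append(ep)
            cursor = ep.end + dt.timedelta(days=1)
    return episodes


def detect_switch(current: RegimenEpisode, drug_events,
                  grace: GraceConfig | None = None):
    """Return ``(switch_date, new_episode)`` or ``(None, None)``.

    A switch is a drug outside the current regimen, newly administered
    while the regimen is alive and persisting under its own grace period.
    """
    grace = grace or GraceConfig()
    admins = _normalize_events(drug_events, grace)
    switch_at = _find_switch(admins, current, grace)
    if switch_at is None:
        return None, None
    return switch_at, _build_episode(admins, switch_at, grace)


def canonical_name(drug_set, name_map: dict[frozenset, str] | None = None) -> str:
    """Canonical regimen name (Vd, VRd, Rd, ...) for a drug set.

    Unmapped sets render deterministically as the '+'-joined sorted drug
    abbreviations, steroids last.
    """
    drugs = frozenset(drug_set)
    if not drugs:
        raise ValueError("empty drug set has no regimen name")
    name_map = name_map if name_map is not None else codes.load_regimen_map()
    if drugs in name_map:
        return name_map[drugs]
    dictionary = codes.load_drug_dictionary()

    def key(d):
        info = dictionary.get(d, {"steroid": False, "abbrev": d[:3].title()})
        return (info["steroid"], info["abbrev"].lower())

    abbrevs = [dictionary.get(d, {"abbrev": d[:3].title()})["abbrev"]
               for d in sorted(drugs, key=key)]
    return "+".join(abbrevs)


def segment_lines(episodes: list[RegimenEpisode], death_date=None, data_end=None,
                  grace: GraceConfig | None = None,
                  name_map: dict[frozenset, str] | None = None) -> list[TherapyLine]:
    """Number the episodes into lines of therapy and classify end reasons.

    End-reason logic per line: a following episode starting while this one
    is alive ends it by *switch* (the day before); otherwise the line ends
    at its last administration by *discontinuation-gap*.  The final line
    ends by *death* or *data-end* when that boundary falls inside the alive
    window, else by discontinuation.
    """
    grace = grace or GraceConfig()
    death = as_date(death_date) if death_date is not None else None
    d_end = as_date(data_end) if data_end is not None else None
    lines: list[TherapyLine] = []
    for k, ep in enumerate(episodes):
        nxt = episodes[k + 1] if k + 1 < len(episodes) else None
        if nxt is not None and nxt.start <= ep.end:
            raise ValueError("episodes overlap after switch resolution")
        end, reason = ep.end, "discontinuation-gap"
        if nxt is not None and nxt.start <= ep.alive_until:
            end, reason = nxt.start - dt.timedelta(days=1), "switch"
        # death inside the line or its alive window truncates it; claims
        # stop at death, so in practice this is always the final episode
        if death is not None and ep.start <= death:
            bound = end if reason == "switch" else ep.alive_until
            if death <= bound:
                end, reason = death, "death"
        if reason == "discontinuation-gap" and nxt is None \
                and d_end is not None and d_end <= ep.alive_until:
            end, reason = d_end, "data-end"
        lines.append(
            TherapyLine(
                line_number=k + 1,
                regimen=canonical_name(ep.drugs, name_map),
                drugs=ep.drugs,
                start=ep.start,
                end=end,
                end_reason=reason,
            )
        )
        if reason == "death":
            break
    return lines


def derive_lines(drug_events, death_date=None, data_end=None,
                 grace: GraceConfig | None = None,
                 name_map: dict[frozenset, str] | None = None) -> list[TherapyLine]:
    """End-to-end per-patient derivation: episodes then numbered lines."""
    grace = grace or GraceConfig()
    episodes = establish_regimen(drug_events, grace)
    return segment_lines(episodes, death_date, data_end, grace, name_map)


def classify_post_sct(lines: list[TherapyLine], sct_date) -> list[str]:
    """Label each line relative to transplant: ``induction`` (initiated
    before the SCT date), ``post-SCT`` (initiated within 4 months = 122
    days after SCT), or ``other``."""
    sct = as_date(sct_date)
    window_end = sct + dt.timedelta(days=POST_SCT_WINDOW_DAYS)
    labels = []
    for line in lines:
        if line.start < sct:
            labels.append("induction")
        elif line.start <= window_end:
            labels.append("post-SCT")
        else:
            labels.append("other")
    return labels
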