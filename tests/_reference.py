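"""Independent day-stepping reference implementation of the line-derivation
rules, used only as a test oracle.

Unlike the production engine (event-driven sweep with bisection), this
walks the calendar one day at a time, maintaining per-member last-seen
administrations, and applies the establishment / addition / switch /
discontinuation rules literally.  Intentionally slow and simple.
"""

from __future__ import annotations

import datetime as dt

from claimlines.config import GraceConfig


def _persists(dates, t, g):
    return any(t < u <= t + dt.timedelta(days=g) for u in dates)


def reference_lines(drug_events, grace: GraceConfig):
    """Return [(drug frozenset, start, end, reason)] with reason in
    {'switch', 'discontinuation-gap'} (no death / data-end handling)."""
    admins: dict[str, list] = {}
    for d, drug in drug_events:
        admins.setdefault(drug, set()).add(d)
    admins = {k: sorted(v) for k, v in admins.items()}
    if not admins:
        return []
    horizon = max(max(v) for v in admins.values()) + dt.timedelta(days=200)
    out = []
    cursor = min(min(v) for v in admins.values())
    while True:
        # anchor: earliest persisting administration of a non-steroid drug
        anchors = [
            t for drug, dates in admins.items()
            if not grace.is_steroid(drug)
            for t in dates
            if t >= cursor and _persists(dates, t, grace.grace(drug))
        ]
        if not anchors:
            break
        start = min(anchors)
        window_end = start + dt.timedelta(days=grace.addition_window_days)
        members = {}
        for drug, dates in admins.items():
            future = [t for t in dates if t >= start]
            if future and future[0] <= window_end \
                    and _persists(dates, future[0], grace.grace(drug)):
                members[drug] = None  # last admin seen so far
        end = None
        reason = None
        switch_at = None
        t = start
        while t <= horizon:
            alive = t == start or any(
                last is not None
                and (t - last).days <= grace.grace(d) + grace.discontinuation_slack_days
                for d, last in members.items()
            )
            if not alive:
                reason = "discontinuation-gap"
                end = max(l for l in members.values() if l is not None)
                break
            # a persisting non-member, non-steroid administration switches
            for drug, dates in admins.items():
                if drug in members or grace.is_steroid(drug):
                    continue
                if t > start and t in dates and _persists(dates, t, grace.grace(drug)):
                    switch_at = t
                    break
            if switch_at is not None:
                reason = "switch"
                end = switch_at - dt.timedelta(days=1)
                break
            for drug in members:
                if t in admins[drug]:
                    members[drug] = t
            t += dt.timedelta(days=1)
        if reason is None:  # ran past horizon: treat as discontinued
            reason = "discontinuation-gap"
            end = max(l for l in members.values() if l is not None)
        out.append((frozenset(members), start, end, reason))
        cursor = switch_at if switch_at is not None else end + dt.timedelta(days=1)
    return out
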