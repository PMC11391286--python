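"""Collective departure coding: grouping rule, cohesion and emptying time.

A *group departure* is two or more birds leaving the roost together:
events in the same compass direction, each within 10 s of the group's
first event, with consecutive events less than 2 s apart; clusters are
separated from other same-direction clusters by at least 2 s.  The
largest group's share of the roost measures departure cohesion, and the
span from first to last departure is the roost-emptying time.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "COMPASS_SECTORS",
    "DepartureEvent",
    "GroupDeparture",
    "DepartureSummary",
    "segment_group_departures",
    "departure_summary",
    "smallest_group_percent",
]

#: Discrete 8-sector compass directions used by video coding.
COMPASS_SECTORS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")


@dataclass(frozen=True)
class DepartureEvent:
    """One video-coded departure: `n_birds` leaving at `time_s` in a
    compass `direction`."""

    time_s: float
    n_birds: int
    direction: str

    def __post_init__(self) -> None:
        if self.n_birds < 1:
            raise ValueError("n_birds must be >= 1")
        if not (self.time_s == self.time_s and abs(self.time_s) != float("inf")):
            raise ValueError("time_s must be finite")


@dataclass(frozen=True)
class GroupDeparture:
    """A cluster of same-direction events totalling >= 2 birds."""

    member_events: tuple[DepartureEvent, ...]
    total_birds: int
    start_s: float
    end_s: float
    direction: str

    def __post_init__(self) -> None:
        if self.total_birds < 2:
            raise ValueError("a group departure needs >= 2 birds")


@dataclass(frozen=True)
class DepartureSummary:
    largest_group_prop: float
    n_groups: int
    time_to_empty_s: float
    roost_size: int


def _cluster_direction(
    events: list[DepartureEvent], window_s: float, gap_s: float
) -> list[list[DepartureEvent]]:
    """Greedy left-to-right clustering of one direction's sorted events:
    a cluster opens at the first unassigned event and absorbs the next
    event while the inter-event gap is < gap_s AND the event lies
    <= window_s after the cluster's first event."""
    clusters: list[list[DepartureEvent]] = []
    current: list[DepartureEvent] = []
    for ev in events:
        if not current:
            current = [ev]
            continue
        if (ev.time_s - current[-1].time_s < gap_s
                and ev.time_s - current[0].time_s <= window_s):
            current.append(ev)
        else:
            clusters.append(current)
            current = [ev]
    if current:
        clusters.append(current)
    return clusters


def segment_group_departures(
    events: list[DepartureEvent],
    window_s: float = 10.0,
    gap_s: float = 2.0,
    return_clusters: bool = False,
):
    """Partition departure events into clusters; return the groups.

    Every event lands in exactly one cluster (per direction, events in
    different compass sectors never merge).  Clusters totalling >= 2
    birds become :class:`GroupDeparture`; single-bird clusters are
    singletons and are not returned unless `return_clusters` is set, in
    which case ``(groups, clusters)`` is returned with the complete
    time-ordered partition.
    """
    ordered = sorted(events, key=lambda e: e.time_s)
    by_dir: dict[str, list[DepartureEvent]] = {}
    for ev in ordered:
        by_dir.setdefault(ev.direction, []).append(ev)
    clusters: list[list[DepartureEvent]] = []
    for evs in by_dir.values():
        clusters.extend(_cluster_direction(evs, window_s, gap_s))
    clusters.sort(key=lambda c: c[0].time_s)
    groups = [
        GroupDeparture(
            member_events=tuple(c),
            total_birds=sum(e.n_birds for e in c),
            start_s=c[0].time_s,
            end_s=c[-1].time_s,
            direction=c[0].direction,
        )
        for c in clusters
        if sum(e.n_birds for e in c) >= 2
    ]
    if return_clusters:
        return groups, clusters
    return groups


def departure_summary(
    groups: list[GroupDeparture],
    events: list[DepartureEvent],
    roost_size: int,
) -> DepartureSummary:
    """Cohesion and emptying time for one departure morning.

    `largest_group_prop` is the biggest group's share of the roost (0
    if no cluster reached two birds); `time_to_empty_s` spans the first
    to the last departure event, singletons included.
    """
    if roost_size <= 0:
        raise ValueError("roost_size must be positive")
    departing = sum(e.n_birds for e in events)
    if departing > roost_size:
        raise ValueError(f"{departing} departing birds exceed roost_size {roost_size}")
    largest = max((g.total_birds for g in groups), default=0)
    times = [e.time_s for e in events]
    span = (max(times) - min(times)) if times else 0.0
    return DepartureSummary(
        largest_group_prop=largest / roost_size,
        n_groups=len(groups),
        time_to_empty_s=span,
        roost_size=roost_size,
    )


def smallest_group_percent(roost_size: int) -> float:
    """Percentage of the roost represented by the smallest possible
    group (two birds), rounded to 2 decimal places."""
    if roost_size < 2:
        raise ValueError("roost_size must be >= 2")
    return round(100.0 * 2.0 / roost_size, 2)
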