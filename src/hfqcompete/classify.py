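"""Per-molecule competition observables and mode classification.

From paired resident (Cy3) and competitor (Cy5) interval lists this module
builds a piecewise-constant occupancy timeline and derives the quantities of
a competition experiment:

* ``t_bind`` -- time from competitor addition (flow) to the first competitor
  that colocalises with the resident;
* ``t_bind_diss`` -- the same, restricted to the binding episode after which
  the resident departs;
* ``t_diss`` -- displacement time: from the start of a colocalisation
  episode to resident departure, provided competitors remain bound;
* ``t_co`` -- duration of each colocalisation episode, with the outcome
  (resident left, competitor left, or censored at the movie end).

Modes: *passive* (resident dissociates before any competitor ever
colocalises), *active* (resident departs after a competitor binds, i.e. a
``t_diss`` exists), *stable coexistence* (any ``t_co`` exceeding the
threshold, 20 s by default), otherwise *none*.  Active and stable
coexistence can co-occur on one molecule; passive and active cannot.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .segment import BoundInterval

__all__ = [
    "OccupancyTimeline",
    "Episode",
    "Dwell",
    "CompetitionRecord",
    "pair_intervals",
    "episodes",
    "extract_tbind",
    "extract_tdiss",
    "extract_tco",
    "classify_molecule",
    "count_competitors_before_displacement",
    "analyze_molecule",
    "resident_survival_curve",
    "percent_remaining_endpoint",
    "photobleaching_qc",
    "records_to_frame",
    "dwells_to_frame",
]

STABLE_THRESHOLD_S = 20.0  # see fitkinetics.access_time_bound for the rationale

Dwell = namedtuple("Dwell", ["value", "censored", "outcome"])


@dataclass
class OccupancyTimeline:
    """Piecewise-constant (resident_bound, competitor_count) over a movie."""

    edges: np.ndarray  # segment boundaries, edges[0]=0, edges[-1]=movie_end
    resident: np.ndarray  # bool per segment
    competitors: np.ndarray  # int per segment

    @property
    def movie_end(self) -> float:
        return float(self.edges[-1])

    def segments(self):
        for i in range(self.resident.size):
            yield float(self.edges[i]), float(self.edges[i + 1]), bool(self.resident[i]), int(self.competitors[i])

    def resident_departure(self) -> float | None:
        """Resident dissociation time, or None if bound through the movie end."""
        on = np.flatnonzero(self.resident)
        if on.size == 0:
            return 0.0
        last = on[-1]
        if last == self.resident.size - 1:
            return None
        return float(self.edges[last + 1])


Episode = namedtuple("Episode", ["start", "end", "outcome", "competitor_remaining", "n_arrivals"])


def _check_sorted_nonoverlapping(intervals: list[BoundInterval], channel: str) -> None:
    prev_end = -np.inf
    for iv in sorted(intervals, key=lambda i: i.t_start):
        if iv.t_start < prev_end:
            raise DataError(f"overlapping {channel} intervals on one molecule")
        prev_end = iv.t_end


def pair_intervals(
    cy3: list[BoundInterval],
    cy5: list[BoundInterval],
    movie_end: float,
) -> OccupancyTimeline:
    """Overlay resident and competitor intervals into an occupancy timeline.

    Competitor count uses an interval's stepwise ``segments`` when present
    (stoichiometry > 1 during sub-segments), otherwise its constant
    ``stoichiometry``.
    """
    _check_sorted_nonoverlapping(cy3, "cy3")
    _check_sorted_nonoverlapping(cy5, "cy5")
    cuts = {0.0, float(movie_end)}
    pieces5 = []
    for iv in cy5:
        segs = iv.segments or [(iv.t_start, iv.t_end, iv.stoichiometry)]
        for s0, s1, c in segs:
            pieces5.append((s0, s1, c))
            cuts.update((s0, s1))
    for iv in cy3:
        cuts.update((iv.t_start, iv.t_end))
    edges = np.array(sorted(c for c in cuts if 0.0 <= c <= movie_end))
    mids = 0.5 * (edges[:-1] + edges[1:])
    resident = np.zeros(mids.size, dtype=bool)
    for iv in cy3:
        resident |= (mids >= iv.t_start) & (mids < iv.t_end)
    competitors = np.zeros(mids.size, dtype=int)
    for s0, s1, c in pieces5:
        competitors += np.where((mids >= s0) & (mids < s1), c, 0)
    return OccupancyTimeline(edges=edges, resident=resident, competitors=competitors)


def episodes(timeline: OccupancyTimeline) -> list[Episode]:
    """Maximal colocalisation episodes (resident bound and >= 1 competitor).

    ``n_arrivals`` counts competitor binding steps during the episode: the
    initial occupancy plus every later increment of the competitor count
    (stoichiometry steps included).
    """
    state = timeline.resident & (timeline.competitors >= 1)
    out: list[Episode] = []
    i = 0
    n = state.size
    while i < n:
        if not state[i]:
            i += 1
            continue
        j = i
        arrivals = int(timeline.competitors[i])
        while j + 1 < n and state[j + 1]:
            delta = int(timeline.competitors[j + 1]) - int(timeline.competitors[j])
            if delta > 0:
                arrivals += delta
            j += 1
        start, end = float(timeline.edges[i]), float(timeline.edges[j + 1])
        if j == n - 1:
            outcome, remaining = "censored", bool(timeline.competitors[j] >= 1)
        elif not timeline.resident[j + 1]:
            outcome = "resident_left"
            remaining = bool(timeline.competitors[j + 1] >= 1)
        else:
            outcome, remaining = "competitor_left", False
        out.append(Episode(start, end, outcome, remaining, arrivals))
        i = j + 1
    return out


def extract_tbind(timeline: OccupancyTimeline, t_flow: float):
    """(t_bind, t_bind_diss, censored_at) from an occupancy timeline.

    ``t_bind`` is the first colocalisation episode start minus ``t_flow``;
    ``t_bind_diss`` is the same for the episode that ends in displacement.
    When no competitor ever colocalises both are ``None`` and ``censored_at``
    carries the right-censoring time (movie end minus ``t_flow``).
    """
    if not 0 <= t_flow <= timeline.movie_end:
        raise DataError("t_flow outside the movie")
    eps = episodes(timeline)
    if not eps:
        return None, None, timeline.movie_end - t_flow
    t_bind = eps[0].start - t_flow
    t_bind_diss = None
    for ep in eps:
        if ep.outcome == "resident_left" and ep.competitor_remaining:
            t_bind_diss = ep.start - t_flow
            break
    return t_bind, t_bind_diss, None


def extract_tdiss(timeline: OccupancyTimeline) -> list[Dwell]:
    """Displacement times: episode start to resident departure with
    competitors remaining bound afterwards."""
    return [
        Dwell(ep.end - ep.start, False, "resident_left")
        for ep in episodes(timeline)
        if ep.outcome == "resident_left" and ep.competitor_remaining
    ]


def extract_tco(timeline: OccupancyTimeline) -> list[Dwell]:
    """Coexistence dwells: one per colocalisation episode, with outcome."""
    return [Dwell(ep.end - ep.start, ep.outcome == "censored", ep.outcome) for ep in episodes(timeline)]


@dataclass
class CompetitionRecord:
    """Derived per-molecule observables of one competition movie."""

    molecule_id: str
    t_flow: float
    movie_end: float
    t_bind: float | None = None
    t_bind_diss: float | None = None
    t_bind_censored_at: float | None = None
    t_diss_list: list = field(default_factory=list)
    t_co_list: list = field(default_factory=list)
    n_competitors_at_displacement: int | None = None
    max_concurrent_srnas: int = 1
    t_resident_end: float | None = None  # None = bound through movie end
    resident_ever_present: bool = True
    modes: frozenset = frozenset({"none"})


def classify_molecule(record: CompetitionRecord, stable_threshold: float = STABLE_THRESHOLD_S) -> frozenset:
    """Mode flags for one molecule: subset of {passive, active,
    stable_coexistence} or {none}.

    Passive requires that the resident departed with no competitor having
    colocalised at any earlier time; active requires an observed
    displacement; stable coexistence requires any coexistence episode longer
    than ``stable_threshold`` (censored episodes already exceeding it count).
    """
    modes = set()
    if record.t_diss_list:
        modes.add("active")
    if any(d.value > stable_threshold for d in record.t_co_list):
        modes.add("stable_coexistence")
    departed = record.t_resident_end is not None and record.resident_ever_present
    if departed and not record.t_co_list and not record.t_diss_list:
        modes.add("passive")
    return frozenset(modes) if modes else frozenset({"none"})


def count_competitors_before_displacement(timeline: OccupancyTimeline) -> int | None:
    """Competitor binding steps during the episode that displaced the
    resident (stoichiometry increments counted); None without displacement."""
    for ep in episodes(timeline):
        if ep.outcome == "resident_left" and ep.competitor_remaining:
            return ep.n_arrivals
    return None


def analyze_molecule(
    molecule_id: str,
    cy3: list[BoundInterval],
    cy5: list[BoundInterval],
    t_flow: float,
    movie_end: float,
    stable_threshold: float = STABLE_THRESHOLD_S,
) -> CompetitionRecord:
    """Full per-molecule analysis: timeline, dwells, counts and mode flags."""
    timeline = pair_intervals(cy3, cy5, movie_end)
    t_bind, t_bind_diss, censored_at = extract_tbind(timeline, t_flow)
    record = CompetitionRecord(
        molecule_id=molecule_id,
        t_flow=t_flow,
        movie_end=movie_end,
        t_bind=t_bind,
        t_bind_diss=t_bind_diss,
        t_bind_censored_at=censored_at,
        t_diss_list=extract_tdiss(timeline),
        t_co_list=extract_tco(timeline),
        n_competitors_at_displacement=count_competitors_before_displacement(timeline),
        max_concurrent_srnas=int(np.max(timeline.resident.astype(int) + timeline.competitors, initial=0)),
        t_resident_end=timeline.resident_departure(),
        resident_ever_present=bool(timeline.resident.any()),
    )
    record.modes = classify_molecule(record, stable_threshold)
    return record


# ---------------------------------------------------------------------------
# population-level summaries


def resident_survival_curve(records, movie_end: float | None = None, bin_s: float = 1.0):
    """Percent of molecules whose resident is still bound, sampled every
    ``bin_s`` seconds, relative to the count at the movie start.

    Returns ``(times, percent)`` arrays.
    """
    records = list(records)
    if not records:
        raise DataError("no molecules for a survival curve")
    if movie_end is None:
        movie_end = max(r.movie_end for r in records)
    times = np.arange(0.0, movie_end + 0.5 * bin_s, bin_s)
    ends = np.array(
        [np.inf if (r.t_resident_end is None and r.resident_ever_present) else (r.t_resident_end or 0.0) for r in records]
    )
    n0 = sum(r.resident_ever_present for r in records)
    if n0 == 0:
        raise DataError("no residents present at movie start")
    bound = (ends[None, :] > times[:, None]).sum(axis=1)
    return times, 100.0 * bound / n0


def percent_remaining_endpoint(before_counts, after_counts):
    """Endpoint competition statistic across fields of view.

    Per-FOV percent remaining = 100 x after / mean(before); returns the mean
    and (ddof=1) standard deviation over the after-FOVs.
    """
    before = np.asarray(before_counts, dtype=float)
    after = np.asarray(after_counts, dtype=float)
    if before.size < 2 or after.size < 2:
        raise DataError("need at least 2 fields of view")
    ref = before.mean()
    if ref <= 0:
        raise DataError("zero molecules before competition")
    pct = 100.0 * after / ref
    return float(pct.mean()), float(pct.std(ddof=1))


def photobleaching_qc(end_of_movie_count: float, fov_mean_count: float, max_percent: float = 15.0):
    """Photobleaching check: end-of-movie count vs fresh-FOV mean count.

    Returns ``(percent_difference, passed)``; movies failing (>= 15%
    difference by default) are excluded from kinetic analysis.
    """
    if fov_mean_count <= 0:
        raise DataError("FOV mean count must be positive")
    pct = 100.0 * abs(end_of_movie_count - fov_mean_count) / fov_mean_count
    return float(pct), bool(pct < max_percent)


# ---------------------------------------------------------------------------
# I/O


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "molecule_id": r.molecule_id,
                "t_flow_s": r.t_flow,
                "t_bind_s": r.t_bind,
                "t_bind_diss_s": r.t_bind_diss,
                "t_bind_censored_at_s": r.t_bind_censored_at,
                "n_t_diss": len(r.t_diss_list),
                "n_t_co": len(r.t_co_list),
                "n_competitors_at_displacement": r.n_competitors_at_displacement,
                "max_concurrent_srnas": r.max_concurrent_srnas,
                "t_resident_end_s": r.t_resident_end,
                "passive": "passive" in r.modes,
                "active": "active" in r.modes,
                "stable_coexistence": "stable_coexistence" in r.modes,
                "none": "none" in r.modes,
            }
        )
    return pd.DataFrame(rows)


def dwells_to_frame(records) -> pd.DataFrame:
    """One row per dwell observation (t_bind / t_diss / t_co) across molecules."""
    rows = []
    for r in records:
        if r.t_bind is not None:
            rows.append((r.molecule_id, "t_bind", r.t_bind, False, ""))
        elif r.t_bind_censored_at is not None:
            rows.append((r.molecule_id, "t_bind", r.t_bind_censored_at, True, ""))
        if r.t_bind_diss is not None:
            rows.append((r.molecule_id, "t_bind_diss", r.t_bind_diss, False, ""))
        for d in r.t_diss_list:
            rows.append((r.molecule_id, "t_diss", d.value, d.censored, d.outcome))
        for d in r.t_co_list:
            rows.append((r.molecule_id, "t_co", d.value, d.censored, d.outcome))
    return pd.DataFrame(rows, columns=["molecule_id", "type", "value_s", "censored", "outcome"])
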