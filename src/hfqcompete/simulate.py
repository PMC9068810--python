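"""Stochastic simulation of sRNA competition on immobilised Hfq.

The model is a phenomenological kinetic scheme for one surface-tethered Hfq
hexamer carrying a Cy3-labelled resident sRNA.  After competitor sRNAs are
flowed into the chamber, Cy5-labelled competitors arrive as a Poisson
process (pseudo-first-order rate ``k_arrival`` = k_on x concentration).
Each arrival is either

* a transient *probe* -- a short, non-productive visit with an exponential
  dwell (``tau_probe``); several probes typically precede a stable event;
* a *displacing* binder -- the resident departs after a delay drawn from a
  1-3 component exponential mixture (``diss_mixture``); delays shorter than
  the 0.2 s per-channel sampling produce the apparent zero-lifetime
  displacement class seen in alternating-excitation data;
* a *coexisting* binder -- resident and competitor share the hexamer for a
  joint dwell drawn from ``co_mixture``, after which either the resident or
  the competitor leaves (``p_resident_leaves_first``).

Independently, a resident with no competitor bound can dissociate
spontaneously at rate ``k_passive`` (passive competition, rare).  Up to
``max_competitors`` competitors can be bound at once, so stable complexes
with 2-4 sRNAs (resident + competitors) arise naturally.

Event times are exact (Gillespie-style); discretisation to camera frames
happens only when rendering traces or movies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError
from .traces import IntensityTrace, alternating_excitation

__all__ = [
    "CompetitionParams",
    "AcquisitionParams",
    "Event",
    "EventLog",
    "simulate_molecule",
    "simulate_experiment",
    "exact_intervals",
    "ground_truth_intervals",
    "render_traces",
    "render_movie",
    "grid_positions",
    "PRESETS",
]

RESIDENT = "resident"


def _validate_mixture(mixture, name: str) -> list[tuple[float, float]]:
    mix = [(float(a), float(tau)) for a, tau in mixture]
    if not mix:
        raise ConfigurationError(f"{name} must have at least one component")
    fracs = np.array([a for a, _ in mix])
    taus = np.array([tau for _, tau in mix])
    if np.any(fracs < 0) or np.any(taus < 0):
        raise ConfigurationError(f"{name}: fractions and lifetimes must be >= 0")
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ConfigurationError(f"{name}: fractions must sum to 1 (got {fracs.sum():.12g})")
    return mix


@dataclass
class CompetitionParams:
    """Kinetic parameters of one resident/competitor pair.

    Rates are per second, lifetimes in seconds, probabilities in [0, 1].
    ``diss_mixture`` and ``co_mixture`` are lists of ``(fraction, tau_s)``.
    """

    k_arrival: float = 0.05
    p_probe: float = 0.3
    tau_probe: float = 1.5
    p_displace: float = 0.5
    diss_mixture: list = field(default_factory=lambda: [(1.0, 10.0)])
    co_mixture: list = field(default_factory=lambda: [(1.0, 30.0)])
    p_resident_leaves_first: float = 0.5
    k_passive: float = 0.0
    max_competitors: int = 3
    k_bleach: float = 0.0
    probes_can_displace: bool = False

    def validate(self) -> None:
        for name in ("k_arrival", "tau_probe", "k_passive", "k_bleach"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("p_probe", "p_displace", "p_resident_leaves_first"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.max_competitors < 1:
            raise ConfigurationError("max_competitors must be >= 1")
        self.diss_mixture = _validate_mixture(self.diss_mixture, "diss_mixture")
        self.co_mixture = _validate_mixture(self.co_mixture, "co_mixture")


@dataclass
class AcquisitionParams:
    """Camera / excitation / rendering geometry.

    The camera field is split into two half-fields of ``field_size``
    (height, width) pixels each: Cy3 emission on the left, Cy5 on the right.
    ``channel_transform`` is a 3x3 affine matrix mapping Cy3 full-frame
    (x, y) coordinates to the matching Cy5 position; by default a pure
    translation by one half-field width.
    """

    frame_interval: float = 0.1
    n_frames: int = 3000
    flow_frame: int = 100
    unit_intensity: float = 300.0
    background_cy3: float = 100.0
    background_pre: float = 100.0
    background_post: float = 160.0
    noise_sd: float = 30.0
    field_size: tuple = (128, 128)
    psf_sigma: float = 1.0
    channel_transform: np.ndarray | None = None
    n_both_start: int = 10
    n_both_end: int = 10

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ConfigurationError("frame_interval must be positive")
        if not 0 <= self.flow_frame < self.n_frames:
            raise ConfigurationError("flow_frame must lie within the movie")
        if self.background_post < self.background_pre:
            raise ConfigurationError("background_post must be >= background_pre")
        if self.channel_transform is None:
            t = np.eye(3)
            t[0, 2] = self.field_size[1]
            self.channel_transform = t
        else:
            self.channel_transform = np.asarray(self.channel_transform, dtype=float)

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval

    @property
    def flow_time(self) -> float:
        return self.flow_frame * self.frame_interval

    def excitation_masks(self) -> dict[str, np.ndarray]:
        return alternating_excitation(self.n_frames, self.n_both_start, self.n_both_end)


@dataclass(frozen=True)
class Event:
    time: float
    species: str  # "resident" or "competitor_<i>"
    action: str  # "bind" | "dissociate" | "bleach"


@dataclass
class EventLog:
    """Ground-truth timeline of binding events at one Hfq molecule."""

    molecule_id: str
    events: list
    duration: float
    flow_time: float
    resident_present_at_start: bool = True

    def species_intervals(self) -> dict[str, tuple[float, float | None]]:
        """Bound interval per fluorophore: species -> (t_bind, t_end or None).

        ``t_end`` is the dissociation or bleach time; ``None`` means bound
        through the end of the movie (right-censored).
        """
        out: dict[str, tuple[float, float | None]] = {}
        if self.resident_present_at_start:
            out[RESIDENT] = (0.0, None)
        for ev in self.events:
            if ev.action == "bind":
                out[ev.species] = (ev.time, None)
            else:
                start, _ = out[ev.species]
                out[ev.species] = (start, ev.time)
        return out


def _sample_mixture(mixture, rng: np.random.Generator) -> float:
    fracs = [a for a, _ in mixture]
    j = rng.choice(len(mixture), p=fracs) if len(mixture) > 1 else 0
    tau = mixture[j][1]
    return rng.exponential(tau) if tau > 0 else 0.0


def simulate_molecule(
    params: CompetitionParams,
    duration: float,
    flow_time: float,
    rng_seed,
) -> EventLog:
    """Simulate one immobilised Hfq-resident complex for ``duration`` seconds.

    The resident is bound at t=0; competitor arrivals start at ``flow_time``.
    Returns an exact-time :class:`EventLog`.  ``rng_seed`` may be an int or a
    :class:`numpy.random.Generator`.
    """
    params.validate()
    if duration <= 0:
        raise ConfigurationError("duration must be positive")
    if not 0 <= flow_time < duration:
        raise ConfigurationError("flow_time must lie within [0, duration)")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)

    events: list[Event] = []
    t = 0.0
    resident_bound = True
    comp_departures: dict[str, float] = {}  # species -> scheduled departure (inf = stays)
    resident_scheduled: list[float] = []  # displacement / coexistence-end departures
    next_cid = 0

    while True:
        # Memoryless clocks are redrawn after every event; fixed delays persist.
        t_arr = math.inf
        if params.k_arrival > 0:
            base = max(t, flow_time)
            t_arr = base + rng.exponential(1.0 / params.k_arrival)
        t_passive = math.inf
        if params.k_passive > 0 and resident_bound and not comp_departures:
            t_passive = t + rng.exponential(1.0 / params.k_passive)
        t_comp = min(comp_departures.values(), default=math.inf)
        t_res = min(resident_scheduled, default=math.inf) if resident_bound else math.inf

        t_next = min(t_arr, t_passive, t_comp, t_res)
        if t_next >= duration:
            break
        t = t_next

        if t_next == t_res:
            events.append(Event(t, RESIDENT, "dissociate"))
            resident_bound = False
            resident_scheduled.clear()
        elif t_next == t_comp:
            species = min(comp_departures, key=comp_departures.get)
            events.append(Event(t, species, "dissociate"))
            del comp_departures[species]
        elif t_next == t_passive:
            events.append(Event(t, RESIDENT, "dissociate"))
            resident_bound = False
            resident_scheduled.clear()
        else:  # arrival; discard (thinning) if all competitor slots are taken
            if len(comp_departures) < params.max_competitors:
                species = f"competitor_{next_cid}"
                next_cid += 1
                events.append(Event(t, species, "bind"))
                if rng.random() < params.p_probe:
                    dep = t + (rng.exponential(params.tau_probe) if params.tau_probe > 0 else 0.0)
                    if params.probes_can_displace and resident_bound and rng.random() < params.p_displace:
                        resident_scheduled.append(t + _sample_mixture(params.diss_mixture, rng))
                        comp_departures[species] = dep
                    else:
                        comp_departures[species] = dep
                elif resident_bound and rng.random() < params.p_displace:
                    resident_scheduled.append(t + _sample_mixture(params.diss_mixture, rng))
                    comp_departures[species] = math.inf  # displacer stays (censored)
                else:
                    dwell = _sample_mixture(params.co_mixture, rng)
                    if resident_bound and rng.random() < params.p_resident_leaves_first:
                        resident_scheduled.append(t + dwell)
                        comp_departures[species] = math.inf
                    else:
                        comp_departures[species] = t + dwell

    return EventLog(
        molecule_id="mol",
        events=events,
        duration=duration,
        flow_time=flow_time,
        resident_present_at_start=True,
    )


def simulate_experiment(
    params: CompetitionParams,
    acq: AcquisitionParams,
    n_molecules: int,
    rng_seed,
) -> list[EventLog]:
    """Simulate ``n_molecules`` independent Hfq molecules under one condition."""
    ss = rng_seed if isinstance(rng_seed, np.random.SeedSequence) else np.random.SeedSequence(rng_seed)
    logs = []
    for i, child in enumerate(ss.spawn(n_molecules)):
        log = simulate_molecule(params, acq.duration, acq.flow_time, np.random.default_rng(child))
        log.molecule_id = f"mol{i:04d}"
        logs.append(log)
    return logs


# ---------------------------------------------------------------------------
# ground-truth interval export


def exact_intervals(log: EventLog) -> dict[str, list[tuple[float, float, bool]]]:
    """Continuous-time bound intervals per channel.

    Returns ``{"cy3": [...], "cy5": [...]}`` where each entry is
    ``(t_start, t_end, right_censored)``; the resident is the only Cy3
    fluorophore, every competitor is Cy5.
    """
    out = {"cy3": [], "cy5": []}
    for species, (a, b) in log.species_intervals().items():
        censored = b is None
        end = log.duration if censored else b
        channel = "cy3" if species == RESIDENT else "cy5"
        if end > a:
            out[channel].append((a, end, censored))
    for v in out.values():
        v.sort()
    return out


def occupancy_counts(log: EventLog, acq: AcquisitionParams) -> dict[str, np.ndarray]:
    """Number of bound fluorophores per channel at each frame midpoint."""
    mid = (np.arange(acq.n_frames) + 0.5) * acq.frame_interval
    counts = {"cy3": np.zeros(acq.n_frames, dtype=int), "cy5": np.zeros(acq.n_frames, dtype=int)}
    for channel, ivs in exact_intervals(log).items():
        for a, b, _ in ivs:
            counts[channel] += (mid >= a) & (mid < b)
    return counts


def ground_truth_intervals(
    log: EventLog,
    acq: AcquisitionParams,
    min_frames: int = 2,
    gap_frames: int = 1,
):
    """Ground-truth bound intervals discretised to each channel's timebase.

    This is what an ideal (noise-free) segmentation of the rendered traces
    should recover: occupancy is sampled at frame midpoints on the excited
    frames of each channel, runs shorter than ``min_frames`` are dropped and
    gaps up to ``gap_frames`` are bridged, mirroring the segmentation rules.

    Returns ``{"cy3": [BoundInterval...], "cy5": [...]}``.
    """
    from .segment import intervals_from_counts

    masks = acq.excitation_masks()
    counts = occupancy_counts(log, acq)
    out = {}
    for channel in ("cy3", "cy5"):
        idx = np.flatnonzero(masks[channel])
        out[channel] = intervals_from_counts(
            counts[channel][idx],
            frame_indices=idx,
            frame_interval=acq.frame_interval,
            n_frames=acq.n_frames,
            channel=channel,
            min_frames=min_frames,
            gap_frames=gap_frames,
        )
    return out


# ---------------------------------------------------------------------------
# rendering


def _bleach_counts(
    log: EventLog,
    acq: AcquisitionParams,
    masks: dict[str, np.ndarray],
    k_bleach: float,
    rng: np.random.Generator,
):
    """Per-frame unbleached-fluorophore counts and the bleach events drawn.

    Bleaching consumes a fluorophore only on frames where its channel is
    excited (exposure-proportional), with per-exposure probability
    ``1 - exp(-k_bleach * frame_interval)``.  A dye still emits during the
    frame on which it bleaches and is dark afterwards.
    """
    mid = (np.arange(acq.n_frames) + 0.5) * acq.frame_interval
    counts = {"cy3": np.zeros(acq.n_frames, dtype=int), "cy5": np.zeros(acq.n_frames, dtype=int)}
    bleach_events: list[Event] = []
    p = 1.0 - math.exp(-k_bleach * acq.frame_interval) if k_bleach > 0 else 0.0
    for species, (a, b) in log.species_intervals().items():
        channel = "cy3" if species == RESIDENT else "cy5"
        end = log.duration if b is None else b
        bound = (mid >= a) & (mid < end)
        if p > 0:
            exposed = np.flatnonzero(bound & masks[channel])
            if exposed.size:
                g = rng.geometric(p)  # exposures until bleaching, >= 1
                if g <= exposed.size:
                    f_bleach = exposed[g - 1]
                    bound &= np.arange(acq.n_frames) <= f_bleach
                    bleach_events.append(Event((f_bleach + 1) * acq.frame_interval, species, "bleach"))
        counts[channel] += bound
    return counts, bleach_events


@dataclass
class TracePair:
    """Rendered two-channel trace of one molecule plus any bleach events."""

    cy3: IntensityTrace
    cy5: IntensityTrace
    bleach_events: list


def render_traces(log: EventLog, acq: AcquisitionParams, rng_seed, k_bleach: float | None = None) -> TracePair:
    """Render an event log into a noisy two-channel intensity trace pair.

    Per-frame intensity = background + unit_intensity x (unbleached bound
    fluorophores) x excitation mask + Gaussian noise.  The Cy5 background
    steps from ``background_pre`` to ``background_post`` at the flow frame
    (competitor addition); backgrounds are recorded on every frame.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    masks = acq.excitation_masks()
    kb = 0.0 if k_bleach is None else k_bleach
    counts, bleach_events = _bleach_counts(log, acq, masks, kb, rng)

    frames = np.arange(acq.n_frames)
    bg5 = np.where(frames >= acq.flow_frame, acq.background_post, acq.background_pre)
    cy3 = acq.background_cy3 + acq.unit_intensity * counts["cy3"] * masks["cy3"]
    cy5 = bg5 + acq.unit_intensity * counts["cy5"] * masks["cy5"]
    if acq.noise_sd > 0:
        cy3 = cy3 + rng.normal(0.0, acq.noise_sd, acq.n_frames)
        cy5 = cy5 + rng.normal(0.0, acq.noise_sd, acq.n_frames)
    mk = lambda ch, v: IntensityTrace(log.molecule_id, ch, v, masks[ch], acq.frame_interval)
    return TracePair(mk("cy3", cy3), mk("cy5", cy5), bleach_events)


def grid_positions(n: int, field_size: tuple, margin: int = 8, spacing: float | None = None) -> np.ndarray:
    """Well-separated (x, y) spot positions on a regular jittered-free grid."""
    h, w = field_size
    if spacing is None:
        side = math.ceil(math.sqrt(n))
        spacing = min((w - 2 * margin) / max(side - 1, 1), (h - 2 * margin) / max(side - 1, 1))
    side = math.ceil(math.sqrt(n))
    xs, ys = [], []
    for i in range(n):
        r, c = divmod(i, side)
        xs.append(margin + c * spacing)
        ys.append(margin + r * spacing)
    pos = np.column_stack([xs, ys]).astype(float)
    if pos[:, 0].max() > w - margin or pos[:, 1].max() > h - margin:
        raise ConfigurationError("too many molecules for the field size")
    return pos


def _apply_affine(transform: np.ndarray, xy: np.ndarray) -> np.ndarray:
    xy = np.atleast_2d(xy)
    hom = np.column_stack([xy, np.ones(len(xy))])
    mapped = hom @ transform.T
    return mapped[:, :2] / mapped[:, 2:3]


def render_movie(
    logs: list[EventLog],
    acq: AcquisitionParams,
    positions: np.ndarray,
    rng_seed,
    k_bleach: float | None = None,
) -> np.ndarray:
    """Render event logs into a TIRF-like image stack (uint16, multi-page).

    The frame is two side-by-side half-fields of ``acq.field_size``: Cy3
    emission on the left, Cy5 on the right at the affine-mapped position.
    Each bound, unbleached fluorophore contributes a 2D Gaussian spot of
    total integrated intensity ``unit_intensity`` (sigma ``psf_sigma``), so
    AOI-integrated movie intensities match :func:`render_traces` up to PSF
    truncation by the integration box.
    """
    h, w = acq.field_size
    positions = np.asarray(positions, dtype=float)
    if len(positions) != len(logs):
        raise ConfigurationError("one position per event log required")
    if positions.size and (
        positions[:, 0].min() < 0 or positions[:, 0].max() >= w or positions[:, 1].min() < 0 or positions[:, 1].max() >= h
    ):
        raise ConfigurationError("spot positions must lie inside the Cy3 half-field")

    ss = rng_seed if isinstance(rng_seed, np.random.SeedSequence) else np.random.SeedSequence(rng_seed)
    noise_child, *mol_children = ss.spawn(len(logs) + 1)
    masks = acq.excitation_masks()
    kb = 0.0 if k_bleach is None else k_bleach

    frames = np.arange(acq.n_frames)
    bg5 = np.where(frames >= acq.flow_frame, acq.background_post, acq.background_pre)
    stack = np.empty((acq.n_frames, h, 2 * w), dtype=np.float32)
    stack[:, :, :w] = acq.background_cy3
    stack[:, :, w:] = bg5[:, None, None]

    cy5_pos = _apply_affine(acq.channel_transform, positions) if len(positions) else positions
    sigma = acq.psf_sigma
    half = max(1, int(math.ceil(4 * sigma)))
    offs = np.arange(-half, half + 1)
    amp = acq.unit_intensity / (2.0 * math.pi * sigma**2)

    for log, pos3, pos5, child in zip(logs, positions, cy5_pos, mol_children):
        rng = np.random.default_rng(child)
        counts, _ = _bleach_counts(log, acq, masks, kb, rng)
        for channel, (x, y) in (("cy3", pos3), ("cy5", pos5)):
            n_vis = counts[channel] * masks[channel]
            on = np.flatnonzero(n_vis)
            if on.size == 0:
                continue
            cx, cy = int(round(x)), int(round(y))
            gx = np.exp(-((cx + offs - x) ** 2) / (2 * sigma**2))
            gy = np.exp(-((cy + offs - y) ** 2) / (2 * sigma**2))
            stamp = amp * np.outer(gy, gx)
            ys = slice(max(cy - half, 0), min(cy + half + 1, h))
            xs_lo, xs_hi = cx - half, cx + half + 1
            sy = slice(ys.start - (cy - half), stamp.shape[0] - ((cy + half + 1) - ys.stop))
            xs = slice(max(xs_lo, 0), min(xs_hi, 2 * w))
            sx = slice(xs.start - xs_lo, stamp.shape[1] - (xs_hi - xs.stop))
            sub = stamp[sy, sx]
            stack[np.ix_(on, range(ys.start, ys.stop), range(xs.start, xs.stop))] += (
                n_vis[on, None, None] * sub[None, :, :]
            )

    if acq.noise_sd > 0:
        rng = np.random.default_rng(noise_child)
        stack += rng.normal(0.0, acq.noise_sd, stack.shape).astype(np.float32)
    np.clip(stack, 0, 65535, out=stack)
    return np.rint(stack).astype(np.uint16)


# ---------------------------------------------------------------------------
# regime presets
#
# Named after the four resident/competitor pairs studied (H = Hfq, DA = DsrA,
# a class I sRNA; CX = ChiX, a class II sRNA).  The lifetimes and fractions
# are regime-faithful fixtures chosen inside the experimentally reported
# ranges for each pair -- not claims of the exact fitted values.

PRESETS: dict[str, CompetitionParams] = {
    # Class II challenging class I: fast binding, efficient displacement.
    "H-DA_vs_CX": CompetitionParams(
        k_arrival=0.10,
        p_probe=0.35,
        tau_probe=1.5,
        p_displace=0.75,
        diss_mixture=[(0.40, 0.4), (0.40, 8.0), (0.20, 90.0)],
        co_mixture=[(0.60, 8.0), (0.40, 40.0)],
        p_resident_leaves_first=0.45,
        k_passive=3.0e-4,
        max_competitors=3,
    ),
    # Class I challenging class II: slow binding, little displacement,
    # frequent stable coexistence on opposite faces.
    "H-CX_vs_DA": CompetitionParams(
        k_arrival=0.02,
        p_probe=0.35,
        tau_probe=1.5,
        p_displace=0.12,
        diss_mixture=[(0.45, 0.4), (0.40, 10.0), (0.15, 100.0)],
        co_mixture=[(0.58, 8.0), (0.42, 40.0)],
        p_resident_leaves_first=0.40,
        k_passive=2.0e-4,
        max_competitors=3,
    ),
    # Homotypic class I: intermediate exchange, coexistence rare but long.
    "H-DA_vs_DA": CompetitionParams(
        k_arrival=0.014,
        p_probe=0.35,
        tau_probe=1.5,
        p_displace=0.55,
        diss_mixture=[(0.45, 0.15), (0.37, 5.0), (0.18, 60.0)],
        co_mixture=[(0.84, 6.0), (0.16, 70.0)],
        p_resident_leaves_first=0.50,
        k_passive=3.0e-4,
        max_competitors=3,
    ),
    # Homotypic class II: intermediate exchange, same-face clash.
    "H-CX_vs_CX": CompetitionParams(
        k_arrival=0.066,
        p_probe=0.35,
        tau_probe=1.5,
        p_displace=0.55,
        diss_mixture=[(0.42, 0.15), (0.40, 9.0), (0.18, 110.0)],
        co_mixture=[(0.83, 6.0), (0.17, 70.0)],
        p_resident_leaves_first=0.50,
        k_passive=3.0e-4,
        max_competitors=3,
    ),
}
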