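"""Simulator: kinetic correctness, event bookkeeping, rendering fidelity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfqcompete import (
    AcquisitionParams,
    CompetitionParams,
    ConfigurationError,
    render_movie,
    render_traces,
    simulate_experiment,
    simulate_molecule,
)
from hfqcompete.simulate import Event, EventLog, grid_positions


def test_no_process_limit_keeps_resident_bound(idle_params):
    log = simulate_molecule(idle_params, duration=300.0, flow_time=10.0, rng_seed=0)
    assert log.events == []
    assert log.species_intervals() == {"resident": (0.0, None)}


def test_passive_survival_matches_exponential():
    """With only spontaneous dissociation the survival at t is exp(-k t)."""
    params = CompetitionParams(k_arrival=0.0, k_passive=0.01)
    n = 4000
    ss = np.random.SeedSequence(101)
    still_bound = 0
    for child in ss.spawn(n):
        log = simulate_molecule(params, 300.0, 10.0, np.random.default_rng(child))
        still_bound += not log.events
    p = math.exp(-0.01 * 300.0)
    sd = math.sqrt(p * (1 - p) / n)
    assert abs(still_bound / n - p) < 3 * sd


def test_displacement_delay_mean_matches_mixture():
    """Displacement delays are drawn from the configured exponential."""
    params = CompetitionParams(
        k_arrival=0.5,
        p_probe=0.0,
        p_displace=1.0,
        diss_mixture=[(1.0, 13.0)],
        k_passive=0.0,
        max_competitors=1,
    )
    delays = []
    for child in np.random.SeedSequence(7).spawn(2500):
        log = simulate_molecule(params, 160.0, 0.0, np.random.default_rng(child))
        bind = next((e.time for e in log.events if e.action == "bind"), None)
        gone = next((e.time for e in log.events if e.species == "resident"), None)
        if bind is not None and gone is not None:
            delays.append(gone - bind)
    mean = np.mean(delays)
    assert abs(mean - 13.0) < 3 * 13.0 / math.sqrt(len(delays))


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    seed=st.integers(0, 2**31 - 1),
    k_arrival=st.floats(0.0, 0.5),
    p_probe=st.floats(0.0, 1.0),
    p_displace=st.floats(0.0, 1.0),
    k_passive=st.floats(0.0, 0.02),
)
def test_event_conservation_and_capacity(seed, k_arrival, p_probe, p_displace, k_passive):
    """Binds minus ends equals molecules bound at the movie end; the number
    of concurrent competitors never exceeds the slot limit."""
    params = CompetitionParams(
        k_arrival=k_arrival, p_probe=p_probe, p_displace=p_displace, k_passive=k_passive, max_competitors=3
    )
    log = simulate_molecule(params, 60.0, 5.0, seed)
    times = [e.time for e in log.events]
    assert times == sorted(times)
    n_bind = sum(e.action == "bind" for e in log.events)
    n_end = sum(e.action in ("dissociate", "bleach") for e in log.events)
    censored = sum(1 for _, (a, b) in log.species_intervals().items() if b is None)
    assert (n_bind + 1) - n_end == censored  # +1: resident bound at t=0
    concurrent = 0
    for ev in log.events:
        if ev.species.startswith("competitor"):
            concurrent += 1 if ev.action == "bind" else -1
            assert 0 <= concurrent <= 3
    assert all(e.time >= 5.0 for e in log.events if e.action == "bind" and e.species != "resident")


def test_identical_seeds_reproduce_events_and_traces(quiet_acq):
    params = CompetitionParams(k_arrival=0.1, k_passive=0.001)
    a = simulate_molecule(params, 300.0, 10.0, 42)
    b = simulate_molecule(params, 300.0, 10.0, 42)
    assert a.events == b.events
    ta = render_traces(a, quiet_acq, 5)
    tb = render_traces(b, quiet_acq, 5)
    assert np.array_equal(ta.cy3.intensity, tb.cy3.intensity)
    assert np.array_equal(ta.cy5.intensity, tb.cy5.intensity)


def test_render_constant_resident_levels(idle_params, quiet_acq):
    """A resident bound throughout gives 400 on Cy3-excited frames (unit 300
    over background 100) and bare background elsewhere."""
    log = simulate_molecule(idle_params, quiet_acq.duration, quiet_acq.flow_time, 0)
    tp = render_traces(log, quiet_acq, 0)
    exc = tp.cy3.excited
    assert np.all(tp.cy3.intensity[exc] == 400.0)
    assert np.all(tp.cy3.intensity[~exc] == 100.0)


def test_render_two_competitors_plateau(quiet_acq):
    """Intensity is linear in occupancy: two bound competitors double the step."""
    log = EventLog(
        molecule_id="m",
        events=[Event(50.0, "competitor_0", "bind"), Event(60.0, "competitor_1", "bind")],
        duration=quiet_acq.duration,
        flow_time=quiet_acq.flow_time,
    )
    tp = render_traces(log, quiet_acq, 0)
    t = tp.cy5.times
    exc = tp.cy5.excited
    both = exc & (t >= 60.0) & (t < 300.0)
    assert np.all(tp.cy5.intensity[both] == quiet_acq.background_post + 2 * quiet_acq.unit_intensity)
    pre = exc & (t >= quiet_acq.flow_time) & (t < 50.0)
    assert np.all(tp.cy5.intensity[pre] == quiet_acq.background_post)


def test_cy5_background_steps_at_flow_frame(idle_params, quiet_acq):
    log = simulate_molecule(idle_params, quiet_acq.duration, quiet_acq.flow_time, 0)
    tp = render_traces(log, quiet_acq, 0)
    f = quiet_acq.flow_frame
    assert np.all(tp.cy5.intensity[:f][~tp.cy5.excited[:f]] == quiet_acq.background_pre)
    assert tp.cy5.intensity[f] >= quiet_acq.background_post


def test_bleaching_scales_with_exposure(idle_params):
    """Alternating excitation halves the exposure rate, doubling the mean
    bleach time relative to continuous excitation."""

    def mean_bleach(acq):
        times = []
        for seed in range(150):
            log = simulate_molecule(idle_params, acq.duration, 10.0, seed)
            tp = render_traces(log, acq, seed, k_bleach=0.05)
            times.append(tp.bleach_events[0].time if tp.bleach_events else acq.duration)
        return np.mean(times)

    alternating = AcquisitionParams(noise_sd=0.0)
    continuous = AcquisitionParams(noise_sd=0.0, n_both_start=1500, n_both_end=1500)
    ratio = mean_bleach(alternating) / mean_bleach(continuous)
    assert 1.7 < ratio < 2.3


def test_movie_background_only():
    acq = AcquisitionParams(n_frames=20, flow_frame=5, noise_sd=4.0, field_size=(24, 24))
    stack = render_movie([], acq, np.empty((0, 2)), 0)
    assert stack.shape == (20, 24, 48)
    assert abs(stack[:5, :, 24:].mean() - acq.background_pre) < 1.0
    assert abs(stack[5:, :, 24:].mean() - acq.background_post) < 1.0


def test_movie_integration_matches_traces(idle_params):
    """AOI-integrated movie intensity equals the rendered trace after
    accounting for the PSF mass captured by the box (noise-free)."""
    acq = AcquisitionParams(
        n_frames=200, flow_frame=20, noise_sd=0.0, field_size=(32, 32), unit_intensity=3000.0
    )
    log = simulate_molecule(idle_params, acq.duration, acq.flow_time, 0)
    x, y = 15.0, 17.0
    stack = render_movie([log], acq, np.array([[x, y]]), 0)
    # brute-force expected PSF mass: the Gaussian stamp summed over the box
    offs = np.arange(-2, 3)
    g = np.exp(-(offs**2) / (2 * acq.psf_sigma**2))
    mass = np.outer(g, g).sum() / (2 * np.pi * acq.psf_sigma**2)
    tp = render_traces(log, acq, 0)
    box = stack[:, int(y) - 2 : int(y) + 3, int(x) - 2 : int(x) + 3].sum(axis=(1, 2))
    n_fluor = (tp.cy3.intensity - acq.background_cy3) / acq.unit_intensity
    expected = acq.background_cy3 * 25 + n_fluor * acq.unit_intensity * mass
    assert np.max(np.abs(box - expected)) < 0.01 * acq.unit_intensity


def test_movie_identity_transform_coincident_channels(quiet_acq):
    acq = AcquisitionParams(
        n_frames=40, flow_frame=5, noise_sd=0.0, field_size=(24, 24), channel_transform=np.eye(3)
    )
    log = EventLog("m", [Event(1.0, "competitor_0", "bind")], acq.duration, acq.flow_time)
    stack = render_movie([log], acq, np.array([[12.0, 12.0]]), 0)
    cy5_frames = np.flatnonzero(acq.excitation_masks()["cy5"] & (np.arange(40) >= 11))
    peak = acq.unit_intensity / (2 * np.pi * acq.psf_sigma**2)
    # the Cy5 spot is drawn at the (identity-mapped) Cy3 position
    assert stack[cy5_frames[0], 12, 12] == pytest.approx(acq.background_cy3 + peak, abs=1.0)


def test_movie_position_outside_field_rejected():
    acq = AcquisitionParams(n_frames=20, flow_frame=5, field_size=(24, 24))
    log = EventLog("m", [], acq.duration, acq.flow_time)
    with pytest.raises(ConfigurationError):
        render_movie([log], acq, np.array([[30.0, 5.0]]), 0)


def test_invalid_mixture_rejected():
    params = CompetitionParams(diss_mixture=[(0.5, 1.0), (0.4, 10.0)])
    with pytest.raises(ConfigurationError):
        simulate_molecule(params, 10.0, 1.0, 0)
    with pytest.raises(ConfigurationError):
        simulate_molecule(CompetitionParams(), 10.0, 20.0, 0)


def test_experiment_molecule_ids_unique():
    logs = simulate_experiment(CompetitionParams(), AcquisitionParams(n_frames=50, flow_frame=5), 7, 3)
    assert len({log.molecule_id for log in logs}) == 7


def test_grid_positions_respect_field():
    pos = grid_positions(9, (64, 64), margin=8)
    assert pos.shape == (9, 2)
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    assert d[~np.eye(9, dtype=bool)].min() > 5.0
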