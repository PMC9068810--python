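"""End-to-end pipeline orchestration and per-pair competition summaries.

``run_pipeline`` wires the stages together -- simulate -> (render movie ->
extract | render traces) -> segment -> classify -> fit -> summarise -- and
writes every artifact (CSV tables, fit JSON, heat-map and survival figures,
and a machine-readable run manifest) into an output directory.  Heat maps
give, per resident/competitor pair, the percent of Hfq complexes showing
passive competition, stable coexistence and active competition; the three
need not sum to 100 because some molecules show neither and some show both
coexistence and displacement.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd
import tifffile
from matplotlib.figure import Figure

from . import __version__
from .classify import analyze_molecule, records_to_frame, dwells_to_frame, resident_survival_curve
from .errors import ConfigurationError, DataError, FitError, HfqCompeteError
from .extract import detect_spots, extract_traces, filter_aois, map_channels
from .fitkinetics import bootstrap_errors, fit_cdf_exponentials, fit_mle_mixture, select_model
from .segment import detect_flow_time, estimate_unit_intensity, intervals_to_frame, quantize_stoichiometry, segment_trace
from .simulate import PRESETS, AcquisitionParams, CompetitionParams, grid_positions, render_movie, render_traces, simulate_experiment

__all__ = ["PairSummary", "summarize_pair", "run_pipeline", "validate_config"]

logger = logging.getLogger(__name__)

MODES = ("passive", "stable_coexistence", "active")


@dataclass
class PairSummary:
    """Competition-mode percentages for one resident/competitor pair."""

    resident_label: str
    competitor_label: str
    percent_passive: float
    percent_coexistence: float
    percent_active: float
    sem_passive: float
    sem_coexistence: float
    sem_active: float
    n_molecules: int
    endpoint_percent_remaining: float

    def __post_init__(self) -> None:
        for name in ("percent_passive", "percent_coexistence", "percent_active"):
            if not 0.0 <= getattr(self, name) <= 100.0:
                raise DataError(f"{name} outside [0, 100]")


def summarize_pair(records, replicate_ids, resident_label: str = "", competitor_label: str = "") -> PairSummary:
    """Mean and SEM of per-replicate mode percentages over molecules."""
    records = list(records)
    replicate_ids = list(replicate_ids)
    if len(records) != len(replicate_ids):
        raise DataError("one replicate id per record required")
    if not records:
        raise DataError("no molecules to summarise")
    reps = sorted(set(replicate_ids))
    pct = {m: [] for m in MODES}
    remaining = []
    for rep in reps:
        recs = [r for r, rid in zip(records, replicate_ids) if rid == rep]
        if not recs:
            raise DataError(f"replicate {rep!r} is empty")
        n = len(recs)
        for m in MODES:
            pct[m].append(100.0 * sum(m in r.modes for r in recs) / n)
        remaining.append(100.0 * sum(r.t_resident_end is None for r in recs) / n)

    def mean_sem(vals):
        v = np.asarray(vals, dtype=float)
        sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
        return float(v.mean()), sem

    mp, sp = mean_sem(pct["passive"])
    mc, sc = mean_sem(pct["stable_coexistence"])
    ma, sa = mean_sem(pct["active"])
    return PairSummary(
        resident_label=resident_label,
        competitor_label=competitor_label,
        percent_passive=mp,
        percent_coexistence=mc,
        percent_active=ma,
        sem_passive=sp,
        sem_coexistence=sc,
        sem_active=sa,
        n_molecules=len(records),
        endpoint_percent_remaining=float(np.mean(remaining)),
    )


# ---------------------------------------------------------------------------
# configuration


_REQUIRED = ["mode", "n_molecules", "pairs"]
_REQUIRED_ACQ = ["frame_interval", "n_frames", "flow_frame"]


def validate_config(config: dict) -> dict:
    """Check a pipeline configuration; raises naming the offending field."""
    if not isinstance(config, dict):
        raise ConfigurationError("config must be a JSON object")
    for key in _REQUIRED:
        if key not in config:
            raise ConfigurationError(f"config missing required field: {key}")
    acq = config.get("acquisition", {})
    for key in _REQUIRED_ACQ:
        if key not in acq:
            raise ConfigurationError(f"config missing required field: acquisition.{key}")
    if config["mode"] not in ("trace", "movie"):
        raise ConfigurationError("config field 'mode' must be 'trace' or 'movie'")
    if not config["pairs"]:
        raise ConfigurationError("config field 'pairs' must list at least one resident/competitor pair")
    for i, pair in enumerate(config["pairs"]):
        if "preset" not in pair and "params" not in pair:
            raise ConfigurationError(f"config pairs[{i}] needs a 'preset' name or explicit 'params'")
    return config


def _pair_params(pair: dict) -> CompetitionParams:
    if "preset" in pair:
        if pair["preset"] not in PRESETS:
            raise ConfigurationError(f"unknown preset {pair['preset']!r}; options: {sorted(PRESETS)}")
        params = replace(PRESETS[pair["preset"]])
    else:
        params = CompetitionParams()
    for key, val in pair.get("params", {}).items():
        if not hasattr(params, key):
            raise ConfigurationError(f"unknown kinetic parameter {key!r}")
        setattr(params, key, val)
    params.validate()
    return params


# ---------------------------------------------------------------------------
# stage helpers


def _segment_all(trace_map, acq: AcquisitionParams, flow_time: float, seg_cfg: dict, box_area: int = 1):
    """Segment every molecule's two traces; returns {mol: {channel: intervals}}.

    ``box_area`` rescales the acquisition background and noise for
    box-integrated movie traces (background x area, noise x sqrt(area)).
    """
    kw = dict(
        threshold_k=seg_cfg.get("threshold_k", 2.5),
        min_frames=seg_cfg.get("min_frames", 2),
        gap_frames=seg_cfg.get("gap_frames", 1),
        noise_sd=acq.noise_sd * np.sqrt(box_area),
    )
    out = {}
    for mol, by_channel in trace_map.items():
        out[mol] = {
            "cy3": segment_trace(by_channel["cy3"], background=acq.background_cy3 * box_area, **kw),
            "cy5": segment_trace(
                by_channel["cy5"],
                background=acq.background_pre * box_area,
                flow_time=flow_time,
                background_post=acq.background_post * box_area,
                **kw,
            ),
        }
    return out


def _quantize_all(trace_map, intervals, acq: AcquisitionParams, flow_time: float, box_area: int = 1):
    """Estimate the per-fluorophore unit and count competitor stoichiometry."""
    items = [(trace_map[mol]["cy5"], ivs["cy5"]) for mol, ivs in intervals.items()]
    bg_kw = dict(
        background=acq.background_pre * box_area,
        flow_time=flow_time,
        background_post=acq.background_post * box_area,
    )
    try:
        unit = estimate_unit_intensity(items, **bg_kw)
    except DataError:
        unit = acq.unit_intensity
        logger.info("too few Cy5 intervals to estimate the fluorophore unit; using acquisition value")
    for mol, ivs in intervals.items():
        for iv in ivs["cy5"]:
            quantize_stoichiometry(iv, trace_map[mol]["cy5"], unit, **bg_kw)
    return unit


def _movie_to_traces(stack, acq: AcquisitionParams, extract_cfg: dict):
    """Reference-image spot detection through AOI integration."""
    ref = stack[: acq.n_both_start].mean(axis=0)
    w = acq.field_size[1]
    centers = detect_spots(
        ref[:, :w],
        detection_threshold=extract_cfg.get("detection_threshold", 5.0),
        box_halfwidth=extract_cfg.get("box_halfwidth", 2),
    )
    n_detected = len(centers)
    centers = filter_aois(centers, min_separation=extract_cfg.get("min_separation", 5.0))
    aois = map_channels(
        centers,
        acq.channel_transform,
        stack.shape[1:],
        box_halfwidth=extract_cfg.get("box_halfwidth", 2),
    )
    logger.info("extract: %d spots detected, %d AOIs retained", n_detected, len(aois))
    return extract_traces(stack, aois, acq), aois


def _fit_dwells(dwells: pd.DataFrame, fit_cfg: dict, seed: int) -> dict:
    """Mixture fits of the pooled dwell-time distributions of one pair."""
    resolution = fit_cfg.get("resolution", 0.2)
    k_max = fit_cfg.get("k_max", 3)
    n_boot = fit_cfg.get("n_boot", 0)
    out = {}
    for dwell_type in ("t_diss", "t_co", "t_bind"):
        sub = dwells[dwells["type"] == dwell_type]
        values = sub["value_s"].to_numpy()
        censored = sub["censored"].to_numpy(dtype=bool)
        if dwell_type == "t_bind":  # cumulative-fraction fit on observed times
            values, censored = values[~censored], censored[~censored]
        if values.size < max(20, 10):
            continue
        try:
            if dwell_type == "t_bind":
                fits = [fit_cdf_exponentials(values, k=k, seed=seed) for k in range(1, k_max + 1)]
            else:
                fits = [
                    fit_mle_mixture(values, censored, k=k, resolution=resolution, seed=seed)
                    for k in range(1, k_max + 1)
                ]
            sel = select_model(fits)
            best = fits[sel.chosen_k - 1]
            if n_boot and best.method == "mle":
                best = bootstrap_errors(values, censored, best, n_boot=n_boot, seed=seed)
            out[dwell_type] = {
                "chosen_k": sel.chosen_k,
                "selection": sel.table,
                "lifetimes_s": list(best.lifetimes),
                "fractions": list(best.fractions),
                "loglik": best.loglik,
                "method": best.method,
                "n_observations": best.n_observations,
                "n_censored": best.n_censored,
                "ci95_lower": list(best.ci_lower) if best.ci_lower else None,
                "ci95_upper": list(best.ci_upper) if best.ci_upper else None,
            }
        except (FitError, DataError) as exc:
            logger.warning("fit of %s skipped: %s", dwell_type, exc)
    return out


def _heatmap_tables(summaries) -> dict:
    residents = sorted({s.resident_label for s in summaries})
    competitors = sorted({s.competitor_label for s in summaries})
    tables = {}
    for mode, attr in (
        ("passive", "percent_passive"),
        ("coexistence", "percent_coexistence"),
        ("active", "percent_active"),
    ):
        df = pd.DataFrame(np.nan, index=residents, columns=competitors)
        for s in summaries:
            df.loc[s.resident_label, s.competitor_label] = getattr(s, attr)
        tables[mode] = df
    return tables


def _heatmap_figure(tables: dict, path) -> None:
    fig = Figure(figsize=(4 * len(tables), 3.5))
    axes = fig.subplots(1, len(tables))
    for ax, (mode, df) in zip(np.atleast_1d(axes), tables.items()):
        im = ax.imshow(df.to_numpy(), cmap="viridis", vmin=0, vmax=100)
        ax.set_xticks(range(len(df.columns)), df.columns)
        ax.set_yticks(range(len(df.index)), df.index)
        ax.set_xlabel("competitor")
        ax.set_ylabel("resident")
        ax.set_title(f"% {mode}")
        for (i, j), val in np.ndenumerate(df.to_numpy()):
            if np.isfinite(val):
                ax.text(j, i, f"{val:.0f}", ha="center", va="center", color="w")
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)


def _survival_figure(curves: dict, path) -> None:
    fig = Figure(figsize=(5, 3.5))
    ax = fig.subplots()
    for label, (t, pct) in curves.items():
        ax.plot(t, pct, label=label, lw=1.2)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("% resident remaining")
    ax.set_ylim(0, 105)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(config: dict, outdir, seed: int | None = None):
    """Execute the full competition analysis described by ``config``.

    Returns the run manifest (also written to ``manifest.json``); artifacts
    (intervals, records, dwells, fits, summaries, heat maps, survival
    curves, and in movie mode the rendered TIFF stacks) land in ``outdir``.
    """
    from pathlib import Path

    config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    acq = AcquisitionParams(**config.get("acquisition", {}))
    n_molecules = int(config["n_molecules"])
    n_replicates = int(config.get("replicates", 1))
    stable_threshold = float(config.get("stable_threshold_s", 20.0))
    detect_flow = bool(config.get("detect_flow", False))
    seg_cfg = config.get("segmentation", {})
    fit_cfg = config.get("fit", {})
    mode = config["mode"]

    root_ss = np.random.SeedSequence([seed, 0x5F0A])
    pair_seeds = root_ss.spawn(len(config["pairs"]))

    all_records, all_intervals, all_dwells, summaries, fits_json, counts = [], {}, [], [], {}, []
    survival_curves = {}
    for pair, pair_ss in zip(config["pairs"], pair_seeds):
        stage = "simulate"
        try:
            params = _pair_params(pair)
            label = f"{pair.get('resident', 'R')}_vs_{pair.get('competitor', 'C')}"
            rep_records, rep_ids = [], []
            for rep, rep_ss in enumerate(pair_ss.spawn(n_replicates)):
                sim_ss, render_ss = rep_ss.spawn(2)
                stage = "simulate"
                logs = simulate_experiment(params, acq, n_molecules, sim_ss)
                for log in logs:
                    log.molecule_id = f"{label}_r{rep}_{log.molecule_id}"

                if mode == "movie":
                    stage = "extract"
                    positions = grid_positions(n_molecules, acq.field_size, spacing=config.get("spot_spacing"))
                    stack = render_movie(logs, acq, positions, render_ss, k_bleach=params.k_bleach)
                    tiff_path = outdir / f"movie_{label}_r{rep}.tif"
                    if config.get("write_movies", False):
                        tifffile.imwrite(tiff_path, stack)
                    trace_map, _ = _movie_to_traces(stack, acq, config.get("extract", {}))
                else:
                    stage = "render"
                    trace_map = {}
                    for log, child in zip(logs, render_ss.spawn(len(logs))):
                        tp = render_traces(log, acq, np.random.default_rng(child), k_bleach=params.k_bleach)
                        trace_map[log.molecule_id] = {"cy3": tp.cy3, "cy5": tp.cy5}

                stage = "segment"
                if detect_flow:
                    flows = []
                    for by_channel in trace_map.values():
                        try:
                            flows.append(detect_flow_time(by_channel["cy5"]))
                        except HfqCompeteError:
                            continue
                    if not flows:
                        raise DataError("flow time could not be detected in any trace")
                    flow_time = float(np.median(flows))
                else:
                    flow_time = acq.flow_time
                hw = config.get("extract", {}).get("box_halfwidth", 2)
                box_area = (2 * hw + 1) ** 2 if mode == "movie" else 1
                intervals = _segment_all(trace_map, acq, flow_time, seg_cfg, box_area=box_area)
                _quantize_all(trace_map, intervals, acq, flow_time, box_area=box_area)

                stage = "classify"
                for mol, ivs in intervals.items():
                    rec = analyze_molecule(
                        mol, ivs["cy3"], ivs["cy5"], flow_time, acq.duration, stable_threshold
                    )
                    rep_records.append(rec)
                    rep_ids.append(rep)
                all_intervals.update(intervals)
                counts.append(
                    {"pair": label, "replicate": rep, "n_molecules": len(trace_map), "flow_time_s": flow_time}
                )

            stage = "fit"
            dwells = dwells_to_frame(rep_records)
            dwells.insert(0, "pair", label)
            all_dwells.append(dwells)
            fits_json[label] = _fit_dwells(dwells, fit_cfg, seed)

            stage = "summarize"
            summaries.append(
                summarize_pair(rep_records, rep_ids, pair.get("resident", "R"), pair.get("competitor", "C"))
            )
            survival_curves[label] = resident_survival_curve(rep_records, movie_end=acq.duration)
            all_records.extend(rep_records)
        except HfqCompeteError as exc:
            raise type(exc)(f"pipeline stage '{stage}' failed for pair {pair}: {exc}") from exc

    # artifacts
    records_to_frame(all_records).to_csv(outdir / "records.csv", index=False)
    intervals_to_frame(all_intervals).to_csv(outdir / "intervals.csv", index=False)
    dwells_df = pd.concat(all_dwells, ignore_index=True) if all_dwells else pd.DataFrame()
    dwells_df.to_csv(outdir / "dwells.csv", index=False)
    with open(outdir / "fits.json", "w") as fh:
        json.dump(fits_json, fh, indent=2)
    pd.DataFrame([asdict(s) for s in summaries]).to_csv(outdir / "pair_summaries.csv", index=False)
    tables = _heatmap_tables(summaries)
    for modename, df in tables.items():
        df.to_csv(outdir / f"heatmap_{modename}.csv")
    _heatmap_figure(tables, outdir / "heatmaps.png")
    surv_df = pd.concat(
        [pd.DataFrame({"pair": lab, "time_s": t, "percent_remaining": p}) for lab, (t, p) in survival_curves.items()],
        ignore_index=True,
    )
    surv_df.to_csv(outdir / "survival.csv", index=False)
    _survival_figure(survival_curves, outdir / "survival.png")

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "stage_counts": counts,
        "artifacts": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
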