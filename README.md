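# hfqcompete

Single-molecule TIRF analysis of small-RNA competition on the bacterial RNA
chaperone Hfq — from two-channel fluorescence movies or intensity traces,
through interval segmentation and competition-event classification, to
multi-exponential dwell-time kinetics — together with a stochastic kinetic
simulator that generates realistic ground-truth data for every stage.

## The problem

Hfq is a hexameric chaperone whose proximal face, rim and distal face bind
different classes of small regulatory RNA (sRNA). Because many sRNAs share a
limited pool of Hfq, an incoming *competitor* sRNA (Cy5-labelled, in
solution) must contend with a *resident* sRNA (Cy3-labelled, pre-bound to a
surface-tethered hexamer). Colocalisation movies of single Hfq molecules
distinguish three outcomes:

- **passive competition** — the resident dissociates spontaneously before
  any competitor has bound the same hexamer (rare);
- **active competition** — the resident departs after a competitor binds;
  the displacement time `t_diss` runs from the start of the colocalisation
  episode to resident departure, with competitors remaining bound;
- **stable coexistence** — resident and competitor share the hexamer;
  episodes with coexistence time `t_co` > 20 s count as stable, a threshold
  justified by the in-cell RNA access time (see below).

Dwell-time distributions are modelled as exponential mixtures,
`f(t) = Σ_j (a_j/τ_j) e^(−t/τ_j)` with `Σ a_j = 1`. Fits use either least
squares on the cumulative fraction `F(t) = Σ_j a_j (1 − e^(−t/τ_j))`
(association times) or censoring-aware maximum likelihood in which
right-censored dwells enter through the survival function and dwells below
the 0.2 s per-channel resolution (alternating excitation) enter as interval
probabilities; a fitted lifetime below the resolution is reported as a
zero-lifetime, sub-resolution class. Model order (1–3 components) is chosen
by nested likelihood-ratio tests; errors are case-resampling bootstrap
percentile intervals.

The package is aimed at single-molecule biophysicists who want a tested,
scriptable equivalent of the usual interactive trace-analysis stack, and at
method developers who need a simulator with exact ground truth to validate
colocalisation pipelines.

## Worked example

Simulate 200 Hfq·DsrA complexes challenged by the strong class II competitor
ChiX, render noisy traces, segment, classify and fit the displacement times:

```python
import numpy as np
import hfqcompete as hc

acq = hc.AcquisitionParams()              # 3,000 frames, 100 ms, flow at 10 s
params = hc.PRESETS["H-DA_vs_CX"]         # DsrA resident vs ChiX competitor
logs = hc.simulate_experiment(params, acq, 200, rng_seed=1)

records = []
for i, log in enumerate(logs):
    tp = hc.render_traces(log, acq, rng_seed=1000 + i)
    cy3 = hc.segment_trace(tp.cy3, background=acq.background_cy3, noise_sd=acq.noise_sd)
    cy5 = hc.segment_trace(tp.cy5, background=acq.background_pre, noise_sd=acq.noise_sd,
                           flow_time=acq.flow_time, background_post=acq.background_post)
    records.append(hc.analyze_molecule(log.molecule_id, cy3, cy5, acq.flow_time, acq.duration))

summary = hc.summarize_pair(records, [0] * len(records), "DsrA", "ChiX")
print(f"active: {summary.percent_active:.1f}%  stable coexistence: "
      f"{summary.percent_coexistence:.1f}%  passive: {summary.percent_passive:.1f}%")

t_diss = np.array([d.value for r in records for d in r.t_diss_list])
cens = np.array([d.censored for r in records for d in r.t_diss_list])
fits = [hc.fit_mle_mixture(t_diss, cens, k=k, resolution=0.2, seed=0) for k in (1, 2, 3)]
sel = hc.select_model(fits)
best = hc.bootstrap_errors(t_diss, cens, fits[sel.chosen_k - 1], n_boot=500, seed=0)
print(f"t_diss: n={best.n_observations}, chosen k={sel.chosen_k}")
for tau, frac, lo, hi in zip(best.lifetimes, best.fractions,
                             best.ci_lower[:sel.chosen_k], best.ci_upper[:sel.chosen_k]):
    print(f"  tau = {tau:5.1f} s  ({100*frac:4.1f}%)  95% CI [{lo:.1f}, {hi:.1f}] s")

bound = hc.access_time_bound(copies=(10, 60), volume_um3=0.5, k_on=2e5)
print(f"in-cell access time: {bound.access_time_min_s:.0f}-{bound.access_time_max_s:.0f} s "
      f"({bound.concentration_low_nM:.0f}-{bound.concentration_high_nM:.0f} nM)")
```

which prints:

```
active: 96.5%  stable coexistence: 14.5%  passive: 2.5%
t_diss: n=202, chosen k=2
  tau =   0.8 s  (45.8%)  95% CI [0.6, 1.1] s
  tau =  15.1 s  (54.2%)  95% CI [11.8, 18.9] s
in-cell access time: 25-151 s (33-199 nM)
```

Against a strong competitor nearly every resident is actively displaced
(passive dissociation stays rare), and at this sample size the
likelihood-ratio test supports two displacement classes — a fast ~1 s clash
component and a slower ~15 s rearrangement component; the minor slow class
in the generator needs more events to resolve. The access-time bound is why
20 s is a sensible floor for calling a ternary complex "stable": an mRNA
present at 10–60 copies per cell needs ~25–150 s to find an Hfq, so only
complexes outliving that window can matter for regulation.

The same analysis runs end-to-end from a rendered TIFF movie (spot
detection → AOI filtering → channel mapping → integration) via the `movie`
pipeline mode, or from the command line:

```sh
hfqcompete run --config config.json --seed 1 --out results/
```

## Layout

| module | role |
| --- | --- |
| `hfqcompete.simulate` | Gillespie-style kinetic simulator, trace/movie rendering, regime presets |
| `hfqcompete.extract` | spot detection, AOI filtering, channel mapping, intensity integration |
| `hfqcompete.segment` | flow-step detection, interval segmentation, stoichiometry counting |
| `hfqcompete.classify` | occupancy timelines, `t_bind`/`t_diss`/`t_co`, competition modes |
| `hfqcompete.fitkinetics` | exponential-mixture fits, model selection, bootstrap, KS test, analytic bounds |
| `hfqcompete.report` | pipeline orchestration, pair summaries, heat maps, manifests |

See `docs/methods.md` for the model, its assumptions and the numerical
choices.
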