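# Methods

## Kinetic model of the simulator

Each simulated molecule is one surface-tethered Hfq hexamer carrying a
Cy3-labelled resident sRNA at t = 0. After the competitor solution reaches
the chamber at `flow_time`, Cy5-labelled competitors arrive as a Poisson
process with pseudo-first-order rate `k_arrival` (units s⁻¹; the product of
the association rate constant and the competitor concentration). Arrivals
are thinned whenever all `max_competitors` slots (default 3, so up to four
sRNAs with the resident) are occupied. Each accepted arrival is classified
at binding time:

- with probability `p_probe`, a **probe**: a transient, non-productive visit
  with an exponential dwell of mean `tau_probe`. Probes reproduce the bursts
  of short Cy5 events that precede a stable binding event. Whether probes
  can themselves trigger displacement is not observable in the data this
  emulates; the default is that they cannot (`probes_can_displace=False`).
- otherwise, with probability `p_displace`, a **displacing** binder: the
  resident departs after a delay drawn from the 1–3-component exponential
  mixture `diss_mixture`; the displacer remains bound (right-censored at the
  movie end). Sub-frame delays are preserved exactly and produce the
  apparent zero-lifetime displacement class after discretisation.
- otherwise a **coexisting** binder: the joint dwell is drawn from
  `co_mixture`, after which the resident leaves with probability
  `p_resident_leaves_first`, else the competitor does.

Independently, a resident with no competitor bound dissociates spontaneously
at rate `k_passive`. All memoryless clocks are redrawn after every event
(valid by memorylessness); displacement and coexistence delays, which are
not exponential in general, are scheduled once at the triggering arrival.
Event times are continuous; discretisation to 100 ms camera frames happens
only at rendering.

The four presets (`H-DA_vs_DA`, `H-DA_vs_CX`, `H-CX_vs_DA`, `H-CX_vs_CX`,
after the DsrA/ChiX resident–competitor pairs) are regime-faithful fixtures:
their lifetimes and fractions are chosen inside the experimentally reported
ranges for each pair (fast clash displacement well below a second, a
seconds-scale rearrangement class, a minor slow class near 100 s, homotypic
coexistence near 70 s and heterotypic near 40 s, passive exchange held
rare), not reproductions of any particular fitted value.

## Rendering

Traces follow `intensity = background + unit_intensity × n_bound ×
excitation + N(0, noise_sd²)`, evaluated from the occupancy at each frame
midpoint. The Cy5 background steps from `background_pre` to
`background_post` at the flow frame and is recorded on every frame, which is
what makes flow detection possible at full 0.1 s resolution. The standard
excitation scheme excites both dyes on the first and last ten frames and
alternates in between (Cy3 even, Cy5 odd frames), so each channel is sampled
every 0.2 s during the bulk of the movie. Photobleaching, when enabled,
consumes a fluorophore only on frames where its channel is excited, with
per-exposure probability `1 − e^(−k_bleach·Δt)`; this reproduces the
factor-of-two lifetime gain of alternating over continuous excitation.

Movies place each bound fluorophore as a 2-D Gaussian of total mass
`unit_intensity` (σ = `psf_sigma`, default 1 px) on a two-half-field camera:
Cy3 on the left, Cy5 at the affine-mapped position on the right (default: a
pure translation by one half-field width). Stacks are 16-bit grayscale,
TIFF-writable. Box-integrated movie intensities equal the rendered traces up
to the PSF mass captured by the 5×5 box (~98% at σ = 1), which the unit
estimator absorbs automatically.

What the generator does **not** emulate: stage drift, nonlinear field
distortion, EMCCD gain statistics and excess noise, fluorophore blinking
beyond what the gap-bridging rule absorbs, spectral crosstalk, non-specific
surface binding, and any sequence- or structure-dependence of the kinetics
(the scheme is purely phenomenological). Passing tests therefore validate
the analysis logic and its statistics, not robustness to those instrument
artifacts.

## Extraction

AOIs are local maxima of a reference image (mean of the first ten
both-excited frames) above `median + k·(1.4826·MAD)` (default k = 5),
refined to background-subtracted intensity centroids. Every member of any
AOI pair closer than `min_separation` (default 5 px) is discarded — a box
containing two Hfq molecules cannot be salvaged by keeping one centre — so
the filter is order-independent. Cy3 centres map to Cy5 through a known,
invertible affine transform; mapping calibration (bead fiducials) is out of
scope and the transform is taken as input. Coordinates are 0-based subpixel
`(x, y) = (column, row)` throughout; one stated convention avoids off-by-one
channel-mapping bugs.

## Segmentation

Binding analysis runs on each channel's own excited-frame timebase and
reports half-open `[t_start, t_end)` intervals on the global clock, so
dwells are quantised to 0.2 s during alternation — the origin of the
sub-resolution displacement class. Frames brighter than `background +
threshold_k·SD` are "on"; runs of at least `min_frames` (default 2)
consecutive on-frames survive, and dark gaps of at most `gap_frames`
(default 1) between surviving runs are bridged (blinking). The order —
minimum length first, bridging second — matters: bridging first would let
two isolated single-frame noise excursions fabricate an interval. Whether
the original analyses bridged blinking gaps is unknowable from the data this
emulates; `gap_frames` is an explicit, configurable choice.

`threshold_k` defaults to 2.5. At a trace signal-to-noise of 5 a 3σ
threshold misses ~2.3% of genuinely bound frames, and occasional double
dropouts split long dwells (measured 88% interval recovery on a standard
fixture, versus 100% at 2.5σ); 2.5σ keeps the false-on rate per background
frame at 0.6%, which the min-length rule then suppresses.

Intervals touching the first or last excited frame are flagged
left-/right-censored. The competitor-addition time is found by fitting a
two-level constant model to a Cy5 trace, iteratively masking binding pulses
as high outliers against per-side lowest-histogram-mode background
estimates; if the best split improves the one-level fit by less than 5% the
step is declared undetectable and an explicit flow time must be supplied.

Stoichiometry: the single-fluorophore unit intensity is the median
background-subtracted plateau of the lowest mode of the plateau
distribution (≥ 20 intervals required). Within an interval, each excited
frame's background-subtracted intensity is divided by the unit and rounded —
equivalent to detecting every internal step of at least half a unit — with
zero-rounding frames (bridged gaps) inheriting the neighbouring count. A
greedy binary mean-shift splitter was tried first and rejected: on
staircases (1→2→3→2→…) the top-level split's mean difference can fall below
any fixed threshold even though each local step is a full unit, so whole
staircases went undetected; per-frame rounding is exact on noise-free data
and equally threshold-limited on noisy data.

## Classification

Paired interval lists become a piecewise-constant timeline of
`(resident_bound, competitor_count)`, with the count following the
stoichiometry segments. A colocalisation episode is a maximal span with the
resident bound and at least one competitor; it resets only when the count
returns to zero, so multi-competitor loading before displacement stays one
episode. Episodes yield `t_co` (duration, with outcome: resident left,
competitor left, or censored) and, when the resident departs while
competitors remain, `t_diss` (departure minus episode start — by
construction every `t_diss` also appears as a `t_co` with outcome
"resident left"). `t_bind` is the first episode start minus the flow time;
`t_bind_diss` the same for the displacing episode. Molecules whose
competitors never colocalise are right-censored at the movie end.

Mode flags: *active* if any `t_diss` exists; *stable coexistence* if any
`t_co` exceeds the threshold (default 20 s; censored episodes already
longer than the threshold count, since their true dwell can only be
longer); *passive* only if the resident departed with no competitor
colocalisation at any earlier time — a conservative reading under which a
departure after an earlier, completed coexistence is neither passive nor
active. Active and stable coexistence can co-occur; a molecule with no
qualifying event carries `{none}`. Mode percentages per pair therefore need
not sum to 100.

The number of competitors engaged before displacement counts the initial
occupancy plus every later increment of the competitor count (stoichiometry
steps included) within the displacing episode. Maximum concurrent sRNA
occupancy is resident + quantised competitor count; cumulative-visitor
counting would be an alternative reading, and the concurrent definition is
the one implemented.

## Dwell-time statistics

Cumulative-fraction fits minimise the squared distance between
`F(t) = Σ a_j(1−e^(−t/τ_j))` and the ECDF at the observed times
(Levenberg–Marquardt, ≥ 5 starts spread over data quantiles). The
censoring-aware MLE maximises

```
Σ_obs log Σ_j (a_j/τ_j) e^(−t_i/τ_j)
+ Σ_cens log Σ_j a_j e^(−t_i/τ_j)
+ n_subres · log Σ_j a_j (1 − e^(−resolution/τ_j))
```

with lifetimes parameterised on a log scale (positivity) and fractions
through a softmax (simplex), optimised by multi-start Nelder–Mead;
single-component fits without sub-resolution data use the closed form
`τ̂ = Σtᵢ / n_uncensored`. Components whose fitted lifetime falls below the
resolution are reported as lifetime 0; the raw estimate is retained.
Censored observations are excluded from ECDF construction but enter the MLE
through survival terms, which matters because a 300 s observation window
truncates the slowest class. Never-binding molecules are dropped from
association-time CDFs by default (their censoring times are recorded, so
the alternative is available to the caller).

Model order is the smallest k not rejected against k+1 by a likelihood-ratio
test at α = 0.05 with 2 degrees of freedom per added component (BIC is
reported alongside for transparency); the mixture boundary makes the χ²
reference approximate, which the calibration test tolerates. Errors are
case-resampling bootstrap percentile intervals (68% and 95%, default 1000
replicates, each refit from the point estimate; label switching resolved by
ascending-lifetime sort; measured 94–95% coverage for a single-exponential
lifetime at n = 1000). Density histograms use `density = n_i/(N·w_i)` with
binomial error bars `sqrt(p_i(1−p_i)/N)/w_i` — a stated convention of this
package, as is the use of the standard two-sample Kolmogorov–Smirnov test
(exact p for small samples, asymptotic otherwise).

The stable-coexistence threshold traces to an in-cell estimate: an mRNA at
10–60 copies in ~0.5 µm³ is 33–199 nM (copies/(V·N_A)), and with an apparent
association rate constant of 2×10⁵ M⁻¹s⁻¹ needs ~25–151 s to access an Hfq;
20 s is therefore the least time a ternary complex must survive to be
regulatorily relevant. These values, and the 16.7 s lifetime implied by a
0.06 s⁻¹ dissociation rate, serve as analytic checks of the arithmetic.

## Pipeline and problem sizes

`run_pipeline` derives every stage's random stream from one root seed, so
runs are bit-reproducible; the manifest records the seed, configuration,
package version and per-stage molecule counts (the AOI and QC filters
silently shrink N, so the counts are logged at every stage). In movie mode
the background and noise passed to segmentation are rescaled by the
integration-box area (background × area, noise × √area). Photobleaching QC
compares end-of-movie counts with fresh fields of view and excludes movies
differing by ≥ 15%.

Default validation sizes were chosen to make the statistics decisive while
keeping runs comfortable on a laptop: 10,000 dwells for mixture recovery
(~30% censored through independent exponential observation windows within
the 300 s movie — censoring only at the window end would censor ~2%, so the
windows emulate bleaching- or arrival-limited observation), 500 molecules
for noise-free ground-truth equivalence, 10,000 molecules for the
passive-survival limit, 100 simulations × 1000 bootstrap replicates for CI
calibration, and a 100-molecule movie at trace SNR 5 for the image path.

## Known limitations

- Per-trace background estimation (lowest histogram mode) fails for
  fluorophores bound through the entire movie; pipelines should pass known
  or pooled background levels, as `run_pipeline` does.
- The unit-intensity estimator assumes single fluorophores dominate the
  lowest plateau mode; fields dominated by multi-occupancy would bias it.
- The LRT/χ² model-selection reference is approximate at the mixture
  boundary, and with ≤ a few dozen dwells close lifetimes are unresolvable
  (by design the selector then prefers fewer components).
- Simulated displacers remain bound until the movie ends; competitor-only
  dwell statistics after resident departure are therefore not meaningful.
- The spatial channel map is taken as known; no drift correction or
  nonlinear registration is implemented.
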