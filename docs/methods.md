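# Methods

## The problem

Pulsatile hormones — cortisol is the motivating case — are secreted in
discrete bursts superimposed on slower ultradian and circadian
structure. In a 24-h profile sampled every 10 minutes, a single rise or
fall can itself be built from several embedded pulses. `hapalysis`
implements hierarchically adaptive (HAP) analysis: instead of fitting a
pharmacokinetic model or choosing detection thresholds, it treats the
profile as a string in a context-free language of nested rises and
falls and parses it. The parse is parameter-free, deterministic, and
robust to missing samples.

## Feature classification (the comparator)

For each interior sample `c_i`, the comparator is the ordered pair of
three-way comparisons `(c_{i-1} vs c_i, c_i vs c_{i+1})`. The nine
possible pairs map onto nine feature codes:

| left,right | `>` `<` | `<` `>` | `<` `<` | `>` `>` | `<` `=` | `=` `>` | `>` `=` | `=` `<` | `=` `=` |
|---|---|---|---|---|---|---|---|---|---|
| code | N (nadir) | P (peak) | R (rise) | D (fall) | RF | FD | DF | FR | F (flat) |

Equality is exact by default (`epsilon = 0`): assay outputs are already
quantised and the method advertises itself as requiring no user
parameters, so a nonzero tolerance is opt-in configuration only.
Comparisons skip missing samples to the nearest observed neighbour on
each side (no imputation); a sample with no observed neighbour on one
side is tagged `M` and excluded. This makes classification of a gappy
series identical to classification of its compressed observed sequence.

## Plateaus

Flat spans are resolved by what bounds them:

- down–flat–up (`DF … FR`): one **broad nadir**, represented by the
  span's first sample;
- up–flat–down (`RF … FD`): one **broad peak**, first sample;
- staircases (down–flat–down, up–flat–up): not extrema as a whole; the
  `DF`/`FR` end stays nadir-class and the `RF`/`FD` end peak-class.

These conventions guarantee strict nadir/peak alternation, which is
what the segment extraction below relies on.

## Boundary anchors and flanks

A series start that the data rise away from acts as the opening nadir
of the first pulse; symmetrically, an end the data fall into closes the
last pulse. Such boundary samples enter the level's nadir list flagged
as *anchors*; they delimit segments but are reported separately from
detected (interior) nadirs. A leading flat run is absorbed into the
start anchor at the *last* flat sample — the onset of the first rise —
and a trailing flat run into the end anchor at its *first* flat sample.
(Interior broad nadirs keep the first-sample representative; only the
boundary case differs, so that a profile sitting at zero until its
first secretion event dates its first nadir at the rise onset, not at
time 0.) If instead the series falls away from its start, that
monotone run is a leading flank, rendered `>`; a rising tail is a
trailing flank, rendered `<`.

## The recursion

One iteration = classify, collapse plateaus, keep the nadir-class
points {N, DF, FR}. The next iteration re-parses the sub-series
(first sample, selected nadirs, last sample) *at the original, now
non-uniform, times* — the comparator only uses value order, never
spacing. Iteration stops at the first level that identifies no
interior peak (no rise-and-fall left); that peakless level is recorded
as the terminal level. A parse with `m` pulse-bearing levels therefore
has `m + 1` recorded levels, and a monotone or flat series terminates
at level 1. Each pulse-bearing iteration strictly shrinks the point
set (its peaks are dropped), so termination is guaranteed; a guard
raises if the level count ever exceeds the level-1 nadir count, which
would indicate an implementation bug.

Nadir anchoring (rather than the symmetric peak-to-peak partition,
also provided as `select_peaks`) is used because pulse start times are
traditionally associated with nadirs: a level-1 nadir approximates the
timing of a signal to secrete.

## Production graph and pulsicons

Level-1 segments (nadir → peak → nadir) are leaves; a level-k segment
(k ≥ 2) is a composite whose children are the level-(k−1) segments in
its span, split into a rising side and a falling side at the
composite's peak. The pulsicon at level k renders nodes at level ≥ k:
a node at the cutoff level is `()`, a composite is
`(rising:falling)`, the whole core is wrapped in one outer group, and
flanks contribute one `>`/`<` each. Consequences used as test oracles:
the pulsicon alphabet is `( ) : < >`; strings are balanced; the number
of `()` leaf pairs at level 1 equals the level-1 peak count; string
length strictly decreases with level; the outermost core depth at
level k is `terminal_level − k + 1`; and the deepest pulse-bearing
level of a fully nested parse is exactly `(())`. A composite side with
no embedded children contributes the empty string; in practice both
sides are populated, because a composite's peak is a nadir of the
level below and therefore has at least one child segment on each side.
`validate_pulsicon` is the independent recogniser: a recursive-descent
parser that accepts exactly the language and reports the first
offending position on rejection.

## Rates

For each segment at each level:

- accumulation rate = rise amplitude / rise duration (µg/(dL·min)),
- dissipation rate = fall amplitude / fall duration,
- inter-nadir interval = nadir-to-nadir time (min).

A level with `m` nadirs yields `m − 1` of each. Level-1 values are
*analogous to* secretory rate, clearance rate and interpulse interval;
they are not pharmacokinetic constants, because secretion and
clearance are assumed temporally distinct within a segment and no
deconvolution is performed. Per level, amplitude is also regressed on
duration (OLS with intercept, separately for rises and falls); the
slope is the level's average accumulation/dissipation rate, reported
with a 95% CI and R² when at least 3 segments exist. The per-level
summary reports min/median/max of the five segment quantities (the
median of two values being their mean) plus the median inter-nadir
interval in hours — the parse's time-scale components (pulse scale at
level 1, ultradian scales above).

Two conservation/symmetry identities double as tests: at every level,
Σ(rise amplitudes) − Σ(fall amplitudes) telescopes to the last-minus-
first nadir value; rescaling time by `s` divides all rates by `s` and
multiplies intervals by `s`, while adding a constant to all values
changes nothing.

## The simulator

The validation simulator drives a one-compartment model with
first-order clearance: each secretion event infuses its amplitude at a
constant rate over `secretion_spread` minutes; otherwise
`dC/dt = −λC`. Dynamics are integrated exactly between breakpoints
(event edges and sample times), `C(0) = 0`, sampling every 10 min over
24 h (145 samples). The train's gamma parameter scales the clearance
*time constant*: effective half-life = `gamma ×
clearance_halflife_base`, so larger gamma means slower clearance. (In
random-train mode gamma's other published role — shaping the renewal
process — is covered by the gamma-distributed interpulse intervals.)
Sampled values below the assay's lower limit of detection report as 0,
as a real assay would; an optional reporting-resolution rounding knob
exists but is off by default.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `duration`, `delta_t` | 1440, 10 min | the study's sampling design |
| `clearance_halflife_base` | 60 min | textbook cortisol plasma half-life (60–90 min) |
| `secretion_spread` | 10 min | one sampling interval; near-instantaneous secretory bursts |
| `detection_limit` | 0.03 µg/dL | modern cortisol assay analytical sensitivity (~0.02–0.05) |
| `quantize` | 0 (off) | exact values by default |

The published model this reconstructs is specified only by external
code, so the free constants above were fixed once against the
published detectability profile of the six printed validation trains:
under these defaults the parser recovers 116 of the 120 printed events
and misses exactly the four printed sub-resolution events (amplitudes
0.00–0.27 µg/dL), the documented behaviour. This outcome is stable
over a wide region (half-life base 40–80 min, spread 10–20 min,
detection limit ~0.03), not a knife-edge. Two mechanisms produce the
misses: a small event riding a steep post-pulse decline does not
reverse the decline at any 10-min sample (swamping), and a small event
on a zero baseline stays below the detection floor. Coarse value
quantisation was considered as an alternative mechanism and rejected:
at 0.05–0.2 µg/dL it misses large events too, via plateau-representative
shifts.

Random trains draw interpulse intervals from a gamma renewal process
(default mean 70 min, shape 2, in the published ultradian range) with
a sinusoidal 24-h amplitude envelope peaking near the end of the sleep
period (acrophase 480 min, depth 0.8), emulating circadian amplitude
modulation. A seed is mandatory.

### What the simulator does and does not emulate

It reproduces pulsatile rise/decay geometry, circadian amplitude
modulation, sampling and assay floor effects — the features the parser
consumes. It does **not** add assay noise, inter-assay drift,
physiological feedback, or sampling jitter. Passing tests on simulated
profiles therefore demonstrate correctness of the parse and rate
algebra under clean pulsatile geometry, not detection performance on
noisy clinical data; on real data the first iteration level mixes
pulses with assay noise by design (no smoothing is ever applied, since
smoothing can destroy exactly the low-amplitude structure of
interest).

## Numerical choices and degenerate inputs

- Exact float comparison (`epsilon = 0`) everywhere by default;
  equality classes in plateau logic are chains of pairwise-equal
  neighbours.
- Grid completion in I/O infers `delta_t` as the minimal positive time
  difference and requires all gaps to be integer multiples (relative
  tolerance 1e-6); a declared `delta_t` that disagrees with the
  inferred one is a hard error rather than a silent resample.
- Series shorter than 3 samples, or with fewer than 3 observed
  samples, are rejected at analysis entry points.
- A monotone series parses to a single terminal level whose pulsicon
  is the flank symbol alone; a flat series parses to one empty level.
- Negative concentrations are retained with a warning (they can occur
  in background-subtracted assays); the parser is
  translation-invariant so results are unaffected.
- All outputs (CSV/JSON/DOT/pulsicons) are byte-stable across reruns:
  no timestamps, sorted JSON keys, deterministic float formatting.

## Known limitations

- Pulse/noise discrimination is out of scope: level-1 rates on noisy
  data bound, rather than estimate, secretory kinetics.
- The simulator is a reconstruction; its constants are matched to
  published detectability behaviour, not fitted to data, and
  higher-order secretion/clearance dynamics are not modelled.
- Level counting includes the final peakless iteration as the terminal
  level (the convention the worked micro-example fixes); published
  per-subject iteration counts that stop at the last pulse-bearing
  step are one lower than `terminal_level` and equal
  `n_pulse_levels`.
- Whether boundary samples may act as nadirs is underdetermined in the
  method's public description; the anchor convention above is this
  package's documented choice.
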