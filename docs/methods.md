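# Methods

## Model and procedure

`cobaltqa` verifies one treatment fraction by comparing a machine delivery
log against the approved plan for a three-head cobalt-60 machine with
30-pair MLCs.  The verification runs in report order: patient identity →
prescription → day-of-treatment source data → plan structure → per-beam
parameters → per-segment parameters → per-beam fluence maps, and ends with
an overall verdict.  Every compared item yields exactly one result
(pass / fail / warn) with its planned value, delivered value and tolerance;
the report renders one row per result with failures highlighted.

### Geometry conventions

All aperture geometry is projected to the isocenter plane: `x` is the
leaf-travel direction, `y` the stacking direction, units cm.  Leaf pair 1
sits at the most-negative `y`; the 30-pair stack is centered on the beam
axis.  The projected leaf width defaults to 1.05 cm (configurable), giving
a 31.5 cm stack.  Gantry angles are stored normalized to [0, 360°) and all
angular differences are taken on the circle (min of |a−b| and 360−|a−b|),
so 359.8° vs 0.1° is a 0.3° deviation, never 359.7°.

### Source decay and time scales

Planned segment times are defined at the nominal planning dose rate
(default 1.85 Gy/min); logged times are as-delivered at the day's decayed
rate of the delivering head.  Each of the three sources decays
independently from its own calibration: factor `2^(−Δt/T½)` with Δt in
Julian years (365.25 d) and T½ = 5.2711 y held in the configuration XML so
it is auditable rather than hard-coded.  Plan-vs-log time comparisons are
made on the **nominal** scale (logged time × day_rate / nominal_rate).
This choice is deliberate: a log that reports times before the decay
correction then shows a deviation of `(1 − day/nominal) × t`, which for a
30 s segment at a 10%-decayed source is 3 s — far over the 0.2 s tolerance
— and simultaneously scales the delivered fluence map, so the failure is
caught twice.  The logged decayed strength and dose rate themselves are
recomputed from the configured reference calibration and compared at a
10⁻³ relative tolerance (our choice, configurable; no published value
exists for this consistency check).

### Fluence composition and comparison

Per beam, `F(x,y) = Σₖ tₖ·Aₖ(x,y)` in seconds on a raster grid (default
1 mm spacing, 31.5 × 31.5 cm, both configurable; 1 mm comfortably resolves
the 2 mm MLC tolerance).  Rasterization is **area-weighted**: a pixel's
aperture value is the exact fraction of its area inside the opening
(product of the x-overlap with [left, right] and the y-overlap with the
leaf row).  This makes the map integral equal `Σₖ tₖ × open-area(k)` to
rounding error and keeps pass rates insensitive to grid phase; a binary
center-in/out raster would satisfy neither.  The delivered map is composed
from decay-normalized times (otherwise every comparison would fail by the
decay ratio).

Comparison: pixels with planned intensity strictly greater than 10% of the
planned maximum are evaluated; an evaluated pixel passes when the absolute
difference is strictly less than 2% of that maximum; a beam is acceptable
at a pass rate ≥ 90%.  Absolute difference is used (the criterion is
symmetric in sign).  Mean and SD are reported for the signed difference,
max for its magnitude.  An all-closed planned beam has no evaluable pixels;
its pass rate is undefined and reported as *warn*, not fail.

### Tolerances and statuses

Defaults: 0.5° gantry, 2 mm per individual MLC leaf, 0.2 s beam-on time
(applied both per segment and to the per-beam total, since both are checked
quantities).  Fail iff deviation **strictly exceeds** tolerance, so a
deviation exactly at tolerance passes, and positive and negative deviations
of equal magnitude receive identical statuses.  Identity fields (names,
IDs, serials, dates, counts) compare exactly.  *Warn* is reserved for
non-safety findings: fraction number beyond the prescribed course, missing
screen captures, the degenerate fluence denominator.  Beams are matched
plan↔log by `beam_id`, falling back to (head, gantry within tolerance);
an unmatched plan beam is an incomplete delivery and fails, as does an
unplanned delivered beam.  Per-leaf comparisons aggregate to one MLC result
per segment carrying the worst deviation and naming the offending leaf when
over tolerance, keeping the report at one row per checked item.

## File dialects

The vendor's plan-overview and log formats are proprietary, so the package
defines its own line-oriented `KEY = value` dialect in `[SECTION]` blocks
with a versioned `FORMAT_VERSION = 1` header (unknown versions rejected).
Times serialize at 3 decimals (ms), positions and gantry at 2 (0.1 mm /
0.01°) — below every tolerance — and the generator quantizes to the same
resolution, so write→parse round-trips are exact identities.  Parsers are
strict: missing sections/keys, unknown keys, wrong leaf counts and
non-numeric values raise errors naming the line; no required field is ever
silently defaulted.  The same strictness applies to the configuration XML
(unknown elements or attributes are errors, so a misspelled tolerance
cannot fall back to a default).  Screen captures are embedded in the report
but never analyzed; a missing capture is a recorded warning.

The delivery log carries a prescription section in addition to patient and
plan identity, so a delivered plan whose daily dose was changed (e.g. 2 Gy
→ 1.8 Gy) is detectable from the log alone.

## Synthetic data

The generator is the package's data source for tests and demos.  Plans are
reproducible per seed: rectangular or staircase apertures 2–10 cm wide over
4–12 contiguous leaf pairs (remaining pairs closed at a common junction),
segment times uniform in [1, 60] s, beam groups 120° apart with heads
assigned in order.  `simulate_delivery` produces the log a well-behaved
machine would write: times stretched by each head's decay, optional
Gaussian jitter on gantry/leaves/times (defaults zero; "realistic" jitter
is taken as 10% of each tolerance).  `inject_error` applies exactly one
error from a twelve-kind catalogue, leaving every other field identical;
`interruption_split` takes a delivered fraction as magnitude so it models
both a resumed interruption (1.0 — verifies clean) and an aborted one
(< 1 — fails).

What the generator does **not** emulate: real patient anatomy or dose,
leaf-end penumbra and transmission, scatter, systematic MLC calibration
drifts, or vendor file quirks.  Passing tests therefore demonstrate the
correctness of the comparison logic and its boundaries under controlled
conditions, not parser robustness against real vendor exports.

A geometric caveat worth knowing: under leaf jitter the fluence criterion
is edge-dominated — a δ-cm edge shift changes an edge pixel's value by
t·δ/spacing, which exceeds 2% of max long before δ reaches the 2 mm leaf
tolerance.  The pass rate then hinges on the fraction of evaluated pixels
lying in the edge band, which shrinks with finer grids and larger
apertures.  At the default 1 mm grid and the generator's aperture sizes,
jitter at 10% of tolerances keeps pass rates comfortably above 90%
(observed worst ≈ 94% over 50 seeds); a much coarser grid would not.

## Numerical choices

- Raster coverage is clipped to [0, 1] after accumulation to guard float
  accumulation; leaf rows are disjoint so this is a no-op in exact
  arithmetic.
- Interruption partials must sum to the recorded segment time within 10⁻⁶ s
  (absolute), comfortably above float noise at ms serialization.
- Source strength/rate must share one decay factor within 10⁻⁶ relative at
  construction (data consistency), distinct from the 10⁻³ *check* tolerance
  against the recomputed reference decay.
- `leaf_offset` injection pushes the partner leaf when the offset would
  cross it (one pair cannot physically interdigitate); the position error
  remains on the targeted leaf.
- Bisection over injected magnitudes brackets the detection boundary to
  ~6×10⁻⁸ after 24 halvings; boundaries land on the configured tolerances
  because the comparison is strict-greater.

## Problem sizes

Tests and the acceptance script run on deliberately small conditions: plans
of 1–3 groups × 1–3 beams × 1–4 segments, 100 apertures for conservation,
supersampling oracles on sampled pixels (100 × 100 sub-pixels each, i.e.
0.01 mm at the default grid), 50 seeds for the zero-error sweep, 100
round-trips.  These sizes were chosen as the smallest that exercise every
code path and boundary; all results are deterministic given the seed.

## Report

The HTML report is self-contained (stylesheet inlined from an external CSS
file, images base64-embedded): plan/fraction header, overall verdict with
pass/fail/warn counts, setup captures, source table, the full results table
(one row per result, failures highlighted), and per-beam fluence statistics
with planned / delivered / difference images.  Fluence images are scaled to
the planned maximum; the difference image shares that scale symmetrically
in magnitude, so an error-free delivery renders an all-black difference
map.  PDF export renders the same content through matplotlib's PDF backend
and is optional at runtime — HTML is always produced.

## Known limitations

- Only 2D intensity difference is computed; no gamma analysis with
  distance-to-agreement, no dose reconstruction.
- Couch and collimator parameters are not modelled (not part of the checked
  set for this machine class).
- Single-fraction reports only; no cross-fraction aggregation.
- The dialects are this package's own; real vendor exports and DICOM-RT
  Plan/Record are out of scope.
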