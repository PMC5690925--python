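# cobaltqa

Automatic daily treatment-delivery verification and reporting for a
three-head cobalt-60 radiotherapy machine with 30-pair multileaf
collimators (MLC).

## The problem

On an MRI-guided cobalt-60 system, each treatment fraction is delivered
step-and-shoot: the plan is a set of *beam groups* (1–3 beams at gantry
angles 120° apart, one per treatment head), each beam a sequence of
*segments* — a static MLC aperture plus a beam-on time.  The machine writes
a delivery log at the end of every fraction, but without tooling a physicist
must compare that log against the plan line by line.  `cobaltqa` automates
the comparison and produces a single archivable daily report, so
therapists, physicians and physicists can verify the accuracy and
completeness of every delivery immediately after it finishes.

Two subtleties make this more than a diff:

1. **Source decay.** Planned beam-on times are defined at the nominal
   planning dose rate (1.85 Gy/min at new-source installation).  Cobalt-60
   decays with half-life T½ ≈ 5.2711 y, so the machine stretches every
   delivered time by `nominal_rate / day_rate`.  All time comparisons are
   made on the nominal scale — logged times are normalized back by the
   delivering head's day rate — which also catches logs that report times
   *without* the decay correction.

2. **Fluence comparison.** Per-beam parameter checks can miss compensating
   errors, so each beam's integrated primary fluence map is composed at the
   isocenter plane:

       F(x, y) = Σₖ tₖ · Aₖ(x, y)        [seconds]

   where `tₖ` is segment k's beam-on time and `Aₖ` its aperture indicator,
   rasterized area-weighted from the MLC leaf positions.  Pixels where the
   planned map exceeds 10% of its maximum are evaluated; a pixel passes if
   |delivered − planned| is under 2% of that maximum; the beam is
   acceptable at a pass rate ≥ 90%.

Every checked quantity carries a tolerance (defaults 0.5° gantry, 2 mm per
MLC leaf, 0.2 s beam-on time, all user-configurable in an XML file along
with the reference source calibration data).  A deviation strictly greater
than its tolerance fails; the overall fraction verdict is *fail* iff any
individual check fails.

## Worked example

Generate a synthetic fixture pair (plan overview + delivery log + matching
configuration) and verify it:

```
$ cobaltqa generate --seed 11 --out demo/fx --groups 1 --beams-per-group 2 --segments 2
... INFO fixtures written to demo/fx
$ cobaltqa check --plan demo/fx/fixture.plan.txt --log demo/fx/fixture.log.txt \
                 --config demo/fx/config.xml --out demo/out
... INFO running verification checks
... INFO verification pass: 48 pass / 0 fail / 0 warn
... INFO wrote demo/out/report.html
... INFO done in 0.07 s
$ echo $?
0
```

The 48 results cover patient identity, prescription, the three sources'
serials / calibration data / decayed dose rates, beam count, and per beam:
gantry, segment count, total time, per-segment MLC and time, and the
fluence pass rate (100.0% here — the report's difference maps are all
black).  Exit code 0 means the delivery verified clean; 1 means at least
one check failed (the report is still written, failing rows highlighted);
2 means the inputs could not be parsed.

Injecting a delivery error flips the verdict.  With a manifest
`[{"kind": "gantry_offset", "magnitude": 0.7, "beam_id": "G1B1"}]` passed
to `generate --errors`, the same check exits 1 and the report highlights
exactly one row: `Gantry angle (beam G1B1)`, planned 179.74 vs delivered
180.44, tolerance 0.5.  The full injectable catalogue covers gantry/leaf/
time offsets, beam weighting changes, skipped beams and segments, wrong
patient or plan version, decay-uncorrected log times, interruptions
(resumed interruptions verify clean; aborted ones fail), wrong source decay
data and closed-pair junction walks.

The same workflow is available as a library: `generate_plan`,
`simulate_delivery`, `inject_error`, `verify_delivery`, `render_report`.

## Layout

- `src/cobaltqa/datamodel.py` — domain types (plans, records, sources, tolerances)
- `src/cobaltqa/fileio.py` — plan/log text dialect, XML config, screen captures
- `src/cobaltqa/decay.py` — cobalt-60 decay and time-scale conversion
- `src/cobaltqa/fluence.py` — aperture rasterization, map composition, pass rate
- `src/cobaltqa/checks.py` — the comparison engine
- `src/cobaltqa/report.py` — HTML report (self-contained) and PDF export
- `src/cobaltqa/synthgen.py` — synthetic plans, simulated deliveries, error injection
- `src/cobaltqa/cli.py` — `cobaltqa check` / `cobaltqa generate`

See `docs/methods.md` for the model, conventions and design choices.
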