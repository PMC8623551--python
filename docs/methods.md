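# Methods

## Assay model

A 384-well plate holds up to 4 phages × 22 strains in technical triplicate:
strains across columns, each phage in a block of three replicate rows,
three untreated-control rows (bacteria without phage), one sterility row
(medium + phage) and a few medium blanks. OD600 is read every 30 minutes
for 24 h (Salmonella/Pseudomonas presets, TSB) or 40 h (Listeria preset,
BHI) at 25 °C, with bacteria and phage mixed in equal volumes at
10^7 CFU/mL and 10^7 PFU/mL — a theoretical input MOI of 1.

## Curve statistics

- **Detection time** is the time of the first reading at or above the
  threshold (default OD 0.2), with no interpolation. Detection is therefore
  resolved to the reading grid: all delays and inhibition times are
  quantized to one interval (0.5 h by default). This is deliberate — it is
  reproducible, transparent, and matches the lookup semantics of
  spreadsheet-based analysis of 30-min readings.
- **Rolling growth rate** is the least-squares slope of the trailing
  `slope_window` readings (default 3) against time, not a finite
  difference; least squares is symmetric to read noise. A well shows a
  **growth trend** when any rolling slope reaches `min_growth_rate`
  (default 0.02 OD/h).
- **Blank correction** (off by default) subtracts the per-timepoint mean of
  blank wells and clamps at 0, since OD cannot be negative.

The note-worthy ambiguity: "average growth rate of the last three growth
rate readings" could also denote a slope of slopes in spreadsheet practice.
This package exposes the rolling slope of the readings themselves; the
growth-trend gate only asks whether growth ever exceeds a small rate, for
which either reading is equivalent on real curves.

## Designation rules and boundaries

Delay bins are left-closed, `[1, 5)` h for D and `[5, …)` for D+,
following the "≥" convention of the class definitions; endpoint-ratio bins
are right-closed, `≤ 0.40`, `(0.40, 0.70]`, `(0.70, 0.85]`, because the
deepest class is defined with an explicit "≤ 40 %". A sample detecting
exactly at the final reading is D+ — "never reaches the threshold" is
strictly false. These choices make the rule a total partition, which is
property-tested including the exact boundary values.

## Control aggregation and QC (design choices)

The per-strain control detection time is the mean (configurable median)
over control replicates that both reach the threshold and pass the
growth-trend gate; if none do, the strain fails QC and all its treatments
are reported as not-evaluable — never silently dropped. Sterility wells
that reach the threshold flag phage-stock contamination; blanks whose OD
range exceeds 0.05 flag medium contamination. The control-aggregation rule
and both QC limits are package design choices where the field has no fixed
convention.

## Replicate consensus and outliers

Each replicate is classified on its own, then a deterministic majority rule
flags a replicate as an outlier when at least three replicates exist and a
strict majority of the *others* agree on a different designation. The
consensus is the modal designation of the unflagged replicates, ties broken
toward the weaker (less inhibitory) class, with strength ordered
C > D+ > D > N/L++ > N/L+ > N/L > N: delay classes outrank endpoint
classes because they postpone growth outright, and deeper endpoint
suppression outranks shallower. An optional secondary screen (off by
default) additionally flags replicates whose detection time is more than
two reading intervals from the replicate median. Classifying the
replicate-averaged curve instead is available via
`ExperimentConfig.classify_mode = "averaged"`; the default is
per-replicate-then-consensus because it is the mode under which outliers
can be identified at all.

## The inhibition score

`T_actual` is completed as the detection delay of the treated culture
relative to the untreated control, floored at 0, capped at `T_max`, with
never-detecting cultures scoring the full `T_max`. This is the only
completion under which `Is = T_actual/T_max` lies in [0, 1], complete
inhibition scores exactly 1 (`I_max`, the normalized ceiling of the score)
and no-effect pairs score 0. Consensus-C pairs are assigned `Is = 1`
directly, so a single outlying replicate that grew cannot leak into the
score. Endpoint-effect (N/L) classes contribute to `Is` only through their
sub-interval delay — the index is time-based by definition — and the
OD_max ratio is reported alongside so endpoint effects remain visible.
Strains whose control fails QC contribute 0 to the sum while `HR_max`
stays at the declared panel size, keeping HRi comparable across phages on
the same panel. HRi is reported on the 0–1 scale; a percent display is a
formatting option only.

## Synthetic plates

The simulator emulates what downstream stages need to see, not phage–host
population dynamics. Untreated growth is logistic,
`OD(t) = OD0 + (K − OD0)/(1 + exp(−r (t − t_mid)))`, with per-strain
parameters drawn once per plate: floor OD0 = 0.05, plateau K ∈ [0.9, 1.1],
rate r ∈ [1.0, 1.4] /h, midpoint t_mid ∈ [5, 7] h — a typical mesophile
crossing OD 0.2 at 4–6 h and reaching stationary phase well inside 24 h.
Phage effects transform the control curve:

- **C**: flat at OD0 (lysis from the start);
- **D/D+**: midpoint shifted right by a delay Δ, mimicking regrowth of
  resistant mutants — the threshold crossing is delayed by exactly Δ;
- **N/L classes**: carrying capacity scaled by a factor f, mimicking
  chronic-infection phenotypes. Scaling K alone would also delay the
  threshold crossing (by ~1.2 h at f = 0.4 under the default kinetics) and
  leak endpoint scenarios into the delay classes, so the midpoint is
  advanced by the closed-form crossing shift, holding the crossing time at
  the control's;
- **N**: the control curve unchanged.

Read noise is Gaussian, i.i.d. per reading, clamped at 0 — adequate for
photometric noise at bench scale; the default sd 0.02 OD is a realistic
plate-reader figure. Δ and f are drawn at least 0.5 h from the 1 h/5 h
delay cutoffs and at least 0.05 from the 0.40/0.70/0.85 ratio edges by
default, so ground truth stays unambiguous under noise (a margin of 0
produces boundary-stress plates). Every generated scenario is re-classified
noise-free at generation time and must reproduce its own label; generation
fails loudly otherwise.

What the simulator does **not** model: mechanistic adsorption/burst
dynamics, partial lysis followed by resistance (curves that dip), diauxic
or non-logistic growth, evaporation and edge effects, well-to-well optical
crosstalk, or correlated (drift-like) noise. Passing the recovery tests
shows the pipeline correctly inverts the designation definitions on curves
that follow them cleanly — it does not certify performance on curve shapes
outside this family.

## Numerical and formatting choices

- Detection grid: all detection-derived quantities are exact multiples of
  the reading interval; tests that compare against continuous ground truth
  allow one interval of slack.
- Plate CSVs are written with `%.10g` floats so write→read round-trips to
  1e-9 and identical seeds give byte-identical files.
- Fractions and HRi are stored unrounded; percentages round to 0 decimals
  only for display.
- Time-unit auto-detection: a header containing "min" means minutes, an
  hour-like header means hours, otherwise values whose maximum exceeds
  3× the configured duration are taken as minutes.
- The three N/L sub-designations are reported individually in tables and
  pooled into one N/L band for stacked-bar display by default.

## Problem sizes

The test suite and the acceptance script run on full simulated plates
(4 × 22 × 3 = 264 treatment wells, 49–81 readings per well), 10,000
randomized classifier inputs and 1,000 random oracle curves — the same
plate geometry as the real assay, chosen so a complete verification run
finishes in seconds on a laptop.

## Known limitations

- The index is time-based: phages acting purely on the endpoint (chronic
  infection) score near 0 however strong the OD_max suppression; consult
  the designation and OD_max-ratio columns for those.
- Detection resolution is one reading interval; very small true delays
  (< 30 min) are indistinguishable from none.
- A strain panel is assumed constant across the phages being compared;
  HRi values from different panels or conditions are not comparable.
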