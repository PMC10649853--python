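# Methods

## Data model

A compound's profile is the matrix of log10 ratios (treated vs. vehicle
control) over (cell system, biomarker, concentration). The package stores
values only on this scale; raw optical densities or fluorescence are out of
scope. The reference panel is 12 stimulated primary human cell systems
(ids 3C, 4H, LPS, SAg, BT, BF4T, BE3C, CASM3C, HDF3CGF, KF3CT, MyoF,
lMphg) with ~148 biomarker readouts in total; dose grids are
compound-specific, strictly ascending, length ≥ 2 (four in the reference
study: e.g. 1.9/5.6/17/50 µM for C15:0, 0.3/1/3/9 µM for rapamycin,
190/560/1700/5000 µM for metformin, 1.1/3.3/10/30 µM for acarbose).

Biomarker names are canonicalized through a packaged synonym dictionary
plus case/hyphen/whitespace folding, because the printed tables spell the
same readout several ways (PAI-1/PAI-I, TIMP-1/TIMP1, Esel/E-selectin,
Eot3/eotaxin-3, ITAC/I-TAC, Col-I/collagen-I, TM/thrombomodulin,
TF/tissue factor, MMP9/MMP-9, sIgG/IgG, …). A bare "proliferation" is
qualified by its system's proliferation format (3C/4H → endothelial cell,
SAg → T cell, BT → B cell, CASM3C → coronary artery, HDF3CGF →
fibroblast), since the tables use the bare and qualified names
interchangeably for the same readout. Unknown names pass through with
whitespace collapsed and a one-time warning; the mapping is total and
idempotent. The dictionary is necessarily partial: the full 148-readout
name list is not published, so only table-appearing names are covered.
The system id printed "/Mphg" is canonicalized to "lMphg".

## Significance envelope

The envelope for a readout is a symmetric interval [−h, +h] centered at 0
(no change), sized to cover a stated fraction (default 95%) of the
historical vehicle-control distribution for that (system, biomarker).
Two deliberate readings are baked in:

- It is a **tolerance band for individual readouts**, not a confidence
  interval of the control mean. A mean CI shrinks as 1/√n with control
  count and would flag nearly every treated readout; the envelope's job is
  to gate single treated measurements against typical vehicle variability.
- It is **centered at zero**, not at the control mean: controls define
  width only. This matches the band's description as symmetric upper and
  negative lower bounds around no-change.

Estimators: `normal` sets h = z₁₋α/₂ · s with s the ddof-1 sample SD
(z ≈ 1.959964 at 95%); `empirical` takes max(|q₍α/₂₎|, |q₁₋α/₂|) of the
sample (numpy linear-interpolation quantiles). Readouts with < 2 control
replicates fall back to a configurable default half-width (0.1, matching
the effect-size threshold — conservative and scale-consistent); zero
variance gives a zero-width envelope. Boundary values classify as
*inside*: "outside the envelope" is strict everywhere.

## Activity calling

Thresholds (all configurable, defaults in `AnnotationConfig`):
effect size 0.1 |log10 ratio| (a 20% change), minimum run length 2,
cytotoxicity −0.3 (a >50% viability loss), antiproliferative −0.1, broad
cytotoxicity 3 systems. All comparators are strict; values exactly at a
threshold never qualify.

**Hits** are per-dose: outside the envelope and |value| > 0.1.

**Dose-dependent activities** are runs: per readout, each tested dose is
classified up/down/inside; maximal runs of ≥ 2 *adjacent* doses sharing one
side qualify if their peak |value| exceeds 0.1. Key conventions:

- Every dose in the run must itself be outside the envelope on the shared
  side (the stricter of the two possible readings of "changed in the same
  direction … were outside"; the looser one — agreeing deltas with a single
  significant dose — would not reproduce the sparsity of the reference
  annotations).
- Runs are maximal: a qualifying 3-dose run is one activity, not two
  overlapping 2-dose activities.
- At most one activity per (system, biomarker, direction). Two disjoint
  same-direction qualifying runs cannot occur on a 4-dose grid; on longer
  grids the run with the larger peak wins (tie: lower doses).
- A U-shaped response crossing zero can yield both an up and a down
  activity for one readout; both are reported and counted separately, and
  the *modulated* label marks biomarkers annotated up in one system and
  down in a different system.

**Viability flags**: viability-class channels (SRB/alamarBlue at assay
density) below −0.3 flag a (system, dose) cytotoxic; proliferation-class
readouts (cells plated at lower density) below −0.1 flag antiproliferative.
One concentration suffices. A dose cytotoxic in ≥ 3 distinct systems is
excluded from hit calling and annotation; the excluded dose keeps its grid
slot, so an excluded *interior* dose breaks run adjacency (the tested
series eligible for annotation is what "consecutive" refers to). Viability
channels are themselves eligible as hits/activities by default (the
reference optimal-dose table lists "↓ SRB" entries); a config switch
removes them from tallies.

## Comparison

The optimal dose is the argmax of per-dose hit counts, ties to the lowest
dose (conservative dosing; no tie occurs in the reference counts). Shared
activities require equality of (system, canonical biomarker, direction) —
direction-mismatched pairs (e.g. one compound raising and the other
lowering E-selectin in lMphg) do not match. System-coverage percentages
are reported rounded to the nearest integer over the 12-system panel.

`reproduce_reference_report` recomputes 23 printed claims from the packaged
table transcriptions. Seven are genuine internal inconsistencies of the
printed tables and are reported as discrepancies, never reconciled:

- the per-compound grand totals (36/32/17) exceed the per-system
  enumerations (34/30/16) — the remainder presumably lives in an
  unpublished appendix;
- the stated 12 dose-dependent C15:0/rapamycin overlaps enumerate to 13;
- the stated 11-across-5 optimal-dose C15:0/metformin overlap recomputes
  to 13 across 6 (↓IL-8 in 3C and ↓tPA in BE3C also co-occur);
- the stated single C15:0/acarbose overlap recomputes to 2 once TIMP1 and
  TIMP-1 are recognized as the same MyoF readout.

Per-dose hit counts themselves are transcription inputs to the optimal-dose
rule, not recomputed outputs, because the underlying per-biomarker profiles
are not published.

## Synthetic panels

The generator emulates the reference layout: 12 systems × 12 biomarkers
(~148 readouts, near the panel's 148; exact per-system counts are not
published) plus one SRB viability channel per system, 4 ascending doses
(default grid 1.9/5.6/17/50), i.i.d. Gaussian vehicle noise with sd 0.025
log10 units, and 100 control replicates per readout. The noise sd was
chosen so that the 95% normal envelope half-width (≈ 0.049) sits well below
the 0.1 effect-size threshold, as the two-condition hit definition
presupposes; the injected default amplitude 0.3 mirrors a strong but
realistic screening effect (a 2× change).

Shapes: monotone = a ± amplitude step from an onset dose; u_shape =
amplitude at an interior peak and half-amplitude at its neighbors
(activity falling off again at the top dose); threshold_onset = a linear
ramp to full amplitude at the top dose; null = zero. The shape enum in the
container carries a separate `direction` field because a U-shape or ramp
has no inherent sign. Noise is independent across doses and readouts — no
within-series correlation, no plate effects, no heteroscedasticity across
biomarkers — so passing recovery tests demonstrate the correctness and
calibration of the *rules*, not robustness to structured real-assay
artifacts.

Ground truth: `expected_annotations` are what the annotation rules yield on
the noise-free signal under a stated envelope half-width (default: the
noise model's own 95% band). Hence as noise → 0 the pipeline must recover
the truth exactly, and recovery metrics are well defined at any noise
level. Determinism: controls and profile use separate streams spawned from
the panel seed, so identical seeds give byte-identical outputs.

## Benchmarks and problem sizes

Null calibration uses a 25,000-readout all-null panel (100,000 readout-dose
classifications, 100 control replicates each); the achieved outside rate at
95% envelopes is ≈ 5.2% — slightly above nominal because the z·s band with
n = 100 estimated SDs is marginally anti-conservative relative to a
t-based band; this bias is well inside a percentage point and shrinks with
control count. Dose-dependent false annotations are bounded by the union
bound 3p² (three adjacent pairs, two same-side outside calls each); the
0.1 effect-size gate at 4 noise SDs makes the realized rate ≈ 0.

The recovery benchmark runs 500 replicate panels of 4 systems × 6
biomarkers with two monotone effects per system (one per direction,
amplitude 0.3, onset dose 2) under the fixed 1.96σ envelope — sizes chosen
to give tight Monte-Carlo estimates (4,000 injected effects, 12,000
readouts) while keeping the whole suite fast.

## Known limitations

- Envelopes are per (system, biomarker); per-biomarker-global or panel-wide
  alternatives were not examined (control structure is not published).
- No multiple-testing correction across the ~148 biomarkers (none is
  applied in the reference procedure) and no dose-response curve fitting
  (EC50/Hill) — the rules are purely threshold/run based.
- The synonym dictionary covers only table-appearing biomarkers; vendor
  exports and plate-level data are out of scope.
- Profile plots (arrow glyphs, envelope overlays) are not reproduced.
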