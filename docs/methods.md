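# Methods

## Coordinate and measurement conventions

All geometry lives in the 2-D sagittal image plane, **+x anterior, +y
superior, units mm**. Landmarks are digitized points — four
vertebral-body corners per vertebra, one or more canal point pairs
(posterior body wall ↔ spinolaminar line), and an optional osteophyte
flag; no pixel data is handled.

Per motion segment and view the pipeline measures:

- **A, B** — Euclidean distances between the facing anterior
  (respectively posterior) corners of the two vertebrae bounding the
  disc.
- **C** — distance between the midpoints of the superior and inferior
  endplates of the inferior vertebra.
- **angular displacement** — the acute angle (0–90°) between the two
  endplate *lines* bounding the shared disc: the inferior endplate of
  the upper vertebra against the superior endplate of the lower one.
  This shared-disc convention measures the same disc wedge the
  curvature index captures; an inferior–inferior (segmental Cobb)
  convention is available via `angle_convention="inferior_inferior"`,
  and a signed variant is exposed for generator round-trip checks.
- **horizontal displacement** — signed perpendicular distance from the
  posteroinferior corner of the upper vertebra to the posterior-margin
  line of the lower vertebra. The phrase "anterior side" is resolved in
  the image frame (+x), so the sign is stable for any film orientation
  within 90° of upright and flips under film mirroring. Positive =
  anterolisthesis.
- **canal diameter** — minimum over the supplied canal point pairs.
  When a vertebra is osteophyte-flagged, the annotator must supply
  osteophyte-aware pairs (digitized clear of posterior osteophytes or
  ligament calcification); the measurement refuses to fall back
  silently.

**Repeats and rounding.** Up to three repeat digitizations are measured
independently; the repeats are averaged first and the average rounded
once — lengths to the nearest 0.01 mm, angles to the nearest degree,
ties away from zero. Rounding to the *nearest* increment was chosen
over ceiling rounding: ceiling would bias every length upward and defeat
the purpose of averaging. The rule lives in one function
(`round_half_away`) with a 1e-7 relative guard so decimal inputs such as
4.005 round as intended despite binary floating point. Indices are
computed from the rounded measurements, i.e. from the numbers an
observer would actually have recorded.

**Missing data.** A missing landmark invalidates only the segment/view
that needs it (NaN + `complete=False`); a view's CCI requires all five
segments, the ROM index both dynamic views. Degenerate geometry (zero
central height, coincident posterior corners, zero-length endplates)
raises instead of returning a number.

## Indices and the instability rule

SCI = (A − B)/C per segment; CCI = Σ SCI over C2/C3…C6/C7 (exactly
those five segments); ROM = CCI(extension) − CCI(flexion), oriented so a
normally mobile spine is positive; HDI = |d|/c with c the canal diameter
of the *inferior* vertebra (displacement is measured relative to it);
MHDI = HDI(flexion) + HDI(extension). All threshold comparisons are
inclusive: a segment is unstable iff MHDI ≥ 0.30, and the nested
reporting categories are MHDI ≥ 0.20 / 0.25 / 0.30.

"Displaced segment" incidence needs a per-view HDI cutoff that has no
published definition; it is exposed as `tau_displaced` (default 0.10)
and clearly labelled a reporting convention, not a clinical threshold.
Incidence denominators are exact trial counts: subjects × 5 segments for
the neutral view, × 2 additionally for the combined flexion–extension
assessment (each dynamic view is one trial — the only reading consistent
with per-group denominators of 620/590/620 at 62/59/62 subjects).

## Statistical battery

- One-way ANOVA (F, df = (k−1, N−k)) for approximately normal
  quantities (ROM, per-segment MHDI between groups), summarised as
  mean ± SD.
- **Student–Newman–Keuls**: ordered means, studentized-range statistic
  over each stretch of p adjacent means against q(1−α; p, df_error),
  stepwise with the containment rule (a non-rejected stretch closes all
  comparisons inside it). Unequal group sizes use the harmonic mean of
  all group sizes, the convention of classical packages. Critical
  values come from the studentized-range distribution and are cached
  (the quantile is expensive). The gated ANOVA→SNK pipeline holds its
  familywise null error near nominal (measured ≤ 0.07 at α = 0.05 over
  2 000 simulations in the test suite).
- Kruskal–Wallis (tie-corrected, χ² approximation) for skewed
  quantities (per-view CCI, within-group MHDI), summarised as
  median (Ql, Qu). Fully tied data return H = 0 rather than an error.
  As a post hoc an **SNK-on-ranks analog** is provided (the SNK
  procedure applied to jointly rank-transformed data). This mirrors
  common clinical-software practice but is not a distribution-free
  guarantee, and is labelled as an analog.
- Pearson χ² without continuity correction for count data (the
  uncorrected statistic is what the incidence tables reproduce), and a
  **partitioned χ²** for multiple comparisons: all pairwise 2×c
  sub-tables at Bonferroni-adjusted level α/k. The named partitioning
  method has no canonical definition; the pairwise-with-adjustment
  reading was chosen and is tested against the Lancaster-style additive
  decomposition on random tables.
- Pearson correlation with the two-sided t-transform p-value for the
  angular-vs-horizontal-displacement association, computed over pooled
  dynamic segment-views.
- Quartiles default to linear interpolation between order statistics
  (numpy's default); the convention is configurable because published
  two-decimal quartiles cannot adjudicate it. α = 0.05 throughout.

## Synthetic cohort generator

The generator is the pipeline's test substrate: it emulates a
three-group study — 62 subjects with neurological deficits (group I),
59 with neck pain only (group II), 62 healthy controls (group III) —
with three views per subject and three repeat digitizations per view.

Targets are specified **on the index scale** (the reporting scale) and
the generator solves backwards to geometry; anatomy is nuisance. Default
group targets carry the published group statistics: per-view CCI
location/spread (spread recovered from quartiles as IQR/1.349 where only
quartiles are published), ROM means ± SD (1.19 ± 0.42 / 1.59 ± 0.49 /
1.73 ± 0.40), and per-segment MHDI means ± SD. Neutral-view HDI levels
(mean 0.05–0.06, SD 0.05) were chosen once so that neutral incidences at
tau = 0.10 fall in the reported ≈ 18–23 % band. Anatomy priors are
generic adult values: vertebral central height 15 ± 1 mm, endplate width
16 ± 1.2 mm, canal diameter 13.5 ± 1.1 mm, mean disc height 6 mm,
landmark noise SD 0.2 mm per coordinate per repeat.

Distribution shapes are a choice (only locations and spreads are
published): normal for curvature quantities, zero-truncated normal for
MHDI and neutral HDI. Per-subject curvature is drawn as
(CCI_neutral, CCI_flexion, ROM) with CCI_extension = CCI_flexion + ROM,
then spread over segments with mean-centred jitter (SD 0.05) so the sum
is preserved. Each segment's MHDI draw is split between flexion and
extension by a uniform (0.25, 0.75) fraction; flexion translation is
anterior, extension posterior (both configurable), neutral sign random.

**Exact inverse construction.** For a segment with targets sci and hdi
(translation t = sign·hdi·c), disc height D and inferior central height
C, the anterior/posterior space heights are set to A = D + sci·C/2,
B = D − sci·C/2, and the upper vertebra's inferior corners are placed at
PS + t·u + √(B²−t²)·v and AS + t·u + √(A²−t²)·v in the lower vertebra's
orthonormal endplate frame. Measured at zero noise, A, B and t are
recovered *exactly* (verified to rounding granularity), so index
recovery errors isolate digitization noise. Infeasible deterministic
targets (non-positive disc height, |t| ≥ disc space) raise an error
naming the segment; stochastic tail draws are clipped to the feasible
region and the clipped values recorded in the truth table, so
parameter-recovery comparisons are against what was actually injected.

**RNG contract.** One root seed; each subject gets an independent
substream keyed by (seed, group, subject index), so enlarging a cohort
never reshuffles existing subjects, and identical config + seed
reproduces identical bytes.

**What the generator does not emulate.** No biomechanical coupling
(curvature and displacement are drawn independently per subject), no
age–index dependence (age structure is not modelled although the
emulated groups differ in age), no osteophytes, no missing landmarks,
and isotropic Gaussian digitization noise rather than observer-specific
error. Passing tests therefore demonstrate fidelity of the measurement
and statistics chain, not clinical realism of any single synthetic film.

## Calibration tensions in the emulated study

The published group summaries are not mutually consistent, and the
generator follows the index distributions where they conflict with the
count tables:

- With per-segment MHDI ≈ 0.33 ± 0.14–0.23 in group I, the expected
  share of segments at MHDI ≥ 0.30 is ≈ 50 %, not the ≈ 16 % the
  published unstable-segment counts imply. The default cohort therefore
  reproduces the *ordering* of unstable-segment counts (I ≫ II ≥ III)
  but not their magnitudes.
- Likewise group I's reported *lowest* dynamic displaced-segment
  incidence (25.65 %) cannot coexist with its highest MHDI
  distribution under any per-view cutoff; the default cohort shows
  group I highest. The exact printed incidences and their χ² statistics
  are instead reproduced directly from the printed counts, which is how
  they enter the acceptance script.

## Problem sizes used

Tests and the acceptance script run the full 62/59/62 default cohort
(one to twenty seeded replicates depending on the check), 2 000 null
simulations for the post-hoc error-rate check, and 500 random tables for
the χ² oracle; together they complete in well under five minutes on one
CPU.

## Known limitations

- Landmarks are the input; automatic landmark extraction, DICOM/PACS
  handling and image processing are out of scope.
- The horizontal-displacement construction is the standard
  listhesis construction (corner to posterior-margin line); the verbal
  description it derives from is ambiguous, so the sign convention and
  construction are configurable and documented rather than guaranteed to
  match any specific historical implementation.
- No angular-displacement instability criterion is provided (angular
  and horizontal displacement are empirically uncorrelated and no
  angular threshold is defined for the index method).
- The SNK-on-ranks post hoc and the pairwise partitioned χ² are named
  analogs of loosely specified procedures; both are documented above.
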