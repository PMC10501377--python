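# Methods

## Problem and scope

Non-target HRMS screening asks which of thousands of aligned LC-MS
features in a biological extract are per- and polyfluoroalkyl substances.
This package implements the data-side of that workflow — feature
alignment, the PFAS prioritization cascade, homologous-series detection,
and MS/MS annotation with confidence assignment — for negative-mode,
singly charged ions. Peak picking, acquisition, extraction chemistry and
quantification are out of scope; the pipeline starts from observation
tables (CSV) and centroided MS/MS spectra (MGF).

## Mass arithmetic

All masses derive from a pinned in-package table of monoisotopic atomic
masses (most-abundant isotope, ≥6 decimals; C, H, N, O, S, F, Cl, P, Na,
K). Anion m/z includes one electron mass (0.000549 Da) per charge — many
tools omit it; inclusion is the documented contract here and matters only
below roughly m/z 110 at 5 ppm. The (M+1)/M isotope ratio uses the exact
single-substitution identity Σ nᴇ·(pᴇ/qᴇ) over ¹³C, ²H, ¹⁵N, ¹⁷O, ³³S;
higher isotopologues and M+2 elements (Cl, K) are out of scope because the
suspect-screening criterion only uses the first isotope.

The Kendrick transform uses the conventional rounded CF2 constant
(KM = m/z × 50/49.996806, KMD = nearest-integer(KM) − KM, ties-to-even),
while exact-mass arithmetic uses the full-precision table. With the
rounded constant, KMD is exactly invariant (to 1e−9) under shifts of
k × 49.996806, the property the homologue logic relies on. Ring-and-
double-bond equivalents C − (H+F+Cl)/2 + (N+P)/2 + 1 are returned
half-integral for ionic/radical compositions rather than raising, since
RDB is only a plausibility screen.

Two printed fragment annotations in the source spectra are internally
inconsistent (an NO2S⁻-mass fragment labelled SO3⁻; a CH3NO2S⁻-mass
fragment ~11 ppm from its printed value). The fragment tables carry
theoretical masses with comments; the 0.01 Da MS/MS tolerance absorbs the
offsets.

## Filter cascade

Filters are independent predicates; `prioritize` records a flag per filter
for every feature so the survivor set equals the conjunction of the
individual pass-sets (tested against a brute-force oracle), and relaxing
any threshold can only grow the survivor set.

- **Alignment**: greedy clustering seeded by descending intensity (m/z,
  RT, run-id tie-breaks for determinism); members within 0.02 Da and 30 s
  of the seed; per-injection intensity is the max over members; consensus
  m/z and RT are intensity-weighted means. Greedy seeding is reproducible
  without vendor algorithm details and matches transitive-closure
  clustering whenever clusters are well separated.
- **Replicate RSD** (< 20%, raw intensities): computed per case pool over
  its triplicate injections; a feature passes when at least one case pool
  detects it in all injections with RSD below the cap. The pooled-sample
  design makes "present in all triplicates" a per-pool statement; raw
  rather than log intensities because the criterion is defined on the mean
  intensity.
- **Blank ratio** (> 10×, strict): mean intensity over all case injections
  against the *maximum* procedural-blank intensity — maximum rather than
  mean as the conservative reading; configurable. Blank-absent features
  pass when detected in cases.
- **RT window** 1–13 min and **KMD window** −0.15..0.15, both inclusive;
  strict inequalities are used only where the criterion is stated as
  strict (RSD, blank ratio, fold change, p).
- **Case-control selection**: pool-level mean intensities (4 vs 4), zeros
  imputed at 0.5 × the smallest positive intensity in the whole aligned
  table (avoids infinite fold changes; table-wide floor keeps
  control-absent features strongly ranked), log₂ transform, Welch
  unequal-variance t-test (Welch–Satterthwaite df; both-groups-degenerate
  case: p = 1 when means are equal). Fold-change base is configurable;
  log₂ with threshold 0.9 (≈1.87-fold) is the default convention. No
  multiple-testing correction by default (raw p < 0.05 is the stated
  criterion); Benjamini–Hochberg is available but off.

## Homologous series

Series detection formalises the visual KMD-plot reading: an edge joins two
features when their m/z difference is within 0.01 Da per unit step of an
integer number (1–12) of repeat-unit masses and their KMDs differ by
≤ 0.005; connected components are pruned (drop the farthest member
iteratively) until every KMD is within 0.005 of the component mean.
Tolerances were chosen so that a measured two-unit C2F4 spacing ~2 mDa off
theory still links, while 2 ppm mass noise (~1 mDa at m/z 500) stays well
inside. Repeat units: CF2 default; C2F4, CH2, C2H4O available; automatic
unit discovery is a non-goal. RT consistency demands retention increasing
with m/z (reversed-phase convention) with a configurable slack per unit.

## Annotation and confidence

The library **fit score** is an intensity-weighted coverage: 100 × matched
library intensity / total library intensity within 0.01 Da — 100 means the
library spectrum is fully contained in the unknown's. (The vendor score it
stands in for is proprietary; equivalence of thresholds is not claimed —
they are calibration parameters.) A library hit requires < 5 ppm mass
error, score ≥ 80 in ≥ 3 replicate spectra, and homologue-consistent RT.
Suspect hits require < 5 ppm and, when an observed M+1 ratio exists, < 5%
isotope-ratio difference (skipped, not failed, when absent — SWATH
features often lack a clean M+1). Diagnostic-fragment rules list required
fragments/neutral losses and optionally forbidden fragments (the
N-methyl-sulfuramidous class requires the sulfonate SO3⁻ to be absent).

Confidence follows the PFAS 1a–5b ladder, implemented as a deterministic
decision list from strongest to weakest evidence: 1a library + standard
RT; 1b library MS/MS only; 3a class-consistent MS/MS with positional
isomer candidates; 2a diagnostic fragments for a known (suspect-supported)
structure; 2b literature-spectrum match; 3b fragmentation-only novel
proposal; 4 unequivocal formula; 5a suspect exact mass; 5b exact mass of
interest. Weakening any evidence item never raises the level (tested
exhaustively over single-item downgrades).

## Synthetic data

The generator emulates the pooled study design: 4 case and 4 control
pools, triplicate injections, one procedural-blank pool. Planted classes —
perfluoroalkyl sulfonates (C4–C8), perfluoroalkane sulfonamides
(C4/C6/C8), chlorinated sulfonates (C6–C8) and sulfonamido-propanoates
(C4/C6/C8) — carry exact ion compositions, class fragments, retention
increasing with chain length, Gaussian mass error (σ = 2 ppm, truncated at
5 ppm, matching a < 2 ppm-calibrated instrument), and log-normal
intensities (case median 2–8 × 10⁴ cps by class, between-pool GSD 1.6,
replicate RSD 10%, 5% chance of trace control contamination at 2% of the
case level). Matrix features (500) use a CH2-like mass defect
(+0.0011 Da/Da) so their CF2-KMD is strongly negative; at high mass the
defect can wrap past the next integer back into the PFAS window, and draws
landing inside ±0.15 are redrawn with 90% probability so at most ~10%
mimic PFAS-like defects — the false-positive load the KMD filter must
reject. Matrix features share case/control medians (they should fail the
statistical filter only); 40 blank-derived features sit below the 10×
blank ratio. Intensity distributions in real blood extracts are not
published; the log-normal parameters are declared assumptions.

What passing recovery tests shows — and does not: with these defaults the
cascade recovers every detectable planted feature with no matrix
survivors. Real data differ in ways the generator does not model
(chromatographic coelution, ion suppression, isotope interferences,
in-source fragments, RT drift), so recovery here validates the filter
logic and its thresholds' interplay, not field performance.

## Problem sizes and numerics

Default runs use 554 features × 27 injections (~13k observations), which
keeps the full workflow and test suite to seconds while leaving the
planted:background ratio (14:540) realistic enough that the cascade's
specificity is exercised. Alignment is O(n log n) via m/z-sorted window
queries. Degenerate inputs: empty observation lists align to empty;
fewer than two replicates raise for RSD; zero-variance groups are handled
explicitly in the Welch test; deprotonating a hydrogen-free formula
raises.

## Known limitations

Negative mode and single charge only; no adducts beyond deprotonation; no
isotopic fine structure beyond M+1; no in-silico fragmentation or external
database queries; no PCA/visualization (selection uses fold change + p
only); no batch RT alignment. The suspect list and spectral library ship
as user-supplied CSVs — no curated compound database is bundled.
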