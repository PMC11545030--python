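# Methods

This note documents the models, conventions and design choices of the
package, and what its synthetic data do and do not establish about real
measurements.

## Trajectories and RMSF

A trajectory is a stack of per-residue coordinate frames for one
thermodynamic condition, reduced to one point per residue (the C-alpha
convention — the standard residue-level reduction when fluctuations are
quoted "per amino acid"). Coordinates are nanometres by convention
(documented, not enforced); the multi-model PDB reader/writer converts
to/from the format's Angstrom fields, so round trips are exact to the
format's 10⁻³ Å precision.

Frames are superposed by unweighted least-squares rigid-body fitting over
all residues (proper rotation only; implemented with the standard
least-squares rotation solver). The superposition reference is the first
frame by default; a `mean_structure` policy refits against the mean of
first-frame-fitted coordinates (one refinement pass, the usual fixed-point
approximation). No equilibration discard is applied by default —
equilibration is assumed to precede the analyzed production frames — but a
`discard_frames` option exists.

RMSF is computed about the per-residue **time-average** position (the
standard definition), with an option to measure about the superposition
reference instead for sensitivity checks. Two numerical details:

* A residue occupying exactly one point in every superposed frame reports
  exactly 0 (the zero-iff-static invariant), not summation round-off.
* Superposing a trajectory absorbs 6 rigid-body degrees of freedom out of
  3N per frame, deflating the RMSF of pure uncorrelated noise by a factor of
  about √(1 − 2/N). Calibration checks against the closed form
  RMSF = σ√3 for isotropic per-axis Gaussian noise are therefore run with
  superposition off (the noise contains no rigid motion to remove);
  superposition correctness is established separately by the invariance
  check that a globally rotated/translated copy of a trajectory yields the
  same profile to 10⁻⁸.

## Stability classification and candidate scoring

A residue is *stable* when its RMSF is **strictly** below the
protein-average RMSF of the same profile; ties count as unstable, and a
constant profile has no stable residues. With several conditions
(temperature/pressure series), per-condition masks are combined by a
configurable policy; the default `all_conditions` (logical AND) is the
conservative reading of "stable during processing" — a residue must stay
quiet at every simulated condition. `any_condition` and
`single:<label>` are available because the original choice is not
derivable from the counts alone.

Candidate epitopes carry 1-based inclusive spans. The displayed stable
proportion is `floor(100·k/n)`: truncation is the only convention consistent
with displaying 5/18 as 27 % (rounding would give 28). Selection compares
the displayed percent **inclusively** against the 60 % threshold, since a
candidate at exactly 9/15 = 60 % participates in fusion.

One reported figure is internally inconsistent: the candidate at 138–152 is
printed with counts 9/15 alongside 66 %, but 9/15 displays as 60 %. The
package follows the counts; the printed 66 % is not asserted anywhere.

## Fusion and trimming

Overlapping *selected* candidates are fused. The union span is formed
(spans must overlap or touch, and agree letter-for-letter on the overlap);
the retained sub-span is then chosen among contiguous sub-spans that

1. are reachable by deleting residues only from the two termini,
2. **begin and end on stable residues**, and
3. keep a floored stable percentage ≥ the threshold,

maximizing length, with ties broken toward the later (higher-position)
terminus. Requirement 2 is the load-bearing design choice: without it, a
union that already clears the threshold would never be trimmed at all, and
the documented removal of the unstable N-terminal block 58–65 from the
58–86 fusion (leaving CAQKKIIAEKTKIPAVFKIDA at 66–86) could not be
reproduced by any mask. With it, trimming coincides with stripping terminal
unstable runs whenever the stripped core clears the threshold, and falls
back to threshold-guided shortening when it does not. The rule is exhaustive
to verify (the test suite enumerates all sub-spans independently) and
deterministic.

The screening orchestration fuses greedily by largest overlap first and
re-evaluates the overlap graph after every fusion. This matters because the
candidate at 47–60 also overlaps the one at 58–77 by three residues: fusing
the larger 72–77 overlap first and trimming 58–65 removes the 58–60 overlap
as a side effect, leaving three non-overlapping final peptides — the
published outcome.

Fused sequences are assembled from the parents' own letters; no full-length
reference sequence is required (a cross-check against an optional FASTA can
be layered on top, but all bundled candidates are mutually consistent).

## Peptide design and masses

Each final peptide receives one supplementary C-terminal cysteine as the
dedicated maleimide handle for KLH coupling. The cysteine is appended even
when the sequence already ends in C — the conjugation residue is defined to
be terminal and dedicated — and the event is logged. Theoretical masses are
residue-mass sums plus one water, on both the average and monoisotopic
scales (computed via Biopython's protein molecular-weight tables; the test
suite cross-checks against an independent mass calculator).

## 4PL calibration and inversion

The calibration model is `y = d + (a−d)/(1+(x/c)^b)` with `y` either raw
OD₄₅₀ or B/B₀ (default: B/B₀, with B₀ the mean blank OD, or the mean
zero-concentration standard when no blanks exist). Zero-concentration
observations evaluate to the asymptote `a` and may enter the fit; at least
four distinct positive levels are required, and flat responses raise a
non-identifiability error rather than returning arbitrary parameters.
Initialization: a = max response, d = min response, c = geometric mean of
the positive levels, b = 1; c is bounded positive; convergence tolerances
are 10⁻¹² on the objective, which yields parameter recovery to 10⁻⁶
relative on noise-free synthetic plates. The valid range is the
[min, max] positive standard concentration.

Inversion is algebraic, `x = c·((a−d)/(y−d) − 1)^{1/b}`, with round-trip
identity to 10⁻⁸ inside the valid range. Responses beyond the zero-analyte
asymptote censor **low** (concentration 0); responses at or past the
infinite-analyte asymptote censor **high**. Blank wells inverted for
LOD/LOQ floor censored-low reads at 0 (about half of noisy blanks read
above the asymptote; negative concentrations are not meaningful), and the
flooring is logged.

## Detection limits, conversions and performance

* LOD = blank mean + 3·SD, LOQ = mean + 10·SD, computed on the
  **concentration scale** after inverting ten (configurable) blank reads
  through the curve. Sample SD (n − 1) is used everywhere; the denominators
  are a package convention, stated here because reports rarely print them.
* Extract-to-food conversion multiplies by the extraction ratio k (default
  10 mL buffer per g sample): µg/mL × mL/g = µg/g = mg/kg. The milk-protein
  equivalent divides the food-scale value by the BLG share of milk protein
  (default 0.10). The chain is exactly linear and composable.
* Censored reporting: below LOD → `<LOD`; at/above LOD but below LOQ →
  `<LOQ`; values exactly at LOQ are reported numerically (quantifiable-at-
  LOQ reading).
* P/N = positive OD / negative-control OD; a point is *effective* when P/N
  is **strictly** above 2.1.
* Inhibition rate is exactly `(OD_ctrl − OD_sample)/OD_ctrl × 100`; negative
  rates (sample above control) are returned and flagged, not clipped.
* Recovery = measured/spiked × 100. Intra-assay CV is SD/mean over the
  replicate estimates of one run (validation design: 25); inter-assay CV is
  computed over **all** cross-day values (design: 5 × 5 days), with day
  means reported alongside — per-day means alone do not determine the
  cross-day CV, so the full-data definition is used.

## Synthetic data: what it emulates and what it does not

* Toy backbones are fixed-step (0.38 nm) random walks with soft
  self-avoidance — geometry only, no chemistry. This suffices because every
  downstream computation consumes coordinates, never energetics.
* Fluctuations are per-residue isotropic Gaussians, so the target RMSF is
  known exactly (σ√3) and convergence is O(T^{-1/2}); real trajectories have
  correlated, anisotropic motions and slow modes the generator does not
  emulate. Passing the calibration tests therefore validates the estimator,
  not any claim about real protein dynamics.
* Plate noise is multiplicative Gaussian (constant CV), chosen because
  immunoassay precision is reported as percent CVs; real plates add
  edge effects, drift and heteroscedastic pipetting error beyond this model.
* The bundled full-chain stability mask is a deterministic *reconstruction*:
  the original trajectories are not public, so any mask matching the six
  reported count pairs is admissible; the bundled one also reproduces the
  published fusion outcome. Scoring results on it are exact consequences of
  the counts, not re-derivations of the original simulation.
* Default plate conditions mirror the assay design: positive standards
  0.1–500 µg/mL in triplicate, ten blanks, 5 % read CV (a mid-range value
  consistent with the reported intra-assay CVs of ~6–8 %), true curve
  (a, b, c, d) = (1.8, 1.2, 5.0, 0.06) on the OD scale.

## Problem sizes

Statistical checks use sizes at which their Monte-Carlo error bounds are
sharp but cheap: RMSF calibration at 10⁴ frames (per-residue SE
σ/√(2T) ≈ 7·10⁻⁴ nm), blank-limit and CV sampling oracles at 100–200
repetitions, pipeline-level trajectory tests at 150 frames × 162 residues ×
two conditions, and the trim rule is verified exhaustively for all span
lengths up to 30.

## Known limitations

* Only the multi-model PDB dialect is read/written (no XTC/DCD), C-alpha
  only, no periodic-boundary unwrapping, no mass-weighting.
* The fusion rule is defined for pairs and applied greedily; pathological
  overlap graphs (three mutually overlapping selected candidates of equal
  overlap) are resolved deterministically by the tie-break, not globally
  optimized.
* LOD/LOQ are only computed on the concentration scale; an OD-scale
  alternative is deliberately not offered.
* Cross-reactivity, matrix effects beyond recovery arithmetic, and epitope
  prediction are out of scope; candidate epitopes are inputs.
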