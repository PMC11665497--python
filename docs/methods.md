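# Methods

## Multiplexed design and what is being modeled

Each simulated LC–MS run is one TMT10plex: ten isobaric labels whose MS2
reporter cations differ in their 13C/15N substitution pattern. Reporter m/z
values are computed from elemental composition with the electron mass
subtracted and stored to 5 decimals (126 → 126.12773; N/C isotopologues of
one nominal mass differ by ~6.32 mDa). Nine channels are used per run: six
single cells, one analyte-abundant carrier, one blank and one IS-blank that
carries the heavy-isotope internal standards. The default layout is
carrier = 126, blank = 127N, unused = 127C, cells = 128N…130C,
IS-blank = 131. The channel left empty sits next to the carrier because the
carrier's isotope envelope contaminates its ±1 Da neighbours most strongly;
the layout is configurable since reasonable designs differ on which 127
channel to sacrifice.

Targeted quantitation is scan-level: for every analyte (and for its heavy
internal standard, a separate tPRM transition at +6×13C) the simulator
emits centroided MS2 scans every 0.02 min across ±3 FWHM of a Gaussian
elution profile. The per-channel ideal intensity is
`response_factor × amount × exp(−(t−rt)²/2σ²)` with σ = FWHM/2.3548. The
observed vector is `M·ideal` for an isobaric impurity matrix `M`, plus an
optional phenomenological coalescence bleed (a fraction of the carrier's
intensity added to 127N/127C only — the physics of ion coalescence is not
modeled), plus noise, truncated at zero, then rescaled by
`min(1, agc_target/Σ)` so every scan respects the ion-budget cap. That cap
is what makes reporter data compositional: only intra-scan ratios survive
it, which is why the untargeted branch divides by the carrier channel of
the same scan.

The default analyte panel is ten amino acids with their observed retention
times and peak widths (aspartic acid 13.40/2.15 min through phenylalanine
26.91/0.05 min); cystine and lysine carry two tags and two charges
([M+2TMT+2H]²⁺), the rest one tag and one charge.

## Parameters that matter

| parameter | default | why |
|---|---|---|
| `carrier_amount` | 120 fmol | top of the calibration range; "analyte-abundant" without dominating AGC entirely |
| `is_amount` | 12 fmol | internal-standard load; responses are analyte/IS area ratios, so the true calibration slope is 1/12 per fmol |
| `response_factor` | 1e4 counts/fmol | sets absolute signal scale; with the noise floor below it puts LODs in low attomoles |
| `noise_sd` | 20 counts | additive floor, sampled per channel per scan; drives the S/N-based LOD/LOQ |
| `noise_cv` | 0.02 | proportional (2 %) intensity noise; the term that limits calibration accuracy across the 4-decade range |
| `agc_target` | 1e8 | effectively uncapped for targeted runs; lower it to exercise compositional rescaling |
| impurity matrix | ±1 Da 3–4 %, ±2 Da ≤0.3 % | vendor-CoA-like; ±1 Da lands two positions away in the m/z-ordered channel list (the +1 Da isotopologue of 126 *is* the 127C composition) |
| `tol_mda` | 5 mDa | absolute reporter-match tolerance; simulated mass accuracy is exact, real accuracies are sub-mDa |
| diameters | HEK-293 15.1±1.2, TYK-nu 21.6±1.5, TYK-nu.CP-r 20.0±1.8 μm | put mean spherical volumes at ≈1.8 / 5.3 / 4.2 pL with per-type ranges inside 1.0–8.5 pL |
| concentrations | log-normal, log10 means −2.2…−4.3 mol/L, sd 0.25 | low-mM to high-μM cellular amino acid levels; glutamate/lysine/methionine/valine shifted +0.25 in HEK-293, glutamate −0.25 in the resistant line |
| `lam` (ridge λ) | 1.0 | on standardized features; selection quality is insensitive over ~2 orders of magnitude here |

Noise is additive Gaussian truncated at zero *plus* a proportional term.
A pure additive model cannot both give attomole LODs and a measurable
error at 120 fmol; the proportional 2 % term is what calibration-accuracy
statements are made against, the additive floor is what LOD/LOQ measures.

## Targeted chain, in order

1. **Extraction** — each centroid peak is assigned to the nearest reporter
   channel within ±5 mDa; a channel keeps its most intense assigned peak.
   The tolerance must stay below the minimum adjacent reporter spacing
   (6.32 mDa): beyond that, nearest-channel assignment itself can tie, and
   the configuration is rejected.
2. **Impurity correction** per scan — solve `M·x = observed` (condition
   number ≤ 1e6 enforced), clamp negative solutions to zero (ion counts are
   nonnegative), *then* build per-channel EICs and integrate. Integration
   uses a shared window, apex ± 2·FWHM of the most intense channel (all
   channels of an analyte co-elute by construction), with linear
   interpolation at window edges so integration is exactly additive.
3. **Normalization** — analyte area / IS area from the IS's own transition;
   nonpositive IS areas flag the response missing rather than zero.
4. **Calibration** — weighted least squares with w = 1/x ("1/x" on nominal
   amount and "1/c" being the same weighting), R reported as the Pearson
   correlation weighted with the same weights, residuals screened with
   Grubbs' one-outlier test (α = 0.05, critical value from the t
   distribution, at most two iterative removals, first occurrence wins on
   ties). Residuals at floating-point scale (a numerically perfect line)
   are never screened — Grubbs on rounding noise would discard valid
   levels. Levels below the LOQ are excluded before fitting, so the
   calibration range's lower bound is ≥ LOQ by construction.
5. **LOD/LOQ** — noise is the sample SD (n−1) of a peak-free window
   (≥5 points, disjoint from apex ± 2·FWHM); response is apex *height* per
   amol. LOD = 3·noise/response, LOQ = 10·noise/response, so LOQ/LOD is
   exactly 10/3. With the ±3 FWHM scan span and 0.02 min sampling, the
   peak-free right tail only holds ≥5 points for FWHM ≥ ~0.1 min; the
   bundled measurement therefore uses cystine (FWHM 0.15 min). Height
   rather than area is an assumption; either choice rescales LODs by a
   common factor.
6. **Cells** — volume `(π/6)d³·10⁻³` pL from one dispensing-time diameter
   (spherical cells; no second axis is measured, so no ellipsoid option),
   concentration `amount/volume·10⁻³` mol/L. Cells with missing or
   nonpositive diameters are dropped, never imputed. Group comparisons per
   analyte use only in-range results: Kruskal–Wallis (tie-corrected, χ²
   reference), Dunn's post-hoc z with the pooled tie term and Bonferroni
   adjustment by default (none/Holm configurable), and classic
   mean-centered Levene. With all values tied the statistics are defined
   as H = 0, z = 0, W = 0 with p = 1.

## Untargeted branch

Feature "presence" means non-missing and nonzero in at least one replicate
of a cell; the ≥25 % filter counts distinct cells, boundary inclusive.
Values are log2(x+1)-transformed with missing = 0 ("not detected" in DDA;
median-fill and drop are configurable), standardized with training-fold
statistics only.

Greedy RLS: ridge with unpenalized intercept (handled by centering), and
the LOOCV objective computed from leverages — an identity, not an
approximation, verified in the tests against explicit n-refit leave-one-out
to 1e−8 and against exhaustive single-feature search for the first step.
Ties break to the lowest feature index, making the path deterministic. For
the three-class problem the selection objective is the LOOCV MSE summed
over the three one-vs-all ±1 targets (they share the hat matrix, so this
costs one leverage computation); classification takes the argmax of the
class scores. The outer evaluation holds out all replicates of one cell per
fold (replicates are not independent samples); accuracy is counted per
held-out replicate and averaged over folds.

Annotation removes the tag contribution from the precursor:
`neutral = m/z·z − z·m_H+ − n_tags·m_tag`, matched against a bundled
24-compound table of nitrogen-containing amines (masses computed from
formulas at run time). A mass-only match is Level 4; Level 2 is reserved
for caller-supplied spectral matches — no spectral library is bundled or
queried.

### Planted effect sizes

The feature-table generator plants class-informative features at a nominal
effect of 2 within-type standard deviations. "Standard deviation" here is
that of the values **as analyzed** — zero-filled log2 scale — which
includes the dropout term `p(1−p)·baseline²` alongside the biological
(0.5) and replicate (0.3) log2 SDs. Defining the effect against the
biological SD alone would let a 20 % missingness rate silently shrink the
realized effect to a fraction of its nominal size.

## What the simulator does not emulate

Profile-mode spectra, MS1 beyond precursor bookkeeping, retention-time
drift, ionization suppression, labeling-efficiency variation, carryover,
matrix effects, cell-cycle structure, and the physics of ion coalescence.
Passing tests therefore demonstrate that the *analysis* is correct and
well-conditioned under the stated noise model — not that the analytical
method performs identically on real raw files, where feature detection,
RT alignment and DDA stochasticity dominate the untargeted losses.

## Problem sizes

The test suite and the reproducibility script use a 7-level calibration
(0.03–120 fmol, six replicate channels per level), a 60-cell cohort
(20 per type, 10 runs), 12-replicate repeatability sets at 0.3 and 3 fmol,
and untargeted tables of 200 features × 48 cells × 3 replicates (selection)
and 60 features × 12 cells (nested CV), sizes at which every result is
recomputed from scratch in seconds while matching the study's structure.
The nested-CV accuracy reported on clearly separable synthetic data is 1.0
by construction; accuracy on overlapping populations depends entirely on
the planted effect sizes and is not a reproduction of any real-data value.

## Known limitations

- The IS and analyte transitions are separate scans; per-scan AGC scaling
  is assumed not to differ between them (true here because targeted runs
  are effectively uncapped). Under a binding AGC cap, absolute targeted
  quantitation would need scan-level renormalization.
- Grubbs' test assumes normal residuals; on 5–7 calibration points it is a
  screening heuristic, which is why removals are capped at two.
- The exact-LOOCV shortcut requires fixed preprocessing; standardization
  is computed per training fold, not per LOO split, matching standard
  greedy-RLS practice.
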