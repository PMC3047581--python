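# Methods

This note records the model, the algorithmic choices, and the limits of
what the test suite demonstrates.  It is the maintainer-facing companion to
the README.

## The amplification model

The package models background-subtracted fluorescence `F_C` with a
per-cycle efficiency that is linear in the current signal:

    E_C = F_C/F_{C-1} − 1 = E_max + ΔE·F_C ,     ΔE < 0.

Two conventions are fixed here.  First, `E_C` is the consecutive-reading
ratio **minus one**, so `E_max = 1.0` means perfect doubling; the intercept
of the efficiency regression is then directly the familiar "efficiency"
figure of merit (a ratio convention would put the intercept near 2 and
clash with how `E_max` values are quoted on profile labels).  Second, the
discrete dynamics consistent with the linear law are

    F_C = F_{C-1}(1 + E_max) / (1 + E_max·F_{C-1}/F_max),

whose exact solution is the logistic

    F_C = F_max / (1 + ((F_max − F_0)/F_0)(1+E_max)^{−C}).

This identity matters: the recurrence (used by the simulator) and the
logistic inverse (used for F_0 back-calculation) are *the same model*, so
on model-conforming data the regression recovers the generating parameters
to floating-point precision and every window cycle back-calculates the
same F_0.  A superficially similar recurrence,
`F_C = F_{C-1}(1 + E_max(1 − F_{C-1}/F_max))`, makes efficiency linear in
the *previous* cycle's fluorescence and is not used: it neither linearizes
the (F_C, E_C) plot nor admits the logistic solution.

Back-calculation has a pole at `F_C = F_max`; the implementation treats
readings at or above 99.9% of the fitted plateau as out of range
(`back_calculate_f0` returns NaN, window expansion stops there).  Numerical
conditioning of the OLS also degrades for windows placed below ~0.1% of
`F_max`, where the efficiency variation across the window is a ~1e−5
relative signal; the selection rules never place windows there.

## Baseline subtraction

Raw instrument fluorescence carries an additive background that corrupts
the efficiency ratio exactly where it matters most (low signal).  The
baseline is the mean raw reading over a configurable early-cycle range
(default cycles 4–9), with a guard that rejects ranges overlapping the
amplification rise: a reading counts as "rise" when it exceeds the
segment's median by more than max(10% of the profile's dynamic range,
5×MAD).  Median/MAD rather than mean/std, because the contamination being
guarded against inflates the latter; the noise clause keeps flat
zero-template wells (whose whole trace is read noise) from tripping the
guard.  Known residual effect: with very abundant targets the exponential
signal already present in cycles 4–9 inflates the baseline slightly; at
the defaults this costs at most ~0.5% in F_0 at 3×10⁵ starting molecules
and is negligible below 10⁴.

## Provisional half-max and start-cycle rules

The default start cycle is the largest integer strictly below the
profile's half-maximum cycle.  Before any fit exists, that half-max must
be estimated fit-free.  The plateau is located where the rise *ends*: the
first cycle after the peak per-cycle increment at which the increment has
decayed to 5% of its peak, or has stopped shrinking in the lower half of
its decline (the signature of post-plateau drift).  The plateau level is
the mean of the next up-to-3 readings, and the half-max crossing is linear
interpolation of the baselined trace.  Anchoring on the end of the rise
rather than the trailing maximum keeps a drifting plateau from dragging
the estimate upward.  A profile whose plateau is less than 8× the median
absolute per-cycle increment is flagged non-amplifying: any real
amplification towers over its typical increment, a noise-only trace does
not.

The minimum-F_C override sets the start cycle to the cycle *after* the
first reading above the user's minimum, so the efficiency denominator of
the start cycle is itself above the minimum — the point of the rule on
instruments whose read precision collapses at low signal.

## Window expansion

From an initial 3-cycle window: fit, back-calculate the F_0 of the cycle
immediately above the window with the current fit, and accept it if the
unsigned fractional difference from the window-average F_0 is within the
F_0 threshold (default 6%); refit after every acceptance (fully recursive
— both the candidate F_0 and the window average are always computed with
the current fit).  Expansion also stops at the end of the profile, at the
0.999·F_max pole, and if a refit ever turns unphysical (the previous
window is kept).  The absolute value makes both drift (F_0 rising) and
collapse (F_0 falling) terminate expansion.  If the *initial* 3-point fit
is invalid (non-negative slope — at low fluorescence a 3-point slope is
fragile against read noise), the initial window is retried up to 3 cycles
larger before the profile is declared aberrant.

Lowering the threshold can only shrink the selected window (tested as a
property), and the full selection — start rule plus expansion — is tested
for exact agreement against an independently coded transcription of the
rules on 200 mixed-distortion profiles.

## Quantification

`molecules = (F_0/OCF)·9.1×10¹¹/size_bp`, the constant being the LRE
literature's rounding of Avogadro's number over 660 g·mol⁻¹·bp⁻¹
(overridable).  Single-stranded targets (cDNA entering cycle 1) weigh half
as much per base and get 2× molecules per ng.  The OCF is the mean of
per-profile `avg_F0/known_ng` over valid calibration profiles, with the SD
reported; `known_ng` is the amplicon-equivalent mass of the calibrator.

Replicate sets quantify through the per-cycle average profile **only when
the replicates are tightly clustered** (C_1/2 range ≤ 1.0 cycles,
configurable).  Desynchronized sigmoids average into a flattened curve
whose apparent efficiency is biased low and whose back-calculated quantity
is biased high — at 8 starting molecules the bias is around 2×.  That is
also why the low-copy gate cannot trust the average profile near its own
threshold: the set takes the per-replicate path when *either* the
average-profile quantity *or* the per-replicate mean falls below 10
molecules, or when the replicates are scattered.  In the per-replicate
mean, a non-amplifying replicate counts as 0 molecules provided at least
one sibling amplified (a zero-template draw at limiting dilution); a set
with no amplifying replicate at all reports no quantity, since it is
indistinguishable from assay failure.

Precision is summarized by the Av Repl-F_0 CV (mean over sets of the
sample CV of replicate `avg_F0` values).  `optimize_min_fc` implements the
standard tuning guideline — scan minimum-F_C candidates and keep the CV
minimizer (ties to the lower value) — and `optimize_window_params`
generalizes it to a joint (minimum F_C, F_0 threshold) grid, preferring
settings that keep the most replicate sets usable before comparing CVs.
This matters on noisy instruments: with 1% multiplicative read noise the
default rules leave 3–5-cycle windows whose intercept error, amplified by
(1+E_max)^C, produces per-reaction F_0 errors of 50–100%; CV-tuned
settings (minimum F_C a few percent of the plateau, threshold 0.2–0.3)
widen the window to 9–12 cycles and bring per-reaction errors inside the
±30% envelope.  The tuning statistic uses replicate agreement only — no
ground truth — so it is applicable to real runs as-is.

## Kinetic diagnostics

Classification is annotation only; the window selector is what excludes
aberrant cycles from quantification.  With `r_C = E_C − (E_max + ΔE·F_C)`
the residual from the fitted LRE line:

- **drift score**: the steepest OLS slope of `r_C` versus cycle over the
  leading 3–6 residuals above the window, divided by `E_max`.  Several
  spans are scanned because the deviation onset sits an unknown 0–3
  cycles above wherever expansion stopped: collapse is a 2–3-cycle cliff
  followed by a flat stalled tail (a long span dilutes it), drift a ramp
  that may begin past the first clean post-window cycles (a short span
  misses it).  Beyond +0.05/cycle → plateau drift; beyond −0.05 → profile
  collapse.
- **arcing** is called when the window r² falls below 0.9 (windows of ≥5
  cycles only — r² of 3 noisy points is meaningless), when within-window
  residuals show significant quadratic curvature (|t| > 3 *and* a bend of
  ≥2% of E_max, windows of ≥8 cycles), or when the mean residual of the
  rise cycles *below* the window exceeds +5% of E_max.  The below-window
  test is the workhorse: arcing suppresses efficiency symmetrically around
  the window (the fit absorbs the local suppression, both sides sit above
  the line), whereas drift and collapse act only above it.
- no valid fit → non-amplifying.

All thresholds live in `DiagnosticsConfig`; the defaults are package
choices, as the pathologies are described in the literature only
pictorially.  At the generator's default distortion strengths and read
noise, per-mode recall and conforming specificity are ≥99% over 100
profiles per mode (measured by the acceptance script).

## The synthetic-data generator

`SimSpec` defaults describe a 50-cycle SYBR Green I assay on a well-tuned
96-well instrument: `E_max` 0.95, plateau 7×10⁶ units, background 5×10⁴
units, 0.2% multiplicative read noise with an additive floor of
noise·background (early cycles are noise-limited, as real optics are), a
200 bp double-stranded target at 10⁴ molecules, OCF 10⁵ units/ng.  The
0.2% default reproduces the windowing behavior of a high-precision bench
(accepted-cycle %Av F_0 values in the low single percents); 1% represents
a mediocre instrument and is used explicitly in the accuracy-envelope
experiments.  Below 10 molecules the template count is a Poisson draw per
reaction (configurable), and a zero draw yields a background-only trace.

Distortions are injected with localized, documented mechanics: drift adds
a linear ramp of `strength·F_max` per cycle from plateau onset (0.97
F_max; default 0.10); collapse multiplies the efficiency by
`1 − strength·(C − onset)` from 0.6 F_max (default 0.50/cycle, so
amplification dies within ~2 cycles and the trace stalls visibly short of
the plateau — a slow deficit is asymptotically invisible, the profile
merely reaches F_max later); arcing modulates `E_max` by a sinusoidal
half-period across the rise (default 30% peak suppression).  Cycles before
the rise midpoint are untouched by drift and collapse, baseline cycles by
all modes.  Every stochastic output requires a seed.

What passing tests show — and don't.  The generator satisfies the LRE
model exactly apart from the effects it injects, so the tests demonstrate
correctness of the machinery (exact recovery, rule equivalence, branch
logic, statistical behavior under known noise), not robustness to
everything real instruments do: ramp-rate artifacts, well-to-well optical
cross-talk, non-specific products and primer dimers (visible in melt
curves, which are out of scope), pipetting variance between replicates,
or targets whose true kinetics deviate from linear-efficiency decline.
The kinetic-distortion recall figures are specific to the documented
injection mechanics and strengths.

## Problem sizes

The shipped suite and acceptance script use desk-scale designs: 3×3×3
runs (27 reactions plus triplicate calibration), 200-profile oracle
sweeps, 100 profiles per distortion mode, and ~200 low-copy replicate
sets — sizes at which every statistic tested has a comfortably stable
distribution while the whole suite runs in seconds.

## Storage and exchange

Projects persist as a single versioned JSON document holding the three
collections (experiment runs, calibration setups with their OCF, and the
amplicon registry), chosen over an opaque object database for
transparency and diffability; schema-version mismatches fail loudly
rather than reinterpreting silently.  Spreadsheet import/export uses one
documented layout for CSV and XLSX (UTF-8, period decimal separator,
RFC 4180); numeric cells round-trip at IEEE double precision (read CSVs
with a round-trip float parser).  Import is column-atomic: a malformed
well is rejected with its row/column coordinates and the remaining wells
import, with counts reported.  Vendor-native run files and RDML are out
of scope.
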