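# Methods

## Problem setting

Atrial fibrillation (AF) produces an irregular ventricular response: the
RR-interval series (times between consecutive heartbeats) loses the
serial structure of sinus rhythm and looks close to uncorrelated noise,
typically at an elevated heart rate. Entropy statistics computed on
short non-overlapping RR windows (30 or 12 beats) quantify that
irregularity and can flag AF windows in long ambulatory or wearable ECG
recordings where beat-by-beat expert review is impractical.

`afentropy` implements four such statistics on a common template-matching
core, plus the preprocessing, synthetic-data and ROC machinery needed to
run and evaluate them end to end.

## The measures

All measures embed the segment `x(1..N)` into template vectors
`X_i^m = (x(i), ..., x(i+m-1))`. At both dimensions `m` and `m+1` the
first `N - m` templates are used, so numerator and denominator average
over the same number of templates.

**SampEn** counts template pairs (self-matches excluded) whose Chebyshev
distance is within a fixed tolerance `r`, at dimensions `m` and `m+1`,
and reports `-ln(A/B)`. Zero match counts yield a flagged non-finite
result — a known failure mode on short windows that this package never
papers over (the ROC layer drops non-finite scores and reports the count).

**FuzzyMEn** replaces the hard 0/1 match with the graded membership
`exp(-d^n / r)` and sums a *local* term (each template's own mean
removed, shape information) and a *global* term (series mean removed,
level information), each a `-ln(A/B)` with self-matches excluded.

**COSEn** is SampEn at `m = 1` with two changes aimed at very short
windows: the tolerance is found by a match-quota search instead of being
fixed, and the result is converted to a density by adding `ln(2r)` and
adjusted for heart rate by subtracting `ln(mean RR)`.

**Entropy_AF** combines five ingredients:

1. *Ranged distance*: `d = (max|Δ| - min|Δ|) / (max|Δ| + min|Δ| + ε)`
   over the element-wise differences `Δ` of two templates — normalised
   to `[0, 1)` and invariant to a common gain or offset.
2. *Fuzzy similarity* `exp(-d^n / r)`.
3. *Density estimation*: `-ln(A/B) + ln(2r)`, the volume-normalised form
   of the conditional match ratio.
4. *Flexible tolerance*: `r` grows from 0.05 in steps of 0.05 until the
   average per-template similarity mass at dimension `m+1` reaches a
   quota (default 5).
5. *Weighted heart-rate adjustment*: `- w · ln(mean RR)` with `w`
   defaulting to 1.

Self-pairs are *included* in the Entropy_AF double sums (matching the
printed index ranges of its defining equations) and *excluded* for
SampEn/COSEn (their original convention). Both behaviors are unit-tested.

## Parameter defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `m` (entropy_af) | 2 | beats | smallest non-degenerate embedding for the ranged distance (see below) |
| `m` (cosen) | 1 | beats | short-window convention for Chebyshev matching |
| `m` (sampen, fuzzymen) | 2 | beats | standard HRV practice |
| `n` | 2 | — | common fuzzy-similarity weight |
| `r` (sampen, fuzzymen) | 0.2·SD | s | standard HRV tolerance convention |
| `r_init`, `r_step`, `r_max` (ranged) | 0.05, 0.05, 1.0 | — | ranged distance lives in [0, 1) |
| `r_step`, `r_max` (Chebyshev) | 0.01·SD, max pairwise distance | s | tolerance lives on the data scale |
| `min_avg_matches` | 5 | matches | minimum-numerator heuristic for stable log ratios |
| `w` | 1 | — | plain heart-rate subtraction; `[0, 2]` grid-searchable |
| `ε` | 1e-10 | s | denominator guard of the ranged distance |

**Why `m = 2` for Entropy_AF.** For single-element templates the ranged
distance is identically zero (max and min of one absolute difference
coincide), so at `m = 1` the dimension-`m` similarity `B` is exactly 1
and the statistic degenerates to an unconditional density. `m = 2` is
the smallest embedding at which the conditional structure survives.
`m = 1` remains selectable and the degeneracy is documented, not patched.

## Numerical choices

* **Unit-mean pre-scaling in Entropy_AF.** The `ε` guard in the ranged
  distance does not scale with the signal, so the printed formula is
  gain-invariant only up to a relative error of order
  `n·d^n·ε / (r·(max|Δ|+min|Δ|))`, which can reach a few times `10·ε`.
  Entropy_AF therefore divides each segment by its mean before computing
  ranged distances (the heart-rate term uses the raw mean). This
  perturbs every distance by `O(ε)` — equivalent to using
  `ε' = ε·meanRR` — and makes gain invariance exact to machine
  precision, which is the property the measure is designed around.
* **Non-finite policy**: a vanished numerator or denominator produces a
  flagged result (`A_ZERO`/`B_ZERO`), never a substituted number; the
  ROC layer drops non-finite scores and records how many.
* **Tolerance-search termination**: if the quota is never met the grid
  cap is returned with `quota_met=False` and a warning.
* **ROC construction**: 101 thresholds from the score minimum to maximum
  (1% steps of the range); AUC by trapezoidal integration with the curve
  anchored at (0,0) and (1,1); orientation chosen so AUC ≥ 0.5 and
  recorded. An exact Mann–Whitney pair-counting AUC is exposed for
  cross-checks; at small n the trapezoid can differ from it by up to one
  pair quantum `1/(n_pos·n_neg)`.
* **Youden ties** break toward the smaller threshold. Rule-in/rule-out
  operating points use the grid threshold with `Se > level`
  (resp. `Sp > level`) that maximizes the other metric, flagged when the
  constraint is unattainable on the grid.
* **AUC comparison**: two-sided paired DeLong test; a zero-variance
  difference (e.g. identical scores) is flagged degenerate with p = 1.
  No multiple-testing correction is applied.

## Synthetic study conditions

The generator defaults define the conditions all shipped tests run under:

* **AF-like**: i.i.d. log-normal intervals, mean 0.6 s (~100 bpm),
  coefficient of variation 0.25 — a fast, serially uncorrelated
  ventricular response.
* **NSR-like**: mean 0.85 s (~70 bpm), Gaussian SD 0.03 s, plus a
  respiratory sinus-arrhythmia sinusoid of 0.04 s depth at 0.25 Hz in
  cumulative beat time.
* Intervals are clipped to (0.25 s, 2.0 s) with clip counts reported;
  the upper bound mirrors the ≤ 2 s preprocessing filter.
* A shuffled-NSR variant provides a second null with identical marginals
  but no serial structure.

What the generator does *not* emulate: ectopic beats, AV-nodal
correlation structure within AF, atrial flutter or junctional rhythms,
QRS-detection errors, and non-stationarity across windows. Passing the
shipped tests therefore demonstrates correctness and discriminative
behavior under idealised rhythms, not clinical-grade performance; on
these synthetic conditions the Chebyshev-based COSEn can reach a higher
AUC than Entropy_AF because the NSR null differs from AF mainly in
amplitude scale — precisely the information the ranged distance is
designed to discard in exchange for gain robustness on real,
artifact-laden recordings.

Default evaluation size: 500 AF + 500 NSR segments per window length
(30 and 12 beats), chosen to give stable AUC estimates (binomial SE
≈ 0.005) at desk-scale runtimes.

## Preprocessing pipeline

Rhythm-pure RR episodes are extracted from beat annotations; within each
episode, intervals > 2 s are removed and windowing restarts after every
removal (a gap would otherwise create spurious long-range templates);
remaining runs are cut into non-overlapping 30- or 12-beat windows. For
task construction, `AF_vs_N` discards atrial-flutter and junctional
windows while `AF_vs_nonAF` merges them with N into the non-AF class.
A 10-s ECG stretch is deemed noisy when at least two of five
signal-quality predicates fire (bSQI < 0.5, tSQI = 0, iSQI = 0,
pSQI < 0.8, kSQI < 3); a window overlapping any noisy stretch is flagged
(configurable to a majority rule). SQI values are consumed, not
computed — their extraction from raw ECG is out of scope, as are QRS
detection and ectopic-beat removal.

## Known limitations

* The trained value of the heart-rate weight `w` used in the published
  clinical evaluations is not public; the default `w = 1` plus the
  optional `[0, 2]` AUC grid search is a reconstruction.
* The match quota ("a specified number of average matches") is likewise
  a declared default (5), and the quota is counted as fuzzy similarity
  mass for the fuzzy kernel (self-pair included) — the thresholded-count
  alternative is noted but not the default.
* Wall-clock timing of the measures is exposed (`afentropy.io.time_measures`)
  for information only; timings are hardware-dependent and carry no
  acceptance weight.
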