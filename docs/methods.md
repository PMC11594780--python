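# Methods

## Data model

A CZE-IS case is six aligned absorbance curves over the same migration-time
axis: the reference run P (no antisera) and five antisera runs G, A, M
(anti-IgG/IgA/IgM) and K, L (anti-κ/anti-λ).  Curves are stored as float
vectors of `n_points` (300 by default, matching a 300 s acquisition at 1 s
per point), so a case is a 6×300 matrix.  Indexing is 0-based and zone
intervals are half-open `[start, end)` — uniform and off-by-one-safe.

Instrument exports do not label fraction boundaries, so the `ZoneMap` ships a
conventional serum-protein layout as axis fractions (albumin 0.05–0.25, α1
0.25–0.35, α2 0.35–0.48, β1 0.48–0.58, β2 0.58–0.70, γ 0.70–0.98), fully
overridable via YAML/JSON.  The default orientation puts albumin at low
indices; `gamma_first` mirrors the axis for exports recorded the other way.
Absorbance values are kept as-is in instrument arbitrary units — every index
is either a difference, a ratio, or a second difference of them, so no
rescaling is needed and none is applied.

## The five indexes

All five indexes are evaluated at the apex of P within the zone (argmax, ties
to the smallest index).  The apex is the most faithful reading of evaluating
indexes "of the peak"; an extremum-over-zone mode exists for the sharpness
index only and is not the default.  The apex's prominence (apex minus the
larger zone-edge value) is always reported so callers can gate flat zones;
evaluation itself is unconditional.

* Sharpness: `−[P(x+1) + P(x−1) − 2P(x)]`, the negated central second finite
  difference.  Positive at peaks; strictly decreasing in peak width for
  Gaussian peaks of fixed height.  No smoothing is applied before
  differencing by default; an optional centered odd-window moving average is
  available for noisy instrument data.
* Light chain: `Q = (P−K)/(P−L)`.  When `|P−L| < 1e-9` a.u. the index is
  reported as an explicit undefined marker with a reason, never ±inf; an
  undefined Q is treated downstream as a monoclonal-suspicion trigger, since
  P≈L at an immunoglobulin peak means essentially all of its mass carries λ.
* IgG/IgA/IgM: `P − G`, `P − A`, `P − M`.  Negative values are expected at
  low immunoglobulin concentration (two noisy, overlapping curves are
  subtracted) and are never clamped.

Stored values keep full precision.  Display rounding mimics how such
intervals are printed: light chain to 2 decimals, everything else to the
nearest integer.

## Reference intervals

* **Outlier screen** — the D/R one-third rule: for each extreme observation,
  D is its gap to the adjacent order statistic and R the sample range; the
  extreme is excluded when D/R strictly exceeds 1/3 (equality retains).
  Passes repeat until no removal.  Within one filter call R is held at the
  range of the sample as submitted: recomputing R on the shrinking sample
  would cascade (e.g. `[1,2,3,100]` would lose 100, then 3, then fail at
  n<3), while the fixed-R fixed point removes only `100`.  When a
  replenishment source is supplied, exclusions are replaced in source order
  (preserving seeded reproducibility) until the target n (default 1000) is
  restored, and the filter re-runs on the replenished sample.
* **Limits** — 2.5th/97.5th percentiles by the nonparametric rank convention
  `r = p(n+1)` with linear interpolation and ranks clamped to `[1, n]`
  (numpy's "weibull" method).  Other percentile conventions exist; this one
  is the standard nonparametric reference-limit rule and is the only one
  implemented.
* **Confidence intervals of the limits** — the narrowest order-statistic
  pair `(l, u)` with `P(l ≤ B ≤ u−1) ≥ 0.90`, `B ~ Binomial(n, p)`, from the
  exact binomial CDF (no normal approximation).  Ties between equally narrow
  pairs break toward the pair whose midpoint is closest to the target rank
  `p(n+1)`, then toward the smaller lower rank.  At n=120 and p=0.025 this
  yields ranks (1, 7) with achieved coverage 0.9205; below n≈91 no pair
  reaches 0.90 and an explicit "insufficient n" error is raised rather than
  a degraded interval.
* **Validation** — binomial transference: n_outside counts values strictly
  outside the limits (full precision); the interval is valid when
  `n_outside ≤ floor(0.10·n)`, invalid when `n_outside > 0.20·n`,
  indeterminate between (further testing).  At the customary n=20 this is
  valid ≤2, invalid ≥5; under a true 95% interval the valid probability is
  exactly `P(Bin(20, 0.05) ≤ 2) = 0.9245`.

## Synthetic electropherograms

The generator emulates what the pipeline assumes about real traces, not
electrophoretic physics.  Each case is a sum of Gaussian fractions:

* Non-immunoglobulin background: albumin (1200 a.u. at fraction 0.15, σ 9
  pts), α1 (180, 0.30, 5), α2 (280, 0.42, 6), β1 (260, 0.52, 5) and a β2
  band for complement C3/transferrin (130, 0.615, 5).  The β2 band matters:
  without it the zone's apex falls on the β2/γ boundary under the rising IgG
  tail, which makes the sharpness evaluation an edge artifact.
* Immunoglobulin humps per isotype, with per-case log-normal amplitudes:
  IgG (median 220 a.u., log-σ 0.45, center 0.82, σ 28 pts), IgA (60, 0.50,
  0.63, 15), IgM (30, 0.50, 0.66, 17).  A per-case κ fraction ~
  Beta(mean 0.62, concentration 80) splits all polyclonal mass between the
  light chains; the physiological κ excess centers the normal light-chain
  index around 1.6.
* Channels: `REF = background + immunoglobulins [+ spike] + noise`; each
  antiserum channel subtracts a fraction ε = 0.95 (incomplete
  immunosubtraction, one shared ε) of its target mass, plus independent
  i.i.d. Gaussian noise (σ 1.5 a.u. per channel; negative-value clipping is
  off by default so the subtraction algebra is exact).  ε = 0 is accepted as
  a degenerate no-subtraction control.
* Monoclonal cases add one narrow Gaussian spike (σ 1.5–3 pts) in γ or β2,
  attributed wholly to one isotype and one light chain; cohort spikes are
  drawn relative to the case's local hump apex (5–12×) so "spike k× the
  hump" statements hold per case, and the realized absolute amplitude is
  recorded in the label.
* Polyclonal cases scale all three isotype amplitudes by a factor drawn from
  U(3, 5) and draw their κ fraction with the Beta concentration scaled by
  the same factor — a flare recruits many more clones, so the aggregate κ/λ
  ratio regresses toward the population mean.

These defaults were calibrated once, forward from the model: simulated
normal cohorts give γ intervals of roughly 0.4–10 (sharpness), 1.05–2.6
(light chain) and 50–500 a.u. (IgG index) — the same order as published
intervals for these indexes — and the three case types separate cleanly.
They were then frozen.  What the simulator does **not** model: electro-osmotic
drift, carbohydrate-variant shoulders, baseline wander, instrument QC
artifacts, correlated noise, or biclonal disease.  Passing tests therefore
demonstrate the correctness and calibration of the pipeline's statistics on
well-behaved traces, not clinical performance on hospital data.

## Interpretation

Each panel value is flagged low/normal/high against its interval (strict
comparisons at full precision; a value equal to a limit is normal).  A
data-driven rule table (`czeis/data/rules.yaml`, editable) maps the ten flags
to one pattern, tried in precedence order:

1. `suspect_monoclonal` — sharpness high, or light chain high/low/undefined,
   in either zone.  Precedence favors screening sensitivity.
2. `polyclonal` — any immunoglobulin index high, with no monoclonal trigger.
   A *low* sharpness flag deliberately does not block this call: a
   blunter-than-normal peak argues against monoclonality, and a diffuse
   elevation can shift the apex onto a flatter part of the curve.
3. `hypogammaglobulinemia` — any immunoglobulin index low with everything
   else normal.
4. `normal` — all ten flags normal; anything else is `mixed_other` with the
   abnormal flags as rationale.

## Problem sizes and numerical choices

The replicated studies in the test suite and `scripts/acceptance.py` use the
sizes of the underlying design: n=1000 establishment cohorts, n=20
validation sets, 150–200 pipeline replicates, 500-case discrimination
cohorts, 5000-set validation calibration.  All randomness flows from
`numpy.random.default_rng` seeds; identical (config, seed) reproduces traces
bit-for-bit, and CSV I/O uses shortest round-trip float formatting with
round-trip parsing so files reproduce doubles exactly.  Known limitations:
the D/R rule's fixed-R convention and the apex evaluation point are
documented choices among several defensible readings of laboratory practice;
the rule table reconstructs a branching diagram that was never published as
prose and should be reviewed before any clinical use.
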