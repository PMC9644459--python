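# Methods

## The decision model

`devicemcda` implements an additive (weighted-sum) MCDA model for comparing
implantable medical devices in a tender. An instrument is an ordered list of
criteria, each with a weight `w_i` (percent of the decision, Σ w_i = 100)
and a discrete scoring function: a set of options, each worth a fraction
`s ∈ [0, 1]` of the criterion's weight. A device's total is `Σ w_i s_i` on a
0–100 scale. The model assumes preferential independence between criteria —
the value of a good supply record does not depend on the device's country
of origin — which is the standard assumption behind additive MCDA and was
implicit in the expert panel's design of the instrument.

Two options are exclusion rules (technical fulfilment below 70%; no
pharmacovigilance system). Exclusion is modelled as removal, not as a zero
score: an excluded assessment carries `total = None` together with its full
per-criterion audit trail, so no arithmetic can ever rank an excluded
device above a surviving one. This mirrors tender practice, where such a
device is simply out of the running.

The bundled default configuration is the final eight-criterion instrument
(weights 29.4, 19.5, 14.9, 11.7, 9.0, 6.9, 4.6, 4.0, summing to exactly
100.0). Weights are stored at the published one-decimal precision and
treated as canonical — no renormalisation is applied. The interim
nine-criterion draft from the first workshop is shipped as a non-current
fixture; its published weights total 99.8 due to rounding, so it validates
only in lenient mode (tolerance ±0.5). The published record gives no
scoring table for the interim draft, so the fixture reuses the final
scoring functions where criteria overlap and gives the later-removed
"training" criterion a minimal provided/not-provided function.

## Measurement kinds and bucketing

Each criterion declares how evidence arrives:

- `categorical` — a named option (certificates, pharmacovigilance grade, …).
- `technical_fulfillment_pct` — percent of required technical
  specifications met, or a raw `specs_met/specs_required` pair converted by
  `fulfillment_percentage` (16 of 20 → 80%).
- `supplier_fulfillment_pct` — percent of committed requirements fulfilled
  over the last three years.
- `stagnant_count` — how many times the product appeared in the stagnant
  (unsold-for-three-months) report in the last year.

Quantitative criteria carry bucket rules written in interval notation.
Boundary choices, where the published option labels are ambiguous or
overlapping:

- Technical buckets follow the explicit half-open labels: exactly 100 is
  required for the full score; `[90,100)` → 0.8, `[80,90)` → 0.6,
  `[70,80)` → 0.1, below 70 → exclusion.
- Supplier-reliability labels overlap at 70 and 90; the engine uses
  `(90,100]` → 1.0, `[70,90]` → 0.8, `[50,70)` → 0.6, `[0,50)` → 0.1, so
  each printed anchor ("more than 90", "<50") is honoured and a supplier at
  exactly 70 or 90 gets the benefit of the doubt.
- Stagnant counts: ≤1 → 1.0, 2 → 0.7, 3 → 0.5, ≥4 → 0.2. The scale stops
  at four appearances and defines no exclusion, so higher counts keep the
  0.2 floor. "Subsequently" in the two middle rows is modelled as a plain
  count; consecutiveness of monthly reports is not tracked, and users
  adjudicating real stagnant reports should count accordingly.

Validation checks that each quantitative criterion's buckets partition its
domain — `[0,100]` for percentages (real-valued), the non-negative integers
for counts — with no gap or overlap. The CE-certificate-only option on "use
in reference countries" is restricted to local (Egyptian-origin) products;
selecting it for an imported device is an error rather than a zero, and a
device matching none of the certificate sets is likewise reported as a
validation error rather than silently scored or excluded, since the
instrument defines no outcome for that case.

## Weight elicitation

The elicitation module reproduces the workshop protocol:

1. **Modification votes** are adopted on a strict majority (more than half
   of participants; exactly half fails).
2. **Ranking**: each expert orders all criteria; the consensus is the
   ascending mean of voted positions. Exact ties are broken by the order
   criteria appear in the configuration and flagged in the result, since
   the protocol defines no tie rule — flagged ties are meant to go back to
   the panel.
3. **SMART swing weighting**: for each adjacent pair of ranked criteria,
   experts vote on a 0–100% scale where 0% means equal importance and 100%
   means the higher-ranked criterion is twice as important. The scale is
   interpolated linearly between those anchors (ratio = 1 + v); this is the
   minimal assumption consistent with the two stated anchor points. Mean
   votes are chained from the bottom (u_n = 1, u_i = u_{i+1}(1 + v̄_i)) and
   normalised to percentages.

Mean (not median) aggregation is used for both rank positions and swing
votes, matching the panel's stated practice of averaging all voting
exercises. Votes outside [0, 1] are rejected, not clamped, to surface
data-entry errors. Each elicitation run is treated as independent; no
state carries over between rounds.

The bundled round-trip fixture (`final_workshop_vote_fixture`) contains the
adjacent-pair votes implied by the adopted weight table — consecutive
weight ratios minus one, computed at full floating precision. Chaining
these votes reproduces the published weights exactly; rounding the votes to
four decimals would already shift the top weight by ~0.06.

## Financial phase and sensitivity

The financial phase is strictly sequential after the technical phase,
mirroring the separation between the technical and pricing committees. It
consumes only non-excluded assessments, requires a price for each, and
ranks by price per point ascending. The output is labelled a
recommendation: the lowest price per point indicates best value for money
but the decision remains with the committee, and exact ties are reported
rather than broken. Devices with a zero total cannot be priced per point
and are flagged unpriceable. The ordering is invariant under scaling all
prices by a positive constant.

`reweight` supports pilot-style what-if analysis: one criterion's weight is
set and the rest are rescaled proportionally (`(100 − new)/(100 − old)`),
the standard order-independent compensation; ranks are re-derived from the
new weights. `rank_reversal_scan` sweeps a weight grid, rescoring all
devices at each point and reporting every grid value whose leader differs
from the baseline leader. The scan is deterministic arithmetic — no seed —
so reports are exactly reproducible.

## Synthetic data

The fixtures module generates the data the instrument would meet in use,
with known ground truth:

- **Panels** (`gen_vote_set`): experts perturb the true importance ordering
  by independent adjacent swaps (probability `rank_noise` per pair) and
  report swing votes equal to the true adjacent ratio minus one plus
  Gaussian noise (`swing_noise_sd`), truncated to [0, 1]. Truncation rather
  than rejection keeps every expert voting but biases recovery slightly
  when true ratios sit near the ends of the scale. Defaults are noise-free;
  the test battery exercises sd = 0.05 with panels of 5–50 experts,
  bracketing the 14–20 experts of the real workshops.
- **Profiles** (`gen_profiles`): options are drawn per criterion (by
  default, exclusion options are jointly sized so a device is excluded with
  probability `exclusion_rate`; non-exclusion options are uniform), then a
  raw measurement consistent with the drawn option is synthesised for
  quantitative criteria — uniform within the option's bucket, with raw
  spec-count pairs emitted half the time for technical evidence. Ground
  truth totals are computed by `naive_total`, a deliberately plain
  weight-times-fraction loop over the drawn options that never touches the
  engine's bucketing, so engine-vs-truth agreement is a genuine
  dual-implementation check. Prices are uniform in `price_range`
  (default 1 000–50 000, a plausible span for implantable-device unit
  prices in Egyptian pounds).

What passing tests on this synthetic data do *not* show: the generator
draws criteria independently and uniformly, whereas real tender dossiers
correlate strongly (a reputable manufacturer tends to score well across
quality criteria), and real measurement distributions are unknown. The
fixtures validate the arithmetic and the contracts, not the instrument's
discriminative behaviour on real markets.

## Numerical choices

- Weight-sum tolerance: 1e-6 strict, ±0.5 lenient. Derived weight vectors
  sum to 100 within 1e-9.
- Ties (totals, price per point) are detected at 1e-9 and annotated; sort
  order within a tie falls back to device_id for determinism.
- Bucket membership uses exact floating comparison against interval
  endpoints; all published thresholds are exactly representable or
  compared consistently on both sides.
- Comparison totals are reported at full precision and rounded only at the
  rendering layer (two decimals on sheets, six in CSV exports).
- Problem sizes in the test battery (≤ 300 profiles for oracle checks,
  10 000 for frequency convergence, 10-seed batteries for recovery) keep
  the whole suite under ten seconds while leaving the Monte-Carlo checks
  well-powered.

## Known limitations

- The instrument's qualitative inputs (certificate validity, EDA
  pharmacovigilance grades) arrive as already-adjudicated options;
  document verification is out of scope.
- The spreadsheet edition of the instrument compares five devices at a
  time; this implementation accepts any number and treats the five-device
  cap as a spreadsheet artefact, not policy.
- Consecutiveness of stagnant-report appearances is not modelled (see
  above).
- The elicitation module does not model the discussion and re-voting
  process between workshop rounds, only the arithmetic of a single round.
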