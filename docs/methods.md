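# Methods

## Model

ROAR analysis treats a reported 2×2 table (a, b experimental
endpoint-positive/negative; c, d control) as potentially incomplete: x
subjects redacted from the experimental arm and y from the control arm, in
the cells that would have worked against the reported effect. For a reported
risk ratio above 1 the restored table is (a, b+x / c+y, d); below 1 it is
(a+x, b / c, d+y). With ν_c the (1−α) quantile of χ²(1), the identity

  g(x, y) = χ²_Pearson(restored table) − ν_c

defines the attainable-redaction region {g ≤ 0} in the non-negative
quadrant. Clearing the (strictly positive) denominator yields a bivariate
polynomial of degree ≤ 3 in each variable with at most 15 monomials; the
x³y³ coefficient is identically zero. The minimal redaction explaining away
significance is the boundary point closest to the origin (the FOCK point),
characterized by the Lagrange condition: g = 0 together with
h = y·∂g/∂x − x·∂g/∂y = 0, the multiplier having been eliminated
analytically. By Bézout's bound the polynomial pair admits up to 25
solutions; only non-negative real ones are candidates and the minimum-norm
one is selected. The minimum may also sit on an axis, where only g = 0 is
required — the implementation permits and reports axis minima.

Assumptions inherited from the chi-square framework: dichotomous outcomes,
two arms, all four margins positive, no continuity correction, and the
large-sample χ² approximation (results for rare events in very small trials
can disagree with Fisher's exact test). Time-to-event designs are out of
scope. Redaction counts x, y are treated as continuous in the geometry; the
integer-valued summaries (r_min, subject counts) are derived afterwards.

## Parameters

- **alpha** (default 0.05): significance level; ν_c is always derived from
  it at run time via the χ²(1) quantile, never hard-coded.
- **confounding threshold** (default 0.10): pooled meta-analysis tables are
  analyzed only when |1 − RR_CMH/RR_C| is strictly below it; the crude pooled
  table (exact cellwise integer sums, unweighted) is then the analysis input.
- **CI level** (default 0.95): risk-ratio intervals use the Katz log-RR Wald
  construction, exp(ln RR ± z·√(1/a − 1/(a+b) + 1/c − 1/(c+d))). The choice
  is ours (the source tables print CIs without naming a method); it
  reproduces the published intervals to two decimals.
- **scan resolution** (default 4096 slices): density of the global boundary
  scan that seeds the Newton solve; see below.

## Numerical procedure

1. **Expansion.** The cleared polynomial is built by programmatic
   convolution of the factor polynomials with exact integer coefficients,
   converted to floats only when the ν_c term is subtracted. Gradients and h
   are exact coefficient-level derivatives; finite differences appear only
   as test oracles.
2. **Axis intercepts.** g(x, 0) and g(0, y) are univariate cubics; roots
   come from the companion matrix (`numpy.roots`), are polished with Newton
   steps, filtered to real values (|Im| ≤ 1e−7·(1+|Re|)), and the smallest
   positive root is taken.
3. **FOCK point.** The boundary is sliced at 4097 evenly spaced x positions
   in [0, min(x_c, y_c)] — a boundary point with larger x is necessarily
   farther from the origin than the nearer axis intercept — solving the
   cubic in y at each slice via stacked companion-matrix eigenvalues. The
   minimum-distance sample seeds a damped Newton iteration on {g = 0, h = 0}
   (at most 100 iterations; convergence when |g| and |h| fall below 1e−9
   times the local coefficient magnitude Σ|cᵢⱼ|xⁱyʲ, which keeps tolerances
   meaningful for tables of any size). The converged point competes with the
   two axis intercepts; the minimum-norm feasible candidate wins. If
   polishing fails, the scan minimum is returned with a diagnostic flag
   rather than an exception.
4. **Summaries.** r_min rounds xₑ+yₑ to the nearest integer. The printed
   convention in the source material is a floor, but its own worked values
   (r_min = 12 from a coordinate sum of 11.68) are consistent only with
   rounding, which we therefore adopt; the raw real sum is always reported
   alongside. ρ_E and ρ_C use the real-valued intercepts; ρ_A uses the
   integer r_min. Display output floors x_c and y_c into whole-subject
   counts; full double precision is always present in the JSON report.
5. **Degenerate inputs.** Zero margins are rejected at the table boundary;
   RR exactly 1 has no redaction direction and is rejected by the
   classifier; a table not significant at α yields a flagged all-zero result
   rather than an error so batch callers can proceed. Counts are validated
   as integers at the API boundary; all downstream arithmetic is floating
   point.

A note on reproduction accuracy: the published worked example's metrics are
internally consistent with an effective threshold slightly below
ν_c(0.05) = 3.8415 (direct evaluation of g at the published FOCK point gives
≈ −0.03, and the published meta-analysis FOCK norm slightly exceeds its own
x-axis intercept, which a true minimum cannot). This package always uses the
exact quantile; recomputed values (e.g. FOCK (6.83, 4.75) vs the published
(6.89, 4.79)) differ by under 2% and all integer summaries agree. We do not
tune ν_c to chase exact reproduction.

## Synthetic data

`random_significant_table(seed, n_range=(40, 400), alpha=0.05)` draws the
total n uniformly, allocates cells by a symmetric multinomial (probability
1/4 per cell), and rejection-samples until the table has positive margins
and a chi-square above ν_c. This emulates null-generated tables that cross
the significance threshold by chance — the adversarial case ROAR is designed
to expose — in the sample-size range of small trials, and stresses both
effect directions equally. It does not emulate: genuinely effective
treatments (large |RR−1| with matching power), unbalanced arm allocation,
rare-event tables, or correlated multi-study structures. A green property
suite on these fixtures therefore establishes internal consistency of the
solver (polynomial expansion, gradients, Lagrange solution vs brute-force
scans, mirror symmetry) across moderate tables, not calibration on any
particular clinical domain; the published worked examples cover the
large-sample regime separately.

## Verification oracles

Two brute-force oracles ship in the package (exposed via `roar oracle`) and
back the property tests: a dense grid scan of the boundary (nested
refinement, so doubling the slice count never worsens the reported minimum)
and an exhaustive integer search over x + y ≤ bound. The integer L1 minimum
can be *smaller* than r_min (11 vs 12 in the worked example): the Euclidean
FOCK summary is deliberately not the integer fewest-subjects optimum, and
the oracle reports both.

## Known limitations

- Applicable only to 2×2 dichotomous comparisons; odds-ratio variants and
  stratified/multi-arm designs are not implemented.
- Meta-analysis support pools studies into one crude table after the
  confounding gate; it cannot attribute hypothetical redaction to specific
  studies, and a gate pass is necessary but not sufficient grounds for
  causal interpretation.
- The boundedness of the region is assumed (and holds on all exercised
  inputs) but is not proven for pathological near-degenerate tables; the
  grid oracle is the recommended cross-check there.
- p-values are 1-df chi-square upper tails; no Fisher's exact option.
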