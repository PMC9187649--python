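# Methods

## Scope and model

`resmon` implements the deterministic (point-estimate) tier of dietary
risk assessment used in routine residue surveillance. It does not attempt
probabilistic exposure (Monte-Carlo percentiles), age-stratified body
weights, or processing-factor corrections for washing/peeling; those are
deliberate non-goals. Wet-lab stages (extraction, clean-up, instrument
acquisition) are out of scope — the pipeline starts from quantified
concentrations.

### Compliance screening

A residue's verdict is a pure function of (concentration, LOD, MRL):

* concentration < LOD → not detected,
* LOD ≤ concentration ≤ MRL → below MRL,
* concentration > MRL → above MRL.

Exceedance is strict because regulatory practice treats a result equal to
the limit as compliant. The MRL for a pair is the registered limit when
one exists, otherwise the Positive List System default
(`pls_default_mrl`, 0.01 mg/kg) — the fallback is total, so resolution
never fails. A sample is categorised by its worst residue verdict; the
survey this package reconstructs happens to have exactly one residue per
contaminated sample, but the rule matters for general (multi-residue)
data and is exercised by the stochastic generator.

Percentages are presented round-half-up at one decimal
(`percent_decimals`). One knock-on effect: the insecticide share of
detected pesticides is 100 × 14/32 = 43.75 → 43.8, where the source
summary prints 43.7; the source's rounding rule is unstated and we follow
arithmetic. In the published occurrence layout the percentage beside the
below-MRL count is the *any-residue* rate ((n_below + n_above)/n_total) —
verified against the per-commodity counts (e.g. 9/46 = 19.6%); machine
output adds an unambiguous `pct_below` column rather than propagating the
ambiguity.

### Exposure indices

ESTI (acute) uses the pair's highest detected concentration, EDI
(chronic) the arithmetic mean over *detected* concentrations only;
non-detects are excluded rather than LOD/2-substituted, matching how a
survey that reports only detected ranges must be read. Both use one
per-commodity consumption value (kg/person/day) and a single scalar body
weight (`body_weight`, default 60 kg — the conventional adult value;
surveys rarely print it, so real use should supply it). aHQ and HQ are
the intakes as percentages of ARfD and ADI; cHI is the plain sum of HQs
across pairs, and an index strictly above 100% is read as a potential
risk. An absent ARfD propagates as absent through records and summary
maxima — setting it to zero would fabricate an infinite quotient.

### Method validation

LOD = 3.3 × SD, LOQ = 10 × SD from replicate spiked analyses. SD uses the
n−1 denominator (five replicates is small; the convention is unstated in
most QC write-ups and the sample SD is the safer estimator), so LOQ/LOD is
identically 10/3.3 before presentation rounding (three decimals in
mg/kg). Recovery bounds are inclusive at both ends (70 and 120% pass);
the RSD bound is strict (< 10%). Linearity is the R² of one OLS line over
all pooled (concentration, response) replicate points; a constant
response has zero explained variance, reported as R² = 0.

## Synthetic data

### Stochastic generator

Each sample is independently contaminated with probability
`detection_prob` (default 0.079, the campaign-wide any-residue rate); a
contaminated sample carries 1 + Poisson(`multi_residue_rate`) distinct
pesticides, so multi-residue samples occur and exercise the worst-verdict
rule. Compliant concentrations are lognormal (`conc_lognormal`, default
μ = −2.5, σ = 1.2: median ≈ 0.08 mg/kg with a central 95% range spanning
roughly two orders of magnitude, matching the spread of field residue
ranges) truncated to (LOD, MRL] by rejection; a residue violates with
probability `violation_prob` (default 11/91) and is then drawn uniformly
in (MRL, 3 × MRL]. All randomness flows from
`numpy.random.default_rng(seed)`.

What the generator does *not* emulate: commodity- or pesticide-specific
detection rates, seasonal structure, censoring quirks of individual
instruments, and correlated co-occurrence of pesticides. Tests that pass
on generated data therefore demonstrate the statistics are computed
correctly, not that real campaigns look like the generator.

### Deterministic survey reconstruction

The published survey gives only marginals: per-commodity sample
categories, per-pesticide detection/violation counts with concentration
and MRL ranges, and the set of pesticide × commodity pairs with
detections. `build_survey_dataset` rebuilds a concrete sample-level
dataset reproducing those marginals exactly. The detection-to-commodity
split is solved as an integral transportation problem (networkx min-cost
flow, zero costs) in two stages — violations first, then compliant
detections with a mandatory unit on every published pair. An exact flow
is used instead of a greedy pass because greedy assignment can dead-end
on feasible instances; the solve is still a deterministic function of the
tables (sorted node/edge insertion, no seed). Within a pesticide, the
printed range endpoints are placed first (maximum to the hardest
compatible slot, minimum to the last compatible slot) and interior slots
take the geometric midpoint of the range clipped to the slot's
verdict-determined interval.

Reconstruction limits inherent to the marginals: one residue per
contaminated sample is forced by the 91 = 91 count identity; a pesticide
found in a single commodity can realise only one MRL endpoint (diazinon's
published 0.05–0.1 range collapses to 0.05); fixture LOD/LOQ are a
uniform 0.005/0.015 mg/kg because published per-pesticide LODs cover under
half the detected pesticides and one exceeds its own minimum detected
concentration. Two cells of the published exposure table are internally
inconsistent with their own printed operands (myclobutanil/aster scaber
HQ, prochloraz/banana aHQ); they are kept verbatim in the packaged CSV,
flagged in its header, and excluded from replay comparisons.

## Numerical choices

* Round-half-up (decimal arithmetic) for all presentation percentages;
  full precision retained internally.
* Replay comparisons against printed exposure cells use the error bound
  the printing itself implies: a two-significant-figure intake carries a
  relative half-ulp of 0.05/mantissa (up to 5% when the mantissa is close
  to 1), plus the absolute half-ulp of the quotient's printed decimals.
* Verdict ties: concentration equal to LOD is detected; equal to MRL is
  compliant; cumulative index equal to 100% is acceptable (thresholds are
  strict on the risk side).
* Degenerate inputs: empty residue lists give clean samples, empty HQ
  lists give cHI = 0, a constant calibration response gives R² = 0, an
  empty registered-MRL table routes everything to the PLS default.

## Problem sizes

The packaged reconstruction is the survey's actual size (1,146 samples,
91 detections, 62 exposure pairs) and builds in well under a second.
Generator parameter-recovery checks use 10⁴ samples, where binomial
3-standard-error bounds are tight enough to detect rate errors of ~1
percentage point.
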