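# Methods

This note documents the models implemented in `corrikit`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions taken where the design was open.

## Poisson occupancy and MPN

Founder cells deposited into wells by limiting dilution are modeled as
X ~ Poisson(λ) per well, independent across wells. Two consequences drive
plate design: the positive-well fraction `p = 1 − e^(−λ)` and the clonality
of positives `P(X = 1 | X ≥ 1) = λe^(−λ)/(1 − e^(−λ))`. Both are exact under
the model; solving `p = 0.30` gives λ = 0.3567 and a clonal fraction of
0.832, the classic "~80% clonal at 30% occupancy" operating point. The model
assumes cells are well dispersed; aggregated inocula (common in soil
slurries) break the Poisson assumption and push clonality below the
prediction, which is out of scope here.

The MPN estimator maximizes the binomial likelihood of positive counts
`p_i` out of `w_i` wells at relative inocula `d_i`, solving the score
equation by bracketed Brent root finding (the score is monotone decreasing
in λ). With one dilution level this reduces exactly to `−ln(1 − p/w)/d`.
Confidence intervals are log-normal Wald intervals built from the Fisher
information `I(λ) = Σ w_i d_i² e^(−λd_i)/(1 − e^(−λd_i))` — the classical
Cochran-style approximation; it is approximate for small plates and
degenerate at the boundary, so all-negative plates return λ = 0 with an
exact one-sided upper bound (`−ln α / Σw_i d_i`) and all-positive plates
return a flagged infinite sentinel rather than an exception, keeping batch
runs alive. Single- and multi-level designs are both supported since plate
layouts vary.

Concentrations are carried in molar units throughout; unit formatting
(nM/pM/fM, 2 significant figures by default) is presentation only. The
dilution-series builder takes the fold factor explicitly; the conventional
12-point series from 10 nM uses fold 4, which ends at 2.384 fM.

## Dependence testing

The decision statistic is the corrinoid-specific growth enhancement
`E = log2(1 + (OD_with − OD_noc)/OD_noc) = log2(OD_with/OD_noc)`, in
doublings attributable to the corrinoid. Design choices:

- **Blank floor (default OD 0.01).** Readings below the floor are clamped
  before the ratio; otherwise near-blank no-corrinoid wells produce
  unbounded E. Clamped values are flagged.
- **Decisive passage.** E is evaluated at the final (4th) passage, where
  carryover washout is maximal: each ~3 μl → 200 μl transfer dilutes
  carried corrinoid ~67-fold, ~2×10⁷-fold over four passages.
- **Threshold τ = max + sample SD** of the enhancement values of isolates
  that were themselves isolated without corrinoid and serially transferred
  the same way. The SD uses the n−1 denominator and is computed across the
  pooled control values. With fewer than two control values the pipeline
  falls back to a configured default τ (0.5) with a logged warning.
- **Positivity condition.** A replicate is called dependent when E ≥ τ
  *and* E > 0. The second condition is physically necessary — zero
  enhancement means the two arms are indistinguishable — and only bites in
  the degenerate case where noise-free controls give τ = 0; for any τ > 0
  it coincides with the threshold rule.
- **Growth floor (default OD 0.1).** Replicates whose with-corrinoid arm
  never clears it are "no-growth" and the isolate is not pursued.
- **Vote.** An isolate is dependent when ≥ 2 of 3 replicates are dependent
  (majority-or-greater for other replicate counts); incomplete replicates
  yield "inconclusive" unless the remaining calls already decide the vote.

Time-to-saturation groups (24/48/168/336 h) use a 95%-of-maximum criterion
with linear interpolation between readings — chosen because "saturating
growth" needs an operational definition and 95%-of-max is parameter-free
and robust to plateau noise. A curve whose last inter-point rise still
exceeds the 5% tolerance band has not shown its plateau and is unassigned,
as are blank curves.

## Bioassay

The corrinoid-detection metric is `(OD_ΔmetE − OD_ΔmetEΔmetH)/OD_wt`:
subtraction removes growth attributable to methionine in the sample,
division normalizes to overall sample quality. Normalization is read as
plain division (the printed ≥ 2 producer threshold is only self-consistent
under that reading). A sample is producer-positive when the metric is ≥ 2
**or** the ΔmetE OD is ≥ 0.1, non-producer when both fail; thresholds are
configurable. Replicate disagreement and invalid assays (wildtype OD ≤ 0.1)
make the sample inconclusive with machine-readable reasons; lysates that
suppress the wildtype below 50% of the plate median are flagged as
growth-repressing.

Quantification inverts a 4PL standard curve fitted to replicate-averaged
responses: `x = EC50·((top − bottom)/(y − bottom) − 1)^(−1/h)`. Responses
at or below the curve bottom are below-detection; at or above the top,
above-range — both sentinels, not errors. Percent provided is
`100·extra/(extra + intra)`, undefined when both are zero and reported as
0% with a not-detected flag when only the extracellular amount is zero.

## Dose–response and preference

The 4PL `y = bottom + (top − bottom)/(1 + (EC50/x)^h)` is fitted by
bounded trust-region least squares in the parameterization (bottom, span,
h, log10 EC50): tested ranges span ~6 decades, so EC50 is estimated on the
log scale, and span ≥ 0 enforces top ≥ bottom. Hill slopes are constrained
to (0, 10] (growth responses are monotone increasing) and bottom ≥ 0.
Multistart initialization places the initial log10 EC50 on a 6-point grid
across the tested range with bottom/top from the data extremes and h = 1;
the best of the converged starts wins. Replicates enter the loss
individually, unweighted. Statuses: `NG` (no growth: every response below
the growth floor), `ND` (no regression: < 4 distinct concentrations,
response range below 0.05, optimizer failure, or a collapsed span).

Confidence intervals are 95% Wald intervals on log10 EC50 from the
residual-scaled Gauss–Newton covariance, back-transformed. They are
approximate (chosen over profile likelihood for speed); bounds that are
non-finite or fall outside the tested concentration range are replaced by
one-sided "<"/">" sentinels at the range edge, mirroring the reporting
convention for undetermined bounds. Seeded simulation at the default study
conditions (12 concentrations, 2 replicates, OD noise sd 0.02) shows
log10 EC50 recovered within ±0.3 in ≥ 90% of fits and interval coverage in
the 90–99% band (see `tests/test_acceptance.py`).

Preference ranks a dependent's corrinoids by fitted EC50 ascending; NG/ND
entries stay in the table but out of the ranking. Exact ties are broken
lexicographically and flagged.

## Genus-level prediction

Species with any predicted producer likelihood (very likely / likely /
possible) are producers; predicted non-producers are dependents when they
encode ≥ 1 corrinoid-dependent function (regardless of corrinoid-independent
alternative enzymes) and independents otherwise. A genus is called when it
has ≥ 20 species and ≥ 95% of them share a category — both boundaries
inclusive, and the fraction comparison is done as
`count · den ≥ num · total` in exact integers so that 19/20 classifies and
no floating-point edge exists at 0.95. Genus labels are taken as given in
the input table; re-deriving species predictions or updating taxonomy is
out of scope. Species with unknown likelihood labels are rejected with a
logged reason.

## Sufficiency

Fold-sufficiency is `volume_ratio · provided_concentration / EC50`,
computed on the corrinoid the provider releases against each dependent's
fitted EC50 for it. The interpretation — EC50 as the per-culture
requirement at equal culture volumes — is stated in the output metadata,
and the volume ratio is an explicit parameter rather than an assumption.
Entries are undefined (NaN) for non-providers, NG/ND dependents, and pairs
with no common corrinoid. A fold ≥ 1 marks a dependent supportable at
half-maximal growth.

## Synthetic data

The generators emulate the study conditions: 10 nM corrinoid in isolation
and passage media; four passages at carryover fold 200/3 with three
replicates; a 12-point 4-fold dose–response series from 10 nM with two
replicates; a three-strain bioassay with a 12-point standard curve; and
additive Gaussian OD noise (sd 0.02, truncated at 0 and capped at OD 2) —
the simplest model consistent with plate-reader behavior. Default community
ground truth: plateau ODs uniform on [0.5, 1.0], baselines on [0.03, 0.08],
dependent B12 EC50s log-uniform on [10⁻¹³, 10⁻¹⁰·⁵] M (picomolar-scale
preferences) with other corrinoids 1–100× higher or unusable (NG with
probability 0.4 for the rarely-used corrinoids), producer totals log-uniform
on [10⁻¹⁰, 10⁻⁹·¹] M in the assay, and a provided fraction between 1.3% and
21% for roughly 7 of 11 producers (the observed provider frequency and
range). Dependents' no-corrinoid plateau is their own 4PL evaluated at the
carried concentration, tying the passage simulation and the dose–response
module to one shared ground truth. The species-table generator draws genus
compositions multinomially, or exactly (largest-remainder rounding) for
boundary fixtures; the pipeline uses exact composition because the table
stands in for a fixed external prediction dataset.

What the generators do **not** emulate: well-position and edge effects,
correlated (non-Gaussian) reader noise, cell aggregation and the resulting
sub-Poisson clonality, growth-curve kinetics between passages, corrinoid
degradation, matrix effects in lysates, and real taxonomic structure.
Passing the recovery tests therefore shows the decision rules and
estimators are correct and well-calibrated under the stated statistical
model — not that real plate data are this clean.

## Pipeline

Decision order follows the experimental logic: dependence is decided first;
only isolates that grow without corrinoid are bioassayed; voted dependents
go to dose–response for confirmation and preference. Identity-based QC uses
the printed strict inequalities: drop when > 99% identical to an
uninoculated-well sequence, flag as novel when < 98.6% identical to the
best reference hit. Stage failures isolate the affected isolates as
inconclusive (reasons: `assay-invalid`, `replicate-inconsistency`,
`growth-repression`, `no-bioassay-data`, `no-reproducible-growth`) and
never abort the batch. Stage seeds are derived from the run seed through a
`SeedSequence`, so identical config + seed gives byte-identical outputs.
When a growth-curve table is supplied, isolates in the slowest saturation
group — or with no assignable group — are excluded from phenotyping and
reported as untested (configurable), mirroring the practice of not testing
slow or inconsistent growers; synthetic mode supplies no growth-curve
table, so nothing is excluded there.

Problem sizes used in the shipped tests — 60-isolate communities, 10⁵
simulated wells, 100–200 seeded dose–response datasets — were chosen so the
binomial/Monte-Carlo error bars are far tighter than the tolerances being
checked while a full suite run stays in the tens of seconds.

## Known limitations

- Wald intervals (MPN and EC50) are first-order approximations; profile or
  bootstrap intervals would be better near identifiability boundaries.
- The enhancement statistic conditions on end-point ODs only; kinetic
  information within a passage is unused.
- The sufficiency definition is one defensible reading of "dependents per
  producer"; it is stated in output metadata rather than asserted as the
  only one.
- Genus calls inherit whatever bias the upstream species predictions carry;
  the classifier only aggregates them.
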