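# Methods

## Problem and model

The package estimates, for every country and year in an estimation period,
the composition of live births over five delivery locations: public or
non-profit hospital, private for-profit hospital, public or non-profit
lower-level facility, private for-profit lower-level facility, and
non-facility. "Hospital" means a facility capable of comprehensive
emergency obstetric and neonatal care (caesarean section and blood
transfusion); every other delivery facility is "lower-level". Ownership is
collapsed to two modelled sectors because private non-profit facilities
are rare and behave like public ones on cost and quality: public + private
non-profit (`public_nfp`) vs private for-profit (`private_fp`).

Inputs are (i) survey-style microdata, one row per birth, with free-text
delivery-location responses, survey weights, and caesarean flags; (ii) a
location hierarchy (country → region → super-region) with live births per
country-year; (iii) covariates per country-year; (iv) an externally
estimated in-facility delivery share supplied as draws (the "envelope").
Six indicators are modelled independently on the logit scale — the four
level×sector shares and the two level-only shares — and reconciled
afterwards by raking.

## Categorisation

Response options are mapped to (facility status, level, sector) by an
ordered keyword rulebook (shipped as JSON data, editable without code
change). Matching is case- and whitespace-folded whole-word search; the
first matching rule wins; a per-country override table, representing
expert cross-survey harmonisation, takes precedence over all generic
rules; a terminal catch-all maps anything unmatched to `unknown`.

Options whose level the name cannot resolve are classified by caesarean
rate: the pooled caesarean rates of the already-identified hospital and
lower-level options in the same source-location act as comparators, and
the ambiguous option takes the strictly nearer level. Ties (within 1e-12)
and options with fewer than 25 weighted births (configurable) stay
unknown. Both comparators must exist, otherwise the step is skipped.

Inclusion in modelling is per location-year and nested: at least 85% of
facility births with known level *and* sector for the four level-and-sector
indicators, at least 95% with known level for the two level-only
indicators. Comparisons are inclusive ("at least").

## Preparation

Each (source, country, birth year) cell — surveys contribute the five
birth-year cohorts before the interview — yields one observed proportion
per indicator, with all births of known facility status in the
denominator. Unknown facility mass is redistributed before tabulation:
unknown-level mass splits across hospital/lower in proportion to the
cell's known-level mass (carrying its sector along), then unknown-sector
mass within each level splits in proportion to that level's known-sector
mass. Total facility mass is conserved exactly. A cell with no known mass
in a redistribution group falls back to the country's earlier-survey
shares; with no prior either, the mass stays unknown — it still counts in
the level totals when only the sector is unknown, and is dropped from the
sector-specific shares with a logged warning.

Sampling uncertainty: Kish effective sample size `(Σw)²/Σw²` and binomial
variance `p(1−p)/n_eff`, times a configurable design-effect inflation
(default 1.0; the generator draws births independently, so no clustering
is emulated). Administrative (vital-registration-like) sources are rows
with unit weights, which makes `n_eff` the birth count under the same
formula.

Modelling happens on the logit scale with proportions clamped to
`[c, 1−c]`. The clamp is `c = 0.001`: the smallest shares this method must
report (private lower-level shares well under 0.5% in many countries) have
to stay representable, and a larger clamp demonstrably biases the smallest
category upward by flooring its zero observations. Delta-method variance
`var_y = var_p / (p(1−p))²` propagates the sampling variance to the logit
scale.

## ST-GPR

**Stage 1 — covariate ensemble.** For every subset of the covariates
(plus intercept-only; subset size configurable, default all), a linear
mixed-effects model with nested random intercepts for super-region, region
and country is fit to the logit-scale data (statsmodels `MixedLM`; REML,
L-BFGS). If the optimiser fails numerically the spec falls back to its
fixed-effects least-squares solution with zero random intercepts, logged —
such models are penalised by their out-of-sample error anyway.
Out-of-sample RMSE comes from cross-validation whose folds partition
*sources* (default 10 folds), so the ≤5 cohorts of one survey never
straddle the split; squared errors are pooled across folds before the
root. Ensemble weights are normalised inverse RMSE; a zero-RMSE model
takes the full weight, split equally among zero-RMSE models. Predictions
for any country-year add the fixed effects and the sum of available
estimated random intercepts (unseen groups contribute zero).

**Stage 2 — space-time smoothing.** Residuals (datum − stage 1) are
averaged into each country-year with weight = time weight × space weight.
Time weight: `(1 − (Δt/(1+Δt_max))^λ)³` with `λ = 0.5` and `Δt_max` the
largest gap between the prediction year and any contributing datum's year.
Space weight: `ζ = 0.9` within the same country, `ζ(1−ζ)` same region,
`ζ(1−ζ)²` same super-region, 0 beyond; within a tier the mass is split
equally across contributing countries, and within a country the time
weights are normalised. Locations with no reachable data return stage 1
unchanged.

**Stage 3 — GP.** Per country, a Gaussian process over years with prior
mean the stage-2 series, Matérn-5/2 kernel with length-scale `ℓ = 5`
years, and heteroskedastic noise equal to each datum's logit-scale
sampling variance. The amplitude is `η = mult × 1.4826 × MAD` of the
stage-1/stage-2 differences, pooled by region and floored at 0.05 (logit
units) so the prior never collapses; `mult = 1.0` by default. The
differences are measured at location-years that have data: cells far from
any datum receive near-zero smoothing corrections and would dilute the
scale toward the floor. Conditioning is dense Cholesky with a 1e-10
jitter retry; posterior draws (default 1000; the study-sized runs in this
repository use 100) are multivariate normal in logit space,
back-transformed by the inverse logit, seeded per (indicator, country).

## Raking, aggregation, uncertainty

All reconciliation is per draw, in proportion space, multiplicative
(preserving zeros): first (hospital, lower) totals are scaled to sum to
the envelope draw, defining hospital and lower envelopes; then each sector
pair is scaled into its level envelope; non-facility is 1 − envelope. A
cell whose components are all zero against a positive envelope gets an
equal split with a logged warning; a zero envelope zeroes the components.
An envelope supplied as a single column is replicated across draws and
flagged.

Regions, super-regions and the global aggregate are live-birth-weighted
means of country draws — never of summaries — so aggregation commutes
with summing categories. Single-member aggregates copy the member's draws
exactly. Summaries are the draw mean and the 2.5th/97.5th percentiles with
linear interpolation between order statistics (pinned for
reproducibility). The change decomposition differences the start- and
end-year compositions per draw; the share of the facility increase
attributed to each category is reported only over draws where the absolute
facility change exceeds 1e-6 (the excluded count is logged and written).

## Synthetic world

The generator emulates the statistical structure of multi-survey inputs:
true compositions are softmax of per-category logistic time trends with
region- and country-level Gaussian shifts (facility share rising over the
period; year-to-year changes bounded by construction below 5 percentage
points); covariates are noisy monotone transforms of the facility logit;
the envelope is the true in-facility share with logit-normal noise (scale
0.1) applied both to the centre and per draw, emulating an honest external
estimate; surveys draw births multinomially from the truth within 5-year
recall windows, attach labels from a ~45-term dialect catalogue, flag
caesareans at 15% (hospital) vs 3% (lower-level), and carry log-normal
weights.

Defaults: 2 super-regions × 2 regions × 5 countries (20 countries),
1995–2023, 3 surveys per country, 2000 births per survey; 2% of facility
births get a level-ambiguous label and 7% a sector-ambiguous one (half the
level-ambiguous labels are resolvable only by caesarean sorting); 0.5% of
responses are missing. Not emulated: survey design (strata/clusters),
recall bias, systematic misreporting between survey and administrative
sources, subnational geography. Passing recovery tests therefore show the
estimator recovers truth under honest, independent, unbiased sampling —
not robustness to the reporting biases of real surveys.

## Numerical choices

- Clamp `c = 0.001` on proportions before logit and variance (see above).
- Caesarean-sort ties resolve to unknown within 1e-12.
- GP jitter ladder 0, 1e-12, 1e-10, 1e-8 for Cholesky; non-PSD after that
  raises.
- Percentiles: linear interpolation; draws are columns, reordering them
  never changes a summary.
- All randomness flows from one root seed through named substreams
  (simulation per country, folds, draws per indicator and country), keeping
  any two runs of the same configuration byte-identical.
- Fold assignment: sources sorted, shuffled once per indicator, dealt
  round-robin into folds.

## Known limitations

- The six indicators are modelled independently; coherence is imposed only
  at raking. Within-country correlation between categories is therefore
  not carried into the draws beyond what raking induces.
- Uncertainty calibration is inherited from the three-stage design: the GP
  prior mean is itself fit to the same data, and the amplitude measures
  the stage-1/stage-2 disagreement, which understates the smoothed
  series' true error (only the component of ensemble error visible above
  sampling noise is corrected, and hence measured). On the default
  synthetic world the recovery check in `tests/test_acceptance.py`
  computes mean absolute error well under 1 percentage point but empirical
  95%-interval coverage in the low-to-mid 80s rather than the high 90s.
  `gp_amplitude_mult` exists precisely to widen the prior where better
  calibration information is available; the default stays 1.0.
- The caesarean sorter needs both comparator rates in the same
  source-location; sources seeing only one level keep their ambiguous
  options unknown.
- Envelope draws are consumed as given; no coherence between the envelope
  and the indicator models is enforced beyond raking.
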