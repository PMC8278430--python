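# Methods

This note documents the statistical model, the defaults and why they were
chosen, the numerical conventions, and what the synthetic-data tests do and
do not demonstrate.

## Quantification model and QC

Quantification follows the plain Livak 2^−ΔΔCt scheme with amplification
efficiency fixed at 2 (one doubling per cycle); no efficiency correction or
standard curves are attempted. Duplicate wells are collapsed by the
arithmetic mean of Ct — averaging on the cycle scale, i.e. the geometric
mean on the abundance scale, which is the standard convention for
replicate Ct values.

The duplicate-concordance rule is **inclusive**: a pair is excluded when
|Ct₁ − Ct₂| ≥ threshold (default 0.2 cycles). Because Ct readings are
decimal values, the pair difference is rounded to 9 decimal places before
the comparison; otherwise (20.00, 20.20) would evade an inclusive 0.2 rule
purely through binary-float representation. Missing Ct (instrument
"undetermined", modeled as Ct beyond the detection limit) excludes the
pair; values are never imputed. A sample whose **spike-in** pair fails QC
is dropped for *all* markers: the spike-in is a per-extraction reference,
so every ΔCt of that sample is uninterpretable — sample-wide invalidation
is the only self-consistent scope for the exclusion rule. All exclusions
are logged at WARNING level with sample, assay, reason and Ct difference,
since they change the effective n.

Two RQ estimators are provided because group fold changes can be computed
either from the group-mean contrast (pooled, RQ = 2^−ΔΔCt, the default) or
by averaging per-sample 2^−ΔΔCtᵢ values. The per-sample mean is ≥ the
pooled value whenever case ΔCt varies (Jensen's inequality for 2^−x, an
invariant the tests enforce); published fold changes computed one way are
routinely irreproducible from cycle differences computed the other way, so
both are reported side by side.

## Group testing

The Mann-Whitney U is defined as the count of case–control pairs with the
case value larger, plus ½ per tie. This orientation makes U/(n₁n₂)
*identically* the empirical AUC of the higher-in-cases polarity, welding
the test to the ROC module; the suite asserts the identity to 1e-12 on
random tied data. Exact two-sided p-values (2·min tail of the permutation
null) are used for tie-free samples with n₁+n₂ ≤ 20; larger or tied
samples use the normal approximation with continuity correction and
tie-corrected variance (the common SPSS-style choice). Agreement between
the exact and approximate paths is within 0.02 when each group has ≥ 5
members; splits with a group of 2–4 can disagree by up to ≈ 0.04 from the
granularity of the discrete exact null — an inherent property of the
approximation, not a defect. No multiplicity adjustment is applied by
default (panels of ~4 markers are reported unadjusted in this literature);
Benjamini-Hochberg is available by flag.

## ROC analysis

Curves are computed over the unique observed thresholds with sentinels, so
they start at (0,0) and end at (1,1); ties produce diagonal segments whose
trapezoidal area gives the ½-credit convention automatically. Polarity
`auto` picks the orientation with AUC ≥ 0.5 and records it, since marker
panels routinely contain both up- and downregulated species.

Variance of a single AUC uses the DeLong structural-components estimator;
confidence intervals are Wald on the logit scale via the delta method,
back-transformed and clipped. The logit interval was chosen over a plain
Wald interval because empirical high-AUC intervals are visibly asymmetric
(e.g. AUC 0.975 with SE 0.018 yields roughly 0.90–0.99); coverage of the
combination is checked by simulation (93–97% at a true AUC of 0.8 with
n = 38/28). The operating point maximizes Youden's J = sens + spec − 1
over observed thresholds; ties are broken toward higher sensitivity (a
screening context favors detection), then toward the lower cutoff.

Marker combination uses a maximum-likelihood logistic score, fitted by
Newton-Raphson/IRLS (tolerance 1e-8 on the max coefficient update, 100
iterations). The combined ROC of a linear score is the standard
construction for multi-marker panels and the only one reproducible from
first principles; point-and-click packages do not document theirs.
Complete/quasi-separation (any |standardized slope| > 15, or every fitted
probability within 1e-6 of its label) sets a flag and triggers a refit
with ridge 1e-4 on the slopes (intercept unpenalized), keeping the score
finite without materially changing its ranking. A singular Hessian (e.g.
duplicated markers) falls back to the pseudoinverse step. The IRLS fit is
cross-checked against an independent ML implementation in the tests.

Subset selection fits every non-empty subset (capped at 16 markers);
among subsets within ΔAUC = 0.01 of the maximum the smallest wins, ties
broken lexicographically, and every excluded marker's marginal ΔAUC is
recorded in the trace. Selection is **in-sample** — no cross-validation —
matching how small biomarker studies typically report combined models; the
winning AUC is therefore optimistically biased, most visibly at small n
where a 3–4 marker logistic fit on ~60 samples can reach AUC ≈ 1. Treat
the selected panel's AUC as descriptive, not as an out-of-sample estimate.

## Pathway counting

Membership counts only: the number of a panel's validated targets falling
in each gene set, per miRNA or pooled (the pooled hit set equals the union
of per-miRNA hit sets — tested), plus unique/shared-target summaries and
per-category distinct-gene rollups. Gene identity is the upper-cased
symbol string with no alias resolution. Database snapshots (two-column
TSV target lists, standard GMT) replace live web-service queries: such
counts are database-version-dependent, so reproducibility requires frozen
inputs. The packaged `synthetic_*` files are small synthetic stand-ins
for real miRWalk/KEGG exports, suitable for tests and demos only; plug in
a real GMT export for actual studies. An optional one-sided hypergeometric
p per pathway (against a stated background-universe size) is provided as a
clearly-labeled extension; no over-representation statistic is computed by
default.

## Synthetic cohort generator

The generator emulates the data structure the analysis assumes: duplicate
wells per assay, an exogenous spike-in whose per-sample draw is shared by
all assays of that sample (one extraction per sample — so spike-in
variability cancels in ΔCt up to technical noise), normal between-subject
variation of ΔCt (log-normal abundance, the standard qPCR noise model),
independent normal technical noise per well, optional per-subject outlier
shifts, planted discordant duplicate pairs for QC testing, and missing
values above a detection limit (default 40 cycles). All randomness flows
from one explicit seed; identical specs give byte-identical tables.

Defaults of the example study cohort (38 cases vs 28 controls, four
markers):

| parameter | value | rationale |
|---|---|---|
| effects (ΔΔCt, cycles) | −2.83, +1.63, −2.16, −2.83 | the per-marker group contrasts such serum panels report; both polarities represented |
| subject SD (cycles) | 2.14, 1.39, 2.20, 5.20 | back-solved from per-marker AUCs ≈ 0.825/0.796/0.756/0.65 via the binormal identity AUC = Φ(|ΔΔCt|/(σ√2)), so discriminability — not just shift — matches a realistic panel |
| spike-in | mean 21 Ct, SD 0.5 | mid-range reference abundance with modest extraction variability |
| replicate SD | 0.05 cycles | typical duplicate-well precision; makes natural violations of the inclusive 0.2 rule rare (~0.5% of pairs, ~1–2 per cohort), consistent with a design that loses only a couple of samples to QC. Note 0.15 would put the SD of the pair difference at 0.21 and exclude ~⅓ of all pairs |
| qc_fail_shift | 0.5 cycles | planted discordance comfortably ≥ any reasonable threshold, so planted counts are exact when technical noise is off |

What passing tests on this generator show: the estimators are unbiased and
calibrated (ΔΔCt recovery, CI coverage, type-I error, closed-form AUC) and
the pipeline's filtering/selection logic behaves as specified under the
assumed model. What they do not show: robustness to features of real qPCR
data the generator deliberately omits — plate/batch effects,
amplification-efficiency differences between assays, pre-amplification
bias, heavy-tailed or skewed subject distributions, and covariate
structure (sex is not simulated; the motivating study context reports
sex-related differences as small and insignificant).

## Numerical conventions and degenerate inputs

- Ct pair differences rounded to 9 decimals before the inclusive QC
  comparison (see above).
- Constant pooled data in the U test → p = 1 with a warning rather than a
  0/0 variance.
- AUC at the boundary {0, 1} or SE = 0 → zero-width CI with a warning (the
  logit transform is undefined there).
- DeLong variance floored at 0 before the square root.
- IRLS weights clipped at 1e-10; singular Hessians solved by pseudoinverse.
- Reports contain no timestamps and hash only analysis-relevant config
  fields, so identical configs + seeds give byte-identical JSON.
- Problem sizes used by the simulation-based checks (500–2,000 replicates
  at the 38/28 design; 5,000 per group for closed-form AUC checks) were
  chosen so Monte-Carlo error is well inside each test's tolerance band.

## Known limitations

- In-sample panel selection (no CV); optimism grows as markers approach n.
- No efficiency correction, multi-plate calibration or absolute
  quantification.
- Gene symbols are matched as strings; no alias/ID mapping.
- The exact U path enumerates arrangements only for n₁+n₂ ≤ 20 tie-free
  samples; tied small samples use the approximation.
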