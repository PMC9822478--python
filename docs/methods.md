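# Methods

## Problem and model

`toxcp` builds prediction-set classifiers for binary molecular toxicity
endpoints. Instead of a single forced class call, each compound receives a
subset of {0, 1} — one label, both, or neither — with a distribution-free
guarantee on the error rate. The machinery is Mondrian (class-conditional)
inductive conformal prediction (ICP) aggregated over an ensemble:

1. **Split.** The training pool is partitioned per ensemble member into a
   proper-training part, an optional validation part (used only by base
   learners that need early stopping; otherwise folded into proper
   training), and a calibration part. Default fractions (0.72, 0.08, 0.20)
   follow the published split sizes of the acute-toxicity benchmark this
   pipeline targets (6004/662/1670 of an 8336-compound pool). Partitions
   are stratified by label; part sizes use largest-remainder rounding so
   they sum exactly to the pool size.
2. **Score.** A probabilistic base classifier (default: scikit-learn
   `RandomForestClassifier` with default options) is fitted on the
   proper-training part. The nonconformity of a compound for candidate
   class c is `alpha = 1 − P(c | x)`, the inverse-probability score. This
   choice keeps the internal path and the external-score path (below)
   structurally identical; margin-based nonconformity would not.
3. **Calibrate (Mondrian).** Calibration compounds are grouped by their
   *true* class; class c's table holds the `alpha` of each class-c
   calibration compound. Because each class is calibrated against its own
   scores, the coverage guarantee holds per class — the property that lets
   heavily imbalanced endpoints (the 11:1 very-toxic regime) be modelled
   without resampling, class weighting or cost-sensitive tricks.
4. **P-values.** For a test compound and class c,
   `p_c = (#{alpha_i ≥ alpha} + 1) / (n_c + 1)` over class-c calibration
   scores. Ties count as ≥ and the +1 includes the test point itself, so
   the p-value is conservative and deterministic. Optional smoothing
   replaces the tie mass with a seeded uniform fraction
   (`p = (#{>} + τ·(#{=}+1)) / (n_c+1)`, τ ~ U(0,1)), giving exactly valid
   but randomized p-values; it is off by default so that runs are
   reproducible bit for bit and validity errs on the safe side.
5. **Aggregate.** K members (default 10), each with its own independent
   split and learner seed, produce K p-value pairs per compound; the
   ensemble p-value is the per-class median (even K: mean of the two
   central order statistics). Re-partitioning per member is what makes the
   median aggregation meaningful — members differ in both training and
   calibration randomness.
6. **Predict.** Class c enters the prediction set iff `p_c > ε`
   (strict: a p-value exactly at the significance level is excluded).

**External scores.** Predictions from models trained outside the pipeline
(e.g. fine-tuned SMILES language models) enter as per-compound class-1
scores `s ∈ [0,1]`; they are treated as the probability pair `(1−s, s)` and
run through the identical Mondrian machinery, calibrated per member split
and median-aggregated. The equivalence of the two paths is asserted bitwise
in the test suite.

**Seed discipline.** One master seed spawns per-member child seeds via
`numpy.random.SeedSequence`; each child seeds the member's partition, its
learner's `random_state`, and (when smoothing is on) its tie-breaks. Same
config + seed ⇒ byte-identical outputs, which the pipeline tests assert on
the written report files.

## Chemistry preprocessing

Standardization applies, in order: largest carbon-containing fragment
(salt stripping; ties broken by lexicographically smallest canonical
SMILES), stereochemistry removal, an organic element filter
({H, B, C, N, O, F, P, S, Cl, Br, I}, carbon required), charge
neutralization, and RDKit tautomer canonicalization, emitting canonical
SMILES. Neutralization protonates/deprotonates simple charged centres via
the standard SMARTS
`[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]`; quaternary
ammonium cannot be neutralized and is kept charged, not excluded.
Standardized SMILES longer than 200 characters (configurable) are excluded
— a stand-in for the sequence-length caps of downstream SMILES language
models, for which no canonical number exists. Every exclusion carries a
reason (`parse_failure`, `inorganic`, `empty_after_salt_strip`,
`too_long`); batch counts conserve the input size, and standardization is
idempotent on its own output (tested).

Featurization computes a frozen 96-name physico-chemical RDKit descriptor
panel (`src/toxcp/data/descriptors.yaml`) through
`MolecularDescriptorCalculator`. The panel is configuration, not code:
point `--descriptors` at any YAML list. The shipped panel was chosen once
for numerical robustness — families that return NaN on ordinary organics
(2-D BCUT, partial-charge extrema, the overflow-prone information-content
index) are excluded. Molecules for which any descriptor still fails are
dropped and reported, never imputed: silently filled values would break
the exchangeability between calibration and evaluation sets that the
coverage guarantee rests on.

## Evaluation measures

Per class c, over true-class-c evaluation compounds:

* **validity** — fraction whose set contains c (both-label sets always
  correct, empty sets always errors). A model is *flagged valid* at ε when
  `1 − validity ≤ ε + 0.025`.
* **efficiency** — fraction receiving exactly one label, right or wrong.

SE/SP/BA are computed over single-label predictions only, positive class
= 1 (the minority/toxic class); both/empty sets carry no committed call
and are excluded from these ratios but reported in the full 2×4
outcome-by-true-class contingency. Zero-denominator ratios are reported as
missing, never as 0. The report table blanks efficiency/SE/SP/BA for rows
whose validity flag fails, since efficiency of an invalid model is not
meaningful. These identities are asserted exactly against the contingency:
`validity ≡ (single_correct + both)/n_c`, `efficiency ≡ singles/n_c`,
`BA ≡ (SE+SP)/2`.

## Synthetic data: what it emulates and what it does not

`generate_tabular` draws i.i.d. rows: two multivariate-normal classes with
identity within-class covariance, means separated by δ along a random unit
direction, at a configurable majority:minority ratio, with optional
independent label flips. Defaults mirror the two endpoint regimes the
pipeline targets: `vt_like()` (ratio 11) and `nt_like()` (ratio 1.6), both
at δ = 1.5 — a moderately informative regime where a default random forest
reaches validity comfortably but efficiency stays well below 1, i.e. the
regime where conformal behaviour is actually interesting. Being i.i.d.,
any later split is exchangeable by construction, which is exactly the
assumption under which the coverage guarantee is proved — so passing
coverage tests here validates the implementation, not the exchangeability
of any particular real-world dataset. The generator does not emulate
descriptor correlation structure, activity cliffs, assay noise structure,
or train/evaluation distribution shift; results on real endpoints depend
on those.

`generate_score_fixture` draws class-1 scores from Beta distributions
whose means separate with a quality dial (quality 0: both classes uniform;
quality 1: concentrated near the true label), emulating external model
prediction files. `toy_smiles_fixture` ships 26 curated SMILES — salts,
zwitterions, stereocentres, two tautomer pairs, a quaternary ammonium, and
one representative of every exclusion reason — with hand-written expected
structures frozen beside them.

## Numerical choices and edge cases

* P-values are computed by `searchsorted` on the sorted calibration array;
  equality with a brute-force counting loop is asserted over 1,000 random
  instances, exactly. An independent reference ICP (own learner fit, full
  pairwise-comparison p-values) must agree with the pipeline to 1e-12 on a
  matched split.
* Prediction sets are nested in ε by construction (tested), and p-values
  are non-increasing in nonconformity (property-tested).
* Degenerate inputs are hard errors, never silent: single-class
  calibration sets, splits that would give a part fewer than 2 members of
  either class, duplicate ids, scores outside [0,1], NaN in feature files,
  ragged ensemble ids.
* Two properties one might expect of "better separated ⇒ better sets"
  hold only for confidence-saturated scorers and are tested as such: with
  continuous scores (a forest's), the true-class p-value is near-uniform,
  so ~ε of compounds receive empty sets however separable the classes are
  — near the efficiency ceiling (1 − ε) this makes efficiency
  non-monotone in separation, and it caps the single-label fraction below
  1 − ε. A fully grown tree emits exact 0/1 probabilities; its sets are
  never empty (one class always has zero nonconformity, hence p = 1), so
  on separable data nearly all predictions are single-label and
  efficiency falls cleanly out of the both-rate. The relevant tests use
  the tree scorer and document the mechanism.

## Problem sizes

The study-scale checks run the heavily imbalanced regime at a
5000-compound training pool and 2000-compound evaluation set with K = 10
(one run ≈ 25 s on one CPU; minority calibration tables hold ≈ 80 scores,
so the minority p-value granularity is ≈ 1/80). The balance property
averages five such seeds. Unit and property tests use pools of 600–2000
compounds with K ≤ 3.

## Known limitations

* Binary endpoints only; no multi-class Mondrian taxonomy, no regression
  CP, no transductive CP.
* The external-score path assumes scores are class-1 probabilities (or
  monotone equivalents on [0,1]); uncalibrated margins must be squashed
  first.
* The benchmark ingestion adapter locates columns by common-name guesses
  plus an explicit mapping override; it has been exercised only against
  synthetic files shaped like public exports, since the pipeline never
  downloads data.
* Validity flags use the fixed 2.5-point tolerance convention; there is no
  finite-sample confidence adjustment on the flag itself.
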