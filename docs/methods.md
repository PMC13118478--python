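# Methods

## The measurement model

One digestion produces two physical fractions: the dialysate (the 500 mL
water bath outside the cellulose membrane after the intestinal phase) and
the retentate (the contents of the dialysis tube). Each fraction is
mineralized and measured by ICP-OES as a concentration in a final diluted
digest. The pipeline converts a measured concentration `C` (µg/mL) to an
iron amount

    mg = max(0, C − Cc) · V · R / (1000 · f)

where `Cc` is the reagent-blank concentration, `V` the final digest
volume (mL), `R` any further dilution applied before measurement, and `f`
the share of the physical fraction represented in the digest. The default
conventions are:

| fraction  | V (mL) | R | f | rationale |
|-----------|--------|---|------|-----------|
| dialysate | 10 | 1 | 5/500 = 0.01 | a 5 mL aliquot of the 500 mL bath, digested and diluted to 10 mL |
| retentate | 10 | 1 | 1/50 = 0.02 | 1 g of the ~50 g tube residue, digested and diluted to 10 mL |

The amount rule is a design choice: assay protocols state volumes and
aliquots but not a closed-form concentration→amount conversion, and this
factorization is the dimensionally consistent one. Negative
blank-corrected differences are clamped to zero (concentrations below the
blank are measurement noise; amounts are physically non-negative).

The bioaccessibility statistic is

    B% = (D + Dr) / (T + D) · 100,   Dr = (Cd − Cc) · Vt · R / 1000

with default geometry `Vt` = 50 mL (the 50 g diluted digest inside the
tube), bath volume 500 mL, and `R` = 2 — the dialysate's own 5 → 10 mL
digest dilution, which converts the measured digest concentration back to
the bath (= tube-equilibrium) concentration. `R` here is interpreted as
the dialysate's analytical dilution factor; it is configurable for
protocols where a different factor applies. Whether `D` itself is blank
corrected is also configurable (`blank_correct_dialysate`); correction is
the default, since the blank represents reagent-borne iron present in
every fraction.

Interpretation limits: `B% ≤ 100` is guaranteed only when `Dr ≤ T`, which
holds for all generator output and for any physically consistent record
(the equilibrium iron inside the tube is part of the retentate); strongly
inconsistent inputs can exceed 100 and are not clipped, so that QC
problems remain visible.

## Study design and enumeration

The default design is 8 products × 3 diets × 3 batches × 3 replicates,
plus one diet-only model per diet run as a single batch of 3 replicates,
plus 3 reagent blanks: 27 models and 228 digestions, hence 456 analytical
samples and 462 including the 6 reference-material replicates. Blanks are
modeled as digestions without product or diet; they enter sample counts
but no bioaccessibility group.

One published inconsistency is worth noting: the pooled summary tables
print n = 27 for the diet-only stratum, while the stated enumeration
(3 diets × 3 replicates within a 228-sample total) yields 9 diet-only
digestions. The package follows the enumeration; pooled diet-only means
are unaffected because the per-diet replicate counts are equal.

## Statistics engine

* Descriptives: mean, median, min, max, IQR and sample SD (n − 1).
  Quantiles use linear interpolation — the most common default; the
  choice matters only for small n and is stated here because published
  tables rarely name their rule.
* Normality gate: Shapiro–Wilk per group at α = 0.05; the parametric
  branch (one-way ANOVA + Tukey HSD, Tukey–Kramer for unequal n) requires
  *every* group to pass; otherwise Kruskal–Wallis (tie-corrected H,
  chi-square p) + Dunn's test. Gating is per comparison, not global. A
  constant group routes to the rank branch (W is undefined at zero
  variance).
* Dunn's test: mean-rank z statistics with the tie correction
  `S² = N(N+1)/12 − Σ(t³−t)/(12(N−1))`, two-sided normal p, Bonferroni
  adjustment by default (Holm and unadjusted selectable). The adjustment
  is a package default; the convention in the source literature is
  unstated.
* Kruskal–Wallis additionally offers an exact permutation p
  (`p_method="exact"`, N ≤ 12) by enumerating all assignments of the
  pooled values to groups of the observed sizes; used for validating the
  asymptotic path on tiny samples.
* Levene (Brown–Forsythe) is provided as an optional diagnostic only; it
  is not part of the gate.
* Significance tiers: p < 0.05 / p < 0.01 / p < 0.001, else `ns`.

## Aggregation

Pooling levels: product × diet, chemical form × diet, chemical form,
pharmaceutical form, and the diet-only pool. Because every product × diet
cell has equal replication, a pooled mean equals the unweighted mean of
its constituent cell means (equal-n identity, tested exactly).

The pharmaceutical-form grouping used for pooled reporting assigns
products {1, 2, 3, 4, 7} to coated tablets, {5} to tablets, {6} to
capsules and {8} to extended-release tablets. Product 3 is labeled
"tablet" in the catalog but pooled with coated tablets: only that
grouping reproduces the published pooled means (coated n = 135, tablets
n = 27, means 3.02 and 19.31 re-derivable exactly). The catalog label is
preserved; the reporting rule is explicit in
`ferrodial.aggregate.REPORTING_PHARMA_GROUPS`. Two published
pooled values are not exactly re-derivable from their own constituents:
the coated-tablet mean prints 7.02 where the constituent per-model means
average to 7.0147 (→ 7.01), and the bisglycinate pool is quoted once as
7.32 against a tabulated 7.31 (constituents average 7.3133). The package
reports the re-derived values; the printed variants presumably come from
unpublished raw data or rounding slips. Display rounding is half-up to 2
decimals via `decimal`; all pooling is done at full precision.

## Method validation

Reference-material replicates (certified flour–milk mixture, 22.9 mg/kg)
are summarized as mean, sample SD, RSD% and recovery%. Recovery is
reported at full precision (21.7667/22.9 = 95.05%); the commonly printed
95.2% arises from dividing the display-rounded mean (21.8) by the
reference and is deliberately not reproduced. LOD/LOQ use the ICH-style
blank-noise convention 3.3·σ/slope and 10·σ/slope; published LOD/LOQ
values cannot be checked without the underlying blank series, so the
package computes them only from user-supplied blanks.

## Synthetic-data generator

What it emulates: the complete sample inventory (models × batches ×
replicates × fractions, blanks, reference replicates) and the group-level
distribution of B%. Per model, true B ~ Normal(target mean, target SD)
truncated to (0.1, 99)% — the bounds avoid degenerate zero-recovery
samples — and the draw is inverted through the exact amount rules into
concentration records, so `compute_table` recovers each drawn B to
floating-point precision (measured ~1e-14). Default targets are the 27
published per-model (mean, SD) pairs; total iron per digestion is the
product dose plus an assumed 4 mg of diet iron per 25 g homogenate (diet
iron content is unpublished; 4 mg per quarter of a whole-day ration is a
realistic middle ground), with an analytical recovery fraction of 0.9.

Because the equilibrium correction is a deterministic function of the
dialysate concentration, the share of the bioaccessible pool carried by
`Dr` is fixed by geometry at `k/(1+k)` with
`k = Vt·R·f_d/(V_d·R_d) = 0.1` (share ≈ 1/11). `GroupParams.dr_share`
therefore defaults to this implied value, and a requested share
inconsistent with the geometry is rejected as admitting no valid
allocation rather than silently renormalized.

Seeding: one master `SeedSequence(seed)` spawned into one child per
experimental model in design order, plus one child for the reference
replicates; identical seeds give byte-identical datasets, and any stratum
can be regenerated independently. Batch is carried as a label only; no
batch variance component is added by default (the replication scheme
pools 3 × 3 without a published batch model), which is the main respect
in which the generator is simpler than real data. Other real-data
features it does not emulate: instrument-level noise (noise is placed on
B directly), inter-element interference, membrane-to-membrane variation,
and any correlation between fractions beyond mass balance. Passing tests
therefore demonstrate correctness of the computation and the statistical
machinery under the stated group-level model, not robustness to raw
instrument artifacts.

`perturb_for_nonnormality` replaces one model's draws with the transform
`B' = m + (exp(skew·(B−m)/s) − 1)·s/skew` (identity at skew = 0,
right-skewed for skew > 0, clipped to the truncation bounds) and
re-inverts concentrations, to exercise the nonparametric branch.

## Problem sizes and numerical choices

The test suite's calibration checks use 10,000 null replicates (type-I
error of Shapiro–Wilk and ANOVA at n = 9 within 0.05 ± 0.01) and the
contrast-detection check uses 100 generator seeds; parameter recovery is
checked at 900 replicates within 2%. Exact Kruskal–Wallis enumeration is
limited to N ≤ 12. Comparisons of derived to published group means use
±0.005 — agreement at the printed 2-decimal precision — because the
published tables round inconsistently at the half-ulp (e.g. a printed
12.04 whose constituents average 12.045).

## Known limitations

* Dialyzability is a proxy: it captures passive diffusion only, not
  DMT1-mediated transport, hepcidin regulation or colonic absorption, so
  B% ranks conditions rather than predicting absolute absorption.
* Published per-model medians/IQRs cannot be reproduced exactly (raw
  per-replicate data are not public); the generator matches means and
  SDs, and order statistics only in distribution.
* The batch factor is a label without a variance component; an optional
  batch random effect would be the natural extension if batch-level
  heterogeneity matters.
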