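# Methods

`mirsig` implements a complete desk-scale analysis pipeline for circulating
miRNA biomarker discovery in vulnerable coronary artery disease: Ct-matrix
preprocessing, SAM-based signature selection, signature evaluation,
differential coexpression networks, and microparticle (MP) quantification,
together with a synthetic cohort generator that reproduces the statistical
structure the analysis assumes. This note records the models, the defaults
and their rationale, the numerical choices, and the limits of what the
synthetic experiments demonstrate.

## Measurement model

Quantitative PCR reports the cycle threshold Ct at which amplification
crosses the detection level; abundance is proportional to 2^−Ct. Relative
expression against a reference assay r (U6 for plasma, hsa-miR-24 for MP
RNA) is

    expr[i, s] = 2^−(Ct[i,s] − Ct[r,s]),

dimensionless and positive. Statistics that assume roughly symmetric noise
(SAM's d, correlations, PCA, ROC cut-offs, logistic predictors) operate on
log10(expr); fold changes are ratios of arithmetic group means on the
linear scale. A well with no amplification by the 40th cycle is
undetected; the detection rule is strict (Ct < 40), so a stored value of
exactly 40 is also treated as undetected. This makes the cohort detection
filter (kept iff detected in ≥ 21 of 26 samples, the derivation-cohort
rule) well defined at the boundary. Undetected wells propagate as missing
values and are never imputed during preprocessing; each downstream
operation states its own missing-data policy (pairwise-complete means and
correlations; mean imputation only inside PCA, which requires complete
data and operates after the filter has capped missingness at 5/26 per
assay).

## SAM

The selection statistic is the moderated two-sample score

    d_i = (x̄_case,i − x̄_ctrl,i) / (s_i + s0),

with s_i the pooled standard error
sqrt[(1/n1 + 1/n2) · ΣSSQ_within / (n1 + n2 − 2)] on log10 expression. The
fudge factor s0 is chosen from the percentiles {0, 5, …, 100} of the s_i
distribution as the candidate minimizing the coefficient of variation of
the median absolute deviations of d computed within ten s_i-decile
windows, ties broken toward the smaller candidate; this decouples |d| from
the per-feature variance. The choice is deterministic given the data.

The null distribution uses relabelings of the samples that preserve group
sizes. When C(n, n1) ≤ the requested permutation count, all relabelings
are enumerated (so the null is exact and seed-independent); otherwise
distinct relabelings are sampled without replacement from a seeded
generator — C(26, 13) ≈ 10.4 million makes enumeration infeasible at the
cohort scale, and 1000 sampled relabelings are the default. For a
threshold t on |d|,

    FDR(t) = π0 · median over relabelings of #{null |d| ≥ t} / #{obs |d| ≥ t},

with π0 the fraction of observed d inside the interquartile range of the
pooled null, divided by 0.5 and capped at 1. A feature's q-value is the
minimum FDR over thresholds at or below its own |d|, which is
automatically monotone non-increasing in |d|; tied |d| values share a
q-value. The published selection rule — fold change > 8 (or < 1/8) and
q < 0.0001%, i.e. q < 1e-6 as a proportion — is applied with strict
inequalities; with ~1000 permutations, q < 1e-6 is operationally q = 0 (no
null exceedance at the feature's threshold). A miRNA enters calling only
when each group has at least two defined values.

Fold change is the ratio of arithmetic group means of linear expression
over pairwise-available samples. An alternative definition
(2^ΔΔCt of group-mean Cts) gives different values for skewed data; the
mean-ratio convention is exposed as the default because it is
scale-invariant and pairs naturally with the log-scale d.

## Evaluation

*Clustering.* Both matrix axes are clustered with average-linkage
agglomeration on Euclidean distances computed over pairwise-complete
coordinates (scipy's deterministic tie handling fixes the dendrogram).

*PCA.* Samples are projected onto the top three principal components of
the column-centered log10 matrix (SVD). The sign of each component is
fixed by making its largest-magnitude loading positive. The published
analysis reports a "correctly classified" percentage without defining the
rule; the default here is leave-one-out nearest group centroid in
component space. This is a genuine open choice — visual cluster assignment
on the 3-D score plot would give different percentages — so the rule is a
swappable parameter and the reported rates are rule-dependent.

*ROC.* AUC is the rank-based Mann–Whitney estimate with half credit for
ties; its 95% CI follows Hanley & McNeil, and the p-value against
AUC = 0.5 uses the normal approximation of U with tie correction. The
cut-off maximizes Youden's J (positive call = value ≥ cut-off), ties
broken toward higher specificity; the cut-off criterion is not stated in
the source analysis and Youden's J is the field convention. Cut-offs are
on the log10(2^−ΔCt) scale.

*Logistic regression.* Outcome (UA vs SA, UA vs control) on one miRNA's
log10 expression plus the covariate set {age, sex, hypertension,
dyslipidemia, diabetes, smoking, statin, antiplatelet}, fitted by Newton
IRLS (tolerance 1e-8, ≤ 100 iterations). The odds ratio is per unit of
log10 expression, i.e. per 10-fold expression change, matching the scale
of the ROC cut-offs. Perfect separation or non-convergence yields a
flagged result (infinite OR), not an exception. Samples with an
undetected marker value are dropped from that fit; missing covariates are
a hard error naming the column.

*Group tests.* Continuous variables pass a Shapiro–Wilk gate (α = 0.05 in
both groups) choosing between the pooled t-test and Mann–Whitney U, both
two-sided; 2×2 tables use Pearson χ² without continuity correction unless
any expected cell is below 5, then the two-sided Fisher exact test.

## Coexpression networks

Within each clinical group, Pearson correlations of log10 expression are
computed for all miRNA pairs over pairwise-complete samples (minimum
overlap 3); two-sided p-values come from t = r·sqrt((m−2)/(1−r²)) on m−2
degrees of freedom. Edges require r ≥ 0.79 and p < 0.02 — the published
construction thresholds, read as a positive-correlation criterion; an
|r|-based option exists because the sign convention is not settled by the
source description. Node sets contain only endpoints of surviving edges
(degree ≥ 1), which is how node counts far below the assay count arise.
Subnetworks take the PCR-validated panel as seeds plus their first
neighbors, with induced edges. Network comparison operates on unordered
edge pairs; exports (SIF, GraphML, edge-list TSV) are lexicographically
ordered for reproducible diffs.

## Microparticles

Concentration per µL plasma = (matching events in the 0.1–1 µm gate /
bead events) × (beads per tube / test volume). Annexin V⁺ events
partition exactly into CD31⁺ and CD31⁻ at the event level, so the
concentration identity CD31⁺ + CD31⁻ = total holds to machine precision
per sample and propagates to group means. Gating is consumed as boolean
event flags; inferring gates from raw scatter intensities is out of
scope. MP miRNA levels are 2^−(Ct − Ct[miR-24]) divided by the sample's
Annexin V⁺ concentration; adjusting to total Annexin V⁺ counts (rather
than a subtype) is the default because the source analysis says only
"adjusted to MP counts".

## Synthetic data

The generator defines the study conditions; its defaults are the
conditions of the emulated cohorts, not tuning knobs.

*Profiling cohort* (derivation defaults): 754 assays; 13 UA vs 13
controls; per-assay baseline Ct ~ N(28, 3²) across assays with 0.6-cycle
within-assay dispersion; U6 reference at Ct 25 with SD 0.15, always
detected; a 30-miRNA signature planted as −log2(FC) Ct shifts in cases
with FC uniform on [8, 24] (the printed range of the published
signature); logistic detection dropout centered at Ct 37 with scale 3
cycles, calibrated so ~5–15% of assays fail the 21/26 filter; and four
10-miRNA per-group latent-factor correlation blocks. The block parameter
is the target *pairwise* correlation ρ (default 0.9): each member loads
√ρ on a shared per-sample factor with √(1−ρ) residual. (A loading of 0.9
would give pair correlation 0.81 and, by the Fisher-z tail at 13 samples,
only ~55% edge recall at r ≥ 0.79 — inconsistent with the intended
≥ 80% recall behaviour, so the pairwise-ρ convention is used.)
Covariates are drawn marginally independent per group with the
validation-cohort frequencies; adjustment tests therefore verify
invariance of the marker OR, not correction of real confounding. The
validation preset uses groups 45/31/37, the 7-miRNA validated panel
planted at FC ∈ [2, 6], and a wider 1.6-cycle dispersion to produce
realistic AUCs (~0.7–0.85).

*MP study*: 5 vs 5 samples; per-subject true concentrations drawn from
the published group means with SD = SEM·√5 (Annexin V⁺ 5213 ± 882 vs
2240 ± 585 /µL; CD31⁺ 4318 ± 988 vs 1646 ± 462), floored at 1% of the
group mean; Poisson event counts at a fixed bead calibration (500 bead
events, 25 000 beads/tube, 100 µL). Note that at these dispersions the
5 vs 5 t-test has only moderate power (~0.7 at α = 0.05) for the Annexin
V⁺ difference; the generator keeps the printed dispersions rather than
shrinking them to force significance. The MP Ct matrix plants a 2-fold
case effect on the *count-adjusted* scale by including the sample's MP
load in the Ct model (more particles → lower Ct), so adjustment by
measured counts recovers the planted ratio.

What the synthetic experiments do **not** show: real plasma profiles have
heavier-tailed, assay-dependent noise, correlated covariates, batch
structure, and hemolysis artifacts; passing recovery tests here
demonstrates the correctness of the machinery under the stated model, not
field performance of the signature.

## Numerical choices and limitations

- All randomness flows through `numpy.random.default_rng(seed)`; reports
  and TSV bundles are byte-identical under a fixed seed.
- Written Ct matrices use repr-precision floats so write∘read is the
  identity.
- Problem sizes in the test suite and acceptance script (150–250 assays,
  100–1000 relabelings, 10–20 seeds) are chosen so the full synthetic
  battery completes in minutes on one CPU while keeping Monte-Carlo error
  well inside the asserted margins; the cohort-scale defaults (754 assays,
  1000 relabelings) run in seconds per cohort.
- Exact reproduction of the published per-miRNA scores would require the
  original SAM software defaults (permutation count, π0 estimator,
  statistic scale), which are not recorded; second-decimal differences in
  d are expected. The published network node/edge counts likewise depend
  on unrecorded choices (sign handling, node universe) and are treated as
  rule-dependent.
- GEO series-matrix ingestion is not bundled; any delimited Ct matrix in
  the documented TSV/CSV dialect can be analyzed directly.
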