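# Methods

This note documents the models, statistics, and design choices behind
`yprofiler`. The pipeline links the in-vitro sensitivity of cancer cell lines
to a beta-emitting radionuclide (⁹⁰Y microspheres) with their baseline
transcriptomes. It has four analytic stages — dose–response phenotyping,
bootstrap elastic-net stability selection, nearest-template subtype
classification, and a two-group differential-expression summary — plus a
synthetic-data generator that provides ground-truth cohorts for all of them.

## Dose–response phenotyping (nAUC)

Raw viability readouts are collected per cell line and replicate over an
activity ladder, by default {0, 0.1, 0.5, 1, 2, 4, 10, 20} MBq/mL. Within
each (line, replicate), readouts are divided by the untreated (activity 0)
readout, giving surviving fractions with fraction(0) = 1 exactly. The area
under each replicate's fraction-vs-activity curve is computed by the
trapezoid rule on the **linear** activity axis and normalized by the area of
a flat 100%-survival reference over the same span:

    nAUC = AUC_curve / (A_max − A_min)

so nAUC = 1 means full resistance and values near 0 mean strong
sensitivity. Replicate nAUCs are summarized as mean ± SEM (sample SD,
n − 1 denominator). Integration uses the linear axis because the
100%-survival reference area is only well defined there; values slightly
above 1 caused by replicate noise are reported as-is rather than clamped, to
keep replicate statistics unbiased.

Lines are grouped by the Z-score of their mean nAUC across lines (sample-SD
convention): resistant when z ≥ 0, sensitive when z ≤ −0.45, intermediate
otherwise. Both thresholds are configurable; the defaults reproduce the
canonical 5 resistant / 2 intermediate / 3 sensitive split of the ten-line
hepatocellular-carcinoma screen this package was built around. In practice
group assignment also weighs expression-space clustering (e.g. PCA), which
is why the thresholds are knobs and not constants.

Between-line differences in replicate nAUC are tested by one-way ANOVA with
Tukey's studentized-range adjustment for all pairwise comparisons
(`scipy.stats.f_oneway` / `scipy.stats.tukey_hsd`); subtype–phenotype
association uses the Kruskal–Wallis rank-sum test with tie correction. The
all-tied Kruskal–Wallis case is defined as H = 0, p = 1.

### Dosimetry utilities

Absorbed dose from an activity concentration follows the medical internal
radiation dose (MIRD) formalism under three simplifying assumptions:
complete decay of the administered activity, full local absorption of the
mean beta energy, and a uniform unit-density medium. With decay constant
λ = ln 2 / T½,

    D [Gy] = (A / λ) · E_mean / m

Defaults describe ⁹⁰Y: T½ = 64.2 h, E_mean = 0.93 MeV per decay, density
1 g/mL. Under these defaults 20 MBq/mL — the top of the ladder — converts to
≈ 993 Gy, i.e. the conventional "0 to 1,000 Gy" clinical in-vitro range.
`decay_activity` and `half_lives_elapsed` implement exponential decay
(a₀ · 2^(−t/T½)) and elapsed half-life counting; a 10-day assay spans
240 h / 64.2 h ≈ 3.7 half-lives, so essentially all dose is delivered within
the assay window. qPCR utilities implement relative expression
2^−(Ct_target − Ct_housekeeping) and the ΔΔCt log2 fold change.

## Synthetic cohorts

The generator draws survival curves from an exponential-decay-to-plateau
model: V(A) = s + (1 − s)·e^(−kA) + ε, where s ∈ [0, 1] is the unkillable
(plateau) fraction, k ≥ 0 the per-(MBq/mL) kill rate, and ε additive
Gaussian noise on the fraction scale, truncated at 0 (default replicate
noise SD 0.05, three replicates — typical bench-assay spread). The model was
chosen because real curves flatten at high activity and because it yields a
closed-form nAUC for oracle testing:

    nAUC = s + (1 − s)·(1 − e^(−k·A_max)) / (k·A_max),   limit k→0: 1

Expression is simulated as a negative-binomial count matrix
(variance μ + φμ², default dispersion φ = 0.1, library size 10⁶) with
gene-wise log-baselines Uniform(log 5, log 500). A planted subset of genes
has log-mean baseline + effect·z(phenotype), with the phenotype standardized
so the effect (default 2.0) is a log-fold change per phenotype SD — a strong
but realistic association for a screen designed around a resistant/sensitive
contrast. Signature profiles for classifier testing are class templates (+1
on own markers, −1 on other classes' markers) plus Gaussian noise.

What the generator does **not** emulate: batch and library-composition
effects, gene–gene correlation beyond the planted cluster, count
overdispersion heterogeneity across genes, plate-position dose gradients,
and microsphere/β-transport geometry. Passing tests therefore demonstrate
the correctness and calibration of the algorithms under a clean generative
model, not performance on real RNA-seq.

## Bootstrap elastic-net stability selection

Expression enters on the log-CPM scale, standardized per gene (mean 0,
SD 1, sample-SD; zero-variance genes dropped with a warning). The phenotype
vector is the per-line mean nAUC — one value per line. For b = 1..B
(default 100), lines are resampled with replacement (resamples with a
constant phenotype are redrawn and counted in a diagnostic), an elastic net

    (1/2n)‖y − β₀ − Xβ‖² + λ(α‖β‖₁ + (1−α)/2 ‖β‖²)

is fit (scikit-learn `ElasticNet`; intercept unpenalized), and each gene's
coefficient sign is tallied. The stability score is

    score_g = max(freq_pos_g, freq_neg_g),

the larger of the fractions of resamples in which gene g carried a positive
or negative coefficient; genes with score ≥ 0.7 are retained, ordered by
score, then |mean coefficient|, then identifier. The max-of-sign-frequencies
definition rewards direction-consistent selection, lives on the 0–1 scale of
the threshold, and penalizes genes that are selected often but with
alternating signs. A gene's marginal Pearson correlation with the phenotype
is reported alongside, computed on the full (unresampled) data.

**Penalty selection.** Per resample, λ is chosen by inner 3-fold
cross-validation over a 20-point geometric grid spanning two decades below
the data-derived λ_max (`ElasticNetCV`); a fixed-λ override bypasses the CV.

**Mixing default.** α (the L1 fraction) defaults to 0.1 — ridge-dominant —
and this is deliberate. Phenotype-associated genes come in correlated
clusters, and sign-frequency scoring only works if the whole cluster is
co-selected in most resamples. An L1-dominant penalty picks one arbitrary
cluster member per resample (the lasso's behavior on correlated predictors),
splitting the sign frequency across the cluster so that *no* member reaches
the threshold: on planted cohorts, per-gene frequencies plateau near 0.55 at
α = 0.5 regardless of λ. A ridge-dominant mixing engages the elastic net's
grouping effect — near-identical columns receive near-identical coefficients
— so the cluster is selected or dropped as a unit, while the small L1
component still zeroes unrelated genes. α remains configurable.

With n = 10 lines, bootstrap resamples often contain only 4–7 distinct
phenotype values, so individual resamples are weakly informative;
consistency across B = 100 resamples is what separates signal from noise.
Under a shuffled (null) phenotype the fraction of genes reaching score 0.7
is ~0 (checked at 500 genes); on planted cohorts (500 genes, 5 planted,
effect 2.0) mean recall and precision across 10 cohort seeds are ≥ 0.9.

## Nearest-template subtype classification

Marker signatures are read from GMT (one set per class; a `_dn` suffix marks
down-regulated marker sets). Each class template is the vector over the
marker-gene universe carrying each own-marker's direction on that gene and 0
elsewhere, unit-normalized; templates of disjoint marker sets are therefore
orthogonal. An `off_target_weight` parameter optionally places
−weight·direction on other classes' markers for contrast-style templates.

Each sample is assigned, independently, to the class minimizing the cosine
distance d_c = 1 − cos(profile, template_c) over marker genes (ties broken
by class order and flagged). Significance comes from a permutation null:
marker labels are permuted over the profile's genes (equivalently, template
rows are jointly permuted), and the null statistic is the **minimum**
distance over all permuted class templates — matching the minimum taken over
classes in the observed statistic. Comparing the observed minimum against
single-template permutation draws would be anti-conservative (minimum-
selection bias); with the matched statistic the add-one p-value

    p = (1 + #{null ≤ observed}) / (1 + n_perm)

is exact, and under pure-noise profiles it is uniform (verified by KS test).
BH step-up FDR is applied across samples. Counts are transformed to
log2 CPM, log2((c + 0.5)/(lib + 1)·10⁶), a plain log-count transform to a
roughly microarray-like scale; no precision weighting is applied.

## Differential-expression summary

The DE stage is deliberately a transparent surrogate: a gene-wise Welch
t-test on log-CPM values between the resistant and sensitive groups, with BH
adjustment across genes. It is not a count-model (negative-binomial) fit,
and its output header says so. The parts downstream analyses rely on are
test-agnostic: the significance filter keeps genes with FDR < 0.05 **and**
|log2FC| > 2 (both strict; the fold-change cut is two-sided), and gene-set
summaries report the arithmetic mean log2FC over all set members present in
the table (with n_present/n_set), without leading-edge weighting. Genes with
zero variance in both groups get p = 1 and a flag.

## Pipeline, reproducibility, numerics

`run_pipeline` executes simulate → nAUC → select → classify → DE in
dependency order, validates inputs first (column schemas, activity-0
presence, GMT well-formedness with line numbers, viability/expression sample
consistency), and writes every artifact as TSV/JSON with `#`-metadata
headers plus a manifest of sha256 content hashes. A single run seed is
fanned out to per-stage sub-seeds via `numpy.random.SeedSequence.spawn`, so
any stage can be re-run in isolation and reproduce its outputs bit for bit;
identical config + seed gives identical hashes.

Numerical choices worth knowing:

- trapezoid integration is exact for piecewise-linear curves on their knot
  grids; on smooth curves its error is O(h²·curvature), ~10⁻⁶ for
  realistic kill rates on a 1,000-point grid.
- elastic-net fits inside the bootstrap use tolerance 1e-4 (only coefficient
  *signs* are consumed); the standalone `fit_elastic_net` uses 1e-8 so it
  can be compared against an independent coordinate-descent implementation
  to 1e-6.
- degenerate cases are defined explicitly: ANOVA with zero within-group
  variance and distinct means reports F = ∞, p = 0; all-tied Kruskal–Wallis
  reports H = 0, p = 1; single-replicate SEM is 0 with a warning.

## Problem sizes

The bundled evaluation runs (test suite and `scripts/acceptance.py`) use
cohorts of 10 lines × 500 genes with 5 planted genes and B = 100 bootstrap
resamples over 10 cohort seeds for stability selection, 200 pure-noise
samples at 200 permutations for the classifier's null-uniformity check, and
1,000-point activity grids for the nAUC oracle — sizes chosen to estimate
each property with comfortable margin while keeping a full run around a
minute.

## Known limitations

- The stability-selection defaults are calibrated for small-n (≈10-sample)
  cohort designs; for larger cohorts a sparser mixing and fewer bootstrap
  redraw pathologies apply, and α should be revisited.
- The DE surrogate has lower power than count-model DE on real counts and
  its fold-change estimates shrink differently at low expression.
- Template classification assumes marker universes overlap the expression
  matrix; genes missing from the data silently shrink the universe (an
  error is raised only below 2 genes).
- The protein-coding/biotype filter applied in typical downstream reporting
  is an external annotation input, not bundled.
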