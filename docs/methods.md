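# Methods

## Model

For one trait on `n` lines the per-marker model is

    Y = Qv + Sα + Zu + ε,   u ~ N(0, VG·2K),   ε ~ N(0, VE·I)

`Q` is an intercept plus 0 or more structure covariates, `S` the tested
marker's minor-allele dosage, and `K` a marker-estimated kinship matrix.
`Z` is the identity in the uncompressed model and the sample→group
incidence matrix in the compressed model. Two configurations of the
correction terms are supported:

* **global** — one `K` and one `Q` estimated from all markers;
* **loco** — for markers on chromosome `c`, `K(−c)` and `Q(−c)` estimated
  from all markers *not* on `c` (plus a global pair kept alongside). This
  prevents proximal contamination: the tested marker and its LD partners
  can never enter the polygenic correction for their own chromosome. The
  cost is one null-model fit per chromosome per trait.

## REML by spectral profiling

Writing `A = 2K` and `δ = VE/VG`, the covariance is `VG(A + δI)`. `A + δI`
shares the eigenvectors `U` of `A` for every `δ`, so after one
eigendecomposition every likelihood evaluation reduces to weighted least
squares in the rotated coordinates `(U'y, U'X)` with weights
`1/(λᵢ + δ)`. The restricted likelihood (Patterson–Thompson form,
including the `+½ log|X'X|` term so it is invariant to the basis of `X`)
is profiled over `VG` in closed form and maximized over `δ` on a 101-point
log-spaced grid over `[1e−5, 1e5]` followed by bounded local refinement to
1e−8 in `log δ`. The bracket covers variance ratios corresponding to
heritabilities from ~2·10⁻⁵ to ~1−2·10⁻⁵; optima pinned at either end are
returned with a `boundary` flag (`δ → ∞` is the VG→0 / OLS limit). The fit
also records the profiled **ML** log-likelihood at the REML-estimated
ratio, used wherever likelihoods must be compared across different
fixed-effect structures (BIC, R²_LR) — restricted likelihoods are not
comparable there.

Numerical choices: kinship eigenvalues are clipped at 0 (Loiselle
truncation can leave the matrix slightly indefinite; the clip is a PSD
repair with negligible distortion and a warning when the most negative
eigenvalue is materially below −1e−6). A constant trait raises a
`ZeroVarianceError` rather than fitting a degenerate model. Singular
covariate designs are rejected.

## P3D marker tests

Variance parameters are estimated once per null model — per trait in
global mode, per (trait, chromosome) in loco mode, since `K` changes with
the excluded chromosome — and held fixed for every marker on that scan
("population parameters previously determined"). Each marker is tested by
a generalized-least-squares F test of `α = 0` with 1 numerator and
`n − rank(Q) − 1` denominator degrees of freedom; the covariance *shape*
(`δ`) is fixed while the residual scale is re-estimated per marker, so
with `VG = 0` the test is exactly the OLS F test. Effects and standard
errors are reported per minor-allele copy. Markers monomorphic in the
analyzed sample, or collinear with the covariates, yield all-NA rows with
a reason code — they stay in the table so marker counts are stable across
models. The per-marker `r2_lr` column is the likelihood-ratio R² of the
marker model against the null at the fixed ratio, which reduces to
`1 − RSS_marker/RSS_null` in the rotated coordinates.

In compressed mode, individuals are clustered by average-linkage
hierarchical clustering on `d_il = max(K) − K_il`, the grouped kinship is
the mean of `K` over group pairs, and the implied sample-level covariance
`Z K_g Z'` feeds the same spectral machinery. The compression level is
chosen by maximizing the null REML log-likelihood over a grid (default ~10
geometric levels from 1 to `n`; ties keep fewer groups; all evaluated
levels are returned as an audit trail). The marker-test denominator df
keeps the sample count `n`, a documented convention.

## Covariate selection and R²_LR

`select_pcs_bic` fits the null model for nested candidate sets
(intercept + 0..k leading components) and minimizes
`BIC = −2·ML log-likelihood + (#fixed effects + 2)·ln n`, the `+2`
counting the two variance components; ties go to fewer covariates. In
loco mode the selection runs per chromosome on that chromosome's own
`Q(−c)` candidates. `R²_LR = 1 − exp(−(2/n)(LL_full − LL_null))`, clipped
to `[0, 1)`, computed from ML likelihoods; for an ordinary linear model it
equals the classical R² exactly.

## Kinship estimators

* **VanRaden**: `K = ZZ' / (2Σ pⱼ(1−pⱼ))` with `Z` the column-centered
  dosage matrix. Frequencies come from the same marker subset used for
  the cross-products, so the estimate stays internally consistent under
  the 10% subsampling option. Monomorphic markers are dropped.
* **Loiselle**: biallelic single-allele form with the `(n−1)` small-sample
  bias correction,
  `f_il = [Σⱼ(y_ij−pⱼ)(y_lj−pⱼ) + Σⱼ pⱼ(1−pⱼ)/(n−1)] / Σⱼ pⱼ(1−pⱼ)`,
  `y = dosage/2`. Negative off-diagonal estimates are truncated to 0;
  the diagonal is left untruncated. The original reference admits several
  variants (allele-wise double sums, diagonal treatment); this is the
  reduction used by the common MLM-GWAS toolchains, documented here as
  the package's choice rather than asserted as the historical one.

Both estimators require imputed genotypes (imputation precedes kinship in
the supported recipes) and are invariant to marker order; minor-allele
recoding makes them invariant to ref/alt relabeling. Eigenvector and PC
sign is fixed by forcing each component's largest-magnitude loading
positive, for reproducibility across platforms.

## QC and conventions

Dosage codes the minor allele, recomputed per marker from the data, so
"major-allele imputation" fills 0 and heterozygote imputation fills 1.
The MAF filter is strict (`MAF < threshold` removed; exactly at the
threshold retained). QC order is fixed: restrict to the trait's phenotyped
samples, drop unanchored markers, MAF filter, impute (the per-trait MAF
filter is the default because sample subsets shift frequencies; a
pre-alignment variant is configurable). Positions are 1-based; all window
arithmetic is inclusive. FDR is controlled genome-wide per trait by
Benjamini–Hochberg, pooling all chromosomes' p-values after the
per-chromosome loco scans; the significance boundary is inclusive.

## Model comparison

The novel-region scan declares a model-A significant marker *novel* when
model B has no significant marker on the same chromosome within ±250 kb
(boundary inclusive; the window is configurable). The regional comparison
pairs the two models' p-values marker-by-marker inside a genomic region
and applies the Wilcoxon signed-rank test: zero differences dropped
(classical treatment rather than Pratt's), exact enumeration when the
non-zero sample is ≤ 25 without ties in |d|, otherwise the normal
approximation with tie and continuity corrections; two-sided by default.
P-values are reported at full precision with a separate display string
floored at 2.20×10⁻¹⁶ for journal-style tables.

## Simulator

Genotypes: ancestral allele frequencies are drawn per LD block
(Uniform(maf_floor, 1−maf_floor) block base + N(0, 0.05²) per-marker
jitter — tightly linked SNPs on shared haplotype backgrounds have
correlated frequencies, and without this the thresholding step caps
attainable dosage-scale LD); subpopulation frequencies follow
Balding–Nichols `Beta(p(1−F)/F, (1−p)(1−F)/F)` at the target FST (copied
exactly when F = 0); haplotype alleles arise by thresholding an AR(1)
latent Gaussian with parameter `ld_rho` within blocks (independent across
blocks and chromosomes); two haplotypes sum to a dosage, and columns are
flipped into minor-allele coding. Markers sit 1 kb apart, so a 20-marker
block spans ~20 kb. This design gives closed-form control of FST and LD
without an external coalescent simulator, at the cost of realism in
recombination history: LD decays geometrically within fixed blocks rather
than following a demographic process, and there is no mutation/ascertainment
model. Missingness is uniform when enabled.

Traits: `y = Σ β_q x_q + u + structure effect + e` with `e` standard
normal, the polygenic `u` drawn from the panel's own VanRaden kinship
(`N(0, 2K)` rescaled so `var(u)/var(e) = h²_poly/(1−h²_poly)`), so the
mixed model is correctly specified at the requested background
heritability; an infinitesimal per-marker toggle provides a misspecified
alternative. The structure effect adds `structure_beta` times centered
subpopulation-indicator contrasts. Presets: `mendelian` (one huge-effect
locus), `polygenic` (8 moderate loci over background), `complex` (50 small
loci). What passing simulation tests shows is therefore internal
consistency — the estimators recover the parameters of the generating
model — not robustness to the missingness patterns, allele-frequency
spectra or cryptic relatedness of real panels.

## Benchmarks and their conditions

`locogwas.benchmarks` fixes the study conditions used by the acceptance
script and tests:

* *Proximal contamination* (the headline power scenario): n = 300, 10
  chromosomes × 200 markers, `ld_rho = 0.95`, blocks of 20, one QTL of
  0.5 residual SD in the interior of a block, `h²_poly = 0.4`; both
  models run with VanRaden kinship and no structure covariates; power and
  FDP scored with a 25 kb window (one LD block plus slack) at 5% FDR,
  25 seeds.
* *Fully null error control*: n = 200, 5 × 200 markers, same LD, and a
  trait with **no genetic signal at all** (no QTL, no structure effect,
  no polygenic background), 25 seeds. The distinction matters: under a
  polygenic background the trait is genetic genome-wide, markers tagging
  the background on their own chromosome are not cleanly "false", and the
  loco model — by design — refuses to absorb that share of signal; that
  regime is a power property, not an error-control one.
* *Heritability recovery*: VG = VE = 1 drawn through the realized kinship
  of a structured panel (n = 200, FST 0.2), 20 seeds; the estimand
  vg/(vg+ve) has truth 0.5.
* *BIC selection*: structure-confounded traits (FST 0.3, subpopulation
  effect 2 residual SD) versus panmictic unconfounded traits, n = 150,
  10 seeds each.

Problem sizes were chosen so the whole battery runs in well under a
minute on one CPU while keeping Monte-Carlo error small relative to the
effects being measured.

## Known limitations

* P3D is an approximation; per-marker variance re-estimation is available
  only as a diagnostic path (the scans agree to Spearman ≥ 0.99 in the
  tested regimes, but P3D can understate uncertainty for very large
  single-marker effects).
* No multi-locus or stepwise models, no dominance/epistatic kinship, no
  GxE, no genotype likelihoods or phasing; integer dosages only.
* The compressed model's denominator-df convention and the Loiselle
  variant are documented choices, not the only defensible ones.
* Real-panel ingestion is supported (HapMap/VCF/CSV) but all shipped
  validation is simulation-based.
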