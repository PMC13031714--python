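# Methods

This note documents the statistical model, the estimation choices, and
the synthetic data used to validate them. Notation: $n$ samples, $m$
transcripts, $y$ the outcome (a polygenic score), $C$ the fixed-effect
design, $W$ the column-standardized $n \times m$ expression matrix.

## Polygenic scores

Scores follow the per-allele average convention
$\mathrm{PGS}_j = \sum_i S_i G_{ij} / (2M_j)$ with $M_j$ the per-sample
count of non-missing SNPs. The divisor makes scores comparable across
samples with different missingness; a raw weighted sum is available
(`average=False`) for workflows that standardize downstream.

Allele handling: weights and genotypes typically come from different
cohorts, so the coded allele of a genotype file is matched to the weight
file's effect allele per variant. Swapped codings flip the dosage
($g \to 2-g$); palindromic A/T and C/G pairs are dropped because strand
cannot be verified from the files alone; allele-set mismatches are
dropped. All drops are counted in an alignment report. Missing dosages
reduce $M_j$ rather than being imputed; per-SNP mean imputation is an
explicit option because some scoring tools default to it.

Correlations between score vectors are summarized with the Fisher-z 95%
interval ($z = \operatorname{atanh} r$, SE $1/\sqrt{n-3}$) and a
two-sided p from $t = r\sqrt{n-2}/\sqrt{1-r^2}$. At $|r| = 1$ the
interval degenerates to a point and $p = 0$ — documented rather than
special-cased away.

## Omics relationship matrix

$A = WW'/m$ over transcripts with positive variance. Transcript means
and variances use the $n-1$ (sample) denominator, which matches the hand
evaluation of the defining formula on small examples and the convention
of omics-REML software. A consequence worth stating explicitly: the mean
of $\operatorname{diag}(A)$ is then exactly $(n-1)/n$, not 1; it equals
1 exactly only when the population ($n$) denominator is used throughout
(`build_orm(..., ddof=0)`). Zero-variance transcripts (non-detected
genes) are excluded with a logged warning, not an error, because
filtered real matrices routinely contain them.

## OREML

Model: $y = C\beta + Wu + e$, $u \sim N(0, I\sigma_u^2)$,
$e \sim N(0, I\sigma_e^2)$, hence
$\mathrm{var}(y) = A\sigma_o^2 + I\sigma_e^2$ with
$\sigma_o^2 = m\sigma_u^2$. The target quantity is
$R^2 = \sigma_o^2 / (\sigma_o^2 + \sigma_e^2)$. An intercept is always
appended to $C$: without a mean model REML results would depend on
arbitrary centering of $y$.

**Optimization.** With one relationship matrix the REML problem is
one-dimensional. $A$ is eigendecomposed once; for each variance ratio
$\lambda = \sigma_o^2/\sigma_e^2$ the residual variance profiles out in
closed form, and the profile restricted likelihood is maximized by
bounded Brent search on $\log\lambda \in [-18, 18]$ (xatol $10^{-10}$).
The boundary $\sigma_o^2 = 0$ is always evaluated explicitly and wins
ties, so boundary estimates are reported as exactly
$\sigma_o^2 = 0,\ R^2 = 0$ with a `boundary` flag — never as negative
variances. This avoids the step-halving fragility iterative AI-REML
shows near boundaries, and the profile optimum is verified against a
dense grid in the test suite.

**Uncertainty.** Standard errors come from the inverse expected (Fisher)
information, $\mathcal I_{ij} = \tfrac12\operatorname{tr}(PA_iPA_j)$
with $A_1 = A$, $A_2 = I$; $\mathrm{SE}(R^2)$ follows by the delta
method. Expected and observed information coincide only in expectation;
on single data sets of a few hundred samples they differ by
$O(1/\sqrt n)$ (10–20%), which is why the tests compare their average
over instances, and why these SEs are labelled Fisher SEs in outputs.

**Testing $\sigma_o^2 = 0$.** The null puts the parameter on the
boundary of its space, so the likelihood-ratio statistic is referred to
the 50:50 mixture $\tfrac12\chi^2_0 + \tfrac12\chi^2_1$ (default) with a
plain $\chi^2_1$ option. The mixture is conservative in finite samples;
the test suite checks that the null p-value distribution is
stochastically no smaller than uniform at the 5% and 10% quantiles.

Across tissues, variance-component p-values are adjusted by
Benjamini–Hochberg FDR within trait × sex (a flag pools sexes).

## MOA

Each transcript is tested as a fixed effect with the full transcriptome
kept as the random background:
$y = w_ib_i + C\beta + Wu + e$. The variance components are estimated
once under the covariates-only null and $\hat V$ is then fixed, giving

$$\hat b_i = \frac{w_i'\hat Py}{w_i'\hat Pw_i},\qquad
\mathrm{var}(\hat b_i) = \frac{1}{w_i'\hat Pw_i},\qquad
\chi^2_i = \hat b_i^2\, w_i'\hat Pw_i,$$

with two-sided p from $\chi^2_1$ and no genomic-control rescaling. This
fixed-V scan is the standard efficiency device for mixed-model
association; `fit(exact=True)` refits the variance components per
transcript (GLS under each refit) for small panels where the
approximation is worth checking. Two deliberate properties:

- The tested transcript stays **inside** the background ORM (no
  leave-one-out). For a transcript with a strong effect this absorbs
  part of its own signal into $\hat V$ (proximal contamination), making
  the scan slightly conservative; at $m$ in the thousands the effect of
  one column on $A$ is $O(1/m)$.
- With $\sigma_o^2$ pinned to 0 the scan reduces exactly to
  covariate-adjusted regression: $\hat b_i$ equals the OLS coefficient
  (Frisch–Waugh), and the Wald statistic uses the null-model REML
  residual variance with a $\chi^2_1$ reference — not the OLS $t$ test,
  whose residual variance comes from the model that includes the
  transcript. The test suite's OLS oracle is constructed accordingly.

Significance: per-tissue Bonferroni $0.05/m$ (strict inequality), and a
nominal $p < 10^{-3}$ screen feeding per-tissue hit counts and
per-transcript tissue counts. No cross-tissue correction is applied to
the MOA scan itself.

## Synthetic data

The generator stands in for the controlled-access inputs of the
motivating study and is first-class, tested code. What it emulates:

- **Genotypes**: Hardy–Weinberg dosages, per-SNP MAF uniform in
  (0.05, 0.5], linkage equilibrium. LD is deliberately absent — score
  arithmetic is LD-agnostic, and LD-aware weight estimation happens
  upstream of this package.
- **Weights**: a shared causal SNP subset (10% of SNPs by default) with
  bivariate-normal male/female weights at correlation 0.17 by default —
  the weak cross-sex sharing the motivating study measured between
  female scores built from female vs male weights. $\rho = 1$ gives
  identical sets exactly; non-causal weights are exactly zero.
- **Expression**: rank-inverse-normal marginals per transcript
  ($\Phi^{-1}((r-0.5)/n)$, average ranks for ties; Blom offset
  available), mirroring the normalization applied to the real panels.
- **Covariates**: age uniform on 20–70 years (the cohort's range), BMI
  $\sim N(27, 4^2)$ kg/m²; their effects (0.2 SD each by default) enter
  the outcome through the fixed-effect span.
- **Outcome**: $y = C\beta + Wu + e$ where $e$ is the *standardized
  genotype polygenic score* — the unexplained part of the proxy really
  is genetic — and the expression term is rescaled so the realized
  in-sample fraction $\mathrm{var}(Wu)/(\mathrm{var}(Wu)+\mathrm{var}(e))$
  equals `r2_target` exactly. Exact rescaling removes simulation
  variance from recovery tests: the truth is sharp, not merely an
  expectation.
- **Study structure**: per sex, one donor pool whose tissues subsample
  at least 30 donors (configurable floor); per-tissue `r2_target`
  overrides let one tissue carry signal while others are null.

In the real study the outcome is a donor-level score constant across
tissues; here the proxy outcome is tissue-specific, because a per-tissue
variance share cannot otherwise be controlled. The pipeline therefore
reads per-tissue score files when present (what the generator writes)
and computes scores from weights + genotypes when not.

What the generator does **not** emulate: LD and realistic allele-
frequency spectra, batch/PEER-like structure, cross-transcript
correlation, sex-chromosome dosage, and ancestry structure. Passing
tests therefore validate the estimators under the model's own
assumptions, not robustness to those real-data complications.

One distributional caveat surfaced during validation: with few causal
SNPs the genotype score is coarse (a sum of a handful of binomials), its
kurtosis inflates the tails of the null $\hat R^2$ distribution, and the
zero-censored estimator's null mean ($\approx \mathrm{SE}/\sqrt{2\pi}$,
about 0.06 at $n = 200$, $m = 500$) should not be mistaken for bias.
Fixtures therefore use several hundred SNPs, as in real scores.

## Problem sizes and determinism

Validation sizes were chosen so the whole suite runs on a laptop-class
single core: recovery uses 200 replicates at $n = 150$, $m = 500$
(mean $\hat R^2$ within ±0.05 of 0.30, ~95% coverage of ±2 SE
intervals); MOA calibration pools 10,000 null tests at $n = 200$
(type-I error in [0.04, 0.06] at $\alpha = 0.05$); the grid-search
oracle uses 20 instances at $n = 20$. All generators take explicit
seeds; bundle writing uses fixed float formats, so outputs are
byte-reproducible, and a rerun of the full pipeline on the same inputs
produces byte-identical tables.

## Known limitations

- Single variance component only; no GxE, sex-interaction or multi-ORM
  partitioning.
- Fisher SEs can be optimistic near the $\sigma_o^2 = 0$ boundary, where
  the sampling distribution of $\hat R^2$ is a censored mixture; the
  boundary flag should be consulted before interpreting SEs there.
- The MOA fixed-V approximation and the in-background testing are
  slightly conservative for very strong single-transcript effects.
- The delta-method $\mathrm{SE}(R^2)$ assumes an interior optimum.
- Ancestry filtering of samples is the caller's responsibility; the
  scoring module scores every sample it is given.
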