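# Methods

## Model and procedure

The estimator counts the spiked eigenvalues of the sample covariance of a
normalized genotype matrix. The data model is a hard-assignment
latent-subpopulation model: individual i in subpopulation k has
minor-allele count vector `c_{k,l} = μ_k + ε_{k,l}`, where μ_k is the
subpopulation mean vector and the noise vectors ε are i.i.d. with mean
zero and a common covariance Σ. Under the ultra-high-dimensional
asymptotics n → ∞, n/p → 0, and subpopulation means diverging pairwise,
the consecutive eigenvalue ratios `r_i = ℓ_{i+1}/ℓ_i` of
`S_p = M Mᵀ / p` split into K − 1 spike ratios strictly below 1 and a
bulk converging to 1.

The null fluctuation of a bulk ratio at index k is approximated by
mapping the top two eigenvalues (w1, w2) of an n × n GOE matrix through
the bulk location/dispersion coefficients

    â^(k) = mean(ℓ_k, …, ℓ_{n−1}),
    b̂^(k) = p/(n−k)² Σ_{i=k}^{n−1} (ℓ_i − â^(k))²,
    r_null = (w2·s + â^(k)) / (w1·s + â^(k)),   s = √(b̂^(k)/p),

with Monte-Carlo replication of (w1, w2). The decision rule scans
k = 1 … K̂_c and returns the smallest k from which *every* ratio meets or
exceeds its lower-α critical value. Ties count as passing. All K̂_c
indices are evaluated (no short-circuit) so the per-k table is complete
for diagnostics.

Two approximations are inherited as stated: the null for index k uses the
full n-dimensional GOE (not an (n−k+1)-dimensional one), and the raw
(uncentered) GOE top eigenvalues enter the ratio map with no explicit
2√n centering — the centering cancels to first order in the ratio, and
the b̂/â scaling absorbs the remainder. Both are sensitive only at k
values comparable to n, far beyond K̂_c = ⌊n/10⌋.

`p` in the coefficient and ratio formulas is the *kept* marker count
(`p_effective`): markers dropped as monomorphic, all-missing, or below an
optional MAF threshold never enter S_p, so they do not enter its null
either.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.001 | significance level of each one-sided ratio test; the critical value is the `⌊α·rep⌋`-th smallest simulated null ratio (floored at the 1st) |
| `rep` | 5000 | GOE Monte-Carlo replications; must satisfy rep ≥ 1/α, recommended 2/α–5/α |
| `K_c` | ⌊n/10⌋ | coarse upper bound on the spike count; clamped to n−2 with a warning for tiny n |
| `impute_mode` | `raw_zero` | missing cells imputed as raw count 0, then centered and scaled: `(0 − μ̂_j)·d_j`. `centered_zero` (≡ mean imputation) is the alternative |
| `maf_threshold` | off | optional in-memory filter on min(μ̂/2, 1 − μ̂/2); external pre-filtering is the expected workflow |
| `memory_budget` | 2 GiB | drives the column chunk width: `(budget − 8n²)/(8·n·4)` columns per chunk, the constant 4 covering read buffer, normalized copy, transpose workspace and slack |
| `workers` | 1 | joblib processes for the GOE simulation; results are bit-identical for any worker count because replication m draws from a child stream spawned deterministically from the master seed |

Column means are computed over observed entries (nan-aware), then the
default imputation fills missing cells with raw zero; this matches the
reference behaviour of imputing missing data by 0 while keeping the
per-marker moments unbiased by missingness.

## Numerical choices

- All accumulation is double precision regardless of input storage;
  ratios are sensitive to cancellation.
- The gram matrix is symmetrized after accumulation; chunked and
  single-pass covariance agree to ≤ 1e-10 relative (tested).
- Exactly n − 1 eigenvalues are retained (centering consumes one rank).
  A retained eigenvalue ≤ 1e-10 · ℓ_1 raises a rank-deficiency error
  advising removal of highly correlated markers or duplicated
  individuals; if no index satisfies the decision rule, an
  estimation-failure error gives the same multicollinearity remedy.
- GOE matrices are built as `(G + Gᵀ)/√2` from an i.i.d. standard normal
  square — exactly N(0, 2) diagonal and N(0, 1) off-diagonal — and fully
  eigendecomposed (dense `eigvalsh`); no iterative shortcut.
- The order-statistic index `⌊α·rep⌋` is floored (conservative: a smaller
  critical value can only defer rejection).

## The synthetic generator

The generator realizes the latent-subpopulation model directly: group
k's frequency at marker j is `clamp(base_j ± separation, 0.02, 0.98)`
with independent symmetric signs per group and marker, base frequencies
Uniform[0.05, 0.5], and genotypes Binomial(2, f_{k,j}). Equal-magnitude
shifts keep the per-group binomial noise variance balanced (f(1−f) is
insensitive to the sign of the shift), so the common-Σ assumption holds
to first order.

With *balanced* group sizes the K − 1 structure eigenvalues are nearly
degenerate and the spike ratios collapse towards 1; distinct spike
strengths come from *unbalanced* group sizes, since a spike's magnitude
scales with its group's size. The 12-subpopulation preset therefore uses
a 1:3 size ladder (25…75 individuals at n = 600), mirroring real panels,
which are always unbalanced. An optional Gaussian-copula block
correlation (`ld_rho`, blocks of 50 markers) induces LD-like dependence;
the default is independent markers.

What the generator does *not* emulate: haplotype/coalescent ancestry,
admixed individuals (hard assignment only), realistic allele-frequency
spectra, and genome-scale LD. Passing tests therefore demonstrate
correctness of the algorithm and its calibration under the model it
assumes, not performance on real sequencing panels.

## Study scales

The reference illustration regime is K = 12, n = 2500, p = 8,000,000.
The package's tests and the acceptance script run it scaled to
n = 600, p = 60,000 (preserving n ≪ p with p = 100 n), rep = 2000,
which completes in about a minute per run on one CPU while keeping the
spike/bulk separation unambiguous: the 11 spike ratios sit entirely
below the smallest bulk ratio, and the 11th smallest ratio lies far
below the bulk's interquartile band. Note that a handful of *bulk*
ratios at the soft lower edge of the spectrum also fall below a
1 − 5·IQR line — edge spacings are wide — so "exactly K − 1 spikes" is
asserted as the K − 1 smallest ratios being exactly r_1 … r_{K−1} and
strictly below every bulk ratio.

Size control is checked on K = 1 data (n = 200, p = 20,000, 20 seeds):
with α = 0.001 and ⌊n/10⌋ = 20 candidate indices, the sequential test
returns K̂ = 1 in at least 19 of 20 runs.

An external validation target exists at full scale: the 2504-individual
whole-genome panel (26 subpopulations, MAF > 0.001, ~28.8 M markers),
where the estimator with α = 0.001, rep = 5000 returns K̂ = 25 stably
across repeated runs. The data are a multi-ten-GB external download, so
this target is documented here and pinned as a configuration contract in
the test suite rather than executed.

## Limitations

- The estimator assumes n ≪ p; a warning is raised when n > p and the
  preset warns below p = 50 n.
- Heterogeneous per-group noise covariance (which real binomial genotype
  noise has, mildly) perturbs the bulk edge; at strong separations this
  can surface extra borderline indices. The sequential rule is robust to
  spike-side perturbations but not to bulk-edge ones.
- No LD pruning, kinship correction, or PC projection is provided;
  eigenvectors are never computed because the estimator needs only
  eigenvalues.
- The VCF converter handles diploid GT fields and biallelic sites only;
  multi-allelic records are skipped (and tallied in the manifest), not
  split.
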