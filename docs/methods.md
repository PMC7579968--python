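# Methods

## Model

Observed data are a G×C matrix of z-values z_gc = Φ⁻¹(p_gc) obtained from
per-cancer DM p-values. The generative model:

- a_g ~ Categorical(π₁..π_K): the pan-cancer pattern (cluster) of site g;
- H_gc | a_g = k ~ Bernoulli(q_kc), independent across cancers given a_g;
- z_gc | H_gc = 1 ~ 𝒩(μ_c1, σ²_c1) (alternative), z_gc | H_gc = 0 ~
  𝒩(μ_c0, σ²_c0) (empirical null).

The emission components are shared across clusters; clusters differ only
through their Q rows. Conditional independence across cancers given the
cluster label is the key assumption: all between-cancer correlation is
mediated by the pattern. The model deliberately distinguishes DM from non-DM
only — hyper- vs hypo-methylation direction would need a three-component
emission mixture and is out of scope.

Identifiability: the p→z map sends strong DM evidence to negative z, so the
alternative is constrained to the negative side, μ_c1 ≤ μ_c0 for every c.
After each M-step, any cancer whose weighted moments violate this is
resolved by swapping its two components and flipping that column of Q
(1 − q), which leaves the likelihood unchanged.

## EM inference

E-step. Membership posteriors are
Pr(a_g = k | Z) ∝ π_k ∏_{c observed} [q_kc 𝒩_c1(z_gc) + (1−q_kc) 𝒩_c0(z_gc)],
and the joint quantities E[I(a_g = k) H_gc | Z] multiply the membership by the
per-entry conditional DM probability. All products are accumulated in
log-space with per-site max subtraction (log-sum-exp), so z-values hundreds
of standard deviations out remain finite.

M-step. π averages the memberships; q_kc ratios joint mass over membership
mass among entries observed in cancer c. Because the emission parameters are
shared across clusters, the normal-component updates weight each observed
z_gc by its *total* alternative mass w1_gc = Σ_k E[I(a_g=k) H_gc | Z] (and
1 − w1 for the null); this is the unique maximizer of the EM objective with
shared components.

Missing data: likelihood products and every M-step sum run over observed
entries only (marginal-likelihood treatment). The reported DM probability of
a missing entry is the cluster-weighted prior Σ_k Pr(a_g=k|Z) q_kc.

Convergence is declared when the infinity norm of the concatenated parameter
vector (π, Q, μ₀, σ₀, μ₁, σ₁) changes by less than `tol` between iterations
(default 1e−4); `max_iter` defaults to 1000. The observed log-likelihood is
recorded every iteration and is non-decreasing up to 1e−8 slack (a standing
test invariant).

Numerical guards: Q is clamped to [1e−6, 1 − 1e−6] so ln q and ln(1−q) stay
finite; standard deviations are floored at 1e−3; a cluster whose total
membership falls below 1e−8·G keeps its previous Q row (with a warning)
rather than propagating 0/0. Ties in any argmax resolve to the lowest index.

Initialization. Each cancer's z-column is first fitted with an independent
two-component normal mixture (the Type II baseline machinery); the lower-mean
component initializes (μ_c1, σ_c1). Hard per-column DM indicators
(posterior > 0.5) are clustered by K-means (10 restarts, seeded) to produce
initial labels, hence π and Q as empirical frequencies. This start is
deterministic given the seed; additional restarts (off by default — the
data-driven start is reliable on well-separated data) perturb Q with
Uniform(−0.1, 0.1) noise. Restarts compete by final observed log-likelihood.

## Pattern-number selection

BIC(K) = −2 ln L̂_obs + (K − 1 + KC + 4C) ln G, minimized over a user grid
(default 2..10). Each K is fitted independently with the same restart
policy — no warm starts across the grid, so the BIC comparison carries no
path dependence. Ties break toward smaller K.

## DM calling

local fdr: fdr_gc = 1 − Pr(H_gc = 1 | Z, Θ̂). Global FDR at cutoff τ is the
mean local fdr among entries with fdr ≤ τ, pooled over sites and cancers;
the calling cutoff is the largest observed fdr value whose pooled mean stays
within the target level t (default 0.01). The pooled rule is a step function
of τ, so only observed fdr values are candidates, and tied values enter or
leave the called set as a block. A per-cancer scope (`scope="per-cancer"`)
repeats the rule column-wise for users who want column-level control; pooled
is the default. Missing entries never enter the sums and are never called.

Pattern display order uses complete-linkage, Euclidean-distance hierarchical
clustering of Q's rows and columns (leaf orders only; no plotting mandates).
A sampling diagnostic draws from the fitted marginal mixture per cancer for
Q-Q comparison against the observed column.

## Synthetic data and what it does (not) show

`default_scenario()` defines the study design used by all tests: C = 9
cancers, K = 5 patterns, unequal proportions π = (0.35, 0.20, 0.175, 0.15,
0.125), and a block-structured Q contrasting 0.9 against 0.05 — an
all-non-DM background (largest cluster, as in real methylomes), an all-DM
pattern, and three patterns each DM in a distinct block of three cancers.
Null components sit near 𝒩(0,1) with ±0.1 mean offsets and σ ∈ [0.9, 1.1];
alternative means are −1.8 to −2.2 with similar spreads. These values are
this package's own documented stand-in design, chosen so that the patterns
are well separated in pattern space yet the per-entry evidence is noisy
enough for joint modeling to matter: with stronger emission separation every
method ranks the top sites perfectly and the power comparison degenerates;
with much weaker separation pattern recovery drifts beyond its tolerance. G = 100,000 at full scale; tests and the acceptance
script use the G = 20,000 variant, where every headline property (BIC
minimum at the true K, pattern recovery within 0.05, power dominance over
separate analyses, FDR calibration) is comfortably measurable in minutes on
one CPU.

The generator draws exactly from the model, so passing tests demonstrate
correct inference under the model's own assumptions. They do not probe
model misspecification in real methylation data: between-cancer dependence
beyond the shared cluster, non-normal z-value tails, spatial correlation
along the genome, or direction-of-effect structure. The mis-specified-K
experiments (merging at K̂ < K, splitting at K̂ > K) are the only deliberate
misspecification exercised.

## Baselines

Type I: rank sites by p-value per cancer; binary calls by per-cancer
Benjamini–Hochberg at the target level (the standard p-value-based global
FDR control; the specific procedure is this package's choice). Type II: an
independent per-cancer two-component normal mixture (scikit-learn
GaussianMixture), ranking by posterior non-null probability, calling by the
pooled-FDR rule applied column-wise. K-means clustering of binary Type I
call patterns (10 restarts, seeded) provides the pattern-recovery
comparator; scikit-learn's K-means handles empty-cluster relocation
internally. Evaluation: row-normalized pattern-matching (confusion)
matrices, true positives among top-n ranked sites (stable sort, ties by
site index), and per-cancer sets of sites called only by the joint model.

## Design choices that were genuinely open

- The emission M-step updates are written with the cluster index summed out,
  the unique reading consistent with the EM objective when components are
  shared across clusters.
- Convergence norm: infinity norm on the concatenated parameter vector.
- Boundary p-values are clipped at 1e−15 before the quantile transform
  (p = 0/1 would give infinite z). Near p = 1 the double-precision
  representation of 1 − clip limits quantile accuracy to ~1e−2; this end of
  the scale carries no DM evidence, so it is immaterial.
- Posterior storage is the full G×K×C joint array (~70 MB at G = 100,000,
  K = 10, C = 9), the simplest layout satisfying all invariants.
- File formats: TSV/CSV tables with "NA" for missing, 6 significant digits
  in result tables, full double precision in the JSON model descriptor.

## Known limitations

- K is assumed small relative to 2^C; with K approaching G the BIC penalty
  is the only guard against overfitting.
- The empirical-null normality assumption is inherited from the summary
  statistics; grossly non-normal p-value distributions should be inspected
  with the sampling (Q-Q) diagnostic before trusting calls.
- Labels are exchangeable: cluster numbering is arbitrary across runs and
  must be matched (e.g. by best permutation) before comparing fits.
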