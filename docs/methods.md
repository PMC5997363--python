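# Methods

This note defines every score the package computes, the defaults and the
reasoning behind them, the synthetic-data generators, and the numerical
choices that are not forced by the definitions.

## Model and notation

The data is an M × N matrix D with entries ±1 (binarization: expression
matrices are median-centered per column and mapped to their sign; genotype
dosages are thresholded on minor-allele presence). A **loop** through rows
(j, j′) and columns (k, k′) contributes the product
D_jk · D_j′k · D_j′k′ · D_jk′ ∈ {−1, +1}: +1 iff the 2×2 submatrix is rank-1.

Throughout, Σ̃ denotes a **normalized sum**: a sum over loop terms divided by
its number of summands, so each Σ̃ of a ±1 matrix lies in [−1, 1]. Unless
stated otherwise, sums exclude the degenerate loops (j′ = j or k′ = k).

### Uncorrected scores

Raw row score: z_j = [(DDᵀ)²]_jj; raw column score: z_k = [(DᵀD)²]_kk (exact
integers, including degenerate loops). Normalized scores remove the degenerate
loops and divide by the count:

- rows: (z_j − N(N + M − 1)) / ((M − 1)N(N − 1)),
- columns: (z_k − M(M + N − 1)) / ((N − 1)M(M − 1)).

A rank-1 sign matrix scores exactly 1 everywhere. The **d-scores** generalize
the path length — diag((DDᵀ)^(d+1)) — and converge, after normalization, to the
entrywise squares of the leading singular vectors; that limit is the one-shot
**spectral comparator** (`spectral_scores`), with a deterministic tie-break
(diagonal of the projector onto the tied leading subspace) when the top
singular values coincide.

### Control correction

With cases D (M_D × N) and controls X (M_X × N), the corrected score is the
within-case Σ̃ minus the case/control Σ̃, e.g. for rows:

z_j = ([DDᵀDDᵀ]_jj − N(N + M_D − 1)) / ((M_D − 1)N(N − 1))
    − ([DXᵀXDᵀ]_jj − M_X N) / (M_X N(N − 1)),

and analogously for columns. Each term lies in [−1, 1], so every corrected
score (and hence every elimination trace) lies in [−2, 2]; the bound is
attained by D = ones(2×2) against X = [[1, −1], [−1, 1]]. A bicluster that
straddles cases and controls scores ≈ 0; a fully case-specific one keeps its
uncorrected score.

### Categorical covariates

With two categories of sizes M_a, M_b (M = M_a + M_b), a row in category a is
scored min(Z_within / p, Z_cross / q) with p = (M_a − 1)/(M − 1),
q = M_b/(M − 1); columns take the minimum of the four within/cross sums
ZCOL_ab / α_ab with α_ab = M_a(M_b − δ_ab)/(M² − M). Structure concentrated in
one category is thereby demoted. More than two categories generalize by
keeping the best I_req categories per row/column and minimizing over them
(their pairs, for columns); this reduces exactly to the two-category formulas
at I_cat = 2 and is flagged as a documented generalization. Default I_req = 2.

### Continuous covariates

Covariate rows T_j (dimension N_T) are unit-normalized (all-zero rows stay
zero). For rows, with ⌊x⌋ = max(0, x):

z²_j = ⌊Z_base⌋²_j − (1/κ²) · mean_t ⌊Z[t]⌋²_j,

where Z[t] weights each loop term by T_jt T_j′t. The reported row score is
sign(z²)·√|z²| so it stays on the per-loop scale (the squared form is exposed
in `extras["z_row_sq"]`). Columns subtract the covariate term linearly with no
floor or square, as defined. A covariate-concentrated bicluster (members
sharing one covariate direction) is demoted to ≈ 0; a covariate-balanced one
keeps its full score.

**κ² (attenuation constant).** κ² is the expected attenuation
mean_t u_t⁴ of the covariate-averaged score of a fully concentrated rank-1
bicluster whose members share a random unit covariate vector u. The default
ensemble draws the squared components (u_1², …, u_{N_T}²) uniformly from the
probability simplex — every split of covariate energy across dimensions
equally likely, treating axis-aligned and diagonal concentrations
symmetrically — giving κ² = 2/(N_T(N_T + 1)): exactly 1 at N_T = 1 (a single
unit weight attenuates nothing) and 1/3 ≈ 0.34 at N_T = 2. An alternative
`ensemble="sphere"` draws u uniformly on the unit sphere, giving
κ² = 3/(N_T(N_T + 2)) (0.375 at N_T = 2). The simplex ensemble is the default
because it reproduces the expected N_T = 1 and N_T = 2 values simultaneously;
the choice only rescales the subtracted covariate term. κ² is estimated once
by Monte-Carlo (default n_mc = 10⁵, seeded) or can be passed explicitly.

### Sparsity

With p_k the fraction of +1 entries in column k (clamped to
[1/(2M), 1 − 1/(2M)] by default so constant columns stay finite), columns are
centered by α_k = 2p_k − 1 and loops weighted by Δ_k = 1/(4 p_k q_k), the
inverse column variance. At p_k = 1/2 everywhere this reduces exactly to the
normalized uncorrected score; abundant signs contribute little, rare ones more.

### Combination

`combined_scores` applies all enabled corrections in one normalized pass, in
the fixed order sparsity → continuous → categorical → controls: sparsity
centering/weights enter every loop term; each case-side per-category term is
covariate-corrected; the categorical minimum is taken over the best I_req
categories; the pooled control term (not covariate-corrected — demoting the
control term would inflate the final score) is subtracted last. With
everything disabled the result equals the normalized uncorrected score
exactly.

## Elimination, delineation, significance

- **Elimination** (γ default 0.05): each iteration scores the remaining
  submatrix, records mean row/column scores (**traces**), and removes the
  max(1, ⌈γ·remaining⌉) lowest-scoring rows and columns (never all); ties
  break stably by index; stops below 2 rows or columns; survivors are appended
  in ascending final score. Scores are recomputed from scratch each iteration.
- **Delineation**: the members are the rows/columns remaining at the argmax of
  the median-of-3-smoothed row trace, restricted to iterations whose column
  trace exceeds its median; flat traces yield an empty result with a warning.
  Membership is validated by the **alignment AUC**: |Pearson correlation| of
  each row with the member block's leading right singular vector, members
  versus controls (or versus non-member cases when no controls exist).
- **Permutation p-value** (default 256 shuffles): labels are shuffled freely
  (H0) or within categories (H0x; single-label categories stay fixed with a
  warning); each rerun maps to the point (max row-trace, mean row-trace); both
  coordinates are converted to percentiles among the shuffles, the original's
  larger percentile sets one threshold applied to both axes, b counts shuffles
  exceeding either axis's threshold, and p = (b + 1)/(n + 1) (add-one, never
  zero). Calibration is verified empirically (KS distance from uniform < 0.1
  over 200 null pipelines).

## Planted-bicluster benchmark

`make_planted(M, m, l, epsilon, seed)` embeds an m × m block at random
positions in an M × M Rademacher matrix; the block is a Gaussian matrix whose
singular values are reset to l ones followed by ε's (every trailing value set
to ε makes ε the single noise knob), then binarized by sign. Recovery is
scored by A = (A_R + A_C)/2, where A_R is the exact rank-based probability
that a random non-member row is eliminated before a random member row.
g_{l,ε,m}, the rank-1 loop fraction of the block, is estimated by Monte-Carlo.
The detection heuristic m³(2g − 1)^p ≥ c·M^s uses defaults (p, s, c) =
(1, 1.5, 2), chosen to reproduce the log_M(m) = 0.5 success edge at ε = 0;
the exponents are configurable because only that edge is pinned down.

## Tricluster extension

For a ±1 cube (M × N × P) there are three loop categories — iso-layer,
iso-column, iso-row (the fixed axis names which index is held). Each axis
score adds the two Σ̃-normalized category sums that pair indices on that axis
(so a coherent rank-1 sub-cube approaches 2); empty constituents (a dimension
of size 1) contribute 0. Because entries are ±1 each category sum collapses to
a squared Gram tensor minus a constant. Elimination proceeds as in 2-D over
all three axes simultaneously. No corrections are applied in 3-D.

## Numerical and testing choices

- All sums are evaluated with Gram products in O(M²N); an independent
  brute-force module (`loopbic.bruteforce`) builds explicit 4- and 5-index
  loop tensors and is used to certify every score exactly on small instances.
- All randomness flows through `derive_rng(seed, *keys)`
  (`numpy.random.SeedSequence`); derived integer seeds stay below 2³¹.
- **Null-score bias**: the minimum-based categorical scores have a small
  negative null bias (a min of zero-mean terms; ≈ −0.002 row / −0.003 column
  at 50×80) and the floored continuous row score a small positive one; the
  calibration suite requires those to stay within 1% of the unit per-loop
  scale and all linear scores to have mean 0 within 3 standard errors.
- Problem sizes in the test suite: oracle checks at ≤ 8×10 and 5×5×5;
  null calibration 200 trials at 50×80; planted recovery M = 400 (32 seeds);
  loop-vs-spectral M = 256, l = 2, 64 trials; p-value calibration 200
  pipelines of 64 shuffles at 30×40; triclusters 12³ in 40³ (16 seeds).

## Limitations

- The categorical generalization beyond two categories and the combined-score
  composition are documented design choices validated by simulation, not
  closed-form derivations.
- Delineation uses the smoothed-trace argmax; it selects the dominant
  bicluster only (secondary biclusters via scramble-and-rerun).
- No overlapping-bicluster deconvolution, no automatic selection of the
  number of biclusters, no corrected scoring in 3-D, and no binary genotype
  container formats (plain delimited text only).
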