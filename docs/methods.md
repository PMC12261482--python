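# Methods

## Model

Given a genotype matrix X (n subjects x p SNPs, additive minor-allele
dosages, columns z-scored) and F phenotype views Y_f (n x q_f, z-scored)
with a diagnosis vector z, the model estimates per-view genetic weights u_f,
phenotype weights v_f, and a shared vector of nonnegative sample weights Q
(sum Q_i = n) by minimizing

    sum_f [ -u_f' X' diag(Q) Y_f v_f  +  psi(v_f; Y_f, z) ]
      + eta * sum_k sum_{i<j in pi_k} cov_Q(X_i, X_j)^2
      + lambda_u1 ||U||_FGL2,1 + lambda_u2 ||U||_2,1 + lambda_u3 ||U||_1,1
      + lambda_v sum_f ||v_f||_1 + lambda_Q ||Q||_2^2
    subject to ||X u_f||_2 = 1, ||Y_f v_f||_2 = 1,

where cov_Q(X_i, X_j) = (1/n) sum_l Q_l x_li x_lj -
[(1/n) sum_l Q_l x_li][(1/n) sum_l Q_l x_lj] is the weighted covariance and
pi_k are disjoint LD blocks.  The decorrelation term drives the weighted
within-block SNP covariances toward zero, emulating a reweighted population
in which LD-driven indirect associations vanish, so the association term
credits SNPs for their direct contribution.  psi is a linear
(least-squares) or logistic loss tying each phenotype projection to the
diagnosis, attached with weight 1 (equal footing with the association term);
the logistic form requires binary labels, ordinal codings use the linear
form.  Empirical expectations carry the 1/n factor so eta is comparable
across sample sizes.

Assumptions: a single canonical component per view (no deflation); LD is
local, so blocks are index intervals along the genome; phenotype views share
the subject axis; diagnosis is driven by the same latent process that links
genotype and phenotype.

## Optimization

Alternating minimization, one outer iteration = U step, Q step, V step.

* **U** — the three structured norms are majorized by half-quadratic (IRLS)
  diagonal surrogates: sqrt(s + eps) <= sqrt(s0 + eps) + (s - s0)/(2
  sqrt(s0 + eps)), giving diagonal weights D1 (fused pairs, boundary terms
  dropped), D2 (row norms), D3 (per entry), with eps = 1e-8 guarding exact
  zeros.  Each (LD block, view) pair then has the closed-form solution
  (lambda_u1 D1 + lambda_u2 D2 + lambda_u3 D3 + gamma' X_k' diag(Q) X_k)^{-1}
  X_k' diag(Q) Y_f v_f; block systems are independent, cutting the solve
  from O(n p^2) to O(n sum_k p_k^2).  Systems with a common block size are
  solved as one stacked batch.  After concatenation each u_f is rescaled to
  ||X u_f|| = 1.
* **Q** — one projected-gradient step on the Q-dependent terms with
  backtracking (halving, at most 30 times), then Euclidean projection onto
  {Q >= 0, sum Q = n} by the sorted-threshold algorithm.  Nonnegativity is
  imposed because negative sample weights would break the covariance-
  balancing interpretation; a config flag (`allow_negative_q`) relaxes it to
  the sum constraint only.  `fix_q` holds Q at its uniform initialization,
  which is the "reweighting off" ablation.
* **V** — per view, a proximal-gradient step (soft-thresholding realizes the
  l1 term) followed by rescaling to ||Y_f v_f|| = 1, with backtracking.

A fixed-step alternation with post-step rescaling cannot guarantee a
monotone objective, so every sub-update is safeguarded: the candidate is
accepted only if the exact objective does not increase (slack 1e-12); the U
candidate is damped toward the current iterate (geometric interpolation,
then rescale) until it is accepted or abandoned.  The recorded trace is
therefore non-increasing by construction, and iteration stops when the
relative objective change falls below `tol` (1e-5), when no parameter moves,
or at `max_iter` (100).

Initialization: Q uniform; (u_f, v_f) at the leading singular pair of the
cross-covariance X'Y_f via seeded power iteration (default).  An all-ones
("constant") mode exists but is not the default: when planted or real
effects carry both signs, constant directions are nearly orthogonal to the
signal and the alternation can stall in a noise optimum.  All modes are
deterministic given the seed.

Numerical notes: the unit-scale constraints fix only the magnitude, so the
sign of a (u_f, v_f) pair is aligned by the optimization toward positive
association; a view whose phenotype projection collapses to zero under heavy
penalties is reinitialized and reported as pruned; a singular block system
(possible only with all penalties zero and a rank-deficient block) raises an
error suggesting a larger eps or gamma'.

## LD partitioning

Blocks come from the empirical SNP correlation matrix at cutoff |r| > 0.2
(absolute value: allele-coding flips negate correlations without changing
LD).  Default rule: scan adjacent SNPs in order and cut where |r| <= 0.2
(interval blocks, matching the divide-and-conquer solve); a
connected-components rule is available for unordered panels.  Blocks larger
than `max_block_size` (500) are split at their weakest adjacent link to
bound the cubic per-block cost.  Constant SNPs get correlation 0 and are
flagged.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| eta | 0.1 | decorrelation weight; grid searches on held-out CCC flagged 0.1 as a good operating point, larger values decorrelate harder at the cost of association fit |
| lambda_u1..u3 | 0.01 | fused-group / l2,1 / l1,1 penalties on U (unitless; tied to one lambda_u during CV) |
| lambda_v | 0.01 | l1 penalty on each v_f |
| lambda_Q | 0.01 | ridge on Q; sets the inverse of the allowed weight spread. The default follows a scale argument: with the 1/n expectation convention the decorrelation gain per unit weight spread is O(eta * #pairs / n), so lambda_Q must be well below 1 for reweighting to act at n ~ 100-500. The cross-validation protocol fixes lambda_Q = 1 instead, which effectively freezes Q near uniform during benchmark model selection |
| gamma_ridge | 1.0 | weight of the Gram term in the U solve (realizes the scale constraint as a ridge) |
| epsilon | 1e-8 | IRLS smoothing; larger values round the penalties, smaller risk ill-conditioning |
| tol / max_iter | 1e-5 / 100 | convergence controls |

## Model selection

Nested five-fold cross-validation over the grid 10^i, i = -4..4.  The three
U penalties are tied (lambda_u1 = lambda_u2 = lambda_u3 = lambda_u), eta is
fixed at 0.1 and lambda_Q at 1, and (lambda_u, lambda_v) is selected by the
highest mean inner-test CCC averaged over views.  The full 9 x 9 grid is
combinatorial overkill at desk scale, so the default search sweeps lambda_u
first (lambda_v at its default) and then lambda_v at the best lambda_u; the
full grid remains available (`search="grid"`).  Candidate scoring runs the
fit under a reduced iteration budget (30); the winner is refit at the full
budget.  Standardization always uses training-fold statistics and the LD
partition is re-estimated from each training set, so no test information
leaks into fitting.  Reports carry both aggregation orders (views-then-folds
and folds-then-views).

## Synthetic benchmarks

A latent score mu_l ~ N(0,1) per subject drives both sides:
x_li ~ N(mu_l u_i, sigma_x Sigma_x) with Sigma_x equicorrelated (0.7) inside
each 10-SNP LD group and independent across groups, and
(y_f)_lk ~ N(mu_l v_fk, sigma_y I).  sigma scales the noise *covariance*
(noise sd = sqrt(sigma)), following the generating distributions above.
Ground truth u has group-aligned contiguous signed runs (magnitudes
U(0.8, 1.2)); each v_f has one contiguous signed run.  The diagnosis label
is a median (or tertile) threshold of mu.  Columns are z-scored;
an optional quantile discretization yields 0/1/2 codings.

Presets: data1/2/3 share one seed-fixed truth (n = 500, p = 100,
q = (120, 100, 80), u sparsity 0.2, v sparsity 0.2) and differ only in noise
(sigma = 0.1 / 0.6 / 1.2, so SNR falls from data1 to data3); data4 is the
large-p-small-n regime (n = 80, p = 1000, sigma = 0.3, u support = 20 SNPs
in 2 LD groups).  data4's per-view phenotype supports are (2, 6, 24) of
(120, 100, 80) features: an imaging-like wide view with very few affected
features, a proteomic-like middle view, and a cognitive-like narrow view
whose items are mostly informative.  This modality heterogeneity is what
produces the characteristic per-view difficulty ordering in the
small-sample regime — with so few informative columns, view 1's latent
estimate carries an irreducible noise floor that no method can average
away, while view 3's dense signal remains easy.  Under this design the
five-seed benchmark yields held-out CCCs near (0.98, 0.98, 0.98) on data1
and roughly (0.87, 0.92, 0.94) on data4.

The spurious-proxy scenario plants one phenotype-driving SNP and one LD
proxy at r = 0.9 whose only phenotype path runs through the causal SNP,
among 10 null SNPs (n = 30, q = 20, noise sd 2.5).  The sample size and
noise are deliberately harsh so that the causal-vs-proxy ranking is
unstable for an association-only model — the regime sample reweighting
targets.  In our experiments the reweighting at eta = 0.1 shrinks the
pair's weighted covariance but does not reliably improve the paired ranking
over the no-reweighting ablation; see the limitations below.

What the generator does *not* emulate: discrete allele-count marginals
(unless discretization is switched on), allele-frequency spectra,
haplotype-scale LD decay, population stratification, missingness, and
view-specific correlated phenotype noise.  Passing benchmarks therefore
demonstrate correct mechanics and the claimed qualitative behaviors on
rank-one latent data, not performance on real cohorts.

## Problem sizes and runtime

The shipped benchmark protocol uses the preset sizes above with five seeds
per preset and the coordinate search; one preset completes in a few minutes
on a single CPU.  The blockwise solve keeps the per-iteration cost linear in
the number of blocks at fixed block size, which the test suite checks as a
timing trend (p = 200 vs p = 800 at block size 10).

## Known limitations

* One canonical component per view; no deflation for secondary signals.
* The decorrelation strength at eta = 0.1 with the 1/n scaling produces
  mild reweighting at desk-scale n; driving weighted covariances to zero
  needs eta one to two orders larger (at the cost of association fit).  In
  the spurious-proxy experiment this shows up directly: the learnable Q adds
  estimation variance that offsets its modest decorrelation benefit, so the
  paired ranking comparison against the Q-fixed ablation is a statistical
  tie at eta = 0.1.
* The fused penalty spans adjacent rows across block boundaries by default
  (`fgl_respect_blocks` cuts it at block starts); neither option uses
  genomic distance.
* CCC is a correlation, so single-view sign flips are meaningful; reports
  preserve signs but downstream consumers should compare magnitudes across
  methods only after sign alignment.
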